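# Methods

## Viability model

A reaction universe holds an ordered list of N internal reactions (the
genotype-indexed set), a list of transport/exchange reactions and one
biomass reaction, both assumed present in every metabolism, and a metabolite
table. A genotype is a length-N bit vector; bit i always refers to the i-th
internal reaction in model-file order, and that order is serialized with the
model so hex-encoded genotypes are comparable across runs (canonical form:
lowercase zero-padded hex of the bit integer, bit 0 = first reaction = least
significant bit).

Viability is decided by flux balance analysis. The LP is

    max Z = c^T v   subject to   S v = 0,   a <= v <= b

with one column per reaction (internal, transport, biomass) and one mass
balance row per *internal* metabolite; metabolites flagged external are
boundary species and are not balanced. Reactions absent from the genotype
have both bounds clamped to zero. Irreversible reactions have a = 0;
reversible reactions may carry flux of either sign. The solver is HiGHS via
`scipy.optimize.linprog`; a numeric failure is retried once with presolve
off and tightened feasibility tolerances (1e-10) and then surfaced as an
explicit `SolverError` — never silently treated as unviable. An infeasible
LP reports rate 0 (it cannot occur with v = 0 feasible); an unbounded LP
raises `ModelError`, since it means the model produces biomass from nothing.

Default flux bounds (arbitrary flux units; all configurable per engine or
per environment):

| quantity | default | rationale |
|---|---|---|
| generic flux bound B | 1000 | effectively unbounded at model scale |
| sole carbon source uptake | 10 | the only scale-setting bound; viability is threshold-relative so its absolute value cancels |
| fixed-nutrient uptake (ammonium etc.) | 1000 | non-limiting minimal-medium components |
| secretion | 1000 | waste export is never limiting |
| import of metabolites absent from the medium | 0 | closed; e.g. other carbon sources when testing a sole source |

An environment names one carbon source, optional explicit per-transport
uptake bounds, and the fixed nutrients importable in every environment.

A genotype is **viable** when its optimal biomass flux exceeds
`max(threshold_fraction * reference_rate, 1e-6)`, with
`threshold_fraction = 0.01` and `reference_rate` the full universe's optimum
in the same environment. The 1e-6 absolute floor keeps LP round-off from
being read as growth. Using the full-universe rate generalizes the
fixed-reference convention to arbitrary universes; the reference is
recomputed once per environment and can be overridden per call. With several
environments, "viable" means viable on every one separately; a reaction is
**essential** when its single deletion abolishes viability on at least one
of them. The **superessentiality index** of a reaction over a genotype
sample is the fraction of sampled genotypes containing it in which it is
essential (genotypes lacking it are skipped; the index is reported undefined
when nothing in the sample contains it).

Viability verdicts are memoized on (genotype bit pattern, environment name);
this cache is the main cost lever for enumeration and walks, and LP solves
and cache hits are counted separately so run reports can state both.

## Enumeration

Two structural facts make exhaustive per-size enumeration tractable:
viability is monotone under reaction addition (a column can only enlarge the
feasible set), so (a) a reaction whose deletion from the *full* universe is
fatal in every environment — an environment-general superessential reaction
— must be present in every viable genotype and can be pinned, shrinking the
space from 2^N to 2^(N−k); and (b) removal of a reaction from an unviable
metabolism can never restore viability, so every viable genotype of size
n−1 is a child of a viable genotype of size n. The enumerator therefore
sweeps sizes strictly downward from the full genotype, testing only
deduplicated children of the current viable frontier and never clearing a
pinned bit. Pinning is a pure optimization: results with and without it are
identical (property-tested). With several environments the pinned set is
*sound but not complete* — a reaction fatal on only one source is also
forced into every genotype required to be viable on all sources, but does
not meet the environment-general definition; the sweep does not rely on
completeness.

The exhaustive sweep refuses universes with N > 24 (worst case ≈ 16.7M
candidates) unless forced, and writes an optional JSON checkpoint (current
size and frontier) at every size boundary so interrupted runs resume.
Output order is deterministic (sorted canonical hex). Binomial counts
Ω(n) = C(N, n) are exact big integers (`math.comb`).

## Genotype networks

Two genotypes of equal n are adjacent when they share all but one reaction
(swap distance 1, i.e. half the Hamming distance). Edges are discovered by
generating each node's n × (N − n) swap neighbors and hashing them into the
node set — O(|V| · n · (N − n)) instead of all-pairs — and components come
from graph traversal (networkx). Components are labeled deterministically
(size descending, then smallest member hex).

For climbing the size ladder without rebuilding networks, the propagation
rule: the N − n parents of a genotype form a clique; parent images of
connected sets are connected; hence components at n + 1 are obtained by
merging each size-n component's parent image into one block, merging blocks
that share a genotype or are joined by a swap edge, attaching the new
minimal (childless) genotypes to any adjacent block, and leaving unattached
minimal genotypes as new components. Every non-minimal viable genotype at
n + 1 has a viable child, so parents ∪ minimals is exactly V(n + 1) when
the inputs are complete; supplied "minimal" genotypes are validated (viable,
no viable child) before use. Cross-block merges are detected by neighbor
hashing over the whole node set, not only via shared parents, because
distinct components' parent images can touch through an edge without sharing
a node. The result is property-tested for exact equality with direct
component computation at every fixture size.

## Walks

**Deletion walks.** Starting from a viable genotype (default: the full
universe), pick a present reaction uniformly at random and delete it iff the
child stays viable, resetting a failure counter on success. After 1000
consecutive failures (the default; fixtures use smaller limits since their
sizes are far below 1000) the endpoint is certified by exhaustive
single-deletion testing: if some deletion is viable the walk continues
there, otherwise the endpoint is a certified minimal metabolism. The
deletion order is recorded so any prefix — the unique on-path genotype of a
given size — can be replayed and re-verified.

**Guided connector.** To connect same-size viable genotypes G1 → G2, list
L1 holds the walker's private reactions (in G1, not G2), nonessential first,
each group shuffled; L2 holds the target's missing reactions, essential (in
G2) first. Each step adds the next L2 reaction, then deletes the first
L1 reaction whose removal preserves viability on all environments. If no L1
reaction is deletable, the addition is reverted and random universe
reactions are tried instead, screened for stoichiometric connectedness:
every substrate and product must be shared with the walker's active
reactions, the biomass reaction, or a transport (which can also secrete an
otherwise unshared product). Random additions not in the target are appended
to L1 so they are deleted again before the walk can terminate. "Attempted
swaps" counts attempted additions, accepted or reverted — the stricter
reading — and the default budget is 5000. Essentiality for list construction
is computed once at walk start; per-step recomputation is exposed as an
option because earlier swaps can make previously dispensable reactions
essential. All randomness flows from one recorded seed, and success
certificates (the step list) replay through the viability engine
independently.

A failed search is reported **unresolved**, never "disconnected". The
heuristic is genuinely incomplete near minimal sizes: it never deletes
reactions shared by walker and target, yet some paths require temporarily
displacing a shared reaction. On the double-motif fixture at one reaction
above the tightest connected size this occasionally stalls a pair that the
oracle certifies as connected; with more slack it reliably succeeds. Tests
and drivers therefore sample at sizes with at least one reaction of slack
and treat residual stalls as unresolved, not as evidence.

**Neighbor census.** A genotype has n × (N − n) possible swap neighbors,
each tested by FBA; minimal genotypes additionally have zero viable deletion
neighbors and N − n viable addition neighbors by construction. The rank
correlation between size and viable-neighbor count is Spearman's ρ
(scipy.stats).

**Probability bound.** If more than a fraction p of V(n) lay outside the
largest component, M independent viable draws would all avoid it with
probability below (1 − p)^M; the bound is computed in closed form.

## Synthetic universes

The generator emulates the minimal-medium, precursor-biomass structure the
analysis assumes: a carbon source imported and converted through an
essential backbone (its first step sheds a waste metabolite, exported by a
transport) to a hub; precursor reactions consuming hub plus ammonium, one
per biomass precursor; optional pairs of disjoint alternative routes of
configurable lengths from the hub to an extra required precursor; optional
duplicate reactions (each duplicable conversion is covered once, in random
order, before any repeats, so a redundancy count equal to the number of
conversions doubles them all); and optionally a second carbon source
entering the backbone through its own internal reaction plus a second
minimal environment (this adds one reaction beyond the base size formula).
All coefficients are ±1: the connectivity phenomena under study depend on
route topology, not stoichiometric detail, and unit coefficients keep the
LPs well conditioned. Generation is deterministic in the spec seed and the
emitted model JSON is byte-stable.

What generated universes deliberately do **not** model: cofactor cycling and
ATP/redox balancing, realistic biomass stoichiometries, reversible internal
chemistry, thermodynamic feasibility, or gene–protein–reaction structure.
Passing tests on them demonstrates that the algorithms are correct for the
route-topology mechanism (fragmentation by alternative essential pathways of
length ≥ 2, merging with size, parent-clique propagation, walk behavior) —
not that any particular real metabolism shows these numbers. Replicating the
published 51-reaction central-carbon figures requires transcribing that
model from its supplementary material (see README) and, for the full
enumeration, cluster-scale computation.

The brute-force oracle evaluates all 2^N genotypes with one FBA verdict
each (no pruning), derives minimal sets by child lookup in the exhaustive
table, and components by all-pairs swap distance with an inline union-find —
deliberately independent of the production network code. It is capped at
N ≤ 16 (65,536 LP solves, minutes on one CPU) and used only in tests,
validation drivers and the acceptance script.

## Numerical and design choices

* LP feasibility: optimal solutions satisfy |S v| ≤ 1e-6 componentwise and
  bounds within 1e-9 (asserted in tests at those tolerances).
* Viability decisions are invariant to permuting reaction columns (tested by
  shuffling the internal reaction order).
* Determinism: every stochastic procedure takes an explicit seed; traces
  store it; chain connection derives per-pair seeds from one master seed via
  `numpy.random.SeedSequence` (kept below 2^31).
* Reference-rate choice: the full-universe optimum per environment, not a
  fixed external reference; exposed as an override for studies that pin the
  reference to a sub-universe.
* Tie-breaks: component ordering by (size desc, smallest hex); candidate
  orders in walks come from the seeded RNG only.
* Degenerate inputs: empty environment lists, unviable essentiality queries,
  size-mismatched connector calls, out-of-range bound parameters and
  undefined superessentiality indices all raise typed errors rather than
  returning sentinel numbers.

## Problem sizes used in the shipped analyses

Fixture universes span N = 5–11 (oracle-checked exhaustively) plus one
N = 20 universe used only by the sampling procedures; the random
oracle-equivalence sweep draws 25 specs with N ≤ 12. These sizes exercise
every code path — prefilter, pruning, fragmentation, merging, walks — while
keeping the complete suite and the acceptance script at about a minute of
LP time each.

## Known limitations

* The guided connector's incompleteness near minimal sizes (above).
* The superessential prefilter is sound but not complete under multiple
  environments; completeness holds for a single environment (tested).
* The exhaustive enumerator is desk-scale by design (N ≤ 24 without force);
  the N = 51 replication is a documented recipe, not a shipped run.
* SBML import maps boundary/extracellular species and exchange reactions by
  convention (compartment names, cobra boundary detection) and is a
  convenience; the JSON dialect is normative.
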