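# genonet

Connectivity analysis of metabolic genotype spaces by flux-balance viability.

A metabolism can be written as a binary vector over an ordered universe of
*N* biochemical reactions: bit *i* is 1 when the organism catalyzes reaction
*i*. Every such *genotype* either can or cannot synthesize all required
biomass precursors from the nutrients of a minimal environment — a verdict
computed by flux balance analysis (FBA): maximize biomass flux
*Z = cᵀv* subject to steady-state mass balance *Sv = 0* and flux bounds
*a ≤ v ≤ b*, and call the genotype **viable** when *Z* exceeds 1% of the
full universe's rate in the same environment. `genonet` asks how the viable
genotypes of a fixed size *n* are organized: do they form one connected
**genotype network** under *reaction swaps* (simultaneous addition of one
reaction and deletion of another), or do they fragment into components that
gradual, viability-preserving evolution cannot bridge?

The package is aimed at systems/evolutionary biologists who want to run this
style of analysis on their own reaction universes, and ships everything
needed to exercise it end to end without external data:

* `genonet.universe` — reaction universes, environments, genotype bit
  vectors and their JSON dialect (optional SBML import via cobra);
* `genonet.fba` — the LP viability engine (scipy/HiGHS), essentiality,
  minimality, superessentiality indices;
* `genonet.enumeration` — exhaustive per-size enumeration with the two
  pruning principles: superessential prefilter (reactions whose deletion
  from the full universe is fatal in every environment are pinned into all
  candidates) and downward closure (children of unviable genotypes are
  unviable, so only children of the current viable frontier are tested);
* `genonet.network` — swap-adjacency networks by neighbor hashing,
  components, and parent-clique connectivity propagation (each genotype's
  *N − n* parents form a clique; parent images of connected sets stay
  connected; only childless *minimal* metabolisms can seed new components);
* `genonet.walks` — random viability-preserving deletion walks to certified
  minimal metabolisms, the guided swap connector, viable-neighbor censuses,
  and the (1 − p)^M largest-component probability bound;
* `genonet.synth` — synthetic universe generator (essential backbone,
  precursor branches, pairs of alternative routes, redundancy) plus
  brute-force 2^N oracles used only for verification.

## Worked example

```python
from genonet import (fixture_library, generate_universe, brute_force_enumerate,
                     enumerate_viable, environment_general_superessential,
                     build_network)

universe, envs = generate_universe(fixture_library()["pentose_like"].spec)
print(universe.N)                                        # 9
print(sorted(environment_general_superessential(universe, envs)))
#  ['B1', 'B2', 'B3', 'PR1']    <- forced members of every viable genotype

viable = enumerate_viable(universe, envs)                # pruned top-down sweep
print({n: len(v) for n, v in viable.items() if v})       # {6: 1, 7: 4, 8: 5, 9: 1}

net = build_network(viable[7], universe)
print([len(c) for c in net.components])                  # [3, 1]
```

This universe carries two disjoint routes (lengths 2 and 3) to one required
precursor. At the smallest sizes the genotype network fragments into a
component per route — the three genotypes using the short route cannot be
swapped into the one using the long route without breaking viability — and
one reaction later the network merges into a single component of 5. The
route reactions have superessentiality index 1.0 inside their own component
and 0.0 wherever they appear in the other, which is the mechanistic
signature of fragmentation: alternative *essential* pathways of two or more
reactions.

The numbered drivers under `analysis/` run the full story and write tables
under `results/`:

```
python analysis/01_generate_universes.py    # fixture models (JSON)
python analysis/02_census_enumeration.py    # per-size census, oracle-checked
python analysis/03_fragmentation_mechanism.py
python analysis/04_minimal_sampling.py      # deletion walks, neighbor census
python analysis/05_connectivity.py          # chain connection + (1-p)^M bounds
```

A `genonet` console script exposes the same stages
(`viability`, `superessential`, `enumerate`, `network`, `minimize`,
`connect`, `neighbors`, `bound`, `synth`, `oracle`); e.g.
`genonet bound --p 0.01 --m 500` prints `0.0066`.

## Replicating the central-carbon analysis

The published 51-reaction central carbon universe (13 biomass precursors,
10 alternative sole carbon sources) is distributed as supplementary
material of the original study and is not redistributed here. To replicate
it: transcribe the reaction table into the model JSON dialect (see
`genonet.universe` for the schema — metabolites, reactions with signed
stoichiometries, `biomass`, and one environment per carbon source), then

1. `genonet superessential --model central_carbon.json` — one deletion test
   per reaction per carbon source (~510 LP solves, well under a minute);
2. `genonet enumerate --model central_carbon.json --force --checkpoint ck.json`
   — the full top-down sweep is cluster-scale (order 10^9 LP evaluations);
   checkpoints are written at every size boundary so the sweep is resumable
   and can be sharded by frontier;
3. `genonet network` / `connect` / `minimize` on the per-size genotype
   files for the component and walk analyses.
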