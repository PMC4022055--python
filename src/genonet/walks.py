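"""Viability-preserving walks through genotype space.

Three procedures from the genome-scale toolkit:

* *Random deletion walks* strip randomly chosen reactions from a viable
  metabolism, accepting only viability-preserving deletions, until a run of
  failed attempts signals a candidate minimal metabolism, which is then
  certified by exhaustive single-deletion testing.
* The *guided connector* tries to transform one viable genotype into
  another of the same size through viability-preserving reaction swaps,
  preferring to add reactions essential in the target and delete reactions
  private to the walker.  Success certifies the pair lies in one genotype
  network component; failure is explicitly *not* a proof of disconnection.
* *Viable-neighbor enumeration* counts how many of a genotype's
  n x (N - n) swap neighbors are viable.

All randomness flows from one seed per run; traces record the seed and the
step list so any walk can be replayed exactly.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .fba import get_engine
from .universe import Environment, Genotype, Reaction, ReactionUniverse


@dataclass
class WalkTrace:
    """A viability-preserving trajectory with its RNG provenance.

    ``steps`` holds ``(removed_id, added_id)`` pairs; deletion walks have
    ``added_id = None``.  ``L1``/``L2`` are the connector's ordered reaction
    lists (None for deletion walks).
    """

    start: Genotype
    steps: list[tuple[str | None, str | None]]
    success: bool
    attempted_swaps: int
    seed: int | None
    L1: list[str] | None = None
    L2: list[str] | None = None
    universe_N: int = 0

    def genotypes_visited(self, universe: ReactionUniverse) -> Iterator[Genotype]:
        g = self.start
        yield g
        for removed, added in self.steps:
            if added is not None:
                g = g.with_reaction(universe.reaction_index(added))
            if removed is not None:
                g = g.without_reaction(universe.reaction_index(removed))
            yield g

    def endpoint(self, universe: ReactionUniverse) -> Genotype:
        g = self.start
        for g in self.genotypes_visited(universe):
            pass
        return g

    def to_dict(self) -> dict:
        return {
            "start": self.start.to_hex(),
            "N": self.start.N,
            "steps": [list(s) for s in self.steps],
            "success": self.success,
            "attempted_swaps": self.attempted_swaps,
            "seed": self.seed,
            "L1": self.L1,
            "L2": self.L2,
        }


@dataclass(frozen=True)
class ComponentBoundEstimate:
    """Probability that M random viable genotypes all avoid an off-component
    set of measure p: (1 - p)^M."""

    p: float
    M: int
    bound: float


def component_bound(p: float, M: int) -> ComponentBoundEstimate:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p!r}")
    if M < 1:
        raise ValueError(f"sample size M must be >= 1, got {M!r}")
    return ComponentBoundEstimate(p, M, (1.0 - p) ** M)


# ---------------------------------------------------------------------------
# Random deletion walks to minimal metabolisms
# ---------------------------------------------------------------------------

def random_deletion_walk(
    universe: ReactionUniverse,
    envs: Environment | Sequence[Environment],
    seed: int,
    *,
    start: Genotype | None = None,
    failure_limit: int = 1000,
) -> WalkTrace:
    """Delete random reactions while preserving viability until certified minimal.

    Each step picks a present reaction uniformly at random; the deletion is
    accepted iff the child stays viable (resetting the failure counter).
    After ``failure_limit`` consecutive failed attempts the endpoint is
    certified by deleting every reaction in turn; if some deletion is viable
    the walk continues from there, otherwise the endpoint is minimal and the
    walk stops.  The deletion order is recorded so any prefix can be
    replayed (:func:`genotype_at_size`).
    """
    engine = get_engine(universe)
    env_list = [envs] if isinstance(envs, Environment) else list(envs)
    g = Genotype.full(universe.N) if start is None else start
    if not engine.is_viable_all(g, env_list):
        raise ValueError("deletion walk must start from a viable genotype")
    rng = random.Random(seed)
    steps: list[tuple[str | None, str | None]] = []
    attempts = 0
    failures = 0
    while True:
        present = g.present_indices()
        if not present:
            break
        i = rng.choice(present)
        attempts += 1
        child = g.without_reaction(i)
        if engine.is_viable_all(child, env_list):
            g = child
            steps.append((universe.internal_reactions[i].id, None))
            failures = 0
            continue
        failures += 1
        if failures < failure_limit:
            continue
        # certification by exhaustive single deletion
        viable_children = [
            j
            for j in g.present_indices()
            if engine.is_viable_all(g.without_reaction(j), env_list)
        ]
        if not viable_children:
            break  # certified minimal
        j = rng.choice(viable_children)
        g = g.without_reaction(j)
        steps.append((universe.internal_reactions[j].id, None))
        failures = 0
    return WalkTrace(
        start=Genotype.full(universe.N) if start is None else start,
        steps=steps,
        success=True,
        attempted_swaps=attempts,
        seed=seed,
        universe_N=universe.N,
    )


def genotype_at_size(
    trace: WalkTrace, n: int, universe: ReactionUniverse
) -> Genotype:
    """Replay a deletion walk's prefix down to the unique genotype of size n."""
    endpoint_n = trace.start.n - len(trace.steps)
    if not endpoint_n <= n <= trace.start.n:
        raise ValueError(
            f"size {n} outside the walked range [{endpoint_n}, {trace.start.n}]"
        )
    g = trace.start
    for removed, added in trace.steps:
        if added is not None:
            raise ValueError("genotype_at_size applies to pure deletion walks")
        if g.n == n:
            return g
        g = g.without_reaction(universe.reaction_index(removed))
    return g


# ---------------------------------------------------------------------------
# Guided random-walk connector
# ---------------------------------------------------------------------------

def candidate_is_connected(
    reaction: Reaction, walker: Genotype, universe: ReactionUniverse
) -> bool:
    """Screen for random additions: could the reaction possibly carry flux?

    True iff every substrate and every product of the candidate is shared
    with the walker's active reactions (its internal reactions, the biomass
    reaction, or a transport reaction, which can also secrete an otherwise
    unshared product).  A candidate failing the screen is stoichiometrically
    disconnected and cannot contribute to viability.
    """
    active_mets: set[str] = set()
    for i in walker.present_indices():
        active_mets |= set(universe.internal_reactions[i].stoichiometry)
    active_mets |= set(universe.biomass.stoichiometry)
    for t in universe.transport_reactions:
        active_mets |= set(t.stoichiometry)
    return set(reaction.stoichiometry) <= active_mets


def guided_connect(
    g1: Genotype,
    g2: Genotype,
    universe: ReactionUniverse,
    envs: Environment | Sequence[Environment],
    *,
    max_swaps: int = 5000,
    seed: int = 0,
    recompute_essentials: bool = False,
) -> WalkTrace:
    """Try to connect two same-size viable genotypes by viability-preserving swaps.

    The walker starts at ``g1``.  List L1 holds the walker's private
    reactions (absent from ``g2``), nonessential first, each group in random
    order; list L2 holds the target's missing reactions, essential first.
    Each step adds the next L2 reaction and deletes the first deletable L1
    reaction.  If nothing in L1 is deletable the addition is reverted and
    random universe reactions passing the connectedness screen are tried
    instead; reactions added this way that are not part of the target are
    appended to L1 for later deletion.  Attempted additions (accepted or
    reverted) count toward ``max_swaps``.  A failed search is reported as
    unresolved — it is not a proof of disconnection.
    """
    if g1.N != g2.N or g1.N != universe.N:
        raise ValueError("genotypes must belong to the same universe")
    if g1.n != g2.n:
        raise ValueError(f"genotypes of different size (n={g1.n} vs {g2.n})")
    engine = get_engine(universe)
    env_list = [envs] if isinstance(envs, Environment) else list(envs)
    for g, label in ((g1, "g1"), (g2, "g2")):
        if not engine.is_viable_all(g, env_list):
            raise ValueError(f"{label} is not viable; nothing to connect")
    rng = random.Random(seed)

    if g1 == g2:
        return WalkTrace(g1, [], True, 0, seed, [], [], universe.N)

    ess1 = engine.essential_reactions(g1, env_list)
    ess2 = engine.essential_reactions(g2, env_list)
    ids = [r.id for r in universe.internal_reactions]
    only1 = [ids[i] for i in g1.present_indices() if not g2.has(i)]
    only2 = [ids[i] for i in g2.present_indices() if not g1.has(i)]

    def split_shuffled(pool: list[str], first: set[str]) -> list[str]:
        a = [r for r in pool if r in first]
        b = [r for r in pool if r not in first]
        rng.shuffle(a)
        rng.shuffle(b)
        return a + b

    L1 = split_shuffled(only1, {r for r in only1 if r not in ess1})  # nonessential first
    L2 = split_shuffled(only2, ess2 & set(only2))  # target-essential first

    walker = g1
    steps: list[tuple[str | None, str | None]] = []
    pending_L1 = list(L1)
    pending_L2 = list(L2)
    attempted = 0
    target_ids = set(g2.reaction_ids(universe))

    def current_deletable(genotype: Genotype) -> str | None:
        if recompute_essentials:
            ess_now = engine.essential_reactions(genotype, env_list)
        else:
            ess_now = None
        for rid in pending_L1:
            i = universe.reaction_index(rid)
            if not genotype.has(i):
                continue
            if ess_now is not None and rid in ess_now:
                continue
            if engine.is_viable_all(genotype.without_reaction(i), env_list):
                return rid
        return None

    while attempted < max_swaps:
        if walker == g2:
            return WalkTrace(g1, steps, True, attempted, seed, L1, L2, universe.N)
        # part (i): add the next missing target reaction
        added_rid = None
        while pending_L2:
            rid = pending_L2[0]
            if walker.has(universe.reaction_index(rid)):
                pending_L2.pop(0)
                continue
            added_rid = rid
            break
        if added_rid is not None:
            attempted += 1
            trial = walker.with_reaction(universe.reaction_index(added_rid))
            del_rid = current_deletable(trial)
            if del_rid is not None:
                walker = trial.without_reaction(universe.reaction_index(del_rid))
                pending_L1.remove(del_rid)
                pending_L2.remove(added_rid)
                steps.append((del_rid, added_rid))
                continue
            # revert; retry this target reaction later
            pending_L2.remove(added_rid)
            pending_L2.append(added_rid)
        # part (ii) fallback: random universe additions through the screen
        accepted = False
        candidates = [
            i for i in walker.absent_indices()
            if universe.internal_reactions[i].id not in pending_L2
        ]
        rng.shuffle(candidates)
        for i in candidates:
            if attempted >= max_swaps:
                break
            rxn = universe.internal_reactions[i]
            if not candidate_is_connected(rxn, walker, universe):
                continue
            attempted += 1
            trial = walker.with_reaction(i)
            del_rid = current_deletable(trial)
            if del_rid is None:
                continue
            walker = trial.without_reaction(universe.reaction_index(del_rid))
            pending_L1.remove(del_rid)
            if rxn.id not in target_ids:
                pending_L1.append(rxn.id)  # must be deleted again before the end
            steps.append((del_rid, rxn.id))
            accepted = True
            break
        if not accepted and added_rid is None:
            break  # exhausted all moves
    success = walker == g2
    return WalkTrace(g1, steps, success, attempted, seed, L1, L2, universe.N)


def replay_trace(
    trace: WalkTrace,
    universe: ReactionUniverse,
    envs: Environment | Sequence[Environment],
) -> bool:
    """Independently re-verify that every genotype on a trace is viable."""
    engine = get_engine(universe)
    env_list = [envs] if isinstance(envs, Environment) else list(envs)
    return all(
        engine.is_viable_all(g, env_list) for g in trace.genotypes_visited(universe)
    )


def chain_connect(
    sample: Sequence[Genotype],
    universe: ReactionUniverse,
    envs: Environment | Sequence[Environment],
    *,
    max_swaps: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the guided connector over consecutive pairs of a sample.

    If every pair connects, transitivity puts the whole sample inside one
    genotype-network component.
    """
    rows = []
    seeds = np.random.SeedSequence(seed).spawn(max(len(sample) - 1, 0))
    for k in range(len(sample) - 1):
        pair_seed = int(seeds[k].generate_state(1)[0] % (2**31))
        trace = guided_connect(
            sample[k], sample[k + 1], universe, envs,
            max_swaps=max_swaps, seed=pair_seed,
        )
        rows.append(
            {
                "pair": k,
                "g_from": sample[k].to_hex(),
                "g_to": sample[k + 1].to_hex(),
                "success": trace.success,
                "swaps": len(trace.steps),
                "attempted_swaps": trace.attempted_swaps,
                "seed": pair_seed,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pair", "g_from", "g_to", "success", "swaps", "attempted_swaps", "seed",
        ],
    )


# ---------------------------------------------------------------------------
# Viable neighbors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeighborRow:
    genotype: Genotype
    n: int
    possible_neighbors: int  # n * (N - n)
    viable_neighbors: int
    addition_neighbors: int  # N - n, all viable by monotonicity
    viable_deletion_neighbors: int  # zero iff minimal


def viable_neighbors(
    genotype: Genotype,
    universe: ReactionUniverse,
    envs: Environment | Sequence[Environment],
) -> NeighborRow:
    """Count the viable swap neighbors of a viable genotype by direct FBA."""
    engine = get_engine(universe)
    env_list = [envs] if isinstance(envs, Environment) else list(envs)
    if not engine.is_viable_all(genotype, env_list):
        raise ValueError("neighbor enumeration expects a viable genotype")
    n, N = genotype.n, genotype.N
    viable = 0
    present = genotype.present_indices()
    absent = genotype.absent_indices()
    for i in present:
        base = genotype.mask ^ (1 << i)
        for j in absent:
            if engine.is_viable_all(Genotype(base | (1 << j), N), env_list):
                viable += 1
    deletions = sum(
        engine.is_viable_all(genotype.without_reaction(i), env_list) for i in present
    )
    return NeighborRow(genotype, n, n * (N - n), viable, N - n, deletions)


def neighbor_report(
    sample: Sequence[Genotype],
    universe: ReactionUniverse,
    envs: Environment | Sequence[Environment],
) -> tuple[pd.DataFrame, float]:
    """Per-genotype neighbor counts plus the Spearman rank correlation
    between metabolism size n and viable-neighbor count."""
    rows = [viable_neighbors(g, universe, envs) for g in sample]
    table = pd.DataFrame(
        {
            "genotype": [r.genotype.to_hex() for r in rows],
            "n": [r.n for r in rows],
            "possible_neighbors": [r.possible_neighbors for r in rows],
            "viable_neighbors": [r.viable_neighbors for r in rows],
            "addition_neighbors": [r.addition_neighbors for r in rows],
            "viable_deletion_neighbors": [r.viable_deletion_neighbors for r in rows],
        }
    )
    if table["n"].nunique() > 1 and table["viable_neighbors"].nunique() > 1:
        rho = float(_scipy_stats.spearmanr(table["n"], table["viable_neighbors"]).statistic)
    else:
        rho = float("nan")
    return table, rho
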