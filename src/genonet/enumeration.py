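"""Exhaustive enumeration of viable genotypes per metabolism size.

Two structural facts make exhaustive enumeration feasible far beyond naive
2^N sweeps:

* *Superessential prefilter* — a reaction whose deletion from the full
  universe abolishes viability in every environment must be present in every
  viable genotype, shrinking the space from 2^N to 2^(N-k).
* *Downward closure* — removing a reaction from an unviable metabolism can
  never restore viability, so all viable genotypes of size n-1 are children
  of viable genotypes of size n.  A top-down sweep that only tests children
  of the current viable frontier therefore finds every viable genotype.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .fba import ViabilityEngine, get_engine
from .universe import Environment, Genotype, ReactionUniverse

#: Default ceiling on universe size for exhaustive sweeps.  Above this the
#: worst case exceeds ~16.7M candidate subsets and runs belong on a cluster.
EXHAUSTIVE_CAP = 24


class ExhaustiveCapError(RuntimeError):
    """Universe too large for a desk-scale exhaustive sweep without force."""


def count_genotypes(N: int, n: int) -> int:
    """Exact number of genotypes of size n over N reactions: C(N, n)."""
    if n < 0 or n > N:
        raise ValueError(f"size n={n} outside [0, N={N}]")
    return math.comb(N, n)


def environment_general_superessential(
    universe: ReactionUniverse,
    envs: Environment | Sequence[Environment],
    engine: ViabilityEngine | None = None,
) -> set[str]:
    """Reactions whose deletion from the full universe kills viability in *every* environment.

    These are forced members of every viable genotype.
    """
    engine = engine or get_engine(universe)
    env_list = [envs] if isinstance(envs, Environment) else list(envs)
    if not env_list:
        raise ValueError("at least one environment is required")
    full = Genotype.full(universe.N)
    for env in env_list:
        if not engine.is_viable(full, env).viable:
            raise ValueError(
                f"full universe is not viable in environment {env.name!r}"
            )
    result = set()
    for i in range(universe.N):
        child = full.without_reaction(i)
        if all(not engine.is_viable(child, env).viable for env in env_list):
            result.add(universe.internal_reactions[i].id)
    return result


@dataclass
class EnumerationStats:
    lp_calls: int = 0
    candidates_evaluated: int = 0
    cache_hits: int = 0
    pruned_by_pinning: int = 0


def enumerate_viable(
    universe: ReactionUniverse,
    envs: Environment | Sequence[Environment],
    n_min: int = 0,
    n_max: int | None = None,
    *,
    exhaustive_cap: int = EXHAUSTIVE_CAP,
    force: bool = False,
    pin_superessential: bool = True,
    checkpoint: str | Path | None = None,
    stats: EnumerationStats | None = None,
) -> dict[int, set[Genotype]]:
    """Top-down sweep returning exactly the viable genotypes for each size.

    Starting from the full universe, each size level tests only the children
    of the previous level's viable genotypes (downward closure), never
    clearing a bit pinned by the superessential prefilter.  Returns a map
    ``n -> set of viable genotypes`` for ``n`` in ``[n_min, n_max]``; sizes
    below the smallest viable metabolism map to empty sets.
    """
    N = universe.N
    if n_max is None:
        n_max = N
    if not 0 <= n_min <= n_max <= N:
        raise ValueError(f"bad size range [{n_min}, {n_max}] for N={N}")
    if N > exhaustive_cap and not force:
        raise ExhaustiveCapError(
            f"universe has N={N} > cap {exhaustive_cap}; worst case "
            f"~2^{N} = {2**N:.2e} viability evaluations. Pass force=True "
            "to run anyway."
        )
    engine = get_engine(universe)
    env_list = [envs] if isinstance(envs, Environment) else list(envs)

    results: dict[int, set[Genotype]] = {n: set() for n in range(n_min, n_max + 1)}

    full = Genotype.full(N)
    frontier: set[int] = set()
    start_n = N
    if checkpoint is not None and Path(checkpoint).exists():
        state = json.loads(Path(checkpoint).read_text())
        start_n = state["n"]
        frontier = {int(h, 16) for h in state["frontier"]}
    else:
        if engine.is_viable_all(full, env_list):
            frontier = {full.mask}
        if n_min <= N <= n_max:
            results[N] = {Genotype(m, N) for m in frontier}

    pinned_mask = 0
    if pin_superessential and frontier:
        for rid in environment_general_superessential(universe, env_list, engine):
            pinned_mask |= 1 << universe.reaction_index(rid)

    stats = stats if stats is not None else EnumerationStats()
    for n in range(start_n, n_min, -1):
        if not frontier:
            break  # no viable genotypes below an empty level, by monotonicity
        candidates: set[int] = set()
        for mask in frontier:
            bits = mask & ~pinned_mask
            while bits:
                low = bits & -bits
                candidates.add(mask ^ low)
                bits ^= low
        stats.candidates_evaluated += len(candidates)
        lp0, ch0 = engine.lp_calls, engine.cache_hits
        frontier = {
            m for m in candidates if engine.is_viable_all(Genotype(m, N), env_list)
        }
        stats.lp_calls += engine.lp_calls - lp0
        stats.cache_hits += engine.cache_hits - ch0
        if n_min <= n - 1 <= n_max:
            results[n - 1] = {Genotype(m, N) for m in sorted(frontier)}
        if checkpoint is not None:
            Path(checkpoint).write_text(
                json.dumps(
                    {
                        "n": n - 1,
                        "frontier": sorted(Genotype(m, N).to_hex() for m in frontier),
                    }
                )
            )
    return results


def find_minimal_in(
    viable_set: set[Genotype],
    universe: ReactionUniverse,
    envs: Environment | Sequence[Environment],
) -> set[Genotype]:
    """Genotypes in the set with no viable child (every reaction essential)."""
    engine = get_engine(universe)
    env_list = [envs] if isinstance(envs, Environment) else list(envs)
    minimal = set()
    for g in viable_set:
        if not any(
            engine.is_viable_all(g.without_reaction(i), env_list)
            for i in g.present_indices()
        ):
            minimal.add(g)
    return minimal


def build_census(
    universe: ReactionUniverse,
    viable_by_size: Mapping[int, set[Genotype]],
    envs: Environment | Sequence[Environment],
    networks: Mapping[int, "object"] | None = None,
) -> pd.DataFrame:
    """Per-size census: |Omega(n)|, |V(n)|, minimal counts, component structure.

    Column semantics follow the per-size summary tables of genotype-space
    studies: the number of possible genotypes, viable genotypes, minimal
    metabolisms, and (when networks are supplied) component counts and the
    fraction of viable genotypes in the largest component.
    """
    rows = []
    for n in sorted(viable_by_size):
        viable = viable_by_size[n]
        omega = count_genotypes(universe.N, n)
        minimal = find_minimal_in(viable, universe, envs) if viable else set()
        row = {
            "n": n,
            "omega_n": omega,
            "viable_count": len(viable),
            "viable_fraction": len(viable) / omega if omega else 0.0,
            "minimal_count": len(minimal),
            "minimal_fraction": len(minimal) / len(viable) if viable else float("nan"),
        }
        if networks is not None and n in networks:
            net = networks[n]
            row["component_count"] = len(net.components)
            row["largest_component_fraction"] = net.largest_fraction
        rows.append(row)
    return pd.DataFrame(rows)
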