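"""Flux-balance viability engine.

Viability of a metabolism (a genotype over a reaction universe) in a given
minimal environment is decided by linear programming: maximize the biomass
flux Z = c^T v subject to steady-state mass balance S v = 0 and per-reaction
flux bounds a <= v <= b.  Reactions absent from the genotype are clamped to
zero flux; transport reactions and the biomass reaction are always present.
A genotype is *viable* when its optimal biomass flux exceeds a fixed
fraction (default 1%) of the reference rate of the full universe in the
same environment, with a small absolute floor to keep LP round-off from
being read as growth.

Key facts used throughout the package: adding a reaction can only enlarge
the feasible flux space, so viability is monotone under reaction addition,
and removing a reaction from an unviable metabolism can never make it
viable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linprog

from .universe import Environment, Genotype, ReactionUniverse


class SolverError(RuntimeError):
    """The LP solver failed for numeric reasons even after a retry."""


class ModelError(RuntimeError):
    """The model itself is defective (e.g. an unbounded free-lunch cycle)."""


@dataclass
class FluxSolution:
    v: np.ndarray | None
    Z: float
    status: str  # optimal | infeasible | unbounded | numeric_failure


@dataclass(frozen=True)
class ViabilityResult:
    viable: bool
    biomass_rate: float
    reference_rate: float
    threshold_fraction: float


@dataclass
class FluxProblem:
    """Assembled LP for one (genotype, environment) pair."""

    S: np.ndarray
    c: np.ndarray
    a: np.ndarray
    b: np.ndarray
    active_mask: np.ndarray
    column_ids: tuple[str, ...]


def _as_env_list(envs: Environment | Sequence[Environment]) -> list[Environment]:
    if isinstance(envs, Environment):
        return [envs]
    out = list(envs)
    if not out:
        raise ValueError("at least one environment is required")
    return out


class ViabilityEngine:
    """Caches the LP skeleton and viability verdicts for one universe.

    Columns are ordered internal reactions (genotype bit order), then
    transports, then biomass.  Only non-external metabolites are mass
    balanced; external metabolites are boundary species.
    """

    def __init__(
        self,
        universe: ReactionUniverse,
        *,
        flux_bound: float = 1000.0,
        default_carbon_uptake: float = 10.0,
        threshold_fraction: float = 0.01,
        absolute_floor: float = 1e-6,
    ) -> None:
        self.universe = universe
        self.flux_bound = float(flux_bound)
        self.default_carbon_uptake = float(default_carbon_uptake)
        self.threshold_fraction = float(threshold_fraction)
        self.absolute_floor = float(absolute_floor)

        balanced = [m.id for m in universe.metabolites if not m.external]
        self._row = {mid: i for i, mid in enumerate(balanced)}
        cols = universe.all_reactions()
        self.column_ids = tuple(r.id for r in cols)
        S = np.zeros((len(balanced), len(cols)))
        for j, rxn in enumerate(cols):
            for mid, coef in rxn.stoichiometry.items():
                if mid in self._row:
                    S[self._row[mid], j] = coef
        self.S = S
        self.n_internal = universe.N
        self.biomass_col = len(cols) - 1
        self.c = np.zeros(len(cols))
        self.c[self.biomass_col] = -1.0  # linprog minimizes

        self._env_bounds: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._reference: dict[str, float] = {}
        self._viability_cache: dict[tuple[int, str], float] = {}
        self.lp_calls = 0
        self.cache_hits = 0

    # -- per-environment bound templates ----------------------------------
    def _transport_bounds(self, rxn, env: Environment) -> tuple[float, float]:
        B = self.flux_bound
        lo = -B if rxn.reversible else 0.0
        if rxn.id in env.uptake_bounds:
            return lo, float(env.uptake_bounds[rxn.id])
        imported = {
            m for m in rxn.substrates if self.universe.metabolite(m).external
        }
        if not imported:  # pure secretion
            return lo, B
        medium = set(env.fixed_nutrients)
        if imported <= medium:
            return lo, B
        if imported <= medium | {env.carbon_source}:
            return lo, self.default_carbon_uptake
        return lo, 0.0  # imports something absent from the medium

    def env_bounds(self, env: Environment) -> tuple[np.ndarray, np.ndarray]:
        """Bound template with every internal reaction enabled."""
        try:
            return self._env_bounds[env.name]
        except KeyError:
            pass
        self.universe.validate_environment(env)
        B = self.flux_bound
        cols = self.universe.all_reactions()
        lb = np.zeros(len(cols))
        ub = np.full(len(cols), B)
        for j, rxn in enumerate(cols):
            if j < self.n_internal:
                lb[j] = -B if rxn.reversible else 0.0
            elif j == self.biomass_col:
                lb[j] = 0.0
            else:
                lb[j], ub[j] = self._transport_bounds(rxn, env)
        self._env_bounds[env.name] = (lb, ub)
        return lb, ub

    def flux_problem(self, genotype: Genotype, env: Environment) -> FluxProblem:
        lb, ub = self.env_bounds(env)
        lb, ub = lb.copy(), ub.copy()
        active = np.ones(len(self.column_ids), dtype=bool)
        for i in range(self.n_internal):
            if not genotype.mask >> i & 1:
                lb[i] = ub[i] = 0.0
                active[i] = False
        return FluxProblem(self.S, self.c, lb, ub, active, self.column_ids)

    # -- solving -----------------------------------------------------------
    def _solve(self, lb: np.ndarray, ub: np.ndarray) -> FluxSolution:
        self.lp_calls += 1
        zeros = np.zeros(self.S.shape[0])
        res = linprog(
            self.c, A_eq=self.S, b_eq=zeros, bounds=np.column_stack([lb, ub]),
            method="highs",
        )
        if res.status == 1 or res.status == 4:  # iteration limit / numeric
            res = linprog(
                self.c, A_eq=self.S, b_eq=zeros,
                bounds=np.column_stack([lb, ub]), method="highs",
                options={
                    "presolve": False,
                    "primal_feasibility_tolerance": 1e-10,
                    "dual_feasibility_tolerance": 1e-10,
                },
            )
        if res.status == 0:
            return FluxSolution(res.x, -res.fun, "optimal")
        if res.status == 2:
            return FluxSolution(None, 0.0, "infeasible")
        if res.status == 3:
            raise ModelError(
                "LP unbounded: the model contains a flux cycle that produces "
                "biomass without nutrient uptake"
            )
        raise SolverError(f"LP solver failed twice (status {res.status}): {res.message}")

    def biomass_rate(
        self, genotype: Genotype, env: Environment
    ) -> tuple[float, FluxSolution]:
        if genotype.N != self.universe.N:
            raise ValueError("genotype does not belong to this universe")
        problem = self.flux_problem(genotype, env)
        sol = self._solve(problem.a, problem.b)
        return max(sol.Z, 0.0), sol

    def reference_rate(self, env: Environment) -> float:
        try:
            return self._reference[env.name]
        except KeyError:
            rate, _ = self.biomass_rate(Genotype.full(self.universe.N), env)
            self._reference[env.name] = rate
            return rate

    def _cached_rate(self, genotype: Genotype, env: Environment) -> float:
        key = (genotype.mask, env.name)
        try:
            rate = self._viability_cache[key]
            self.cache_hits += 1
            return rate
        except KeyError:
            rate, _ = self.biomass_rate(genotype, env)
            self._viability_cache[key] = rate
            return rate

    def is_viable(
        self,
        genotype: Genotype,
        env: Environment,
        reference_rate: float | None = None,
    ) -> ViabilityResult:
        ref = self.reference_rate(env) if reference_rate is None else reference_rate
        if ref <= 0:
            raise ValueError(
                f"reference rate must be positive (got {ref!r}); the full "
                f"universe is not viable in environment {env.name!r}"
            )
        rate = self._cached_rate(genotype, env)
        threshold = max(self.threshold_fraction * ref, self.absolute_floor)
        return ViabilityResult(rate > threshold, rate, ref, self.threshold_fraction)

    def is_viable_all(
        self, genotype: Genotype, envs: Environment | Sequence[Environment]
    ) -> bool:
        return all(self.is_viable(genotype, env).viable for env in _as_env_list(envs))

    # -- essentiality ------------------------------------------------------
    def essential_reactions(
        self, genotype: Genotype, envs: Environment | Sequence[Environment]
    ) -> set[str]:
        """Reactions whose single deletion abolishes viability on >= 1 environment."""
        env_list = _as_env_list(envs)
        if not self.is_viable_all(genotype, env_list):
            raise ValueError("essentiality is undefined for an unviable genotype")
        essential = set()
        for i in genotype.present_indices():
            child = genotype.without_reaction(i)
            if not self.is_viable_all(child, env_list):
                essential.add(self.universe.internal_reactions[i].id)
        return essential

    def is_minimal(
        self, genotype: Genotype, envs: Environment | Sequence[Environment]
    ) -> bool:
        return len(self.essential_reactions(genotype, envs)) == genotype.n


def get_engine(universe: ReactionUniverse, **kwargs) -> ViabilityEngine:
    """Return the engine cached on the universe (created on first use)."""
    if kwargs:
        return ViabilityEngine(universe, **kwargs)
    if universe._engine is None:
        universe._engine = ViabilityEngine(universe)
    return universe._engine


# ---------------------------------------------------------------------------
# Functional façade mirroring the engine, for one-off calls
# ---------------------------------------------------------------------------

def biomass_rate(
    universe: ReactionUniverse, genotype: Genotype, env: Environment
) -> tuple[float, FluxSolution]:
    return get_engine(universe).biomass_rate(genotype, env)


def is_viable(
    universe: ReactionUniverse,
    genotype: Genotype,
    env: Environment,
    reference_rate: float | None = None,
) -> ViabilityResult:
    return get_engine(universe).is_viable(genotype, env, reference_rate)


def is_viable_all(
    universe: ReactionUniverse,
    genotype: Genotype,
    envs: Environment | Sequence[Environment],
) -> bool:
    return get_engine(universe).is_viable_all(genotype, envs)


def essential_reactions(
    universe: ReactionUniverse,
    genotype: Genotype,
    envs: Environment | Sequence[Environment],
) -> set[str]:
    return get_engine(universe).essential_reactions(genotype, envs)


def is_minimal(
    universe: ReactionUniverse,
    genotype: Genotype,
    envs: Environment | Sequence[Environment],
) -> bool:
    return get_engine(universe).is_minimal(genotype, envs)


def superessentiality_index(
    universe: ReactionUniverse,
    reaction_id: str,
    genotype_sample: Sequence[Genotype],
    envs: Environment | Sequence[Environment],
) -> float:
    """Fraction of sampled genotypes containing the reaction in which it is essential.

    Genotypes lacking the reaction are skipped.  Raises ``ValueError`` when
    no sampled genotype contains the reaction (the index is undefined).
    """
    if not genotype_sample:
        raise ValueError("empty genotype sample")
    engine = get_engine(universe)
    idx = universe.reaction_index(reaction_id)
    env_list = _as_env_list(envs)
    containing = essential_in = 0
    for g in genotype_sample:
        if not g.has(idx):
            continue
        containing += 1
        child = g.without_reaction(idx)
        if not engine.is_viable_all(child, env_list):
            essential_in += 1
    if containing == 0:
        raise ValueError(
            f"superessentiality index of {reaction_id!r} undefined: no sampled "
            "genotype contains the reaction"
        )
    return essential_in / containing
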