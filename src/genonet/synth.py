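"""Synthetic reaction universes with controlled redundancy, plus brute-force oracles.

The generator emulates the structure the connectivity analysis assumes: a
shared essential backbone converting the sole carbon source into a hub
metabolite, precursor reactions branching off the hub (the biomass reaction
consumes every precursor), optional pairs of disjoint alternative routes of
configurable lengths between the hub and an extra required precursor, and
optional redundant duplicate reactions.  Pairs of alternative routes of
length >= 2 are the mechanism that fragments genotype networks at the
smallest viable sizes: a metabolism carrying only route A cannot reach one
carrying only route B through single viability-preserving swaps.

The brute-force oracle evaluates *all* 2^N genotypes directly (no pruning)
and derives viable sets, minimal sets and component partitions from first
principles (all-pairs swap distance + union-find, independent of the
genotype_network module).  It exists to verify the pipeline, never to run
it.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .fba import get_engine
from .universe import (
    Environment,
    Genotype,
    Metabolite,
    Reaction,
    ReactionUniverse,
    save_model,
)

ORACLE_CAP = 16  # 2^16 = 65,536 LP evaluations: the hard oracle ceiling


@dataclass(frozen=True)
class SyntheticUniverseSpec:
    """Blueprint for a generated toy universe.

    ``alt_pathways`` lists (len_A, len_B) route-length pairs; each pair adds
    one extra biomass precursor reachable from the hub through either of two
    disjoint routes.  ``redundant_reactions`` duplicates randomly chosen
    backbone/precursor reactions.  ``second_carbon_source`` adds one more
    internal entry reaction plus a second minimal environment, to exercise
    multi-environment viability.
    """

    backbone_length: int = 3
    precursor_count: int = 1
    alt_pathways: tuple[tuple[int, int], ...] = ()
    redundant_reactions: int = 0
    seed: int = 0
    second_carbon_source: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "alt_pathways", tuple(map(tuple, self.alt_pathways)))
        if self.backbone_length < 1 or self.precursor_count < 1:
            raise ValueError("backbone_length and precursor_count must be >= 1")
        for la, lb in self.alt_pathways:
            if la < 1 or lb < 1:
                raise ValueError("alternative route lengths must be >= 1")
        if self.redundant_reactions < 0:
            raise ValueError("redundant_reactions must be >= 0")

    @property
    def N(self) -> int:
        return (
            self.backbone_length
            + self.precursor_count
            + sum(la + lb for la, lb in self.alt_pathways)
            + self.redundant_reactions
            + (1 if self.second_carbon_source else 0)
        )


def generate_universe(
    spec: SyntheticUniverseSpec, path: str | Path | None = None
) -> tuple[ReactionUniverse, list[Environment]]:
    """Build the universe and its minimal environment(s); deterministic in the seed.

    All stoichiometric coefficients are +-1.  With every reaction present the
    universe is viable; deleting one complete alternative route preserves
    viability while deleting one reaction from each route of a pair abolishes
    it.  When ``path`` is given the model JSON is also written (byte-stable
    for a fixed spec).
    """
    if spec.N > 30:
        import warnings

        warnings.warn(f"synthetic universe with N={spec.N} > 30 reactions")
    rng = random.Random(spec.seed)
    mets: list[Metabolite] = [
        Metabolite("carbon_ext", "carbon source (medium)", external=True),
        Metabolite("carbon", "carbon source (internal)"),
        Metabolite("nh4_ext", "ammonium (medium)", external=True),
        Metabolite("nh4", "ammonium (internal)"),
        Metabolite("waste_ext", "waste (medium)", external=True),
        Metabolite("waste", "waste (internal)"),
    ]
    internal: list[Reaction] = []

    # essential backbone: carbon -> m1 -> ... -> hub (first step sheds waste)
    k = spec.backbone_length
    for i in range(1, k + 1):
        mets.append(Metabolite(f"m{i}", f"backbone intermediate {i}"))
    hub = f"m{k}"
    stoich = {"carbon": -1.0, "m1": 1.0, "waste": 1.0}
    internal.append(Reaction("B1", stoich))
    for i in range(2, k + 1):
        internal.append(Reaction(f"B{i}", {f"m{i-1}": -1.0, f"m{i}": 1.0}))

    if spec.second_carbon_source:
        mets += [
            Metabolite("carbon2_ext", "alternative carbon source (medium)", external=True),
            Metabolite("carbon2", "alternative carbon source (internal)"),
        ]
        internal.append(Reaction("C2U", {"carbon2": -1.0, "m1": 1.0}))

    # precursor branches off the hub (consume nitrogen)
    biomass_stoich: dict[str, float] = {}
    for j in range(1, spec.precursor_count + 1):
        mets.append(Metabolite(f"p{j}", f"biomass precursor {j}"))
        internal.append(Reaction(f"PR{j}", {hub: -1.0, "nh4": -1.0, f"p{j}": 1.0}))
        biomass_stoich[f"p{j}"] = -1.0

    # alternative route pairs hub -> q_j, both routes disjoint
    for j, (la, lb) in enumerate(spec.alt_pathways, start=1):
        mets.append(Metabolite(f"q{j}", f"route-pair precursor {j}"))
        biomass_stoich[f"q{j}"] = -1.0
        for route, length in (("A", la), ("B", lb)):
            prev = hub
            for step in range(1, length + 1):
                out = f"q{j}" if step == length else f"{route.lower()}{j}_{step}"
                if out != f"q{j}":
                    mets.append(Metabolite(out, f"route {route}{j} intermediate {step}"))
                internal.append(Reaction(f"{route}{j}_{step}", {prev: -1.0, out: 1.0}))
                prev = out

    # redundant duplicates of backbone/precursor reactions; each duplicable
    # conversion is covered once (in random order) before any repeats, so a
    # redundancy count equal to the number of conversions doubles them all
    duplicable = [r for r in internal if r.id.startswith(("B", "PR", "C2U"))]
    order: list[Reaction] = []
    while len(order) < spec.redundant_reactions:
        block = list(duplicable)
        rng.shuffle(block)
        order += block
    for d, template in enumerate(order[: spec.redundant_reactions], start=1):
        internal.append(
            Reaction(f"{template.id}_dup{d}", dict(template.stoichiometry),
                     reversible=template.reversible)
        )

    biomass = Reaction("BIOMASS", biomass_stoich)
    transports = [
        Reaction("T_carbon", {"carbon_ext": -1.0, "carbon": 1.0}, transport=True),
        Reaction("T_nh4", {"nh4_ext": -1.0, "nh4": 1.0}, transport=True),
        Reaction("T_waste", {"waste": -1.0, "waste_ext": 1.0}, transport=True),
    ]
    envs = [
        Environment(
            name="carbon_minimal",
            carbon_source="carbon_ext",
            fixed_nutrients=("nh4_ext",),
        )
    ]
    if spec.second_carbon_source:
        transports.append(
            Reaction("T_carbon2", {"carbon2_ext": -1.0, "carbon2": 1.0}, transport=True)
        )
        envs.append(
            Environment(
                name="carbon2_minimal",
                carbon_source="carbon2_ext",
                fixed_nutrients=("nh4_ext",),
            )
        )

    universe = ReactionUniverse(
        tuple(internal), tuple(transports), biomass, tuple(mets)
    )
    assert universe.N == spec.N, "generator drifted from the size formula"
    if path is not None:
        save_model(universe, path, envs)
    return universe, envs


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

@dataclass
class OracleResult:
    """Ground truth from exhaustive 2^N evaluation (test/validation use only)."""

    N: int
    viable_by_size: dict[int, set[Genotype]]
    minimal_by_size: dict[int, set[Genotype]]
    components_by_size: dict[int, list[frozenset[Genotype]]]

    @property
    def smallest_viable_size(self) -> int | None:
        sizes = [n for n, v in self.viable_by_size.items() if v]
        return min(sizes) if sizes else None


def _components_all_pairs(nodes: list[Genotype]) -> list[frozenset[Genotype]]:
    """Components of the swap-distance-1 relation by all-pairs comparison."""
    parent = list(range(len(nodes)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            if (nodes[a].mask ^ nodes[b].mask).bit_count() == 2:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    blocks: dict[int, set[Genotype]] = {}
    for idx, g in enumerate(nodes):
        blocks.setdefault(find(idx), set()).add(g)
    return sorted(
        (frozenset(b) for b in blocks.values()),
        key=lambda b: (-len(b), min(g.to_hex() for g in b)),
    )


def brute_force_enumerate(
    universe: ReactionUniverse,
    envs: Environment | Sequence[Environment],
) -> OracleResult:
    """Evaluate all 2^N genotypes directly — no pruning, no shortcuts.

    Viable sets come from one FBA verdict per genotype; minimal sets are the
    viable genotypes all of whose children are unviable (checked by lookup
    in the exhaustive viable table); components come from all-pairs swap
    distance.  Refuses universes with N > 16.
    """
    N = universe.N
    if N > ORACLE_CAP:
        raise ValueError(
            f"brute-force oracle capped at N <= {ORACLE_CAP} (got N={N})"
        )
    engine = get_engine(universe)
    env_list = [envs] if isinstance(envs, Environment) else list(envs)
    viable_masks: set[int] = set()
    for mask in range(1 << N):
        if engine.is_viable_all(Genotype(mask, N), env_list):
            viable_masks.add(mask)
    viable_by_size: dict[int, set[Genotype]] = {n: set() for n in range(N + 1)}
    for mask in viable_masks:
        viable_by_size[mask.bit_count()].add(Genotype(mask, N))
    minimal_by_size: dict[int, set[Genotype]] = {}
    for n, genos in viable_by_size.items():
        minimal_by_size[n] = {
            g
            for g in genos
            if not any(
                (g.mask ^ (1 << i)) in viable_masks for i in g.present_indices()
            )
        }
    components_by_size = {
        n: _components_all_pairs(sorted(genos)) for n, genos in viable_by_size.items() if genos
    }
    return OracleResult(N, viable_by_size, minimal_by_size, components_by_size)


# ---------------------------------------------------------------------------
# Fixture library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureCase:
    name: str
    spec: SyntheticUniverseSpec
    notes: str


def fixture_library() -> dict[str, FixtureCase]:
    """Named toy universes with known qualitative structure.

    The notes describe what the oracle should find; tests re-derive every
    expectation from the oracle rather than trusting these strings.
    """
    return {
        "all_essential_chain": FixtureCase(
            "all_essential_chain",
            SyntheticUniverseSpec(backbone_length=3, precursor_count=2, seed=11),
            "Every reaction essential: the full genotype is the only viable one "
            "and the unique minimal metabolism.",
        ),
        "redundant_pairs": FixtureCase(
            "redundant_pairs",
            SyntheticUniverseSpec(
                backbone_length=2, precursor_count=1, redundant_reactions=3, seed=23
            ),
            "Every conversion covered twice: no environment-general "
            "superessential reactions.",
        ),
        "pentose_like": FixtureCase(
            "pentose_like",
            SyntheticUniverseSpec(
                backbone_length=3, precursor_count=1, alt_pathways=((2, 3),), seed=7
            ),
            "Two disjoint routes of lengths 2 and 3 to one required precursor: "
            "the genotype network fragments by route membership at the "
            "smallest sizes and merges once both routes fit.",
        ),
        "single_swap_routes": FixtureCase(
            "single_swap_routes",
            SyntheticUniverseSpec(
                backbone_length=2, precursor_count=1, alt_pathways=((1, 1),), seed=3
            ),
            "Both routes are single reactions, so one swap interconverts them: "
            "no fragmentation can arise from this pair.",
        ),
        "double_motif": FixtureCase(
            "double_motif",
            SyntheticUniverseSpec(
                backbone_length=2,
                precursor_count=1,
                alt_pathways=((2, 2), (2, 2)),
                seed=5,
            ),
            "Two independent route pairs: at the smallest viable size the "
            "component count is the product of per-motif route choices (4).",
        ),
        "multi_source": FixtureCase(
            "multi_source",
            SyntheticUniverseSpec(
                backbone_length=2,
                precursor_count=1,
                alt_pathways=((2, 2),),
                second_carbon_source=True,
                seed=13,
            ),
            "Two minimal environments with different sole carbon sources; the "
            "per-source entry reactions are essential on one source each, so "
            "they are not environment-general superessential.",
        ),
    }


def random_spec(rng: random.Random, max_N: int = 12) -> SyntheticUniverseSpec:
    """Draw a random small universe spec (for oracle-equivalence sweeps)."""
    while True:
        spec = SyntheticUniverseSpec(
            backbone_length=rng.randint(1, 3),
            precursor_count=rng.randint(1, 2),
            alt_pathways=tuple(
                (rng.randint(1, 3), rng.randint(1, 3))
                for _ in range(rng.randint(0, 2))
            ),
            redundant_reactions=rng.randint(0, 2),
            seed=rng.randrange(2**31),
        )
        if spec.N <= max_N:
            return spec
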