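"""Reaction universes, environments and genotype bit vectors.

A *reaction universe* is an ordered set of N internal (genotype-indexed)
reactions plus transport/exchange reactions and one biomass reaction that
are assumed present in every metabolism.  A *genotype* is a length-N bit
vector over the internal reactions: bit i set means internal reaction i is
present.  Bit 0 always refers to the first internal reaction in file order,
and this order is serialized with the model so genotype encodings are
comparable across runs.

The normative on-disk format is a small JSON dialect (see
:func:`load_universe` / :func:`save_model`); SBML import is a convenience
layered on cobra.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class ModelValidationError(ValueError):
    """A model file or in-memory universe violates a structural invariant."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    external: bool = False


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric reaction.

    ``stoichiometry`` maps metabolite id to a signed coefficient
    (negative = consumed, positive = produced).  ``transport`` marks
    exchange/transport reactions, which cross the system boundary, are
    assumed present in every metabolism, and are never genotype-indexed.
    """

    id: str
    stoichiometry: Mapping[str, float]
    reversible: bool = False
    transport: bool = False
    enzyme_label: str | None = None

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        for met, coef in self.stoichiometry.items():
            if not math.isfinite(coef) or coef == 0:
                raise ModelValidationError(
                    f"reaction {self.id!r}: coefficient for {met!r} is {coef!r}"
                )
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))

    @property
    def substrates(self) -> set[str]:
        return {m for m, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> set[str]:
        return {m for m, c in self.stoichiometry.items() if c > 0}


@dataclass(frozen=True)
class Environment:
    """A minimal growth medium with a sole carbon source.

    ``uptake_bounds`` gives explicit maximum uptake fluxes per transport
    reaction id; transports without an entry fall back to the engine
    defaults (carbon source capped, fixed nutrients effectively unbounded,
    imports of anything else closed, secretion always open).
    """

    name: str
    carbon_source: str
    uptake_bounds: Mapping[str, float] = field(default_factory=dict)
    fixed_nutrients: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "uptake_bounds", dict(self.uptake_bounds))
        object.__setattr__(self, "fixed_nutrients", tuple(self.fixed_nutrients))
        if not self.carbon_source:
            raise ModelValidationError(f"environment {self.name!r}: no carbon source")


@dataclass
class ReactionUniverse:
    """Ordered universe of N internal reactions plus always-present machinery."""

    internal_reactions: tuple[Reaction, ...]
    transport_reactions: tuple[Reaction, ...]
    biomass: Reaction
    metabolites: tuple[Metabolite, ...]

    def __post_init__(self) -> None:
        self.internal_reactions = tuple(self.internal_reactions)
        self.transport_reactions = tuple(self.transport_reactions)
        self.metabolites = tuple(self.metabolites)
        self._validate()
        self._index = {r.id: i for i, r in enumerate(self.internal_reactions)}
        self._met = {m.id: m for m in self.metabolites}
        self._engine = None  # lazy ViabilityEngine cache, set by genonet.fba

    # -- basic accessors -------------------------------------------------
    @property
    def N(self) -> int:
        return len(self.internal_reactions)

    @property
    def m(self) -> int:
        return len(self.metabolites)

    def reaction_index(self, rid: str) -> int:
        try:
            return self._index[rid]
        except KeyError:
            raise KeyError(f"unknown internal reaction id {rid!r}") from None

    def metabolite(self, mid: str) -> Metabolite:
        return self._met[mid]

    def all_reactions(self) -> tuple[Reaction, ...]:
        """Internal reactions, then transports, then biomass (column order)."""
        return self.internal_reactions + self.transport_reactions + (self.biomass,)

    # -- validation ------------------------------------------------------
    def _validate(self) -> None:
        if self.N < 1:
            raise ModelValidationError("universe has no internal reactions")
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.all_reactions()]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dup}")
        known = set(met_ids)
        external = {m.id for m in self.metabolites if m.external}
        for rxn in self.all_reactions():
            missing = set(rxn.stoichiometry) - known
            if missing:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} references undeclared metabolites: "
                    f"{sorted(missing)}"
                )
        for rxn in self.transport_reactions:
            if not rxn.transport:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} listed as transport but not flagged"
                )
            if not (set(rxn.stoichiometry) & external):
                raise ModelValidationError(
                    f"transport reaction {rxn.id!r} touches no external metabolite"
                )
        if self.biomass.transport:
            raise ModelValidationError("biomass reaction cannot be a transport")
        if not self.biomass.substrates:
            raise ModelValidationError("biomass reaction consumes nothing")

    def validate_environment(self, env: Environment) -> None:
        if env.carbon_source not in self._met:
            raise ModelValidationError(
                f"environment {env.name!r}: unknown carbon source "
                f"{env.carbon_source!r}"
            )
        transport_ids = {r.id for r in self.transport_reactions}
        for rid in env.uptake_bounds:
            if rid not in transport_ids:
                raise ModelValidationError(
                    f"environment {env.name!r}: uptake bound for unknown "
                    f"transport reaction {rid!r}"
                )
        for mid in env.fixed_nutrients:
            if mid not in self._met:
                raise ModelValidationError(
                    f"environment {env.name!r}: unknown fixed nutrient {mid!r}"
                )


@dataclass(frozen=True, order=True)
class Genotype:
    """A point in genotype space: a length-N bit vector over internal reactions.

    ``mask`` holds the bits as a non-negative integer, bit i (least
    significant bit = bit 0) corresponding to internal reaction i.  The
    canonical serialization is the lowercase zero-padded hex of ``mask``.
    """

    mask: int
    N: int

    def __post_init__(self) -> None:
        if not 0 <= self.mask < (1 << self.N):
            raise ValueError(f"mask {self.mask:#x} out of range for N={self.N}")

    @property
    def n(self) -> int:
        """Metabolism size: number of reactions present."""
        return self.mask.bit_count()

    # -- codec -----------------------------------------------------------
    def to_hex(self) -> str:
        width = (self.N + 3) // 4
        return format(self.mask, f"0{width}x")

    @classmethod
    def from_hex(cls, s: str, N: int) -> "Genotype":
        return cls(int(s, 16), N)

    @classmethod
    def full(cls, N: int) -> "Genotype":
        return cls((1 << N) - 1, N)

    @classmethod
    def empty(cls, N: int) -> "Genotype":
        return cls(0, N)

    # -- bit algebra -----------------------------------------------------
    def has(self, i: int) -> bool:
        return bool(self.mask >> i & 1)

    def with_reaction(self, i: int) -> "Genotype":
        return Genotype(self.mask | (1 << i), self.N)

    def without_reaction(self, i: int) -> "Genotype":
        return Genotype(self.mask & ~(1 << i), self.N)

    def present_indices(self) -> list[int]:
        return [i for i in range(self.N) if self.mask >> i & 1]

    def absent_indices(self) -> list[int]:
        return [i for i in range(self.N) if not self.mask >> i & 1]

    def reaction_ids(self, universe: ReactionUniverse) -> list[str]:
        return [universe.internal_reactions[i].id for i in self.present_indices()]

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"Genotype(n={self.n}/{self.N}, {self.to_hex()})"


def genotype_from_reaction_ids(
    universe: ReactionUniverse, ids: Iterable[str]
) -> Genotype:
    """Build a genotype from a set of internal-reaction ids.

    Transport and biomass reactions are not genotype-indexed; passing one
    of their ids is an error.
    """
    mask = 0
    special = {r.id for r in universe.transport_reactions} | {universe.biomass.id}
    for rid in ids:
        if rid in special:
            raise ValueError(
                f"{rid!r} is a transport/biomass reaction and not genotype-indexed"
            )
        mask |= 1 << universe.reaction_index(rid)
    return Genotype(mask, universe.N)


def hamming_swap_distance(g1: Genotype, g2: Genotype) -> int:
    """Minimum number of reaction swaps between two same-size genotypes.

    Equal to half the bit-vector Hamming distance; a distance of 1 means
    the genotypes share all but one reaction (adjacency in the genotype
    network).
    """
    if g1.N != g2.N:
        raise ValueError(f"genotypes over different universes (N={g1.N} vs {g2.N})")
    if g1.n != g2.n:
        raise ValueError(f"genotypes of different size (n={g1.n} vs {g2.n})")
    return (g1.mask ^ g2.mask).bit_count() // 2


# ---------------------------------------------------------------------------
# Model JSON dialect
# ---------------------------------------------------------------------------

def _reaction_from_record(rec: Mapping, where: str) -> Reaction:
    try:
        return Reaction(
            id=rec["id"],
            stoichiometry=rec["stoichiometry"],
            reversible=bool(rec.get("reversible", False)),
            transport=bool(rec.get("transport", False)),
            enzyme_label=rec.get("enzyme_label"),
        )
    except ModelValidationError:
        raise
    except (KeyError, TypeError) as exc:
        raise ModelValidationError(f"malformed reaction record in {where}: {rec!r}") from exc


def universe_from_dict(doc: Mapping) -> ReactionUniverse:
    try:
        met_recs = doc["metabolites"]
        rxn_recs = doc["reactions"]
        biomass_id = doc["biomass"]
    except (KeyError, TypeError) as exc:
        raise ModelValidationError(
            "model document needs 'metabolites', 'reactions' and 'biomass' keys"
        ) from exc
    metabolites = tuple(
        Metabolite(
            id=rec["id"], name=rec.get("name", ""), external=bool(rec.get("external", False))
        )
        for rec in met_recs
    )
    reactions = [_reaction_from_record(rec, "reactions") for rec in rxn_recs]
    by_id = {r.id: r for r in reactions}
    if biomass_id not in by_id:
        raise ModelValidationError(f"biomass reaction {biomass_id!r} not declared")
    biomass = by_id[biomass_id]
    internal = tuple(r for r in reactions if not r.transport and r.id != biomass_id)
    transports = tuple(r for r in reactions if r.transport)
    return ReactionUniverse(internal, transports, biomass, metabolites)


def environments_from_dict(doc: Mapping) -> dict[str, Environment]:
    envs = {}
    for rec in doc.get("environments", []):
        env = Environment(
            name=rec["name"],
            carbon_source=rec["carbon_source"],
            uptake_bounds=rec.get("uptake_bounds", {}),
            fixed_nutrients=rec.get("fixed_nutrients", []),
        )
        envs[env.name] = env
    return envs


def model_to_dict(
    universe: ReactionUniverse, environments: Sequence[Environment] = ()
) -> dict:
    def rxn_rec(r: Reaction) -> dict:
        rec = {
            "id": r.id,
            "stoichiometry": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
            "reversible": r.reversible,
            "transport": r.transport,
        }
        if r.enzyme_label:
            rec["enzyme_label"] = r.enzyme_label
        return rec

    return {
        "metabolites": [
            {"id": m.id, "name": m.name, "external": m.external}
            for m in universe.metabolites
        ],
        "reactions": [rxn_rec(r) for r in universe.all_reactions()],
        "biomass": universe.biomass.id,
        "environments": [
            {
                "name": e.name,
                "carbon_source": e.carbon_source,
                "uptake_bounds": {k: e.uptake_bounds[k] for k in sorted(e.uptake_bounds)},
                "fixed_nutrients": list(e.fixed_nutrients),
            }
            for e in environments
        ],
    }


def save_model(
    universe: ReactionUniverse,
    path: str | Path,
    environments: Sequence[Environment] = (),
) -> None:
    """Write a model JSON file (deterministic byte layout)."""
    doc = model_to_dict(universe, environments)
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def load_universe(path: str | Path, dialect: str = "json") -> ReactionUniverse:
    """Load a reaction universe from a model file.

    Reaction order in the file defines the genotype bit order.  ``dialect``
    is ``"json"`` (normative) or ``"sbml"`` (convenience import via cobra).
    """
    if dialect == "json":
        doc = json.loads(Path(path).read_text())
        return universe_from_dict(doc)
    if dialect == "sbml":
        return _load_sbml(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def load_environments(path: str | Path) -> dict[str, Environment]:
    doc = json.loads(Path(path).read_text())
    envs = environments_from_dict(doc)
    universe = universe_from_dict(doc)
    for env in envs.values():
        universe.validate_environment(env)
    return envs


def load_model(path: str | Path) -> tuple[ReactionUniverse, dict[str, Environment]]:
    doc = json.loads(Path(path).read_text())
    universe = universe_from_dict(doc)
    envs = environments_from_dict(doc)
    for env in envs.values():
        universe.validate_environment(env)
    return universe, envs


_EXTERNAL_COMPARTMENTS = {"e", "ext", "extracellular", "external", "boundary"}


def _load_sbml(path: str | Path) -> ReactionUniverse:
    """SBML Level-3 import via cobra.

    Species in a boundary/extracellular compartment become external
    metabolites; cobra boundary reactions (exchanges, sinks, demands) and
    reactions touching an external species become transports; the reaction
    carrying the objective becomes the biomass reaction.
    """
    import cobra.io

    model = cobra.io.read_sbml_model(str(path))
    metabolites = tuple(
        Metabolite(
            id=met.id,
            name=met.name or "",
            external=(met.compartment or "").lower() in _EXTERNAL_COMPARTMENTS,
        )
        for met in model.metabolites
    )
    external = {m.id for m in metabolites if m.external}
    boundary_ids = {r.id for r in model.boundary}

    biomass = None
    internal: list[Reaction] = []
    transports: list[Reaction] = []
    for rxn in model.reactions:
        stoich = {met.id: coef for met, coef in rxn.metabolites.items()}
        is_transport = rxn.id in boundary_ids or bool(set(stoich) & external)
        rec = Reaction(
            id=rxn.id,
            stoichiometry=stoich,
            reversible=rxn.lower_bound < 0,
            transport=is_transport and rxn.objective_coefficient == 0,
            enzyme_label=rxn.name or None,
        )
        if rxn.objective_coefficient != 0:
            if biomass is not None:
                raise ModelValidationError("SBML model has several objective reactions")
            biomass = rec
        elif rec.transport:
            transports.append(rec)
        else:
            internal.append(rec)
    if biomass is None:
        raise ModelValidationError("SBML model declares no objective (biomass) reaction")
    return ReactionUniverse(tuple(internal), tuple(transports), biomass, metabolites)


# ---------------------------------------------------------------------------
# Genotype files: one hex string per line under a provenance header
# ---------------------------------------------------------------------------

def save_genotypes(
    genotypes: Iterable[Genotype], path: str | Path, universe_name: str, N: int
) -> None:
    lines = [f"# universe={universe_name} N={N}"]
    lines += sorted(g.to_hex() for g in genotypes)
    Path(path).write_text("\n".join(lines) + "\n")


def load_genotypes(path: str | Path) -> list[Genotype]:
    text = Path(path).read_text().splitlines()
    if not text or not text[0].startswith("#"):
        raise ModelValidationError(f"{path}: missing genotype header line")
    header = dict(
        kv.split("=", 1) for kv in text[0].lstrip("# ").split() if "=" in kv
    )
    try:
        N = int(header["N"])
    except (KeyError, ValueError) as exc:
        raise ModelValidationError(f"{path}: header does not declare N") from exc
    return [Genotype.from_hex(line, N) for line in text[1:] if line.strip()]
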