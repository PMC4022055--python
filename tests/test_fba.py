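"""Viability engine: LP correctness, thresholding, essentiality, invariants."""

import random

import numpy as np
import pytest

from genonet import (
    Genotype,
    ReactionUniverse,
    essential_reactions,
    generate_universe,
    genotype_from_reaction_ids,
    get_engine,
    is_minimal,
    is_viable,
    is_viable_all,
    superessentiality_index,
)
from genonet.synth import SyntheticUniverseSpec


def _route_genotype(universe, *, include):
    """Genotype with the shared core plus the named route reactions."""
    core = [
        r.id
        for r in universe.internal_reactions
        if r.id.startswith(("B", "PR", "C2U")) and "_" not in r.id
    ]
    return genotype_from_reaction_ids(universe, set(core) | set(include))


class TestBiomassRate:
    def test_full_genotype_grows_and_zero_genotype_does_not(self, pentose):
        universe, envs = pentose
        engine = get_engine(universe)
        rate_full, sol = engine.biomass_rate(Genotype.full(universe.N), envs[0])
        assert rate_full > 0 and sol.status == "optimal"
        rate_zero, _ = engine.biomass_rate(Genotype.empty(universe.N), envs[0])
        assert rate_zero == 0.0

    def test_optimal_solution_is_mass_balanced_within_tolerance(self, pentose):
        universe, envs = pentose
        engine = get_engine(universe)
        _, sol = engine.biomass_rate(Genotype.full(universe.N), envs[0])
        residual = np.abs(engine.S @ sol.v).max()
        assert residual <= 1e-6
        lb, ub = engine.env_bounds(envs[0])
        assert (sol.v >= lb - 1e-9).all() and (sol.v <= ub + 1e-9).all()

    def test_disabled_reactions_carry_no_flux(self, pentose):
        universe, envs = pentose
        engine = get_engine(universe)
        g = _route_genotype(universe, include=["A1_1", "A1_2"])
        _, sol = engine.biomass_rate(g, envs[0])
        for i in g.absent_indices():
            assert abs(sol.v[i]) <= 1e-9


class TestViabilityPredicate:
    def test_rate_equal_to_reference_is_viable(self, pentose):
        universe, envs = pentose
        res = is_viable(universe, Genotype.full(universe.N), envs[0])
        assert res.viable and res.biomass_rate == pytest.approx(res.reference_rate)

    def test_zero_rate_is_not_viable(self, pentose):
        universe, envs = pentose
        assert not is_viable(universe, Genotype.empty(universe.N), envs[0]).viable

    def test_nonpositive_reference_is_a_configuration_error(self, pentose):
        universe, envs = pentose
        with pytest.raises(ValueError, match="reference"):
            is_viable(universe, Genotype.full(universe.N), envs[0], reference_rate=0.0)

    def test_route_completeness_decides_viability(self, pentose):
        universe, envs = pentose
        assert is_viable(universe, _route_genotype(universe, include=["A1_1", "A1_2"]), envs[0]).viable
        assert is_viable(universe, _route_genotype(universe, include=["B1_1", "B1_2", "B1_3"]), envs[0]).viable
        # one reaction missing from each route: no complete path to the precursor
        broken = _route_genotype(universe, include=["A1_1", "B1_1", "B1_2"])
        assert not is_viable(universe, broken, envs[0]).viable

    def test_viable_on_one_environment_only(self, multi_source):
        universe, envs = multi_source
        full = Genotype.full(universe.N)
        no_c2 = full.without_reaction(universe.reaction_index("C2U"))
        assert is_viable(universe, no_c2, envs[0]).viable
        assert not is_viable(universe, no_c2, envs[1]).viable
        assert not is_viable_all(universe, no_c2, envs)
        assert is_viable_all(universe, full, envs)

    def test_empty_environment_list_rejected(self, pentose):
        universe, _ = pentose
        with pytest.raises(ValueError):
            is_viable_all(universe, Genotype.full(universe.N), [])


class TestEssentiality:
    def test_full_fixture_essentials_are_the_shared_core(self, pentose):
        universe, envs = pentose
        ess = essential_reactions(universe, Genotype.full(universe.N), envs)
        assert ess == {"B1", "B2", "B3", "PR1"}

    def test_minimal_metabolism_has_all_reactions_essential(self, pentose):
        universe, envs = pentose
        g = _route_genotype(universe, include=["A1_1", "A1_2"])
        assert essential_reactions(universe, g, envs) == set(g.reaction_ids(universe))
        assert is_minimal(universe, g, envs)
        assert not is_minimal(universe, Genotype.full(universe.N), envs)

    def test_essentiality_undefined_for_unviable_genotype(self, pentose):
        universe, envs = pentose
        with pytest.raises(ValueError, match="unviable"):
            essential_reactions(universe, Genotype.empty(universe.N), envs)

    def test_superessentiality_index_extremes(self, pentose, pentose_oracle):
        universe, envs = pentose
        sample = sorted(pentose_oracle.viable_by_size[7])
        # backbone reactions are essential in every viable genotype
        assert superessentiality_index(universe, "B1", sample, envs) == 1.0
        # at size 8 every genotype retains redundancy for at least one route
        sample8 = sorted(pentose_oracle.viable_by_size[8])
        idx = superessentiality_index(universe, "B1_3", sample8, envs)
        assert 0.0 <= idx < 1.0

    def test_superessentiality_undefined_when_reaction_absent(self, pentose, pentose_oracle):
        universe, envs = pentose
        b_only = [
            g for g in pentose_oracle.viable_by_size[7]
            if not g.has(universe.reaction_index("A1_1"))
        ]
        with pytest.raises(ValueError, match="undefined"):
            superessentiality_index(universe, "A1_1", b_only, envs)


class TestStructuralInvariants:
    def test_addition_never_abolishes_viability(self, pentose, pentose_oracle):
        universe, envs = pentose
        engine = get_engine(universe)
        rng = random.Random(0)
        viable = [g for genos in pentose_oracle.viable_by_size.values() for g in genos]
        for g in rng.sample(viable, min(8, len(viable))):
            for j in g.absent_indices():
                assert engine.is_viable_all(g.with_reaction(j), envs)

    def test_children_of_unviable_genotypes_stay_unviable(self, pentose):
        universe, envs = pentose
        engine = get_engine(universe)
        rng = random.Random(1)
        checked = 0
        while checked < 8:
            mask = rng.getrandbits(universe.N)
            g = Genotype(mask, universe.N)
            if g.n == 0 or engine.is_viable_all(g, envs):
                continue
            checked += 1
            for i in g.present_indices():
                assert not engine.is_viable_all(g.without_reaction(i), envs)

    def test_viability_invariant_under_reaction_order_permutation(self, pentose):
        universe, envs = pentose
        engine = get_engine(universe)
        rng = random.Random(2)
        perm = list(range(universe.N))
        rng.shuffle(perm)
        shuffled = ReactionUniverse(
            tuple(universe.internal_reactions[i] for i in perm),
            universe.transport_reactions,
            universe.biomass,
            universe.metabolites,
        )
        engine2 = get_engine(shuffled)
        for _ in range(20):
            mask = rng.getrandbits(universe.N)
            g = Genotype(mask, universe.N)
            g2 = Genotype(
                sum(((mask >> perm[k]) & 1) << k for k in range(universe.N)),
                universe.N,
            )
            assert engine.is_viable_all(g, envs) == engine2.is_viable_all(g2, envs)

    def test_viability_cache_hits_are_counted(self, pentose):
        universe, envs = pentose
        engine = get_engine(universe)
        g = Genotype.full(universe.N)
        engine.is_viable(g, envs[0])
        before = engine.cache_hits
        engine.is_viable(g, envs[0])
        assert engine.cache_hits == before + 1


class TestAgainstCobra:
    """Independent FBA oracle: the same model assembled in cobra."""

    def test_biomass_optimum_matches_cobra(self):
        cobra = pytest.importorskip("cobra")
        spec = SyntheticUniverseSpec(
            backbone_length=2, precursor_count=2, alt_pathways=((2, 1),), seed=17
        )
        universe, envs = generate_universe(spec)
        engine = get_engine(universe)

        model = cobra.Model("xcheck")
        mets = {
            m.id: cobra.Metabolite(m.id, compartment="e" if m.external else "c")
            for m in universe.metabolites
        }
        reactions = []
        for g_idx, rxn in enumerate(universe.all_reactions()):
            lb, ub = engine.env_bounds(envs[0])
            r = cobra.Reaction(rxn.id, lower_bound=lb[g_idx], upper_bound=ub[g_idx])
            # drop external species: cobra balances every metabolite it sees
            r.add_metabolites(
                {mets[m]: c for m, c in rxn.stoichiometry.items()
                 if not universe.metabolite(m).external}
            )
            reactions.append(r)
        model.add_reactions(reactions)
        model.objective = universe.biomass.id

        ours = engine.reference_rate(envs[0])
        theirs = model.slim_optimize()
        assert ours == pytest.approx(theirs, abs=1e-6)

        # and for a strict subset genotype
        sub = Genotype.full(universe.N).without_reaction(universe.reaction_index("A1_1"))
        for i in sub.absent_indices():
            rid = universe.internal_reactions[i].id
            model.reactions.get_by_id(rid).bounds = (0.0, 0.0)
        rate, _ = engine.biomass_rate(sub, envs[0])
        assert rate == pytest.approx(model.slim_optimize(), abs=1e-6)
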