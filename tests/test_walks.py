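"""Deletion walks, the guided connector, neighbor counts and the probability bound."""

import random

import pytest
from hypothesis import given, strategies as st

from genonet import (
    Genotype,
    Metabolite,
    Reaction,
    ReactionUniverse,
    build_network,
    candidate_is_connected,
    chain_connect,
    component_bound,
    genotype_at_size,
    get_engine,
    guided_connect,
    is_minimal,
    neighbor_report,
    random_deletion_walk,
    replay_trace,
    viable_neighbors,
)


class TestDeletionWalks:
    def test_all_essential_universe_gives_zero_step_walk(self, chain):
        universe, envs = chain
        trace = random_deletion_walk(universe, envs, seed=0, failure_limit=50)
        assert trace.steps == []
        assert trace.endpoint(universe) == Genotype.full(universe.N)

    def test_endpoint_is_certified_minimal_and_prefixes_viable(self, pentose):
        universe, envs = pentose
        engine = get_engine(universe)
        for seed in range(5):
            trace = random_deletion_walk(universe, envs, seed=seed, failure_limit=50)
            endpoint = trace.endpoint(universe)
            assert is_minimal(universe, endpoint, envs)
            for g in trace.genotypes_visited(universe):
                assert engine.is_viable_all(g, envs)

    def test_redundant_universe_walk_strips_to_an_oracle_minimal(
        self, redundant, redundant_oracle
    ):
        universe, envs = redundant
        trace = random_deletion_walk(universe, envs, seed=3, failure_limit=50)
        endpoint = trace.endpoint(universe)
        all_minimal = set().union(*redundant_oracle.minimal_by_size.values())
        assert endpoint in all_minimal

    def test_same_seed_gives_identical_trace(self, pentose):
        universe, envs = pentose
        t1 = random_deletion_walk(universe, envs, seed=11, failure_limit=50)
        t2 = random_deletion_walk(universe, envs, seed=11, failure_limit=50)
        assert t1.steps == t2.steps and t1.attempted_swaps == t2.attempted_swaps

    def test_unviable_start_rejected(self, pentose):
        universe, envs = pentose
        with pytest.raises(ValueError, match="viable"):
            random_deletion_walk(
                universe, envs, seed=0, start=Genotype.empty(universe.N)
            )

    def test_genotype_at_size_replays_the_recorded_path(self, pentose):
        universe, envs = pentose
        engine = get_engine(universe)
        trace = random_deletion_walk(universe, envs, seed=2, failure_limit=50)
        start_n = trace.start.n
        end_n = trace.endpoint(universe).n
        assert genotype_at_size(trace, start_n, universe) == trace.start
        assert genotype_at_size(trace, end_n, universe) == trace.endpoint(universe)
        for n in range(end_n, start_n + 1):
            g = genotype_at_size(trace, n, universe)
            assert g.n == n
            assert engine.is_viable_all(g, envs)
        with pytest.raises(ValueError, match="range"):
            genotype_at_size(trace, end_n - 1, universe)


class TestGuidedConnect:
    def test_identical_genotypes_connect_in_zero_swaps(self, pentose, pentose_oracle):
        universe, envs = pentose
        g = next(iter(pentose_oracle.viable_by_size[8]))
        trace = guided_connect(g, g, universe, envs, seed=0)
        assert trace.success and trace.steps == []

    def test_adjacent_pair_connects_in_one_swap(self, pentose, pentose_oracle):
        universe, envs = pentose
        net = build_network(pentose_oracle.viable_by_size[8], universe)
        a, b = next(iter(net.edges))
        trace = guided_connect(a, b, universe, envs, seed=0)
        assert trace.success and len(trace.steps) == 1

    def test_size_mismatch_rejected(self, pentose, pentose_oracle):
        universe, envs = pentose
        g8 = next(iter(pentose_oracle.viable_by_size[8]))
        g7 = next(iter(pentose_oracle.viable_by_size[7]))
        with pytest.raises(ValueError, match="size"):
            guided_connect(g8, g7, universe, envs, seed=0)

    def test_cross_component_search_reports_unresolved(self, pentose, pentose_oracle):
        universe, envs = pentose
        blocks = pentose_oracle.components_by_size[7]
        assert len(blocks) == 2  # oracle-certified fragmentation
        g_a, g_b = min(blocks[0]), min(blocks[1])
        trace = guided_connect(g_a, g_b, universe, envs, max_swaps=300, seed=5)
        assert not trace.success

    def test_lifting_above_the_fragmented_size_restores_connectivity(
        self, pentose, pentose_oracle
    ):
        universe, envs = pentose
        blocks = pentose_oracle.components_by_size[7]
        g_a, g_b = min(blocks[0]), min(blocks[1])
        assert len(pentose_oracle.components_by_size[8]) == 1
        # lift both endpoints one reaction up, into the single size-8 component
        lift_a = next(
            p for p in sorted(
                {g_a.with_reaction(j) for j in g_a.absent_indices()}
            ) if p in pentose_oracle.viable_by_size[8]
        )
        lift_b = next(
            p for p in sorted(
                {g_b.with_reaction(j) for j in g_b.absent_indices()}
            ) if p in pentose_oracle.viable_by_size[8]
        )
        trace = guided_connect(lift_a, lift_b, universe, envs, seed=5)
        assert trace.success
        assert replay_trace(trace, universe, envs)
        assert trace.endpoint(universe) == lift_b

    def test_success_certificates_replay_cleanly(self, double_motif, double_motif_oracle):
        universe, envs = double_motif
        o = double_motif_oracle
        n = max(n for n, b in o.components_by_size.items() if len(b) == 1 and len(o.viable_by_size[n]) >= 4)
        nodes = sorted(o.viable_by_size[n])
        rng = random.Random(7)
        for _ in range(3):
            a, b = rng.sample(nodes, 2)
            trace = guided_connect(a, b, universe, envs, seed=rng.randrange(100))
            assert trace.success
            assert replay_trace(trace, universe, envs)
            assert trace.endpoint(universe) == b


class TestCandidateScreen:
    @staticmethod
    def _toy_universe():
        mets = [
            Metabolite("s_ext", external=True), Metabolite("s"),
            Metabolite("x"), Metabolite("orphan"), Metabolite("w"),
            Metabolite("w_ext", external=True), Metabolite("p"),
        ]
        internal = (
            Reaction("U1", {"s": -1, "x": 1}),
            Reaction("U2", {"x": -1, "p": 1}),
            Reaction("DEAD", {"x": -1, "orphan": 1}),   # orphan: nowhere else, no export
            Reaction("VENT", {"x": -1, "w": 1}),        # w: exportable only
        )
        transports = (
            Reaction("T_s", {"s_ext": -1, "s": 1}, transport=True),
            Reaction("T_w", {"w": -1, "w_ext": 1}, transport=True),
        )
        biomass = Reaction("BM", {"p": -1})
        return ReactionUniverse(internal, transports, biomass, tuple(mets))

    def test_orphan_product_fails_the_screen(self):
        universe = self._toy_universe()
        walker = Genotype(0b0011, universe.N)  # U1, U2 active
        dead = universe.internal_reactions[2]
        assert not candidate_is_connected(dead, walker, universe)

    def test_fully_shared_metabolites_pass(self):
        universe = self._toy_universe()
        walker = Genotype(0b0001, universe.N)  # U1 active
        u2 = universe.internal_reactions[1]
        assert candidate_is_connected(u2, walker, universe)

    def test_product_reachable_only_through_secretion_passes(self):
        universe = self._toy_universe()
        walker = Genotype(0b0011, universe.N)
        vent = universe.internal_reactions[3]
        assert candidate_is_connected(vent, walker, universe)


class TestChainConnect:
    def test_single_genotype_sample_is_vacuous_success(self, pentose, pentose_oracle):
        universe, envs = pentose
        g = next(iter(pentose_oracle.viable_by_size[8]))
        table = chain_connect([g], universe, envs, seed=0)
        assert table.empty

    def test_connected_size_sample_fully_chains(self, double_motif, double_motif_oracle):
        universe, envs = double_motif
        o = double_motif_oracle
        # one reaction of slack above the tightest size: the guided heuristic
        # never deletes walker/target-shared reactions, so it needs room
        n = next(
            n for n in sorted(o.components_by_size)
            if len(o.components_by_size[n]) == 1 and len(o.viable_by_size[n]) >= 20
        )
        rng = random.Random(9)
        sample = rng.sample(sorted(o.viable_by_size[n]), 6)
        table = chain_connect(sample, universe, envs, seed=1)
        assert table["success"].all()

    def test_mixed_component_sample_has_a_failing_pair(self, pentose, pentose_oracle):
        universe, envs = pentose
        blocks = pentose_oracle.components_by_size[7]
        sample = sorted(blocks[0])[:2] + [min(blocks[1])]
        table = chain_connect(sample, universe, envs, max_swaps=300, seed=2)
        assert not table["success"].all()


class TestComponentBound:
    def test_printed_value_for_500_draws(self):
        est = component_bound(0.01, 500)
        assert est.bound == pytest.approx(0.99**500)
        assert round(est.bound, 4) == 0.0066

    @pytest.mark.parametrize("p,M,expected", [(0.0, 10, 1.0), (1.0, 10, 0.0)])
    def test_degenerate_probabilities(self, p, M, expected):
        assert component_bound(p, M).bound == expected

    @given(
        st.floats(0.0, 1.0, allow_nan=False),
        st.floats(0.0, 1.0, allow_nan=False),
        st.integers(1, 1000),
    )
    def test_monotone_in_p_and_M(self, p1, p2, M):
        lo, hi = sorted((p1, p2))
        assert component_bound(hi, M).bound <= component_bound(lo, M).bound
        assert component_bound(lo, M + 1).bound <= component_bound(lo, M).bound

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            component_bound(-0.1, 10)
        with pytest.raises(ValueError):
            component_bound(0.5, 0)


class TestViableNeighbors:
    def test_possible_neighbor_formula(self, pentose, pentose_oracle):
        universe, envs = pentose
        g = next(iter(pentose_oracle.viable_by_size[7]))
        row = viable_neighbors(g, universe, envs)
        assert row.possible_neighbors == 7 * (universe.N - 7)
        assert row.addition_neighbors == universe.N - 7

    def test_counts_match_oracle_membership(self, pentose, pentose_oracle):
        universe, envs = pentose
        for n in (7, 8):
            members = pentose_oracle.viable_by_size[n]
            for g in sorted(members):
                row = viable_neighbors(g, universe, envs)
                expected = sum(
                    1
                    for i in g.present_indices()
                    for j in g.absent_indices()
                    if Genotype(g.mask ^ (1 << i) | (1 << j), universe.N) in members
                )
                assert row.viable_neighbors == expected

    def test_minimal_genotype_in_all_essential_universe_has_no_swap_neighbors(self, chain):
        universe, envs = chain
        row = viable_neighbors(Genotype.full(universe.N), universe, envs)
        assert row.viable_neighbors == 0
        assert row.viable_deletion_neighbors == 0

    def test_rank_correlation_matches_brute_force_ranks(self, pentose, pentose_oracle):
        universe, envs = pentose
        sample = sorted(pentose_oracle.viable_by_size[7]) + sorted(
            pentose_oracle.viable_by_size[8]
        )
        table, rho = neighbor_report(sample, universe, envs)

        def ranks(values):
            order = sorted(range(len(values)), key=lambda k: values[k])
            r = [0.0] * len(values)
            k = 0
            while k < len(order):
                j = k
                while j + 1 < len(order) and values[order[j + 1]] == values[order[k]]:
                    j += 1
                avg = (k + j) / 2 + 1
                for t in range(k, j + 1):
                    r[order[t]] = avg
                k = j + 1
            return r

        rx = ranks(list(table["n"]))
        ry = ranks(list(table["viable_neighbors"]))
        mx = sum(rx) / len(rx)
        my = sum(ry) / len(ry)
        num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
        den = (
            sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
        ) ** 0.5
        assert rho == pytest.approx(num / den)
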