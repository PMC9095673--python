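"""Half-life ratio categories, network randomization, path profiles and
degronon detection."""

import networkx as nx
import numpy as np
import pytest

from degronon.network import (
    HalfLifeTable,
    RatioCategory,
    build_pair_records,
    category_fractions,
    dedupe_member_sets,
    degree_halflife_correlation,
    detect_degronons,
    half_life_ratio_and_category,
    randomize_network,
    ratio_distribution_vs_random,
    shortest_path_ratio_profile,
    validate_network,
)


class TestRatioCategory:
    @pytest.mark.parametrize(
        "t1,t2,ratio,cat",
        [
            (10, 10, 1.0, RatioCategory.SIMILAR),
            (40, 50, 0.8, RatioCategory.SIMILAR),       # boundary -> upper
            (50, 100, 0.5, RatioCategory.DIFFERENT),    # boundary -> upper
            (20, 100, 0.2, RatioCategory.VERY_DIFFERENT),
            (79, 100, 0.79, RatioCategory.DIFFERENT),
        ],
    )
    def test_boundaries(self, t1, t2, ratio, cat):
        got_ratio, got_cat = half_life_ratio_and_category(t1, t2)
        assert got_ratio == pytest.approx(ratio)
        assert got_cat is cat

    def test_categories_partition_unit_interval(self):
        # exhaustive sweep across (0, 1]: every ratio maps to exactly one category
        for r in np.linspace(0.001, 1.0, 1000):
            _, cat = half_life_ratio_and_category(r, 1.0)
            if r >= 0.8:
                assert cat is RatioCategory.SIMILAR
            elif r >= 0.5:
                assert cat is RatioCategory.DIFFERENT
            else:
                assert cat is RatioCategory.VERY_DIFFERENT

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            half_life_ratio_and_category(0, 5)


@pytest.fixture
def toy_net():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("a", "f"), ("f", "c")])
    return g


@pytest.fixture
def random_test_net():
    rng = np.random.default_rng(8)
    g = nx.gnm_random_graph(200, 600, seed=3)
    return nx.relabel_nodes(g, {i: f"n{i:03d}" for i in g.nodes()})


class TestRandomization:
    def test_same_seed_identical(self, random_test_net):
        r1, _ = randomize_network(random_test_net, seed=5)
        r2, _ = randomize_network(random_test_net, seed=5)
        assert set(r1.edges()) == set(r2.edges())

    def test_degree_multiset_preserved_before_pruning(self, random_test_net):
        rnd, diag = randomize_network(random_test_net, seed=1, prune=False)
        assert sorted(d for _, d in rnd.degree()) == sorted(
            d for _, d in random_test_net.degree()
        )
        assert rnd.number_of_edges() == random_test_net.number_of_edges()

    def test_edge_count_accounting(self, random_test_net):
        _, diag = randomize_network(random_test_net, seed=1)
        assert diag.n_edges_out == diag.n_edges_in - diag.removed_original_edges
        assert diag.residual_original_overlap == 0

    def test_no_original_edges_after_pruning(self, random_test_net):
        rnd, _ = randomize_network(random_test_net, seed=2)
        assert not any(random_test_net.has_edge(*e) for e in rnd.edges())

    def test_no_self_loops_or_duplicates(self, random_test_net):
        rnd, _ = randomize_network(random_test_net, seed=3)
        assert not list(nx.selfloop_edges(rnd))

    def test_node_set_preserved(self, random_test_net):
        rnd, _ = randomize_network(random_test_net, seed=4)
        assert set(rnd.nodes()) == set(random_test_net.nodes())

    def test_pruning_loss_small_on_sparse_graph(self, random_test_net):
        losses = []
        for seed in range(5):
            _, diag = randomize_network(random_test_net, seed=seed)
            losses.append(diag.removed_original_edges / diag.n_edges_in)
        assert max(losses) < 0.05

    def test_self_loop_input_rejected(self):
        g = nx.Graph()
        g.add_edge("a", "a")
        with pytest.raises(ValueError):
            validate_network(g)


class TestPairRecords:
    def test_missing_halflife_excluded(self, toy_net):
        hl = HalfLifeTable({"a": 10, "b": 9})  # others missing
        records = build_pair_records(toy_net, hl)
        assert [r.pair for r in records] == [("a", "b")]

    def test_toy_category_counts_match_hand_tabulation(self, toy_net):
        hl = HalfLifeTable({"a": 100, "b": 95, "c": 60, "d": 58, "e": 20, "f": 99})
        records = build_pair_records(toy_net, hl)
        cats = {r.pair: r.category for r in records}
        # hand: a-b 0.95 S; b-c 0.631 D; c-d 0.967 S; d-e 0.345 VD;
        #       a-f 0.99 S; c-f 0.606 D
        assert cats[("a", "b")] is RatioCategory.SIMILAR
        assert cats[("b", "c")] is RatioCategory.DIFFERENT
        assert cats[("c", "d")] is RatioCategory.SIMILAR
        assert cats[("d", "e")] is RatioCategory.VERY_DIFFERENT
        assert cats[("a", "f")] is RatioCategory.SIMILAR
        assert cats[("c", "f")] is RatioCategory.DIFFERENT
        fr = category_fractions(records)
        assert fr[RatioCategory.SIMILAR] == pytest.approx(3 / 6)

    def test_annotations_optional(self, toy_net):
        hl = HalfLifeTable({n: 10.0 for n in toy_net.nodes()})
        semsim = {frozenset(("a", "b")): 0.9}
        records = build_pair_records(toy_net, hl, semsim=semsim)
        by_pair = {r.pair: r for r in records}
        assert by_pair[("a", "b")].semsim == 0.9
        assert by_pair[("b", "c")].semsim is None


class TestRatioEnvelope:
    def test_equal_halflives_all_mass_at_one(self, random_test_net):
        hl = HalfLifeTable({n: 42.0 for n in random_test_net.nodes()})
        env = ratio_distribution_vs_random(random_test_net, hl, n_random=3, seed=0)
        assert env.observed_similar_fraction == pytest.approx(1.0)
        assert env.observed[-1] == pytest.approx(1.0)

    def test_random_envelope_matches_shuffled_baseline(self, random_test_net):
        rng = np.random.default_rng(1)
        hl = HalfLifeTable(
            {n: float(v) for n, v in zip(sorted(random_test_net.nodes()),
                                         rng.lognormal(4, 0.6, 200))}
        )
        env = ratio_distribution_vs_random(random_test_net, hl, n_random=5, seed=0)
        # with i.i.d. half-lives the real network is itself a null draw:
        # its similar fraction must sit within ~3 sd of the random envelope
        z = abs(env.observed_similar_fraction - env.random_similar_mean)
        assert z < 3 * max(env.random_similar_sd, 0.01) + 0.05


class TestPathProfile:
    def test_distance_one_equals_edge_records(self, toy_net):
        rng = np.random.default_rng(2)
        hl = HalfLifeTable(
            {n: float(v) for n, v in zip(sorted(toy_net.nodes()), rng.lognormal(3, 0.5, 6))}
        )
        profile = shortest_path_ratio_profile(toy_net, hl)
        records = build_pair_records(toy_net, hl)
        assert sorted(profile["1"]) == pytest.approx(
            sorted(r.half_life_ratio for r in records)
        )

    def test_star_graph_leaf_pairs_at_distance_two(self):
        g = nx.star_graph(5)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes()})
        hl = HalfLifeTable({n: 10.0 for n in g.nodes()})
        profile = shortest_path_ratio_profile(g, hl)
        assert len(profile["1"]) == 5      # hub-leaf edges
        assert len(profile["2"]) == 10     # leaf-leaf pairs


class TestDegronons:
    def _chain(self, n=7):
        nodes = [f"m{i}" for i in range(n)]
        g = nx.Graph()
        for u, v in zip(nodes, nodes[1:]):
            g.add_edge(u, v)
        return g, nodes

    def test_planted_chain_detected_with_unit_ratios(self):
        g, nodes = self._chain(7)
        hl = HalfLifeTable({n: 50.0 for n in nodes})
        semsim = {frozenset((a, b)): 1.0 for a in nodes for b in nodes if a != b}
        degs, _, high = detect_degronons(g, hl, semsim)
        assert any(d.members == nodes for d in degs)
        best = next(d for d in degs if d.members == nodes)
        assert best.length == 6
        assert all(r == pytest.approx(1.0) for r in best.ratio_vs_first)

    def test_member_below_cutoff_excludes_path(self):
        g, nodes = self._chain(7)
        hl = HalfLifeTable({n: 50.0 for n in nodes})
        semsim = {frozenset((a, b)): 1.0 for a in nodes for b in nodes if a != b}
        semsim[frozenset((nodes[0], nodes[3]))] = 0.59
        degs, _, _ = detect_degronons(g, hl, semsim)
        assert not any(d.members == nodes for d in degs)

    def test_missing_semsim_excludes_quietly(self):
        g, nodes = self._chain(7)
        hl = HalfLifeTable({n: 50.0 for n in nodes})
        semsim = {frozenset((a, b)): 1.0 for a in nodes for b in nodes if a != b}
        del semsim[frozenset((nodes[0], nodes[3]))]
        degs, _, _ = detect_degronons(g, hl, semsim)
        assert not any(d.members == nodes for d in degs)

    def test_reverse_paths_dedupe_to_one_member_set(self):
        g, nodes = self._chain(7)
        hl = HalfLifeTable({n: 50.0 for n in nodes})
        semsim = {frozenset((a, b)): 1.0 for a in nodes for b in nodes if a != b}
        degs, _, _ = detect_degronons(g, hl, semsim)
        full = [d for d in degs if set(d.members) == set(nodes)]
        assert len(full) == 2  # forward and reverse ordered paths
        assert len(dedupe_member_sets(full)) == 1

    def test_recovery_on_default_synthetic_network(self):
        from degronon.synth import (
            SynthConfig,
            gen_codegradation_network,
            module_semsim_table,
        )

        cfg = SynthConfig(seed=3)
        net, hl, _, truth = gen_codegradation_network(cfg)
        semsim = module_semsim_table(cfg, truth)
        degs, _, _ = detect_degronons(net, hl, semsim)
        degs = dedupe_member_sets(degs)
        mm = truth.module_membership
        inside = [
            len({mm[x] for x in d.members}) == 1 and mm[d.members[0]] != ""
            for d in degs
        ]
        assert degs and all(inside)  # precision 1: no background degronons
        covered = {mm[d.members[0]] for d in degs}
        planted = {mm[p[0]] for p in truth.planted_degronon_paths}
        assert covered == planted  # every planted module recovered


class TestDegreeHalflife:
    def test_independent_halflives_uncorrelated(self):
        g = nx.gnm_random_graph(1000, 3000, seed=1)
        g = nx.relabel_nodes(g, {i: f"n{i:04d}" for i in g.nodes()})
        rng = np.random.default_rng(0)
        hl = HalfLifeTable(
            {n: float(v) for n, v in zip(sorted(g.nodes()), rng.lognormal(4, 0.6, 1000))}
        )
        out = degree_halflife_correlation(g, hl)
        r, _, n = out["degree"]
        assert n == 1000
        assert abs(r) < 0.1

    def test_constructed_monotone_gives_r_near_one(self):
        g = nx.Graph()
        # path graph with strictly increasing degrees is hard; use a graph
        # where half-life is proportional to degree
        g.add_edges_from([("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("e", "a")])
        hl = HalfLifeTable({n: float(g.degree(n)) for n in g.nodes()})
        r, _, _ = degree_halflife_correlation(g, hl)["degree"]
        assert r == pytest.approx(1.0)

    def test_mean_partner_abundance_matches_hand_average(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("a", "c")])
        hl = HalfLifeTable({"a": 10, "b": 20, "c": 30})
        ab = {"a": 100.0, "b": 10.0, "c": 30.0}
        out = degree_halflife_correlation(g, hl, abundances=ab)
        assert "mean_partner_abundance" in out
        # hand: mean partner abundance a=(10+30)/2=20, b=100, c=100
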