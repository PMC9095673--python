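"""Synthetic-data generator: construction guarantees, seed determinism and
ground-truth consistency with the downstream analyses."""

import numpy as np
import pytest

from degronon.masking import (
    DegronClass,
    Relation,
    classify_region_relation,
    infer_tertiary_degron,
)
from degronon.semsim import GoDag, PairwiseSemSim, filter_annotations
from degronon.synth import (
    SynthConfig,
    gen_abundance_datasets,
    gen_codegradation_network,
    gen_go_dag_and_annotations,
    gen_interaction_records,
    gen_regulatory_modules,
    gen_substrates_with_degrons,
)


class TestConfigValidation:
    def test_counts_must_be_positive(self):
        with pytest.raises(ValueError):
            SynthConfig(n_substrates=0)

    def test_fractions_bounded(self):
        with pytest.raises(ValueError):
            SynthConfig(masking_fraction=1.5)

    def test_module_size_at_least_two(self):
        with pytest.raises(ValueError):
            SynthConfig(module_size=1)

    def test_fold_greater_than_one(self):
        with pytest.raises(ValueError):
            SynthConfig(e3_ap_fold=0.5)


class TestSubstrates:
    def test_construction_guarantees(self):
        cfg = SynthConfig(seed=1, n_substrates=5)
        seqs, degrons, profiles = gen_substrates_with_degrons(cfg)
        assert len(seqs) == 5
        by_class = {}
        for d in degrons:
            by_class.setdefault(d.degron_class, []).append(d)
        assert len(by_class[DegronClass.PRIMARY]) == 5
        assert len(by_class[DegronClass.SECONDARY]) >= 5
        for sid, seq in seqs.items():
            assert 200 <= len(seq) <= 800
            assert len(profiles[sid]) == len(seq)
            assert all(0.0 <= s <= 1.0 for s in profiles[sid])
        for d in by_class[DegronClass.PRIMARY]:
            assert 6 <= len(d.region) <= 14
            assert d.sequence == seqs[d.region.protein_id][d.region.start - 1 : d.region.end]
        for d in by_class[DegronClass.SECONDARY]:
            assert seqs[d.region.protein_id][d.ubsite_position - 1] == "K"

    def test_seed_determinism(self):
        cfg = SynthConfig(seed=11, n_substrates=4)
        out1 = gen_substrates_with_degrons(cfg)
        out2 = gen_substrates_with_degrons(SynthConfig(seed=11, n_substrates=4))
        assert out1[0] == out2[0]
        assert out1[1] == out2[1]
        assert out1[2] == out2[2]

    def test_tertiary_roundtrip_through_inference(self):
        """The inference applied to the generated profile must return exactly
        the planted tertiary degron."""
        cfg = SynthConfig(seed=5, n_substrates=20)
        _, degrons, profiles = gen_substrates_with_degrons(cfg)
        tert = {d.region.protein_id: d for d in degrons if d.degron_class is DegronClass.TERTIARY}
        ubsites = {
            d.region.protein_id: d.ubsite_position
            for d in degrons
            if d.degron_class is DegronClass.SECONDARY
        }
        for sid, d in tert.items():
            got = infer_tertiary_degron(profiles[sid], ubsites[sid], protein_id=sid)
            assert got is not None
            assert (got.start, got.end) == (d.region.start, d.region.end)


class TestInteractions:
    def test_zero_masking_fraction(self):
        cfg = SynthConfig(seed=2, n_substrates=4, masking_fraction=0.0)
        seqs, degrons, _ = gen_substrates_with_degrons(cfg)
        _, pairs, _ = gen_interaction_records(cfg, seqs, degrons)
        assert pairs == set()

    def test_full_masking_clean_recovery(self):
        cfg = SynthConfig(
            seed=2,
            n_substrates=4,
            masking_fraction=1.0,
            low_confidence_fraction=0.0,
            ups_partner_fraction=0.0,
        )
        seqs, degrons, _ = gen_substrates_with_degrons(cfg)
        records, pairs, ups = gen_interaction_records(cfg, seqs, degrons)
        assert ups == set()
        assert len(pairs) == len(records)
        # every planted feature genuinely overlaps/abuts a degron
        by_sub = {}
        for d in degrons:
            by_sub.setdefault(d.region.protein_id, []).append(d)
        for r in records:
            assert any(
                classify_region_relation(d.region, f.region)[0] is not Relation.NONE
                for f in r.binding_features()
                for d in by_sub[r.substrate_id]
            )

    def test_low_confidence_pairs_excluded_from_truth(self):
        cfg = SynthConfig(seed=3, n_substrates=10, masking_fraction=1.0,
                          low_confidence_fraction=0.5, ups_partner_fraction=0.0)
        seqs, degrons, _ = gen_substrates_with_degrons(cfg)
        records, pairs, _ = gen_interaction_records(cfg, seqs, degrons)
        low = {(r.substrate_id, r.partner_id) for r in records if r.confidence < 0.3}
        assert low  # the mixture planted some
        assert not (pairs & low)

    def test_masking_count_within_binomial_band(self):
        # masking_fraction=0.5 with 20 partners per substrate: the per-substrate
        # masking count should sit within the binomial 99% band around 10
        cfg = SynthConfig(seed=4, n_substrates=30, n_partners_per_substrate=20,
                          masking_fraction=0.5, low_confidence_fraction=0.0,
                          ups_partner_fraction=0.0)
        seqs, degrons, _ = gen_substrates_with_degrons(cfg)
        _, pairs, _ = gen_interaction_records(cfg, seqs, degrons)
        from scipy import stats

        lo, hi = stats.binom.ppf([0.005, 0.995], 20, 0.5)
        counts = {}
        for sid, _ in pairs:
            counts[sid] = counts.get(sid, 0) + 1
        in_band = sum(1 for sid in seqs if lo <= counts.get(sid, 0) <= hi)
        assert in_band >= 27  # a rare outlier substrate is tolerated


class TestGoGenerator:
    def test_dag_is_acyclic_and_rooted(self, small_cfg):
        terms, edges, ns, _ = gen_go_dag_and_annotations(small_cfg)
        dag = GoDag(terms, edges, ns)  # constructor asserts acyclicity
        root = "GO:0000001"
        for t in dag.terms:
            if t != root:
                assert root in dag.ancestors(t)

    def test_identical_term_sets_similarity_one(self, small_cfg):
        terms, edges, ns, ann = gen_go_dag_and_annotations(small_cfg)
        dag = GoDag(terms, edges, ns)
        filtered = filter_annotations(ann, dag)
        g1, g2 = "M00_00", "M00_01"  # same module -> same shared terms
        assert filtered[g1] == filtered[g2]
        calc = PairwiseSemSim(filtered, dag)
        assert calc.gene_sim(g1, g2) == pytest.approx(1.0)

    def test_within_module_exceeds_background_similarity(self, small_cfg):
        terms, edges, ns, ann = gen_go_dag_and_annotations(small_cfg)
        dag = GoDag(terms, edges, ns)
        filtered = filter_annotations(ann, dag)
        calc = PairwiseSemSim(filtered, dag)
        within = [
            calc.gene_sim(f"M00_{i:02d}", f"M00_{j:02d}")
            for i in range(small_cfg.module_size)
            for j in range(i + 1, small_cfg.module_size)
        ]
        rng = np.random.default_rng(0)
        bg = []
        for _ in range(50):
            i, j = rng.choice(small_cfg.n_background, size=2, replace=False)
            s = calc.gene_sim(f"B{i:04d}", f"B{j:04d}")
            if s is not None:
                bg.append(s)
        assert np.mean(within) > np.mean(bg)

    def test_ups_branch_annotates_flagged_partners(self, small_cfg):
        from degronon.synth import UPS_ROOT_TERM

        terms, edges, ns, ann = gen_go_dag_and_annotations(
            small_cfg, ups_partners=["P_X"]
        )
        dag = GoDag(terms, edges, ns)
        ups_terms = dag.descendants(UPS_ROOT_TERM) | {UPS_ROOT_TERM}
        px_terms = {t for g, t, c in ann if g == "P_X"}
        assert px_terms and px_terms <= ups_terms


class TestAbundanceGenerator:
    def test_every_dataset_sums_to_a_million(self, small_cfg):
        roles = {"s1": "substrate", "e1": "e3", "a1": "ap"}
        datasets = gen_abundance_datasets(small_cfg, roles)
        for ds in datasets:
            assert sum(ds.abundances.values()) == pytest.approx(1e6, abs=1.0)

    def test_fold_effect_recovered(self):
        cfg = SynthConfig(seed=6, n_datasets=50)
        roles = {}
        for i in range(20):
            roles[f"s{i}"] = "substrate"
            roles[f"e{i}"] = "e3"
            roles[f"a{i}"] = "ap"
        datasets = gen_abundance_datasets(cfg, roles)
        e3 = [ds.abundances[p] for ds in datasets for p, r in roles.items() if r == "e3"]
        ap = [ds.abundances[p] for ds in datasets for p, r in roles.items() if r == "ap"]
        fold = np.median(ap) / np.median(e3)
        assert 5 <= fold <= 20

    def test_null_roles_give_uniform_pvalues(self):
        """With equal role medians the Mann-Whitney P between substrate and E3
        pools is uniform (KS calibration over 100 seeds)."""
        from scipy import stats

        from degronon.stats import two_group_test

        pvals = []
        roles = {**{f"s{i}": "substrate" for i in range(8)},
                 **{f"e{i}": "e3" for i in range(8)}}
        for seed in range(100):
            cfg = SynthConfig(
                seed=seed,
                n_datasets=3,
                substrate_e3_latent_sd=0.0,
                role_median_log_ppm={"substrate": 1.5, "e3": 1.5, "ap": 1.5},
            )
            datasets = gen_abundance_datasets(cfg, roles, n_background_proteins=50)
            x = [ds.abundances[p] for ds in datasets for p, r in roles.items() if r == "substrate"]
            y = [ds.abundances[p] for ds in datasets for p, r in roles.items() if r == "e3"]
            pvals.append(two_group_test(x, y)[1])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestCodegradationNetwork:
    def test_no_self_loops_or_duplicate_edges(self):
        import networkx as nx

        cfg = SynthConfig(seed=7)
        net, _, _, _ = gen_codegradation_network(cfg)
        assert not list(nx.selfloop_edges(net))

    def test_planted_pairs_have_similar_halflives(self):
        cfg = SynthConfig(seed=8)  # CV = 0.05
        net, hl, _, truth = gen_codegradation_network(cfg)
        ratios = []
        for path in truth.planted_degronon_paths:
            for u, v in zip(path, path[1:]):
                t1, t2 = hl.values[u], hl.values[v]
                ratios.append(min(t1, t2) / max(t1, t2))
        assert np.mean(np.asarray(ratios) >= 0.8) >= 0.8

    def test_background_pairs_ratio_median_well_below_similar(self):
        cfg = SynthConfig(seed=9)
        net, hl, _, truth = gen_codegradation_network(cfg)
        rng = np.random.default_rng(1)
        bg = [n for n, m in truth.module_membership.items() if m == ""]
        ratios = []
        for _ in range(2000):
            i, j = rng.choice(len(bg), size=2, replace=False)
            t1, t2 = hl.values[bg[i]], hl.values[bg[j]]
            ratios.append(min(t1, t2) / max(t1, t2))
        assert np.median(ratios) < 0.7

    def test_planted_paths_lie_inside_modules(self):
        cfg = SynthConfig(seed=10)
        _, _, _, truth = gen_codegradation_network(cfg)
        assert len(truth.planted_degronon_paths) == cfg.n_modules
        for path in truth.planted_degronon_paths:
            assert len(path) == cfg.module_size
            mods = {truth.module_membership[n] for n in path}
            assert len(mods) == 1 and "" not in mods

    def test_coexpression_separates_modules_from_background(self):
        cfg = SynthConfig(seed=12)
        net, _, coexpr, truth = gen_codegradation_network(cfg)
        mm = truth.module_membership
        within, bg = [], []
        for key, r in coexpr.items():
            a, b = tuple(key)
            if mm.get(a) and mm.get(a) == mm.get(b):
                within.append(r)
            elif mm.get(a) == "" and mm.get(b) == "":
                bg.append(r)
        assert np.mean(within) > 0.6
        assert abs(np.mean(bg)) < 0.2
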