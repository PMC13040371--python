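import numpy as np
import pandas as pd
import pytest

from helpers import best_match_jaccard
from pidsle.gene_db import GeneSet
from pidsle.overlap import hypergeometric_overlap
from pidsle.ppi import find_complexes
from pidsle.scoring import gsva_scores
from pidsle.synthetic import (
    SimulationConfig,
    generate_expression_cohort,
    generate_gene_universe,
    generate_ppi_graph,
    generate_risk_set,
)


def small_config(**overrides):
    defaults = dict(
        n_genes=400, n_pid=60, n_categories=6, n_patients=60, n_controls=20,
        module_sizes=[15], effect_size_per_module=[1.0], seed=0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_pid_larger_than_universe_rejected(self):
        with pytest.raises(ValueError, match="n_pid"):
            small_config(n_pid=500)

    def test_modules_exceeding_pid_rejected(self):
        with pytest.raises(ValueError, match="module_sizes"):
            small_config(module_sizes=[40, 40], effect_size_per_module=[1, 1])

    def test_probability_ordering_enforced(self):
        with pytest.raises(ValueError, match="p_between"):
            small_config(p_within=0.1, p_between=0.5)


class TestGeneUniverse:
    def test_pid_count_and_uniqueness(self):
        u = generate_gene_universe(small_config())
        assert len(u) == 400
        assert len(set(u.symbols)) == 400
        assert len(u.pid_genes()) == 60

    def test_zero_pid_supported(self):
        u = generate_gene_universe(small_config(n_pid=0, module_sizes=[]))
        assert len(u.pid_genes()) == 0

    def test_deterministic_for_fixed_seed(self):
        a = generate_gene_universe(small_config(seed=5))
        b = generate_gene_universe(small_config(seed=5))
        pd.testing.assert_frame_equal(a.records, b.records)
        c = generate_gene_universe(small_config(seed=6))
        assert not a.records.equals(c.records)

    def test_each_gene_has_one_category(self):
        u = generate_gene_universe(small_config())
        assert u.records["functional_category"].notna().all()
        assert u.records["functional_category"].str.startswith("C").all()


class TestRiskSet:
    def test_exhaustive_draw_contains_all_pid(self):
        u = generate_gene_universe(small_config())
        rs = generate_risk_set(u, set_size=400, pid_enrichment_odds=1.0, seed=0)
        assert len(rs.symbols & u.pid_genes().symbols) == 60

    def test_infinite_odds_limit_is_all_pid(self):
        u = generate_gene_universe(small_config())
        rs = generate_risk_set(u, set_size=50, pid_enrichment_odds=1e12, seed=0)
        assert rs.symbols <= u.pid_genes().symbols

    def test_oversized_draw_rejected(self):
        u = generate_gene_universe(small_config())
        with pytest.raises(ValueError, match="set_size"):
            generate_risk_set(u, set_size=401)

    def test_null_overlap_is_hypergeometric(self):
        """At odds = 1 the PID overlap of drawn sets matches the closed-form
        null: the standardized overlap has mean ~0 and sd ~1 over 200
        replicate draws."""
        u = generate_gene_universe(small_config())
        pid = u.pid_genes().symbols
        closed = hypergeometric_overlap(400, 60, 80, 0)
        zs = []
        for rep in range(200):
            rs = generate_risk_set(u, 80, pid_enrichment_odds=1.0, seed=rep)
            k = len(rs.symbols & pid)
            zs.append((k - closed.mean) / closed.sd)
        assert abs(np.mean(zs)) < 0.2
        assert 0.8 < np.std(zs, ddof=1) < 1.2

    def test_pid_fraction_increases_with_odds(self):
        u = generate_gene_universe(small_config())
        pid = u.pid_genes().symbols

        def mean_overlap(odds):
            return np.mean([
                len(generate_risk_set(u, 80, odds, seed=rep).symbols & pid)
                for rep in range(40)
            ])

        overlaps = [mean_overlap(o) for o in (1.0, 3.0, 10.0)]
        assert overlaps[0] < overlaps[1] < overlaps[2]


class TestPPIGraph:
    def test_deterministic_limit_two_triangles(self):
        u = generate_gene_universe(small_config())
        genes = sorted(u.pid_genes().symbols)[:6]
        assignment = {g: ("m1" if i < 3 else "m2") for i, g in enumerate(genes)}
        g = generate_ppi_graph(u, assignment, p_within=1.0, p_between=0.0, seed=0)
        comps = [set(c) for c in __import__("networkx").connected_components(g)]
        assert sorted(map(len, comps)) == [3, 3]
        assert g.number_of_edges() == 6

    def test_unknown_gene_rejected(self):
        u = generate_gene_universe(small_config())
        with pytest.raises(ValueError, match="outside universe"):
            generate_ppi_graph(u, {"NOPE": "m1"}, 0.5, 0.1)

    def test_no_self_loops_and_deterministic(self):
        u = generate_gene_universe(small_config())
        genes = sorted(u.pid_genes().symbols)[:30]
        assignment = {g: None for g in genes}
        g1 = generate_ppi_graph(u, assignment, 0.3, 0.3, seed=4)
        g2 = generate_ppi_graph(u, assignment, 0.3, 0.3, seed=4)
        assert set(g1.edges) == set(g2.edges)
        assert all(a != b for a, b in g1.edges)

    def test_uniform_probabilities_give_chance_level_recovery(self):
        """When p_within = p_between the planted labels carry no signal:
        recovered clusters match the planted module no better than a
        permuted relabelling of the same nodes."""
        rng = np.random.default_rng(11)
        diffs = []
        for seed in range(5):
            u = generate_gene_universe(small_config(seed=seed))
            genes = sorted(u.pid_genes().symbols)
            assignment = {g: ("m1" if i < 15 else None)
                          for i, g in enumerate(genes)}
            g = generate_ppi_graph(u, assignment, 0.15, 0.15, seed=seed)
            clusters = find_complexes(g)
            planted = {gg for gg, m in assignment.items() if m == "m1"}
            permuted = set(rng.choice(genes, size=15, replace=False))
            diffs.append(
                best_match_jaccard(planted, clusters)
                - best_match_jaccard(permuted, clusters)
            )
        assert abs(np.mean(diffs)) < 0.1


class TestExpressionCohort:
    def test_shapes_labels_and_determinism(self):
        cfg = small_config()
        u = generate_gene_universe(cfg)
        module = GeneSet.from_symbols("m1", sorted(u.pid_genes().symbols)[:15])
        a = generate_expression_cohort(cfg, [module])
        b = generate_expression_cohort(cfg, [module])
        assert a.matrix.shape == (400, 80)
        assert (a.clinical["cohort"] == "control").sum() == 20
        pd.testing.assert_frame_equal(a.matrix, b.matrix)
        pd.testing.assert_frame_equal(a.clinical, b.clinical)

    def test_controls_are_inactive_with_zero_sledai(self):
        cfg = small_config()
        u = generate_gene_universe(cfg)
        module = GeneSet.from_symbols("m1", sorted(u.pid_genes().symbols)[:15])
        cohort = generate_expression_cohort(cfg, [module])
        controls = cohort.clinical[cohort.clinical["cohort"] == "control"]
        assert (controls["sledai"] == 0).all()
        assert (controls["activity_class"] == "inactive").all()

    def test_activity_class_is_pure_function_of_sledai(self):
        cfg = small_config(n_patients=200, n_controls=0)
        u = generate_gene_universe(cfg)
        module = GeneSet.from_symbols("m1", sorted(u.pid_genes().symbols)[:15])
        clin = generate_expression_cohort(cfg, [module]).clinical
        assert (
            (clin["sledai"] >= 6) == (clin["activity_class"] == "active")
        ).all()

    def test_module_gene_outside_universe_rejected(self):
        cfg = small_config()
        with pytest.raises(ValueError, match="not in universe"):
            generate_expression_cohort(cfg, [GeneSet.from_symbols("m", ["ZZZ9"])])

    def test_clinical_trait_directions(self):
        cfg = small_config(n_patients=500, n_controls=0, n_genes=50, n_pid=20,
                           module_sizes=[5])
        u = generate_gene_universe(cfg)
        module = GeneSet.from_symbols("m1", sorted(u.pid_genes().symbols)[:5])
        clin = generate_expression_cohort(cfg, [module]).clinical
        assert clin["sledai"].corr(clin["anti_dsdna"]) > 0
        assert clin["sledai"].corr(clin["c3"]) < 0
        assert clin["sledai"].corr(clin["c4"]) < 0

    def test_noiseless_limit_separates_cohorts_perfectly(self):
        cfg = small_config(noise_sd=0.0)
        u = generate_gene_universe(cfg)
        module = GeneSet.from_symbols("m1", sorted(u.pid_genes().symbols)[:15])
        cohort = generate_expression_cohort(cfg, [module])
        controls = cohort.clinical.index[cohort.clinical["cohort"] == "control"]
        patients = cohort.clinical.index[cohort.clinical["cohort"] == "SLE"]
        sub = cohort.matrix.loc[sorted(module.symbols)]
        assert (sub[patients].min(axis=1) > sub[controls].max(axis=1)).all()

    def test_null_effect_type_one_rate(self):
        """With all effects zero the DE stage calls ~5% of genes at p<=0.05."""
        from pidsle.de import moderated_t
        cfg = small_config(n_genes=1000, n_pid=60, n_patients=50, n_controls=50,
                           effect_size_per_module=[0.0])
        u = generate_gene_universe(cfg)
        module = GeneSet.from_symbols("m1", sorted(u.pid_genes().symbols)[:15])
        cohort = generate_expression_cohort(cfg, [module])
        res = moderated_t(cohort, ("SLE", "control"))
        rate = (res["p"] <= 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_module_score_dose_response_monotone(self):
        """Mean module-score gap (active - control) is non-decreasing in the
        planted effect size, at three effect levels."""
        gaps = []
        for effect in (0.0, 0.5, 1.0):
            reps = []
            for seed in range(6):
                cfg = small_config(
                    n_genes=200, n_pid=30, n_patients=40, n_controls=20,
                    module_sizes=[15], effect_size_per_module=[effect],
                    seed=seed,
                )
                u = generate_gene_universe(cfg)
                module = GeneSet.from_symbols(
                    "m1", sorted(u.pid_genes().symbols)[:15]
                )
                cohort = generate_expression_cohort(cfg, [module])
                scores = gsva_scores(cohort, [module]).scores.iloc[0]
                active = cohort.clinical.index[
                    cohort.clinical["activity_class"] == "active"
                ]
                controls = cohort.clinical.index[
                    cohort.clinical["cohort"] == "control"
                ]
                reps.append(scores[active].mean() - scores[controls].mean())
            gaps.append(np.mean(reps))
        assert gaps[0] <= gaps[1] <= gaps[2]
        assert gaps[2] > 0.3
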