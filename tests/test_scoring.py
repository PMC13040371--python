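import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from conftest import make_cohort
from helpers import gsva_oracle
from pidsle.gene_db import GeneSet
from pidsle.scoring import (
    ModuleScoreMatrix,
    ScoringParams,
    clinical_anova,
    effect_sizes,
    gsva_scores,
    hedges_g,
    hierarchical_stratify,
)


def small_cohort(rng, n_genes=6, n_samples=5):
    return make_cohort(rng.normal(7, 1, size=(n_genes, n_samples)),
                       n_samples - 2, 2)


class TestGsvaScores:
    def test_matches_literal_oracle_on_fixture(self, rng):
        """Main implementation equals an independent loop-based
        transcription of the kernel-ECDF/rank/random-walk recipe."""
        cohort = small_cohort(np.random.default_rng(7))
        module = GeneSet.from_symbols("m1", ["G0000", "G0002", "G0005"])
        for statistic in ("diff_of_extremes", "max_deviation"):
            mine = gsva_scores(
                cohort, [module], ScoringParams(statistic=statistic)
            ).scores.iloc[0].to_numpy()
            oracle = gsva_oracle(cohort.matrix, set(module.symbols),
                                 statistic=statistic)
            assert np.abs(mine - np.array(oracle)).max() < 1e-10

    def test_matches_oracle_with_tau_and_bandwidth(self):
        rng = np.random.default_rng(123)
        cohort = make_cohort(rng.normal(0, 2, size=(9, 7)), 4, 3)
        module = GeneSet.from_symbols("m", ["G0001", "G0004", "G0007", "G0008"])
        params = ScoringParams(kernel_bandwidth_factor=0.5, tau=2.0)
        mine = gsva_scores(cohort, [module], params).scores.iloc[0].to_numpy()
        oracle = gsva_oracle(cohort.matrix, set(module.symbols),
                             bw_factor=0.5, tau=2.0)
        assert np.abs(mine - np.array(oracle)).max() < 1e-10

    def test_gene_row_order_invariance(self, rng):
        cohort = small_cohort(rng, n_genes=12, n_samples=6)
        module = GeneSet.from_symbols("m", ["G0001", "G0003", "G0007"])
        base = gsva_scores(cohort, [module]).scores
        perm = rng.permutation(12)
        shuffled_matrix = cohort.matrix.iloc[perm]
        shuffled = make_cohort(shuffled_matrix.to_numpy(), 4, 2)
        shuffled.matrix.index = shuffled_matrix.index
        out = gsva_scores(shuffled, [module]).scores
        assert np.allclose(base.to_numpy(), out.to_numpy())

    def test_sample_permutation_equivariance(self, rng):
        cohort = small_cohort(rng, n_genes=10, n_samples=6)
        module = GeneSet.from_symbols("m", ["G0000", "G0004"])
        base = gsva_scores(cohort, [module]).scores
        perm = rng.permutation(6)
        permuted = cohort.matrix.iloc[:, perm]
        shuffled = make_cohort(permuted.to_numpy(), 4, 2)
        shuffled.matrix.index = cohort.matrix.index
        out = gsva_scores(shuffled, [module]).scores
        assert np.allclose(base.to_numpy()[:, perm], out.to_numpy())

    def test_scores_bounded(self, rng):
        for _ in range(20):
            n_genes = int(rng.integers(5, 25))
            n_samples = int(rng.integers(3, 10))
            cohort = make_cohort(rng.normal(0, 1, (n_genes, n_samples)),
                                 n_samples - 2, 2)
            size = int(rng.integers(1, n_genes - 1))
            module = GeneSet.from_symbols("m", cohort.genes[:size])
            s = gsva_scores(cohort, [module]).scores.to_numpy()
            assert np.all(s >= -1.0 - 1e-12) and np.all(s <= 1.0 + 1e-12)

    def test_degenerate_module_rejected(self, rng):
        cohort = small_cohort(rng)
        with pytest.raises(ValueError, match="degenerate"):
            gsva_scores(cohort, [GeneSet.from_symbols("all", cohort.genes)])

    def test_too_few_samples_rejected(self, rng):
        cohort = make_cohort(rng.normal(size=(6, 4)), 2, 2)
        tiny = make_cohort(cohort.matrix.to_numpy()[:, :2], 1, 1)
        with pytest.raises(ValueError, match="3 samples"):
            gsva_scores(tiny, [GeneSet.from_symbols("m", cohort.genes[:2])])

    def test_absent_genes_dropped_with_warning(self, rng):
        cohort = small_cohort(rng)
        module = GeneSet.from_symbols("m", ["G0000", "NOT_THERE"])
        with pytest.warns(UserWarning, match="absent"):
            out = gsva_scores(cohort, [module])
        assert out.scores.shape == (1, 5)


class TestEffectSizes:
    def test_identical_groups_give_zero(self):
        scores = ModuleScoreMatrix(pd.DataFrame(
            [[1.0, 2.0, 1.0, 2.0]], index=["m"], columns=list("abcd")
        ))
        out = effect_sizes(scores, (["a", "b"], ["c", "d"]))
        assert out.iloc[0]["hedges_g"] == pytest.approx(0.0)
        assert out.iloc[0]["welch_p"] == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # group1={2,4}, group2={1,3}: d=1/sqrt(2), J=1-3/7 -> g = 0.4041
        assert hedges_g([2, 4], [1, 3]) == pytest.approx(0.4041, abs=1e-4)

    def test_antisymmetric_under_group_swap(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(0.5, 1.2, 12)
        assert hedges_g(x, y) == pytest.approx(-hedges_g(y, x))

    def test_welch_p_invariant_under_swap(self, rng):
        scores = ModuleScoreMatrix(pd.DataFrame(
            rng.normal(0, 0.3, (3, 12)), index=list("XYZ"),
            columns=[f"s{i}" for i in range(12)]
        ))
        g1 = [f"s{i}" for i in range(6)]
        g2 = [f"s{i}" for i in range(6, 12)]
        a = effect_sizes(scores, (g1, g2))
        b = effect_sizes(scores, (g2, g1))
        assert np.allclose(a["welch_p"], b["welch_p"])
        assert np.allclose(a["hedges_g"], -b["hedges_g"])

    def test_zero_variance_flagged(self):
        scores = ModuleScoreMatrix(pd.DataFrame(
            [[0.5, 0.5, 0.5, 0.5]], index=["m"], columns=list("abcd")
        ))
        out = effect_sizes(scores, (["a", "b"], ["c", "d"]))
        assert out.iloc[0]["degenerate"]


class TestStratification:
    def test_k_one_single_cluster(self, rng):
        m = pd.DataFrame(rng.normal(size=(4, 6)),
                         columns=[f"s{i}" for i in range(6)])
        out = hierarchical_stratify(m, k=1)
        assert set(out.labels) == {1}

    def test_k_equals_samples_gives_singletons(self, rng):
        m = pd.DataFrame(rng.normal(size=(4, 5)),
                         columns=[f"s{i}" for i in range(5)])
        out = hierarchical_stratify(m, k=5)
        assert sorted(out.labels) == [1, 2, 3, 4, 5]

    def test_separated_blobs_recovered_exactly(self, rng):
        centers = np.array([0.0, 10.0, 20.0])
        truth = np.repeat([0, 1, 2], 10)
        data = centers[truth][None, :] + rng.normal(0, 1.0, size=(5, 30))
        m = pd.DataFrame(data, columns=[f"s{i:02d}" for i in range(30)])
        out = hierarchical_stratify(m, k=3)
        assert adjusted_rand_score(truth, out.labels.to_numpy()) == 1.0

    def test_duplicated_samples_keep_partition(self, rng):
        data = np.hstack([rng.normal(0, 1, (4, 6)), rng.normal(8, 1, (4, 6))])
        m = pd.DataFrame(data, columns=[f"s{i:02d}" for i in range(12)])
        base = hierarchical_stratify(m, k=2).labels
        doubled = pd.concat(
            [m, m.rename(columns=lambda c: c + "_dup")], axis=1
        )
        out = hierarchical_stratify(doubled, k=2).labels
        # partition restricted to the original samples is unchanged
        assert adjusted_rand_score(base, out[m.columns]) == 1.0

    def test_k_exceeding_samples_rejected(self, rng):
        m = pd.DataFrame(rng.normal(size=(3, 4)), columns=list("abcd"))
        with pytest.raises(ValueError):
            hierarchical_stratify(m, k=5)


class TestClinicalAnova:
    @staticmethod
    def _clinical(values_by_cluster, trait="sledai"):
        rows, labels = [], {}
        i = 0
        for cid, vals in enumerate(values_by_cluster, start=1):
            for v in vals:
                sid = f"s{i:03d}"
                rows.append({"sample": sid, trait: v, "cohort": "SLE"})
                labels[sid] = cid
                i += 1
        clin = pd.DataFrame(rows).set_index("sample")
        return pd.Series(labels), clin

    def test_equal_means_give_zero_f(self):
        labels, clin = self._clinical([[4, 6, 8], [4, 6, 8], [4, 6, 8]])
        out = clinical_anova(labels, clin, traits=["sledai"])
        row = out["anova"].iloc[0]
        assert row["F"] == pytest.approx(0.0)
        assert row["p"] == pytest.approx(1.0)

    def test_constant_trait_flagged(self):
        labels, clin = self._clinical([[5, 5, 5], [5, 5, 5]])
        out = clinical_anova(labels, clin, traits=["sledai"])
        row = out["anova"].iloc[0]
        assert row["constant"] and row["F"] == 0.0 and row["p"] == 1.0

    def test_two_cluster_tukey_matches_equal_var_t_test(self, rng):
        a = rng.normal(5, 2, 12).tolist()
        b = rng.normal(8, 2, 10).tolist()
        labels, clin = self._clinical([a, b])
        out = clinical_anova(labels, clin, traits=["sledai"])
        tukey_p = out["tukey"].iloc[0]["p_adj"]
        _, t_p = stats.ttest_ind(a, b, equal_var=True)
        assert tukey_p == pytest.approx(t_p, rel=1e-6)

    def test_controls_excluded(self):
        labels, clin = self._clinical([[2, 4, 6], [8, 10, 12]])
        extra = pd.DataFrame(
            {"sledai": [0, 0], "cohort": ["control", "control"]},
            index=["c1", "c2"],
        )
        clin2 = pd.concat([clin, extra])
        labels2 = pd.concat([labels, pd.Series({"c1": 1, "c2": 2})])
        base = clinical_anova(labels, clin, traits=["sledai"])
        with_controls = clinical_anova(labels2, clin2, traits=["sledai"])
        assert with_controls["anova"].iloc[0]["F"] == pytest.approx(
            base["anova"].iloc[0]["F"]
        )
        assert with_controls["cluster_stats"]["n"].sum() == 6

    def test_single_cluster_rejected(self):
        labels, clin = self._clinical([[1, 2, 3]])
        with pytest.raises(ValueError, match="2 clusters"):
            clinical_anova(labels, clin, traits=["sledai"])
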