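import numpy as np
import pytest
from scipy.stats import rankdata

from scgrn.synthetic_benchmarks import (SimConfig, apply_dropout,
                                        auc_recovery, coexpression_jaccard,
                                        null_fdr, simulate,
                                        train_test_prediction)


class TestSimulate:
    def test_sparsity_calibration(self):
        cfg = SimConfig(n_genes=300, n_cells=200, seed=3)
        ref, _ = simulate(cfg)
        degraded = apply_dropout(ref, 0.88, seed=4)
        assert 0.87 <= degraded.sparsity() <= 0.89

    def test_reference_hits_target_sparsity(self, sim_small):
        expr, _ = sim_small
        assert abs(expr.sparsity() - 0.03) < 0.01

    def test_deterministic(self):
        cfg = SimConfig(n_genes=100, n_cells=80, seed=9)
        e1, t1 = simulate(cfg)
        e2, t2 = simulate(cfg)
        np.testing.assert_array_equal(e1.dense(), e2.dense())
        np.testing.assert_array_equal(t1.true_pairs, t2.true_pairs)

    def test_coherent_module_pairs_all_true(self):
        """With full adherence and mild noise, every within-module pair
        passes the |Pearson| > 0.8 truth rule by construction."""
        cfg = SimConfig(n_genes=120, n_cells=200, n_modules=1,
                        module_size=10, module_adherence=(1.0, 1.0),
                        module_neg_frac=0.0, dispersion=50.0, de_fold=6.0,
                        seed=5)
        _, truth = simulate(cfg)
        genes = truth.module_genes[0]
        pairs = truth.true_pair_set()
        names = [f"G{g:04d}" for g in genes]
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                assert tuple(sorted((names[i], names[j]))) in pairs

    def test_unreachable_sparsity_errors(self):
        cfg = SimConfig(n_genes=100, n_cells=80, seed=1)
        ref, _ = simulate(cfg)
        degraded = apply_dropout(ref, 0.6, seed=2)
        with pytest.raises(ValueError, match="unreachable"):
            apply_dropout(degraded, 0.1, seed=3)

    def test_truth_recomputable_from_reference(self, sim_small):
        from scgrn.synthetic_benchmarks import reference_correlations
        _, truth = sim_small
        rho = reference_correlations(truth.reference)
        np.testing.assert_array_equal(np.abs(rho) > 0.8, truth.true_pairs)


class TestJaccard:
    def test_examples(self):
        from scgrn.data_model import ExpressionMatrix
        counts = np.zeros((3, 5))
        counts[0, [1, 2, 3]] = 1  # A in cells {1,2,3}
        counts[1, [2, 3, 4]] = 1  # B in cells {2,3,4}
        expr = ExpressionMatrix(["A", "B", "Z"], [f"c{i}" for i in range(5)],
                                counts)
        assert coexpression_jaccard(expr, "A", "B") == pytest.approx(0.5)
        assert coexpression_jaccard(expr, "A", "A") == 1.0
        assert coexpression_jaccard(expr, "A", "Z") == 0.0  # disjoint/empty

    def test_symmetric_and_bounded(self, sim_small):
        expr, _ = sim_small
        rng = np.random.default_rng(2)
        for _ in range(20):
            g1, g2 = rng.choice(expr.genes, 2, replace=False)
            j12 = coexpression_jaccard(expr, g1, g2)
            assert j12 == coexpression_jaccard(expr, g2, g1)
            assert 0.0 <= j12 <= 1.0


class TestNullFdr:
    def test_impossible_threshold_zero_fdr(self, homogeneous_expr):
        res = null_fdr(homogeneous_expr, [50, 50, 60], rho_thresh=1.01,
                       n_reps=2, seed=1)
        assert res["mean"] == 0.0

    def test_homogeneous_data_low_fdr(self, homogeneous_expr):
        """Random cluster assignments on structureless data yield well below
        0.5% of pairs above a typical adaptive threshold.

        Chance correlations shrink with the number of cluster-pair columns,
        so the null uses a cluster count comparable to a real recursive
        clustering, not a minimal one.
        """
        res = null_fdr(homogeneous_expr, [20] * 8, rho_thresh=0.9,
                       n_reps=3, seed=2)
        assert res["mean"] < 0.005
        assert len(res["fdr_per_rep"]) == 3

    def test_oversized_clusters_rejected(self, homogeneous_expr):
        with pytest.raises(ValueError, match="exceed"):
            null_fdr(homogeneous_expr, [1000, 1000], rho_thresh=0.9)


class TestTrainTest:
    def test_nesting_and_structure(self, sim_small):
        expr, _ = sim_small
        res = train_test_prediction(expr, split_seed=1, rho_train=0.8,
                                    rho_tests=(0.8, 0.6), min_size=30)
        assert res["n_train_pairs"] > 0
        assert res["fractions"][0.6] >= res["fractions"][0.8]
        assert res["background"][0.6] >= res["background"][0.8]

    def test_too_few_cells_rejected(self):
        from scgrn.data_model import ExpressionMatrix
        expr = ExpressionMatrix(["g0"], [f"c{i}" for i in range(10)],
                                np.ones((1, 10)))
        with pytest.raises(ValueError, match="halves"):
            train_test_prediction(expr)


class TestAucRecovery:
    def test_auc_equals_rank_statistic(self, rng):
        """Trapezoidal ROC AUC equals the tie-aware Mann-Whitney statistic."""
        from sklearn.metrics import roc_auc_score
        labels = rng.random(500) < 0.2
        scores = np.round(rng.random(500), 2)  # with ties
        ranks = rankdata(scores)
        n1 = labels.sum()
        n0 = len(labels) - n1
        u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
        assert roc_auc_score(labels, scores) == pytest.approx(u / (n1 * n0))

    def test_near_self_recovery(self, sim_small):
        expr, truth = sim_small
        auc = auc_recovery(truth, expr, seed=7, min_size=30)
        assert auc > 0.95

    def test_shuffled_scores_are_chance(self, sim_small, pipeline_small):
        _, truth = sim_small
        _, _, tab = pipeline_small
        from sklearn.metrics import roc_auc_score
        ref_genes = {g: i for i, g in enumerate(truth.reference.genes)}
        Gr = len(ref_genes)
        idx = np.array([ref_genes[g] for g in tab.genes])
        ii, jj = tab.pair_indices()
        lo = np.minimum(idx[ii], idx[jj])
        hi = np.maximum(idx[ii], idx[jj])
        flat = Gr * lo - lo * (lo + 1) // 2 + (hi - lo - 1)
        labels = truth.true_pairs[flat]
        rng = np.random.default_rng(1)
        shuffled = rng.permutation(np.abs(tab.rho_combined))
        assert 0.4 < roc_auc_score(labels, shuffled) < 0.6

    def test_empty_truth_rejected(self, sim_small):
        from copy import copy
        expr, truth = sim_small
        t2 = copy(truth)
        t2.true_pairs = np.zeros_like(truth.true_pairs)
        with pytest.raises(ValueError, match="no positive"):
            auc_recovery(t2, expr)

    def test_auc_degrades_with_sparsity_on_average(self):
        """Mean recovery over 10 seeds is non-increasing from moderate to
        extreme dropout."""
        def auc_or_chance(truth, degraded, seed):
            # a pipeline that cannot resolve cluster structure at extreme
            # sparsity recovers nothing: chance performance
            try:
                return auc_recovery(truth, degraded, seed=seed, min_size=25)
            except ValueError:
                return 0.5

        lo, hi = [], []
        for i in range(10):
            cfg = SimConfig(n_genes=150, n_cells=150, n_clusters=3,
                            n_modules=5, module_size=8, seed=100 + i)
            ref, truth = simulate(cfg)
            lo.append(auc_or_chance(truth, apply_dropout(ref, 0.5, seed=i), i))
            hi.append(auc_or_chance(truth, apply_dropout(ref, 0.95, seed=i), i))
        assert np.mean(lo) >= np.mean(hi)
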