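import numpy as np
import pytest

from scgrn.data_model import ExpressionMatrix, normalize
from scgrn.noise_de import (NoiseModel, adjust_raw_score, fit_noise_model,
                            fit_poisson_noise_model, merge_z, raw_de_score,
                            wilcoxon_z, zscore_matrix)


def make_expr(counts, normalized=True):
    counts = np.asarray(counts, float)
    genes = [f"g{i}" for i in range(counts.shape[0])]
    cells = [f"c{i}" for i in range(counts.shape[1])]
    return ExpressionMatrix(genes, cells, counts, normalized=normalized)


def flat_model(p: float) -> NoiseModel:
    """Single-bin model whose p-value is exactly `p` for any non-zero lfc."""
    n_null = round(1.0 / p) - 1
    return NoiseModel(bin_edges=np.array([-np.inf, np.inf]),
                      null_abs_lfc=[np.zeros(n_null)])


class TestNoiseModel:
    def test_p_is_one_for_no_change(self, noise_model):
        for x in (0.0, 1.0, 7.3, 250.0):
            assert noise_model.p_fn(x, x) == 1.0

    def test_smoothing_floor_beyond_all_null_samples(self, noise_model):
        b = int(noise_model.assign_bins(np.array([1e6 / 2]))[0])
        n = len(noise_model.null_abs_lfc[b])
        assert noise_model.p_fn(1e6, 0.0) == pytest.approx(1.0 / (n + 1))

    def test_p_fn_symmetric(self, noise_model, rng):
        for _ in range(50):
            a, b = rng.gamma(2.0, 10.0, size=2)
            assert noise_model.p_fn(a, b) == pytest.approx(
                noise_model.p_fn(b, a), abs=1e-12)

    def test_monotone_in_fold_change_within_bin(self, noise_model):
        b = 5 % noise_model.n_bins
        lfcs = np.linspace(0, 10, 50)
        nlp = noise_model.neglog10_p(lfcs, b)
        assert (np.diff(nlp) >= 0).all()

    def test_too_few_cells_instructs_fallback(self):
        expr = make_expr(np.ones((10, 5)))
        with pytest.raises(ValueError, match="fallback"):
            fit_noise_model(expr)

    def test_poisson_fallback_usable(self):
        rng = np.random.default_rng(1)
        expr = make_expr(rng.poisson(5.0, size=(30, 10)))
        model = fit_poisson_noise_model(expr, seed=1)
        assert model.p_fn(5.0, 5.0) == 1.0
        assert model.p_fn(100.0, 0.0) < 0.05


class TestRawScore:
    def test_arithmetic_all_pairs_same_p(self):
        # 2x3 cells, every pair upregulated at p = 0.01 -> 6 * 2 = 12
        model = flat_model(0.01)
        expr = make_expr([[8, 8, 0, 0, 0]])
        score = raw_de_score(expr, [0, 1], [2, 3, 4], model)
        assert score[0] == pytest.approx(6 * 2.0)

    def test_all_zero_gene_scores_zero(self, noise_model, sim_small_norm):
        expr = make_expr(np.vstack([np.zeros(10),
                                    np.arange(10, dtype=float)]))
        model = flat_model(0.1)
        score = raw_de_score(expr, [0, 1, 2], [5, 6, 7], model)
        assert score[0] == 0.0

    def test_antisymmetric_under_group_swap(self, sim_small_norm, noise_model):
        a, b = np.arange(0, 6), np.arange(6, 12)
        s1 = raw_de_score(sim_small_norm, a, b, noise_model)
        s2 = raw_de_score(sim_small_norm, b, a, noise_model)
        np.testing.assert_allclose(s1, -s2, atol=1e-9)

    def test_matches_naive_pair_loop(self, rng):
        """Chunked vectorised scoring equals the explicit O(n1*n2) loop."""
        counts = rng.poisson(6.0, size=(5, 9)).astype(float)
        expr = make_expr(counts)
        model = fit_poisson_noise_model(expr, n_bins=1, seed=0)
        a, b = [0, 1, 2, 3], [4, 5, 6, 7, 8]
        got = raw_de_score(expr, a, b, model)
        want = np.zeros(5)
        for g in range(5):
            for i in a:
                for j in b:
                    lfc = np.log2(counts[g, i] + 1) - np.log2(counts[g, j] + 1)
                    p = model.p_fn(counts[g, i], counts[g, j])
                    want[g] += np.sign(lfc) * (-np.log10(p))
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_overlapping_groups_rejected(self, sim_small_norm, noise_model):
        with pytest.raises(ValueError, match="overlap"):
            raw_de_score(sim_small_norm, [0, 1, 2], [2, 3, 4], noise_model)


class TestAdjustRawScore:
    def test_reshuffles_must_be_positive(self, sim_small_norm, noise_model):
        raw = np.zeros(sim_small_norm.n_genes)
        with pytest.raises(ValueError, match="reshuffles"):
            adjust_raw_score(raw, sim_small_norm, [0, 1], [2, 3],
                             noise_model, reshuffles=0)

    def test_planted_de_gene_stands_out(self):
        """A 4-fold DE gene separates from the null gene population."""
        rng = np.random.default_rng(5)
        n = 60
        counts = rng.poisson(8.0, size=(80, 2 * n)).astype(float)
        counts[0, :n] = rng.poisson(32.0, size=n)  # 4-fold up in group A
        expr = normalize(make_expr(counts, normalized=False))
        model = fit_noise_model(expr, seed=5)
        a, b = np.arange(n), np.arange(n, 2 * n)
        raw = raw_de_score(expr, a, b, model)
        z = adjust_raw_score(raw, expr, a, b, model, reshuffles=3, seed=5)
        assert abs(z[0]) > np.quantile(np.abs(z[1:]), 0.95)


class TestWilcoxon:
    def test_closed_form_no_ties(self):
        # n1 = n2 = 10, all A > all B -> U = 100, Z = 49.5 / sqrt(175) w/ c.c.
        counts = np.concatenate([np.arange(20, 30), np.arange(10)])[None, :]
        expr = make_expr(counts.astype(float))
        z = wilcoxon_z(expr, list(range(10)), list(range(10, 20)))
        assert z[0] == pytest.approx(49.5 / np.sqrt(175.0), abs=1e-12)
        z_nocc = wilcoxon_z(expr, list(range(10)), list(range(10, 20)),
                            continuity=False)
        assert z_nocc[0] == pytest.approx(50.0 / np.sqrt(175.0), abs=1e-12)

    def test_identical_groups_zero(self):
        expr = make_expr(np.tile([1.0, 2.0, 3.0], (2, 2)))
        z = wilcoxon_z(expr, [0, 1, 2], [3, 4, 5])
        np.testing.assert_array_equal(z, 0.0)

    def test_antisymmetric(self, sim_small_norm):
        a, b = np.arange(0, 8), np.arange(8, 20)
        z1 = wilcoxon_z(sim_small_norm, a, b)
        z2 = wilcoxon_z(sim_small_norm, b, a)
        np.testing.assert_allclose(z1, -z2, atol=1e-12)

    def test_magnitude_bounded_by_group_sizes(self, sim_small_norm):
        n1, n2 = 10, 12
        z = wilcoxon_z(sim_small_norm, np.arange(n1),
                       np.arange(n1, n1 + n2))
        zmax = (n1 * n2 / 2.0) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
        assert np.all(np.abs(z) <= zmax + 1e-9)


class TestMergeZ:
    @pytest.mark.parametrize("zn,zw,expected", [
        (3.0, 4.0, 5.0),
        (0.0, 0.0, 0.0),
        (-3.0, -4.0, -5.0),
        (0.0, -2.0, -2.0),   # sign falls back to Wilcoxon
        (1.0, -1.0, np.sqrt(2)),  # sign from Z_num
    ])
    def test_examples(self, zn, zw, expected):
        assert merge_z([zn], [zw])[0] == pytest.approx(expected)

    def test_magnitude_dominates_components(self, rng):
        zn = rng.normal(size=200)
        zw = rng.normal(size=200)
        zf = merge_z(zn, zw)
        assert np.all(np.abs(zf) >= np.maximum(np.abs(zn), np.abs(zw)) - 1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            merge_z([1.0], [1.0, 2.0])


class TestZScoreMatrix:
    def test_column_count_is_x_choose_2(self, sim_small_norm, noise_model):
        lab = np.repeat(np.arange(3), sim_small_norm.n_cells // 3 + 1)
        lab = lab[:sim_small_norm.n_cells]
        Z = zscore_matrix(sim_small_norm, lab, model=noise_model, seed=1)
        assert Z.n_comparisons == 3
        assert Z.Z.shape[1] == 3

    def test_ten_clusters_give_45_columns(self):
        rng = np.random.default_rng(2)
        expr = make_expr(rng.poisson(8.0, size=(40, 60)))
        model = fit_poisson_noise_model(expr, seed=2)
        lab = np.repeat(np.arange(10), 6)
        Z = zscore_matrix(expr, lab, model=model, reshuffles=2, seed=2)
        assert Z.n_comparisons == 45

    def test_tiny_cluster_merged_with_warning(self, sim_small_norm,
                                              noise_model):
        n = sim_small_norm.n_cells
        lab = np.zeros(n, dtype=int)
        lab[n // 2:] = 1
        lab[-1] = 2  # singleton cluster
        with pytest.warns(UserWarning, match="merged"):
            Z = zscore_matrix(sim_small_norm, lab, model=noise_model, seed=0)
        assert Z.n_comparisons == 1

    def test_same_cluster_halves_score_below_true_pairs(self, sim_small,
                                                        noise_model,
                                                        sim_small_norm):
        """Splitting each true cluster in half: within-cluster comparisons
        carry weaker DE signal than between-cluster ones on module genes."""
        _, truth = sim_small
        rng = np.random.default_rng(4)
        lab4 = np.empty(sim_small_norm.n_cells, dtype=int)
        # reference truth labels cover the same cells (no cell was dropped)
        for k in range(2):
            cells = np.flatnonzero(truth.labels == k)
            half = rng.permutation(cells)
            lab4[half[: len(half) // 2]] = 2 * k
            lab4[half[len(half) // 2:]] = 2 * k + 1
        lab4[truth.labels >= 2] = 4
        keep = np.flatnonzero(lab4 < 4)
        expr = sim_small_norm.subset_cells(keep)
        Z = zscore_matrix(expr, lab4[keep], model=noise_model, seed=4)
        cols = {c: i for i, c in enumerate(Z.comparisons)}
        within = [cols[(0, 1)], cols[(2, 3)]]
        across = [i for c, i in cols.items() if i not in within]
        genes_pos = {g: i for i, g in enumerate(Z.genes)}
        mod = [genes_pos[f"G{g:04d}"] for g in np.concatenate(truth.module_genes)
               if f"G{g:04d}" in genes_pos]
        zmod = np.abs(Z.Z[mod])
        assert zmod[:, within].max() < zmod[:, across].max()

    def test_tsv_round_trip(self, tmp_path, sim_small_norm, noise_model):
        from scgrn.noise_de import ZScoreMatrix
        lab = np.repeat([0, 1], sim_small_norm.n_cells // 2)
        Z = zscore_matrix(sim_small_norm, lab, model=noise_model, seed=3)
        Z.to_tsv(tmp_path / "z.tsv")
        back = ZScoreMatrix.from_tsv(tmp_path / "z.tsv")
        np.testing.assert_allclose(back.Z, Z.Z, atol=1e-6)


class TestNullCalibration:
    def test_null_z_final_mean_and_sd(self, homogeneous_expr):
        """On a homogeneous population split randomly, the final Z-scores are
        approximately standardised (mean ~0, sd within a sane band)."""
        model = fit_noise_model(homogeneous_expr, seed=11)
        n = homogeneous_expr.n_cells
        rng = np.random.default_rng(11)
        perm = rng.permutation(n)
        a, b = perm[: n // 2], perm[n // 2:]
        raw = raw_de_score(homogeneous_expr, a, b, model)
        zn = adjust_raw_score(raw, homogeneous_expr, a, b, model,
                              reshuffles=3, seed=11)
        zw = wilcoxon_z(homogeneous_expr, a, b)
        zf = merge_z(zn, zw)
        mask = homogeneous_expr.expressed_mask(5)
        zf = zf[mask]
        assert abs(zf.mean()) < 0.1
        assert 0.7 < zf.std() < 1.4
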