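"""GLM estimation, smoothness/resels, EC densities and topological inference."""

import numpy as np
import pytest
from scipy import stats as sps

from topostat.image_export import StatImage
from topostat.stats_rft import (
    Contrast,
    SmoothnessEstimate,
    bonferroni_threshold,
    build_design,
    compute_contrast,
    ec_density,
    estimate_smoothness,
    fit_glm,
    resel_counts,
    rft_cluster_p,
    rft_corrected_threshold,
    rft_peak_p,
    topological_report,
)
from topostat.synthetic import gen_null_volume


class TestDesigns:
    def test_two_sample_shape_rank_dof(self):
        d = build_design("two-sample", (12, 12))
        assert d.X.shape == (24, 2)
        assert d.rank == 2
        assert d.dof == 22

    def test_one_sample(self):
        d = build_design("one-sample", (10,))
        np.testing.assert_array_equal(d.X, np.ones((10, 1)))
        assert d.dof == 9

    def test_paired_rank_by_elimination_oracle(self):
        d = build_design("paired", n_subjects=8)
        # Gaussian elimination oracle for the rank
        M = d.X.copy()
        rank = 0
        for col in range(M.shape[1]):
            piv = np.flatnonzero(np.abs(M[rank:, col]) > 1e-12)
            if piv.size == 0:
                continue
            p = piv[0] + rank
            M[[rank, p]] = M[[p, rank]]
            M[rank] /= M[rank, col]
            for r in range(M.shape[0]):
                if r != rank and abs(M[r, col]) > 1e-12:
                    M[r] -= M[r, col] * M[rank]
            rank += 1
        assert rank == 9
        assert d.rank == 9
        assert d.dof == 7

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError):
            build_design("one-sample", (1,))


class TestGLM:
    def test_exact_fit_gives_zero_residuals(self):
        X = build_design("two-sample", (3, 3)).X
        beta = np.array([[2.0, 1.0], [5.0, -1.0]]).T  # (p=2, 2 voxels)
        Y = (X @ beta).reshape(6, 2)
        m = fit_glm(Y, X)
        np.testing.assert_allclose(m.residuals, 0.0, atol=1e-12)
        np.testing.assert_allclose(m.sigma2, 0.0, atol=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(5), [0, 1, 2, 3, 4.0]])
        Y = rng.standard_normal((5, 7))
        m = fit_glm(Y, X)
        beta_o = np.linalg.solve(X.T @ X, X.T @ Y)
        res_o = Y - X @ beta_o
        s2_o = (res_o**2).sum(axis=0) / 3
        np.testing.assert_allclose(m.beta, beta_o, atol=1e-10)
        np.testing.assert_allclose(m.sigma2, s2_o, atol=1e-10)
        assert m.dof == 3

    def test_missing_voxel_masked_everywhere(self):
        Y = np.ones((4, 3, 3))
        Y[1, 1, 1] = np.nan
        m = fit_glm(Y, build_design("one-sample", (4,)))
        assert not m.mask[1, 1]
        assert np.isnan(m.beta[0, 1, 1])
        assert np.isnan(m.sigma2[1, 1])
        assert m.mask.sum() == 8

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fit_glm(np.ones((5, 2)), build_design("one-sample", (4,)))


class TestContrasts:
    def test_identical_groups_give_zero_t(self):
        rng = np.random.default_rng(1)
        block = rng.standard_normal((6, 10))
        Y = np.concatenate([block, block])
        X = build_design("two-sample", (6, 6))
        m = fit_glm(Y, X)
        img = compute_contrast(m, X, Contrast([1.0, -1.0]))
        np.testing.assert_allclose(img.data, 0.0, atol=1e-10)

    def test_f_equals_t_squared_for_1df(self):
        rng = np.random.default_rng(2)
        Y = rng.standard_normal((10, 25))
        X = build_design("two-sample", (5, 5))
        m = fit_glm(Y, X)
        t_img = compute_contrast(m, X, Contrast([1.0, -1.0], "t"))
        f_img = compute_contrast(m, X, Contrast([[1.0, -1.0]], "F"))
        np.testing.assert_allclose(f_img.data, t_img.data**2, atol=1e-9)
        assert f_img.dof == (1.0, 8.0)

    def test_two_sample_t_direct_formula_oracle(self):
        Y = np.array([1.0, 2.0, 3.0, 2.0, 3.0, 4.0])[:, None]
        X = build_design("two-sample", (3, 3))
        m = fit_glm(Y, X)
        img = compute_contrast(m, X, Contrast([-1.0, 1.0]))
        # direct pooled two-sample formula
        g1, g2 = Y[:3, 0], Y[3:, 0]
        sp2 = ((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()
        sp2 /= 4
        t_direct = (g2.mean() - g1.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert img.data[0] == pytest.approx(t_direct, abs=1e-12)
        assert img.data[0] == pytest.approx(1.2247, abs=1e-4)
        assert img.dof == (4.0,)

    def test_inestimable_contrast_rejected(self):
        # overparameterized one-way layout: intercept + both group
        # indicators; single-column effects are not estimable but their
        # difference is
        X = np.column_stack([np.ones(8),
                             np.r_[np.ones(4), np.zeros(4)],
                             np.r_[np.zeros(4), np.ones(4)]])
        m = fit_glm(np.random.default_rng(0).standard_normal((8, 4)), X)
        with pytest.raises(ValueError, match="estimable"):
            compute_contrast(m, X, Contrast([0.0, 1.0, 0.0]))
        img = compute_contrast(m, X, Contrast([0.0, 1.0, -1.0]))
        assert np.all(np.isfinite(img.data))


class TestSmoothness:
    def test_white_noise_lambda_near_two(self):
        rng = np.random.default_rng(3)
        res = rng.standard_normal((30, 40, 40))
        sm = estimate_smoothness(res)
        expected = np.sqrt(4 * np.log(2) / 2.0)  # ~1.177 voxels
        np.testing.assert_allclose(sm.fwhm, expected, rtol=0.05)

    def test_recovers_generated_fwhm(self):
        vols = np.stack([gen_null_volume((48, 48, 20), 6.0, seed=100 + i)
                         for i in range(30)])
        m = fit_glm(vols, build_design("one-sample", (30,)))
        sm = estimate_smoothness(m.residuals, m.mask)
        np.testing.assert_allclose(sm.fwhm, 6.0, rtol=0.10)

    def test_cubic_mask_resel_count(self):
        mask = np.ones((64, 64, 64), dtype=bool)
        R = resel_counts(mask, np.array([8.0, 8.0, 8.0]))
        assert R[3] == pytest.approx(512.0)
        assert R[1] == pytest.approx(3 * 8.0)
        assert R[2] == pytest.approx(3 * 64.0)

    def test_resels_scale_with_mask_extent(self):
        fwhm = np.array([4.0, 4.0, 4.0])
        full = resel_counts(np.ones((32, 32, 32), bool), fwhm)
        mask = np.zeros((32, 32, 32), bool)
        mask[:16, :16, :16] = True
        half = resel_counts(mask, fwhm)
        assert half[1] == pytest.approx(full[1] / 2)
        assert half[2] == pytest.approx(full[2] / 4)
        assert half[3] == pytest.approx(full[3] / 8)

    def test_single_image_rejected(self):
        with pytest.raises(ValueError):
            estimate_smoothness(np.ones((1, 5, 5)))


class TestECDensities:
    @pytest.mark.parametrize("nu", [8.0, 22.0, 100.0])
    @pytest.mark.parametrize("d", [0, 1, 2, 3])
    def test_f_field_with_1df_is_twice_t_density(self, nu, d):
        # dual-route check: excursions of F(1, nu) above u^2 are the
        # two-sided excursions of t(nu) above u
        for u in (1.5, 2.5, 4.0, 6.0):
            rf = ec_density(u * u, d, "F", (1.0, nu))
            rt = 2.0 * ec_density(u, d, "t", (nu,))
            assert rf == pytest.approx(rt, rel=1e-10)

    def test_t_density_approaches_gaussian_at_large_dof(self):
        for d in range(4):
            for u in (2.0, 3.0, 4.5):
                assert ec_density(u, d, "t", (1e6,)) == pytest.approx(
                    ec_density(u, d, "gaussian"), rel=1e-3)


class TestPeakP:
    def test_point_domain_limit_is_uncorrected(self):
        resels = np.array([1.0, 0.0, 0.0, 0.0])
        for u in (1.0, 2.5, 4.0):
            assert rft_peak_p(u, "gaussian", (), resels) == pytest.approx(
                sps.norm.sf(u), rel=1e-12)

    def test_monotone_nonincreasing_in_threshold(self):
        resels = np.array([1.0, 12.0, 48.0, 64.0])
        us = np.linspace(0.0, 10.0, 200)
        ps = [rft_peak_p(u, "gaussian", (), resels, 20000) for u in us]
        assert np.all(np.diff(ps) <= 1e-12)

    def test_negative_resels_rejected(self):
        with pytest.raises(ValueError):
            rft_peak_p(3.0, "gaussian", (), np.array([1.0, -1.0]))

    @pytest.mark.parametrize("fieldtype,dof",
                             [("gaussian", ()), ("t", (22.0,)),
                              ("F", (1.0, 22.0))])
    @pytest.mark.parametrize("fwhm", [3.0, 4.0, 6.0, 10.0])
    def test_rft_threshold_at_most_bonferroni_when_smooth(self, fieldtype,
                                                          dof, fwhm):
        mask = np.ones((32, 32, 20), dtype=bool)
        resels = resel_counts(mask, np.full(3, fwhm))
        thr = rft_corrected_threshold(0.05, fieldtype, dof, resels,
                                      int(mask.sum()))
        bon = bonferroni_threshold(0.05, fieldtype, dof, int(mask.sum()))
        assert thr <= bon + 1e-9

    def test_probit_transformed_t_matches_gaussian_at_large_dof(self):
        resels = np.array([1.0, 10.0, 30.0, 20.0])
        thr_t = rft_corrected_threshold(0.05, "t", (1000.0,), resels)
        thr_g = rft_corrected_threshold(0.05, "gaussian", (), resels)
        # map the t threshold to the Gaussian scale via its tail prob
        z_equiv = sps.norm.isf(sps.t.sf(thr_t, 1000.0))
        assert z_equiv == pytest.approx(thr_g, abs=1e-2)


class TestClusterP:
    def smoothness(self):
        mask = np.ones((32, 32, 20), dtype=bool)
        fwhm = np.array([6.0, 6.0, 6.0])
        return SmoothnessEstimate(fwhm, resel_counts(mask, fwhm),
                                  int(mask.sum()))

    def test_zero_extent_gives_any_cluster_probability(self):
        sm = self.smoothness()
        u_c = 3.1
        Em = sum(R * ec_density(u_c, d, "gaussian")
                 for d, R in enumerate(sm.resels))
        assert rft_cluster_p(0, u_c, "gaussian", (), sm) == pytest.approx(
            1 - np.exp(-Em), rel=1e-9)

    def test_strictly_decreasing_in_extent(self):
        sm = self.smoothness()
        ps = [rft_cluster_p(k, 3.1, "gaussian", (), sm)
              for k in (0, 10, 50, 200, 1000)]
        assert np.all(np.diff(ps) < 0)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            rft_cluster_p(10, -1.0, "gaussian", (), self.smoothness())


class TestTopologicalReport:
    def stat_image(self, data, fieldtype="gaussian", dof=None):
        return StatImage(data, ("mm",) * data.ndim, (1.0,) * data.ndim,
                         field=fieldtype, dof=dof)

    def test_null_images_rarely_significant(self):
        # unsmoothed standard normal images: Bonferroni floor keeps the
        # false positive rate at ~alpha over the batch
        hits = 0
        n_batch = 40
        for s in range(n_batch):
            data = gen_null_volume((20, 20, 10), 0.0, seed=7000 + s)
            fwhm = np.full(3, np.sqrt(4 * np.log(2) / 2.0))
            mask = np.ones(data.shape, bool)
            sm = SmoothnessEstimate(fwhm, resel_counts(mask, fwhm),
                                    data.size)
            table = topological_report(self.stat_image(data), sm, alpha=0.05)
            hits += bool(table["significant"].any())
        assert hits <= 7  # P(X > 7) < 1e-3 at p = 0.05, n = 40

    def injected_image(self, seed=0):
        data = gen_null_volume((32, 32, 16), 6.0, seed=seed)
        peak = np.array([16, 16, 8])
        ii, jj, kk = np.mgrid[:32, :32, :16]
        bump = 8.0 * np.exp(-((ii - peak[0]) ** 2 + (jj - peak[1]) ** 2
                              + (kk - peak[2]) ** 2) / (2 * 2.5**2))
        return data + bump, peak

    def test_injected_effect_recovered_at_peak(self):
        found = 0
        n_runs = 20
        for s in range(n_runs):
            data, peak = self.injected_image(seed=3000 + s)
            fwhm = np.full(3, 6.0)
            mask = np.ones(data.shape, bool)
            sm = SmoothnessEstimate(fwhm, resel_counts(mask, fwhm), data.size)
            table = topological_report(self.stat_image(data), sm)
            top = table.iloc[0]
            loc = np.array([top["peak_x"], top["peak_y"], top["peak_z"]])
            if top["significant"] and np.linalg.norm(loc - peak) <= 2.0:
                found += 1
        assert found >= 0.95 * n_runs

    def test_window_restriction_never_hurts_the_peak(self):
        data, peak = self.injected_image(seed=42)
        fwhm = np.full(3, 6.0)
        mask = np.ones(data.shape, bool)
        sm = SmoothnessEstimate(fwhm, resel_counts(mask, fwhm), data.size)
        img = self.stat_image(data)
        full = topological_report(img, sm)
        window = np.zeros(data.shape, bool)
        window[10:23, 10:23, 4:13] = True
        small = topological_report(img, sm, window_mask=window)
        assert (small.iloc[0]["p_peak_corrected"]
                <= full.iloc[0]["p_peak_corrected"] + 1e-12)

    def test_disjoint_window_rejected(self):
        data = np.full((10, 10), np.nan)
        data[:5] = 1.0
        img = self.stat_image(data)
        fwhm = np.array([2.0, 2.0])
        sm = SmoothnessEstimate(fwhm, np.array([1.0, 5.0, 6.0]), 50)
        window = np.zeros((10, 10), bool)
        window[6:] = True
        with pytest.raises(ValueError, match="disjoint"):
            topological_report(img, sm, window_mask=window)

    def test_rows_sorted_by_corrected_p(self):
        data, _ = self.injected_image(seed=5)
        fwhm = np.full(3, 6.0)
        sm = SmoothnessEstimate(fwhm,
                                resel_counts(np.ones(data.shape, bool), fwhm),
                                data.size)
        table = topological_report(self.stat_image(data), sm)
        p = table["p_peak_corrected"].to_numpy()
        assert np.all(np.diff(p) >= 0)
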