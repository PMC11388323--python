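"""GLM stage: confound removal, subject fits, Fisher pooling, contrasts."""

import numpy as np
import pytest
from scipy import stats

from segflow import (
    VolumeSeries,
    compare_groups_glm,
    compare_lags,
    fisher_combine,
    fit_subject_glm,
    regress_out_confound,
    spearman_association,
)
from segflow.glm import build_lagged_design, rank_sum_map
from segflow.regressor import hrf_convolve, lag_regressor


def _vol_from_flat(flat: np.ndarray, shape=(2, 2, 1), tr=2.0, **kw) -> VolumeSeries:
    n_vox = int(np.prod(shape))
    assert flat.shape[0] == n_vox
    data = flat.reshape(*shape, -1)
    return VolumeSeries(data=data, mask=np.ones(shape, bool), tr=tr, **kw)


class TestConfoundRemoval:
    def test_voxel_equal_to_confound_becomes_zero(self, rng):
        c = rng.normal(size=50)
        flat = np.tile(c, (4, 1))
        out = regress_out_confound(_vol_from_flat(flat), c)
        assert np.max(np.abs(out.masked())) < 1e-10

    def test_orthogonal_zero_mean_voxel_unchanged(self, rng):
        c = rng.normal(size=50)
        x = rng.normal(size=50)
        x = x - x.mean()
        x = x - (x @ c - x.sum() * c.mean()) / ((c - c.mean()) @ c) * (c - c.mean())
        flat = np.tile(x, (4, 1))
        out = regress_out_confound(_vol_from_flat(flat), c)
        np.testing.assert_allclose(out.masked()[0], x, atol=1e-10)

    def test_small_case_matches_normal_equations(self):
        y = np.array([1.0, 2.0, 3.0, 5.0])
        c = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.column_stack([np.ones(4), c])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        expect = y - X @ beta
        out = regress_out_confound(_vol_from_flat(np.tile(y, (4, 1))), c)
        np.testing.assert_allclose(out.masked()[0], expect, atol=1e-12)

    def test_residuals_orthogonal_to_confound_everywhere(self, desk_dataset,
                                                        desk_residuals):
        rms = desk_dataset.rms
        rms_c = rms - rms.mean()
        for v in desk_residuals[:2]:
            R = v.masked()
            num = R @ rms_c
            denom = np.sqrt((R**2).sum(axis=1) * (rms_c**2).sum())
            ok = denom > 1e-12
            assert np.max(np.abs(num[ok] / denom[ok])) <= 1e-10

    def test_constant_confound_rejected(self, rng):
        v = _vol_from_flat(rng.normal(size=(4, 20)))
        with pytest.raises(ValueError, match="constant confound"):
            regress_out_confound(v, np.ones(20))


class TestSubjectGLM:
    def test_exact_recovery_noise_free(self, rng):
        reg = rng.gamma(2.0, 1.0, size=80)
        lag0 = hrf_convolve(lag_regressor(reg, 0), tr=2.0)
        flat = np.tile(2.0 * lag0, (4, 1))
        glm = fit_subject_glm(_vol_from_flat(flat), reg)
        i0 = glm.lags.index(0)
        assert glm.betas[i0, 0] == pytest.approx(2.0, abs=1e-10)
        for i, lag in enumerate(glm.lags):
            if lag != 0:
                assert abs(glm.betas[i, 0]) < 1e-8

    def test_three_voxel_toy_matches_hand_solved_least_squares(self):
        reg = np.array([0.0, 1.0, 0.0, 2.0, 1.0, 0.0, 0.5, 0.0])
        Y = np.array([
            [1.0, 2.0, 0.5, 3.0, 2.5, 0.2, 1.0, 0.1],
            [0.0, -1.0, 0.3, -2.0, -1.2, 0.1, -0.4, 0.0],
            [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
        ])
        vol = VolumeSeries(Y.reshape(3, 1, 1, 8), np.ones((3, 1, 1), bool), 2.0)
        glm = fit_subject_glm(vol, reg, hrf="identity")
        X = build_lagged_design(reg, (-1, 0, 1), tr=2.0, hrf="identity")
        expect = np.linalg.solve(X.T @ X, X.T @ Y.T)[1:]
        np.testing.assert_allclose(glm.betas, expect, atol=1e-10)

    def test_type_one_error_calibrated(self, rng):
        n_sim, n = 400, 60
        reg = rng.gamma(2.0, 1.0, size=n)
        flat = rng.normal(size=(n_sim, n))
        vol = VolumeSeries(flat.reshape(n_sim, 1, 1, n),
                          np.ones((n_sim, 1, 1), bool), 2.0)
        glm = fit_subject_glm(vol, reg)
        i0 = glm.lags.index(0)
        rate = np.mean(2 * np.minimum(glm.p_pos[i0], glm.p_neg[i0]) < 0.05)
        lo, hi = stats.binom.ppf([0.005, 0.995], n_sim, 0.05) / n_sim
        assert lo <= rate <= hi

    def test_p_pos_p_neg_sum_to_one(self, rng):
        reg = rng.gamma(2.0, 1.0, size=50)
        vol = _vol_from_flat(rng.normal(size=(4, 50)))
        glm = fit_subject_glm(vol, reg)
        np.testing.assert_allclose(glm.p_pos + glm.p_neg, 1.0, atol=1e-12)

    def test_confound_nuisance_column_restores_exact_recovery(self, rng):
        # residualising the data but not the design biases betas whenever
        # the confound correlates with the design columns; carrying the
        # confound as a nuisance column (Frisch-Waugh) removes the bias
        reg = rng.gamma(2.0, 1.0, size=100)
        lag0 = hrf_convolve(lag_regressor(reg, 0), tr=2.0)
        conf = 0.3 * lag0 + rng.normal(size=100)  # confound shares signal
        flat = np.tile(2.0 * lag0 + 0.7 * conf, (4, 1))
        resid = regress_out_confound(_vol_from_flat(flat), conf)
        i0 = (-1, 0, 1).index(0)
        biased = fit_subject_glm(resid, reg).betas[i0, 0]
        exact = fit_subject_glm(resid, reg, confound=conf).betas[i0, 0]
        assert exact == pytest.approx(2.0, abs=1e-8)
        assert abs(biased - 2.0) > 0.05

    def test_collinear_design_named(self):
        reg = np.zeros(30)  # all lagged copies identically zero -> collinear
        vol = _vol_from_flat(np.random.default_rng(0).normal(size=(4, 30)))
        with pytest.raises(ValueError, match="collinear"):
            fit_subject_glm(vol, reg)


class TestFisher:
    def test_all_ones_give_stat_zero_p_one(self):
        gm = fisher_combine(np.ones((5, 3)))
        np.testing.assert_allclose(gm.stat, 0.0)
        np.testing.assert_allclose(gm.p, 1.0)

    def test_single_study_identity(self, rng):
        p = rng.uniform(0.01, 0.99, size=10)[None, :]
        gm = fisher_combine(p)
        np.testing.assert_allclose(gm.p, p[0], atol=1e-9)

    def test_two_study_closed_form(self):
        gm = fisher_combine(np.array([[0.05], [0.10]]))
        stat = -2 * (np.log(0.05) + np.log(0.10))
        assert gm.stat[0] == pytest.approx(stat, abs=1e-9)
        assert gm.p[0] == pytest.approx(stats.chi2.sf(stat, 4), abs=1e-9)

    def test_zero_p_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            gm = fisher_combine(np.array([[0.0], [0.5]]))
        assert np.isfinite(gm.stat[0])

    def test_null_statistic_matches_chi_square(self, rng):
        k = 36
        draws = rng.uniform(size=(k, 10_000))
        stat = -2 * np.log(draws).sum(axis=0)
        ks = stats.kstest(stat, "chi2", args=(2 * k,))
        assert ks.pvalue > 0.01


class TestLagAndGroupComparisons:
    def _glms(self, betas_by_subject, groups=None):
        """Fabricate SubjectGLM-like stats via real fits on constructed data."""
        from segflow.glm import SubjectGLM

        glms = []
        for s, b in enumerate(betas_by_subject):
            b = np.asarray(b, float)
            glms.append(
                SubjectGLM(
                    subject_id=f"s{s}", group=(groups[s] if groups else "g"),
                    lags=(-1, 0, 1), betas=b, t_stats=b,
                    p_pos=np.full_like(b, 0.5), p_neg=np.full_like(b, 0.5),
                    dof=10, mask=np.ones((b.shape[1], 1, 1), bool),
                )
            )
        return glms

    def test_identical_maps_give_p_one(self, rng):
        b = rng.normal(size=(3, 5))
        b[1] = b[0]  # lag -1 and lag 0 identical across all subjects
        glms = self._glms([b] * 6)
        maps = compare_lags(glms)
        np.testing.assert_allclose(maps[(-1, 0)].p, 1.0)

    def test_complete_separation_matches_enumeration(self):
        subj = [np.array([[i + 10.0], [i + 0.0], [0.0]]) for i in range(5)]
        glms = self._glms(subj)
        maps = compare_lags(glms)
        res = maps[(-1, 0)]
        assert res.p[0] == pytest.approx(2 / 252)

    def test_planted_lag_shift_detected(self, rng):
        hits = 0
        n_runs = 40
        for run in range(n_runs):
            r = np.random.default_rng(run)
            a = r.normal(2.0, 1.0, size=(18, 4))  # 2 SD shift
            b = r.normal(0.0, 1.0, size=(18, 4))
            z, p = rank_sum_map(a, b)
            hits += np.all(p < 0.05)
        assert hits / n_runs >= 0.95

    def test_group_comparison_antisymmetry_and_null(self, rng):
        b = [rng.normal(size=(3, 6)) for _ in range(8)]
        groups = ["musician"] * 4 + ["nonmusician"] * 4
        glms = self._glms(b, groups)
        gm = compare_groups_glm(glms, lag=0)
        assert np.all((gm.p > 0) & (gm.p <= 1))
        flipped = self._glms(b, [
            {"musician": "nonmusician", "nonmusician": "musician"}[g]
            for g in groups
        ])
        gm2 = compare_groups_glm(flipped, lag=0)
        np.testing.assert_allclose(gm.stat, -gm2.stat, atol=1e-12)

    def test_group_label_permutation_calibrated(self, rng):
        n_sim = 300
        rej = 0
        for s in range(n_sim):
            r = np.random.default_rng(s)
            a = r.normal(size=(6, 1))
            b = r.normal(size=(6, 1))
            _, p = rank_sum_map(a, b)
            rej += p[0] < 0.05
        lo, hi = stats.binom.ppf([0.005, 0.995], n_sim, 0.05) / n_sim
        # exact test is conservative at tiny n; allow the lower side
        assert rej / n_sim <= hi


class TestSpearman:
    def test_voxel_equal_to_regressor(self, rng):
        reg = rng.normal(size=30)
        vol = _vol_from_flat(np.tile(reg, (4, 1)))
        rho, p = spearman_association(vol, reg)
        np.testing.assert_allclose(rho, 1.0)

    def test_monotone_transform_invariance(self, rng):
        reg = rng.uniform(1, 2, size=30)
        vol = _vol_from_flat(np.tile(np.exp(reg), (4, 1)))
        rho, _ = spearman_association(vol, reg)
        np.testing.assert_allclose(rho, 1.0)

    def test_small_series_matches_exhaustive_ranks(self):
        reg = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        vol = _vol_from_flat(np.tile(y, (4, 1)))
        rho, p = spearman_association(vol, reg)
        assert rho[0] == pytest.approx(0.8, abs=1e-12)
        ref = stats.spearmanr(y, reg)
        assert rho[0] == pytest.approx(ref.statistic, abs=1e-12)

    def test_constant_voxel_flagged_nan(self):
        flat = np.vstack([np.ones(10), np.arange(10.0), np.arange(10.0),
                          np.arange(10.0)])
        vol = _vol_from_flat(flat)
        rho, p = spearman_association(vol, np.arange(10.0))
        assert np.isnan(rho[0]) and rho[1] == pytest.approx(1.0)
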