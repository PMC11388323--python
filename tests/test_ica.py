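"""Two-step reduction, spatial ICA, GICA3 identity, lag profiles, group maps."""

import numpy as np
import pytest

from segflow import (
    VolumeSeries,
    compare_groups_ica,
    fit_spatial_ica,
    match_components,
    profile_lag_significance,
    reduce_two_step,
    scan_model_orders,
)


def _vols_from_flat(flats, tr=2.0, groups=None):
    vols = []
    n_vox = flats[0].shape[0]
    shape = (n_vox, 1, 1)
    for i, f in enumerate(flats):
        vols.append(
            VolumeSeries(
                f.reshape(*shape, -1), np.ones(shape, bool), tr,
                subject_id=f"s{i}",
                group=(groups[i] if groups else "g"),
            )
        )
    return vols


class TestReduction:
    def test_exact_rank_data_reduced_losslessly(self, rng):
        tcs = rng.normal(size=(3, 40))
        maps = rng.normal(size=(3, 60))
        flat = maps.T @ tcs  # rank 3, (60 voxels, 40 scans)
        vols = _vols_from_flat([flat])
        red = reduce_two_step(vols, subject_dim=3, group_dim=3)
        # back-projection through retained bases reproduces the demeaned data
        F = red.subject_bases[0]
        Yc = (flat - flat.mean(axis=1, keepdims=True)).T
        recon = F @ (F.T @ Yc)
        np.testing.assert_allclose(recon, Yc, atol=1e-8)

    def test_white_noise_retained_variance_matches_eigvals(self, rng):
        flat = rng.normal(size=(80, 50))
        vols = _vols_from_flat([flat])
        k = 10
        red = reduce_two_step(vols, subject_dim=k, group_dim=k)
        Yc = (flat - flat.mean(axis=1, keepdims=True)).T
        eig = np.linalg.svd(Yc, compute_uv=False) ** 2
        expect = eig[:k].sum() / eig.sum()
        got = (red.subject_reduced[0] ** 2).sum() / (Yc**2).sum()
        assert got == pytest.approx(expect, abs=1e-10)

    def test_scale_invariant_subspace(self, rng):
        flat = rng.normal(size=(40, 30))
        red1 = reduce_two_step(_vols_from_flat([flat]), 5, 5)
        red2 = reduce_two_step(_vols_from_flat([2.0 * flat]), 5, 5)
        P1 = red1.subject_bases[0] @ red1.subject_bases[0].T
        P2 = red2.subject_bases[0] @ red2.subject_bases[0].T
        np.testing.assert_allclose(P1, P2, atol=1e-8)

    def test_rank_overflow_reports_achievable(self, rng):
        tcs = rng.normal(size=(2, 30))
        maps = rng.normal(size=(2, 40))
        vols = _vols_from_flat([maps.T @ tcs])
        with pytest.raises(ValueError, match="achievable rank"):
            reduce_two_step(vols, subject_dim=10, group_dim=5)


class TestSpatialICA:
    def _planted(self, rng, n_subj=4, n_vox=400, n_scans=60, noise=0.0):
        maps = np.zeros((2, n_vox))
        maps[0, 30:70] = rng.uniform(1, 2, 40)
        maps[1, 200:260] = rng.uniform(1, 2, 60)
        flats = []
        for _ in range(n_subj):
            tcs = rng.normal(size=(2, n_scans))
            f = maps.T @ tcs + noise * rng.normal(size=(n_vox, n_scans))
            flats.append(f)
        return maps, flats

    def test_planted_sources_recovered_noise_free(self, rng):
        maps, flats = self._planted(rng)
        red = reduce_two_step(_vols_from_flat(flats), 2, 2)
        dec = fit_spatial_ica(red, model_order=2, seed=0)
        mz = (maps - maps.mean(1, keepdims=True)) / maps.std(1, keepdims=True)
        matches = match_components(mz, dec.group_maps, threshold=0.9)
        assert len(matches) == 2
        assert all(c >= 0.99 for _, c in matches.values())

    def test_determinism_bit_for_bit(self, rng):
        _, flats = self._planted(rng, noise=0.5)
        red = reduce_two_step(_vols_from_flat(flats), 10, 8)
        d1 = fit_spatial_ica(red, 3, seed=42)
        d2 = fit_spatial_ica(red, 3, seed=42)
        np.testing.assert_array_equal(d1.group_maps, d2.group_maps)
        np.testing.assert_array_equal(d1.subject_timecourses,
                                      d2.subject_timecourses)

    def test_order_exceeding_group_dim_rejected(self, rng):
        _, flats = self._planted(rng, noise=0.5)
        red = reduce_two_step(_vols_from_flat(flats), 6, 4)
        with pytest.raises(ValueError, match="model_order"):
            fit_spatial_ica(red, 10)

    def test_gica3_mean_identity(self, rng):
        _, flats = self._planted(rng, noise=0.5)
        red = reduce_two_step(_vols_from_flat(flats), 10, 8)
        for order in (2, 4):
            dec = fit_spatial_ica(red, order, seed=1)
            num = np.abs(dec.subject_maps.mean(axis=0) - dec.group_maps).max()
            denom = np.abs(dec.group_maps).max()
            assert num / denom <= 1e-6

    def test_single_subject_map_equals_group_map(self, rng):
        maps, flats = self._planted(rng, n_subj=1, noise=0.2)
        red = reduce_two_step(_vols_from_flat(flats), 10, 8)
        dec = fit_spatial_ica(red, 2, seed=0)
        np.testing.assert_allclose(dec.subject_maps[0], dec.group_maps,
                                   atol=1e-8)

    def test_subject_gains_rank_ordered(self, rng):
        # a subject with 1.5x signal amplitude gets a stronger subject map
        maps = np.zeros((1, 300))
        maps[0, 100:160] = 1.0
        tc = rng.normal(size=(1, 80))
        flats = [maps.T @ (g * tc) + 0.1 * rng.normal(size=(300, 80))
                 for g in (1.0, 1.5)]
        red = reduce_two_step(_vols_from_flat(flats), 10, 6)
        dec = fit_spatial_ica(red, 1, seed=0)
        amp = [np.abs(dec.subject_maps[s, 0, 100:160]).mean() for s in (0, 1)]
        assert amp[1] > amp[0]


class TestModelOrderScan:
    def test_planted_components_stable_across_orders(self, rng):
        maps = np.zeros((2, 400))
        maps[0, 30:70] = rng.uniform(1, 2, 40)
        maps[1, 200:260] = rng.uniform(1, 2, 60)
        flats = [maps.T @ rng.normal(size=(2, 60))
                 + 0.3 * rng.normal(size=(400, 60)) for _ in range(4)]
        red = reduce_two_step(_vols_from_flat(flats), 10, 8)
        scan = scan_model_orders(red, [2, 3, 4], seed=0)
        assert scan.reference_order == 2
        assert np.all(scan.stability >= 0.9)

    def test_single_order_scan_is_one_fit(self, rng):
        maps = np.zeros((1, 200))
        maps[0, 50:90] = 1.0
        flats = [maps.T @ rng.normal(size=(1, 40))
                 + 0.2 * rng.normal(size=(200, 40)) for _ in range(3)]
        red = reduce_two_step(_vols_from_flat(flats), 8, 6)
        scan = scan_model_orders(red, [2], seed=0)
        assert scan.orders == [2] and len(scan.decompositions) == 1
        np.testing.assert_array_equal(scan.stability, np.ones(2))

    def test_noise_only_components_less_stable_than_planted(self, rng):
        maps = np.zeros((1, 300))
        maps[0, 100:150] = rng.uniform(1, 2, 50)
        flats = [maps.T @ rng.normal(size=(1, 50)) * 3.0
                 + rng.normal(size=(300, 50)) for _ in range(4)]
        red = reduce_two_step(_vols_from_flat(flats), 10, 8)
        scan = scan_model_orders(red, [3, 4, 5], seed=0)
        mz = (maps - maps.mean(1, keepdims=True)) / maps.std(1, keepdims=True)
        m = match_components(mz, scan.decompositions[3].group_maps, 0.5)
        planted_idx = m[0][0]
        others = [i for i in range(3) if i != planted_idx]
        assert scan.stability[planted_idx] >= max(
            [scan.stability[i] for i in others] + [0.0]
        )


class TestLagProfile:
    def test_constructed_early_component(self, rng):
        from segflow.regressor import hrf_convolve, lag_regressor

        reg = rng.gamma(2.0, 1.0, size=100)
        lagm1 = hrf_convolve(lag_regressor(reg, -1), tr=2.0)
        tcs = np.stack([
            np.stack([lagm1 + 0.2 * rng.normal(size=100)]) for _ in range(8)
        ])
        prof = profile_lag_significance(tcs, reg, tr=2.0)
        assert prof.classification[0] == "early"
        assert np.argmin(prof.p[0]) == 0  # lag -1 is the first column

    def test_white_noise_rarely_significant(self, rng):
        alpha = 0.01
        n_comp, n_runs = 10, 20
        n_sig = 0
        for _ in range(n_runs):
            reg = rng.gamma(2.0, 1.0, size=80)
            tcs = rng.normal(size=(8, n_comp, 80))
            prof = profile_lag_significance(tcs, reg, tr=2.0, alpha=alpha)
            n_sig += sum(c != "unrelated" for c in prof.classification)
        rate = n_sig / (n_comp * n_runs)
        # per-component rate is bounded by ~3*alpha (three lags tested)
        se = np.sqrt(3 * alpha * (1 - 3 * alpha) / (n_comp * n_runs))
        assert rate <= 3 * alpha + 2 * se

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="6 subjects"):
            profile_lag_significance(rng.normal(size=(4, 2, 50)),
                                     rng.gamma(2, 1, size=50))

    def test_constant_timecourse_excluded_with_warning(self, rng):
        reg = rng.gamma(2.0, 1.0, size=60)
        tcs = rng.normal(size=(7, 1, 60))
        tcs[2, 0] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            prof = profile_lag_significance(tcs, reg, tr=2.0)
        assert np.isnan(prof.betas[2, 0]).all()


class TestGroupComparison:
    def test_identical_groups_no_significant_clusters(self, rng):
        maps = rng.normal(size=(8, 120))
        mask = np.ones((120, 1, 1), bool)
        groups = ["a"] * 4 + ["b"] * 4
        gm, table = compare_groups_ica(maps, groups, mask,
                                       n_permutations=200, seed=0)
        assert len(table.significant(0.01)) == 0

    def test_label_swap_flips_statistic_sign(self, rng):
        maps = rng.normal(size=(8, 50))
        mask = np.ones((50, 1, 1), bool)
        g1 = ["a"] * 4 + ["b"] * 4
        g2 = ["b"] * 4 + ["a"] * 4
        gm1, _ = compare_groups_ica(maps, g1, mask, n_permutations=120, seed=0)
        gm2, _ = compare_groups_ica(maps, g2, mask, n_permutations=120, seed=0)
        np.testing.assert_allclose(gm1.stat, -gm2.stat, atol=1e-12)

    def test_small_group_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            compare_groups_ica(rng.normal(size=(3, 20)), ["a", "a", "b"],
                               np.ones((20, 1, 1), bool))
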