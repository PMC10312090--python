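"""Three-pool fitting: initialization, single-voxel and volume fits."""

import numpy as np
import pytest

import cswater as cw
from cswater.relaxometry import Q_NONCONVERGED, Q_OK, Q_UNFITTABLE, _objective, _pack

from conftest import three_pool_signal

TE = np.array(cw.DEFAULT_TE_MS)


class TestLogLinearInit:
    def test_exact_mono_exponential(self):
        te4 = TE[:4]
        s = 100.0 * np.exp(-te4 / 70.0)
        assert cw.loglinear_init_t2(s, te4) == pytest.approx(70.0, rel=1e-10)

    def test_constant_signal_clamps_to_upper_bound(self):
        assert cw.loglinear_init_t2(np.full(4, 50.0), TE[:4]) == 200.0

    def test_zero_signal_falls_back(self):
        s = np.array([100.0, 80.0, 0.0, 40.0])
        assert cw.loglinear_init_t2(s, TE[:4]) == 70.0

    def test_rising_signal_falls_back(self):
        s = np.array([10.0, 20.0, 40.0, 80.0])
        assert cw.loglinear_init_t2(s, TE[:4]) == 70.0


class TestInitPools:
    def test_amplitude_and_t2_initialization_rule(self):
        s = np.array([1000.0, 900.0, 800.0, 500.0, 200.0, 50.0])
        init = cw.init_pools(s, TE)
        assert init.amplitudes == pytest.approx((100.0, 900.0, 50.0))
        assert init.t2s[0] == 10.0 and init.t2s[2] == 2000.0

    def test_pure_iew_pool_recovers_t2_init(self):
        s = 100.0 * np.exp(-TE / 70.0)
        init = cw.init_pools(s, TE)
        assert init.t2s[1] == pytest.approx(70.0, rel=1e-8)

    def test_all_zero_voxel_is_unfittable(self):
        assert cw.init_pools(np.zeros(6), TE) is None


class TestFitVoxel:
    def test_noiseless_round_trip(self):
        amps, t2s = (10.0, 85.0, 5.0), (10.0, 70.0, 1000.0)
        s = three_pool_signal(amps, t2s, TE)
        pools, resid, conv = cw.fit_voxel(s, TE)
        wf = cw.compute_wf(pools)
        assert conv
        assert wf == pytest.approx((0.10, 0.85, 0.05), abs=0.01)

    def test_single_pool_signal_yields_negligible_other_pools(self):
        s = three_pool_signal((0.0, 100.0, 0.0), (10.0, 70.0, 1000.0), TE)
        pools, _, _ = cw.fit_voxel(s, TE)
        mwf, iewf, csff = cw.compute_wf(pools)
        assert mwf <= 0.01 and csff <= 0.01

    def test_zero_signal_flagged(self):
        pools, _, conv = cw.fit_voxel(np.zeros(6), TE)
        assert pools is None and conv

    def test_objective_never_increases_from_init(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            amps = rng.uniform(0, 100, 3)
            t2s = (rng.uniform(8, 15), rng.uniform(50, 120), rng.uniform(800, 2000))
            s = three_pool_signal(amps, t2s, TE) + rng.normal(0, 2.0, TE.size)
            s = np.maximum(s, 0.0)
            init = cw.init_pools(s, TE)
            if init is None:
                continue
            pools, resid, _ = cw.fit_voxel(s, TE, init=init)
            f_init = _objective(_pack(init), TE, s)[0]
            assert resid**2 <= f_init + 1e-9

    def test_t2s_respect_pool_bounds(self):
        rng = np.random.default_rng(6)
        bounds = cw.DEFAULT_BOUNDS.as_tuple()
        for _ in range(30):
            amps = rng.uniform(0, 100, 3)
            t2s = (rng.uniform(8, 15), rng.uniform(50, 120), rng.uniform(800, 2000))
            s = three_pool_signal(amps, t2s, TE) + rng.normal(0, 5.0, TE.size)
            pools, _, _ = cw.fit_voxel(np.maximum(s, 0), TE)
            for t, (lo, hi) in zip(pools.t2s, bounds):
                assert lo - 1e-9 <= t <= hi + 1e-9

    def test_round_trip_recovery_property(self):
        # over 100 random well-separated truths, noiseless fits recover
        # fractions within 0.02 in at least 95% of cases
        rng = np.random.default_rng(11)
        n_ok = 0
        for _ in range(100):
            amps = rng.uniform(5, 100, 3)
            t2s = (rng.uniform(8, 15), rng.uniform(50, 120), rng.uniform(800, 2000))
            s = three_pool_signal(amps, t2s, TE)
            pools, _, _ = cw.fit_voxel(s, TE)
            wf = np.array(cw.compute_wf(pools))
            truth = np.array(amps) / np.sum(amps)
            if np.max(np.abs(wf - truth)) <= 0.02:
                n_ok += 1
        assert n_ok >= 95


class TestComputeWF:
    @pytest.mark.parametrize(
        "amps,expected",
        [((10.0, 85.0, 5.0), (0.10, 0.85, 0.05)), ((0.0, 1.0, 0.0), (0.0, 1.0, 0.0))],
    )
    def test_direct_ratios(self, amps, expected):
        pools = cw.VoxelPools(amplitudes=amps, t2s=(10, 70, 1000))
        wf = cw.compute_wf(pools)
        assert wf == pytest.approx(expected)
        assert sum(wf) == pytest.approx(1.0, abs=1e-12)

    def test_zero_total_is_undefined(self):
        pools = cw.VoxelPools(amplitudes=(0.0, 0.0, 0.0), t2s=(10, 70, 1000))
        assert cw.compute_wf(pools) is None


def _toy_volume(signals, voxel_size=(1.3, 1.3, 5.0)):
    """1 x n x 1 echo volume from a list of per-voxel signals."""
    data = np.zeros((1, len(signals), 1, TE.size))
    for i, s in enumerate(signals):
        data[0, i, 0] = s
    return cw.EchoVolume(data, voxel_size=voxel_size)


class TestFitVolume:
    def test_lambda_zero_equals_independent_voxel_fits(self):
        signals = [
            three_pool_signal((10, 85, 5), (10, 70, 1000), TE),
            three_pool_signal((5, 90, 5), (12, 90, 1500), TE),
            three_pool_signal((0, 100, 0), (10, 70, 1000), TE),
        ]
        vol = _toy_volume(signals)
        mask = np.ones(vol.shape, dtype=bool)
        res = cw.fit_volume(vol, mask)
        for i, s in enumerate(signals):
            pools, rnorm, _ = cw.fit_voxel(s, TE)
            np.testing.assert_allclose(res.amplitudes[0, i, 0], pools.amplitudes)
            np.testing.assert_allclose(res.t2s[0, i, 0], pools.t2s)
            assert res.residual[0, i, 0] == pytest.approx(rnorm, abs=1e-12)

    def test_fraction_normalization_on_fitted_voxels(self, clean_volume, label_volume):
        mask = np.zeros(clean_volume.shape, dtype=bool)
        mask[12:16, 12:16, 7] = True
        mask &= label_volume.labels > 0
        res = cw.fit_volume(clean_volume, mask)
        d = res.wf.defined
        total = res.wf.mwf[d] + res.wf.iewf[d] + res.wf.csff[d]
        np.testing.assert_allclose(total, 1.0, atol=1e-9)

    def test_zero_voxels_flagged_not_silently_zero(self):
        signals = [three_pool_signal((10, 85, 5), (10, 70, 1000), TE), np.zeros(TE.size)]
        vol = _toy_volume(signals)
        res = cw.fit_volume(vol, np.ones(vol.shape, bool))
        assert res.quality[0, 1, 0] == Q_UNFITTABLE
        assert not res.wf.defined[0, 1, 0]
        assert np.isnan(res.wf.csff[0, 1, 0])

    def test_empty_mask_and_nonfinite_input_rejected(self):
        vol = _toy_volume([three_pool_signal((10, 85, 5), (10, 70, 1000), TE)])
        with pytest.raises(ValueError, match="empty"):
            cw.fit_volume(vol, np.zeros(vol.shape, bool))
        vol.data[0, 0, 0, 2] = np.nan
        with pytest.raises(ValueError, match="voxel"):
            cw.fit_volume(vol, np.ones(vol.shape, bool))

    def test_uniform_noiseless_volume_stays_constant_under_smoothing(self):
        s = three_pool_signal((10, 85, 5), (10, 70, 1000), TE)
        data = np.tile(s, (3, 3, 2, 1))
        vol = cw.EchoVolume(data, voxel_size=(1.3, 1.3, 5.0))
        mask = np.ones(vol.shape, bool)
        res = cw.fit_volume(
            vol, mask, config=cw.FitConfig(lambda_laplacian=100.0, n_sweeps=1)
        )
        # the Laplacian penalty vanishes on constants: maps stay uniform
        for arr in (res.wf.mwf, res.wf.iewf, res.wf.csff):
            assert np.nanstd(arr[mask]) < 1e-6

    def test_smoothing_reduces_csff_error_under_noise(self):
        # piecewise-constant two-tissue slab with nc-chi noise: the
        # spatially regularized fit should not be worse than independent
        # fits for the CSFF map, averaged over seeds
        labels = np.ones((6, 6, 2), dtype=np.int16)
        labels[3:, :, :] = 2
        lab = cw.LabelVolume(labels, voxel_size=(1.3, 1.3, 5.0))
        truth = cw.default_tissue_truth()
        clean = cw.forward_signal(truth, lab)
        nm = cw.NoiseModel(10.0, 32)
        tab = cw.build_correction_table(nm)
        true_csff = np.where(labels == 1, 0.05 / 1.0, 0.04 / 1.0)
        mask = np.ones(clean.shape, bool)
        rmse = {0.0: [], 100.0: []}
        for seed in range(10):
            noisy = cw.add_ncchi_noise(clean, nm, seed=seed)
            corr = cw.correct_magnitude(noisy, tab)
            for lam in rmse:
                res = cw.fit_volume(
                    corr, mask, config=cw.FitConfig(lambda_laplacian=lam, n_sweeps=2)
                )
                err = res.wf.csff[mask] - true_csff[mask]
                rmse[lam].append(np.sqrt(np.nanmean(err**2)))
        assert np.mean(rmse[100.0]) <= np.mean(rmse[0.0])

    def test_csff_bias_small_after_noise_correction(self):
        # uniform WM phantom at first-echo SNR 100 with 32-coil nc-chi
        # noise: with bias correction and the spatially regularized fit
        # the mean CSFF error stays below 0.01, and is strictly larger
        # when the correction is skipped
        lab = cw.LabelVolume(np.ones((6, 6, 3), dtype=np.int16), voxel_size=(1.3, 1.3, 5.0))
        truth = cw.default_tissue_truth()
        clean = cw.forward_signal(truth, lab)
        sigma = sum(truth.amplitudes[1]) / 100.0
        nm = cw.NoiseModel(sigma, 32)
        tab = cw.build_correction_table(nm)
        mask = np.ones(clean.shape, bool)
        cfg = cw.FitConfig(lambda_laplacian=100.0, n_sweeps=2)
        bias_corr, bias_raw = [], []
        for seed in range(2):
            noisy = cw.add_ncchi_noise(clean, nm, seed=seed)
            corr = cw.correct_magnitude(noisy, tab)
            fit_c = cw.fit_volume(corr, mask, config=cfg)
            fit_r = cw.fit_volume(noisy, mask, config=cfg)
            bias_corr.append(np.nanmean(fit_c.wf.csff[mask]) - 0.05)
            bias_raw.append(np.nanmean(fit_r.wf.csff[mask]) - 0.05)
        assert abs(np.mean(bias_corr)) < 0.01
        assert abs(np.mean(bias_raw)) > abs(np.mean(bias_corr))
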