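import numpy as np
import pytest

from bbbdce.concentration import ConcentrationCurve
from bbbdce.patlak import (
    default_onset_min,
    fit_patlak_volume,
    fit_patlak_voxel,
    integrate_vif,
    merge_dual_resolution,
)
from bbbdce.phantom import (
    AcquisitionSchedule,
    BolusParams,
    WHITE_MATTER,
    patlak_forward,
    plasma_concentration,
    simulate_vif,
)


@pytest.fixture(scope="module")
def vif():
    return simulate_vif(AcquisitionSchedule())


def _split(curve, n):
    return (
        ConcentrationCurve(curve.times[:n], curve.values[:n], curve.compartment),
        ConcentrationCurve(curve.times[n:], curve.values[n:], curve.compartment),
    )


class TestMergeDualResolution:
    def test_frame_count_29_plus_30(self, vif):
        fast, slow = _split(vif, 29)
        merged = merge_dual_resolution(fast, slow)
        assert len(merged) == 59

    def test_plain_concatenation_when_continuous(self, vif):
        fast, slow = _split(vif, 29)
        merged = merge_dual_resolution(fast, slow, match_offset=False)
        np.testing.assert_array_equal(merged.values, vif.values)
        np.testing.assert_array_equal(merged.times, vif.times)

    def test_offset_matching_removes_step(self, vif):
        fast, slow = _split(vif, 29)
        shifted = slow.with_values(slow.values + 0.1)
        merged = merge_dual_resolution(fast, shifted, match_offset=True)
        # junction is continuous: first slow frame equals last fast frame
        assert merged.values[29] == pytest.approx(fast.values[-1], rel=1e-12)

    def test_overlapping_ranges_rejected(self, vif):
        fast, _ = _split(vif, 29)
        with pytest.raises(ValueError, match="overlap"):
            merge_dual_resolution(fast, fast)


class TestIntegrateVif:
    def test_constant_curve(self):
        t = np.linspace(0.0, 10.0, 51)
        curve = ConcentrationCurve(t, np.ones_like(t), "plasma")
        integral = integrate_vif(curve)
        assert integral.values[0] == 0.0
        assert integral.values[-1] == pytest.approx(10.0, rel=1e-12)

    def test_linear_ramp_exact(self):
        t = np.linspace(0.0, 4.0, 9)
        curve = ConcentrationCurve(t, t, "plasma")
        integral = integrate_vif(curve)
        np.testing.assert_allclose(integral.values, t**2 / 2.0, rtol=0, atol=1e-14)

    def test_gamma_variate_matches_fine_grid(self, vif):
        integral = integrate_vif(vif)
        t_fine = np.linspace(vif.times[0], vif.times[-1], 200_001)
        fine = np.trapezoid(
            plasma_concentration(
                t_fine, AcquisitionSchedule().bolus_arrival_min, BolusParams()
            ),
            t_fine,
        )
        assert integral.values[-1] == pytest.approx(fine, rel=0.01)

    def test_nondecreasing_for_nonnegative_input(self, vif):
        integral = integrate_vif(vif)
        assert np.all(np.diff(integral.values) >= 0)


class TestFitPatlakVoxel:
    def test_forward_model_recovered_to_machine_precision(self, vif):
        ct = patlak_forward(vif, 1e-3, 0.02)
        ki, vp, resid = fit_patlak_voxel(ct, vif, onset_min=0.5)
        assert ki == pytest.approx(1e-3, rel=1e-9)
        assert vp == pytest.approx(0.02, rel=1e-9)
        assert resid == pytest.approx(0.0, abs=1e-12)

    def test_zero_tissue_curve(self, vif):
        ct = vif.with_values(np.zeros_like(vif.values))
        ki, vp, _ = fit_patlak_voxel(ct, vif)
        assert ki == pytest.approx(0.0, abs=1e-15)
        assert vp == pytest.approx(0.0, abs=1e-15)

    def test_matches_brute_force_grid_search(self, vif, rng):
        # independent oracle: exhaustive SSE minimisation on a (Ki, vp) grid
        onset = default_onset_min(AcquisitionSchedule())
        sel = vif.times >= onset
        from scipy.integrate import cumulative_trapezoid

        cum = cumulative_trapezoid(vif.values, vif.times, initial=0.0)
        ki_grid = np.linspace(0.0, 6e-3, 241)
        vp_grid = np.linspace(0.0, 0.06, 241)
        dki = ki_grid[1] - ki_grid[0]
        dvp = vp_grid[1] - vp_grid[0]
        for _ in range(5):
            ki_true = rng.uniform(5e-4, 5e-3)
            vp_true = rng.uniform(0.005, 0.05)
            ct = patlak_forward(vif, ki_true, vp_true)
            noisy = ct.with_values(ct.values + rng.normal(0.0, 1e-4, len(ct)))
            ki_hat, vp_hat, _ = fit_patlak_voxel(noisy, vif, onset)
            model = (
                ki_grid[:, None, None] * cum[None, None, sel]
                + vp_grid[None, :, None] * vif.values[None, None, sel]
            )
            sse = np.sum((model - noisy.values[sel][None, None, :]) ** 2, axis=-1)
            i, j = np.unravel_index(np.argmin(sse), sse.shape)
            assert abs(ki_hat - ki_grid[i]) <= dki
            assert abs(vp_hat - vp_grid[j]) <= dvp

    def test_scaling_equivariance(self, vif, rng):
        ct = patlak_forward(vif, 2e-3, 0.03)
        noisy = ct.with_values(ct.values + rng.normal(0.0, 1e-4, len(ct)))
        ki1, vp1, _ = fit_patlak_voxel(noisy, vif, 0.5)
        a = 7.3
        ki2, vp2, _ = fit_patlak_voxel(
            noisy.with_values(a * noisy.values), vif.with_values(a * vif.values), 0.5
        )
        assert ki2 == pytest.approx(ki1, rel=1e-9)
        assert vp2 == pytest.approx(vp1, rel=1e-9)

    def test_unbiased_under_zero_mean_noise(self, vif):
        rng = np.random.default_rng(7)
        ki_true, vp_true = 1.5e-3, 0.02
        ct = patlak_forward(vif, ki_true, vp_true)
        estimates = np.empty(1000)
        for r in range(1000):
            noisy = ct.with_values(ct.values + rng.normal(0.0, 5e-3, len(ct)))
            estimates[r], _, _ = fit_patlak_voxel(noisy, vif, 0.5)
        se = estimates.std(ddof=1) / np.sqrt(estimates.size)
        assert abs(estimates.mean() - ki_true) < 2 * se

    def test_singular_design_rejected(self):
        t = np.linspace(0.0, 5.0, 10)
        zero_vif = ConcentrationCurve(t, np.zeros_like(t), "plasma")
        ct = ConcentrationCurve(t, np.zeros_like(t), "tissue")
        with pytest.raises(np.linalg.LinAlgError):
            fit_patlak_voxel(ct, zero_vif)

    def test_too_few_points_after_onset(self, vif):
        ct = patlak_forward(vif, 1e-3, 0.02)
        with pytest.raises(ValueError, match="3 time points"):
            fit_patlak_voxel(ct, vif, onset_min=vif.times[-2])

    def test_negative_ki_preserved_for_noise_voxels(self, vif):
        # pure negative-trend curve must be allowed to fit below zero
        cum_like = -1e-3 * np.linspace(0, 1, len(vif)) * vif.values.max()
        ct = vif.with_values(cum_like)
        ki, _, _ = fit_patlak_voxel(ct, vif, 0.5)
        assert ki < 0


class TestFitPatlakVolume:
    def _volume(self, vif, rng, shape=(4, 3, 2), noise=0.0):
        labels = np.full(shape, WHITE_MATTER)
        labels[0, 0, 0] = 0  # background voxel stays unfitted
        ki = rng.uniform(5e-4, 5e-3, shape)
        vp = rng.uniform(0.005, 0.05, shape)
        conc = np.empty(shape + (len(vif),))
        for idx in np.ndindex(shape):
            conc[idx] = patlak_forward(vif, ki[idx], vp[idx]).values
        if noise:
            conc = conc + rng.normal(0.0, noise, conc.shape)
        return labels, ki, vp, conc

    def test_matches_single_voxel_fits(self, vif, rng):
        labels, ki, vp, conc = self._volume(vif, rng, noise=1e-4)
        result = fit_patlak_volume(conc, vif.times, vif, labels, onset_min=0.5)
        for idx in np.ndindex(labels.shape):
            if labels[idx] == 0:
                continue
            curve = ConcentrationCurve(vif.times, conc[idx], "tissue")
            ki_v, vp_v, resid_v = fit_patlak_voxel(curve, vif, 0.5)
            assert result.ki_map[idx] == pytest.approx(ki_v, rel=1e-10)
            assert result.vp_map[idx] == pytest.approx(vp_v, rel=1e-10)
            assert result.residual_map[idx] == pytest.approx(resid_v, abs=1e-12)

    def test_noiseless_recovery_exact(self, vif, rng):
        labels, ki, vp, conc = self._volume(vif, rng)
        result = fit_patlak_volume(conc, vif.times, vif, labels, onset_min=0.5)
        fitted = labels == WHITE_MATTER
        np.testing.assert_allclose(result.ki_map[fitted], ki[fitted], rtol=1e-8)
        np.testing.assert_allclose(result.vp_map[fitted], vp[fitted], rtol=1e-8)
        assert np.nanmax(result.residual_map) < 1e-12

    def test_masked_voxels_are_nan(self, vif, rng):
        labels, _, _, conc = self._volume(vif, rng)
        result = fit_patlak_volume(conc, vif.times, vif, labels, onset_min=0.5)
        assert np.isnan(result.ki_map[0, 0, 0])
        assert np.isnan(result.vp_map[0, 0, 0])
        assert np.isnan(result.residual_map[0, 0, 0])

    def test_empty_mask_rejected(self, vif):
        conc = np.zeros((2, 2, 2, len(vif)))
        labels = np.zeros((2, 2, 2), dtype=int)
        with pytest.raises(ValueError, match="no voxels"):
            fit_patlak_volume(conc, vif.times, vif, labels)

    def test_frame_count_mismatch_rejected(self, vif):
        conc = np.zeros((2, 2, 2, 10))
        labels = np.full((2, 2, 2), WHITE_MATTER)
        with pytest.raises(ValueError, match="frame count"):
            fit_patlak_volume(conc, vif.times, vif, labels)

    def test_noisy_roi_mean_within_10_percent(self, vif):
        # ~1000 voxels, noise sized for voxel-level Ki SNR ~ 2
        rng = np.random.default_rng(21)
        shape = (10, 10, 10)
        labels = np.full(shape, WHITE_MATTER)
        ki_true, vp_true = 2e-3, 0.02
        ct = patlak_forward(vif, ki_true, vp_true)
        conc = np.broadcast_to(ct.values, shape + (len(vif),)).copy()
        conc = conc + rng.normal(0.0, 2.2e-3, conc.shape)
        result = fit_patlak_volume(conc, vif.times, vif, labels, onset_min=0.5)
        assert np.nanmean(result.ki_map) == pytest.approx(ki_true, rel=0.10)
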