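"""Tests for preprocessing, AIF selection and SVD deconvolution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perfstab.perfusion import (
    AifSelection,
    BolusNotFoundError,
    AifSelectionError,
    DynamicSeries,
    PreprocessedSeries,
    _deconvolution_matrix,
    _fwhm_of_curve,
    compute_maps,
    deconvolve_voxelwise,
    normalize_relative,
    preprocess_series,
    select_aif,
)
from perfstab.phantom import AifParams, make_aif


def _series_from_curves(curves, dt=2.0, voxel=(3.0, 3.0, 4.0)):
    """Pack a (nvox, nt) curve bank into a 1-voxel-deep DynamicSeries."""
    curves = np.asarray(curves, dtype=float)
    nvox, nt = curves.shape
    data = curves.reshape(nvox, 1, 1, nt)
    return DynamicSeries(data, np.arange(nt) * dt, voxel)


def _pre_from_curves(curves, dt=2.0, baseline=0.0):
    series = _series_from_curves(curves, dt)
    shape = series.data.shape[:3]
    return PreprocessedSeries(
        series=series,
        baseline=np.full(shape, baseline, dtype=np.float32),
        arrival_index=3,
        brain_mask=np.ones(shape, dtype=bool),
    )


def _aif_from_curve(curve, t):
    return AifSelection(
        curve=np.asarray(curve, float),
        voxel_location=(0, 0, 0),
        time_to_peak_s=float(t[np.argmax(curve)]),
        peak_amplitude_hu=float(np.max(curve)),
        fwhm_s=_fwhm_of_curve(t, np.asarray(curve, float)),
        quality=1.0,
    )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

class TestPreprocess:
    def test_constant_series_has_no_bolus(self):
        curves = np.full((40, 20), 30.0)
        with pytest.raises(BolusNotFoundError):
            preprocess_series(
                _series_from_curves(curves), smoothing_fwhm_mm=0,
                temporal_smoothing_frames=0,
            )

    def test_identity_when_all_filters_off(self, noisy_scan):
        pre = preprocess_series(
            noisy_scan.ctp,
            smoothing_fwhm_mm=0.0,
            temporal_smoothing_frames=0.0,
            motion_correction=False,
        )
        np.testing.assert_array_equal(pre.series.data, noisy_scan.ctp.data)

    def test_arrival_index_matches_bolus_onset(self, noisefree_scan):
        # bolus onset t0 = 10 s at dt = 2 s -> arrival at frame 5 +/- 1
        pre = preprocess_series(noisefree_scan.ctp, smoothing_fwhm_mm=0,
                                temporal_smoothing_frames=0)
        assert abs(pre.arrival_index - 5) <= 1

    def test_baseline_is_mean_of_prearrival_frames(self, noisefree_scan):
        pre = preprocess_series(noisefree_scan.ctp, smoothing_fwhm_mm=0,
                                temporal_smoothing_frames=0)
        expected = noisefree_scan.ctp.data[..., : pre.arrival_index].mean(axis=-1)
        np.testing.assert_allclose(pre.baseline, expected, atol=1e-5)

    def test_early_arrival_warns_and_falls_back(self):
        # bolus already rising at frame 2: fewer than 3 clean baseline frames
        curve = np.array([30.0, 30.0] + [30.0 + 20.0 * i for i in range(1, 19)])
        curves = np.tile(curve, (30, 1))
        pre = preprocess_series(_series_from_curves(curves),
                                smoothing_fwhm_mm=0, temporal_smoothing_frames=0)
        assert pre.arrival_index == 2
        assert pre.warnings and "pre-arrival" in pre.warnings[0]
        np.testing.assert_allclose(pre.baseline.ravel()[0],
                                   curve[:3].mean(), rtol=1e-6)

    def test_rigid_motion_correction_recovers_translation(self):
        rng = np.random.default_rng(0)
        base = np.zeros((24, 24, 12), dtype=np.float32)
        base[6:18, 6:18, 3:9] = 40.0
        from scipy.ndimage import gaussian_filter, shift

        base = gaussian_filter(base, 1.5)
        nt = 15
        data = np.repeat(base[..., None], nt, axis=-1)
        data[..., 7] = shift(base, (2.0, 0.0, 0.0), order=1)
        from perfstab.perfusion import _rigid_motion_correct

        corrected = _rigid_motion_correct(data + 30.0, (3.0, 3.0, 4.0))
        err_before = np.abs(data[..., 7] - data[..., 0]).mean()
        err_after = np.abs(corrected[..., 7] - corrected[..., 0]).mean()
        assert err_after < 0.2 * err_before


class TestSeriesValidation:
    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="time points"):
            DynamicSeries(np.zeros((4, 4, 4, 10)), np.arange(10) * 2.0, (3, 3, 4))

    def test_non_uniform_sampling_rejected(self):
        t = np.arange(20) * 2.0
        t[10:] += 3.0
        with pytest.raises(ValueError, match="uniform"):
            DynamicSeries(np.zeros((4, 4, 4, 20)), t, (3, 3, 4))


# ---------------------------------------------------------------------------
# AIF selection
# ---------------------------------------------------------------------------

class TestSelectAif:
    def test_selects_artery_on_phantom(self, noisy_scan, default_truth):
        pre = preprocess_series(noisy_scan.ctp, brain_mask=default_truth.brain_mask)
        aif = select_aif(pre)
        assert default_truth.artery_mask[aif.voxel_location]
        assert aif.pool == "arterial"
        assert aif.peak_amplitude_hu > 60.0

    def test_arterial_pool_is_earlier_cluster(self):
        # artery: early narrow bolus; vein: 4 s later and 30% taller
        t = np.arange(25) * 2.0
        art = make_aif(AifParams(t0_s=8.0), t)
        vein = 1.3 * make_aif(AifParams(t0_s=12.0), t)
        tissue = 0.05 * make_aif(AifParams(t0_s=10.0, beta_s=4.0), t)
        curves = np.vstack([np.tile(art, (6, 1)), np.tile(vein, (6, 1)),
                            np.tile(tissue, (48, 1))])
        rng = np.random.default_rng(0)
        curves = curves + rng.normal(0, 0.5, curves.shape)
        pre = _pre_from_curves(curves)
        aif = select_aif(pre, candidate_fraction=0.25, min_component_voxels=1)
        assert aif.voxel_location[0] < 6  # one of the arterial voxels
        assert abs(aif.time_to_peak_s - 11.0) <= 2.0

    def test_tie_broken_by_lowest_linear_index(self):
        t = np.arange(25) * 2.0
        cand = make_aif(AifParams(), t)
        curves = np.vstack([np.zeros((3, 25)), np.tile(cand, (2, 1))])
        pre = _pre_from_curves(curves)
        first = select_aif(pre, candidate_fraction=0.5, min_component_voxels=1)
        second = select_aif(pre, candidate_fraction=0.5, min_component_voxels=1)
        assert first.voxel_location == second.voxel_location == (3, 0, 0)

    def test_no_candidates_above_floor_fails(self):
        curves = np.full((40, 20), 30.0)
        curves[:, 10] = 35.0  # tiny bump, far below the floor
        pre = _pre_from_curves(curves, baseline=30.0)
        with pytest.raises(AifSelectionError):
            select_aif(pre, amplitude_floor_hu=60.0)


# ---------------------------------------------------------------------------
# deconvolution
# ---------------------------------------------------------------------------

class TestDeconvolve:
    def test_impulse_aif_identity(self):
        # impulse AIF with rectangle quadrature: A = dt * I, so k = c / dt
        t = np.arange(20) * 2.0
        impulse = np.zeros(20)
        impulse[0] = 1.0
        rng = np.random.default_rng(1)
        curves = rng.uniform(0, 10, size=(15, 20))
        pre = _pre_from_curves(curves)
        aif = _aif_from_curve(impulse, t)
        res = deconvolve_voxelwise(pre, aif, lambda_rel=0.0,
                                   use_circulant=False, quadrature="rectangle")
        np.testing.assert_allclose(res.k.T, curves / 2.0, atol=1e-8)

    def test_recovers_flow_scaled_residue_noise_free(self):
        # discrete forward model c = A k with k = CBF * exp(-t/MTT):
        # lambda <= 0.01 recovers max k (the flow) within 5%
        t = np.arange(25) * 2.0
        aif_curve = make_aif(AifParams(), t)
        cbf = 0.01  # 60 mL/100g/min in 1/s units
        k_true = cbf * np.exp(-t / 4.0)
        A = _deconvolution_matrix(aif_curve, 2.0, use_circulant=False)
        c = A @ k_true
        pre = _pre_from_curves(c[None, :])
        aif = _aif_from_curve(aif_curve, t)
        res = deconvolve_voxelwise(pre, aif, lambda_rel=0.01)
        assert res.k[:, 0].max() == pytest.approx(cbf, rel=0.05)

    def test_pure_delay_peaks_at_delay_sample(self):
        t = np.arange(25) * 2.0
        aif_curve = make_aif(AifParams(), t)
        m = 4
        delayed = np.zeros_like(aif_curve)
        delayed[m:] = aif_curve[:-m]
        pre = _pre_from_curves(delayed[None, :])
        aif = _aif_from_curve(aif_curve, t)
        res = deconvolve_voxelwise(pre, aif, lambda_rel=0.01, use_circulant=True)
        assert abs(int(np.argmax(res.k[:, 0])) - m) <= 1

    def test_matches_direct_tikhonov_solve(self):
        # SVD filter-factor path == normal-equations solve on small systems
        rng = np.random.default_rng(2)
        t = np.arange(18) * 2.0
        aif_curve = make_aif(AifParams(t0_s=4.0), t)
        curves = rng.normal(0, 5, size=(7, 18))
        aif = _aif_from_curve(aif_curve, t)
        for circulant in (False, True):
            pre = _pre_from_curves(curves)
            res = deconvolve_voxelwise(pre, aif, lambda_rel=0.1,
                                       use_circulant=circulant)
            A = _deconvolution_matrix(aif_curve, 2.0, circulant)
            lam = 0.1 * np.linalg.svd(A, compute_uv=False)[0]
            c = curves.T
            if circulant:
                c = np.vstack([c, np.zeros_like(c)])
            k_direct = np.linalg.solve(A.T @ A + lam**2 * np.eye(A.shape[0]),
                                       A.T @ c)
            np.testing.assert_allclose(res.k, k_direct[: len(t)], rtol=1e-8,
                                       atol=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(st.floats(min_value=0.0, max_value=0.5),
           st.floats(min_value=0.01, max_value=0.5))
    def test_regularization_monotonically_shrinks_solution(self, lam1, extra):
        t = np.arange(20) * 2.0
        aif_curve = make_aif(AifParams(t0_s=4.0), t)
        rng = np.random.default_rng(0)
        curves = rng.normal(0, 5, size=(3, 20))
        pre1 = _pre_from_curves(curves)
        pre2 = _pre_from_curves(curves)
        aif = _aif_from_curve(aif_curve, t)
        k1 = deconvolve_voxelwise(pre1, aif, lambda_rel=lam1).k
        k2 = deconvolve_voxelwise(pre2, aif, lambda_rel=lam1 + extra).k
        assert np.linalg.norm(k2) <= np.linalg.norm(k1) + 1e-9

    def test_invalid_inputs_rejected(self):
        t = np.arange(20) * 2.0
        pre = _pre_from_curves(np.ones((2, 20)))
        aif = _aif_from_curve(make_aif(AifParams(t0_s=4.0), t), t)
        with pytest.raises(ValueError):
            deconvolve_voxelwise(pre, aif, lambda_rel=-0.1)
        zero = _aif_from_curve(np.zeros(20), t)
        with pytest.raises(ValueError, match="zero"):
            deconvolve_voxelwise(pre, zero)


# ---------------------------------------------------------------------------
# map computation and normalization
# ---------------------------------------------------------------------------

class TestComputeMaps:
    def _maps_from_k(self, k_bank, curves=None, dt=2.0):
        t = np.arange(k_bank.shape[1]) * dt
        from perfstab.perfusion import ResidueEstimate

        nvox = k_bank.shape[0]
        mask = np.ones((nvox, 1, 1), dtype=bool)
        res = ResidueEstimate(k=k_bank.T.copy(), mask=mask, time_axis=t,
                              lambda_rel=0.1, circulant=True)
        if curves is None:
            curves = np.ones((nvox, len(t)))
        pre = _pre_from_curves(curves, dt)
        aif = _aif_from_curve(make_aif(AifParams(t0_s=4.0), t), t)
        return compute_maps(res, pre, aif)

    def test_tmax_is_time_of_peak(self):
        k = np.zeros((1, 20))
        k[0, 3] = 1.0
        maps = self._maps_from_k(k)
        assert maps.tmax[0, 0, 0] == 6.0
        assert maps.cbf[0, 0, 0] == 1.0

    def test_tmax_tie_takes_first_maximum(self):
        k = np.zeros((1, 20))
        k[0, 3] = k[0, 5] = 2.0
        maps = self._maps_from_k(k)
        assert maps.tmax[0, 0, 0] == 6.0

    def test_mtt_is_cbv_over_cbf(self, default_analysis):
        maps = default_analysis.maps
        ok = maps.brain_mask & (maps.cbf > 1e-9) & np.isfinite(maps.mtt)
        np.testing.assert_allclose(
            maps.mtt[ok], maps.cbv[ok] / maps.cbf[ok], rtol=1e-6
        )

    def test_negative_enhancement_clipped_in_cbv(self):
        k = np.ones((1, 20))
        curves = -5.0 * np.ones((1, 20))
        maps = self._maps_from_k(k, curves)
        assert maps.cbv[0, 0, 0] == 0.0

    def test_phantom_mtt_recovery_via_central_volume(self, noisefree_scan,
                                                     default_truth):
        # noise-free, light regularization, no smoothing: CBV/CBF recovers the
        # true MTT up to the residual CBF damping of the discrete deconvolution
        pre = preprocess_series(noisefree_scan.ctp,
                                brain_mask=default_truth.brain_mask,
                                smoothing_fwhm_mm=0.0,
                                temporal_smoothing_frames=0.0)
        aif = select_aif(pre)
        maps = compute_maps(deconvolve_voxelwise(pre, aif, lambda_rel=0.01),
                            pre, aif)
        gm_normal = (
            default_truth.gm_mask
            & (default_truth.true_delay == 0)
            & ~(default_truth.artery_mask | default_truth.vein_mask)
        )
        rec = np.nanmedian(maps.mtt[gm_normal])
        assert rec == pytest.approx(4.0, rel=0.25)


class TestNormalizeRelative:
    def _uniform_maps(self, cbf_value=1.0, tmax_value=0.0):
        from perfstab.perfusion import PerfusionMaps

        shape = (6, 6, 6)
        mask = np.ones(shape, dtype=bool)
        return PerfusionMaps(
            cbf=np.full(shape, cbf_value),
            cbv=np.full(shape, cbf_value * 4.0),
            mtt=np.full(shape, 4.0),
            tmax=np.full(shape, tmax_value),
            brain_mask=mask,
        )

    def test_uniform_cbf_gives_100_percent(self):
        maps = normalize_relative(self._uniform_maps())
        assert np.allclose(maps.rcbf, 100.0)
        assert np.allclose(maps.rcbv, 100.0)

    def test_scale_invariance(self):
        m1 = normalize_relative(self._uniform_maps(cbf_value=1.0))
        m2 = normalize_relative(self._uniform_maps(cbf_value=2.0))
        np.testing.assert_allclose(m1.rcbf, m2.rcbf)

    def test_no_normal_tissue_is_an_error(self):
        maps = self._uniform_maps(tmax_value=10.0)
        with pytest.raises(ValueError, match="normally perfused"):
            normalize_relative(maps)

    def test_phantom_rcbf_matches_truth_noise_free(self, noisefree_scan,
                                                   default_truth):
        # relative CBF cancels the systematic deconvolution scale, so the
        # recovered rCBF should track the ground-truth rCBF voxelwise
        pre = preprocess_series(noisefree_scan.ctp,
                                brain_mask=default_truth.brain_mask,
                                smoothing_fwhm_mm=0.0,
                                temporal_smoothing_frames=0.0)
        aif = select_aif(pre)
        maps = normalize_relative(
            compute_maps(deconvolve_voxelwise(pre, aif), pre, aif)
        )
        core = default_truth.core_mask
        true_med = np.nanmedian(default_truth.true_rcbf[core])
        assert np.nanmedian(maps.rcbf[core]) == pytest.approx(true_med, abs=3.0)
        assert np.nanmax(maps.rcbf[core]) < 30.0
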