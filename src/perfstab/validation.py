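"""Quantitative validation studies on the synthetic phantom.

These are the package's standing experiments: deconvolution parameter
recovery on a block phantom, lesion-volume recovery at graded sizes,
ASPECTS false-flag calibration, the stable-cohort repeatability study, and
disruptive-event detection.  The test suite asserts on their outputs and
``scripts/acceptance.py`` reports them.

Study design notes
------------------
* The parameter-recovery study measures the deconvolution engine's
  quantitative accuracy.  It therefore runs at the engine's
  quantitative-accuracy operating point: spatial denoising only (the
  temporal denoiser trades peak-amplitude accuracy for threshold-map
  stability, which is irrelevant on a block phantom) and a regularization
  level matched to the effective post-smoothing noise
  (``lambda_rel = 0.05``), with the true AIF supplied so that only the
  deconvolution is under test.  Noise is 1 HU per sample, within the
  phantom's 0-2 HU operating range.
* The lesion-recovery and cohort studies run the full default pipeline at
  default noise (2 HU) — automatic AIF selection included.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .agreement import cohort_report
from .aspects import score_ncct
from .config import RunConfig
from .perfusion import (
    AifSelection,
    DynamicSeries,
    _fwhm_of_curve,
    compute_maps,
    deconvolve_voxelwise,
    preprocess_series,
)
from .phantom import (
    FINE_DT,
    K_FLOW,
    AifParams,
    LesionSpec,
    PhantomSpec,
    build_phantom,
    lesion_spec_for_volume,
    make_aif,
    make_scan_pair,
    simulate_ctp_series,
    simulate_ncct,
    PhantomScan,
)
from .pipeline import analyze_cohort, analyze_scan

__all__ = [
    "parameter_recovery_study",
    "lesion_recovery_study",
    "aspects_false_flag_study",
    "stability_cohort_study",
    "rejection_rates",
    "growth_detection_study",
]


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    denom = a.sum() + b.sum()
    return float(2.0 * (a & b).sum() / denom) if denom else 1.0


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------

RECOVERY_CBF = (15.0, 25.0, 40.0, 60.0, 80.0)  #: mL/100g/min
RECOVERY_MTT = (3.0, 4.0, 6.0, 8.0, 12.0)  #: s
RECOVERY_DELAY = (0.0, 2.0, 5.0)  #: s
_BLOCK = (6, 6, 4)  #: voxels per parameter combination


def _block_phantom_series(
    noise_sd: float, seed: int, dt: float = 2.0, duration: float = 50.0
) -> Tuple[DynamicSeries, AifParams]:
    """Series of uniform parameter blocks, one per (CBF, MTT, delay) combo."""
    aifp = AifParams()
    t = np.arange(int(duration // dt) + 1) * dt
    nf = int(np.ceil(t[-1] / FINE_DT)) + 1
    tf = np.arange(nf) * FINE_DT
    aif_f = make_aif(aifp, tf)
    idx = np.round(t / FINE_DT).astype(int)
    shape = (
        len(RECOVERY_CBF) * _BLOCK[0],
        len(RECOVERY_MTT) * _BLOCK[1],
        len(RECOVERY_DELAY) * _BLOCK[2],
    )
    data = np.full((*shape, t.size), 30.0, dtype=np.float32)
    for i, cbf in enumerate(RECOVERY_CBF):
        for j, mtt in enumerate(RECOVERY_MTT):
            for k, dly in enumerate(RECOVERY_DELAY):
                r = np.exp(-tf / mtt)
                conv = np.convolve(aif_f, r)[:nf] * FINE_DT
                sh = int(round(dly / FINE_DT))
                cur = np.zeros(nf)
                cur[sh:] = conv[: nf - sh]
                enh = K_FLOW * cbf * cur[idx]
                data[
                    i * _BLOCK[0] : (i + 1) * _BLOCK[0],
                    j * _BLOCK[1] : (j + 1) * _BLOCK[1],
                    k * _BLOCK[2] : (k + 1) * _BLOCK[2],
                ] += enh.astype(np.float32)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, data.shape).astype(np.float32)
    return DynamicSeries(data, t, (3.0, 3.0, 4.0)), aifp


def parameter_recovery_study(
    noise_sd: float = 1.0,
    seed: int = 1,
    smoothing_fwhm_mm: float = 6.0,
    lambda_rel: float = 0.05,
) -> Dict[str, float]:
    """Recover (CBF, Tmax) across the 5x5x3 grid of true tissue states.

    Returns the median absolute Tmax error (s) and median relative CBF error
    over all parameter combinations, each combination read out as the median
    over the interior voxels of its block.
    """
    series, aifp = _block_phantom_series(noise_sd, seed)
    t = series.time_axis
    pre = preprocess_series(
        series,
        brain_mask=np.ones(series.data.shape[:3], dtype=bool),
        smoothing_fwhm_mm=smoothing_fwhm_mm,
        temporal_smoothing_frames=0.0,
    )
    aif_curve = make_aif(aifp, t)
    aif = AifSelection(
        curve=aif_curve,
        voxel_location=(0, 0, 0),
        time_to_peak_s=float(t[np.argmax(aif_curve)]),
        peak_amplitude_hu=float(aif_curve.max()),
        fwhm_s=_fwhm_of_curve(t, aif_curve),
        quality=1.0,
    )
    maps = compute_maps(
        deconvolve_voxelwise(pre, aif, lambda_rel=lambda_rel), pre, aif
    )
    cbf_errs, tmax_errs = [], []
    for i, cbf in enumerate(RECOVERY_CBF):
        for j, _ in enumerate(RECOVERY_MTT):
            for k, dly in enumerate(RECOVERY_DELAY):
                ii = slice(i * _BLOCK[0] + 2, (i + 1) * _BLOCK[0] - 2)
                jj = slice(j * _BLOCK[1] + 2, (j + 1) * _BLOCK[1] - 2)
                kk = slice(k * _BLOCK[2] + 1, (k + 1) * _BLOCK[2] - 1)
                cbf_est = float(np.median(maps.cbf[ii, jj, kk])) / K_FLOW
                tmax_est = float(np.median(maps.tmax[ii, jj, kk]))
                cbf_errs.append(abs(cbf_est - cbf) / cbf)
                tmax_errs.append(abs(tmax_est - dly))
    return {
        "median_tmax_error_s": float(np.median(tmax_errs)),
        "median_cbf_rel_error": float(np.median(cbf_errs)),
        "dt_s": float(series.dt),
        "n_states": len(cbf_errs),
    }


# ---------------------------------------------------------------------------
# lesion volume recovery
# ---------------------------------------------------------------------------

def lesion_recovery_study(
    sizes_ml: Sequence[float] = (10.0, 30.0, 60.0),
    seeds: Sequence[int] = (5, 6, 7),
    config: Optional[RunConfig] = None,
) -> List[Dict[str, float]]:
    """Segment spherical lesions of known hypoperfusion volume at default
    noise with the full default pipeline; report volume error and Dice
    (median over seeds) per target size, plus core stats and nesting."""
    cfg = config or RunConfig()
    base = LesionSpec(penumbra_radii_mm=(20.0, 20.0, 20.0), core_radii_mm=None)
    out = []
    for target in sizes_ml:
        spec0 = PhantomSpec(seed=2)
        lesion = lesion_spec_for_volume(
            target, spec0, core_fraction_of_volume=0.45, base=base
        )
        spec = replace(spec0, lesions=[lesion])
        truth = build_phantom(spec)
        vml = truth.voxel_volume_ml
        true_hypo = truth.hypoperfusion_mask.sum() * vml
        true_core = truth.core_mask.sum() * vml
        vols, dices, core_vols, core_dices, nested = [], [], [], [], []
        for seed in seeds:
            rng = np.random.default_rng(seed)
            scan = PhantomScan(
                simulate_ctp_series(truth, spec, rng=rng),
                simulate_ncct(
                    truth, spec.core_hypodensity_hu, spec.ncct_noise_sd, rng=rng
                ),
                "080000.000000",
                truth.affine.copy(),
            )
            seg = analyze_scan(scan, config=cfg).lesions
            vols.append(seg.hypoperfusion_ml)
            dices.append(dice_coefficient(seg.hypoperfusion_mask,
                                          truth.hypoperfusion_mask))
            core_vols.append(seg.core_ml)
            core_dices.append(dice_coefficient(seg.core_mask, truth.core_mask))
            nested.append(bool((seg.core_mask <= seg.hypoperfusion_mask).all()))
        out.append(
            {
                "target_ml": float(target),
                "true_hypoperfusion_ml": float(true_hypo),
                "recovered_hypoperfusion_ml": float(np.median(vols)),
                "hypoperfusion_dice": float(np.median(dices)),
                "true_core_ml": float(true_core),
                "recovered_core_ml": float(np.median(core_vols)),
                "core_dice": float(np.median(core_dices)),
                "core_nested_in_hypoperfusion": all(nested),
            }
        )
    return out


# ---------------------------------------------------------------------------
# ASPECTS calibration
# ---------------------------------------------------------------------------

def aspects_false_flag_study(
    n_seeds: int = 100,
    noise_sd: float = 1.5,
    seed: int = 0,
    config: Optional[RunConfig] = None,
) -> Dict[str, float]:
    """False-flag rate per region on lesion-free NCCTs at a given noise."""
    cfg = config or RunConfig()
    truth = build_phantom(replace(PhantomSpec(), lesions=[]))
    seeds = np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)
    n_flags = 0
    for s in seeds:
        ncct = simulate_ncct(truth, 0.0, noise_sd, rng=np.random.default_rng(int(s)))
        res = score_ncct(
            ncct,
            truth.atlas_labels,
            truth.region_names,
            delta_hu_threshold=cfg.aspects.delta_hu_threshold,
        )
        n_flags += sum(res.flags_left.values()) + sum(res.flags_right.values())
    # 20 region-side comparisons per scan
    return {
        "false_flag_rate": n_flags / (n_seeds * 20),
        "n_seeds": n_seeds,
        "noise_sd_hu": noise_sd,
    }


# ---------------------------------------------------------------------------
# cohort repeatability
# ---------------------------------------------------------------------------

def stability_cohort_study(
    n_pairs: int = 200,
    seed: int = 0,
    config: Optional[RunConfig] = None,
):
    """Analyse a stable-scenario cohort end to end.

    Each pair is an independent simulated patient re-scanned with fresh noise
    and an independently drawn acquisition protocol (temporal sampling and
    duration vary between scanners, as they do clinically).  Returns the
    per-pair results and the cohort agreement report.
    """
    results = analyze_cohort(
        n_pairs, scenario="stable", seed=seed, config=config,
        protocol_jitter=True,
    )
    return results, cohort_report(results)


def rejection_rates(
    pair_results,
    metrics: Sequence[str],
    cohort_size: int = 10,
    n_cohorts: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> Dict[str, Dict[str, float]]:
    """Empirical test-rejection rates over subsampled cohorts.

    Draws ``n_cohorts`` cohorts of ``cohort_size`` pairs (without replacement
    within each cohort) from the pool of pair results, applies the paired
    t-test and the interval-association test to each, and reports the
    fraction rejecting at ``alpha``.  Under stable conditions both rates
    should sit at the nominal level.
    """
    from .agreement import agreement_tests

    rng = np.random.default_rng(seed)
    out: Dict[str, Dict[str, float]] = {}
    intervals = np.array([pr.interval_h for pr in pair_results], float)
    for name in metrics:
        v1 = np.array([getattr(pr.metrics1, name) for pr in pair_results], float)
        v2 = np.array([getattr(pr.metrics2, name) for pr in pair_results], float)
        ok = np.isfinite(v1) & np.isfinite(v2)
        v1, v2, ints = v1[ok], v2[ok], intervals[ok]
        rej_t = rej_i = n_eff = 0
        for _ in range(n_cohorts):
            idx = rng.choice(v1.size, size=cohort_size, replace=False)
            res = agreement_tests(v1[idx], v2[idx], ints[idx])
            if np.isfinite(res.paired_t_p) and np.isfinite(res.interval_p):
                rej_t += res.paired_t_p < alpha
                rej_i += res.interval_p < alpha
                n_eff += 1
        out[name] = {
            "paired_t_rejection_rate": rej_t / max(n_eff, 1),
            "interval_rejection_rate": rej_i / max(n_eff, 1),
            "n_cohorts": n_eff,
        }
    return out


# ---------------------------------------------------------------------------
# disruptive-event sensitivity
# ---------------------------------------------------------------------------

def growth_detection_study(
    n_seeds: int = 50,
    seed: int = 0,
    detection_threshold_ml: float = 10.0,
    config: Optional[RunConfig] = None,
):
    """Detection of a 20 mL new occlusion from the hypoperfusion-volume change.

    Growth counts as detected when the measured scan-to-scan hypoperfusion
    increase exceeds half the simulated 20 mL growth.  Pairs keep the same
    acquisition protocol for both scans (the event, not the protocol, is
    under test).  Also returns the cohort report in which these pairs must
    appear as excluded disruptive events.
    """
    from .pipeline import run_pair_analysis

    seeds = np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)
    results = []
    for s in seeds:
        pair = make_scan_pair(
            PhantomSpec(seed=int(s)), scenario="new_occlusion",
            protocol_jitter=False,
        )
        results.append(run_pair_analysis(pair, config))
    growths = np.array([r.differences["hypoperfusion_ml"] for r in results])
    detected = growths > detection_threshold_ml
    report = cohort_report(results)
    return {
        "detection_rate": float(detected.mean()),
        "mean_measured_growth_ml": float(growths.mean()),
        "n_seeds": n_seeds,
        "n_excluded_as_disruptive": len(report.excluded),
    }, results
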