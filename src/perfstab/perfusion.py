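"""Deconvolution-based CT perfusion quantification.

Turns a dynamic CT perfusion series (attenuation in HU over time) into
voxelwise CBF / CBV / MTT / Tmax maps:

1. ``preprocess_series``  — spatial denoising, optional rigid motion
   correction, bolus-arrival detection and baseline estimation;
2. ``select_aif``         — fully automatic arterial-input-function selection
   by clustering high-enhancement time-attenuation curves on peak timing and
   amplitude, followed by quality ranking;
3. ``deconvolve_voxelwise`` — Tikhonov-regularized SVD deconvolution of all
   tissue curves with the AIF (block-circulant, delay-insensitive by default);
4. ``compute_maps``       — CBF = max of the residue estimate, Tmax = time of
   that maximum, CBV = area ratio of tissue curve to AIF, MTT = CBV/CBF;
5. ``normalize_relative`` — rCBF / rCBV as a percentage of the median over
   normally perfused tissue (Tmax < 4 s).

The tissue model is the standard indicator-dilution relation
``c(t) = CBF * (AIF ⊛ R)(t)`` with residue function ``R``; deconvolution
recovers ``k(t) = CBF * R(t - delay)``.  CBF is reported in raw deconvolution
units (1/s); all downstream metrics are relative (percent) or in seconds, so
no absolute calibration constant is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.linalg import circulant, toeplitz
from sklearn.cluster import KMeans

__all__ = [
    "DynamicSeries",
    "PreprocessedSeries",
    "AifSelection",
    "ResidueEstimate",
    "PerfusionMaps",
    "BolusNotFoundError",
    "AifSelectionError",
    "preprocess_series",
    "select_aif",
    "deconvolve_voxelwise",
    "compute_maps",
    "normalize_relative",
    "quantify_perfusion",
]

#: maximum tolerated relative jitter of the temporal sampling interval
MAX_DT_JITTER = 0.05
MIN_TIME_POINTS = 15


class BolusNotFoundError(RuntimeError):
    """Raised when no contrast bolus can be detected in the series."""


class AifSelectionError(RuntimeError):
    """Raised when no acceptable arterial input candidates exist."""


@dataclass
class DynamicSeries:
    """4D dynamic CT series: attenuation (HU) over x, y, z, t.

    Parameters
    ----------
    data : (nx, ny, nz, nt) float array, Hounsfield units
    time_axis : (nt,) seconds from first frame, strictly increasing,
        near-uniform spacing
    voxel_size : (3,) mm
    acquisition_time : clock time of the acquisition, ``"HHMMSS[.ffffff]"``
    affine : optional 4x4 voxel-to-world matrix (axis-aligned for phantoms)
    """

    data: np.ndarray
    time_axis: np.ndarray
    voxel_size: Tuple[float, float, float]
    acquisition_time: str = "000000.000000"
    affine: Optional[np.ndarray] = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, t)")
        if self.data.shape[3] != self.time_axis.size:
            raise ValueError("time axis length does not match data")
        if self.time_axis.size < MIN_TIME_POINTS:
            raise ValueError(
                f"need at least {MIN_TIME_POINTS} time points, "
                f"got {self.time_axis.size}"
            )
        dts = np.diff(self.time_axis)
        if np.any(dts <= 0):
            raise ValueError("time axis must be strictly increasing")
        if dts.max() / dts.min() - 1 > MAX_DT_JITTER:
            raise ValueError("temporal sampling is not near-uniform")
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size, 1.0])

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time_axis)))

    @property
    def n_frames(self) -> int:
        return int(self.time_axis.size)


@dataclass
class PreprocessedSeries:
    """Output of :func:`preprocess_series`."""

    series: DynamicSeries
    baseline: np.ndarray  #: 3D pre-bolus attenuation (HU)
    arrival_index: int  #: first frame with whole-brain enhancement
    brain_mask: np.ndarray
    warnings: list = field(default_factory=list)

    def enhancement(self) -> np.ndarray:
        """Baseline-subtracted 4D data."""
        return self.series.data - self.baseline[..., None]


@dataclass
class AifSelection:
    """Selected arterial input function and its quality features."""

    curve: np.ndarray  #: baseline-subtracted HU over time
    voxel_location: Tuple[int, int, int]
    time_to_peak_s: float
    peak_amplitude_hu: float
    fwhm_s: float
    quality: float
    pool: str = "arterial"


@dataclass
class ResidueEstimate:
    """Voxelwise residue estimates k(t) inside a mask.

    ``k`` has shape (nt, n_mask_voxels); ``mask`` maps columns back onto the
    grid.  Units are 1/s (CBF-scaled residue).
    """

    k: np.ndarray
    mask: np.ndarray
    time_axis: np.ndarray
    lambda_rel: float
    circulant: bool


@dataclass
class PerfusionMaps:
    """Voxelwise perfusion maps; NaN marks voxels outside the brain mask."""

    cbf: np.ndarray  #: deconvolution units (1/s)
    cbv: np.ndarray  #: area-ratio units (dimensionless)
    mtt: np.ndarray  #: seconds
    tmax: np.ndarray  #: seconds
    brain_mask: np.ndarray
    rcbf: Optional[np.ndarray] = None  #: % of normally perfused tissue
    rcbv: Optional[np.ndarray] = None
    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: Optional[np.ndarray] = None


def _fwhm_of_curve(t: np.ndarray, c: np.ndarray) -> float:
    """Full width at half maximum with linear interpolation at the crossings."""
    peak = c.max()
    if peak <= 0:
        return float(t[-1] - t[0])
    half = peak / 2.0
    above = c >= half
    idx = np.flatnonzero(above)
    i0, i1 = idx[0], idx[-1]
    # left crossing
    if i0 == 0:
        t_left = t[0]
    else:
        f = (half - c[i0 - 1]) / (c[i0] - c[i0 - 1])
        t_left = t[i0 - 1] + f * (t[i0] - t[i0 - 1])
    if i1 == len(c) - 1:
        t_right = t[-1]
    else:
        f = (c[i1] - half) / (c[i1] - c[i1 + 1])
        t_right = t[i1] + f * (t[i1 + 1] - t[i1])
    return float(max(t_right - t_left, t[1] - t[0]))


def _rigid_motion_correct(data: np.ndarray, voxel_size) -> np.ndarray:
    """Rigid frame-to-first registration (SimpleITK, dense mean-squares)."""
    import SimpleITK as sitk

    def to_img(vol):
        img = sitk.GetImageFromArray(np.ascontiguousarray(vol.T.astype(np.float64)))
        img.SetSpacing(tuple(float(v) for v in voxel_size))
        return img

    fixed = to_img(data[..., 0])
    out = np.empty_like(data, dtype=np.float64)
    out[..., 0] = data[..., 0]
    for j in range(1, data.shape[-1]):
        moving = to_img(data[..., j])
        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsMeanSquares()
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=1.0, minStep=1e-3, numberOfIterations=100
        )
        reg.SetInitialTransform(
            sitk.CenteredTransformInitializer(
                fixed, moving, sitk.Euler3DTransform(),
                sitk.CenteredTransformInitializerFilter.GEOMETRY,
            ),
            inPlace=False,
        )
        tx = reg.Execute(fixed, moving)
        fill = float(data[..., j].min())  # voxels entering the FOV look like air
        resampled = sitk.Resample(moving, fixed, tx, sitk.sitkLinear, fill)
        out[..., j] = sitk.GetArrayFromImage(resampled).T
    return out


def preprocess_series(
    series: DynamicSeries,
    brain_mask: Optional[np.ndarray] = None,
    smoothing_fwhm_mm: float = 4.0,
    temporal_smoothing_frames: float = 1.5,
    motion_correction: bool = False,
    arrival_sd_multiple: float = 3.0,
    arrival_floor_hu: float = 0.3,
) -> PreprocessedSeries:
    """Denoise, optionally motion-correct, and detect bolus arrival.

    Denoising is spatio-temporal: a spatial Gaussian of ``smoothing_fwhm_mm``
    per frame plus a mild temporal Gaussian of sd
    ``temporal_smoothing_frames`` (in frames) along the time axis — the
    standard noise-suppression step before deconvolution, since the
    max-over-time statistics (CBF, Tmax) are strongly noise-biased otherwise.

    The baseline volume is the temporal mean of the pre-arrival frames; the
    arrival index is the first frame at which the whole-brain mean enhancement
    over a provisional 3-frame baseline exceeds
    ``max(arrival_sd_multiple * sd_pre, arrival_floor_hu)``.

    Raises
    ------
    BolusNotFoundError
        if no frame exceeds the arrival threshold.
    """
    warnings: list = []
    data = np.asarray(series.data, dtype=np.float32)

    if motion_correction:
        data = _rigid_motion_correct(data, series.voxel_size).astype(np.float32)

    if smoothing_fwhm_mm > 0 or temporal_smoothing_frames > 0:
        sigma_vox = (smoothing_fwhm_mm / 2.3548) / np.asarray(series.voxel_size)
        data = ndimage.gaussian_filter(
            data,
            sigma=(*sigma_vox, temporal_smoothing_frames),
            mode="nearest",
        )

    if brain_mask is None:
        # conservative fallback: soft-tissue attenuation window on frame 0
        first = data[..., 0]
        brain_mask = (first > 0) & (first < 100)
        if not brain_mask.any():
            brain_mask = np.ones(first.shape, dtype=bool)
    brain_mask = brain_mask.astype(bool)

    mean_curve = data[brain_mask].mean(axis=0)
    pre = mean_curve[:3]
    # robust pre-bolus spread (MAD): a bolus leaking into the provisional
    # baseline window must not inflate the detection threshold
    center = float(np.median(pre))
    scale = 1.4826 * float(np.median(np.abs(pre - center)))
    thr = center + max(arrival_sd_multiple * scale, arrival_floor_hu)
    exceed = np.flatnonzero(mean_curve > thr)
    if exceed.size == 0:
        raise BolusNotFoundError(
            "no bolus: whole-brain enhancement never exceeds the arrival threshold"
        )
    arrival = int(exceed[0])
    if arrival < 3:
        warnings.append(
            f"fewer than 3 pre-arrival frames (arrival index {arrival}); "
            "falling back to the first 3 frames for the baseline"
        )
        n_base = 3
    else:
        n_base = arrival
    baseline = data[..., :n_base].mean(axis=-1)

    out = replace(series, data=data)
    return PreprocessedSeries(
        series=out,
        baseline=baseline.astype(np.float32),
        arrival_index=arrival,
        brain_mask=brain_mask,
        warnings=warnings,
    )


def select_aif(
    pre: PreprocessedSeries,
    candidate_fraction: float = 0.005,
    amplitude_floor_hu: float = 60.0,
    top_k: int = 5,
    min_component_voxels: int = 4,
) -> AifSelection:
    """Automatic AIF selection.

    Candidate voxels are the top ``candidate_fraction`` of brain voxels by
    peak enhancement, subject to an absolute amplitude floor and a
    spatial-contiguity filter (isolated candidates are discarded).  Candidates
    are split into two groups by k-means on (time-to-peak, peak amplitude);
    the earlier-peaking group is the arterial pool, the later one venous.
    Within the arterial pool curves are ranked by the quality score
    ``peak / (FWHM * TTP)`` (tall, narrow, early bolus) and the returned AIF
    is the average of the ``top_k`` best curves.  Ties are broken by lowest
    linear voxel index, making the selection fully deterministic.
    """
    t = pre.series.time_axis
    enh = pre.enhancement()
    mask = pre.brain_mask

    flat_idx = np.flatnonzero(mask.ravel())
    curves = enh.reshape(-1, enh.shape[-1])[flat_idx]
    peaks = curves.max(axis=1)

    n_cand = max(int(np.ceil(candidate_fraction * flat_idx.size)), 10)
    order = np.argsort(-peaks, kind="stable")[:n_cand]
    keep = peaks[order] >= amplitude_floor_hu
    order = order[keep]
    if order.size == 0:
        raise AifSelectionError(
            f"AIF selection failed: no candidates above the "
            f"{amplitude_floor_hu:g} HU amplitude floor"
        )

    # spatial-contiguity filter on the candidate set
    cand_mask = np.zeros(mask.shape, dtype=bool)
    cand_mask.ravel()[flat_idx[order]] = True
    labels, _ = ndimage.label(cand_mask)
    sizes = np.bincount(labels.ravel())
    good = sizes >= min_component_voxels
    good[0] = False
    contiguous = good[labels]
    sel = contiguous.ravel()[flat_idx[order]]
    if sel.any():
        order = order[sel]

    cand_curves = curves[order]
    cand_peaks = cand_curves.max(axis=1)
    cand_ttp = t[np.argmax(cand_curves, axis=1)]

    pool = np.zeros(order.size, dtype=bool)  # True -> arterial
    if order.size >= 4 and np.ptp(cand_ttp) > 0:
        feats = np.column_stack([cand_ttp, cand_peaks])
        feats = (feats - feats.mean(0)) / np.where(feats.std(0) > 0, feats.std(0), 1)
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(feats)
        means = [cand_ttp[km.labels_ == g].mean() for g in (0, 1)]
        arterial_group = int(np.argmin(means))
        pool = km.labels_ == arterial_group
    else:
        pool[:] = True

    art = np.flatnonzero(pool)
    fwhms = np.array([_fwhm_of_curve(t, cand_curves[i]) for i in art])
    ttps = np.maximum(cand_ttp[art], t[1] - t[0])
    quality = cand_peaks[art] / (fwhms * ttps)

    # rank by quality, deterministic tie-break on linear voxel index
    lin = flat_idx[order[art]]
    rank = np.lexsort((lin, -quality))
    best = art[rank[: min(top_k, art.size)]]

    aif_curve = cand_curves[best].mean(axis=0)
    winner = art[rank[0]]
    loc = np.unravel_index(flat_idx[order[winner]], mask.shape)
    return AifSelection(
        curve=aif_curve.astype(float),
        voxel_location=tuple(int(v) for v in loc),
        time_to_peak_s=float(t[np.argmax(aif_curve)]),
        peak_amplitude_hu=float(aif_curve.max()),
        fwhm_s=_fwhm_of_curve(t, aif_curve),
        quality=float(quality[rank[0]]),
        pool="arterial",
    )


def _simpson_weights(aif: np.ndarray) -> np.ndarray:
    """Simpson-weighted AIF samples for the convolution matrix.

    The rectangle-rule Toeplitz discretization of the convolution integral
    systematically underestimates sharp residue peaks at clinical sampling
    intervals; the classical correction replaces each AIF sample by the
    local Simpson average (a_{j-1} + 4 a_j + a_{j+1}) / 6.
    """
    ae = np.concatenate([aif, [0.0]])
    w = np.empty_like(aif)
    w[0] = (2.0 * ae[0] + ae[1]) / 3.0
    w[1:] = (ae[:-2] + 4.0 * ae[1:-1] + ae[2:]) / 6.0
    return w


def _deconvolution_matrix(
    aif: np.ndarray, dt: float, use_circulant: bool, quadrature: str = "simpson"
) -> np.ndarray:
    a = _simpson_weights(aif) if quadrature == "simpson" else aif
    if use_circulant:
        L = 2 * a.size
        col = np.zeros(L)
        col[: a.size] = a
        return circulant(col) * dt
    return toeplitz(a, np.zeros_like(a)) * dt


def deconvolve_voxelwise(
    pre: PreprocessedSeries,
    aif: AifSelection,
    lambda_rel: float = 0.15,
    use_circulant: bool = True,
    mask: Optional[np.ndarray] = None,
    quadrature: str = "simpson",
) -> ResidueEstimate:
    """Tikhonov-regularized SVD deconvolution of all masked tissue curves.

    The convolution matrix ``A`` is built from the (Simpson-weighted) AIF
    samples scaled by dt: lower-triangular Toeplitz, or zero-padded
    block-circulant for delay insensitivity.  With ``A = U S V^T``, the
    residue estimate per voxel is

        k = sum_i f_i * (u_i . c / s_i) v_i,   f_i = s_i^2 / (s_i^2 + (λ s_1)^2)

    The SVD is computed once per scan and applied to all voxels at once.
    """
    if lambda_rel < 0:
        raise ValueError("lambda_rel must be non-negative")
    a = np.asarray(aif.curve, dtype=float)
    if not np.any(a != 0):
        raise ValueError("all-zero AIF")
    t = pre.series.time_axis
    nt = t.size
    dt = pre.series.dt
    if mask is None:
        mask = pre.brain_mask
    mask = mask.astype(bool)

    A = _deconvolution_matrix(a, dt, use_circulant, quadrature)
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    lam = lambda_rel * s[0]
    with np.errstate(divide="ignore"):
        filt = np.where(s > 0, s / (s**2 + lam**2), 0.0)

    curves = pre.enhancement()[mask].astype(float).T  # (nt, nvox)
    if use_circulant:
        padded = np.zeros((A.shape[0], curves.shape[1]))
        padded[:nt] = curves
        curves = padded
    K = Vt.T @ (filt[:, None] * (U.T @ curves))
    return ResidueEstimate(
        k=K[:nt],
        mask=mask,
        time_axis=t,
        lambda_rel=lambda_rel,
        circulant=use_circulant,
    )


def compute_maps(
    residues: ResidueEstimate,
    pre: PreprocessedSeries,
    aif: AifSelection,
    cbf_floor: float = 1e-12,
) -> PerfusionMaps:
    """Absolute perfusion maps from the residue estimates.

    CBF is the maximum of k(t); Tmax the time of that maximum (first maximum
    on ties); CBV the trapezoidal area of the enhancement curve divided by the
    AIF area (negatives clipped to zero); MTT = CBV / CBF where CBF exceeds a
    floor, NaN elsewhere.  Voxels outside the mask carry NaN.
    """
    t = residues.time_axis
    mask = residues.mask
    shape = mask.shape
    K = residues.k

    cbf_v = K.max(axis=0)
    tmax_v = t[np.argmax(K, axis=0)]

    enh = pre.enhancement()[mask].astype(float)
    aif_area = np.trapezoid(aif.curve, t)
    cbv_v = np.trapezoid(enh, t, axis=1) / aif_area
    cbv_v = np.clip(cbv_v, 0.0, None)

    with np.errstate(divide="ignore", invalid="ignore"):
        mtt_v = np.where(cbf_v > cbf_floor, cbv_v / cbf_v, np.nan)

    def full(vals):
        out = np.full(shape, np.nan, dtype=float)
        out[mask] = vals
        return out

    return PerfusionMaps(
        cbf=full(cbf_v),
        cbv=full(cbv_v),
        mtt=full(mtt_v),
        tmax=full(tmax_v),
        brain_mask=mask,
        voxel_size=pre.series.voxel_size,
        affine=pre.series.affine,
    )


def normalize_relative(
    maps: PerfusionMaps, normal_tmax_s: float = 4.0
) -> PerfusionMaps:
    """Fill rCBF / rCBV as percent of the median over normally perfused tissue.

    Normal tissue is brain with Tmax below ``normal_tmax_s``.  Raises if that
    reference set is empty.
    """
    normal = maps.brain_mask & (maps.tmax < normal_tmax_s) & np.isfinite(maps.cbf)
    if not normal.any():
        raise ValueError("no normally perfused reference tissue (Tmax < 4 s set empty)")
    ref_cbf = float(np.median(maps.cbf[normal]))
    ref_cbv = float(np.median(maps.cbv[normal]))
    if ref_cbf <= 0 or ref_cbv <= 0:
        raise ValueError("non-positive normalization reference")
    maps.rcbf = 100.0 * maps.cbf / ref_cbf
    maps.rcbv = 100.0 * maps.cbv / ref_cbv
    return maps


def quantify_perfusion(
    series: DynamicSeries,
    brain_mask: Optional[np.ndarray] = None,
    config=None,
) -> Tuple[PerfusionMaps, AifSelection, PreprocessedSeries]:
    """Convenience wrapper running the full engine with a :class:`RunConfig`."""
    from .config import RunConfig

    cfg = (config or RunConfig()).perfusion
    pre = preprocess_series(
        series,
        brain_mask=brain_mask,
        smoothing_fwhm_mm=cfg.smoothing_fwhm_mm,
        temporal_smoothing_frames=cfg.temporal_smoothing_frames,
        motion_correction=cfg.motion_correction,
        arrival_sd_multiple=cfg.arrival_sd_multiple,
        arrival_floor_hu=cfg.arrival_floor_hu,
    )
    aif = select_aif(
        pre,
        candidate_fraction=cfg.aif.candidate_fraction,
        amplitude_floor_hu=cfg.aif.amplitude_floor_hu,
        top_k=cfg.aif.top_k,
        min_component_voxels=cfg.aif.min_component_voxels,
    )
    if aif.curve[-1] > cfg.truncation_fraction * aif.peak_amplitude_hu:
        pre.warnings.append(
            "incomplete bolus capture: AIF has not returned below "
            f"{100 * cfg.truncation_fraction:.0f}% of peak by the last frame"
        )
    residues = deconvolve_voxelwise(
        pre, aif, lambda_rel=cfg.lambda_rel, use_circulant=cfg.circulant
    )
    maps = compute_maps(residues, pre, aif)
    maps = normalize_relative(maps, normal_tmax_s=cfg.normal_tmax_s)
    return maps, aif, pre
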