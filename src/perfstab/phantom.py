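"""Synthetic dynamic-CTP / NCCT phantom with known hemodynamic ground truth.

The phantom emulates paired perfusion scans of one patient: a two-hemisphere
ellipsoidal "brain" with grey- and white-matter shells, a small arterial and a
venous voxel cluster, and one or more ellipsoidal ischemic lesions (an outer
penumbra with graded bolus delay and an inner core with severely reduced
flow).  Tissue curves follow the indicator-dilution forward model

    c(t) = baseline_HU + k * CBF * (AIF ⊛ R)(t - delay),   R(t) = exp(-t/MTT)

with an optional exponential dispersion kernel, evaluated on a fine internal
time grid and sampled at the scan times, plus i.i.d. Gaussian noise in HU.
``k = K_FLOW = 1/6000`` converts CBF in mL/100g/min to 1/s at unit tissue
density, so a grey-matter voxel (CBF 60) enhances by roughly 12 HU at peak
for the default bolus — the magnitude seen in clinical CTP.

Everything downstream (deconvolution, thresholds, ASPECTS, agreement
statistics) can therefore be validated against exact voxelwise ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Set, Tuple

import numpy as np

from .perfusion import DynamicSeries

__all__ = [
    "K_FLOW",
    "ASPECTS_REGION_NAMES",
    "SCENARIOS",
    "AifParams",
    "TissueParams",
    "LesionSpec",
    "PhantomSpec",
    "PhantomGroundTruth",
    "PhantomScan",
    "ScanPair",
    "make_aif",
    "build_phantom",
    "simulate_ctp_series",
    "simulate_ncct",
    "make_scan_pair",
    "make_cohort",
    "lesion_spec_for_volume",
]

#: unit constant of the forward model: CBF [mL/100g/min] -> flow [1/s]
K_FLOW = 1.0 / 6000.0

#: fine internal time step (s) for forward-model convolutions
FINE_DT = 0.1

#: delay quantization (s) of the graded penumbra delay field
DELAY_QUANT = 0.25

ASPECTS_REGION_NAMES = ["C", "L", "IC", "I", "M1", "M2", "M3", "M4", "M5", "M6"]

SCENARIOS = (
    "stable",
    "new_occlusion",
    "thrombus_migration",
    "bolus_truncation",
    "coverage_shift",
    "high_noise",
)

HU_AIR = -1000.0
HU_VESSEL_BASELINE = 45.0


@dataclass
class AifParams:
    """Gamma-variate arterial input: A*(t-t0)^alpha*exp(-(t-t0)/beta)."""

    amplitude: float = 165.0  #: HU scale coefficient (peak ~200 HU at defaults)
    t0_s: float = 10.0
    alpha: float = 2.0
    beta_s: float = 1.5

    @property
    def peak_time_s(self) -> float:
        return self.t0_s + self.alpha * self.beta_s


@dataclass
class TissueParams:
    cbf: float  #: mL/100g/min
    mtt_s: float
    baseline_hu: float


@dataclass
class LesionSpec:
    """Ellipsoidal penumbra with optional nested core.

    The bolus delay is graded from ``delay_s`` at the penumbra rim to
    ``delay_s + delay_center_extra_s`` at the centre, mimicking graded
    hypoperfusion severity.
    """

    center_mm: Tuple[float, float, float] = (52.0, 100.0, 48.0)
    penumbra_radii_mm: Tuple[float, float, float] = (26.0, 21.0, 17.5)
    core_radii_mm: Optional[Tuple[float, float, float]] = (18.7, 15.1, 12.6)
    delay_s: float = 8.0
    delay_center_extra_s: float = 3.0
    dispersion_s: float = 0.0
    penumbra_cbf_fraction: float = 0.85
    core_cbf_fraction: float = 0.15

    def __post_init__(self):
        for frac in (self.penumbra_cbf_fraction, self.core_cbf_fraction):
            if not (0 < frac <= 1):
                raise ValueError("CBF fractions must be in (0, 1]")
        if self.core_radii_mm is not None:
            if any(
                c > p for c, p in zip(self.core_radii_mm, self.penumbra_radii_mm)
            ):
                raise ValueError("core region must be contained in the penumbra")
        if self.dispersion_s < 0 or self.delay_s < 0:
            raise ValueError("delay and dispersion must be non-negative")


@dataclass
class PhantomSpec:
    """Geometry, hemodynamics and acquisition parameters of one phantom scan."""

    grid_shape: Tuple[int, int, int] = (64, 64, 24)
    voxel_size: Tuple[float, float, float] = (3.0, 3.0, 4.0)
    dt: float = 2.0
    duration: float = 50.0
    aif: AifParams = field(default_factory=AifParams)
    gm: TissueParams = field(default_factory=lambda: TissueParams(60.0, 4.0, 35.0))
    wm: TissueParams = field(default_factory=lambda: TissueParams(25.0, 5.0, 28.0))
    lesions: List[LesionSpec] = field(default_factory=lambda: [LesionSpec()])
    noise_sd: float = 2.0  #: HU, per CTP sample
    ncct_noise_sd: float = 1.5  #: HU, NCCT
    core_hypodensity_hu: float = 5.0  #: NCCT HU drop inside the core
    #: brain ellipsoid semi-axes as fractions of the field of view
    brain_radii_frac: Tuple[float, float, float] = (0.40, 0.44, 0.42)
    wm_scale: float = 0.74
    seed: int = 0
    #: permit protocols whose bolus is not fully captured (failure scenarios)
    allow_truncated_bolus: bool = False

    def __post_init__(self):
        if not (1.5 <= self.dt <= 3.5):
            raise ValueError("dt must lie in [1.5, 3.5] s")
        if not (38.0 <= self.duration <= 55.0):
            raise ValueError("duration must lie in [38, 55] s")
        if self.noise_sd < 0 or self.ncct_noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.core_hypodensity_hu < 0:
            raise ValueError("core hypodensity must be non-negative")

    @property
    def time_axis(self) -> np.ndarray:
        n = int(np.floor(self.duration / self.dt)) + 1
        t = np.arange(n) * self.dt
        return t[t <= self.duration + 1e-9]

    @property
    def fov_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape) * np.asarray(self.voxel_size)

    @property
    def affine(self) -> np.ndarray:
        return np.diag([*self.voxel_size, 1.0])


@dataclass
class PhantomGroundTruth:
    """Voxelwise ground truth of one phantom anatomy/hemodynamic state."""

    brain_mask: np.ndarray
    gm_mask: np.ndarray
    wm_mask: np.ndarray
    artery_mask: np.ndarray
    vein_mask: np.ndarray
    atlas_labels: np.ndarray  #: 0 background, 1-10 left, 11-20 right
    region_names: List[str]
    baseline_hu: np.ndarray
    true_cbf: np.ndarray  #: mL/100g/min, NaN outside brain/vessels
    true_mtt: np.ndarray  #: s
    true_delay: np.ndarray  #: s
    true_dispersion: np.ndarray  #: s
    true_tmax: np.ndarray  #: s (delay + residue-peak offset)
    true_rcbf: np.ndarray  #: % of normal-tissue median
    hypoperfusion_mask: np.ndarray
    core_mask: np.ndarray
    affected_regions: Set[int]
    voxel_size: Tuple[float, float, float]
    affine: np.ndarray

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size)) / 1000.0


@dataclass
class PhantomScan:
    """One acquisition: dynamic CTP plus a same-session NCCT."""

    ctp: DynamicSeries
    ncct: np.ndarray
    acquisition_time: str
    affine: np.ndarray


@dataclass
class ScanPair:
    scan1: PhantomScan
    scan2: PhantomScan
    scenario: str
    truth1: PhantomGroundTruth
    truth2: PhantomGroundTruth
    interval_h: float
    seed: Optional[int] = None


# ---------------------------------------------------------------------------
# arterial input function
# ---------------------------------------------------------------------------

def make_aif(
    params: AifParams, time_axis: np.ndarray, allow_truncated: bool = False
) -> np.ndarray:
    """Gamma-variate AIF sampled on ``time_axis`` (baseline-free, HU).

    Raises if the time axis is not strictly increasing, or if the analytic
    peak falls after the last sample (a truncated bolus) unless explicitly
    allowed.
    """
    t = np.asarray(time_axis, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("time axis must be 1D and strictly increasing")
    if params.alpha <= 0 or params.beta_s <= 0:
        raise ValueError("gamma-variate shape and scale must be positive")
    if params.peak_time_s > t[-1] and not allow_truncated:
        raise ValueError(
            "AIF peak occurs after the last sample (bolus truncation); "
            "pass allow_truncated=True if intended"
        )
    tau = t - params.t0_s
    out = np.zeros_like(t)
    pos = tau > 0
    out[pos] = (
        params.amplitude
        * tau[pos] ** params.alpha
        * np.exp(-tau[pos] / params.beta_s)
    )
    return out


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _voxel_coords(spec: PhantomSpec):
    """Voxel-centre world coordinates (mm) as broadcastable 1D arrays."""
    nx, ny, nz = spec.grid_shape
    dx, dy, dz = spec.voxel_size
    x = (np.arange(nx) + 0.5) * dx
    y = (np.arange(ny) + 0.5) * dy
    z = (np.arange(nz) + 0.5) * dz
    return x[:, None, None], y[None, :, None], z[None, None, :]


def _ellipsoid_rho2(spec: PhantomSpec, center, radii) -> np.ndarray:
    """Squared normalized ellipsoid radius field (<=1 inside)."""
    x, y, z = _voxel_coords(spec)
    return (
        ((x - center[0]) / radii[0]) ** 2
        + ((y - center[1]) / radii[1]) ** 2
        + ((z - center[2]) / radii[2]) ** 2
    )


def lesion_spec_for_volume(
    target_ml: float,
    spec: PhantomSpec,
    center_mm=None,
    core_fraction_of_volume: float = 0.45,
    base: Optional[LesionSpec] = None,
    tolerance_voxels: int = 1,
) -> LesionSpec:
    """Lesion spec whose voxelized penumbra volume hits ``target_ml``.

    The base radii are scaled isotropically; a bisection on the scale factor
    drives the voxel count of the penumbra mask to the target within
    ``tolerance_voxels`` (or as close as the voxelization allows).  The core
    radii are set so that the core occupies roughly
    ``core_fraction_of_volume`` of the penumbra volume (0 disables the core).
    """
    base = base or LesionSpec()
    if center_mm is not None:
        base = replace(base, center_mm=tuple(center_mm))
    vox_ml = float(np.prod(spec.voxel_size)) / 1000.0
    target_count = int(round(target_ml / vox_ml))

    def count(scale: float) -> int:
        radii = tuple(r * scale for r in base.penumbra_radii_mm)
        return int((_ellipsoid_rho2(spec, base.center_mm, radii) <= 1.0).sum())

    lo, hi = 0.05, 4.0
    best_scale, best_err = 1.0, np.inf
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        c = count(mid)
        err = abs(c - target_count)
        if err < best_err:
            best_scale, best_err = mid, err
        if err <= tolerance_voxels:
            break
        if c < target_count:
            lo = mid
        else:
            hi = mid
    radii = tuple(r * best_scale for r in base.penumbra_radii_mm)
    if core_fraction_of_volume > 0:
        cscale = core_fraction_of_volume ** (1.0 / 3.0)
        core = tuple(r * cscale for r in radii)
    else:
        core = None
    return replace(base, penumbra_radii_mm=radii, core_radii_mm=core)


def _build_atlas(spec: PhantomSpec, brain: np.ndarray) -> np.ndarray:
    """10 mirror-symmetric regions per hemisphere (2 z-bands x 5 sectors)."""
    nx = spec.grid_shape[0]
    x, y, z = _voxel_coords(spec)
    cx, cy, cz = spec.fov_mm / 2.0
    theta = np.arctan2(y - cy, np.abs(x - cx) + 1e-6)  # (-pi/2, pi/2)
    sector = np.clip(((theta + np.pi / 2) / (np.pi / 5)).astype(int), 0, 4)
    band = (z >= cz).astype(int)
    region = band * 5 + sector + 1  # 1..10
    left = np.broadcast_to(x < cx, spec.grid_shape)
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    labels[brain] = np.broadcast_to(region, spec.grid_shape)[brain]
    labels[brain & ~left] += 10
    return labels


def _vessel_block(spec: PhantomSpec, offset_mm) -> np.ndarray:
    """2x2x3-voxel vessel cluster at a world-space offset from centre.

    The x-extent straddles the midsagittal plane so that the vessel layout is
    mirror-symmetric (vessels are midline structures in this phantom).
    """
    center_vox = (
        (spec.fov_mm / 2.0 + np.asarray(offset_mm)) / np.asarray(spec.voxel_size)
    ).astype(int)
    mask = np.zeros(spec.grid_shape, dtype=bool)
    i0 = spec.grid_shape[0] // 2 - 1
    _, j, k = center_vox
    mask[i0 : i0 + 2, j : j + 2, k - 1 : k + 2] = True
    return mask


def affected_regions(
    atlas_labels: np.ndarray, core_mask: np.ndarray, min_fraction: float = 0.5
) -> Set[int]:
    """Atlas regions whose voxels overlap the core by more than ``min_fraction``.

    A region counts as affected only when the core covers enough of it to
    move its summary attenuation; the default majority fraction matches the
    median statistic used by the ASPECTS scorer.
    """
    out: Set[int] = set()
    for lab in range(1, 2 * len(ASPECTS_REGION_NAMES) + 1):
        region = atlas_labels == lab
        n = region.sum()
        if n and (core_mask & region).sum() / n > min_fraction:
            out.add(int(lab))
    return out


def _residue_peak_offset(mtt_s: float, dispersion_s: float) -> float:
    """Time of the maximum of the (optionally dispersed) residue function."""
    if dispersion_s <= 0:
        return 0.0  # mono-exponential peaks at t = 0
    t = np.arange(0, 10 * max(mtt_s, dispersion_s), FINE_DT)
    r = np.exp(-t / mtt_s)
    h = np.exp(-t / dispersion_s)
    h /= h.sum()
    smeared = np.convolve(r, h)[: t.size]
    return float(t[np.argmax(smeared)])


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------

def build_phantom(spec: PhantomSpec) -> PhantomGroundTruth:
    """Construct voxelwise ground truth for one hemodynamic state.

    Masks are derived from the true maps with the same thresholds the
    analysis applies (Tmax > 6 s, rCBF < 30 % of the normal-tissue median),
    so phantom truth and pipeline output are directly comparable.
    """
    center = tuple(spec.fov_mm / 2.0)
    brain_radii = tuple(f * s for f, s in zip(spec.brain_radii_frac, spec.fov_mm))
    brain = _ellipsoid_rho2(spec, center, brain_radii) <= 1.0
    wm = (
        _ellipsoid_rho2(
            spec, center, tuple(r * spec.wm_scale for r in brain_radii)
        )
        <= 1.0
    )
    gm = brain & ~wm

    artery = _vessel_block(spec, (0.0, -24.0, 0.0)) & brain
    vein = _vessel_block(spec, (0.0, 30.0, 0.0)) & brain
    vessels = artery | vein

    shape = spec.grid_shape
    baseline = np.full(shape, HU_AIR, dtype=float)
    baseline[gm] = spec.gm.baseline_hu
    baseline[wm] = spec.wm.baseline_hu
    baseline[vessels] = HU_VESSEL_BASELINE

    cbf = np.full(shape, np.nan)
    mtt = np.full(shape, np.nan)
    cbf[gm], mtt[gm] = spec.gm.cbf, spec.gm.mtt_s
    cbf[wm], mtt[wm] = spec.wm.cbf, spec.wm.mtt_s
    delay = np.zeros(shape)
    dispersion = np.zeros(shape)

    for lesion in spec.lesions:
        rho2 = _ellipsoid_rho2(spec, lesion.center_mm, lesion.penumbra_radii_mm)
        pen = (rho2 <= 1.0) & ~vessels
        if not (pen <= brain).all() or not pen[brain].any():
            raise ValueError("lesion outside brain")
        rho = np.sqrt(np.clip(rho2, 0.0, 1.0))
        graded = lesion.delay_s + lesion.delay_center_extra_s * (1.0 - rho)
        graded = np.round(graded / DELAY_QUANT) * DELAY_QUANT
        delay[pen] = np.maximum(delay[pen], graded[pen])
        dispersion[pen] = np.maximum(dispersion[pen], lesion.dispersion_s)
        frac = np.ones(shape)
        frac[pen] = lesion.penumbra_cbf_fraction
        if lesion.core_radii_mm is not None:
            core_geom = (
                _ellipsoid_rho2(spec, lesion.center_mm, lesion.core_radii_mm)
                <= 1.0
            ) & ~vessels
            frac[core_geom] = lesion.core_cbf_fraction
        cbf = cbf * frac

    cbf[vessels] = np.nan
    mtt[vessels] = np.nan

    # true Tmax: delay plus the peak offset of the (dispersed) residue
    tmax = np.full(shape, np.nan)
    tissue = brain & ~vessels
    offsets = np.zeros(shape)
    for m in np.unique(mtt[tissue]):
        for d in np.unique(dispersion[tissue]):
            sel = tissue & (mtt == m) & (dispersion == d)
            if sel.any():
                offsets[sel] = _residue_peak_offset(float(m), float(d))
    tmax[tissue] = delay[tissue] + offsets[tissue]

    normal = tissue & (tmax < 4.0)
    ref = float(np.median(cbf[normal]))
    rcbf = np.full(shape, np.nan)
    if ref > 0:
        rcbf[tissue] = 100.0 * cbf[tissue] / ref

    hypo = np.zeros(shape, dtype=bool)
    hypo[tissue] = tmax[tissue] > 6.0
    core = hypo & (rcbf < 30.0)

    atlas = _build_atlas(spec, brain)
    affected = affected_regions(atlas, core)

    return PhantomGroundTruth(
        brain_mask=brain,
        gm_mask=gm,
        wm_mask=wm,
        artery_mask=artery,
        vein_mask=vein,
        atlas_labels=atlas,
        region_names=list(ASPECTS_REGION_NAMES),
        baseline_hu=baseline,
        true_cbf=cbf,
        true_mtt=mtt,
        true_delay=delay,
        true_dispersion=dispersion,
        true_tmax=tmax,
        true_rcbf=rcbf,
        hypoperfusion_mask=hypo,
        core_mask=core,
        affected_regions=affected,
        voxel_size=spec.voxel_size,
        affine=spec.affine,
    )


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

def _tissue_curve_bank(
    truth: PhantomGroundTruth, spec: PhantomSpec
) -> Tuple[np.ndarray, np.ndarray]:
    """Noise-free enhancement curves for every unique tissue parameter tuple.

    Returns (inverse_index_per_tissue_voxel, curves[n_unique, nt]).
    """
    t_scan = spec.time_axis
    tissue = truth.brain_mask & ~(truth.artery_mask | truth.vein_mask)
    params = np.column_stack(
        [
            truth.true_cbf[tissue],
            truth.true_mtt[tissue],
            truth.true_delay[tissue],
            truth.true_dispersion[tissue],
        ]
    )
    uniq, inverse = np.unique(params, axis=0, return_inverse=True)

    n_fine = int(np.ceil(t_scan[-1] / FINE_DT)) + 1
    t_fine = np.arange(n_fine) * FINE_DT
    aif_fine = make_aif(spec.aif, t_fine, allow_truncated=True)
    scan_idx = np.round(t_scan / FINE_DT).astype(int)

    curves = np.zeros((uniq.shape[0], t_scan.size))
    for g, (cbf_v, mtt_v, delay_v, disp_v) in enumerate(uniq):
        if cbf_v < 0 or mtt_v < 0:
            raise ValueError("negative CBF/MTT in ground truth")
        if cbf_v == 0 or mtt_v == 0:
            continue
        r = np.exp(-t_fine / mtt_v)
        if disp_v > 0:
            h = np.exp(-t_fine / disp_v)
            h /= h.sum()
            r = np.convolve(r, h)[:n_fine]
        conv = np.convolve(aif_fine, r)[:n_fine] * FINE_DT
        shift = int(round(delay_v / FINE_DT))
        shifted = np.zeros(n_fine)
        shifted[shift:] = conv[: n_fine - shift]
        curves[g] = K_FLOW * cbf_v * shifted[scan_idx]
    return inverse, curves


def simulate_ctp_series(
    truth: PhantomGroundTruth,
    spec: PhantomSpec,
    rng: Optional[np.random.Generator] = None,
    acquisition_time: str = "080000.000000",
) -> DynamicSeries:
    """Forward-simulate a dynamic CTP series from ground truth."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    t_scan = spec.time_axis
    shape = (*truth.brain_mask.shape, t_scan.size)

    data = np.empty(shape, dtype=np.float32)
    data[:] = truth.baseline_hu[..., None]

    tissue = truth.brain_mask & ~(truth.artery_mask | truth.vein_mask)
    inverse, curves = _tissue_curve_bank(truth, spec)
    data[tissue] += curves[inverse].astype(np.float32)

    n_fine = int(np.ceil(t_scan[-1] / FINE_DT)) + 1
    t_fine = np.arange(n_fine) * FINE_DT
    aif_fine = make_aif(spec.aif, t_fine, allow_truncated=True)
    scan_idx = np.round(t_scan / FINE_DT).astype(int)
    data[truth.artery_mask] += aif_fine[scan_idx].astype(np.float32)
    vein_shift = int(round(4.0 / FINE_DT))
    vein_fine = np.zeros(n_fine)
    vein_fine[vein_shift:] = 1.3 * aif_fine[: n_fine - vein_shift]
    data[truth.vein_mask] += vein_fine[scan_idx].astype(np.float32)

    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)

    return DynamicSeries(
        data=data,
        time_axis=t_scan,
        voxel_size=spec.voxel_size,
        acquisition_time=acquisition_time,
        affine=truth.affine.copy(),
    )


def simulate_ncct(
    truth: PhantomGroundTruth,
    core_hypodensity_hu: float = 5.0,
    noise_sd: float = 1.5,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Non-contrast CT volume: baseline HU, core lowered, Gaussian noise."""
    if core_hypodensity_hu < 0:
        raise ValueError("core hypodensity must be non-negative")
    rng = np.random.default_rng(0) if rng is None else rng
    vol = truth.baseline_hu.copy()
    vol[truth.core_mask] -= core_hypodensity_hu
    if noise_sd > 0:
        vol = vol + rng.normal(0.0, noise_sd, size=vol.shape)
    return vol.astype(np.float32)


# ---------------------------------------------------------------------------
# scan pairs and cohorts
# ---------------------------------------------------------------------------

def _hours_to_timestr(hours: float) -> str:
    hours = hours % 24.0
    h = int(hours)
    m = int((hours - h) * 60)
    s = (hours - h - m / 60.0) * 3600.0
    return f"{h:02d}{m:02d}{s:09.6f}"


def _shift_z(arr: np.ndarray, shift: int, fill):
    out = np.full_like(arr, fill)
    if shift == 0:
        return arr.copy()
    if shift > 0:
        out[..., : arr.shape[2] - shift] = arr[..., shift:]
    else:
        out[..., -shift:] = arr[..., : arr.shape[2] + shift]
    return out


def _shift_truth_z(truth: PhantomGroundTruth, shift: int) -> PhantomGroundTruth:
    """Ground truth as seen by a scan whose z-coverage starts ``shift`` slices
    higher; the affine origin moves so world space stays consistent."""
    def sb(a):  # boolean fields
        return _shift_z(a, shift, False)

    def sf(a, fill=np.nan):
        return _shift_z(a, shift, fill)

    affine = truth.affine.copy()
    affine[2, 3] += shift * truth.voxel_size[2]
    shifted = replace(
        truth,
        brain_mask=sb(truth.brain_mask),
        gm_mask=sb(truth.gm_mask),
        wm_mask=sb(truth.wm_mask),
        artery_mask=sb(truth.artery_mask),
        vein_mask=sb(truth.vein_mask),
        atlas_labels=_shift_z(truth.atlas_labels, shift, 0),
        baseline_hu=sf(truth.baseline_hu, HU_AIR),
        true_cbf=sf(truth.true_cbf),
        true_mtt=sf(truth.true_mtt),
        true_delay=sf(truth.true_delay, 0.0),
        true_dispersion=sf(truth.true_dispersion, 0.0),
        true_tmax=sf(truth.true_tmax),
        true_rcbf=sf(truth.true_rcbf),
        hypoperfusion_mask=sb(truth.hypoperfusion_mask),
        core_mask=sb(truth.core_mask),
        affine=affine,
    )
    return shifted


#: documented scenario constants
COVERAGE_SHIFT_SLICES = 4
HIGH_NOISE_FACTOR = 3.0
TRUNCATION_T0_SHIFT_S = 20.0
NEW_OCCLUSION_VOLUME_ML = 20.0
MIGRATION_SHIFT_MM = (0.0, 24.0, 0.0)


def make_scan_pair(
    spec: Optional[PhantomSpec] = None,
    scenario: str = "stable",
    interval_h: Optional[float] = None,
    seed: Optional[int] = None,
    protocol_jitter: bool = False,
) -> ScanPair:
    """Paired scans of one patient under a named scenario.

    ``stable`` re-scans the identical ground truth with fresh noise;
    ``new_occlusion`` adds a second 20 mL lesion; ``thrombus_migration``
    relocates the lesion by 24 mm; ``bolus_truncation`` delays the bolus by
    20 s on a 38 s protocol so the AIF tail is cut; ``coverage_shift`` moves
    the z-coverage of scan 2 by 4 slices; ``high_noise`` triples the noise sd.

    With ``protocol_jitter`` each scan draws its own temporal sampling and
    duration from the allowed protocol ranges (protocols vary between
    scanners and sites).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    spec = spec or PhantomSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    rng = np.random.default_rng(spec.seed)

    if interval_h is None:
        interval_h = float(rng.uniform(0.7, 8.8))
    if not (0.6 < interval_h < 9.0):
        raise ValueError("interval must lie in (0.6, 9) h")

    def jittered(s: PhantomSpec) -> PhantomSpec:
        if not protocol_jitter:
            return s
        dt = float(rng.uniform(1.5, 3.3))
        dur = float(rng.uniform(max(38.0, 15.5 * dt), 55.0))
        return replace(s, dt=dt, duration=dur)

    spec1 = jittered(spec)
    truth1 = build_phantom(spec1)

    spec2 = jittered(spec)
    if scenario == "stable":
        truth2 = build_phantom(spec2) if protocol_jitter else truth1
    elif scenario == "new_occlusion":
        extra = lesion_spec_for_volume(
            NEW_OCCLUSION_VOLUME_ML,
            spec2,
            center_mm=(56.0, 52.0, 44.0),
            core_fraction_of_volume=0.0,
        )
        spec2 = replace(spec2, lesions=list(spec2.lesions) + [extra])
        truth2 = build_phantom(spec2)
    elif scenario == "thrombus_migration":
        moved = [
            replace(
                les,
                center_mm=tuple(
                    c + d for c, d in zip(les.center_mm, MIGRATION_SHIFT_MM)
                ),
            )
            for les in spec2.lesions
        ]
        spec2 = replace(spec2, lesions=moved)
        truth2 = build_phantom(spec2)
    elif scenario == "bolus_truncation":
        spec2 = replace(
            spec2,
            duration=38.0,
            aif=replace(spec2.aif, t0_s=spec2.aif.t0_s + TRUNCATION_T0_SHIFT_S),
            allow_truncated_bolus=True,
        )
        truth2 = build_phantom(spec2)
    elif scenario == "high_noise":
        spec2 = replace(spec2, noise_sd=spec2.noise_sd * HIGH_NOISE_FACTOR)
        truth2 = build_phantom(spec2)
    else:  # coverage_shift
        truth2 = build_phantom(spec2)

    start_h = float(rng.uniform(0.0, 24.0))
    t1 = _hours_to_timestr(start_h)
    t2 = _hours_to_timestr(start_h + interval_h)

    ctp1 = simulate_ctp_series(truth1, spec1, rng=rng, acquisition_time=t1)
    ncct1 = simulate_ncct(
        truth1, spec1.core_hypodensity_hu, spec1.ncct_noise_sd, rng=rng
    )
    scan1 = PhantomScan(ctp1, ncct1, t1, truth1.affine.copy())

    if scenario == "coverage_shift":
        truth2 = _shift_truth_z(truth2, COVERAGE_SHIFT_SLICES)
    ctp2 = simulate_ctp_series(truth2, spec2, rng=rng, acquisition_time=t2)
    ncct2 = simulate_ncct(
        truth2, spec2.core_hypodensity_hu, spec2.ncct_noise_sd, rng=rng
    )
    scan2 = PhantomScan(ctp2, ncct2, t2, truth2.affine.copy())

    return ScanPair(
        scan1=scan1,
        scan2=scan2,
        scenario=scenario,
        truth1=truth1,
        truth2=truth2,
        interval_h=interval_h,
        seed=spec.seed,
    )


def make_cohort(
    n_pairs: int,
    spec: Optional[PhantomSpec] = None,
    scenario: str = "stable",
    seed: int = 0,
    protocol_jitter: bool = True,
) -> List[ScanPair]:
    """A cohort of independent scan pairs (one simulated patient each)."""
    spec = spec or PhantomSpec()
    seeds = np.random.SeedSequence(seed).generate_state(n_pairs) % (2**31)
    return [
        make_scan_pair(
            replace(spec, seed=int(s)),
            scenario=scenario,
            protocol_jitter=protocol_jitter,
        )
        for s in seeds
    ]
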