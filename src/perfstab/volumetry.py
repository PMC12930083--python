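"""Threshold-based lesion segmentation and volumetry.

Hypoperfused tissue is brain with Tmax strictly above 6 s; the infarct core
is hypoperfused tissue with relative CBF strictly below 30 % of the
normal-tissue median.  Volumes are reported in mL.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .perfusion import PerfusionMaps

__all__ = [
    "LesionMasks",
    "compute_brain_mask",
    "segment_lesions",
    "mask_volume_ml",
]


@dataclass
class LesionMasks:
    hypoperfusion_mask: np.ndarray
    core_mask: np.ndarray
    hypoperfusion_ml: float
    core_ml: float
    mismatch_ml: float
    tmax_threshold_s: float
    rcbf_threshold_pct: float


def mask_volume_ml(mask: np.ndarray, voxel_size) -> float:
    """Volume of a binary mask in mL (count x voxel volume / 1000)."""
    return float(np.count_nonzero(mask)) * float(np.prod(voxel_size)) / 1000.0


def compute_brain_mask(
    volume: np.ndarray,
    hu_window: Tuple[float, float] = (10.0, 60.0),
) -> np.ndarray:
    """Brain mask from an HU-calibrated volume.

    Voxels inside the attenuation window, restricted to the largest connected
    component, with interior holes filled (vessels attenuate outside the
    window but sit inside the brain).  Deterministic.
    """
    lo, hi = hu_window
    raw = (volume >= lo) & (volume <= hi)
    if not raw.any():
        raise ValueError("empty brain mask: no voxels inside the HU window")
    labels, n = ndimage.label(raw)
    if n > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        raw = labels == np.argmax(sizes)
    return ndimage.binary_fill_holes(raw)


def segment_lesions(
    maps: PerfusionMaps,
    brain_mask: Optional[np.ndarray] = None,
    tmax_threshold_s: float = 6.0,
    rcbf_threshold_pct: float = 30.0,
    min_cluster_ml: float = 1.0,
    core_within_hypoperfusion: bool = True,
    inplane_majority: bool = True,
) -> LesionMasks:
    """Segment hypoperfusion and infarct core from perfusion maps.

    Strict inequalities at both thresholds.  Two cleanup steps follow
    thresholding: an in-plane 3x3 majority vote that regularizes the
    single-voxel boundary jitter hard thresholds are prone to (in-plane only,
    since slices are thick relative to the in-plane resolution), and removal
    of connected clusters smaller than ``min_cluster_ml`` (suppresses
    salt-and-pepper noise; 0 disables).  By default the core is restricted to
    the hypoperfused region, so ``core ⊆ hypoperfusion`` holds by
    construction.
    """
    if maps.rcbf is None:
        raise ValueError("rCBF map missing: run normalize_relative first")
    brain = maps.brain_mask if brain_mask is None else brain_mask.astype(bool)

    with np.errstate(invalid="ignore"):
        hypo = brain & (maps.tmax > tmax_threshold_s)
        core_crit = maps.rcbf < rcbf_threshold_pct
    core = (hypo if core_within_hypoperfusion else brain) & core_crit

    vox_ml = float(np.prod(maps.voxel_size)) / 1000.0
    min_vox = int(np.ceil(min_cluster_ml / vox_ml)) if min_cluster_ml > 0 else 0

    def majority(mask):
        if not inplane_majority or not mask.any():
            return mask
        votes = ndimage.uniform_filter(
            mask.astype(np.float32), size=(3, 3, 1)
        )
        return brain & (votes > 0.5)

    def declutter(mask):
        if min_vox <= 1 or not mask.any():
            return mask
        labels, n = ndimage.label(mask)
        if n == 0:
            return mask
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_vox
        keep[0] = False
        return keep[labels]

    hypo = declutter(majority(hypo))
    core = declutter(majority(core))
    if core_within_hypoperfusion:
        core = core & hypo

    hypo_ml = mask_volume_ml(hypo, maps.voxel_size)
    core_ml = mask_volume_ml(core, maps.voxel_size)
    return LesionMasks(
        hypoperfusion_mask=hypo,
        core_mask=core,
        hypoperfusion_ml=hypo_ml,
        core_ml=core_ml,
        mismatch_ml=hypo_ml - core_ml,
        tmax_threshold_s=tmax_threshold_s,
        rcbf_threshold_pct=rcbf_threshold_pct,
    )
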