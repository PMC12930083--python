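"""Automated ASPECTS scoring on non-contrast CT.

ASPECTS (Alberta Stroke Program Early CT Score) rates early ischemic change
in ten anatomical regions per hemisphere (caudate C, lentiform L, internal
capsule IC, insula I, cortical territories M1–M6); one point is deducted per
abnormal region, 10 = normal.  Here a region is abnormal when its summary
attenuation falls more than a fixed ΔHU below the contralateral homologous
region.  Region membership comes from an atlas label volume; on the phantom
the atlas is exact (identity mode), and a moment-based affine alignment is
available when the scan and atlas grids differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "AspectsResult",
    "RegionStats",
    "map_atlas_regions",
    "region_statistics",
    "score_aspects",
    "score_ncct",
]

N_REGIONS = 10  #: per hemisphere; labels 1..10 left, 11..20 right


@dataclass
class RegionStats:
    name: str
    left_hu: float
    right_hu: float


@dataclass
class AspectsResult:
    """Per-region ΔHU, abnormal flags and the 0-10 score per hemisphere."""

    region_names: List[str]
    delta_hu_left: Dict[str, float]  #: contralateral minus ipsilateral, left side
    delta_hu_right: Dict[str, float]
    flags_left: Dict[str, bool]
    flags_right: Dict[str, bool]
    score_left: int
    score_right: int
    affected_side: str  #: "left" | "right" | "none"
    delta_hu_threshold: float

    @property
    def score(self) -> int:
        """Score of the affected hemisphere (10 when none is affected)."""
        if self.affected_side == "left":
            return self.score_left
        if self.affected_side == "right":
            return self.score_right
        return 10


def _moment_affine(moving: np.ndarray, template: np.ndarray, hu_window):
    """Translation aligning foreground centroids (moment-based alignment)."""
    lo, hi = hu_window
    m_mask = (moving >= lo) & (moving <= hi)
    t_mask = (template >= lo) & (template <= hi)
    if not m_mask.any() or not t_mask.any():
        raise ValueError("cannot align: empty foreground in scan or template")
    shift = np.array(ndimage.center_of_mass(m_mask)) - np.array(
        ndimage.center_of_mass(t_mask)
    )
    return shift


def map_atlas_regions(
    ncct: np.ndarray,
    atlas_labels: np.ndarray,
    alignment_mode: str = "identity",
    template: Optional[np.ndarray] = None,
    hu_window: Tuple[float, float] = (10.0, 60.0),
) -> np.ndarray:
    """Atlas labels resampled onto the NCCT grid.

    ``identity`` uses the provided labels directly (the phantom supplies
    exact phantom-space labels).  ``affine`` estimates a moment-based
    transform from the scan to the label template before overlay — a
    deliberate simplification of full non-rigid template registration,
    adequate for the rigid phantom geometry.
    """
    labels = np.asarray(atlas_labels)
    present = set(np.unique(labels)) - {0}
    if present != set(range(1, 2 * N_REGIONS + 1)):
        raise ValueError(
            f"atlas must contain exactly {2 * N_REGIONS} region labels "
            f"(1..{2 * N_REGIONS}); found {sorted(present)}"
        )
    if alignment_mode == "identity":
        aligned = labels
    elif alignment_mode == "affine":
        if template is None:
            raise ValueError("affine alignment requires a label-space template")
        shift = _moment_affine(ncct, template, hu_window)
        aligned = ndimage.shift(labels, shift, order=0, mode="constant", cval=0)
    else:
        raise ValueError(f"unknown alignment_mode {alignment_mode!r}")

    for lab in range(1, 2 * N_REGIONS + 1):
        if not np.any(aligned == lab):
            raise ValueError(f"region label {lab} has no voxels after alignment")
    return aligned


def region_statistics(
    ncct: np.ndarray,
    aligned_labels: np.ndarray,
    region_names: Sequence[str],
    statistic: str = "median",
    trim_fraction: float = 0.1,
) -> List[RegionStats]:
    """Summary HU per region and hemisphere (median, or trimmed mean)."""
    from scipy.stats import trim_mean

    def summarize(values: np.ndarray) -> float:
        if statistic == "median":
            return float(np.median(values))
        if statistic == "trimmed_mean":
            return float(trim_mean(values, trim_fraction))
        raise ValueError(f"unknown statistic {statistic!r}")

    out = []
    for i, name in enumerate(region_names):
        left = ncct[aligned_labels == i + 1]
        right = ncct[aligned_labels == i + 1 + N_REGIONS]
        out.append(RegionStats(name, summarize(left), summarize(right)))
    return out


def score_aspects(
    stats: Sequence[RegionStats], delta_hu_threshold: float = 2.25
) -> AspectsResult:
    """Score both hemispheres from paired region statistics.

    ΔHU for a region on one side is the contralateral homolog's summary HU
    minus that region's (positive when the region is hypodense relative to
    its mirror).  A region is flagged when ΔHU strictly exceeds the
    threshold; each hemisphere scores 10 minus its flag count.  The affected
    side is the one with more flags ("none" on ties, including zero flags).
    """
    names = [s.name for s in stats]
    d_left = {s.name: s.right_hu - s.left_hu for s in stats}
    d_right = {s.name: s.left_hu - s.right_hu for s in stats}
    f_left = {n: d_left[n] > delta_hu_threshold for n in names}
    f_right = {n: d_right[n] > delta_hu_threshold for n in names}
    n_left = sum(f_left.values())
    n_right = sum(f_right.values())
    if n_left > n_right:
        side = "left"
    elif n_right > n_left:
        side = "right"
    else:
        side = "none"
    return AspectsResult(
        region_names=list(names),
        delta_hu_left=d_left,
        delta_hu_right=d_right,
        flags_left=f_left,
        flags_right=f_right,
        score_left=10 - n_left,
        score_right=10 - n_right,
        affected_side=side,
        delta_hu_threshold=delta_hu_threshold,
    )


def score_ncct(
    ncct: np.ndarray,
    atlas_labels: np.ndarray,
    region_names: Sequence[str],
    delta_hu_threshold: float = 2.25,
    statistic: str = "median",
    trim_fraction: float = 0.1,
    alignment_mode: str = "identity",
    template: Optional[np.ndarray] = None,
) -> AspectsResult:
    """Convenience wrapper: align atlas, summarize regions, score."""
    aligned = map_atlas_regions(
        ncct, atlas_labels, alignment_mode=alignment_mode, template=template
    )
    stats = region_statistics(
        ncct, aligned, region_names, statistic=statistic, trim_fraction=trim_fraction
    )
    return score_aspects(stats, delta_hu_threshold=delta_hu_threshold)
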