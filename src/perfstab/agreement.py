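"""Per-scan intensity metrics and scan-to-scan agreement statistics.

Each scan is reduced to six summary metrics: infarct-core and hypoperfusion
volume (mL), ASPECTS, median Tmax within the hypoperfusion volume (s), and
median CBF / NCCT HU within the core expressed as a percentage of the
contralateral homologous (mirrored) region.  Agreement across a cohort of
repeated scan pairs is assessed with Bland–Altman statistics (bias, SD of
differences, 95 % limits of agreement = bias ± 1.96 SD), Pearson correlation,
paired t-tests, and the association of signed differences with the
inter-scan interval.  Signed differences are scan2 − scan1 throughout.

Metrics over empty regions (e.g. CBF in a non-existent core) carry NaN as an
explicit undefined marker and are dropped pairwise, with per-metric n
reported — they are never imputed as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .perfusion import PerfusionMaps
from .volumetry import LesionMasks

__all__ = [
    "METRIC_NAMES",
    "ScanMetrics",
    "BlandAltman",
    "AgreementTests",
    "MetricAgreement",
    "AgreementReport",
    "mirror_contralateral",
    "lesion_intensity_metrics",
    "scan_interval_hours",
    "bland_altman",
    "agreement_tests",
    "cohort_report",
    "plot_agreement",
]

METRIC_NAMES = [
    "core_ml",
    "hypoperfusion_ml",
    "aspects",
    "median_tmax_hypo_s",
    "rel_cbf_core_pct",
    "rel_hu_core_pct",
]

#: scenarios that invalidate a repeatability comparison
DISRUPTIVE_SCENARIOS = frozenset({"new_occlusion", "thrombus_migration"})


@dataclass
class ScanMetrics:
    """Six summary metrics of one scan; NaN marks undefined values."""

    core_ml: float
    hypoperfusion_ml: float
    aspects: float
    median_tmax_hypo_s: float
    rel_cbf_core_pct: float
    rel_hu_core_pct: float
    acquisition_time: str = ""

    def as_dict(self) -> Dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass
class BlandAltman:
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n_used: int
    n_dropped: int = 0


@dataclass
class AgreementTests:
    pearson_r: float
    pearson_p: float
    paired_t_p: float
    interval_r: float
    interval_p: float


@dataclass
class MetricAgreement:
    metric: str
    bland_altman: BlandAltman
    tests: Optional[AgreementTests]


@dataclass
class AgreementReport:
    """Cohort-level agreement across all metrics.

    ``summary()`` renders one row per metric; disruptive pairs are excluded
    from the statistics but listed with their scenario.
    """

    metrics: Dict[str, MetricAgreement]
    n_pairs_total: int
    excluded: List[Tuple[int, str]]  #: (pair index, reason)
    status: str = "ok"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, m in self.metrics.items():
            ba, tst = m.bland_altman, m.tests
            rows.append(
                {
                    "metric": name,
                    "n": ba.n_used,
                    "bias": ba.bias,
                    "sd": ba.sd,
                    "loa_low": ba.loa_low,
                    "loa_high": ba.loa_high,
                    "pearson_r": tst.pearson_r if tst else np.nan,
                    "pearson_p": tst.pearson_p if tst else np.nan,
                    "paired_t_p": tst.paired_t_p if tst else np.nan,
                    "interval_r": tst.interval_r if tst else np.nan,
                    "interval_p": tst.interval_p if tst else np.nan,
                }
            )
        return pd.DataFrame(rows).set_index("metric")

    def summary(self) -> str:
        lines = [
            "Scan-to-scan agreement report",
            f"pairs: {self.n_pairs_total} total, "
            f"{len(self.excluded)} excluded ({self.status})",
        ]
        if self.excluded:
            lines += [
                f"  excluded pair {i}: {reason}" for i, reason in self.excluded
            ]
        with pd.option_context("display.width", 120):
            lines.append(self.to_frame().round(4).to_string())
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# per-scan metrics
# ---------------------------------------------------------------------------

def _check_lr_axis(affine: Optional[np.ndarray]) -> None:
    """The left-right axis must be the first grid axis, axis-aligned."""
    if affine is None:
        raise ValueError("ambiguous orientation: no affine provided")
    rot = np.asarray(affine)[:3, :3]
    off = rot - np.diag(np.diag(rot))
    if np.any(np.abs(off) > 1e-6 * max(1.0, np.abs(rot).max())) or rot[0, 0] == 0:
        raise ValueError(
            "ambiguous orientation: affine is not axis-aligned with the "
            "left-right axis on grid axis 0; refusing to guess the midline"
        )


def mirror_contralateral(mask: np.ndarray, affine: Optional[np.ndarray]) -> np.ndarray:
    """Mask reflected across the midsagittal grid plane.

    The phantom guarantees the midline at the grid centre of axis 0; the
    affine is checked so that a non-axis-aligned grid fails loudly rather
    than silently mirroring the wrong axis.
    """
    _check_lr_axis(affine)
    return mask[::-1, :, :].copy()


def lesion_intensity_metrics(
    maps: PerfusionMaps,
    ncct: np.ndarray,
    lesions: LesionMasks,
) -> Dict[str, float]:
    """Median Tmax in the hypoperfusion volume; CBF and NCCT HU in the core
    as percent of the contralateral mirrored region.

    Empty hypoperfusion or core masks yield NaN for the affected metrics.
    """
    out = {
        "median_tmax_hypo_s": float("nan"),
        "rel_cbf_core_pct": float("nan"),
        "rel_hu_core_pct": float("nan"),
    }
    hypo, core = lesions.hypoperfusion_mask, lesions.core_mask
    if hypo.any():
        out["median_tmax_hypo_s"] = float(np.median(maps.tmax[hypo]))
    if core.any():
        mirror = mirror_contralateral(core, maps.affine)
        mirror_ok = mirror & maps.brain_mask
        if not mirror_ok.any():
            raise ValueError("mirrored core region is empty or outside the brain")
        ref_cbf = float(np.median(maps.cbf[mirror_ok]))
        ref_hu = float(np.median(ncct[mirror_ok]))
        if ref_cbf > 0:
            out["rel_cbf_core_pct"] = 100.0 * float(np.median(maps.cbf[core])) / ref_cbf
        if ref_hu > 0:
            out["rel_hu_core_pct"] = 100.0 * float(np.median(ncct[core])) / ref_hu
    return out


def scan_interval_hours(time1: str, time2: str) -> float:
    """Interval in hours between two ``HHMMSS[.ffffff]`` acquisition times.

    A negative raw difference is taken to wrap past midnight (+24 h).
    """

    def parse(s: str) -> float:
        s = s.strip()
        if len(s) < 6 or not s[:6].isdigit():
            raise ValueError(f"unparseable acquisition time {s!r}")
        h, m = int(s[:2]), int(s[2:4])
        sec = float(s[4:])
        if h > 23 or m > 59 or sec >= 61:
            raise ValueError(f"unparseable acquisition time {s!r}")
        return h + m / 60.0 + sec / 3600.0

    diff = parse(time2) - parse(time1)
    if diff < 0:
        diff += 24.0
    return diff


# ---------------------------------------------------------------------------
# agreement statistics
# ---------------------------------------------------------------------------

def _paired_finite(values1, values2, *extra):
    arrays = [np.asarray(values1, float), np.asarray(values2, float)]
    arrays += [np.asarray(e, float) for e in extra]
    ok = np.all(np.isfinite(arrays), axis=0)
    return [a[ok] for a in arrays], int((~ok).sum())


def bland_altman(values1, values2) -> BlandAltman:
    """Bland–Altman bias, SD of differences and 95 % limits of agreement.

    Differences are scan2 − scan1; the SD uses the n−1 denominator; limits of
    agreement are bias ± 1.96 SD.  Undefined (NaN) values are dropped
    pairwise; fewer than 3 usable pairs is an error.
    """
    (v1, v2), dropped = _paired_finite(values1, values2)
    if v1.size < 3:
        raise ValueError(f"need at least 3 usable pairs, got {v1.size}")
    d = v2 - v1
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(
        bias=bias,
        sd=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n_used=int(v1.size),
        n_dropped=dropped,
    )


def _safe_pearson(x, y) -> Tuple[float, float]:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def agreement_tests(
    values1, values2, intervals_h, interval_method: str = "pearson"
) -> AgreementTests:
    """Pearson r (scan1 vs scan2), paired t-test on the differences, and the
    association of differences with the inter-scan interval.

    All p-values are two-sided.  A zero-variance correlate yields NaN for the
    affected statistic rather than an exception.
    """
    (v1, v2, dt), _ = _paired_finite(values1, values2, intervals_h)
    if v1.size < 3:
        raise ValueError(f"need at least 3 usable pairs, got {v1.size}")
    d = v2 - v1

    r, r_p = _safe_pearson(v1, v2)
    if np.std(d) == 0:
        # zero-variance differences: t statistic is 0/0; for d ≡ 0 the scans
        # are identical and we report p = 1, otherwise the test is undefined
        t_p = 1.0 if np.all(d == 0) else float("nan")
    else:
        t_p = float(stats.ttest_rel(v2, v1).pvalue)
    if interval_method == "spearman":
        if np.std(d) == 0 or np.std(dt) == 0:
            ir, ip = float("nan"), float("nan")
        else:
            res = stats.spearmanr(d, dt)
            ir, ip = float(res.statistic), float(res.pvalue)
    else:
        ir, ip = _safe_pearson(d, dt)
    return AgreementTests(
        pearson_r=r, pearson_p=r_p, paired_t_p=t_p, interval_r=ir, interval_p=ip
    )


def cohort_report(
    pair_results: Sequence,
    interval_method: str = "pearson",
) -> AgreementReport:
    """Aggregate per-pair results into the cohort agreement report.

    ``pair_results`` are objects with ``metrics1``/``metrics2``
    (:class:`ScanMetrics`), ``interval_h`` and ``scenario`` attributes (see
    :mod:`perfstab.pipeline`).  Pairs whose scenario is a disruptive event
    (new occlusion, thrombus migration) are excluded from the statistics but
    listed in the report.
    """
    excluded: List[Tuple[int, str]] = []
    usable = []
    for i, pr in enumerate(pair_results):
        scenario = getattr(pr, "scenario", "stable")
        if scenario in DISRUPTIVE_SCENARIOS:
            excluded.append((i, f"disruptive event: {scenario}"))
        else:
            usable.append(pr)

    if len(usable) < 3:
        return AgreementReport(
            metrics={},
            n_pairs_total=len(pair_results),
            excluded=excluded,
            status="no usable pairs" if not usable else "too few usable pairs",
        )

    intervals = np.array([pr.interval_h for pr in usable], float)
    metrics: Dict[str, MetricAgreement] = {}
    for name in METRIC_NAMES:
        v1 = np.array([getattr(pr.metrics1, name) for pr in usable], float)
        v2 = np.array([getattr(pr.metrics2, name) for pr in usable], float)
        try:
            ba = bland_altman(v1, v2)
            tst = agreement_tests(v1, v2, intervals, interval_method)
        except ValueError:
            ba = BlandAltman(
                float("nan"), float("nan"), float("nan"), float("nan"),
                n_used=int(np.isfinite(v2 - v1).sum()),
            )
            tst = None
        metrics[name] = MetricAgreement(name, ba, tst)
    return AgreementReport(
        metrics=metrics,
        n_pairs_total=len(pair_results),
        excluded=excluded,
        status="ok",
    )


def plot_agreement(pair_results: Sequence, metric: str, ax_pair=None):
    """Correlation + Bland–Altman panel for one metric.

    Disruptive pairs are drawn in red and excluded from the agreement lines,
    mirroring the standard presentation of repeatability cohorts.
    """
    import matplotlib.pyplot as plt

    if ax_pair is None:
        _, ax_pair = plt.subplots(1, 2, figsize=(9, 4))
    ax_c, ax_ba = ax_pair

    v1 = np.array([getattr(pr.metrics1, metric) for pr in pair_results], float)
    v2 = np.array([getattr(pr.metrics2, metric) for pr in pair_results], float)
    disruptive = np.array(
        [getattr(pr, "scenario", "stable") in DISRUPTIVE_SCENARIOS for pr in pair_results]
    )

    ax_c.scatter(v1[~disruptive], v2[~disruptive], s=18, color="tab:blue")
    ax_c.scatter(v1[disruptive], v2[disruptive], s=18, color="tab:red")
    lims = np.nanpercentile(np.concatenate([v1, v2]), [0, 100])
    ax_c.plot(lims, lims, "k-", lw=1)
    ax_c.set_xlabel(f"{metric} scan 1")
    ax_c.set_ylabel(f"{metric} scan 2")

    ok = ~disruptive & np.isfinite(v1) & np.isfinite(v2)
    if ok.sum() >= 3:
        ba = bland_altman(v1[ok], v2[ok])
        mean = (v1 + v2) / 2.0
        ax_ba.scatter(mean[~disruptive], (v2 - v1)[~disruptive], s=18, color="tab:blue")
        ax_ba.scatter(mean[disruptive], (v2 - v1)[disruptive], s=18, color="tab:red")
        ax_ba.axhline(ba.bias, color="k")
        ax_ba.axhline(ba.loa_low, color="k", ls=":")
        ax_ba.axhline(ba.loa_high, color="k", ls=":")
    ax_ba.set_xlabel(f"mean {metric}")
    ax_ba.set_ylabel("difference (scan2 - scan1)")
    return ax_pair
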