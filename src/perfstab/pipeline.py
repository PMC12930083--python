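"""End-to-end pipeline: scan -> metrics, pair -> differences, cohort -> report.

Stage order per scan: preprocess -> AIF selection -> deconvolution -> maps ->
relative normalization -> lesion segmentation -> ASPECTS -> intensity
metrics.  Per pair, signed differences (scan2 - scan1) and the inter-scan
interval from the acquisition timestamps.  Per cohort, the agreement report
with disruptive pairs excluded.  Everything is deterministic given the
configuration and the simulation seeds; every JSON output embeds the config
hash and package version for provenance.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import __version__
from .agreement import (
    ScanMetrics,
    cohort_report,
    lesion_intensity_metrics,
    scan_interval_hours,
)
from .aspects import score_ncct
from .config import RunConfig
from .perfusion import quantify_perfusion
from .phantom import PhantomScan, ScanPair
from .volumetry import compute_brain_mask, segment_lesions

log = logging.getLogger("perfstab")

__all__ = ["ScanAnalysis", "PairResult", "analyze_scan", "run_pair_analysis",
           "run_cohort"]


@dataclass
class ScanAnalysis:
    """Full per-scan analysis products."""

    metrics: ScanMetrics
    maps: object
    lesions: object
    aspects: object
    aif: object
    warnings: List[str] = field(default_factory=list)


@dataclass
class PairResult:
    metrics1: ScanMetrics
    metrics2: ScanMetrics
    differences: Dict[str, float]
    interval_h: float
    scenario: str = "stable"
    warnings1: List[str] = field(default_factory=list)
    warnings2: List[str] = field(default_factory=list)

    def to_dict(self) -> Dict:
        return {
            "scan1": self.metrics1.as_dict(),
            "scan2": self.metrics2.as_dict(),
            "differences": self.differences,
            "interval_h": self.interval_h,
            "scenario": self.scenario,
            "warnings": {"scan1": self.warnings1, "scan2": self.warnings2},
        }


def analyze_scan(
    scan: PhantomScan,
    atlas_labels: Optional[np.ndarray] = None,
    region_names: Optional[Sequence[str]] = None,
    config: Optional[RunConfig] = None,
) -> ScanAnalysis:
    """Run the full single-scan analysis; ASPECTS requires atlas labels."""
    cfg = config or RunConfig()
    t0 = time.perf_counter()

    brain = compute_brain_mask(scan.ncct, hu_window=cfg.lesion.brain_hu_window)
    maps, aif, pre = quantify_perfusion(scan.ctp, brain_mask=brain, config=cfg)
    lesions = segment_lesions(
        maps,
        brain_mask=brain,
        tmax_threshold_s=cfg.lesion.tmax_threshold_s,
        rcbf_threshold_pct=cfg.lesion.rcbf_threshold_pct,
        min_cluster_ml=cfg.lesion.min_cluster_ml,
        core_within_hypoperfusion=cfg.lesion.core_within_hypoperfusion,
        inplane_majority=cfg.lesion.inplane_majority,
    )

    aspects_score = float("nan")
    aspects_res = None
    if atlas_labels is not None:
        aspects_res = score_ncct(
            scan.ncct,
            atlas_labels,
            region_names or [str(i) for i in range(1, 11)],
            delta_hu_threshold=cfg.aspects.delta_hu_threshold,
            statistic=cfg.aspects.statistic,
            trim_fraction=cfg.aspects.trim_fraction,
            alignment_mode=cfg.aspects.alignment,
        )
        aspects_score = float(aspects_res.score)

    intensity = lesion_intensity_metrics(maps, scan.ncct, lesions)
    metrics = ScanMetrics(
        core_ml=lesions.core_ml,
        hypoperfusion_ml=lesions.hypoperfusion_ml,
        aspects=aspects_score,
        acquisition_time=scan.acquisition_time,
        **intensity,
    )
    log.debug("scan analysed in %.2f s", time.perf_counter() - t0)
    return ScanAnalysis(
        metrics=metrics,
        maps=maps,
        lesions=lesions,
        aspects=aspects_res,
        aif=aif,
        warnings=list(pre.warnings),
    )


def run_pair_analysis(
    pair: ScanPair, config: Optional[RunConfig] = None
) -> PairResult:
    """Analyse both scans of a pair and form signed differences.

    The phantom's exact atlas labels are used for ASPECTS (identity
    alignment); the truth maps themselves are never consulted.
    """
    cfg = config or RunConfig()
    res1 = analyze_scan(
        pair.scan1, pair.truth1.atlas_labels, pair.truth1.region_names, cfg
    )
    res2 = analyze_scan(
        pair.scan2, pair.truth2.atlas_labels, pair.truth2.region_names, cfg
    )
    m1, m2 = res1.metrics, res2.metrics
    diffs = {
        k: m2.as_dict()[k] - m1.as_dict()[k] for k in m1.as_dict()
    }
    return PairResult(
        metrics1=m1,
        metrics2=m2,
        differences=diffs,
        interval_h=scan_interval_hours(m1.acquisition_time, m2.acquisition_time),
        scenario=pair.scenario,
        warnings1=res1.warnings,
        warnings2=res2.warnings,
    )


def analyze_cohort(
    n_pairs: int,
    spec=None,
    scenario: str = "stable",
    seed: int = 0,
    config: Optional[RunConfig] = None,
    protocol_jitter: bool = True,
) -> List[PairResult]:
    """Simulate and analyse ``n_pairs`` scan pairs one at a time.

    Streams pair by pair so that only the lightweight :class:`PairResult`
    objects are retained (a full cohort of raw 4D series would not fit in
    memory).
    """
    from dataclasses import replace as dc_replace

    from .phantom import PhantomSpec, make_scan_pair

    spec = spec or PhantomSpec()
    seeds = np.random.SeedSequence(seed).generate_state(n_pairs) % (2**31)
    out = []
    for s in seeds:
        pair = make_scan_pair(
            dc_replace(spec, seed=int(s)),
            scenario=scenario,
            protocol_jitter=protocol_jitter,
        )
        out.append(run_pair_analysis(pair, config))
    return out


def _provenance(cfg: RunConfig) -> Dict:
    return {"config": cfg.model_dump(mode="json"),
            "config_hash": cfg.config_hash(),
            "package_version": __version__}


def write_pair_report(path, result: PairResult, config: Optional[RunConfig] = None):
    cfg = config or RunConfig()
    payload = result.to_dict()
    payload["provenance"] = _provenance(cfg)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def run_cohort(
    pair_results: Sequence[PairResult],
    config: Optional[RunConfig] = None,
    outdir=None,
    make_plots: bool = False,
):
    """Aggregate pair results into the agreement report; optionally write
    JSON/CSV (and Bland-Altman figures) under ``outdir``."""
    cfg = config or RunConfig()
    if len(pair_results) == 0:
        raise ValueError("empty cohort: no pair results supplied")
    report = cohort_report(
        pair_results, interval_method=cfg.agreement.interval_method
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        frame = report.to_frame()
        frame.to_csv(outdir / "agreement.csv")
        payload = {
            "summary": json.loads(frame.to_json(orient="index")),
            "n_pairs_total": report.n_pairs_total,
            "excluded": [
                {"pair_index": i, "reason": r} for i, r in report.excluded
            ],
            "status": report.status,
            "provenance": _provenance(cfg),
        }
        (outdir / "agreement.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True)
        )
        if make_plots:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            from .agreement import METRIC_NAMES, plot_agreement

            for metric in METRIC_NAMES:
                fig, axes = plt.subplots(1, 2, figsize=(9, 4))
                plot_agreement(pair_results, metric, ax_pair=axes)
                fig.tight_layout()
                fig.savefig(outdir / f"agreement_{metric}.png", dpi=110)
                plt.close(fig)
    return report
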