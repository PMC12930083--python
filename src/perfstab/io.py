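"""NIfTI + JSON-sidecar I/O for scans, ground truth and perfusion maps."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import nibabel as nib
import numpy as np

from .perfusion import DynamicSeries, PerfusionMaps
from .phantom import PhantomGroundTruth, PhantomScan, ScanPair

__all__ = [
    "save_volume",
    "load_volume",
    "save_series",
    "load_series",
    "save_scan",
    "load_scan",
    "save_scan_pair",
    "load_scan_pair",
    "save_maps",
]


def save_volume(path, data: np.ndarray, affine: Optional[np.ndarray] = None):
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def load_volume(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def _sidecar_path(path) -> Path:
    p = Path(path)
    name = p.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return p.with_name(name[: -len(suf)] + ".json")
    return p.with_suffix(".json")


def save_series(path, series: DynamicSeries, extra: Optional[Dict] = None):
    """4D NIfTI plus a JSON sidecar with timing and geometry metadata."""
    save_volume(path, series.data.astype(np.float32), series.affine)
    meta = {
        "time_axis_s": [float(v) for v in series.time_axis],
        "voxel_size_mm": [float(v) for v in series.voxel_size],
        "acquisition_time": series.acquisition_time,
    }
    if extra:
        meta.update(extra)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def load_series(path) -> DynamicSeries:
    data, affine = load_volume(path)
    meta = json.loads(_sidecar_path(path).read_text())
    return DynamicSeries(
        data=np.asarray(data, dtype=np.float32),
        time_axis=np.asarray(meta["time_axis_s"], dtype=float),
        voxel_size=tuple(meta["voxel_size_mm"]),
        acquisition_time=meta["acquisition_time"],
        affine=affine,
    )


def save_scan(outdir, scan: PhantomScan, prefix: str, extra: Optional[Dict] = None):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_series(outdir / f"{prefix}_ctp.nii.gz", scan.ctp, extra=extra)
    save_volume(outdir / f"{prefix}_ncct.nii.gz", scan.ncct, scan.affine)


def load_scan(outdir, prefix: str) -> PhantomScan:
    outdir = Path(outdir)
    ctp = load_series(outdir / f"{prefix}_ctp.nii.gz")
    ncct, affine = load_volume(outdir / f"{prefix}_ncct.nii.gz")
    return PhantomScan(
        ctp=ctp,
        ncct=np.asarray(ncct, dtype=np.float32),
        acquisition_time=ctp.acquisition_time,
        affine=affine,
    )


def _save_truth(outdir: Path, truth: PhantomGroundTruth, prefix: str):
    masks = {
        "brain_mask": truth.brain_mask,
        "hypoperfusion_mask": truth.hypoperfusion_mask,
        "core_mask": truth.core_mask,
    }
    for name, m in masks.items():
        save_volume(outdir / f"{prefix}_{name}.nii.gz", m.astype(np.uint8), truth.affine)
    save_volume(
        outdir / f"{prefix}_atlas.nii.gz",
        truth.atlas_labels.astype(np.int16),
        truth.affine,
    )
    meta = {
        "region_names": truth.region_names,
        "affected_regions": sorted(truth.affected_regions),
        "voxel_size_mm": [float(v) for v in truth.voxel_size],
    }
    (outdir / f"{prefix}_truth.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True)
    )


def save_scan_pair(outdir, pair: ScanPair, save_truth: bool = True):
    """Write both scans (4D CTP + NCCT + sidecars) and optionally the truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    common = {"scenario": pair.scenario, "seed": pair.seed}
    save_scan(outdir, pair.scan1, "scan1", extra=common)
    save_scan(outdir, pair.scan2, "scan2", extra=common)
    (outdir / "pair.json").write_text(
        json.dumps(
            {
                "scenario": pair.scenario,
                "seed": pair.seed,
                "interval_h": pair.interval_h,
                "acquisition_time_1": pair.scan1.acquisition_time,
                "acquisition_time_2": pair.scan2.acquisition_time,
            },
            indent=2,
            sort_keys=True,
        )
    )
    if save_truth:
        _save_truth(outdir, pair.truth1, "truth1")
        _save_truth(outdir, pair.truth2, "truth2")


def load_scan_pair(outdir):
    """Load the two scans and pair metadata written by :func:`save_scan_pair`.

    Ground truth is not reloaded; analysis of real or re-loaded data uses
    only the scans.  Returns (scan1, scan2, meta dict).
    """
    outdir = Path(outdir)
    meta = json.loads((outdir / "pair.json").read_text())
    return load_scan(outdir, "scan1"), load_scan(outdir, "scan2"), meta


def save_maps(outdir, maps: PerfusionMaps, prefix: str = "maps"):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fields = {
        "cbf": maps.cbf,
        "cbv": maps.cbv,
        "mtt": maps.mtt,
        "tmax": maps.tmax,
        "rcbf": maps.rcbf,
        "rcbv": maps.rcbv,
    }
    for name, vol in fields.items():
        if vol is not None:
            save_volume(
                outdir / f"{prefix}_{name}.nii.gz",
                vol.astype(np.float32),
                maps.affine,
            )
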