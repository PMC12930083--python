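"""Run configuration for the perfusion analysis pipeline.

All tunables of the pipeline live here so that every output can embed a full,
hashable provenance record.  Defaults follow the thresholds printed in the
clinical workflow this package models (Tmax > 6 s hypoperfusion, rCBF < 30 %
infarct core, Tmax < 4 s normalization reference, ΔHU > 2.25 ASPECTS flag);
everything else is a documented package choice (see docs/methods.md).
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal, Tuple

import yaml
from pydantic import BaseModel, Field


class AifConfig(BaseModel):
    """Automatic arterial-input-function selection parameters."""

    candidate_fraction: float = Field(0.005, gt=0, le=0.2)
    #: candidates must enhance by at least this many HU at peak; vessels reach
    #: well over 100 HU at CTP tube voltages while tissue and partial-volume
    #: halo voxels stay far below, so this floor removes non-vascular curves
    amplitude_floor_hu: float = Field(60.0, ge=0)
    #: number of top-ranked arterial candidates averaged into the final AIF
    top_k: int = Field(5, ge=1)
    #: minimum connected-component size (voxels) for spatial-contiguity filtering
    min_component_voxels: int = Field(4, ge=1)


class PerfusionConfig(BaseModel):
    """Deconvolution and preprocessing parameters."""

    #: Tikhonov regularization as a fraction of the largest singular value
    lambda_rel: float = Field(0.15, ge=0)
    #: block-circulant (delay-insensitive) deconvolution; plain Toeplitz when False
    circulant: bool = True
    smoothing_fwhm_mm: float = Field(4.0, ge=0)
    #: sd of the temporal Gaussian denoiser, in frames (0 disables)
    temporal_smoothing_frames: float = Field(1.5, ge=0)
    motion_correction: bool = False
    #: bolus arrival: whole-brain enhancement must exceed this multiple of the
    #: pre-bolus sd ...
    arrival_sd_multiple: float = Field(3.0, gt=0)
    #: ... with an absolute floor (HU) so the rule is defined for noise-free data
    arrival_floor_hu: float = Field(0.3, ge=0)
    #: Tmax below which tissue counts as normally perfused (normalization set)
    normal_tmax_s: float = 4.0
    #: AIF amplitude fraction at the last frame above which bolus coverage is
    #: flagged as incomplete
    truncation_fraction: float = Field(0.2, gt=0, lt=1)
    aif: AifConfig = AifConfig()


class LesionConfig(BaseModel):
    """Thresholds for hypoperfusion / infarct-core segmentation."""

    tmax_threshold_s: float = 6.0
    rcbf_threshold_pct: float = 30.0
    #: connected clusters smaller than this are removed after thresholding
    min_cluster_ml: float = Field(1.0, ge=0)
    #: in-plane 3x3 majority vote regularizing threshold-mask boundaries
    inplane_majority: bool = True
    #: restrict the core to the hypoperfused region (mismatch-software practice)
    core_within_hypoperfusion: bool = True
    brain_hu_window: Tuple[float, float] = (10.0, 60.0)


class AspectsConfig(BaseModel):
    """Automated ASPECTS scoring parameters."""

    delta_hu_threshold: float = 2.25
    statistic: Literal["median", "trimmed_mean"] = "median"
    #: fraction trimmed from each tail when statistic == "trimmed_mean"
    trim_fraction: float = Field(0.1, ge=0, lt=0.5)
    alignment: Literal["identity", "affine"] = "identity"


class AgreementConfig(BaseModel):
    """Scan-to-scan agreement statistics."""

    alpha: float = 0.05
    interval_method: Literal["pearson", "spearman"] = "pearson"


class RunConfig(BaseModel):
    """Complete, serializable pipeline configuration."""

    perfusion: PerfusionConfig = PerfusionConfig()
    lesion: LesionConfig = LesionConfig()
    aspects: AspectsConfig = AspectsConfig()
    agreement: AgreementConfig = AgreementConfig()
    seed: int = 0

    def config_hash(self) -> str:
        """Stable SHA-256 over the canonical JSON form (provenance stamp)."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})
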