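"""Serializable pipeline configuration.

One YAML document carries every tunable of the pipeline: QC thresholds
per genotyping batch, HMM parameters, filter settings, parent-of-origin
aggregation thresholds, simulation noise and the master seed.  The model
round-trips losslessly through YAML so every stage can be re-run from its
serialized inputs alone.
"""
from __future__ import annotations

import hashlib
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .hmm import HmmParams
from .qc import QcThresholds

__all__ = ["PipelineConfig"]


class QcSection(BaseModel):
    max_lrr_sd: float = 0.3
    max_baf_drift: float = 0.001
    max_abs_wf: float = 0.05
    max_n_calls: int = 100

    def to_thresholds(self) -> QcThresholds:
        return QcThresholds(self.max_lrr_sd, self.max_baf_drift,
                            self.max_abs_wf, self.max_n_calls)


class HmmSection(BaseModel):
    lrr_sds: list[float] = Field(default_factory=lambda: list(HmmParams().lrr_sds))
    baf_sd: float = 0.04
    outlier_weight: float = 0.01
    change_rate: float = 1e-4
    length_scale_bp: float = 1e5

    def to_params(self) -> HmmParams:
        return HmmParams(lrr_sds=tuple(self.lrr_sds), baf_sd=self.baf_sd,
                         outlier_weight=self.outlier_weight,
                         change_rate=self.change_rate,
                         length_scale_bp=self.length_scale_bp)


class FilterSection(BaseModel):
    max_parental_freq: float = 0.01
    min_bp: int = 100_000
    min_markers: int = 10
    min_region_fraction: float = 0.5
    min_recip: float = 0.5
    gap_fraction: float = 0.20

    @field_validator("max_parental_freq", "min_region_fraction", "min_recip",
                     "gap_fraction")
    @classmethod
    def _unit_interval(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("fraction thresholds must lie in [0, 1]")
        return v


class OriginSection(BaseModel):
    min_informative: int = 3
    min_concordance: float = 0.8
    band_tol: float = 0.08


class SimSection(BaseModel):
    n_trios: int = 200
    lrr_sd: float = 0.10
    baf_sd: float = 0.03
    outlier_rate: float = 0.002
    wave_amplitude: float = 0.01
    marker_spacing_bp: float = 5000.0
    flank_bp: int = 500_000
    # Multiplier on the per-region event rates: lets demonstration-sized
    # cohorts carry a usable number of events.
    rate_scale: float = 1.0


class PipelineConfig(BaseModel):
    """Top-level configuration; see section models for the fields."""

    qc: QcSection = Field(default_factory=QcSection)
    qc_batch2: QcSection = Field(default_factory=lambda: QcSection(max_n_calls=130))
    hmm: HmmSection = Field(default_factory=HmmSection)
    filters: FilterSection = Field(default_factory=FilterSection)
    origin: OriginSection = Field(default_factory=OriginSection)
    sim: SimSection = Field(default_factory=SimSection)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)

    def digest(self) -> str:
        """Short configuration hash recorded in output headers."""
        blob = yaml.safe_dump(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
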