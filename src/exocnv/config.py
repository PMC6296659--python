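"""Pipeline configuration: every tunable in one auditable place."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["PipelineConfig"]


class PipelineConfig(BaseModel):
    """All pipeline tunables with their documented ranges.

    Unknown keys are rejected so a typo cannot silently fall back to a
    default.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    # windowing / caller
    window_bp: int = Field(100, ge=1, description="window length for count binning (bp)")
    max_members: int = Field(10, ge=1, description="reference-set size cap")
    q: float = Field(1e-4, gt=0, lt=0.5, description="per-window diploid exit probability")
    cnv_mean_windows: float = Field(50.0, ge=1, description="expected CNV length (windows)")
    theta_floor: float = Field(0.0, ge=0, description="overdispersion lower bound")
    min_ratio_cn0: float = Field(0.15, ge=0, le=1,
                                 description="observed ratio below which a loss is CN 0")

    # aneuploidy
    grubbs_alpha: float = Field(0.05, gt=0, lt=1)
    grubbs_iterative: bool = True
    sex_stratify: bool = True
    min_mosaic_fraction: float = Field(0.2, ge=0, le=1)
    male_share_threshold: float = Field(0.4, gt=0, lt=1)

    # annotation tiers
    bf_medium: float = Field(20.0, ge=0)
    bf_high: float = Field(100.0, ge=0)
    size_high_bp: int = Field(100_000, ge=1)
    min_exons_high: int = Field(3, ge=0)
    isca_similarity_min: float = Field(0.5, ge=0, le=1)
    recurrence_cap: int = Field(2, ge=0)
    band_half_width: float = Field(0.1, gt=0, le=0.5)

    # concordance
    min_overlap_bp: int = Field(1, ge=1)
    reciprocal: float = Field(0.5, ge=0, le=1)
    min_depth: float = Field(10.0, ge=0)

    # simulation
    seed: int = Field(0, ge=0)
    mean_depth: float = Field(62.0, gt=0)
    dispersion: float = Field(0.01, ge=0)
    sample_depth_cv: float = Field(0.1, ge=0)
    capture_sigma: float = Field(0.5, ge=0)
    polymorphic_frequency: float = Field(0.3, gt=0, le=1)
    array_jitter_bp: int = Field(2000, ge=0)
    array_min_size_bp: int = Field(10_000, ge=0)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(), sort_keys=True, default_flow_style=False)
        )

    def config_hash(self) -> str:
        """Stable short hash of the full configuration."""
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
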