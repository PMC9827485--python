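"""Run configuration: a single validated, YAML-round-trippable object.

Defaults reproduce the emulated study design: 26 slide pairs in two stains,
596-8954 macrophages per slide, ten annotators scoring >= 300 cells each
with systematic grade-threshold bias and ~23% misidentified annotations,
iron chemistry censored below 0.4 umol/L, THS cut-off 75, 50 px matching
radius.  Image rendering is opt-in because a full-size study renders to
multi-gigapixel images; small configs enable it for the image-grading stage.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field

from .synthetic import (
    AnnotatorProfile,
    ChemistryParams,
    RenderParams,
    StudyConfig,
    make_default_profiles,
)


class AnnotatorSpec(BaseModel):
    annotator_id: str
    threshold_shift: float = 0.0
    perception_sd: float = Field(0.05, ge=0)
    selection_pattern: Literal["uniform_random", "clustered_fields", "meander"] = (
        "uniform_random"
    )
    n_target: int = Field(300, ge=1)
    misid_rate: float = Field(0.23, ge=0, lt=1)
    jitter_sd: float = Field(10.0, ge=0)

    def to_profile(self) -> AnnotatorProfile:
        return AnnotatorProfile(**self.model_dump())


class ChemistrySpec(BaseModel):
    iron_baseline: float = Field(0.05, ge=0)
    iron_slope: float = Field(4.5, ge=0)
    iron_noise_sigma: float = Field(0.6, ge=0)
    detection_limit: float = Field(0.4, ge=0)
    density_ref: int = Field(4137, ge=1)
    density_exponent: float = 0.25
    rbc_log_mean: float = 5.298317366548036       # ln(200)
    rbc_log_sigma: float = Field(1.0, ge=0)
    hgb_log_mean: float = -1.8971199848858813     # ln(0.15)
    hgb_log_sigma: float = Field(0.8, ge=0)

    def to_params(self) -> ChemistryParams:
        return ChemistryParams(**self.model_dump())


class RunConfig(BaseModel):
    """Complete, serialisable description of one pipeline run."""

    seed: int = 0
    n_slide_pairs: int = Field(26, ge=1)
    cell_count_range: tuple[int, int] = (596, 8954)
    severity_range: tuple[float, float] = (0.0, 1.0)
    distractor_fraction: float = Field(0.35, ge=0, lt=1)
    min_spacing: float = Field(110.0, gt=0)
    grid_jitter: float = Field(15.0, ge=0)
    margin: float = Field(60.0, ge=0)
    grid_occupancy: float = Field(0.7, gt=0, le=1)
    turnbull_content_bias: float = 0.0
    n_annotators: int = Field(10, ge=1)
    annotators: Optional[list[AnnotatorSpec]] = None
    n_target: int = Field(300, ge=1)
    misid_rate: float = Field(0.23, ge=0, lt=1)
    jitter_sd: float = Field(10.0, ge=0)
    chemistry: ChemistrySpec = ChemistrySpec()
    render_images: bool = False
    cutoff: float = 75.0
    match_radius: float = Field(50.0, gt=0)
    min_cells: int = Field(300, ge=1)
    allow_fewer: bool = False
    coverage: float = Field(0.8, gt=0, lt=1)
    consensus_k: int = Field(9, ge=1)

    def study_config(self) -> StudyConfig:
        return StudyConfig(
            n_slide_pairs=self.n_slide_pairs,
            cell_count_range=tuple(self.cell_count_range),
            severity_range=tuple(self.severity_range),
            distractor_fraction=self.distractor_fraction,
            min_spacing=self.min_spacing,
            grid_jitter=self.grid_jitter,
            margin=self.margin,
            grid_occupancy=self.grid_occupancy,
            turnbull_content_bias=self.turnbull_content_bias,
        )

    def profiles(self) -> list[AnnotatorProfile]:
        if self.annotators is not None:
            return [a.to_profile() for a in self.annotators]
        return make_default_profiles(
            n_annotators=self.n_annotators,
            n_target=self.n_target,
            misid_rate=self.misid_rate,
            jitter_sd=self.jitter_sd,
        )

    def chemistry_params(self) -> ChemistryParams:
        return self.chemistry.to_params()

    def render_params(self) -> RenderParams:
        return RenderParams()

    # -- serialisation ------------------------------------------------------

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Provenance hash of the canonical JSON form."""
        canonical = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
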