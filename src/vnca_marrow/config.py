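"""Validated run configuration for the batch pipeline.

The YAML schema mirrors the pipeline stages; unknown keys are rejected so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .bmd import DEFAULT_TARGET_POSITIONS
from .inference import DEFAULT_CUTOFF_PERCENT

__all__ = ["RunConfig", "load_config", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomConfig(_Strict):
    grid_shape: tuple[int, int, int] = (48, 48, 344)
    spacing_mm: tuple[float, float, float] = (1.5, 1.5, 1.5)
    n_vertebrae: int = 18
    body_radius_mm: float = 16.0
    body_height_mm: float = 24.0
    gap_mm: float = 4.0
    cortical_thickness_mm: float = 2.0
    base_soft_fraction: float = 0.05
    infiltration_gain: float = 0.6
    noise_sd_hu: float = 15.0
    cortical_bh_deficit_hu: float = 30.0


class CohortConfig(_Strict):
    n_mm: int = 21
    n_mgus: int = 14
    mm_infiltration_dist: tuple[float, float] = (0.72, 0.95)
    mgus_infiltration_dist: tuple[float, float] | None = None
    bmd_dist: tuple[float, float] = (96.8, 15.0)
    lesion_prob_mm: float = 13.0 / 21.0


class SpectralConfig(_Strict):
    suppression_index: float = 25.0
    basis: dict[str, float] = Field(default_factory=dict)  # MaterialBasis overrides


class SegmentationConfig(_Strict):
    vertebrae: int = 17
    erosion_mm: float = 3.0
    bone_threshold: float = 200.0


class HistogramConfig(_Strict):
    lower_edge: float = -1024.0
    upper_edge: float = 3071.0
    bin_width: float = 5.0
    standard_volume_cm3: float = 336.0


class BMDConfig(_Strict):
    target_positions: tuple[int, ...] = DEFAULT_TARGET_POSITIONS
    roi_erosion_mm: float = 3.0
    # None: derive the reference equivalent densities from the material basis
    density_fat_equiv: float | None = None
    density_muscle_equiv: float | None = None
    reader_subsample: float = 0.05


class InferenceConfig(_Strict):
    alpha: float = 0.05
    cutoff_percent: float = DEFAULT_CUTOFF_PERCENT
    outcome: Literal["lesions", "diagnosis", "both"] = "both"
    f2: float = 0.32
    target_power: float = 0.8


class RunConfig(_Strict):
    seed: int = 0
    output_dir: str = "vnca_marrow_run"
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    spectral: SpectralConfig = Field(default_factory=SpectralConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    histogram: HistogramConfig = Field(default_factory=HistogramConfig)
    bmd: BMDConfig = Field(default_factory=BMDConfig)
    inference: InferenceConfig = Field(default_factory=InferenceConfig)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load and validate a YAML run configuration (defaults when path is None)."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    raw.update(overrides)
    return RunConfig.model_validate(raw)


def config_hash(cfg: RunConfig) -> str:
    """Stable digest of the full configuration, for provenance."""
    canon = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
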