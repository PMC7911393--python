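"""Validated run configuration (JSON) for the pipeline.

Pydantic models with ``extra="forbid"`` so unknown keys are rejected before
any computation starts.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .segment import METHOD_NAMES

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LiverSection(_Strict):
    # None: placed automatically at (0.8, 0.8, 0.5) of the grid extent
    center_mm: tuple[float, float, float] | None = None
    radius_mm: float = 22.0
    mean_suv: float = 2.2
    sd_suv: float = 0.2


class PhantomSection(_Strict):
    n_patients: int = Field(default=40, gt=0)
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (5.3, 5.3, 2.0)
    background: float = Field(default=1.0, gt=0)
    psf_fwhm_mm: float = Field(default=4.4, ge=0)
    noise_sd: float = Field(default=0.15, ge=0)
    liver: LiverSection = LiverSection()


class ObserverSection(_Strict):
    box_margin_jitter: float = Field(default=1.0, ge=0)
    split_merge_probability: float = Field(default=0.3, ge=0, le=1)


class MethodSection(_Strict):
    fraction: float = 0.41
    absolute_level: float = 2.5
    beta: float = 0.15
    high_fraction: float = 0.70
    black_a: float = 0.307
    black_b: float = 0.588
    daisne_m: float | None = None
    daisne_c: float | None = None
    max_iter: int = 100


class StatsSection(_Strict):
    n_boot: int = Field(default=10000, gt=0)
    level: float = Field(default=0.95, gt=0, lt=1)
    hochberg: bool = True


class SurvivalSection(_Strict):
    baseline_hazard: float = Field(default=0.10, gt=0)
    coef_volume: float = 0.84
    coef_ipi: float = 0.59
    coef_ct: float = 1.11
    p_ipi_high: float = 0.582
    p_ct_chop: float = 0.72
    volume_cutoff_cm3: float | None = None
    censor_low_years: float = 3.0
    censor_high_years: float = 10.0
    horizon_years: float = Field(default=5.0, gt=0)


class RunConfig(_Strict):
    phantom: PhantomSection = PhantomSection()
    observers: tuple[ObserverSection, ObserverSection] = (ObserverSection(), ObserverSection())
    methods: dict[str, MethodSection] = Field(
        default_factory=lambda: {name: MethodSection() for name in METHOD_NAMES})
    stats: StatsSection = StatsSection()
    survival: SurvivalSection = SurvivalSection()

    @field_validator("methods")
    @classmethod
    def _known_methods(cls, v):
        unknown = set(v) - set(METHOD_NAMES)
        if unknown:
            raise ValueError(f"unknown method name(s) {sorted(unknown)}; "
                             f"expected a subset of {METHOD_NAMES}")
        if not v:
            raise ValueError("at least one method must be configured")
        return v


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON run configuration."""
    with open(path) as fh:
        data = json.load(fh)
    return RunConfig.model_validate(data)
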