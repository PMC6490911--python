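"""Run configuration: validated settings shared by the CLI and scripts."""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, Field, field_validator

from .doseopt import DEFAULT_BAND_EDGES, TARGET_AUC

__all__ = ["RunConfig", "EstimationConfig"]


class EstimationConfig(BaseModel):
    max_iter: int = Field(300, ge=1)
    inner_gtol: float = Field(1e-5, gt=0)
    outer_gtol: float = Field(5e-3, gt=0)
    compute_rse: bool = True
    init: dict | None = None  # overrides for PopulationModel fields


class RunConfig(BaseModel):
    """Pipeline settings; precedence is CLI flag > config file > default."""

    seed: int = 12345
    vpc_replicates: int = Field(500, ge=1)
    dose_replicates: int = Field(200, ge=1)
    target_auc: float = Field(TARGET_AUC, gt=0)
    weight_bands: list[tuple[float, float]] = Field(
        default_factory=lambda: [tuple(b) for b in DEFAULT_BAND_EDGES])
    regime: str = "exact"
    drop_blq: bool = False
    estimation: EstimationConfig = Field(default_factory=EstimationConfig)

    @field_validator("weight_bands")
    @classmethod
    def _bands_ordered_disjoint(cls, bands):
        for lo, hi in bands:
            if not lo < hi:
                raise ValueError(f"band [{lo}, {hi}) is empty")
        for (_, hi), (lo2, _) in zip(bands, bands[1:]):
            if lo2 < hi:
                raise ValueError("weight bands must be disjoint and ordered")
        return bands

    @field_validator("regime")
    @classmethod
    def _known_regime(cls, v):
        if v not in ("exact", "suspension", "tablet"):
            raise ValueError("regime must be exact, suspension or tablet")
        return v

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(Path(path)) as fh:
            return cls.model_validate(json.load(fh))

    def override(self, **kwargs) -> "RunConfig":
        """Apply non-None keyword overrides (CLI precedence)."""
        data = self.model_dump()
        for k, v in kwargs.items():
            if v is not None:
                data[k] = v
        return RunConfig.model_validate(data)
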