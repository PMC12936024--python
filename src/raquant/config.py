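"""Run configuration: a validated YAML-backed schema for the whole pipeline."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator


class RG4Section(BaseModel):
    min_tract_len: int = 3
    n_tracts: int = 4
    loop_min: int = 1
    loop_max: int = 7
    window: int = 20
    prob_threshold: float = Field(0.5, ge=0.0, le=1.0)
    sweep_thresholds: list[float] = [0.4, 0.5, 0.6]


class ScreenSection(BaseModel):
    lfc_threshold: float = Field(1.5, gt=0)
    fdr_threshold: float = Field(0.01, gt=0)
    pseudocount: float = Field(0.5, gt=0)


class SeveritySection(BaseModel):
    w_count: float = 0.3
    w_diam: float = 0.4
    w_volratio: float = 0.3
    count_cap: int = Field(10, gt=0)
    diam_cap_mm: float = Field(10.0, gt=0)
    grade_cutoffs: tuple[float, float] = (33.3, 66.7)
    connectivity: int = 26
    min_slices: int = 2
    rapid_rate: float = 30.0
    special_site_threshold: float = 0.40

    @model_validator(mode="after")
    def _weights_sum(self) -> "SeveritySection":
        if abs(self.w_count + self.w_diam + self.w_volratio - 1.0) > 1e-9:
            raise ValueError("severity weights must sum to 1")
        return self


class SynthSection(BaseModel):
    n_genes: int = 67
    n_positive: int = 42
    n_count_genes: int = 2000
    n_per_group: int = 20
    nb_dispersion: float = Field(0.1, gt=0)
    n_patients: int = Field(16, ge=3)  # agreement statistics need >= 3 subjects
    target_dsc: float = Field(0.86, gt=0.0, le=1.0)


class EvalSection(BaseModel):
    n_boot: int = 1000


class RunConfig(BaseModel):
    """Top-level pipeline configuration; every field has a sensible default."""

    seed: int = 0
    rg4: RG4Section = RG4Section()
    screen: ScreenSection = ScreenSection()
    severity: SeveritySection = SeveritySection()
    synth: SynthSection = SynthSection()
    eval: EvalSection = EvalSection()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def config_hash(self) -> str:
        """Stable short hash of the canonicalised configuration."""
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
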