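"""Run configuration for a CDM build.

A single YAML document drives every stage of the pipeline: where raw source
bundles live, where the CDM is written, which reference artifacts (code lists,
analyte specs, unit conversion factors, eGFR coefficients) to load, the cohort
inclusion criteria, and the audit identity (user + fixed clock) stamped onto
every persisted row.

The clock is *injectable*: with a fixed ``clock`` value and fixed ``user``,
two runs over identical inputs produce byte-identical output, which makes
idempotence and federated-refresh isolation directly testable.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import importlib.resources
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator


class ConfigurationError(ValueError):
    """Raised for fatal configuration problems (unknown source, bad paths...)."""


def _packaged(name: str) -> str:
    """Path to a reference CSV shipped inside the package."""
    return str(importlib.resources.files("renalcdm.data") / name)


class SourceConfig(BaseModel):
    """One raw data source participating in the federated build."""

    name: str
    country: str = "US"  # ISO 3166 alpha-2
    coding_system: str = "ICD10"
    path: Optional[str] = None  # directory holding the raw bundle
    poolable: bool = True


class CohortCriteriaConfig(BaseModel):
    """The three base-cohort inclusion criteria and their thresholds.

    Defaults encode the protocol: two eGFR measures < 75 mL/min/1.73 m^2
    recorded > 90 days apart (maximum 730 days) from 2008-01-01, a diagnosis
    code for CKD stage 3A through kidney failure, or chronic (> 30 days)
    renal replacement therapy.
    """

    egfr_threshold: float = 75.0
    min_gap_days: int = 90  # strictly greater than
    max_gap_days: int = 730  # inclusive
    window_start: dt.date = dt.date(2008, 1, 1)
    rrt_min_duration_days: int = 30  # strictly greater than
    rrt_episode_break_days: int = 90
    ckd_dx_entity_labels: list[str] = Field(
        default_factory=lambda: [
            "ckd stage 3a",
            "ckd stage 3b",
            "ckd stage 4",
            "ckd stage 5",
            "kidney failure",
        ]
    )
    rrt_entity_labels: list[str] = Field(
        default_factory=lambda: ["hemodialysis", "peritoneal dialysis"]
    )
    chronic_rrt_entity_labels: list[str] = Field(
        default_factory=lambda: ["chronic hemodialysis", "chronic peritoneal dialysis"]
    )

    @model_validator(mode="after")
    def _check_gaps(self) -> "CohortCriteriaConfig":
        if not (0 < self.min_gap_days < self.max_gap_days):
            raise ConfigurationError("require 0 < min_gap_days < max_gap_days")
        if self.egfr_threshold <= 0:
            raise ConfigurationError("egfr_threshold must be positive")
        return self


class EgfrConfig(BaseModel):
    """Equation selection: default equation plus per-country overrides."""

    default_equation: str = "CKD_EPI_NO_RACE"
    equation_by_country: dict[str, str] = Field(default_factory=lambda: {"JP": "MATSUO"})
    age_min: float = 18.0
    age_max: float = 120.0


class LabConfig(BaseModel):
    """Laboratory harmonization knobs (unit inference thresholds)."""

    inference_min_batch: int = 50
    inference_coverage_threshold: float = 0.95
    inference_margin: float = 0.10
    keep_unmapped: bool = False  # route UNMAPPED coded events to observation table?


class RunConfig(BaseModel):
    """Top-level run configuration (the YAML document)."""

    storage_root: str
    user: str = "cdm_etl"
    clock: str = "2022-01-01T00:00:00Z"  # fixed audit timestamp, ISO 8601 UTC
    sources: list[SourceConfig] = Field(default_factory=list)
    code_lists_path: str = Field(default_factory=lambda: _packaged("code_lists.csv"))
    analytes_path: str = Field(default_factory=lambda: _packaged("analytes.csv"))
    acceptable_units_path: str = Field(
        default_factory=lambda: _packaged("acceptable_units.csv")
    )
    egfr_coefficients_path: str = Field(
        default_factory=lambda: _packaged("egfr_coefficients.csv")
    )
    criteria: CohortCriteriaConfig = Field(default_factory=CohortCriteriaConfig)
    egfr: EgfrConfig = Field(default_factory=EgfrConfig)
    lab: LabConfig = Field(default_factory=LabConfig)
    extra_tables: dict[str, list[str]] = Field(default_factory=dict)
    study_window_start: dt.date = dt.date(1990, 1, 1)
    study_window_end: dt.date = dt.date(2030, 12, 31)

    @field_validator("user")
    @classmethod
    def _nonempty_user(cls, v: str) -> str:
        if not v.strip():
            raise ConfigurationError("audit user must be non-empty")
        return v

    def source(self, name: str) -> SourceConfig:
        for s in self.sources:
            if s.name == name:
                return s
        raise ConfigurationError(f"unknown data source: {name!r}")

    def digest(self) -> str:
        """Stable digest of the configuration, recorded in run reports."""
        blob = self.model_dump_json().encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration from disk."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    return RunConfig(**doc)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)
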