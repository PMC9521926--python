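"""Laboratory unit harmonization, plausibility filtering and unit inference.

Harmonization is a two-step process per record:

1. *Acceptable-unit mapping* — the raw unit string is resolved, case- and
   synonym-insensitively, to one of the analyte's acceptable units (any unit
   valid for the measure and convertible to the standard unit). Missing or
   unrecognized strings resolve to UNKNOWN.
2. *Standard-unit conversion* — ``std_value = raw_value * factor + offset``
   using the analyte's reference conversion factors, then a plausibility
   filter against the analyte's clinically credible range in standard units
   (inclusive on both ends).

For source batches carrying an unknown unit, the frequency distribution of
the values themselves is used to assign the closest logical unit: each
candidate acceptable unit's plausible window is mapped back to the raw scale
and scored by the fraction of batch values it covers; the winner must reach a
coverage threshold and beat the runner-up by a margin, otherwise no unit is
assigned. The canonical example: hemoglobin values ranging 3-22 with no unit
infer g/dL; the same shape at 30-220 infers g/L.

Every record keeps its raw value and unit alongside the standardized pair,
and every exclusion (implausible value, unverifiable unit, invalid number)
lands in the exclusion ledger with a reason — nothing is silently dropped:
standardized + excluded = input, exactly, per analyte and per source.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import ConfigurationError, LabConfig

UNKNOWN = "UNKNOWN"

# dispositions
STANDARDIZED = "standardized"
STANDARDIZED_INFERRED = "standardized_inferred_unit"
EXCLUDED_RANGE = "excluded_out_of_range"
EXCLUDED_UNIT = "excluded_unverifiable_unit"
EXCLUDED_INVALID = "excluded_invalid_value"


@dataclass(frozen=True)
class AcceptableUnit:
    unit: str
    factor: float  # raw * factor + offset = standard
    offset: float = 0.0
    synonyms: tuple[str, ...] = ()


@dataclass
class AnalyteSpec:
    """Reference specification for one analyte.

    ``plausible_low``/``plausible_high`` are the clinically credible bounds in
    the standard unit; values outside are excluded.
    """

    analyte: str
    standard_unit: str
    plausible_low: float
    plausible_high: float
    acceptable_units: list[AcceptableUnit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.plausible_low < self.plausible_high:
            raise ConfigurationError(
                f"{self.analyte}: plausible_low must be < plausible_high"
            )
        for au in self.acceptable_units:
            if au.factor <= 0:
                raise ConfigurationError(
                    f"{self.analyte}/{au.unit}: conversion factor must be positive"
                )
        std = self.find_unit(self.standard_unit)
        if std is None or std.factor != 1.0 or std.offset != 0.0:
            raise ConfigurationError(
                f"{self.analyte}: standard unit {self.standard_unit!r} must be "
                "acceptable with factor 1 and offset 0"
            )

    def find_unit(self, raw_unit: str) -> Optional[AcceptableUnit]:
        needle = str(raw_unit).strip().lower()
        if not needle:
            return None
        for au in self.acceptable_units:
            if needle == au.unit.lower():
                return au
            if any(needle == s.strip().lower() for s in au.synonyms):
                return au
        return None


class AnalyteRegistry:
    """All analyte specs, loaded from the two reference CSVs."""

    def __init__(self, specs: dict[str, AnalyteSpec]):
        self._specs = specs

    def __contains__(self, analyte: str) -> bool:
        return analyte in self._specs

    def __iter__(self):
        return iter(self._specs.values())

    def spec(self, analyte: str) -> AnalyteSpec:
        try:
            return self._specs[analyte]
        except KeyError:
            raise ConfigurationError(f"unknown analyte: {analyte!r}") from None

    @property
    def analytes(self) -> list[str]:
        return list(self._specs)


def load_analyte_specs(
    analytes_path: str | Path, units_path: str | Path
) -> AnalyteRegistry:
    """Load analyte plausibility ranges and acceptable-unit conversion tables."""
    ranges = pd.read_csv(analytes_path)
    units = pd.read_csv(units_path).fillna({"synonyms": "", "offset": 0.0})
    specs: dict[str, AnalyteSpec] = {}
    for row in ranges.itertuples(index=False):
        sub = units[units["analyte"] == row.analyte]
        acceptable = [
            AcceptableUnit(
                unit=u.unit,
                factor=float(u.factor),
                offset=float(u.offset),
                synonyms=tuple(s for s in str(u.synonyms).split("|") if s),
            )
            for u in sub.itertuples(index=False)
        ]
        specs[row.analyte] = AnalyteSpec(
            analyte=row.analyte,
            standard_unit=row.standard_unit,
            plausible_low=float(row.plausible_low),
            plausible_high=float(row.plausible_high),
            acceptable_units=acceptable,
        )
    return AnalyteRegistry(specs)


def map_to_acceptable_unit(
    raw_unit: str, analyte: str, registry: AnalyteRegistry
) -> str:
    """Resolve a raw unit string to the analyte's canonical acceptable unit.

    Returns UNKNOWN for missing or unrecognized strings.
    """
    au = registry.spec(analyte).find_unit(raw_unit)
    return au.unit if au is not None else UNKNOWN


def convert_to_standard(
    raw_value: float, unit: str, analyte: str, registry: AnalyteRegistry
) -> tuple[float, str]:
    """Convert a value in an acceptable unit to the analyte's standard unit."""
    spec = registry.spec(analyte)
    au = spec.find_unit(unit)
    if au is None:
        raise ConfigurationError(f"{unit!r} is not an acceptable unit for {analyte}")
    return raw_value * au.factor + au.offset, spec.standard_unit


def to_acceptable(
    std_value: float, unit: str, analyte: str, registry: AnalyteRegistry
) -> float:
    """Inverse conversion: standard unit back to an acceptable unit."""
    au = registry.spec(analyte).find_unit(unit)
    if au is None:
        raise ConfigurationError(f"{unit!r} is not an acceptable unit for {analyte}")
    return (std_value - au.offset) / au.factor


def infer_unit(
    values,
    analyte: str,
    registry: AnalyteRegistry,
    config: LabConfig | None = None,
) -> Optional[str]:
    """Infer the unit of a batch of same-analyte values via range coverage.

    Each candidate acceptable unit's plausible window is translated to the raw
    scale; candidates are scored by the fraction of batch values inside their
    window. The best candidate wins only if its coverage is at least the
    threshold AND it beats the runner-up by the configured margin; otherwise
    returns None (no unit can be verified).
    """
    config = config or LabConfig()
    vals = np.asarray(list(values), dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) < config.inference_min_batch:
        return None
    spec = registry.spec(analyte)
    scores: list[tuple[float, str]] = []
    for au in spec.acceptable_units:
        lo = (spec.plausible_low - au.offset) / au.factor
        hi = (spec.plausible_high - au.offset) / au.factor
        lo, hi = min(lo, hi), max(lo, hi)
        coverage = float(np.mean((vals >= lo) & (vals <= hi)))
        scores.append((coverage, au.unit))
    scores.sort(key=lambda t: (-t[0], t[1]))
    best_cov, best_unit = scores[0]
    runner_cov = scores[1][0] if len(scores) > 1 else 0.0
    if best_cov >= config.inference_coverage_threshold and (
        best_cov - runner_cov
    ) >= config.inference_margin:
        return best_unit
    return None


def harmonize_lab_stream(
    records: pd.DataFrame,
    registry: AnalyteRegistry,
    config: LabConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full harmonization pipeline over a laboratory record stream.

    ``records`` needs columns: patient_id, analyte, raw_value, raw_unit,
    data_source_name, record_id (other columns pass through untouched).

    Returns ``(lab_table, ledger)``. The lab table holds every input record
    with raw value/unit preserved, standardized value/unit where applicable,
    and a disposition; the ledger holds one row per excluded record with its
    reason. Unknown units are inferred in batches per
    (analyte, data_source_name, raw_unit string) so a source-wide unit gap is
    decided once from its value distribution, not per record.
    """
    config = config or LabConfig()
    out = records.copy().reset_index(drop=True)
    n = len(out)
    std_value = np.full(n, np.nan)
    std_unit = np.full(n, None, dtype=object)
    disposition = np.full(n, None, dtype=object)
    resolved_unit = np.full(n, None, dtype=object)

    raw_units = out["raw_unit"].fillna("") if "raw_unit" in out else pd.Series([""] * n)
    analytes = out["analyte"].astype(str)
    raw_values = pd.to_numeric(out["raw_value"], errors="coerce")

    # step 1: acceptable-unit mapping per record
    for i in range(n):
        resolved_unit[i] = map_to_acceptable_unit(
            str(raw_units.iloc[i]), analytes.iloc[i], registry
        )

    # step 2: batched unit inference for UNKNOWN units
    unknown_mask = resolved_unit == UNKNOWN
    if unknown_mask.any():
        groups = out[unknown_mask].groupby(
            [analytes[unknown_mask], out.loc[unknown_mask, "data_source_name"],
             raw_units[unknown_mask].astype(str)]
        )
        for (analyte, _source, _ustr), sub in groups:
            inferred = infer_unit(
                raw_values[sub.index], analyte, registry, config
            )
            if inferred is not None:
                for i in sub.index:
                    resolved_unit[i] = inferred
                    disposition[i] = STANDARDIZED_INFERRED

    # step 3: conversion + plausibility filter
    for i in range(n):
        analyte = analytes.iloc[i]
        spec = registry.spec(analyte)
        value = raw_values.iloc[i]
        if not math.isfinite(value):
            disposition[i] = EXCLUDED_INVALID
            continue
        unit = resolved_unit[i]
        if unit == UNKNOWN:
            disposition[i] = EXCLUDED_UNIT
            continue
        sv, su = convert_to_standard(float(value), unit, analyte, registry)
        if spec.plausible_low <= sv <= spec.plausible_high:
            std_value[i] = sv
            std_unit[i] = su
            if disposition[i] is None:
                disposition[i] = STANDARDIZED
        else:
            disposition[i] = EXCLUDED_RANGE

    out["std_value"] = std_value
    out["std_unit"] = std_unit
    out["disposition"] = disposition
    # inferred-unit records that then failed plausibility are exclusions
    excluded = out["disposition"].isin([EXCLUDED_RANGE, EXCLUDED_UNIT, EXCLUDED_INVALID])
    out.loc[excluded, ["std_value", "std_unit"]] = [np.nan, None]

    ledger_cols = ["data_source_name", "record_id", "patient_id", "analyte",
                   "raw_value", "raw_unit"]
    ledger = out.loc[excluded, [c for c in ledger_cols if c in out.columns]].copy()
    ledger["reason"] = out.loc[excluded, "disposition"].values
    return out, ledger.reset_index(drop=True)
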