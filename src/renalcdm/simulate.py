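"""Synthetic multi-source EHR bundles with complete ground truth.

The generator emits the raw-data heterogeneity the harmonization engine
exists to resolve: four sources across three countries with distinct coding
vocabularies (US ICD-10 claims, UK Read-code EHR, Japanese ICD-10 registry
that must use the Matsuo equation, and a non-poolable US ICD-9 panel),
source-specific column names and date formats, different creatinine and
hemoglobin unit conventions, a source with a large block of unit-less
hemoglobin values (recoverable by frequency-distribution inference), and
injected implausible values and unverifiable unit strings.

Patients are constructed to satisfy or violate each cohort criterion *by
design*: creatinine values are obtained by exactly inverting the eGFR
equation the pipeline will apply to that source, at chosen target eGFR
levels, so eGFR-criterion truth is exact by construction rather than
sampled. Every source additionally plants boundary patients at the criterion
edges — eGFR-pair gaps of 90/91/730/731 days, eGFR values at 74.9/75.0,
RRT spans of 30/31 days, and measurement dates straddling 2008-01-01 — so
off-by-one regressions in any comparison are caught.

Everything is deterministic under the seed; the bundle ships a manifest with
the seed and a config digest, and ``ground_truth_check`` compares a finished
pipeline run against the recorded truth.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import egfr as egfr_mod
from .config import ConfigurationError, RunConfig, SourceConfig
from .labs import AnalyteRegistry, convert_to_standard, load_analyte_specs, to_acceptable


class SourceGenSpec(BaseModel):
    """Generation profile of one synthetic source."""

    name: str
    country: str
    coding_system: str  # ICD10 | ICD9 | READ
    n_patients: int
    poolable: bool = True
    creatinine_unit: str = "mg/dL"
    hemoglobin_unit: str = "g/dL"
    date_format: str = "ISO"  # ISO | DMY
    fraction_unknown_units: float = 0.0  # applied to hemoglobin rows
    fraction_invalid_values: float = 0.005
    fraction_unverifiable_units: float = 0.002


class CohortMix(BaseModel):
    """Target fractions of patients assigned to each qualification path."""

    dx: float = 0.15
    egfr: float = 0.20
    rrt: float = 0.10
    all_three: float = 0.02

    def check(self) -> None:
        total = self.dx + self.egfr + self.rrt + self.all_three
        if not (0 <= total <= 1):
            raise ConfigurationError(f"cohort mixture sums to {total}, must be <= 1")


class GeneratorConfig(BaseModel):
    """Configuration of the synthetic study."""

    seed: int
    sources: list[SourceGenSpec] = Field(default_factory=lambda: default_sources())
    mix: CohortMix = Field(default_factory=CohortMix)
    female_fraction: float = 0.55
    prevalence_t2dm: float = 0.30
    prevalence_hypertension: float = 0.50
    prevalence_heart_failure: float = 0.15
    plant_boundary_patients: bool = True


def default_sources(total_patients: int = 5000) -> list[SourceGenSpec]:
    """The default 4-source mix (3 countries, one non-poolable source)."""
    n1 = int(round(total_patients * 0.3))
    n2 = int(round(total_patients * 0.3))
    n3 = int(round(total_patients * 0.2))
    n4 = total_patients - n1 - n2 - n3
    return [
        SourceGenSpec(
            name="us_claims", country="US", coding_system="ICD10", n_patients=n1,
            creatinine_unit="mg/dL", hemoglobin_unit="g/dL",
        ),
        SourceGenSpec(
            name="uk_ehr", country="GB", coding_system="READ", n_patients=n2,
            creatinine_unit="umol/L", hemoglobin_unit="g/L", date_format="DMY",
            fraction_unknown_units=0.30,
        ),
        SourceGenSpec(
            name="jp_registry", country="JP", coding_system="ICD10", n_patients=n3,
            creatinine_unit="mg/dL", hemoglobin_unit="g/dL",
        ),
        SourceGenSpec(
            name="lc_panel", country="US", coding_system="ICD9", n_patients=n4,
            poolable=False, creatinine_unit="mg/L", hemoglobin_unit="g/dL",
        ),
    ]


# -- per-vocabulary code choices ---------------------------------------------
_CKD_DX = {
    "ICD10": {"ckd stage 3a": "N18.31", "ckd stage 3b": "N18.32",
              "ckd stage 4": "N18.4", "ckd stage 5": "N18.5",
              "kidney failure": "N18.6", "ckd stage 2": "N18.2"},
    "ICD9": {"ckd stage 3a": "585.3", "ckd stage 4": "585.4",
             "ckd stage 5": "585.5", "kidney failure": "585.6",
             "ckd stage 2": "585.2"},
    "READ": {"ckd stage 3a": "1Z12.", "ckd stage 3b": "1Z13.",
             "ckd stage 4": "1Z14.", "ckd stage 5": "1Z15.",
             "kidney failure": "1Z16.", "ckd stage 2": "1Z11."},
}
_COMORBID = {
    "ICD10": {"type 2 diabetes": "E11.34", "hypertension": "I10",
              "heart failure": "I50.9"},
    "ICD9": {"type 2 diabetes": "250.00", "hypertension": "401.9",
             "heart failure": "428.0"},
    "READ": {"type 2 diabetes": "C100112", "hypertension": "G20..",
             "heart failure": "G58.."},
}
_RRT_PROC = {  # (coding_system, hemodialysis code) per source
    "us_claims": ("CPT", "90935"),
    "uk_ehr": ("OPCS4", "X40.1"),
    "jp_registry": ("LOCAL:jp_registry", "HD001"),
    "lc_panel": ("ICD9", "39.95"),
}
_LAB_CODES = {
    "us_claims": {"creatinine": "LAB-CR", "hemoglobin": "LAB-HB", "bmi": "LAB-BMI"},
    "uk_ehr": {"creatinine": "44J3.", "hemoglobin": "423..", "bmi": "22K.."},
    "jp_registry": {"creatinine": "L-CRE", "hemoglobin": "L-HGB", "bmi": "L-BMI"},
    "lc_panel": {"creatinine": "CRE", "hemoglobin": "HGB", "bmi": "BMI"},
}
_RX_CODES = {
    "us_claims": ["RX-ACE1", "RX-SGLT2"],
    "uk_ehr": ["d00231", "d00754"],
    "jp_registry": ["YJ-ACE", "YJ-SGLT"],
    "lc_panel": ["P-ACE", "P-SGLT"],
}

_JUNK_UNITS = ["furlongs", "U/arb", "??", "titer"]


def _fmt_date(date: dt.date, fmt: str) -> str:
    if fmt == "DMY":
        return date.strftime("%d/%m/%Y")
    return date.isoformat()


def _creatinine_for_target(
    target_egfr: float,
    age: int,
    sex: str,
    equation: str,
    unit: str,
    registry: AnalyteRegistry,
    want_below: bool,
    threshold: float = 75.0,
) -> tuple[float, float]:
    """Raw creatinine (in the source's unit) whose round-tripped eGFR lands
    on the intended side of the threshold.

    Inversion is exact up to float rounding; for targets at the threshold the
    value is nudged by ulp-scale steps until the full pipeline arithmetic
    (unit conversion then eGFR) reproduces the intended side. Returns
    ``(raw_value, realized_egfr)``.
    """
    scr = egfr_mod.invert_egfr(equation, target_egfr, age, sex)
    for attempt in range(200):
        raw = to_acceptable(scr, unit, "creatinine", registry)
        std, _ = convert_to_standard(raw, unit, "creatinine", registry)
        realized = egfr_mod.compute_egfr(equation, std, age, sex)
        if (realized < threshold) == want_below:
            return raw, realized
        step = 1e-12 * (attempt + 1)
        scr *= (1 + step) if want_below else (1 - step)
    raise RuntimeError("could not pin creatinine on the intended eGFR side")


class _SourceBuilder:
    """Accumulates one source's raw rows, mapping rules and truth."""

    def __init__(self, spec: SourceGenSpec, cfg: GeneratorConfig,
                 registry: AnalyteRegistry, rng: np.random.Generator):
        self.spec = spec
        self.cfg = cfg
        self.registry = registry
        self.rng = rng
        self.equation = "MATSUO" if spec.country == "JP" else "CKD_EPI_NO_RACE"
        self.patients: list[dict] = []
        self.diagnoses: list[dict] = []
        self.procedures: list[dict] = []
        self.prescriptions: list[dict] = []
        self.labs: list[dict] = []
        self.encounters: list[dict] = []
        self.truth_patients: list[dict] = []
        self.truth_labs: list[dict] = []
        self._rid = {t: 0 for t in
                     ("diagnoses", "procedures", "prescriptions", "labs", "encounters")}
        self._unknown_unit_rids: list[str] = []

    def _record_id(self, table: str) -> str:
        self._rid[table] += 1
        return f"{self.spec.name}-{table[:3].upper()}-{self._rid[table]:06d}"

    def _date(self, year_lo: int = 2009, year_hi: int = 2018) -> dt.date:
        start = dt.date(year_lo, 1, 1).toordinal()
        end = dt.date(year_hi, 12, 31).toordinal()
        return dt.date.fromordinal(int(self.rng.integers(start, end + 1)))

    # -- event emitters ------------------------------------------------------
    def add_diagnosis(self, pid: str, label: str, date: dt.date) -> None:
        code = (_CKD_DX[self.spec.coding_system].get(label)
                or _COMORBID[self.spec.coding_system][label])
        self.diagnoses.append({
            "pid": pid, "code": code, "date": _fmt_date(date, self.spec.date_format),
            "rid": self._record_id("diagnoses"),
        })

    def add_rrt(self, pid: str, start: dt.date, offsets: list[int],
                code_override: Optional[str] = None) -> None:
        _system, code = _RRT_PROC[self.spec.name]
        for off in offsets:
            self.procedures.append({
                "pid": pid, "code": code_override or code,
                "date": _fmt_date(start + dt.timedelta(days=off),
                                  self.spec.date_format),
                "rid": self._record_id("procedures"),
            })

    def add_lab(self, pid: str, analyte: str, raw_value: float, unit: str,
                date: dt.date, expected_disposition: str,
                true_unit: Optional[str] = None) -> str:
        rid = self._record_id("labs")
        self.labs.append({
            "pid": pid, "code": _LAB_CODES[self.spec.name][analyte],
            "value": raw_value, "unit": unit,
            "date": _fmt_date(date, self.spec.date_format), "rid": rid,
        })
        self.truth_labs.append({
            "data_source_name": self.spec.name, "record_id": rid,
            "analyte": analyte, "true_unit": true_unit if true_unit else unit,
            "expected_disposition": expected_disposition,
        })
        return rid

    def add_creatinine_at_egfr(self, pid: str, birth_year: int, sex: str,
                               target: float, date: dt.date, want_below: bool
                               ) -> float:
        age = date.year - birth_year
        raw, realized = _creatinine_for_target(
            target, age, sex, self.equation, self.spec.creatinine_unit,
            self.registry, want_below,
        )
        self.add_lab(pid, "creatinine", raw, self.spec.creatinine_unit, date,
                     "standardized")
        return realized

    def add_baseline_labs(self, pid: str, bmi: float, hgb_gdl: float,
                          hgb_unknown: bool) -> None:
        date = dt.date(2008, 2, 1) + dt.timedelta(days=int(self.rng.integers(0, 28)))
        raw_hgb = to_acceptable(hgb_gdl, self.spec.hemoglobin_unit, "hemoglobin",
                                self.registry)
        if hgb_unknown:
            rid = self.add_lab(pid, "hemoglobin", round(raw_hgb, 1), "", date,
                               "standardized_inferred_unit",
                               true_unit=self.spec.hemoglobin_unit)
            self._unknown_unit_rids.append(rid)
        else:
            self.add_lab(pid, "hemoglobin", round(raw_hgb, 1),
                         self.spec.hemoglobin_unit, date, "standardized")
        self.add_lab(pid, "bmi", round(bmi, 1), "kg/m2", date, "standardized")

    # -- patient construction ------------------------------------------------
    def build_patient(self, idx: int, criteria: set[str],
                      boundary: Optional[str] = None) -> None:
        rng = self.rng
        spec = self.spec
        pid = f"{spec.name}-P{idx:05d}"
        sex = "female" if rng.random() < self.cfg.female_fraction else "male"
        birth_year = int(rng.integers(1935, 1981))
        truth = {
            "patient_id": pid, "data_source_name": spec.name, "sex": sex,
            "birth_year": birth_year, "country": spec.country,
            "boundary_case": boundary or "",
            "dx_date": "", "egfr_date": "", "rrt_date": "",
            "has_t2dm": 0, "has_htn": 0, "has_hf": 0, "bmi": "",
        }
        self.patients.append({
            "pid": pid, "birth_year": birth_year,
            "sex": {"female": "F", "male": "M"}[sex]
            if spec.coding_system != "READ" else sex,
            "country": spec.country,
        })

        # comorbidities, dated before any possible index date
        for flag, label, prev in (
            ("has_t2dm", "type 2 diabetes", self.cfg.prevalence_t2dm),
            ("has_htn", "hypertension", self.cfg.prevalence_hypertension),
            ("has_hf", "heart failure", self.cfg.prevalence_heart_failure),
        ):
            if rng.random() < prev:
                truth[flag] = 1
                self.add_diagnosis(pid, label, self._date(2005, 2007))

        bmi = float(rng.uniform(18, 40))
        truth["bmi"] = round(bmi, 1)
        hgb = float(rng.uniform(11, 16))
        hgb_unknown = rng.random() < spec.fraction_unknown_units
        self.add_baseline_labs(pid, bmi, hgb, hgb_unknown)

        # one encounter per patient
        enc_date = self._date()
        self.encounters.append({
            "pid": pid, "eid": f"{pid}-E1",
            "date": _fmt_date(enc_date, spec.date_format),
            "setting": "I" if rng.random() < 0.3 else "O",
            "rid": self._record_id("encounters"),
        })
        if rng.random() < 0.5:
            self.prescriptions.append({
                "pid": pid, "code": _RX_CODES[spec.name][int(rng.integers(0, 2))],
                "date": _fmt_date(self._date(), spec.date_format),
                "rid": self._record_id("prescriptions"),
            })

        if boundary is not None:
            self._build_boundary(pid, birth_year, sex, truth, boundary)
        else:
            self._build_regular(pid, birth_year, sex, truth, criteria)

        dates = [dt.date.fromisoformat(truth[k])
                 for k in ("dx_date", "egfr_date", "rrt_date") if truth[k]]
        crits = [c for c, k in (("DX_CODE", "dx_date"), ("EGFR_PAIR", "egfr_date"),
                                ("CHRONIC_RRT", "rrt_date")) if truth[k]]
        truth["criteria"] = "|".join(crits)
        truth["in_cohort"] = int(bool(crits))
        truth["index_date"] = min(dates).isoformat() if dates else ""
        self.truth_patients.append(truth)

    def _egfr_pair(self, pid: str, birth_year: int, sex: str, truth: dict,
                   first: dt.date, gap: int, targets: tuple[float, float],
                   below: tuple[bool, bool], qualifies: bool) -> None:
        second = first + dt.timedelta(days=gap)
        self.add_creatinine_at_egfr(pid, birth_year, sex, targets[0], first, below[0])
        self.add_creatinine_at_egfr(pid, birth_year, sex, targets[1], second, below[1])
        if qualifies:
            truth["egfr_date"] = second.isoformat()

    def _build_regular(self, pid: str, birth_year: int, sex: str, truth: dict,
                       criteria: set[str]) -> None:
        rng = self.rng
        if "DX_CODE" in criteria:
            label = str(rng.choice(
                [l for l in _CKD_DX[self.spec.coding_system] if l != "ckd stage 2"]))
            date = self._date()
            self.add_diagnosis(pid, label, date)
            truth["dx_date"] = date.isoformat()
        if "EGFR_PAIR" in criteria:
            first = self._date(2009, 2016)
            gap = int(rng.integers(92, 730))
            targets = (float(rng.uniform(20, 70)), float(rng.uniform(20, 70)))
            self._egfr_pair(pid, birth_year, sex, truth, first, gap, targets,
                            (True, True), qualifies=True)
        if "CHRONIC_RRT" in criteria:
            start = self._date()
            self.add_rrt(pid, start, [0, 7, 14, 21, 28, 35, 42])
            truth["rrt_date"] = start.isoformat()
        if not criteria:
            # controls: normal kidney function, or a deliberately failing pair
            u = rng.random()
            if u < 0.2:  # sub-threshold pair too close together (gap <= 90)
                self._egfr_pair(pid, birth_year, sex, truth, self._date(2009, 2016),
                                int(rng.integers(10, 90)),
                                (float(rng.uniform(40, 70)),) * 2,
                                (True, True), qualifies=False)
            elif u < 0.3:  # sub-threshold pair entirely before the window
                self._egfr_pair(pid, birth_year, sex, truth,
                                self._date(2005, 2006), int(rng.integers(100, 400)),
                                (float(rng.uniform(40, 70)),) * 2,
                                (True, True), qualifies=False)
            else:  # normal function
                date = self._date()
                self.add_creatinine_at_egfr(pid, birth_year, sex,
                                            float(rng.uniform(85, 110)), date,
                                            want_below=False)
            if rng.random() < 0.1:  # stage-2 diagnosis never qualifies
                self.add_diagnosis(pid, "ckd stage 2", self._date())
            if rng.random() < 0.05:  # a single dialysis event (duration 0)
                self.add_rrt(pid, self._date(), [0])

    def _build_boundary(self, pid: str, birth_year: int, sex: str, truth: dict,
                        kind: str) -> None:
        """Plant one patient exactly on a criterion edge."""
        first = dt.date(2010, 3, 1)
        lo = (40.0, 40.0)
        if kind == "gap_90":  # not > 90 days apart: fails
            self._egfr_pair(pid, birth_year, sex, truth, first, 90, lo,
                            (True, True), qualifies=False)
        elif kind == "gap_91":
            self._egfr_pair(pid, birth_year, sex, truth, first, 91, lo,
                            (True, True), qualifies=True)
        elif kind == "gap_730":
            self._egfr_pair(pid, birth_year, sex, truth, first, 730, lo,
                            (True, True), qualifies=True)
        elif kind == "gap_731":  # beyond the 730-day maximum: fails
            self._egfr_pair(pid, birth_year, sex, truth, first, 731, lo,
                            (True, True), qualifies=False)
        elif kind == "egfr_74_9":
            self._egfr_pair(pid, birth_year, sex, truth, first, 180, (74.9, 74.9),
                            (True, True), qualifies=True)
        elif kind == "egfr_75_0":  # not < 75: fails
            self._egfr_pair(pid, birth_year, sex, truth, first, 180, (75.0, 75.0),
                            (False, False), qualifies=False)
        elif kind == "rrt_30":  # span exactly 30 days: not > 30, fails
            self.add_rrt(pid, first, [0, 15, 30])
        elif kind == "rrt_31":
            self.add_rrt(pid, first, [0, 15, 31])
            truth["rrt_date"] = first.isoformat()
        elif kind == "window_2007_12_31":  # first measure one day pre-window
            self._egfr_pair(pid, birth_year, sex, truth, dt.date(2007, 12, 31),
                            182, lo, (True, True), qualifies=False)
        elif kind == "window_2008_01_01":
            self._egfr_pair(pid, birth_year, sex, truth, dt.date(2008, 1, 1),
                            182, lo, (True, True), qualifies=True)
        elif kind == "chronic_code":  # single explicitly-chronic RRT event
            self.add_rrt(pid, first, [0], code_override="CHD01")
            truth["rrt_date"] = first.isoformat()
        else:  # pragma: no cover
            raise ConfigurationError(f"unknown boundary kind {kind!r}")

    # -- injections ----------------------------------------------------------
    def inject_bad_labs(self) -> None:
        """Append implausible-value and junk-unit rows, recorded in truth."""
        rng = self.rng
        spec = self.spec
        n_labs = len(self.labs)
        pids = [p["pid"] for p in self.patients]
        n_invalid = int(round(spec.fraction_invalid_values * n_labs))
        for _ in range(n_invalid):
            pid = pids[int(rng.integers(0, len(pids)))]
            analyte = "creatinine" if rng.random() < 0.5 else "hemoglobin"
            unit = (spec.creatinine_unit if analyte == "creatinine"
                    else spec.hemoglobin_unit)
            std_target = float(rng.uniform(100, 1000))  # far above plausible_high
            raw = to_acceptable(std_target, unit, analyte, self.registry)
            self.add_lab(pid, analyte, round(raw, 2), unit, self._date(),
                         "excluded_out_of_range")
        n_junk = int(round(spec.fraction_unverifiable_units * n_labs))
        for k in range(n_junk):
            pid = pids[int(rng.integers(0, len(pids)))]
            self.add_lab(pid, "hemoglobin", float(rng.uniform(1, 100)),
                         _JUNK_UNITS[k % len(_JUNK_UNITS)], self._date(),
                         "excluded_unverifiable_unit")
        # unit inference needs the configured minimum batch; a source whose
        # unit-less block stays below it yields unverifiable units instead
        from .config import LabConfig

        if 0 < len(self._unknown_unit_rids) < LabConfig().inference_min_batch:
            small = set(self._unknown_unit_rids)
            for row in self.truth_labs:
                if row["record_id"] in small:
                    row["expected_disposition"] = "excluded_unverifiable_unit"

    # -- serialization -------------------------------------------------------
    def column_dialect(self) -> dict[str, dict[str, str]]:
        """Source-specific raw column names: logical name -> dialect name."""
        if self.spec.name == "uk_ehr":
            return {
                "patients": {"pid": "patid", "birth_year": "birthyr", "sex": "sex",
                             "country": "country"},
                "events": {"pid": "patid", "code": "medcode", "date": "eventdate",
                           "rid": "rowid", "value": "result", "unit": "resunit",
                           "eid": "consid", "setting": "constype"},
            }
        if self.spec.name == "us_claims":
            return {
                "patients": {"pid": "member_id", "birth_year": "yob",
                             "sex": "gender", "country": "country"},
                "events": {"pid": "member_id", "code": "svc_code",
                           "date": "svc_date", "rid": "claim_id",
                           "value": "result_value", "unit": "result_unit",
                           "eid": "enc_id", "setting": "setting"},
            }
        return {
            "patients": {"pid": "patient_id", "birth_year": "birth_year",
                         "sex": "sex", "country": "country"},
            "events": {"pid": "patient_id", "code": "code", "date": "event_date",
                       "rid": "record_id", "value": "value", "unit": "unit",
                       "eid": "encounter_id", "setting": "setting"},
        }

    def write(self, out_dir: Path) -> dict[str, int]:
        out_dir.mkdir(parents=True, exist_ok=True)
        dialect = self.column_dialect()
        pcols, ecols = dialect["patients"], dialect["events"]
        counts = {}

        def dump(rows: list[dict], fname: str, order: list[str],
                 rename: dict[str, str]) -> None:
            frame = pd.DataFrame(rows, columns=order).rename(columns=rename)
            frame.to_csv(out_dir / fname, index=False)
            counts[fname.removesuffix(".csv")] = len(frame)

        dump(self.patients, "patients.csv",
             ["pid", "birth_year", "sex", "country"], pcols)
        dump(self.diagnoses, "diagnoses.csv", ["pid", "code", "date", "rid"], ecols)
        dump(self.procedures, "procedures.csv", ["pid", "code", "date", "rid"], ecols)
        dump(self.prescriptions, "prescriptions.csv",
             ["pid", "code", "date", "rid"], ecols)
        dump(self.labs, "labs.csv",
             ["pid", "code", "value", "unit", "date", "rid"], ecols)
        dump(self.encounters, "encounters.csv",
             ["pid", "eid", "date", "setting", "rid"], ecols)
        self._write_mapping(out_dir, dialect)
        return counts

    def _write_mapping(self, out_dir: Path, dialect: dict) -> None:
        """Column-level ETL mapping document for this source."""
        pcols, ecols = dialect["patients"], dialect["events"]
        name = self.spec.name
        date_tf = f"date_parse:{self.spec.date_format}"
        system = self.spec.coding_system
        rules: list[tuple[str, str, str, str, str]] = []

        rules += [
            ("patients", pcols["pid"], "demographics", "patient_id", "copy"),
            ("patients", pcols["birth_year"], "demographics", "birth_year", "to_int"),
            ("patients", pcols["sex"], "demographics", "sex", "sex_normalize"),
            ("patients", pcols["country"], "demographics", "country", "copy"),
        ]
        for src_table, target, sys_const in (
            ("diagnoses", "diagnosis", system),
            ("procedures", "procedure", _RRT_PROC[name][0]),
            ("prescriptions", "prescription", f"LOCAL:{name}"),
        ):
            rules += [
                (src_table, ecols["pid"], target, "patient_id", "copy"),
                (src_table, ecols["code"], target, "raw_code", "copy"),
                (src_table, "", target, "coding_system", f"constant:{sys_const}"),
                (src_table, ecols["date"], target, "event_date", date_tf),
                (src_table, ecols["rid"], target, "record_id", "copy"),
            ]
        rules += [
            ("labs", ecols["pid"], "laboratory", "patient_id", "copy"),
            ("labs", ecols["code"], "laboratory", "analyte_code", "copy"),
            ("labs", "", "laboratory", "coding_system", f"constant:LOCAL:{name}"),
            ("labs", ecols["value"], "laboratory", "raw_value", "to_number"),
            ("labs", ecols["unit"], "laboratory", "raw_unit", "copy"),
            ("labs", ecols["date"], "laboratory", "event_date", date_tf),
            ("labs", ecols["rid"], "laboratory", "record_id", "copy"),
            ("encounters", ecols["pid"], "encounter", "patient_id", "copy"),
            ("encounters", ecols["eid"], "encounter", "encounter_id", "copy"),
            ("encounters", ecols["setting"], "encounter", "descriptor",
             "setting_normalize"),
            ("encounters", ecols["date"], "encounter", "event_date", date_tf),
            ("encounters", ecols["rid"], "encounter", "record_id", "copy"),
        ]
        frame = pd.DataFrame(
            rules, columns=["source_table", "source_column", "target_table",
                            "target_column", "transform_id"],
        )
        frame.insert(0, "data_source_name", name)
        frame.to_csv(out_dir / "mapping.csv", index=False)


_BOUNDARY_KINDS = [
    "gap_90", "gap_91", "gap_730", "gap_731", "egfr_74_9", "egfr_75_0",
    "rrt_30", "rrt_31", "window_2007_12_31", "window_2008_01_01",
]


def generate(config: GeneratorConfig, out_dir: str | Path) -> dict:
    """Emit raw source bundles + ground truth under ``out_dir``.

    Layout: ``<out_dir>/<source>/{patients,diagnoses,...,mapping}.csv`` and
    ``<out_dir>/truth/{patients.csv,labs.csv,counts.csv,manifest.json}``.
    Deterministic under ``config.seed``. Returns the manifest dict.
    """
    config.mix.check()
    out_dir = Path(out_dir)
    registry = load_analyte_specs(
        *(str(p) for p in _default_reference_paths())
    )
    root_rng = np.random.default_rng(config.seed)
    seeds = root_rng.integers(0, 2**31 - 1, size=len(config.sources))
    truth_patients, truth_labs, count_rows = [], [], []
    for spec, seed in zip(config.sources, seeds):
        builder = _SourceBuilder(spec, config, registry,
                                 np.random.default_rng(int(seed)))
        n = spec.n_patients
        boundary = list(_BOUNDARY_KINDS) if config.plant_boundary_patients else []
        if spec.name == "jp_registry" and config.plant_boundary_patients:
            boundary.append("chronic_code")
        boundary = boundary[:n]
        n_rest = n - len(boundary)
        counts = {
            "DX_CODE": int(round(config.mix.dx * n_rest)),
            "EGFR_PAIR": int(round(config.mix.egfr * n_rest)),
            "CHRONIC_RRT": int(round(config.mix.rrt * n_rest)),
            "ALL": int(round(config.mix.all_three * n_rest)),
        }
        assignments: list[tuple[set[str], Optional[str]]] = [
            (set(), kind) for kind in boundary
        ]
        assignments += [({"DX_CODE"}, None)] * counts["DX_CODE"]
        assignments += [({"EGFR_PAIR"}, None)] * counts["EGFR_PAIR"]
        assignments += [({"CHRONIC_RRT"}, None)] * counts["CHRONIC_RRT"]
        assignments += [({"DX_CODE", "EGFR_PAIR", "CHRONIC_RRT"}, None)] * counts["ALL"]
        assignments += [(set(), None)] * (n - len(assignments))
        for idx, (criteria, kind) in enumerate(assignments):
            builder.build_patient(idx, criteria, boundary=kind)
        builder.inject_bad_labs()
        emitted = builder.write(out_dir / spec.name)
        for table, n_rows in emitted.items():
            count_rows.append({"data_source_name": spec.name, "table": table,
                               "n_rows": n_rows})
        truth_patients.extend(builder.truth_patients)
        truth_labs.extend(builder.truth_labs)

    truth_dir = out_dir / "truth"
    truth_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(truth_patients).to_csv(truth_dir / "patients.csv", index=False)
    pd.DataFrame(truth_labs).to_csv(truth_dir / "labs.csv", index=False)
    pd.DataFrame(count_rows).to_csv(truth_dir / "counts.csv", index=False)
    manifest = {
        "seed": config.seed,
        "n_sources": len(config.sources),
        "n_patients": sum(s.n_patients for s in config.sources),
        "config_digest": _digest(config),
    }
    (truth_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _digest(config: GeneratorConfig) -> str:
    import hashlib

    return hashlib.sha256(config.model_dump_json().encode()).hexdigest()[:16]


def _default_reference_paths() -> tuple[Path, Path]:
    import importlib.resources

    base = importlib.resources.files("renalcdm.data")
    return Path(str(base / "analytes.csv")), Path(str(base / "acceptable_units.csv"))


def make_run_config(
    config: GeneratorConfig, raw_root: str | Path, storage_root: str | Path
) -> RunConfig:
    """RunConfig wired to a generated bundle set."""
    return RunConfig(
        storage_root=str(storage_root),
        sources=[
            SourceConfig(
                name=s.name, country=s.country, coding_system=s.coding_system,
                path=str(Path(raw_root) / s.name), poolable=s.poolable,
            )
            for s in config.sources
        ],
    )


def load_ground_truth(raw_root: str | Path) -> dict[str, pd.DataFrame]:
    truth_dir = Path(raw_root) / "truth"
    return {
        "patients": pd.read_csv(truth_dir / "patients.csv",
                                dtype={"patient_id": str}, keep_default_na=False),
        "labs": pd.read_csv(truth_dir / "labs.csv", dtype=str),
        "counts": pd.read_csv(truth_dir / "counts.csv"),
    }


def ground_truth_check(
    store, config: RunConfig, raw_root: str | Path
) -> pd.DataFrame:
    """Compare a finished pipeline run against recorded ground truth.

    Checks cohort membership, per-criterion attribution, index dates, and
    laboratory dispositions. Returns a discrepancy report; an empty frame
    means the pipeline reproduced the truth exactly.
    """
    from .cohort import read_cohort

    truth = load_ground_truth(raw_root)
    rows: list[dict] = []
    tp = truth["patients"]
    for src in config.sources:
        cohort = read_cohort(store, src.name).set_index("patient_id")
        sub = tp[tp["data_source_name"] == src.name]
        for rec in sub.itertuples(index=False):
            in_cohort = rec.patient_id in cohort.index
            if bool(int(rec.in_cohort)) != in_cohort:
                rows.append({"kind": "membership", "patient_id": rec.patient_id,
                             "expected": rec.in_cohort, "observed": int(in_cohort)})
                continue
            if not in_cohort:
                continue
            member = cohort.loc[rec.patient_id]
            if member["qualifying_criteria"] != rec.criteria:
                rows.append({"kind": "criteria", "patient_id": rec.patient_id,
                             "expected": rec.criteria,
                             "observed": member["qualifying_criteria"]})
            if member["index_date"] != rec.index_date:
                rows.append({"kind": "index_date", "patient_id": rec.patient_id,
                             "expected": rec.index_date,
                             "observed": member["index_date"]})
    # laboratory dispositions: loaded rows vs ledger
    lab_frames, ledger_frames = [], []
    for src in config.sources:
        lab_frames.append(store.read_table(src.name, "laboratory"))
        ledger_path = store.root / "ledger" / f"{src.name}.csv"
        if ledger_path.exists():
            ledger_frames.append(pd.read_csv(ledger_path, dtype=str))
    labs = pd.concat(lab_frames, ignore_index=True)
    disp = dict(zip(labs["record_id"], labs["disposition"]))
    if ledger_frames:
        ledger = pd.concat(ledger_frames, ignore_index=True)
        disp.update(dict(zip(ledger["record_id"], ledger["reason"])))
    for rec in truth["labs"].itertuples(index=False):
        observed = disp.get(rec.record_id, "<missing>")
        if observed != rec.expected_disposition:
            rows.append({"kind": "lab_disposition", "patient_id": rec.record_id,
                         "expected": rec.expected_disposition, "observed": observed})
    return pd.DataFrame(rows, columns=["kind", "patient_id", "expected", "observed"])
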