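"""Face-validity outputs: record counts and baseline covariate summaries.

Two tables mirror what a study team inspects after every load:

* record counts by data source and event class (diagnosis events, procedure
  events, drug prescription events, laboratory measurements, ...) — counts
  include non-poolable sources, since raw record tallies are not
  patient-level pooling;
* baseline covariates of the base cohort, one column per source plus an
  "overall" stratum restricted to poolable sources: age at index, % female,
  BMI, baseline eGFR, CKD stage bands from baseline eGFR, and comorbidity
  shares (type 2 diabetes, hypertension, heart failure) on/before index.

Baseline value = most recent measurement on/before the index date. The CKD
stage banding from eGFR (stage 2 or functional decline 60-74, 3a 45-59,
3b 30-44, 4 15-29, 5 <15 mL/min/1.73 m^2) is a reconstruction of the usual
KDIGO bands aligned to the cohort's eGFR entry threshold.
"""

from __future__ import annotations

import math

import pandas as pd

from .cohort import read_cohort
from .config import RunConfig
from .egfr import compute_egfr_series
from .schema import CORE_TABLES, TableStore

STAGE_BANDS = [
    ("ckd stage 2 or functional decline", 60.0, math.inf),
    ("ckd stage 3a", 45.0, 60.0),
    ("ckd stage 3b", 30.0, 45.0),
    ("ckd stage 4", 15.0, 30.0),
    ("ckd stage 5", -math.inf, 15.0),
]

COMORBIDITIES = ["type 2 diabetes", "hypertension", "heart failure"]


def record_counts(store: TableStore, config: RunConfig) -> pd.DataFrame:
    """Record counts by source and event class, plus an overall column."""
    sources = [s.name for s in config.sources]
    rows = []
    for table in CORE_TABLES:
        row: dict = {"event_class": table}
        total = 0
        for src in sources:
            n = len(store.read_table(src, table))
            row[src] = n
            total += n
        row["overall"] = total
        rows.append(row)
    return pd.DataFrame(rows, columns=["event_class", *sources, "overall"])


def _baseline_value(values: pd.DataFrame, index_date: str) -> float:
    """Most recent standardized value on/before the index date."""
    eligible = values[values["event_date"] <= index_date]
    if not len(eligible):
        return math.nan
    return float(eligible.sort_values("event_date").iloc[-1]["std_value"])


def _summarize(
    cohort: pd.DataFrame,
    demographics: pd.DataFrame,
    diagnosis: pd.DataFrame,
    laboratory: pd.DataFrame,
    config: RunConfig,
    stratum: str,
) -> dict:
    """One covariate summary column for a cohort stratum."""
    out: dict = {"stratum": stratum, "n_patients": len(cohort)}
    if not len(cohort):
        return out
    demo = demographics.set_index("patient_id")
    merged = cohort.join(demo[["birth_year", "sex", "country"]], on="patient_id")
    index_year = merged["index_date"].str.slice(0, 4).astype(int)
    age = index_year - pd.to_numeric(merged["birth_year"])
    out["age_mean"] = float(age.mean())
    out["age_sd"] = float(age.std()) if len(age) > 1 else math.nan
    out["pct_female"] = float((merged["sex"] == "female").mean() * 100)

    labs = laboratory.assign(
        std_value=pd.to_numeric(laboratory["std_value"], errors="coerce")
    )
    egfr_table, _ = compute_egfr_series(labs, demographics, config.egfr)
    egfr_by_patient = (
        dict(tuple(egfr_table.rename(columns={"date": "event_date",
                                              "egfr": "std_value"})
                   .groupby("patient_id")))
        if len(egfr_table) else {}
    )
    bmi_rows = labs[labs["analyte"] == "bmi"]
    bmi_by_patient = dict(tuple(bmi_rows.groupby("patient_id"))) if len(bmi_rows) else {}

    baseline_egfr, baseline_bmi = [], []
    for rec in cohort.itertuples(index=False):
        eg = egfr_by_patient.get(rec.patient_id)
        if eg is not None:
            baseline_egfr.append(_baseline_value(eg, rec.index_date))
        bm = bmi_by_patient.get(rec.patient_id)
        if bm is not None:
            baseline_bmi.append(_baseline_value(bm, rec.index_date))
    egfr_series = pd.Series(baseline_egfr, dtype=float).dropna()
    bmi_series = pd.Series(baseline_bmi, dtype=float).dropna()
    out["egfr_mean"] = float(egfr_series.mean()) if len(egfr_series) else math.nan
    out["egfr_sd"] = (float(egfr_series.std())
                      if len(egfr_series) > 1 else math.nan)
    out["bmi_mean"] = float(bmi_series.mean()) if len(bmi_series) else math.nan
    out["bmi_sd"] = float(bmi_series.std()) if len(bmi_series) > 1 else math.nan
    for label, lo, hi in STAGE_BANDS:
        share = float(((egfr_series >= lo) & (egfr_series < hi)).mean() * 100) \
            if len(egfr_series) else math.nan
        out[f"pct_{label.replace(' ', '_')}"] = share

    dx_on_or_before: dict[str, set] = {}
    if len(diagnosis):
        cohort_index = dict(zip(cohort["patient_id"], cohort["index_date"]))
        hits = diagnosis[diagnosis["entity_label"].isin(COMORBIDITIES)]
        for rec in hits.itertuples(index=False):
            idx = cohort_index.get(rec.patient_id)
            if idx is not None and str(rec.event_date) <= idx:
                dx_on_or_before.setdefault(rec.entity_label, set()).add(
                    rec.patient_id
                )
    for label in COMORBIDITIES:
        with_dx = dx_on_or_before.get(label, set())
        out[f"pct_{label.replace(' ', '_')}"] = (
            float(len(with_dx & set(cohort["patient_id"])) / len(cohort) * 100)
        )
    return out


def baseline_covariates(store: TableStore, config: RunConfig) -> pd.DataFrame:
    """Covariate summaries per source plus the poolable-only overall stratum.

    Non-poolable sources appear in their own column but never enter
    "overall"."""
    summaries = []
    pooled_parts: dict[str, list[pd.DataFrame]] = {
        "cohort": [], "demo": [], "dx": [], "lab": []
    }
    for src in config.sources:
        cohort = read_cohort(store, src.name)
        demo = store.read_table(src.name, "demographics")
        dx = store.read_table(src.name, "diagnosis")
        lab = store.read_table(src.name, "laboratory")
        summaries.append(_summarize(cohort, demo, dx, lab, config, src.name))
        if src.poolable:
            pooled_parts["cohort"].append(cohort)
            pooled_parts["demo"].append(demo)
            pooled_parts["dx"].append(dx)
            pooled_parts["lab"].append(lab)
    if pooled_parts["cohort"]:
        summaries.append(
            _summarize(
                _concat(pooled_parts["cohort"]),
                _concat(pooled_parts["demo"]),
                _concat(pooled_parts["dx"]),
                _concat(pooled_parts["lab"]),
                config,
                "overall",
            )
        )
    return pd.DataFrame(summaries)


def _concat(frames: list[pd.DataFrame]) -> pd.DataFrame:
    nonempty = [f for f in frames if len(f)]
    if not nonempty:
        return frames[0]
    return pd.concat(nonempty, ignore_index=True)


def write_reports(store: TableStore, config: RunConfig) -> None:
    """Persist the QC tables as CSV plus a human-readable text rendering."""
    reports_dir = store.root / "reports"
    reports_dir.mkdir(parents=True, exist_ok=True)
    counts = record_counts(store, config)
    counts.to_csv(reports_dir / "record_counts.csv", index=False)
    covariates = baseline_covariates(store, config)
    covariates.round(2).to_csv(reports_dir / "baseline_covariates.csv",
                               index=False)
    text = (
        "Record counts by data source and event class\n"
        + counts.to_string(index=False)
        + "\n\nBaseline covariates of the base cohort "
        "(overall = poolable sources only)\n"
        + covariates.round(2).set_index("stratum").T.to_string()
        + "\n"
    )
    (reports_dir / "face_validity.txt").write_text(text)
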