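"""Base-cohort derivation: the three CKD inclusion criteria, per source.

A patient enters the base cohort by meeting ANY of:

1. DX_CODE — a documented diagnosis code for CKD stage 3A through kidney
   failure (after entity-level standardization, a diagnosis whose entity
   label is in the configured CKD label set);
2. EGFR_PAIR — two eGFR measures < 75 mL/min/1.73 m^2 recorded > 90 days
   apart (maximum 730 days), both on/after 2008-01-01;
3. CHRONIC_RRT — chronic (> 30 days) renal replacement therapy: either RRT
   procedure events of one modality spanning more than 30 days within a
   contiguous episode (episodes split at gaps over 90 days), or a single
   event explicitly coded as chronic RRT.

Cohorts are built per data source and stored in separate tables keyed by
``data_source_name``, then combined federatedly: poolable sources are
concatenated into one cross-source table while non-poolable sources are kept
side-by-side only. Rebuilding one source never touches another source's
cohort table.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .config import CohortCriteriaConfig, ConfigurationError, RunConfig
from .egfr import compute_egfr_series
from .schema import TableStore

DX_CODE = "DX_CODE"
EGFR_PAIR = "EGFR_PAIR"
CHRONIC_RRT = "CHRONIC_RRT"

COHORT_COLUMNS = [
    "patient_id",
    "data_source_name",
    "qualifying_criteria",  # |-joined sorted subset of the three criteria
    "qualifying_dates",  # |-joined dates aligned with qualifying_criteria
    "index_date",
    "poolable",
]


@dataclass
class Qualification:
    criterion: str
    date: dt.date


def _as_date(value) -> dt.date:
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


def criterion_dx(
    events: pd.DataFrame, config: CohortCriteriaConfig
) -> Optional[Qualification]:
    """First diagnosis event whose entity label is CKD stage 3A+ qualifies."""
    if not len(events):
        return None
    hits = events[events["entity_label"].isin(config.ckd_dx_entity_labels)]
    if not len(hits):
        return None
    date = min(_as_date(d) for d in hits["event_date"])
    return Qualification(DX_CODE, date)


def criterion_egfr_pair(
    series: Iterable[tuple[dt.date, float]], config: CohortCriteriaConfig
) -> Optional[Qualification]:
    """Two sub-threshold eGFR measures > 90 and <= 730 days apart.

    Both measures must fall on/after the window start (2008-01-01). Among all
    qualifying pairs the earliest — by second-measure date, ties broken by
    first-measure date — is chosen, and its second measure's date is the
    qualifying date. Intermediate values at or above the threshold do not
    disqualify a pair.
    """
    eligible = sorted(
        _as_date(d)
        for d, v in series
        if v < config.egfr_threshold and _as_date(d) >= config.window_start
    )
    best: Optional[tuple[dt.date, dt.date]] = None
    for i in range(len(eligible)):
        for j in range(i + 1, len(eligible)):
            gap = (eligible[j] - eligible[i]).days
            if config.min_gap_days < gap <= config.max_gap_days:
                key = (eligible[j], eligible[i])
                if best is None or key < best:
                    best = key
    if best is None:
        return None
    return Qualification(EGFR_PAIR, best[0])


def _episodes(dates: list[dt.date], break_days: int) -> list[tuple[dt.date, dt.date]]:
    """Split sorted event dates into contiguous episodes at large gaps."""
    if not dates:
        return []
    episodes = []
    start = prev = dates[0]
    for d in dates[1:]:
        if (d - prev).days > break_days:
            episodes.append((start, prev))
            start = d
        prev = d
    episodes.append((start, prev))
    return episodes


def criterion_chronic_rrt(
    events: pd.DataFrame, config: CohortCriteriaConfig
) -> Optional[Qualification]:
    """Chronic renal replacement therapy: modality episode spanning > 30 days.

    Assessed per modality (hemodialysis / peritoneal dialysis); an episode is
    a run of events with no gap exceeding the episode-break window. A single
    event carrying an explicitly-chronic entity label qualifies on its own.
    """
    if not len(events):
        return None
    qualifying_starts: list[dt.date] = []
    chronic = events[events["entity_label"].isin(config.chronic_rrt_entity_labels)]
    qualifying_starts.extend(_as_date(d) for d in chronic["event_date"])
    for label in config.rrt_entity_labels:
        dates = sorted(
            _as_date(d)
            for d in events.loc[events["entity_label"] == label, "event_date"]
        )
        for start, end in _episodes(dates, config.rrt_episode_break_days):
            if (end - start).days > config.rrt_min_duration_days:
                qualifying_starts.append(start)
    if not qualifying_starts:
        return None
    return Qualification(CHRONIC_RRT, min(qualifying_starts))


def build_base_cohort(
    store: TableStore,
    source_name: str,
    config: RunConfig,
) -> pd.DataFrame:
    """Derive one source's base cohort from its loaded CDM partitions.

    Returns one row per qualifying patient with the set of criteria met,
    the per-criterion qualifying dates, and the index date (earliest
    qualifying date across criteria). Patients meeting several criteria
    appear once.
    """
    source = config.source(source_name)
    diagnosis = store.read_table(source_name, "diagnosis")
    procedure = store.read_table(source_name, "procedure")
    laboratory = store.read_table(source_name, "laboratory")
    demographics = store.read_table(source_name, "demographics")

    laboratory = laboratory.assign(
        std_value=pd.to_numeric(laboratory["std_value"], errors="coerce")
    )
    egfr_table, _skips = compute_egfr_series(
        laboratory, demographics, config.egfr
    )

    members = []
    patients = sorted(set(demographics["patient_id"]))
    dx_by_patient = dict(tuple(diagnosis.groupby("patient_id"))) if len(diagnosis) else {}
    rrt_by_patient = dict(tuple(procedure.groupby("patient_id"))) if len(procedure) else {}
    egfr_by_patient = (
        dict(tuple(egfr_table.groupby("patient_id"))) if len(egfr_table) else {}
    )
    empty_events = pd.DataFrame(columns=["entity_label", "event_date"])
    for pid in patients:
        quals: list[Qualification] = []
        q = criterion_dx(dx_by_patient.get(pid, empty_events), config.criteria)
        if q:
            quals.append(q)
        eg = egfr_by_patient.get(pid)
        if eg is not None:
            q = criterion_egfr_pair(
                zip(eg["date"], eg["egfr"]), config.criteria
            )
            if q:
                quals.append(q)
        q = criterion_chronic_rrt(
            rrt_by_patient.get(pid, empty_events), config.criteria
        )
        if q:
            quals.append(q)
        if not quals:
            continue
        quals.sort(key=lambda x: (DX_CODE, EGFR_PAIR, CHRONIC_RRT).index(x.criterion))
        members.append(
            {
                "patient_id": pid,
                "data_source_name": source_name,
                "qualifying_criteria": "|".join(q.criterion for q in quals),
                "qualifying_dates": "|".join(q.date.isoformat() for q in quals),
                "index_date": min(q.date for q in quals).isoformat(),
                "poolable": source.poolable,
            }
        )
    cohort = pd.DataFrame(members, columns=COHORT_COLUMNS)
    path = store.root / "cohort" / f"{source_name}.csv"
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.sort_values("patient_id", kind="mergesort").to_csv(path, index=False)
    return cohort


def read_cohort(store: TableStore, source_name: str) -> pd.DataFrame:
    path = store.root / "cohort" / f"{source_name}.csv"
    if not path.exists():
        return pd.DataFrame(columns=COHORT_COLUMNS)
    return pd.read_csv(
        path, dtype={"patient_id": str, "data_source_name": str,
                     "qualifying_criteria": str, "qualifying_dates": str,
                     "index_date": str},
    )


def combine_cohorts(store: TableStore, config: RunConfig) -> tuple[pd.DataFrame, list[str]]:
    """Concatenate poolable per-source cohorts; list non-poolable separately.

    Returns ``(combined, non_poolable_sources)`` and persists both: the
    combined table under ``cohort/combined.csv`` and the non-poolable source
    names under ``cohort/non_poolable.txt``. Raises on duplicate
    (data_source_name, patient_id) pairs.
    """
    poolable_frames, non_poolable = [], []
    for src in config.sources:
        cohort = read_cohort(store, src.name)
        if src.poolable:
            poolable_frames.append(cohort)
        else:
            non_poolable.append(src.name)
    combined = (
        pd.concat(poolable_frames, ignore_index=True)
        if poolable_frames
        else pd.DataFrame(columns=COHORT_COLUMNS)
    )
    dup = combined.duplicated(subset=["data_source_name", "patient_id"])
    if dup.any():
        raise ConfigurationError(
            "duplicate cohort members: "
            f"{combined.loc[dup, ['data_source_name', 'patient_id']].values.tolist()}"
        )
    combined = combined.sort_values(
        ["data_source_name", "patient_id"], kind="mergesort"
    ).reset_index(drop=True)
    path = store.root / "cohort" / "combined.csv"
    path.parent.mkdir(parents=True, exist_ok=True)
    combined.to_csv(path, index=False)
    (store.root / "cohort" / "non_poolable.txt").write_text(
        "".join(f"{name}\n" for name in sorted(non_poolable))
    )
    return combined, sorted(non_poolable)
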