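"""CDM table registry and flat-file storage.

The model holds standardized medical entities in seven core entity tables —
diagnosis, procedure, prescription, laboratory, encounter, observation and
outcome — plus one demographics table. Every persisted row carries two kinds
of bookkeeping columns:

* traceability — ``record_id`` (and optional ``encounter_id``) retained from
  the source plus ``data_source_name``, so each CDM row can be matched back
  to exactly one raw source row;
* audit — ``loaded_by`` and ``loaded_at``, recording who loaded the row and
  when. ``loaded_at`` comes from the run configuration's fixed clock so that
  reruns are byte-identical.

Storage is one CSV file per table per data source under
``<storage_root>/cdm/<source>/<table>.csv``, with derived combined views under
``<storage_root>/cdm/combined/``. Per-source partitioning is what makes the
build federated: refreshing or removing one source never touches another
source's files.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .config import ConfigurationError, RunConfig

TRACE_COLUMNS = ["record_id", "encounter_id", "data_source_name"]
AUDIT_COLUMNS = ["loaded_by", "loaded_at"]

_EVENT_BASE = (
    ["patient_id", "event_date", "entity_label", "entity_type", "descriptor"]
    + TRACE_COLUMNS
    + AUDIT_COLUMNS
)

#: the seven core entity tables
CORE_TABLES = [
    "diagnosis",
    "procedure",
    "prescription",
    "laboratory",
    "encounter",
    "observation",
    "outcome",
]

_LAB_EXTRA = ["analyte", "raw_value", "raw_unit", "std_value", "std_unit", "disposition"]

DEMOGRAPHICS_COLUMNS = (
    ["patient_id", "birth_year", "sex", "country", "data_source_name"] + AUDIT_COLUMNS
)


def _default_schemas() -> dict[str, list[str]]:
    schemas = {name: list(_EVENT_BASE) for name in CORE_TABLES}
    schemas["laboratory"] = (
        ["patient_id", "event_date", "entity_label", "entity_type", "descriptor"]
        + _LAB_EXTRA
        + TRACE_COLUMNS
        + AUDIT_COLUMNS
    )
    schemas["demographics"] = list(DEMOGRAPHICS_COLUMNS)
    return schemas


class SchemaViolation(ValueError):
    """Rows failed validation against a registered table schema."""


class TableRegistry:
    """The set of registered CDM tables and their column schemas."""

    def __init__(self, schemas: dict[str, list[str]]):
        self._schemas = schemas

    @property
    def table_names(self) -> list[str]:
        return list(self._schemas)

    def columns(self, table: str) -> list[str]:
        try:
            return list(self._schemas[table])
        except KeyError:
            raise ConfigurationError(f"unknown CDM table: {table!r}") from None

    def __contains__(self, table: str) -> bool:
        return table in self._schemas

    def validate_rows(self, table: str, frame: pd.DataFrame) -> None:
        """Validate a row set against the schema; raise listing offenders."""
        cols = self.columns(table)
        missing = [c for c in cols if c not in frame.columns]
        extra = [c for c in frame.columns if c not in cols]
        problems = []
        if missing:
            problems.append(f"missing columns: {missing}")
        if extra:
            problems.append(f"unexpected columns: {extra}")
        if not problems:
            for col in AUDIT_COLUMNS:
                if col in cols and len(frame):
                    bad = frame[col].isna() | (frame[col].astype(str).str.strip() == "")
                    if bad.any():
                        problems.append(
                            f"audit column {col!r} empty on {int(bad.sum())} row(s)"
                        )
            if "record_id" in cols and len(frame):
                dup = frame.duplicated(subset=["data_source_name", "record_id"])
                if dup.any():
                    ids = frame.loc[dup, "record_id"].head(5).tolist()
                    problems.append(
                        f"duplicate (data_source_name, record_id): {ids} ..."
                    )
        if problems:
            raise SchemaViolation(f"table {table!r}: " + "; ".join(problems))


def register_tables(config: RunConfig) -> TableRegistry:
    """Build the table registry for a run: 7 core + demographics (+ extras).

    The registry is additive — ``config.extra_tables`` maps a new table name
    to its extra payload columns; trace and audit columns are appended
    automatically so the shared contract holds for custom tables too.
    """
    root = Path(config.storage_root)
    root.mkdir(parents=True, exist_ok=True)
    if not os.access(root, os.W_OK):
        raise ConfigurationError(f"storage root not writable: {root}")
    schemas = _default_schemas()
    for name, payload in config.extra_tables.items():
        cols = list(payload)
        for col in TRACE_COLUMNS + AUDIT_COLUMNS:
            if col not in cols:
                cols.append(col)
        schemas[name] = cols
    return TableRegistry(schemas)


class TableStore:
    """Flat-file CDM storage with per-source partitions and combined views."""

    def __init__(self, config: RunConfig, registry: TableRegistry):
        self.config = config
        self.registry = registry
        self.root = Path(config.storage_root)

    # -- paths ---------------------------------------------------------------
    def partition_path(self, source: str, table: str) -> Path:
        return self.root / "cdm" / source / f"{table}.csv"

    def combined_path(self, table: str) -> Path:
        return self.root / "cdm" / "combined" / f"{table}.csv"

    def source_names(self) -> list[str]:
        base = self.root / "cdm"
        if not base.is_dir():
            return []
        return sorted(
            p.name for p in base.iterdir() if p.is_dir() and p.name != "combined"
        )

    # -- IO ------------------------------------------------------------------
    def write_table(self, source: str, table: str, frame: pd.DataFrame) -> Path:
        """Validate and persist one source partition of one table.

        Rows are sorted by (data_source_name, record_id) — or patient_id for
        demographics — so output bytes are order-independent and reruns are
        reproducible.
        """
        cols = self.registry.columns(table)
        frame = frame.reindex(columns=cols)
        self.registry.validate_rows(table, frame)
        sort_keys = (
            ["data_source_name", "record_id"]
            if "record_id" in cols
            else ["data_source_name", "patient_id"]
        )
        frame = frame.sort_values(sort_keys, kind="mergesort").reset_index(drop=True)
        path = self.partition_path(source, table)
        path.parent.mkdir(parents=True, exist_ok=True)
        frame.to_csv(path, index=False)
        return path

    def read_table(self, source: str, table: str) -> pd.DataFrame:
        """Read one source partition; empty schema-valid frame if absent."""
        cols = self.registry.columns(table)
        path = self.partition_path(source, table)
        if not path.exists():
            return pd.DataFrame(columns=cols)
        str_cols = _STRING_COLUMNS & set(cols)
        frame = pd.read_csv(path, dtype={c: str for c in str_cols},
                            float_precision="round_trip")
        frame = frame.reindex(columns=cols)
        for col in str_cols:
            frame[col] = frame[col].fillna("").astype(object)
        return frame

    def read_combined(self, table: str, sources: list[str] | None = None) -> pd.DataFrame:
        frames = [
            self.read_table(s, table)
            for s in (sources if sources is not None else self.source_names())
        ]
        frames = [f for f in frames if len(f)]
        if not frames:
            return pd.DataFrame(columns=self.registry.columns(table))
        return pd.concat(frames, ignore_index=True)

    def rebuild_combined_views(self) -> None:
        """Recompute combined views as the concatenation of all partitions."""
        for table in self.registry.table_names:
            frame = self.read_combined(table)
            cols = self.registry.columns(table)
            sort_keys = (
                ["data_source_name", "record_id"]
                if "record_id" in cols
                else ["data_source_name", "patient_id"]
            )
            frame = frame.sort_values(sort_keys, kind="mergesort").reset_index(drop=True)
            path = self.combined_path(table)
            path.parent.mkdir(parents=True, exist_ok=True)
            frame.to_csv(path, index=False)

    def drop_source(self, source: str) -> None:
        """Remove a source's partitions entirely (federated removal)."""
        base = self.root / "cdm" / source
        if base.is_dir():
            for p in sorted(base.iterdir()):
                p.unlink()
            base.rmdir()


# columns always read back as strings (ids, codes, units, dates)
_STRING_COLUMNS = {
    "patient_id",
    "event_date",
    "entity_label",
    "entity_type",
    "descriptor",
    "analyte",
    "raw_unit",
    "std_unit",
    "disposition",
    "record_id",
    "encounter_id",
    "data_source_name",
    "loaded_by",
    "loaded_at",
    "sex",
    "country",
}
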