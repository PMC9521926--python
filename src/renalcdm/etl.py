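"""Extract -> transform -> load, driven by column-level mapping documents.

Each source ships a mapping document: one row per (source table, source
column) -> (target table, target column) with a named transform drawn from a
closed catalog (``copy``, ``constant:<v>``, ``date_parse:ISO``,
``date_parse:DMY``, ``to_number``, ``to_int``, ``sex_normalize``,
``setting_normalize``). Documenting the transformation logic at column level
— rather than embedding code — is what keeps the ETL traceable and auditable.

Transformation then routes rows through the model's exchangeable components:
coded events through the reference code lists (entity-level
standardization), laboratory rows through unit harmonization with
plausibility filtering. Row-level failures are quarantined into the
per-source exclusion ledger with a reason — conservation holds exactly:
staged rows = loaded rows + ledger rows, per table per source. Only
structural problems (missing file, schema violation, duplicate record ids)
abort a source; other sources are unaffected.

Loads are idempotent and federated: a source's partitions are replaced
wholesale on rebuild, the combined views are derived artifacts, and with the
configured fixed clock two runs over identical inputs are byte-identical.
Refreshing or removing one source leaves every other source's files
bit-identical.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .code_lists import UNMAPPED, CodeListTable, load_code_lists
from .cohort import build_base_cohort, combine_cohorts
from .config import ConfigurationError, RunConfig
from .labs import AnalyteRegistry, harmonize_lab_stream, load_analyte_specs
from .schema import TableRegistry, TableStore, register_tables

MAPPING_COLUMNS = ["data_source_name", "source_table", "source_column",
                   "target_table", "target_column", "transform_id"]

#: intermediate columns each target table requires from its mapping
REQUIRED_TARGET_COLUMNS = {
    "demographics": ["patient_id", "birth_year", "sex", "country"],
    "diagnosis": ["patient_id", "event_date", "raw_code", "coding_system",
                  "record_id"],
    "procedure": ["patient_id", "event_date", "raw_code", "coding_system",
                  "record_id"],
    "prescription": ["patient_id", "event_date", "raw_code", "coding_system",
                     "record_id"],
    "outcome": ["patient_id", "event_date", "raw_code", "coding_system",
                "record_id"],
    "observation": ["patient_id", "event_date", "raw_code", "coding_system",
                    "record_id"],
    "laboratory": ["patient_id", "event_date", "analyte_code", "coding_system",
                   "raw_value", "raw_unit", "record_id"],
    "encounter": ["patient_id", "event_date", "record_id"],
}

ABSENT = "__absent__"  # marker: target column intentionally unmapped

_SEX_MAP = {"f": "female", "female": "female", "m": "male", "male": "male"}
_SETTING_MAP = {"i": "inpatient", "ip": "inpatient", "inpatient": "inpatient",
                "o": "outpatient", "op": "outpatient", "outpatient": "outpatient"}


class TransformError(ValueError):
    """A row-level transform failure (routed to the exclusion ledger)."""


def _parse_date(value: str, fmt: str) -> str:
    value = str(value).strip()
    try:
        if fmt == "DMY":
            return dt.datetime.strptime(value, "%d/%m/%Y").date().isoformat()
        return dt.date.fromisoformat(value).isoformat()
    except ValueError as exc:
        raise TransformError(f"date_parse_error: {value!r}") from exc


def _scalar_transform(transform_id: str, value):
    if transform_id == "copy":
        return "" if pd.isna(value) else str(value)
    if transform_id.startswith("constant:"):
        return transform_id.split(":", 1)[1]
    if transform_id.startswith("date_parse:"):
        return _parse_date(value, transform_id.split(":", 1)[1])
    if transform_id == "to_number":
        try:
            return float(value)
        except (TypeError, ValueError):
            return float("nan")  # handled downstream as invalid_value
    if transform_id == "to_int":
        try:
            return int(float(value))
        except (TypeError, ValueError) as exc:
            raise TransformError(f"int_parse_error: {value!r}") from exc
    if transform_id == "sex_normalize":
        return _SEX_MAP.get(str(value).strip().lower(), "unknown")
    if transform_id == "setting_normalize":
        return _SETTING_MAP.get(str(value).strip().lower(), "")
    raise ConfigurationError(f"unknown transform_id: {transform_id!r}")


def known_transform(transform_id: str) -> bool:
    if transform_id.startswith(("constant:", "date_parse:")):
        suffix = transform_id.split(":", 1)[1]
        return transform_id.startswith("constant:") or suffix in ("ISO", "DMY")
    return transform_id in {"copy", "to_number", "to_int", "sex_normalize",
                            "setting_normalize"}


def load_mapping(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in MAPPING_COLUMNS if c not in frame.columns]
    if missing:
        raise ConfigurationError(f"mapping document missing columns: {missing}")
    return frame


def validate_mapping(
    mapping: pd.DataFrame,
    staged: dict[str, pd.DataFrame],
    registry: TableRegistry,
) -> pd.DataFrame:
    """Technical validation of a mapping document prior to ETL.

    Findings: unknown transforms, references to nonexistent source tables or
    columns, unknown target tables, duplicate rules, and required target
    columns with neither a rule nor an explicit absent marker.
    """
    findings: list[dict[str, str]] = []
    for row in mapping.itertuples(index=False):
        ident = (f"{row.source_table}.{row.source_column} -> "
                 f"{row.target_table}.{row.target_column}")
        if not known_transform(row.transform_id):
            findings.append({"finding": "unknown_transform",
                             "detail": f"{ident}: {row.transform_id!r}"})
        if row.source_table not in staged:
            findings.append({"finding": "missing_source_table",
                             "detail": ident})
        elif (row.source_column not in ("", ABSENT)
              and not row.transform_id.startswith("constant:")
              and row.source_column not in staged[row.source_table].columns):
            findings.append({"finding": "missing_source_column", "detail": ident})
        if row.target_table not in registry and row.target_table not in (
            REQUIRED_TARGET_COLUMNS
        ):
            findings.append({"finding": "unknown_target_table", "detail": ident})
    dup = mapping.duplicated(subset=["target_table", "target_column"])
    for _, row in mapping[dup].iterrows():
        findings.append({"finding": "duplicate_rule",
                         "detail": f"{row['target_table']}.{row['target_column']}"})
    for target, required in REQUIRED_TARGET_COLUMNS.items():
        rules = mapping[mapping["target_table"] == target]
        if not len(rules):
            continue
        covered = set(rules["target_column"])
        absent = set(rules.loc[rules["source_column"] == ABSENT, "target_column"])
        for col in required:
            if col not in covered and col not in absent:
                findings.append({"finding": "uncovered_target_column",
                                 "detail": f"{target}.{col}"})
    return pd.DataFrame(findings, columns=["finding", "detail"])


@dataclass
class EtlRunReport:
    """Counts and exclusion tallies from one source's ETL run."""

    data_source_name: str
    config_digest: str
    table_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    exclusion_reasons: dict[str, int] = field(default_factory=dict)
    warnings: dict[str, int] = field(default_factory=dict)

    def record(self, table: str, n_in: int, n_out: int, n_excluded: int) -> None:
        self.table_counts[table] = {
            "input": n_in, "output": n_out, "excluded": n_excluded
        }
        assert n_in == n_out + n_excluded, "conservation violated"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"data_source_name": self.data_source_name, "table": t, **c}
            for t, c in sorted(self.table_counts.items())
        ]
        return pd.DataFrame(rows,
                            columns=["data_source_name", "table", "input",
                                     "output", "excluded"])


# -- stages ------------------------------------------------------------------

RAW_TABLES = ["patients", "diagnoses", "procedures", "prescriptions", "labs",
              "encounters"]


def extract(source_name: str, config: RunConfig) -> dict[str, pd.DataFrame]:
    """Stage a source's raw tables, untouched, under storage_root/staging."""
    source = config.source(source_name)
    if source.path is None:
        raise ConfigurationError(f"source {source_name!r} has no raw path")
    raw_dir = Path(source.path)
    staged: dict[str, pd.DataFrame] = {}
    staging_dir = Path(config.storage_root) / "staging" / source_name
    staging_dir.mkdir(parents=True, exist_ok=True)
    for table in RAW_TABLES:
        path = raw_dir / f"{table}.csv"
        if not path.exists():
            raise ConfigurationError(f"{source_name}: missing raw file {path}")
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        frame.to_csv(staging_dir / f"{table}.csv", index=False)
        staged[table] = frame
    return staged


def _apply_rules(
    staged_table: pd.DataFrame, rules: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply column rules (vectorized); returns (intermediate, failed rows)."""
    n = len(staged_table)
    out: dict[str, pd.Series] = {}
    fail = pd.Series([None] * n, dtype=object)

    def mark(bad: pd.Series, reason: str) -> None:
        nonlocal fail
        idx = bad.values & fail.isna().values
        fail.iloc[idx] = reason

    for rule in rules.itertuples(index=False):
        tid = rule.transform_id
        if rule.source_column == ABSENT:
            continue
        if tid.startswith("constant:"):
            out[rule.target_column] = pd.Series([tid.split(":", 1)[1]] * n,
                                                dtype=object)
            continue
        if rule.source_column not in staged_table.columns:
            raise ConfigurationError(
                f"mapping references missing column {rule.source_column!r}"
            )
        col = staged_table[rule.source_column].reset_index(drop=True)
        if tid == "copy":
            vals = col.fillna("").astype(str)
        elif tid == "to_number":
            # python strtod is correctly-rounded; keeps raw values exact
            def _f(x):
                try:
                    return float(x)
                except (TypeError, ValueError):
                    return float("nan")  # handled downstream as invalid_value
            vals = col.map(_f)
        elif tid == "to_int":
            nums = pd.to_numeric(col, errors="coerce")
            mark(nums.isna(), "int_parse_error")
            vals = nums.astype("Int64")
        elif tid == "sex_normalize":
            vals = (col.astype(str).str.strip().str.lower()
                    .map(_SEX_MAP).fillna("unknown"))
        elif tid == "setting_normalize":
            vals = (col.astype(str).str.strip().str.lower()
                    .map(_SETTING_MAP).fillna(""))
        elif tid.startswith("date_parse:"):
            fmt = "%d/%m/%Y" if tid.endswith("DMY") else "%Y-%m-%d"
            parsed = pd.to_datetime(col, format=fmt, errors="coerce")
            mark(parsed.isna(), "date_parse_error")
            vals = parsed.dt.strftime("%Y-%m-%d")
        else:
            raise ConfigurationError(f"unknown transform_id: {tid!r}")
        out[rule.target_column] = vals
    inter = pd.DataFrame(out)
    failed_mask = fail.notna()
    failures = staged_table.reset_index(drop=True)[failed_mask.values].copy()
    if len(failures):
        failures["reason"] = fail[failed_mask].values
    ok = (inter[~failed_mask.values].reset_index(drop=True)
          if len(inter) else inter)
    return ok, failures


def transform(
    staged: dict[str, pd.DataFrame],
    mapping: pd.DataFrame,
    code_lists: CodeListTable,
    analytes: AnalyteRegistry,
    config: RunConfig,
    source_name: str,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, EtlRunReport]:
    """Standardize one staged source into CDM rows plus an exclusion ledger."""
    source = config.source(source_name)
    report = EtlRunReport(source_name, config.digest())
    cdm: dict[str, pd.DataFrame] = {}
    ledger_rows: list[dict] = []

    def ledger_from(frame: pd.DataFrame, table: str, reason_col: str = "reason"):
        for _, row in frame.iterrows():
            ledger_rows.append({
                "data_source_name": source_name,
                "target_table": table,
                "record_id": row.get("record_id", ""),
                "patient_id": row.get("patient_id", ""),
                "reason": row[reason_col],
                "raw_value": row.get("raw_value", ""),
                "raw_unit": row.get("raw_unit", ""),
            })

    audit = {"loaded_by": config.user, "loaded_at": config.clock}

    for target_table in ("demographics", "diagnosis", "procedure",
                         "prescription", "outcome", "observation",
                         "laboratory", "encounter"):
        rules = mapping[mapping["target_table"] == target_table]
        if not len(rules):
            continue
        source_tables = sorted(set(rules["source_table"]))
        frames = []
        n_in = n_excluded = 0
        for st in source_tables:
            sub_rules = rules[rules["source_table"] == st]
            staged_table = staged[st]
            n_in += len(staged_table)
            inter, failures = _apply_rules(staged_table, sub_rules)
            if len(failures):
                # carry trace columns into the ledger where identifiable
                rid_col = sub_rules.loc[
                    sub_rules["target_column"] == "record_id", "source_column"
                ]
                failures = failures.rename(
                    columns={rid_col.iloc[0]: "record_id"} if len(rid_col) else {}
                )
                ledger_from(failures, target_table)
                n_excluded += len(failures)
            frames.append(inter)
        inter = (pd.concat(frames, ignore_index=True)
                 if frames else pd.DataFrame())

        if target_table == "demographics":
            final = inter.assign(data_source_name=source_name, **audit)
        elif target_table == "laboratory":
            mapped = inter.copy()
            if len(mapped):
                labels = [
                    code_lists.standardize_event(
                        code, system, "laboratory"
                    ).entity_label
                    for code, system in zip(mapped["analyte_code"],
                                            mapped["coding_system"])
                ]
                mapped["analyte"] = labels
            else:
                mapped["analyte"] = pd.Series(dtype=object)
            unmapped = mapped[mapped["analyte"] == UNMAPPED]
            if len(unmapped):
                ledger_from(unmapped.assign(reason="unmapped_code"), target_table)
                n_excluded += len(unmapped)
            mapped = mapped[mapped["analyte"] != UNMAPPED].reset_index(drop=True)
            mapped["data_source_name"] = source_name
            if len(mapped):
                lab_table, lab_ledger = harmonize_lab_stream(
                    mapped, analytes, config.lab
                )
                kept = lab_table[
                    lab_table["disposition"].str.startswith("standardized")
                ].reset_index(drop=True)
                if len(lab_ledger):
                    ledger_from(lab_ledger.assign(target_table=target_table),
                                target_table)
                    n_excluded += len(lab_ledger)
            else:
                kept = mapped.assign(std_value=None, std_unit=None,
                                     disposition=None)
            final = kept.assign(
                entity_label=kept["analyte"] if len(kept) else None,
                entity_type="laboratory", **audit,
            )
        elif target_table == "encounter":
            final = inter.assign(
                entity_label="encounter", entity_type="encounter",
                data_source_name=source_name, **audit,
            )
        else:  # coded event tables
            mapped = inter.copy()
            if len(mapped):
                mapped["entity_label"] = [
                    code_lists.standardize_event(
                        code, system, target_table
                    ).entity_label
                    for code, system in zip(mapped["raw_code"],
                                            mapped["coding_system"])
                ]
            else:
                mapped["entity_label"] = pd.Series(dtype=object)
            unmapped = mapped[mapped["entity_label"] == UNMAPPED]
            if len(unmapped) and not config.lab.keep_unmapped:
                ledger_from(unmapped.assign(reason="unmapped_code"), target_table)
                n_excluded += len(unmapped)
                mapped = mapped[mapped["entity_label"] != UNMAPPED]
            final = mapped.assign(
                entity_type=target_table, data_source_name=source_name, **audit
            ).reset_index(drop=True)

        if "event_date" in final.columns and len(final):
            # rows outside the study window are loaded but flagged
            outside = (
                (final["event_date"] < config.study_window_start.isoformat())
                | (final["event_date"] > config.study_window_end.isoformat())
            ).sum()
            if outside:
                report.warnings[f"out_of_window:{target_table}"] = int(outside)
        cdm[target_table] = final
        report.record(target_table, n_in, len(final), n_excluded)

    ledger = pd.DataFrame(
        ledger_rows,
        columns=["data_source_name", "target_table", "record_id", "patient_id",
                 "reason", "raw_value", "raw_unit"],
    )
    return cdm, ledger, report


def load(
    cdm: dict[str, pd.DataFrame],
    ledger: pd.DataFrame,
    store: TableStore,
    source_name: str,
) -> None:
    """Persist one source's CDM partition (replace semantics) + its ledger."""
    store.drop_source(source_name)
    for table, frame in cdm.items():
        store.write_table(source_name, table, frame)
    ledger_path = store.root / "ledger" / f"{source_name}.csv"
    ledger_path.parent.mkdir(parents=True, exist_ok=True)
    ledger.sort_values(["target_table", "record_id"], kind="mergesort").to_csv(
        ledger_path, index=False
    )


# -- orchestration -----------------------------------------------------------


def _load_components(config: RunConfig):
    code_lists = load_code_lists(config.code_lists_path)
    analytes = load_analyte_specs(config.analytes_path,
                                  config.acceptable_units_path)
    return code_lists, analytes


def run_source(
    source_name: str,
    config: RunConfig,
    store: TableStore | None = None,
) -> EtlRunReport:
    """extract -> transform -> load -> per-source cohort, for one source."""
    registry = register_tables(config)
    store = store or TableStore(config, registry)
    code_lists, analytes = _load_components(config)
    source = config.source(source_name)
    staged = extract(source_name, config)
    mapping = load_mapping(Path(source.path) / "mapping.csv")
    findings = validate_mapping(mapping, staged, registry)
    if len(findings):
        raise ConfigurationError(
            f"{source_name}: mapping validation failed:\n{findings.to_string()}"
        )
    cdm, ledger, report = transform(staged, mapping, code_lists, analytes,
                                    config, source_name)
    load(cdm, ledger, store, source_name)
    build_base_cohort(store, source_name, config)
    return report


def build_all(
    config: RunConfig,
) -> tuple[list[EtlRunReport], dict[str, str]]:
    """Full federated build: every configured source, then combined views,
    combined cohort and QC reports. A per-source structural failure (missing
    file, invalid mapping) is recorded and the run continues with the other
    sources — the federation contract."""
    registry = register_tables(config)
    store = TableStore(config, registry)
    reports: list[EtlRunReport] = []
    failures: dict[str, str] = {}
    for source in config.sources:
        try:
            reports.append(run_source(source.name, config, store))
        except ConfigurationError as exc:
            failures[source.name] = str(exc)
    store.rebuild_combined_views()
    combine_cohorts(store, config)
    from .qc import write_reports

    write_reports(store, config)
    if reports:
        report_frame = pd.concat([r.to_frame() for r in reports],
                                 ignore_index=True)
        path = store.root / "reports" / "etl_counts.csv"
        path.parent.mkdir(parents=True, exist_ok=True)
        report_frame.to_csv(path, index=False)
    return reports, failures


def refresh_source(source_name: str, config: RunConfig) -> EtlRunReport:
    """Rebuild one source only; every other source's files stay untouched."""
    registry = register_tables(config)
    store = TableStore(config, registry)
    report = run_source(source_name, config, store)
    store.rebuild_combined_views()
    combine_cohorts(store, config)
    return report


def remove_source(source_name: str, config: RunConfig) -> None:
    """Drop one source from the CDM (partitions, ledger, cohort) and rebuild
    the derived combined views without it."""
    registry = register_tables(config)
    store = TableStore(config, registry)
    store.drop_source(source_name)
    for path in (store.root / "ledger" / f"{source_name}.csv",
                 store.root / "cohort" / f"{source_name}.csv"):
        if path.exists():
            path.unlink()
    staging = store.root / "staging" / source_name
    if staging.is_dir():
        for p in sorted(staging.iterdir()):
            p.unlink()
        staging.rmdir()
    store.rebuild_combined_views()
    remaining = RunConfig(**{**config.model_dump(mode="json"),
                             "sources": [s.model_dump() for s in config.sources
                                         if s.name != source_name]})
    combine_cohorts(store, remaining)
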