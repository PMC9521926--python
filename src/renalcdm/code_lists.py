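"""Entity-level standardization of coded medical events.

Events from different coding vocabularies (ICD-9-CM, ICD-10, UK Read, local
source codes) are never mapped code-to-code. Instead a single reference code
lists table maps each (coding_system, code) to a curated clinical *entity
label* — e.g. ICD-10 ``E11.34`` and Read ``C100112`` both standardize to the
entity ``type 2 diabetes``. Lookup misses are data, not errors: they yield
the sentinel ``UNMAPPED`` and are counted, never silently dropped.

Codes are normalized before lookup: whitespace trimmed, upper-cased, and ICD
codes matched both with and without the dot (``E11.34`` == ``E1134``), since
source dialects differ on dot retention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

UNMAPPED = "UNMAPPED"

REQUIRED_COLUMNS = ["coding_system", "code", "entity_label", "entity_type"]

#: entity types that may appear in a code list
ENTITY_TYPES = {
    "diagnosis",
    "procedure",
    "prescription",
    "outcome",
    "observation",
    "laboratory",
}


class CodeListValidationError(ValueError):
    """The reference code lists table violates its invariants."""


def normalize_code(code: str) -> str:
    return str(code).strip().upper()


def normalize_label(label: str) -> str:
    return " ".join(str(label).strip().lower().split())


@dataclass
class StandardizedEvent:
    """Outcome of standardizing one raw coded event."""

    raw_code: str
    coding_system: str
    entity_label: str  # UNMAPPED on lookup miss
    entity_type: str

    @property
    def mapped(self) -> bool:
        return self.entity_label != UNMAPPED


@dataclass
class CodeListTable:
    """In-memory reference code lists table with (system, code, type) lookup."""

    frame: pd.DataFrame
    _lookup: dict[tuple[str, str, str], str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for row in self.frame.itertuples(index=False):
            system = str(row.coding_system).strip()
            label = normalize_label(row.entity_label)
            etype = str(row.entity_type).strip()
            code = normalize_code(row.code)
            keys = {code}
            # dot-insensitive matching for ICD-style codes
            if "." in code:
                keys.add(code.replace(".", ""))
            for key in keys:
                self._lookup.setdefault((system, key, etype), label)

    def __len__(self) -> int:
        return len(self.frame)

    def entity_labels(self, entity_type: str | None = None) -> set[str]:
        frame = self.frame
        if entity_type is not None:
            frame = frame[frame["entity_type"] == entity_type]
        return {normalize_label(x) for x in frame["entity_label"]}

    def standardize_event(
        self, code: str, coding_system: str, entity_type: str
    ) -> StandardizedEvent:
        """Exact-match entity lookup; UNMAPPED on miss (misses are data)."""
        norm = normalize_code(code)
        label = self._lookup.get((coding_system, norm, entity_type))
        if label is None and "." in norm:
            label = self._lookup.get((coding_system, norm.replace(".", ""), entity_type))
        return StandardizedEvent(
            raw_code=str(code),
            coding_system=coding_system,
            entity_label=label if label is not None else UNMAPPED,
            entity_type=entity_type,
        )


def _conflicts(frame: pd.DataFrame) -> pd.DataFrame:
    """(system, code, type) keys mapped to more than one normalized label."""
    work = frame.assign(
        _code=frame["code"].map(normalize_code),
        _label=frame["entity_label"].map(normalize_label),
    )
    grouped = work.groupby(["coding_system", "_code", "entity_type"])["_label"].nunique()
    bad = grouped[grouped > 1]
    return bad.reset_index().rename(columns={"_label": "n_labels"})


def load_code_lists(path: str | Path) -> CodeListTable:
    """Load the reference code lists table from a delimited file.

    Raises :class:`CodeListValidationError` if the same (coding_system, code,
    entity_type) maps to conflicting entity labels.
    """
    frame = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise CodeListValidationError(f"code list file missing columns: {missing}")
    empty_label = frame["entity_label"].str.strip() == ""
    if empty_label.any():
        raise CodeListValidationError(
            f"{int(empty_label.sum())} code list row(s) with empty entity_label"
        )
    conflicts = _conflicts(frame)
    if len(conflicts):
        keys = conflicts[["coding_system", "_code"]].values.tolist()
        raise CodeListValidationError(
            f"conflicting entity labels for codes: {keys}"
        )
    return CodeListTable(frame=frame)


def validate_code_lists(table: CodeListTable) -> pd.DataFrame:
    """Confirmation pass over a loaded table: returns a findings report.

    Findings: conflicting duplicates, exact duplicate rows, labels needing
    normalization, and codes appearing under multiple entity types.
    """
    frame = table.frame
    findings: list[dict[str, str]] = []
    for row in _conflicts(frame).itertuples(index=False):
        findings.append(
            {
                "finding": "conflict",
                "detail": f"{row.coding_system} {row._code} ({row.entity_type}) "
                f"maps to {row.n_labels} labels",
            }
        )
    dup = frame.duplicated()
    if dup.any():
        findings.append(
            {"finding": "duplicate_rows", "detail": f"{int(dup.sum())} exact duplicates"}
        )
    unnormalized = frame["entity_label"] != frame["entity_label"].map(normalize_label)
    for _, row in frame[unnormalized].iterrows():
        findings.append(
            {
                "finding": "label_normalization",
                "detail": f"label {row['entity_label']!r} not in normalized form",
            }
        )
    multi = (
        frame.assign(_code=frame["code"].map(normalize_code))
        .groupby(["coding_system", "_code"])["entity_type"]
        .nunique()
    )
    for (system, code), n in multi[multi > 1].items():
        findings.append(
            {
                "finding": "multi_entity_type",
                "detail": f"{system} {code} used under {n} entity types",
            }
        )
    return pd.DataFrame(findings, columns=["finding", "detail"])


def standardize_frame(
    frame: pd.DataFrame,
    table: CodeListTable,
    code_column: str,
    system_column: str,
    entity_type: str,
) -> pd.Series:
    """Vectorized standardization of a column of raw codes to entity labels."""
    return pd.Series(
        [
            table.standardize_event(code, system, entity_type).entity_label
            for code, system in zip(frame[code_column], frame[system_column])
        ],
        index=frame.index,
        dtype=object,
    )
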