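"""Estimated glomerular filtration rate (eGFR) from serum creatinine.

Two creatinine-based equations, both returning eGFR in mL/min/1.73 m^2:

* CKD-EPI (2009) *without race* — the race multiplier is omitted (set to 1):

      eGFR = 141 * min(Scr/k, 1)^a * max(Scr/k, 1)^-1.209
             * 0.993^age * 1.018 [if female]

  with k = 0.7 (female) / 0.9 (male) and a = -0.329 (female) / -0.411 (male).
  The 2021 race-free refit (142 / -1.200 / 0.9938 / 1.012) ships in the same
  coefficients file under the name CKD_EPI_2021 and can be selected in the
  run configuration.

* Matsuo et al. (2009), the Japanese Society of Nephrology equation adjusted
  to standard physique, used for Japanese sources:

      eGFR = 194 * Scr^-1.094 * age^-0.287 * 0.739 [if female]

Serum creatinine must already be standardized to mg/dL. Coefficients live in
a reference CSV rather than code so either CKD-EPI variant — or a future
equation — can be swapped without touching the implementation.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Mapping

import pandas as pd

from .config import ConfigurationError, EgfrConfig

CKD_EPI_NO_RACE = "CKD_EPI_NO_RACE"
CKD_EPI_2021 = "CKD_EPI_2021"
MATSUO = "MATSUO"


class InvalidInputError(ValueError):
    """Creatinine/age/sex outside the equations' domain."""


def load_egfr_coefficients(path: str | Path) -> dict[str, dict[str, float]]:
    frame = pd.read_csv(path)
    out: dict[str, dict[str, float]] = {}
    for row in frame.itertuples(index=False):
        out.setdefault(row.equation, {})[row.parameter] = float(row.value)
    return out


def _check_inputs(scr: float, age: float, sex: str, config: EgfrConfig) -> str:
    sex = str(sex).strip().lower()
    if sex not in ("female", "male"):
        raise InvalidInputError(f"sex must be female/male, got {sex!r}")
    if not scr > 0:
        raise InvalidInputError(f"serum creatinine must be positive, got {scr}")
    if not (config.age_min <= age <= config.age_max):
        raise InvalidInputError(
            f"age {age} outside [{config.age_min}, {config.age_max}]"
        )
    return sex


def egfr_ckdepi_no_race(
    scr: float,
    age: float,
    sex: str,
    coefficients: Mapping[str, float] | None = None,
    config: EgfrConfig | None = None,
) -> float:
    """CKD-EPI creatinine eGFR with the race multiplier omitted.

    Parameters: scr in mg/dL, age in years, sex "female"/"male".
    """
    config = config or EgfrConfig()
    sex = _check_inputs(scr, age, sex, config)
    c = coefficients or _DEFAULT_COEFFICIENTS[CKD_EPI_NO_RACE]
    kappa = c["kappa_female"] if sex == "female" else c["kappa_male"]
    alpha = c["alpha_female"] if sex == "female" else c["alpha_male"]
    ratio = scr / kappa
    value = (
        c["intercept"]
        * min(ratio, 1.0) ** alpha
        * max(ratio, 1.0) ** c["max_exponent"]
        * c["age_base"] ** age
    )
    if sex == "female":
        value *= c["female_multiplier"]
    return value


def egfr_matsuo(
    scr: float,
    age: float,
    sex: str,
    coefficients: Mapping[str, float] | None = None,
    config: EgfrConfig | None = None,
) -> float:
    """Matsuo (Japanese) creatinine eGFR, standard-physique adjusted."""
    config = config or EgfrConfig()
    sex = _check_inputs(scr, age, sex, config)
    c = coefficients or _DEFAULT_COEFFICIENTS[MATSUO]
    value = c["scale"] * scr ** c["scr_exponent"] * age ** c["age_exponent"]
    if sex == "female":
        value *= c["female_multiplier"]
    return value


def compute_egfr(
    equation: str,
    scr: float,
    age: float,
    sex: str,
    coefficients: Mapping[str, Mapping[str, float]] | None = None,
    config: EgfrConfig | None = None,
) -> float:
    table = coefficients or _DEFAULT_COEFFICIENTS
    if equation == MATSUO:
        return egfr_matsuo(scr, age, sex, table[MATSUO], config)
    if equation in (CKD_EPI_NO_RACE, CKD_EPI_2021):
        return egfr_ckdepi_no_race(scr, age, sex, table[equation], config)
    raise ConfigurationError(f"unknown eGFR equation: {equation!r}")


def invert_egfr(
    equation: str,
    egfr: float,
    age: float,
    sex: str,
    coefficients: Mapping[str, Mapping[str, float]] | None = None,
) -> float:
    """Serum creatinine (mg/dL) that yields a target eGFR — exact inversion.

    Both equations are strictly decreasing in creatinine, so the inverse is
    unique. Used by the synthetic generator to plant patients at precise eGFR
    levels.
    """
    table = coefficients or _DEFAULT_COEFFICIENTS
    sex = str(sex).strip().lower()
    c = table[equation]
    if equation == MATSUO:
        base = c["scale"] * age ** c["age_exponent"]
        if sex == "female":
            base *= c["female_multiplier"]
        return (egfr / base) ** (1.0 / c["scr_exponent"])
    kappa = c["kappa_female"] if sex == "female" else c["kappa_male"]
    alpha = c["alpha_female"] if sex == "female" else c["alpha_male"]
    base = c["intercept"] * c["age_base"] ** age
    if sex == "female":
        base *= c["female_multiplier"]
    # try the scr > kappa branch first (the CKD-relevant one)
    scr = kappa * (egfr / base) ** (1.0 / c["max_exponent"])
    if scr >= kappa:
        return scr
    return kappa * (egfr / base) ** (1.0 / alpha)


def select_equation(country: str, config: EgfrConfig) -> str:
    return config.equation_by_country.get(
        str(country).strip().upper(), config.default_equation
    )


def compute_egfr_series(
    labs: pd.DataFrame,
    demographics: pd.DataFrame,
    config: EgfrConfig | None = None,
    coefficients: Mapping[str, Mapping[str, float]] | None = None,
    analyte: str = "creatinine",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One eGFR row per standardized creatinine record.

    Sources are routed to an equation by country (JP -> Matsuo by default).
    Age at measurement uses the mid-year convention: measurement year minus
    birth year, since anonymized sources rarely carry exact birth dates.
    Records with missing sex/birth year or out-of-domain inputs are skipped
    with a ledger entry rather than aborting the run.

    Returns ``(egfr_table, skip_ledger)``.
    """
    config = config or EgfrConfig()
    table = coefficients or _DEFAULT_COEFFICIENTS
    creat = labs[
        (labs["analyte"] == analyte)
        & (labs["disposition"].astype(str).str.startswith("standardized"))
    ]
    demo = demographics.set_index("patient_id")
    rows, skipped = [], []
    for rec in creat.itertuples(index=False):
        pid = rec.patient_id
        if pid not in demo.index:
            skipped.append({"patient_id": pid, "record_id": rec.record_id,
                            "reason": "missing_demographics"})
            continue
        person = demo.loc[pid]
        sex = str(person["sex"]).strip().lower()
        birth_year = person["birth_year"]
        if sex not in ("female", "male") or pd.isna(birth_year):
            skipped.append({"patient_id": pid, "record_id": rec.record_id,
                            "reason": "missing_sex_or_birth_year"})
            continue
        date = dt.date.fromisoformat(str(rec.event_date))
        age = date.year - int(birth_year)
        equation = select_equation(person["country"], config)
        try:
            value = compute_egfr(equation, float(rec.std_value), age, sex,
                                 table, config)
        except InvalidInputError as exc:
            skipped.append({"patient_id": pid, "record_id": rec.record_id,
                            "reason": f"invalid_input: {exc}"})
            continue
        rows.append(
            {
                "patient_id": pid,
                "date": str(rec.event_date),
                "egfr": value,
                "equation": equation,
                "scr_mg_dl": float(rec.std_value),
                "data_source_name": rec.data_source_name,
                "record_id": rec.record_id,
            }
        )
    egfr_cols = ["patient_id", "date", "egfr", "equation", "scr_mg_dl",
                 "data_source_name", "record_id"]
    skip_cols = ["patient_id", "record_id", "reason"]
    return (
        pd.DataFrame(rows, columns=egfr_cols),
        pd.DataFrame(skipped, columns=skip_cols),
    )


def _builtin_coefficients() -> dict[str, dict[str, float]]:
    import importlib.resources

    path = importlib.resources.files("renalcdm.data") / "egfr_coefficients.csv"
    return load_egfr_coefficients(str(path))


_DEFAULT_COEFFICIENTS = _builtin_coefficients()
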