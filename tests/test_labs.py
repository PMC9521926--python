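"""Laboratory unit mapping, conversion, inference and stream harmonization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import renalcdm as r

from renalcdm.labs import (
    EXCLUDED_RANGE,
    EXCLUDED_UNIT,
    STANDARDIZED,
    STANDARDIZED_INFERRED,
    UNKNOWN,
)


class TestAcceptableUnitMapping:
    @pytest.mark.parametrize(
        "raw,analyte,expected",
        [
            ("umol/L", "creatinine", "umol/L"),
            ("UMOL/L", "creatinine", "umol/L"),
            ("μmol/L", "creatinine", "umol/L"),
            ("MG/DL", "creatinine", "mg/dL"),
            ("mmol", "creatinine", "mmol/L"),  # observed unit-string variant
            ("g/dl", "hemoglobin", "g/dL"),
            ("", "hemoglobin", UNKNOWN),
            ("furlongs", "creatinine", UNKNOWN),
        ],
    )
    def test_synonym_lookup(self, analytes, raw, analyte, expected):
        assert r.map_to_acceptable_unit(raw, analyte, analytes) == expected

    def test_unknown_analyte_is_configuration_error(self, analytes):
        with pytest.raises(r.ConfigurationError):
            r.map_to_acceptable_unit("mg/dL", "troponin", analytes)


class TestConversion:
    def test_creatinine_umol_to_mgdl(self, analytes):
        value, unit = r.convert_to_standard(79.58, "umol/L", "creatinine", analytes)
        assert unit == "mg/dL"
        assert value == pytest.approx(79.58 / 88.42, rel=1e-12)
        assert value == pytest.approx(0.90, abs=5e-4)

    def test_hemoglobin_gl_to_gdl_factor_of_ten(self, analytes):
        assert r.convert_to_standard(140, "g/L", "hemoglobin", analytes)[0] == \
            pytest.approx(14.0)

    def test_standard_unit_is_identity(self, analytes):
        assert r.convert_to_standard(0.9, "mg/dL", "creatinine", analytes)[0] == 0.9

    def test_round_trip_all_units_within_1e9_relative(self, analytes):
        for spec in analytes:
            for au in spec.acceptable_units:
                for std in (spec.plausible_low, 0.5 * (spec.plausible_low +
                                                       spec.plausible_high),
                            spec.plausible_high):
                    raw = r.to_acceptable(std, au.unit, spec.analyte, analytes)
                    back, _ = r.convert_to_standard(raw, au.unit, spec.analyte,
                                                    analytes)
                    assert back == pytest.approx(std, rel=1e-9)


class TestUnitInference:
    def test_hemoglobin_3_to_22_infers_gdl(self, analytes):
        rng = np.random.default_rng(0)
        batch = rng.uniform(3, 22, size=200)
        assert r.infer_unit(batch, "hemoglobin", analytes) == "g/dL"

    def test_hemoglobin_scaled_tenfold_infers_gl(self, analytes):
        rng = np.random.default_rng(0)
        batch = rng.uniform(3, 22, size=200) * 10
        assert r.infer_unit(batch, "hemoglobin", analytes) == "g/L"

    def test_batch_below_minimum_returns_none(self, analytes):
        assert r.infer_unit([12.0] * 49, "hemoglobin", analytes) is None

    def test_ambiguous_batch_straddling_two_windows_returns_none(self, analytes):
        # values plausible under both g/dL (3-22) and mmol/L (1.86-13.65)
        batch = np.linspace(4, 13, 100)
        assert r.infer_unit(batch, "hemoglobin", analytes) is None

    def test_inference_recovers_hidden_unit_when_windows_disjoint(self, analytes):
        """For every unit whose raw-scale window is disjoint from all others,
        a batch drawn inside it must be recovered (soundness)."""
        rng = np.random.default_rng(42)
        for spec in analytes:
            windows = {
                au.unit: ((spec.plausible_low - au.offset) / au.factor,
                          (spec.plausible_high - au.offset) / au.factor)
                for au in spec.acceptable_units
            }
            for unit, (lo, hi) in windows.items():
                disjoint = all(
                    hi < olo or lo > ohi
                    for other, (olo, ohi) in windows.items() if other != unit
                )
                if not disjoint:
                    continue
                batch = rng.uniform(lo, hi, size=100)
                assert r.infer_unit(batch, spec.analyte, analytes) == unit, \
                    (spec.analyte, unit)


def _stream(values, units, analyte="creatinine", source="s1"):
    n = len(values)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "analyte": [analyte] * n,
            "raw_value": values,
            "raw_unit": units,
            "data_source_name": [source] * n,
            "record_id": [f"R{i}" for i in range(n)],
        }
    )


class TestHarmonizeStream:
    def test_dispositions_and_conservation(self, analytes):
        stream = _stream([0.9, 25.0, 1.1], ["mg/dL", "mg/dL", "furlongs"])
        table, ledger = r.harmonize_lab_stream(stream, analytes)
        assert list(table["disposition"]) == [STANDARDIZED, EXCLUDED_RANGE,
                                              EXCLUDED_UNIT]
        assert len(table) == 3 and len(ledger) == 2
        standardized = (table["disposition"].str.startswith("standardized")).sum()
        assert standardized + len(ledger) == len(stream)

    def test_raw_value_and_unit_preserved_on_every_row(self, analytes):
        stream = _stream([0.9, 500.0], ["umol/L", "umol/L"])
        table, _ = r.harmonize_lab_stream(stream, analytes)
        assert list(table["raw_value"]) == [0.9, 500.0]
        assert list(table["raw_unit"]) == ["umol/L", "umol/L"]
        # standardized rows carry both raw and standardized value+unit
        row = table.iloc[1]
        assert row["disposition"] == STANDARDIZED
        assert row["std_unit"] == "mg/dL"

    def test_unknown_unit_batch_is_inferred_per_source(self, analytes):
        rng = np.random.default_rng(1)
        stream = _stream(list(rng.uniform(30, 220, size=80)), [""] * 80,
                         analyte="hemoglobin")
        table, ledger = r.harmonize_lab_stream(stream, analytes)
        assert (table["disposition"] == STANDARDIZED_INFERRED).all()
        assert (table["std_unit"] == "g/dL").all()
        assert len(ledger) == 0

    def test_unverifiable_small_batch_excluded(self, analytes):
        stream = _stream([12.0] * 5, [""] * 5, analyte="hemoglobin")
        table, ledger = r.harmonize_lab_stream(stream, analytes)
        assert (table["disposition"] == EXCLUDED_UNIT).all()
        assert len(ledger) == 5

    def test_all_clean_stream_has_empty_ledger(self, analytes):
        stream = _stream([0.8, 1.0, 1.4], ["mg/dL"] * 3)
        _, ledger = r.harmonize_lab_stream(stream, analytes)
        assert len(ledger) == 0

    def test_non_finite_value_excluded_as_invalid(self, analytes):
        stream = _stream([float("nan")], ["mg/dL"])
        table, ledger = r.harmonize_lab_stream(stream, analytes)
        assert ledger.iloc[0]["reason"] == "excluded_invalid_value"

    @given(widen=st.floats(min_value=0.0, max_value=50.0))
    def test_widening_plausible_range_never_decreases_standardized_count(
        self, widen
    ):
        import importlib.resources

        base = importlib.resources.files("renalcdm.data")
        analytes = r.load_analyte_specs(str(base / "analytes.csv"),
                                        str(base / "acceptable_units.csv"))
        stream = _stream([0.1, 0.9, 5.0, 19.0, 30.0, 60.0],
                         ["mg/dL"] * 6)
        table0, _ = r.harmonize_lab_stream(stream, analytes)
        n0 = table0["disposition"].str.startswith("standardized").sum()
        spec = analytes.spec("creatinine")
        spec.plausible_high += widen
        try:
            table1, _ = r.harmonize_lab_stream(stream, analytes)
        finally:
            spec.plausible_high -= widen
        n1 = table1["disposition"].str.startswith("standardized").sum()
        assert n1 >= n0
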