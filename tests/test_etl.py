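"""Mapping validation, idempotence, conservation, federation, traceability."""

import hashlib
from pathlib import Path

import pandas as pd
import pytest

import renalcdm as r
from renalcdm.etl import ABSENT, load_mapping, validate_mapping


def _checksums(root: Path) -> dict[str, str]:
    return {
        str(p.relative_to(root)): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(root.rglob("*.csv"))
    }


@pytest.fixture(scope="module")
def built(tmp_path_factory):
    root = tmp_path_factory.mktemp("etl")
    gen = r.GeneratorConfig(seed=3, sources=r.default_sources(300))
    r.generate(gen, root / "raw")
    cfg = r.make_run_config(gen, root / "raw", root / "cdm")
    reports, failures = r.build_all(cfg)
    assert not failures
    store = r.TableStore(cfg, r.register_tables(cfg))
    return {"gen": gen, "cfg": cfg, "store": store, "root": root,
            "reports": reports}


class TestMappingValidation:
    def test_generated_mappings_are_clean(self, built):
        cfg = built["cfg"]
        registry = r.register_tables(cfg)
        for src in cfg.sources:
            staged = r.extract(src.name, cfg)
            mapping = load_mapping(Path(src.path) / "mapping.csv")
            findings = validate_mapping(mapping, staged, registry)
            assert len(findings) == 0, findings.to_string()

    def test_missing_source_column_flagged_with_rule_identity(self, built):
        cfg = built["cfg"]
        src = cfg.sources[0]
        staged = r.extract(src.name, cfg)
        mapping = load_mapping(Path(src.path) / "mapping.csv")
        mapping.loc[0, "source_column"] = "nonexistent_col"
        findings = validate_mapping(mapping, staged, r.register_tables(cfg))
        assert (findings["finding"] == "missing_source_column").sum() == 1
        assert "nonexistent_col" in findings.iloc[0]["detail"]

    def test_uncovered_required_target_column_flagged(self, built):
        cfg = built["cfg"]
        src = cfg.sources[0]
        staged = r.extract(src.name, cfg)
        mapping = load_mapping(Path(src.path) / "mapping.csv")
        mapping = mapping[~((mapping["target_table"] == "diagnosis")
                            & (mapping["target_column"] == "event_date"))]
        findings = validate_mapping(mapping, staged, r.register_tables(cfg))
        assert "diagnosis.event_date" in set(findings["detail"])

    def test_absent_marker_silences_coverage_finding(self, built):
        cfg = built["cfg"]
        src = cfg.sources[0]
        staged = r.extract(src.name, cfg)
        mapping = load_mapping(Path(src.path) / "mapping.csv")
        idx = ((mapping["target_table"] == "diagnosis")
               & (mapping["target_column"] == "event_date"))
        mapping.loc[idx, "source_column"] = ABSENT
        findings = validate_mapping(mapping, staged, r.register_tables(cfg))
        assert "diagnosis.event_date" not in set(findings["detail"])

    def test_unknown_transform_flagged(self, built):
        cfg = built["cfg"]
        src = cfg.sources[0]
        staged = r.extract(src.name, cfg)
        mapping = load_mapping(Path(src.path) / "mapping.csv")
        mapping.loc[0, "transform_id"] = "frobnicate"
        findings = validate_mapping(mapping, staged, r.register_tables(cfg))
        assert (findings["finding"] == "unknown_transform").any()


class TestConservationAndTraceability:
    def test_staged_equals_loaded_plus_ledger_per_table(self, built):
        for report in built["reports"]:
            for table, counts in report.table_counts.items():
                assert counts["input"] == counts["output"] + counts["excluded"], \
                    (report.data_source_name, table)

    def test_every_loaded_row_joins_back_to_one_staged_row(self, built):
        store, cfg = built["store"], built["cfg"]
        src = cfg.sources[0].name
        staged_labs = pd.read_csv(
            store.root / "staging" / src / "labs.csv", dtype=str)
        loaded = store.read_table(src, "laboratory")
        staged_ids = staged_labs["claim_id"]
        assert staged_ids.is_unique
        assert set(loaded["record_id"]) <= set(staged_ids)

    def test_raw_value_and_unit_preserved_in_cdm(self, built):
        store, cfg = built["store"], built["cfg"]
        src = cfg.sources[0].name
        staged = pd.read_csv(store.root / "staging" / src / "labs.csv",
                             dtype=str).set_index("claim_id")
        loaded = store.read_table(src, "laboratory")
        sample = loaded.head(50)
        for rec in sample.itertuples(index=False):
            raw_row = staged.loc[rec.record_id]
            assert float(raw_row["result_value"]) == float(rec.raw_value)
            assert str(raw_row["result_unit"]) == str(rec.raw_unit)

    def test_coded_event_standardized_to_entity_label(self, built):
        store = built["store"]
        diag = store.read_table("us_claims", "diagnosis")
        assert len(diag)
        assert "type 2 diabetes" in set(diag["entity_label"])
        # entity labels only, never foreign codes
        assert not set(diag["entity_label"]) & {"E11.34", "C100112"}

    def test_unparseable_date_goes_to_ledger(self, tmp_path, built):
        import shutil

        cfg0 = built["cfg"]
        raw = tmp_path / "raw"
        shutil.copytree(Path(cfg0.sources[0].path), raw / "us_claims")
        diag = pd.read_csv(raw / "us_claims" / "diagnoses.csv", dtype=str)
        diag.loc[0, "svc_date"] = "not-a-date"
        diag.to_csv(raw / "us_claims" / "diagnoses.csv", index=False)
        cfg = r.RunConfig(
            storage_root=str(tmp_path / "cdm"),
            sources=[r.SourceConfig(name="us_claims", country="US",
                                    path=str(raw / "us_claims"))],
        )
        r.run_source("us_claims", cfg)
        ledger = pd.read_csv(tmp_path / "cdm" / "ledger" / "us_claims.csv")
        assert (ledger["reason"] == "date_parse_error").sum() == 1


class TestIdempotenceAndFederation:
    def test_two_builds_with_fixed_clock_are_byte_identical(self, tmp_path):
        gen = r.GeneratorConfig(seed=9, sources=r.default_sources(200))
        r.generate(gen, tmp_path / "raw")
        cfg1 = r.make_run_config(gen, tmp_path / "raw", tmp_path / "cdm1")
        cfg2 = r.make_run_config(gen, tmp_path / "raw", tmp_path / "cdm2")
        r.build_all(cfg1)
        r.build_all(cfg2)
        assert _checksums(Path(cfg1.storage_root)) == \
            _checksums(Path(cfg2.storage_root))

    def test_rerun_replaces_partition_without_duplicates(self, built):
        cfg, store = built["cfg"], built["store"]
        before = len(store.read_table("uk_ehr", "diagnosis"))
        r.refresh_source("uk_ehr", cfg)
        after = len(store.read_table("uk_ehr", "diagnosis"))
        assert before == after

    def test_refresh_of_one_source_leaves_others_bit_identical(self, built):
        store, cfg = built["store"], built["cfg"]
        watched = [p for p in sorted(store.root.rglob("*.csv"))
                   if "uk_ehr" not in p.name and "uk_ehr" not in str(p.parent)
                   and "combined" not in str(p)]
        before = {p: hashlib.sha256(p.read_bytes()).hexdigest() for p in watched}
        r.refresh_source("uk_ehr", cfg)
        after = {p: hashlib.sha256(p.read_bytes()).hexdigest() for p in watched}
        assert before == after

    def test_remove_source_drops_partitions_and_combined_rows(self, tmp_path):
        gen = r.GeneratorConfig(seed=13, sources=r.default_sources(200))
        r.generate(gen, tmp_path / "raw")
        cfg = r.make_run_config(gen, tmp_path / "raw", tmp_path / "cdm")
        r.build_all(cfg)
        store = r.TableStore(cfg, r.register_tables(cfg))
        assert "jp_registry" in store.source_names()
        r.remove_source("jp_registry", cfg)
        assert "jp_registry" not in store.source_names()
        combined = pd.read_csv(store.combined_path("diagnosis"))
        assert "jp_registry" not in set(combined["data_source_name"])

    def test_missing_source_fails_alone_others_continue(self, tmp_path):
        gen = r.GeneratorConfig(seed=17, sources=r.default_sources(120))
        r.generate(gen, tmp_path / "raw")
        cfg = r.make_run_config(gen, tmp_path / "raw", tmp_path / "cdm")
        cfg.sources[1].path = str(tmp_path / "raw" / "nowhere")
        reports, failures = r.build_all(cfg)
        assert set(failures) == {"uk_ehr"}
        assert len(reports) == 3
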