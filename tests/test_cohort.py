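"""Cohort criteria, oracle equivalence, and federated combination."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

import renalcdm as r
from renalcdm.cohort import CHRONIC_RRT, DX_CODE, EGFR_PAIR
from renalcdm.config import CohortCriteriaConfig

CFG = CohortCriteriaConfig()


def _dx(label, date):
    return {"entity_label": label, "event_date": date}


class TestCriterionDx:
    def test_stage_3a_diagnosis_qualifies_on_its_date(self):
        q = r.criterion_dx(pd.DataFrame([_dx("ckd stage 3a", "2015-03-02")]), CFG)
        assert q.criterion == DX_CODE and q.date == dt.date(2015, 3, 2)

    def test_stage_2_only_does_not_qualify(self):
        assert r.criterion_dx(pd.DataFrame([_dx("ckd stage 2", "2015-03-02")]),
                              CFG) is None

    def test_no_events_is_none(self):
        assert r.criterion_dx(pd.DataFrame(columns=["entity_label", "event_date"]),
                              CFG) is None

    def test_earliest_qualifying_diagnosis_wins(self):
        events = pd.DataFrame([_dx("ckd stage 4", "2016-01-01"),
                               _dx("kidney failure", "2014-06-01")])
        assert r.criterion_dx(events, CFG).date == dt.date(2014, 6, 1)


def _series(*pairs):
    return [(dt.date.fromisoformat(d), v) for d, v in pairs]


class TestCriterionEgfrPair:
    def test_gap_120_days_qualifies_on_second_measure(self):
        q = r.criterion_egfr_pair(
            _series(("2009-01-01", 70), ("2009-05-01", 72)), CFG)
        assert q.date == dt.date(2009, 5, 1)

    def test_gap_45_days_does_not_qualify(self):
        assert r.criterion_egfr_pair(
            _series(("2009-01-01", 70), ("2009-02-15", 60)), CFG) is None

    def test_gap_beyond_maximum_does_not_qualify(self):
        assert r.criterion_egfr_pair(
            _series(("2009-01-01", 70), ("2012-01-01", 70)), CFG) is None

    def test_first_measure_before_window_start_disqualifies_pair(self):
        assert r.criterion_egfr_pair(
            _series(("2007-06-01", 70), ("2008-06-01", 70)), CFG) is None

    def test_values_at_threshold_do_not_count(self):
        assert r.criterion_egfr_pair(
            _series(("2009-01-01", 75.0), ("2009-06-01", 75.0)), CFG) is None

    def test_intermediate_high_value_does_not_disqualify(self):
        q = r.criterion_egfr_pair(
            _series(("2009-01-01", 70), ("2009-03-01", 90), ("2009-06-01", 70)),
            CFG)
        assert q is not None and q.date == dt.date(2009, 6, 1)

    def test_agrees_with_exhaustive_all_pairs_oracle(self):
        """1,000 random series of length <= 50: zero disagreements with a
        brute-force scan over every index pair."""
        rng = np.random.default_rng(2024)
        start = dt.date(2005, 1, 1).toordinal()
        disagreements = 0
        for _ in range(1000):
            n = int(rng.integers(0, 51))
            dates = [dt.date.fromordinal(int(o))
                     for o in rng.integers(start, start + 5500, size=n)]
            values = rng.uniform(30, 120, size=n)
            series = list(zip(dates, values))
            mine = r.criterion_egfr_pair(series, CFG)
            oracle = _oracle_pair(series, CFG)
            if (mine is None) != (oracle is None):
                disagreements += 1
            elif mine is not None and mine.date != oracle:
                disagreements += 1
        assert disagreements == 0


def _oracle_pair(series, cfg):
    """Independent exhaustive scan over every ordered index pair."""
    best = None
    for i in range(len(series)):
        for j in range(len(series)):
            d1, v1 = series[i]
            d2, v2 = series[j]
            if d1 >= d2:
                continue
            if v1 >= cfg.egfr_threshold or v2 >= cfg.egfr_threshold:
                continue
            if d1 < cfg.window_start or d2 < cfg.window_start:
                continue
            gap = (d2 - d1).days
            if not (cfg.min_gap_days < gap <= cfg.max_gap_days):
                continue
            if best is None or (d2, d1) < best:
                best = (d2, d1)
    return best[0] if best else None


def _rrt(dates, label="hemodialysis"):
    return pd.DataFrame([{"entity_label": label, "event_date": d} for d in dates])


class TestCriterionChronicRrt:
    def test_weekly_sessions_spanning_42_days_qualify(self):
        days = [dt.date(2010, 1, 1) + dt.timedelta(days=k) for k in range(0, 43, 7)]
        q = r.criterion_chronic_rrt(_rrt([d.isoformat() for d in days]), CFG)
        assert q.criterion == CHRONIC_RRT and q.date == dt.date(2010, 1, 1)

    def test_single_event_does_not_qualify(self):
        assert r.criterion_chronic_rrt(
            _rrt(["2010-01-01"], "peritoneal dialysis"), CFG) is None

    def test_two_events_400_days_apart_are_two_zero_length_episodes(self):
        assert r.criterion_chronic_rrt(
            _rrt(["2010-01-01", "2011-02-05"]), CFG) is None

    def test_modalities_are_not_mixed_across_episodes(self):
        events = pd.concat([
            _rrt(["2010-01-01", "2010-01-20"], "hemodialysis"),
            _rrt(["2010-02-10", "2010-02-20"], "peritoneal dialysis"),
        ])
        # each modality spans < 30 days on its own
        assert r.criterion_chronic_rrt(events, CFG) is None

    def test_single_chronic_coded_event_qualifies(self):
        q = r.criterion_chronic_rrt(
            _rrt(["2010-05-01"], "chronic hemodialysis"), CFG)
        assert q is not None and q.date == dt.date(2010, 5, 1)


class TestMonotonicity:
    def test_adding_sub_threshold_measure_never_removes_qualification(self):
        base = _series(("2009-01-01", 70), ("2009-05-01", 72))
        assert r.criterion_egfr_pair(base, CFG) is not None
        rng = np.random.default_rng(5)
        for _ in range(50):
            extra = (dt.date(2008, 1, 1)
                     + dt.timedelta(days=int(rng.integers(0, 4000))),
                     float(rng.uniform(10, 74.9)))
            assert r.criterion_egfr_pair(base + [extra], CFG) is not None

    def test_raising_threshold_never_loses_a_pair(self):
        series = _series(("2009-01-01", 70), ("2009-05-01", 74))
        tight = CohortCriteriaConfig(egfr_threshold=72)
        loose = CohortCriteriaConfig(egfr_threshold=80)
        assert r.criterion_egfr_pair(series, tight) is None
        assert r.criterion_egfr_pair(series, loose) is not None


class TestBuildAndCombine:
    def test_ground_truth_membership_recovered_exactly(self, small_study):
        disc = r.ground_truth_check(small_study["store"], small_study["cfg"],
                                    small_study["raw"])
        assert len(disc) == 0, disc.to_string()

    def test_multi_criteria_patient_appears_once_with_all_criteria(self, small_study):
        truth = r.load_ground_truth(small_study["raw"])["patients"]
        multi = truth[truth["criteria"].str.count(r"\|") == 2]
        assert len(multi) > 0
        cohort = pd.concat(
            [r.read_cohort(small_study["store"], s.name)
             for s in small_study["cfg"].sources], ignore_index=True)
        for rec in multi.itertuples(index=False):
            rows = cohort[cohort["patient_id"] == rec.patient_id]
            assert len(rows) == 1
            assert rows.iloc[0]["qualifying_criteria"] == \
                "DX_CODE|EGFR_PAIR|CHRONIC_RRT"

    def test_combined_excludes_non_poolable_but_reports_it(self, small_study):
        store, cfg = small_study["store"], small_study["cfg"]
        combined, non_poolable = r.combine_cohorts(store, cfg)
        assert non_poolable == ["lc_panel"]
        assert "lc_panel" not in set(combined["data_source_name"])
        assert len(r.read_cohort(store, "lc_panel")) > 0  # reported side-by-side

    def test_duplicate_membership_across_sources_is_validation_failure(
        self, tmp_path
    ):
        cfg = r.RunConfig(
            storage_root=str(tmp_path),
            sources=[r.SourceConfig(name="a"), r.SourceConfig(name="b")],
        )
        store = r.TableStore(cfg, r.register_tables(cfg))
        member = pd.DataFrame([{
            "patient_id": "P1", "data_source_name": "a",
            "qualifying_criteria": "DX_CODE", "qualifying_dates": "2015-01-01",
            "index_date": "2015-01-01", "poolable": True,
        }])
        (store.root / "cohort").mkdir(parents=True)
        member.to_csv(store.root / "cohort" / "a.csv", index=False)
        member.assign(data_source_name="a").to_csv(
            store.root / "cohort" / "b.csv", index=False)
        with pytest.raises(r.ConfigurationError, match="duplicate"):
            r.combine_cohorts(store, cfg)

    def test_empty_source_yields_empty_but_valid_cohort_table(self, tmp_path):
        cfg = r.RunConfig(storage_root=str(tmp_path),
                          sources=[r.SourceConfig(name="empty_src")])
        store = r.TableStore(cfg, r.register_tables(cfg))
        cohort = r.build_base_cohort(store, "empty_src", cfg)
        assert len(cohort) == 0
        assert list(cohort.columns) == list(
            r.read_cohort(store, "empty_src").columns)
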