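"""Cohort I/O, eligibility screening, and demographic summaries."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from stagecut import (
    RowParseError, SchemaError, read_cohort, screen_cohort,
    screening_criteria, summarize, write_cohort,
)
from helpers import make_cohort, make_record


class TestReadWrite:
    def test_roundtrip_identity(self, tmp_path):
        """write . read is the identity field-for-field, including a
        missing optional tumor size."""
        recs = [
            make_record(0, mln_count=12, lns_examined=30),
            make_record(1, tumor_size_mm=None, sex="female",
                        followup_months=60.0, event=0),
            make_record(2, ethnicity="white", mln_count=7,
                        followup_months=1.5),
        ]
        cohort = make_cohort(recs)
        path = tmp_path / "cohort.csv"
        write_cohort(cohort, path)
        back = read_cohort(path)
        assert len(back) == 3
        assert back.records == recs

    def test_missing_column_is_schema_error(self, tmp_path):
        cohort = make_cohort([make_record(0)])
        path = tmp_path / "cohort.csv"
        write_cohort(cohort, path)
        df = pd.read_csv(path).drop(columns=["mln_count"])
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="mln_count"):
            read_cohort(path)

    def test_malformed_value_names_row(self, tmp_path):
        cohort = make_cohort([make_record(0), make_record(1)])
        path = tmp_path / "cohort.csv"
        write_cohort(cohort, path)
        df = pd.read_csv(path, dtype=str)
        df.loc[1, "mln_count"] = "twelve"
        df.to_csv(path, index=False)
        with pytest.raises(RowParseError, match="row 1"):
            read_cohort(path)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_cohort([make_record(0), make_record(0)])

    def test_mln_exceeding_lns_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_record(0, mln_count=31, lns_examined=30)


class TestScreening:
    def test_boundary_lns_15_excluded(self):
        """Exactly 15 nodes examined fails the > 15 retrieval criterion."""
        cohort = make_cohort([make_record(0, lns_examined=15, mln_count=12)])
        kept, report = screen_cohort(cohort)
        assert len(kept) == 0
        assert report.exclusions["lns_examined_le_15"] == 1

    def test_boundary_lns_16_eligible(self):
        cohort = make_cohort([make_record(0, lns_examined=16, mln_count=12)])
        kept, _ = screen_cohort(cohort)
        assert len(kept) == 1

    def test_followup_below_one_month_excluded(self):
        cohort = make_cohort([make_record(0, followup_months=0.5)])
        kept, report = screen_cohort(cohort)
        assert len(kept) == 0
        assert report.exclusions["survival_lt_1_month"] == 1

    def test_first_failing_criterion_charged(self):
        """A record failing several criteria is charged to the first in
        the fixed order (here: age before M-category)."""
        cohort = make_cohort([make_record(0, age_years=15,
                                          m_category="M1")])
        _, report = screen_cohort(cohort)
        assert report.exclusions["age_under_18"] == 1
        assert report.exclusions["not_m0"] == 0

    def test_toy_batch_counts_match_construction(self):
        """10 records, 4 constructed to fail distinct criteria."""
        recs = [make_record(i) for i in range(6)]
        recs.append(make_record(6, lns_examined=15, mln_count=12))
        recs.append(make_record(7, mln_count=5))
        recs.append(make_record(8, followup_months=0.2))
        recs.append(make_record(9, tumor_size_mm=None))
        kept, report = screen_cohort(make_cohort(recs))
        assert report.n_input == 10
        assert report.n_eligible == 6
        assert len(kept) == 6
        assert report.exclusions["lns_examined_le_15"] == 1
        assert report.exclusions["fewer_than_7_mln"] == 1
        assert report.exclusions["survival_lt_1_month"] == 1
        assert report.exclusions["incomplete_data"] == 1

    def test_missing_field_charged_to_incomplete(self):
        cohort = make_cohort([make_record(0, surgery=None)])
        _, report = screen_cohort(cohort)
        assert report.exclusions["incomplete_data"] == 1

    @given(st.lists(st.sampled_from(
        ["ok", "lns", "mln", "followup", "age", "m1", "surgery",
         "site", "histology", "multiple", "remnant", "size_missing"]),
        min_size=1, max_size=25))
    def test_report_always_reconciles(self, kinds):
        """n_input = n_eligible + sum of exclusion counts, whatever the
        mix of violations."""
        tweak = {
            "ok": {}, "lns": dict(lns_examined=14, mln_count=10),
            "mln": dict(mln_count=3), "followup": dict(followup_months=0.0),
            "age": dict(age_years=12), "m1": dict(m_category="M1"),
            "surgery": dict(surgery="none"),
            "site": dict(primary_site_stomach=False),
            "histology": dict(adenocarcinoma=False),
            "multiple": dict(multiple_primaries=True),
            "remnant": dict(remnant_gastric=True),
            "size_missing": dict(tumor_size_mm=None),
        }
        recs = [make_record(i, **tweak[k]) for i, k in enumerate(kinds)]
        kept, report = screen_cohort(make_cohort(recs))
        assert report.n_input == len(recs)
        assert report.n_eligible == len(kept)
        assert report.n_input == report.n_eligible + sum(
            report.exclusions.values())
        n_ok = sum(1 for k in kinds if k == "ok")
        assert report.n_eligible == n_ok

    def test_criteria_order_is_stable(self):
        order = screening_criteria()
        assert order[0] == "non_gastric_primary"
        assert order[-1] == "incomplete_data"
        assert order.index("lns_examined_le_15") < order.index(
            "fewer_than_7_mln")


class TestSummarize:
    @staticmethod
    def _two_source_cohort():
        recs = []
        i = 0
        for source, male, female in (("SEER", 1024, 809),
                                     ("FMUUH", 674, 246)):
            for sex, count in (("male", male), ("female", female)):
                for _ in range(count):
                    recs.append(make_record(i, source=source, sex=sex))
                    i += 1
        return make_cohort(recs)

    def test_overall_male_percentage(self):
        """1024/1833 + 674/920 male -> 1698 of 2753 = 61.7% overall."""
        summary = summarize(self._two_source_cohort(), by_source=True)
        cat = summary.categorical
        male = cat[(cat.variable == "sex") & (cat.level == "male")].iloc[0]
        assert male["n_overall"] == 1698
        assert male["pct_overall"] == 61.7
        female = cat[(cat.variable == "sex")
                     & (cat.level == "female")].iloc[0]
        assert female["pct_overall"] == 38.3
        assert male["p_value"] < 0.001  # sex mix differs between sources

    def test_single_record_is_100_percent(self):
        summary = summarize(make_cohort([make_record(0)]))
        cat = summary.categorical
        assert (cat[cat.variable == "sex"]["pct_overall"] == 100.0).all()

    def test_identical_proportions_chi2_zero(self):
        recs = []
        i = 0
        for source in ("SEER", "FMUUH"):
            for sex in ("male", "male", "female", "female"):
                recs.append(make_record(i, source=source, sex=sex))
                i += 1
        summary = summarize(make_cohort(recs), by_source=True)
        sexrows = summary.categorical[summary.categorical.variable == "sex"]
        assert np.allclose(sexrows["chi2"], 0.0)
        assert np.allclose(sexrows["p_value"], 1.0)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(5)
        recs = [make_record(i,
                            sex=rng.choice(["male", "female"]),
                            ethnicity=rng.choice(["white", "asian", "black"]),
                            pt_category=rng.choice(["T1", "T3", "T4a"]))
                for i in range(137)]
        summary = summarize(make_cohort(recs))
        for var, grp in summary.categorical.groupby("variable"):
            assert abs(grp["pct_overall"].sum() - 100.0) <= 0.1

    def test_continuous_statistics(self):
        recs = [make_record(i, age_years=a, mln_count=m, lns_examined=40)
                for i, (a, m) in enumerate([(50, 7), (60, 14), (70, 21)])]
        summary = summarize(make_cohort(recs))
        cont = summary.continuous
        age_mean = cont[(cont.variable == "age_years")
                        & (cont.statistic == "mean")].iloc[0]["overall"]
        assert age_mean == 60.0
        mln_med = cont[(cont.variable == "mln_count")
                       & (cont.statistic == "median")].iloc[0]["overall"]
        assert mln_med == 14.0

    def test_empty_cohort_raises(self):
        cohort = make_cohort([make_record(0)])
        cohort.df = cohort.df.iloc[:0]
        with pytest.raises(ValueError):
            summarize(cohort)

    def test_single_source_by_source_raises(self):
        with pytest.raises(ValueError, match="sources"):
            summarize(make_cohort([make_record(0)]), by_source=True)

    def test_mann_whitney_present_for_two_sources(self):
        rng = np.random.default_rng(11)
        recs = [make_record(i, source="SEER",
                            age_years=int(rng.integers(40, 80)))
                for i in range(30)]
        recs += [make_record(100 + i, source="FMUUH",
                             age_years=int(rng.integers(40, 80)))
                 for i in range(30)]
        summary = summarize(make_cohort(recs), by_source=True)
        cont = summary.continuous
        p = cont[cont.variable == "age_years"]["p_value"]
        assert ((0.0 <= p) & (p <= 1.0)).all()
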