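"""Unit conversions, bucketing and descriptive summary tables."""

import numpy as np
import pytest

from helpers import make_report
from pvsignal.cohort import CohortSpec
from pvsignal.descriptives import (
    AGE_SCHEME,
    WEIGHT_SCHEME,
    BucketScheme,
    normalize_age,
    normalize_weight,
    onset_days,
    summarize,
    worst_outcome,
)
from pvsignal.faers_io import ParseWarnings
from pvsignal.synthetic_data import SyntheticConfig, generate


class TestNormalizeAge:
    @pytest.mark.parametrize("value, unit, years", [
        (540, "MON", 45.0),
        (50, "YR", 50.0),
        (5, "DEC", 50.0),
        (104.355, "WK", 2.0),
        (730.5, "DY", 2.0),
    ])
    def test_unit_table(self, value, unit, years):
        assert normalize_age(value, unit) == pytest.approx(years)

    def test_missing_and_negative(self):
        warnings = ParseWarnings()
        assert normalize_age(None, "YR") is None
        assert normalize_age(-1, "YR", warnings) is None
        assert warnings.counts["negative_age"] == 1

    def test_540_months_lands_in_middle_age_bucket(self):
        assert AGE_SCHEME.bucket(normalize_age(540, "MON")) == "45-65"


class TestNormalizeWeight:
    @pytest.mark.parametrize("value, unit, kg", [
        (176, "LBS", 79.832192),
        (65, "KG", 65.0),
        (60000, "GMS", 60.0),
    ])
    def test_unit_table(self, value, unit, kg):
        assert normalize_weight(value, unit) == pytest.approx(kg)

    def test_bucket_assignment(self):
        assert WEIGHT_SCHEME.bucket(normalize_weight(176, "LBS")) == "73-87"
        assert WEIGHT_SCHEME.bucket(normalize_weight(65, "KG")) == "<73"

    def test_nonpositive_is_missing(self):
        warnings = ParseWarnings()
        assert normalize_weight(0, "KG", warnings) is None
        assert warnings.counts["nonpositive_weight"] == 1


class TestBucketScheme:
    def test_edges_must_increase(self):
        with pytest.raises(ValueError):
            BucketScheme("bad", (10.0, 10.0), ("a", "b", "c"))

    def test_exhaustive_and_exclusive_on_real_line(self):
        rng = np.random.default_rng(0)
        for value in rng.uniform(-10, 200, 500):
            labels = [lbl for lbl in AGE_SCHEME.labels
                      if AGE_SCHEME.bucket(float(value)) == lbl]
            assert len(labels) == 1

    def test_age_65_and_66_split_as_labelled(self):
        assert AGE_SCHEME.bucket(65.0) == "45-65"
        assert AGE_SCHEME.bucket(66.0) == "66-75"

    def test_missing_goes_to_unknown(self):
        assert AGE_SCHEME.bucket(None) == "unknown"


class TestOnset:
    def test_calendar_arithmetic_into_three_to_six_month_bucket(self):
        report = make_report(1, ["anemia"], therapy_start="20230110",
                             event="20230425")
        rec = onset_days(report, CohortSpec())
        assert rec.onset_days == 105
        assert rec.bucket == "3-6 months"

    def test_same_day_is_under_one_month(self):
        report = make_report(1, ["anemia"], therapy_start="20230425",
                             event="20230425")
        rec = onset_days(report, CohortSpec())
        assert rec.onset_days == 0 and rec.bucket == "<1 month"

    def test_missing_event_date_propagates(self):
        report = make_report(1, ["anemia"], therapy_start="20230110")
        assert onset_days(report, CohortSpec()) is None

    def test_negative_span_counts_warning(self):
        report = make_report(1, ["anemia"], therapy_start="20230425",
                             event="20230110")
        warnings = ParseWarnings()
        assert onset_days(report, CohortSpec(), warnings=warnings) is None
        assert warnings.counts["negative_onset"] == 1

    def test_partial_start_date_never_fabricates_precision(self):
        report = make_report(1, ["anemia"], event="20230425")
        report.therapy_starts[1] = __import__(
            "pvsignal.faers_io", fromlist=["parse_date"]).parse_date("202301")
        assert onset_days(report, CohortSpec()) is None


class TestSummarize:
    def test_outcome_tally_with_severity_precedence(self):
        reports = [make_report(1, ["anemia"]), make_report(2, ["anemia"]),
                   make_report(3, ["anemia"]), make_report(4, ["anemia"])]
        reports[0].outcomes = ["HO"]
        reports[1].outcomes = ["HO"]
        reports[2].outcomes = ["DE", "HO"]  # death outranks hospitalization
        table = summarize(reports, CohortSpec())["outcome"]
        values = dict(zip(table["category"], table["percent"]))
        assert values == {"hospitalization": 50.0, "death": 25.0,
                          "unknown": 25.0}
        assert worst_outcome(reports[2]) == "death"

    def test_percentages_total_100(self):
        cfg = SyntheticConfig(n_reports=300, seed=4)
        _, truth = generate(cfg)
        reports = [make_report(i, ["anemia"], age=a, weight=w)
                   for i, (a, w) in enumerate([(30, 60), (70, None),
                                               (None, 110), (50, 80)] * 25)]
        tables = summarize(reports, CohortSpec())
        for name, frame in tables.items():
            if name == "onset":
                continue
            assert frame["percent"].sum() == pytest.approx(100.0, abs=0.05)

    def test_empty_cohort_gives_zero_denominators(self):
        tables = summarize([], CohortSpec())
        assert all(frame.empty or (frame["denominator"] == 0).all()
                   for frame in tables.values())

    def test_onset_bucket_shares(self):
        reports = []
        for i, days in enumerate([20, 100, 120, 400]):
            start = "20230110"
            event = (np.datetime64("2023-01-10") + np.timedelta64(days, "D")
                     ).astype("datetime64[D]").astype(str).replace("-", "")
            reports.append(make_report(i, ["anemia"], therapy_start=start,
                                       event=event))
        table = summarize(reports, CohortSpec())["onset"]
        shares = dict(zip(table["category"], table["percent"]))
        assert shares["3-6 months"] == pytest.approx(50.0)
        assert (table["denominator"] == 4).all()

    def test_planted_onset_distribution_recovered(self):
        """The generated onset law should land in the published-style
        buckets with the generator's own probabilities, to binomial error."""
        from scipy.stats import lognorm

        cfg = SyntheticConfig(n_reports=2000, seed=9, onset_missing=0.0,
                              duplicate_rate=0.0, deletion_rate=0.0)
        _, truth = generate(cfg)
        days = truth.reports["onset_days"].to_numpy()
        days = days[days >= 0]
        dist = lognorm(s=cfg.onset_sdlog, scale=np.exp(cfg.onset_meanlog))
        for lo, hi in [(0, 30), (30, 90), (90, 180), (180, 360),
                       (360, np.inf)]:
            observed = ((days >= lo) & (days < hi)).mean()
            expected = dist.cdf(hi) - dist.cdf(lo)
            se = np.sqrt(expected * (1 - expected) / len(days))
            assert abs(observed - expected) < 4 * se + 0.01
        # 3-6 months is the modal documented bucket
        table_share = ((days >= 90) & (days < 180)).mean()
        assert table_share == max(
            ((days >= lo) & (days < hi)).mean()
            for lo, hi in [(0, 30), (30, 90), (90, 180), (180, 360),
                           (360, np.inf)])
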