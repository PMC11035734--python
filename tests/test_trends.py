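"""Weekly aggregation, fill percentages, trend fits and group tests."""

from __future__ import annotations

from collections import defaultdict
from datetime import date

import numpy as np
import pandas as pd
import pytest

from rxtrace import (
    StudyWindow,
    aggregate_quarters,
    aggregate_weekly,
    compare_quarters,
    compare_years,
    count_weeks,
    fit_linear_trend,
    overall_fill_percentage,
    per_capita_rate,
    percent_change_endpoints,
    percent_dispensed,
    week_keys,
)
from rxtrace.trends import quarter_of_week

from .conftest import disp, rx


def make_pct_series(values):
    """Weekly pct series over the default 156-week study calendar."""
    keys = week_keys(StudyWindow())
    assert len(values) == len(keys)
    idx = pd.MultiIndex.from_tuples(keys, names=["iso_year", "iso_week"])
    return pd.Series(np.asarray(values, dtype=float), index=idx)


class TestCalendar:
    def test_default_window_has_156_iso_weeks(self):
        window = StudyWindow()
        keys = week_keys(window)
        assert count_weeks(window) == 156
        assert keys[0] == (2020, 2)
        assert keys[-1] == (2022, 52)
        assert (2020, 53) in keys  # 53-week ISO year
        by_year = defaultdict(list)
        for y, w in keys:
            by_year[y].append(w)
        assert by_year[2020] == list(range(2, 54))
        assert by_year[2021] == list(range(1, 53))
        assert by_year[2022] == list(range(1, 53))

    def test_one_day_window(self):
        assert count_weeks(StudyWindow(start=date(2021, 5, 4), end=date(2021, 5, 5))) in (1, 2)
        w = StudyWindow(start=date(2021, 5, 4), end=date(2021, 5, 4 + 1))
        assert count_weeks(w) == 1

    def test_full_iso_year_2020_has_53_weeks(self):
        assert count_weeks(StudyWindow(start=date(2020, 1, 1), end=date(2020, 12, 31))) == 53


class TestAggregateWeekly:
    def test_single_event_lands_in_its_iso_week(self):
        window = StudyWindow()
        weekly = aggregate_weekly([rx("R1", "P1", 0, 30)], [], window)  # 2022-01-01
        # 2022-01-01 belongs to ISO week 2021-W52
        assert weekly.loc[(2021, 52), "prescribed_tablets"] == 30
        assert weekly["prescribed_tablets"].sum() == 30

    def test_empty_registry_gives_zero_series(self):
        weekly = aggregate_weekly([], [], StudyWindow())
        assert len(weekly) == 156
        assert (weekly == 0).all().all()

    def test_matches_naive_double_loop_oracle(self, default_cohort):
        _, _, prescriptions, dispensations = default_cohort
        window = StudyWindow()
        weekly = aggregate_weekly(prescriptions[:3000], dispensations[:3000], window)
        oracle = defaultdict(lambda: [0, 0])
        for ev in prescriptions[:3000]:
            if window.contains(ev.issue_date):
                iso = ev.issue_date.isocalendar()
                oracle[(iso[0], iso[1])][0] += ev.tablets
        for ev in dispensations[:3000]:
            if window.contains(ev.dispense_date):
                iso = ev.dispense_date.isocalendar()
                oracle[(iso[0], iso[1])][1] += ev.tablets
        for key, (p, d) in oracle.items():
            assert weekly.loc[key, "prescribed_tablets"] == p
            assert weekly.loc[key, "dispensed_tablets"] == d
        assert weekly["prescribed_tablets"].sum() == sum(
            e.tablets for e in prescriptions[:3000] if window.contains(e.issue_date)
        )

    def test_totals_conserved_and_pct_scale_invariant(self):
        window = StudyWindow()
        prescriptions = [rx(f"R{i}", "P1", 30 * i, 30) for i in range(10)]
        dispensations = [disp(f"R{i}", "P1", 30 * i + 2, 30) for i in range(8)]
        weekly = aggregate_weekly(prescriptions, dispensations, window)
        assert weekly["prescribed_tablets"].sum() == 300
        assert weekly["dispensed_tablets"].sum() == 240
        pct1 = percent_dispensed(weekly)["pct_dispensed"]
        scaled = weekly * 7
        pct7 = percent_dispensed(scaled)["pct_dispensed"]
        pd.testing.assert_series_equal(pct1, pct7)


class TestFillPercentage:
    def test_national_totals_round_to_86(self):
        pct = overall_fill_percentage(4_010_716_658, 4_681_614_262)
        assert pct == pytest.approx(85.67, abs=0.005)
        assert round(pct) == 86

    def test_weekly_ratio(self):
        weekly = pd.DataFrame(
            {"prescribed_tablets": [1000, 0], "dispensed_tablets": [860, 0]},
            index=pd.MultiIndex.from_tuples([(2020, 2), (2020, 3)], names=["iso_year", "iso_week"]),
        )
        out = percent_dispensed(weekly)
        assert out["pct_dispensed"].iloc[0] == pytest.approx(86.0)
        assert np.isnan(out["pct_dispensed"].iloc[1])

    def test_full_dispensation_gives_constant_100(self):
        weekly = aggregate_weekly(
            [rx(f"R{i}", "P1", 30 * i, 30) for i in range(5)],
            [disp(f"R{i}", "P1", 30 * i, 30) for i in range(5)],
            StudyWindow(),
        )
        vals = percent_dispensed(weekly)["pct_dispensed"].dropna()
        assert (vals == 100.0).all()


class TestPerCapita:
    def test_self_normalizing_week(self):
        weekly = pd.DataFrame(
            {"prescribed_tablets": [38_089_000], "dispensed_tablets": [0]},
            index=pd.MultiIndex.from_tuples([(2020, 10)], names=["iso_year", "iso_week"]),
        )
        out = per_capita_rate(weekly)
        assert out["prescribed_per_1000"].iloc[0] == pytest.approx(1000.0)
        assert out["dispensed_per_1000"].iloc[0] == 0.0

    def test_population_jump_at_year_boundary(self):
        idx = pd.MultiIndex.from_tuples([(2020, 52), (2021, 1)], names=["iso_year", "iso_week"])
        weekly = pd.DataFrame(
            {"prescribed_tablets": [1_000_000, 1_000_000], "dispensed_tablets": [0, 0]}, index=idx
        )
        out = per_capita_rate(weekly)["prescribed_per_1000"]
        assert out.iloc[1] / out.iloc[0] == pytest.approx(38_089 / 37_908)

    def test_missing_year_rejected(self):
        idx = pd.MultiIndex.from_tuples([(2019, 50)], names=["iso_year", "iso_week"])
        weekly = pd.DataFrame({"prescribed_tablets": [1], "dispensed_tablets": [1]}, index=idx)
        with pytest.raises(KeyError):
            per_capita_rate(weekly)


class TestLinearTrend:
    def test_exact_line_recovered_to_machine_precision(self):
        slope = 2.5 / 155  # 84.9% -> 87.4% over 156 weeks
        values = [84.9 + slope * i for i in range(156)]
        fit = fit_linear_trend(values)
        assert fit.slope_per_week == pytest.approx(slope, rel=1e-12)
        assert round(fit.slope_per_week, 3) == 0.016
        assert fit.first_fitted == pytest.approx(84.9)
        assert fit.last_fitted == pytest.approx(87.4)

    def test_constant_series_zero_slope(self):
        fit = fit_linear_trend([86.0] * 50)
        assert fit.slope_per_week == pytest.approx(0.0, abs=1e-12)

    def test_noisy_slope_within_3_se(self):
        rng = np.random.default_rng(11)
        true = 0.05
        values = 80 + true * np.arange(156) + rng.normal(0, 1.5, 156)
        fit = fit_linear_trend(values)
        import statsmodels.api as sm

        X = sm.add_constant(np.arange(156.0))
        se = sm.OLS(values, X).fit().bse[1]
        assert abs(fit.slope_per_week - true) < 3 * se

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_trend([1.0, 2.0])


class TestPercentChange:
    @pytest.mark.parametrize(
        "first,last,expected",
        [
            (27_418_954, 32_601_689, 18.9),  # prescribed trend endpoints
            (23_133_631, 28_285_831, 22.3),  # dispensed trend endpoints
            (100.0, 100.0, 0.0),
        ],
    )
    def test_endpoint_changes(self, first, last, expected):
        assert percent_change_endpoints(first, last) == expected

    def test_nonpositive_first_rejected(self):
        with pytest.raises(ValueError):
            percent_change_endpoints(0, 5)


class TestQuarters:
    def test_week_to_quarter_mapping(self):
        assert quarter_of_week(1) == 1
        assert quarter_of_week(13) == 1
        assert quarter_of_week(14) == 2
        assert quarter_of_week(27) == 3
        assert quarter_of_week(40) == 4
        assert quarter_of_week(53) == 4

    def test_constant_series_equal_quarters_nonsignificant(self):
        pct = make_pct_series([86.0] * 156)
        q = aggregate_quarters(pct)
        assert (q["mean"] == 86.0).all()
        tests = compare_quarters(pct)
        assert not tests["significant"].any()

    def test_quarter_contrast_detected(self):
        values = []
        for y, w in week_keys(StudyWindow()):
            values.append(82.0 if quarter_of_week(w) == 1 else 87.0)
        pct = make_pct_series(values)
        q = aggregate_quarters(pct)
        assert q.loc[3, "mean"] - q.loc[1, "mean"] == pytest.approx(5.0)
        tests = compare_quarters(pct)
        row = tests[(tests.quarter_a == 1) & (tests.quarter_b == 3)].iloc[0]
        assert row["significant"]

    def test_seasonal_profile_q1_below_q3(self):
        rng = np.random.default_rng(23)
        values = []
        for y, w in week_keys(StudyWindow()):
            base = {1: 82.07, 2: 86.0, 3: 87.40, 4: 87.52}[quarter_of_week(w)]
            values.append(base + rng.normal(0, 2.5))
        pct = make_pct_series(values)
        tests = compare_quarters(pct)
        row = tests[(tests.quarter_a == 1) & (tests.quarter_b == 3)].iloc[0]
        assert row["mean_a"] < row["mean_b"]
        assert row["p_value"] < 0.05


class TestCompareYears:
    def test_identical_groups(self):
        res = compare_years(make_pct_series([86.0] * 156))
        assert res.h_statistic == 0.0
        assert res.p_value == 1.0

    def test_hand_computed_h_statistic(self):
        idx = pd.MultiIndex.from_tuples(
            [(2020, w) for w in (1, 2, 3)]
            + [(2021, w) for w in (1, 2, 3)]
            + [(2022, w) for w in (1, 2, 3)],
            names=["iso_year", "iso_week"],
        )
        pct = pd.Series([1, 2, 3, 4, 5, 6, 7, 8, 9.0], index=idx)
        res = compare_years(pct)
        # rank-sum formula by hand: H = 12/(9*10) * (36+225+576)/3 - 30 = 7.2
        assert res.h_statistic == pytest.approx(7.2)

    def test_null_calibration_over_replicates(self):
        rng = np.random.default_rng(31)
        keys = week_keys(StudyWindow())
        n_sig = 0
        reps = 200
        for _ in range(reps):
            pct = make_pct_series(86.0 + rng.normal(0, 4.9, len(keys)))
            if compare_years(pct).p_value < 0.05:
                n_sig += 1
        assert n_sig / reps <= 0.10  # nominal 5% false-positive rate
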