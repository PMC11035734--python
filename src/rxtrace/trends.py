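"""Weekly aggregation and trend analysis of prescribing/dispensing series.

Everything is keyed by ISO-8601 weeks ``(iso_year, iso_week)``.  For the
default study window (2020-01-08 .. 2022-12-31) the calendar contributes
weeks 2-53 of 2020 (a 53-week ISO year) and weeks 1-52 of 2021 and 2022,
156 keys in total.

The weekly percent-dispensed is the same-week ratio
``100 * dispensed_tablets / prescribed_tablets``; an ever-filled rate per
prescription (share of issued tablets eventually filled, regardless of week)
is available separately because the two readings answer different questions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, timedelta
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .registry import DispensationEvent, PrescriptionEvent, StudyWindow

logger = logging.getLogger(__name__)

#: Poland, thousands of inhabitants on 31 December (national statistics office)
DEFAULT_POPULATION_THOUSANDS: dict[int, float] = {2020: 38_089, 2021: 37_908, 2022: 37_766}

WeekKey = tuple[int, int]


def week_of(d: date) -> WeekKey:
    iso = d.isocalendar()
    return (iso[0], iso[1])


def week_keys(window: StudyWindow) -> list[WeekKey]:
    """Contiguous ISO week keys intersecting the window."""
    keys: list[WeekKey] = []
    monday = window.start - timedelta(days=window.start.weekday())
    d = monday
    while d <= window.end:
        keys.append(week_of(d))
        d += timedelta(days=7)
    return keys


def count_weeks(window: StudyWindow) -> int:
    """Number of ISO weeks intersecting the window (156 for the default)."""
    return len(week_keys(window))


def aggregate_weekly(
    prescriptions: Sequence[PrescriptionEvent],
    dispensations: Sequence[DispensationEvent],
    window: StudyWindow,
) -> pd.DataFrame:
    """Tablet totals per ISO week.

    Each event contributes its tablets to the week of its own date; events
    outside the window are excluded and counted in the log.  Returns a frame
    indexed by (iso_year, iso_week) with ``prescribed_tablets`` and
    ``dispensed_tablets`` columns covering every study week (zeros where no
    events fall).
    """
    keys = week_keys(window)
    idx = pd.MultiIndex.from_tuples(keys, names=["iso_year", "iso_week"])
    out = pd.DataFrame(0, index=idx, columns=["prescribed_tablets", "dispensed_tablets"])
    n_outside = 0
    for col, events, date_of in (
        ("prescribed_tablets", prescriptions, lambda e: e.issue_date),
        ("dispensed_tablets", dispensations, lambda e: e.dispense_date),
    ):
        inside = [ev for ev in events if window.contains(date_of(ev))]
        n_outside += len(events) - len(inside)
        if not inside:
            continue
        frame = pd.DataFrame(
            {
                "key": [week_of(date_of(ev)) for ev in inside],
                "tablets": [ev.tablets for ev in inside],
            }
        )
        sums = frame.groupby("key")["tablets"].sum()
        out.loc[list(sums.index), col] = sums.to_numpy()
    if n_outside:
        logger.info("aggregate_weekly: %d events outside the window excluded", n_outside)
    return out


def percent_dispensed(weekly: pd.DataFrame) -> pd.DataFrame:
    """Add ``pct_dispensed`` = 100 * dispensed / prescribed (NaN where the
    week had no prescriptions)."""
    out = weekly.copy()
    rx = out["prescribed_tablets"].astype(float)
    out["pct_dispensed"] = np.where(
        rx > 0, 100.0 * out["dispensed_tablets"] / rx, np.nan
    )
    return out


def overall_fill_percentage(total_dispensed: float, total_prescribed: float) -> float:
    """Aggregate fill percentage, 100 * sum(dispensed) / sum(prescribed)."""
    if total_prescribed <= 0:
        raise ValueError("total_prescribed must be positive")
    return 100.0 * total_dispensed / total_prescribed


def per_capita_rate(
    weekly: pd.DataFrame,
    population_thousands: Mapping[int, float] = DEFAULT_POPULATION_THOUSANDS,
    columns: Sequence[str] = ("prescribed_tablets", "dispensed_tablets"),
) -> pd.DataFrame:
    """Per-1000-inhabitant weekly rates, dividing by the population (in
    thousands) of each week's ISO year."""
    out = weekly.copy()
    years = out.index.get_level_values("iso_year")
    missing = sorted(set(years) - set(population_thousands))
    if missing:
        raise KeyError(f"no population for years {missing}")
    pop = np.array([population_thousands[y] for y in years], dtype=float)
    for col in columns:
        out[col.replace("_tablets", "_per_1000")] = out[col] / pop
    return out


@dataclass(frozen=True)
class TrendFit:
    slope_per_week: float
    intercept: float
    first_fitted: float
    last_fitted: float
    p_value: float
    r_squared: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def fit_linear_trend(values: Sequence[float]) -> TrendFit:
    """OLS of the series on week index 0..n-1, with the two-sided slope test."""
    y = np.asarray(values, dtype=float)
    mask = ~np.isnan(y)
    if mask.sum() < 3:
        raise ValueError("need at least 3 non-missing points")
    x = np.arange(len(y), dtype=float)
    X = sm.add_constant(x[mask])
    fit = sm.OLS(y[mask], X).fit()
    intercept, slope = fit.params
    return TrendFit(
        slope_per_week=float(slope),
        intercept=float(intercept),
        first_fitted=float(intercept),
        last_fitted=float(intercept + slope * (len(y) - 1)),
        p_value=float(fit.pvalues[1]),
        r_squared=float(fit.rsquared),
    )


def percent_change_endpoints(first: float, last: float) -> float:
    """Relative change between endpoint values, in percent to one decimal."""
    if first <= 0:
        raise ValueError("first endpoint must be positive")
    return round(100.0 * (last - first) / first, 1)


def quarter_of_week(iso_week: int) -> int:
    """Calendar quarter approximated in ISO weeks: 1-13, 14-26, 27-39, 40+."""
    if not 1 <= iso_week <= 53:
        raise ValueError(f"ISO week out of range: {iso_week}")
    return min((iso_week - 1) // 13 + 1, 4)


def aggregate_quarters(pct: pd.Series) -> pd.DataFrame:
    """Mean ± SD of weekly values per quarter, pooled across study years.

    ``pct`` must be indexed by (iso_year, iso_week).
    """
    weeks = pct.index.get_level_values("iso_week")
    quarters = [quarter_of_week(w) for w in weeks]
    grouped = pct.groupby(quarters)
    out = grouped.agg(["mean", "std", "count"])
    out.index.name = "quarter"
    return out


def compare_quarters(pct: pd.Series, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney U tests between quarters (values
    pooled across years).  No multiple-testing correction is applied."""
    weeks = pct.index.get_level_values("iso_week")
    by_q: dict[int, np.ndarray] = {}
    for q in (1, 2, 3, 4):
        vals = pct.values[np.array([quarter_of_week(w) == q for w in weeks])]
        by_q[q] = vals[~np.isnan(vals)]
    rows = []
    for qa, qb in combinations((1, 2, 3, 4), 2):
        a, b = by_q[qa], by_q[qb]
        if len(a) == 0 or len(b) == 0:
            continue
        if np.array_equal(np.unique(a), np.unique(b)) and len(np.unique(np.concatenate([a, b]))) == 1:
            u, p = np.nan, 1.0
        else:
            u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({
            "quarter_a": qa, "quarter_b": qb,
            "mean_a": a.mean(), "mean_b": b.mean(),
            "statistic": u, "p_value": p, "significant": p < alpha,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class YearComparison:
    h_statistic: float
    p_value: float
    normality_p_by_year: dict[int, float]
    center_by_year: dict[int, float]  # means if all groups normal, else medians
    centers_are_means: bool


def compare_years(pct: pd.Series, alpha: float = 0.05) -> YearComparison:
    """Kruskal-Wallis comparison of weekly values across calendar (ISO) years.

    A Shapiro-Wilk pre-check decides whether the per-year centers reported
    alongside are means (all years normal at ``alpha``) or medians.
    """
    years = sorted(set(pct.index.get_level_values("iso_year")))
    groups = []
    for y in years:
        vals = pct.xs(y, level="iso_year").to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) < 2:
            raise ValueError(f"year {y}: need at least 2 values")
        groups.append(vals)
    if len(groups) < 2:
        raise ValueError("need at least 2 years")
    normality = {}
    for y, g in zip(years, groups):
        normality[y] = float(stats.shapiro(g).pvalue) if len(set(g)) > 1 else 0.0
    use_means = all(p >= alpha for p in normality.values())
    centers = {
        y: float(np.mean(g) if use_means else np.median(g))
        for y, g in zip(years, groups)
    }
    pooled = np.concatenate(groups)
    if len(np.unique(pooled)) == 1:
        h, p = 0.0, 1.0  # identical groups: no rank variation
    else:
        h, p = stats.kruskal(*groups)
    return YearComparison(
        h_statistic=float(h),
        p_value=float(p),
        normality_p_by_year=normality,
        center_by_year=centers,
        centers_are_means=use_means,
    )


def ever_filled_rate(
    prescriptions: Sequence[PrescriptionEvent],
    dispensations: Sequence[DispensationEvent],
) -> float:
    """Share of issued tablets that were eventually filled, in percent
    (prescription-linked reading of the fill rate; complements the weekly
    same-week ratio)."""
    total_rx = sum(p.tablets for p in prescriptions)
    if total_rx == 0:
        raise ValueError("no prescribed tablets")
    rx_ids = {p.prescription_id for p in prescriptions}
    filled = sum(d.tablets for d in dispensations if d.prescription_id in rx_ids)
    return 100.0 * filled / total_rx
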