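"""Lockdown calendar, ECDC weekly COVID ingestion, and pandemic-context
comparisons of the statin series.

The lockdown calendar is configured as inclusive ISO-week ranges
(default: weeks 12-22 and 46-52 of 2020 and weeks 12-16 of 2021, 23 weeks
in total).  Ranges are taken as authoritative configuration rather than
re-derived from calendar dates.

COVID case/death series are read from the ECDC national weekly CSV dialect::

    country,year_week,indicator,weekly_count

with ``year_week`` like ``2020-W02`` and ``indicator`` in {cases, deaths}.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trends import WeekKey, fit_linear_trend

logger = logging.getLogger(__name__)

DEFAULT_LOCKDOWN_RANGES: tuple[tuple[int, int, int], ...] = (
    (2020, 12, 22),
    (2020, 46, 52),
    (2021, 12, 16),
)


@dataclass(frozen=True)
class LockdownCalendar:
    """Inclusive (iso_year, week_from, week_to) lockdown ranges."""

    ranges: tuple[tuple[int, int, int], ...] = DEFAULT_LOCKDOWN_RANGES

    def __post_init__(self) -> None:
        for year, w_from, w_to in self.ranges:
            if not (1 <= w_from <= w_to <= 53):
                raise ValueError(f"bad lockdown range {(year, w_from, w_to)}")

    def is_lockdown(self, key: WeekKey) -> bool:
        year, week = key
        return any(
            y == year and w_from <= week <= w_to for y, w_from, w_to in self.ranges
        )

    def flags(self, keys: Sequence[WeekKey]) -> pd.Series:
        idx = pd.MultiIndex.from_tuples(keys, names=["iso_year", "iso_week"])
        return pd.Series([self.is_lockdown(k) for k in keys], index=idx, name="lockdown")

    def week_count(self) -> int:
        """Total flagged weeks across all configured ranges."""
        return sum(w_to - w_from + 1 for _, w_from, w_to in self.ranges)


def lockdown_flags(
    calendar: LockdownCalendar, keys: Sequence[WeekKey]
) -> tuple[pd.Series, int]:
    """Boolean lockdown series over the study weeks plus the flagged count."""
    flags = calendar.flags(keys)
    return flags, int(flags.sum())


def _parse_year_week(text: str) -> WeekKey:
    year, week = text.strip().split("-W")
    return (int(year), int(week))


def format_year_week(key: WeekKey) -> str:
    return f"{key[0]}-W{key[1]:02d}"


def read_ecdc_weekly(
    path: str | Path,
    study_weeks: Sequence[WeekKey],
    country: str = "Poland",
) -> pd.DataFrame:
    """Read an ECDC-dialect weekly CSV into a (iso_year, iso_week)-indexed
    frame with ``covid_cases`` and ``covid_deaths`` columns aligned to the
    study calendar.  Missing study weeks are filled with 0 (logged); rows for
    other countries are dropped; unknown indicators are skipped with a
    warning."""
    cases: dict[WeekKey, int] = {}
    deaths: dict[WeekKey, int] = {}
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            if (row.get("country") or "").strip() != country:
                continue
            indicator = (row.get("indicator") or "").strip()
            if indicator not in ("cases", "deaths"):
                logger.warning("read_ecdc_weekly: unknown indicator %r skipped", indicator)
                continue
            key = _parse_year_week(row["year_week"])
            count = int(float(row["weekly_count"]))
            (cases if indicator == "cases" else deaths)[key] = count
    idx = pd.MultiIndex.from_tuples(study_weeks, names=["iso_year", "iso_week"])
    out = pd.DataFrame(
        {
            "covid_cases": [cases.get(k, 0) for k in study_weeks],
            "covid_deaths": [deaths.get(k, 0) for k in study_weeks],
        },
        index=idx,
    )
    n_missing = sum(k not in cases for k in study_weeks)
    if n_missing:
        logger.info("read_ecdc_weekly: %d study weeks missing in %s, filled with 0", n_missing, path)
    return out


def write_ecdc_weekly(
    cases: Mapping[WeekKey, int] | pd.Series,
    deaths: Mapping[WeekKey, int] | pd.Series,
    path: str | Path,
    country: str = "Poland",
) -> None:
    """Write weekly case/death series in the ECDC dialect."""
    if isinstance(cases, pd.Series):
        cases = {k: int(v) for k, v in cases.items()}
    if isinstance(deaths, pd.Series):
        deaths = {k: int(v) for k, v in deaths.items()}
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["country", "year_week", "indicator", "weekly_count"])
        for key in sorted(cases):
            w.writerow([country, format_year_week(key), "cases", int(cases[key])])
        for key in sorted(deaths):
            w.writerow([country, format_year_week(key), "deaths", int(deaths[key])])


def correlate_series(
    a: Sequence[float],
    b: Sequence[float],
    method: str = "spearman",
) -> tuple[float, float]:
    """Rank (Spearman, default) or Pearson correlation with two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("series lengths differ")
    if len(a) < 3:
        raise ValueError("need at least 3 points")
    if method == "spearman":
        rho, p = stats.spearmanr(a, b)
    elif method == "pearson":
        rho, p = stats.pearsonr(a, b)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(rho), float(p)


@dataclass(frozen=True)
class LockdownComparison:
    mean_lockdown: float
    mean_other: float
    percent_deficit: float  # 100 * (mean_other - mean_lockdown) / mean_other
    p_value: float
    n_lockdown: int
    n_other: int
    detrended: bool = False


def compare_lockdown(
    series: pd.Series,
    flags: pd.Series,
    detrend: bool = False,
) -> LockdownComparison:
    """Lockdown vs non-lockdown group comparison (Mann-Whitney U).

    With ``detrend`` the series is first divided by an OLS linear fit on the
    non-lockdown weeks, removing secular growth so the deficit isolates the
    lockdown effect; the default compares raw group means.
    """
    values = series.to_numpy(dtype=float)
    mask = flags.to_numpy(dtype=bool)
    if mask.all() or not mask.any():
        raise ValueError("both lockdown and non-lockdown groups must be non-empty")
    if detrend:
        x = np.arange(len(values), dtype=float)
        fit = fit_linear_trend(np.where(mask, np.nan, values))
        trend = fit.intercept + fit.slope_per_week * x
        if np.any(trend <= 0):
            raise ValueError("non-positive fitted trend; cannot detrend")
        values = values / trend
    lock, other = values[mask], values[~mask]
    if np.array_equal(np.sort(lock), np.sort(other)):
        p = 1.0
    else:
        _, p = stats.mannwhitneyu(lock, other, alternative="two-sided")
    mean_lock, mean_other = float(lock.mean()), float(other.mean())
    return LockdownComparison(
        mean_lockdown=mean_lock,
        mean_other=mean_other,
        percent_deficit=100.0 * (mean_other - mean_lock) / mean_other,
        p_value=float(p),
        n_lockdown=int(mask.sum()),
        n_other=int((~mask).sum()),
        detrended=detrend,
    )


def lockdown_effect_regression(
    series: pd.Series,
    flags: pd.Series,
) -> tuple[float, float]:
    """Calendar-adjusted lockdown deficit, in percent, with its p-value.

    Fits OLS of log weekly counts on a linear week-index trend, week-of-year
    fixed effects and a lockdown indicator; the indicator coefficient
    ``delta`` converts to a mean weekly deficit ``100 * (1 - exp(delta))``.
    Unlike the raw group-mean comparison this is unconfounded by secular
    growth and seasonality, so it recovers a multiplicative intensity
    multiplier applied during lockdown weeks.
    """
    import statsmodels.api as sm

    values = series.to_numpy(dtype=float)
    mask = flags.to_numpy(dtype=bool)
    if np.any(values <= 0):
        raise ValueError("log-linear model needs positive weekly counts")
    if mask.all() or not mask.any():
        raise ValueError("both lockdown and non-lockdown groups must be non-empty")
    n = len(values)
    weeks_of_year = series.index.get_level_values("iso_week").to_numpy()
    uniq = sorted(set(weeks_of_year))
    X = np.zeros((n, 1 + (len(uniq) - 1) + 1))
    X[:, 0] = np.arange(n) / 52.0  # trend, per year
    for j, wk in enumerate(uniq[1:]):
        X[:, 1 + j] = weeks_of_year == wk
    X[:, -1] = mask
    X = sm.add_constant(X)
    fit = sm.OLS(np.log(values), X).fit()
    delta = fit.params[-1]
    return 100.0 * (1.0 - math.exp(delta)), float(fit.pvalues[-1])


@dataclass(frozen=True)
class MatchedWeekResult:
    lockdown_year: int
    week_from: int
    week_to: int
    weeks_used: tuple[int, ...]
    mean_lockdown: float
    mean_reference: float
    difference: float  # lockdown minus reference
    p_value: float


def matched_week_comparison(
    pct: pd.Series,
    calendar: LockdownCalendar = LockdownCalendar(),
    reference_year: int = 2022,
) -> list[MatchedWeekResult]:
    """Compare each lockdown period's weekly values with the same-numbered
    weeks of an 'open' reference year (paired Wilcoxon test; falls back to
    reporting p=1 for all-zero differences).  Week numbers absent from the
    reference year (e.g. week 53) are excluded with a warning."""
    results = []
    ref_weeks = {w for (y, w) in pct.index if y == reference_year}
    for year, w_from, w_to in calendar.ranges:
        weeks = []
        for w in range(w_from, w_to + 1):
            if w not in ref_weeks:
                logger.warning(
                    "matched_week_comparison: week %d has no %d counterpart, excluded",
                    w, reference_year,
                )
                continue
            if (year, w) in pct.index:
                weeks.append(w)
        if not weeks:
            continue
        lock_vals = np.array([pct.loc[(year, w)] for w in weeks], dtype=float)
        ref_vals = np.array([pct.loc[(reference_year, w)] for w in weeks], dtype=float)
        diffs = lock_vals - ref_vals
        if np.allclose(diffs, 0):
            p = 1.0
        elif len(diffs) < 2:
            p = 1.0
        else:
            _, p = stats.wilcoxon(lock_vals, ref_vals)
        results.append(
            MatchedWeekResult(
                lockdown_year=year,
                week_from=w_from,
                week_to=w_to,
                weeks_used=tuple(weeks),
                mean_lockdown=float(lock_vals.mean()),
                mean_reference=float(ref_vals.mean()),
                difference=float(lock_vals.mean() - ref_vals.mean()),
                p_value=float(p),
            )
        )
    return results
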