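"""Synthetic e-prescription registry and COVID series generator.

The generator emulates the statistical structure a national statin claims
analysis assumes, so the whole downstream pipeline can be exercised without
access to payer data:

* a cohort of patients — a prevalent pool already on therapy at the study
  start plus incident users accruing over the window with a mild
  multiplicative weekly growth trend;
* exhaustion-anchored refills: the gap to the next prescription is gamma
  distributed around the days of supply of the previous fill (packs of
  28/30 tablets and their multiples, one tablet per day), so the mean
  prescription interval tracks the configured value and early/late refills
  arise from the gamma dispersion;
* primary non-adherence: each prescription is never dispensed with a fixed
  probability, after which the patient re-requests a replacement within days;
* discontinuation: at every issuance the patient continues with probability
  ``exp(-hazard * gap_months)`` — a per-refill Bernoulli whose telescoping
  product makes time-to-last-exhaustion follow the configured constant
  monthly hazard;
* deaths at a constant annual probability, truncating refills;
* calendar structure: week-of-year seasonal multipliers (year-end trough,
  new-year rebound) applied through an operational-time warp (each calendar
  day consumes ``multiplier`` demand-days), and lockdown multipliers applied
  by per-visit thinning — a refill visit falling in a lockdown week is, with
  probability ``1 - multiplier``, skipped entirely (the patient forgoes that
  fill and returns at the natural next cadence point), so in-lockdown weekly
  event counts drop by the configured factor without a compensating
  post-lockdown rebound;
* a paired weekly COVID case/death series shaped as phenomenological
  Gaussian waves, deaths being a lagged noisy fraction of cases.

Everything is reproducible from the explicit seed; no global random state.
"""

from __future__ import annotations

import math
from datetime import date, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .covid import DEFAULT_LOCKDOWN_RANGES, LockdownCalendar, write_ecdc_weekly
from .registry import (
    DispensationEvent,
    Patient,
    PrescriptionEvent,
    StudyWindow,
    write_registry,
)
from .trends import week_keys

DAYS_PER_MONTH = 30.4375

#: ATC mix of the generated prescriptions (plain statins dominate, with a
#: small share of the retained fixed-dose lipid combinations).
DEFAULT_ATC_MIX: dict[str, float] = {
    "C10AA05": 0.40,  # atorvastatin
    "C10AA07": 0.30,  # rosuvastatin
    "C10AA01": 0.15,  # simvastatin
    "C10AA03": 0.07,  # pravastatin
    "C10AA04": 0.03,  # fluvastatin
    "C10BA02": 0.03,  # simvastatin + ezetimibe
    "C10BA05": 0.02,  # atorvastatin + ezetimibe
}

#: Tablets per prescription: 28/30 packs and their multiples, weighted toward
#: the 3-month sizes used for chronic therapy (mean ~75 tablets, matching the
#: mean refill interval so steady-state supply balances demand).
DEFAULT_PACK_MIX: dict[int, float] = {28: 0.04, 30: 0.10, 56: 0.04, 60: 0.14, 84: 0.20, 90: 0.48}

#: Mild year-end prescribing trough with a new-year rebound.
DEFAULT_SEASONAL: dict[int, float] = {51: 0.90, 52: 0.90, 53: 0.90, 1: 1.05, 2: 1.05, 3: 1.05}


class CohortParams(BaseModel):
    """Parameters of the synthetic cohort; defaults are calibrated so the
    pipeline recovers them (86% fill, ~40% 12-month persistence, 6.8%
    lockdown prescribing deficit)."""

    n_patients: int = Field(10_000, ge=1)
    prevalent_frac: float = Field(0.285, ge=0.0, le=1.0)
    rx_interval_mean: float = Field(75.0, gt=0)
    rx_interval_cv: float = Field(0.12, gt=0, le=1.0)
    pack_mix: dict[int, float] = Field(default_factory=lambda: dict(DEFAULT_PACK_MIX))
    atc_mix: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_ATC_MIX))
    p_primary_nonadherence: float = Field(0.14, ge=0.0, le=1.0)
    dispense_delay_mean: float = Field(2.0, ge=0.0)
    rerequest_delay_mean: float = Field(3.0, ge=0.0)
    discontinuation_hazard_monthly: float = Field(0.0764, ge=0.0)
    annual_death_prob: float = Field(0.033, ge=0.0, le=1.0)
    seasonal_multipliers: dict[int, float] = Field(default_factory=lambda: dict(DEFAULT_SEASONAL))
    lockdown_multiplier_rx: float = Field(0.932, gt=0.0, le=1.0)
    lockdown_multiplier_disp: float = Field(0.941, gt=0.0, le=1.0)
    lockdown_ranges: tuple[tuple[int, int, int], ...] = DEFAULT_LOCKDOWN_RANGES
    trend_per_week: float = Field(default=1.189 ** (1.0 / 155.0), gt=0.0)
    sex_probs: dict[str, float] = Field(
        default_factory=lambda: {"F": 0.554, "M": 0.444, "missing": 0.002}
    )
    age_mean: float = 67.6
    age_sd: float = Field(12.3, gt=0)
    seed: int = 0

    @field_validator("pack_mix")
    @classmethod
    def _packs_valid(cls, v: dict[int, float]) -> dict[int, float]:
        if not v or any(size < 1 for size in v) or any(w < 0 for w in v.values()):
            raise ValueError("pack_mix must map positive sizes to non-negative weights")
        total = sum(v.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"pack_mix weights must sum to 1 (got {total})")
        return v

    @model_validator(mode="after")
    def _probs_valid(self) -> "CohortParams":
        for mix in (self.atc_mix, self.sex_probs):
            total = sum(mix.values())
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise ValueError(f"categorical weights must sum to 1 (got {total})")
        if any(m <= 0 for m in self.seasonal_multipliers.values()):
            raise ValueError("seasonal multipliers must be positive")
        return self

    @property
    def mean_pack_tablets(self) -> float:
        return sum(size * w for size, w in self.pack_mix.items())


class CovidWave(BaseModel):
    center_week: int = Field(ge=0)  # index into the study week calendar
    width_weeks: float = Field(gt=0)
    height: float = Field(ge=0)  # peak weekly case count


class CovidParams(BaseModel):
    """Phenomenological weekly COVID case/death series: Gaussian waves with
    multiplicative log-normal noise; deaths are a lagged fraction of cases."""

    waves: list[CovidWave] = Field(
        default_factory=lambda: [
            CovidWave(center_week=44, width_weeks=5.0, height=150_000),
            CovidWave(center_week=62, width_weeks=5.0, height=180_000),
            CovidWave(center_week=99, width_weeks=6.0, height=140_000),
            CovidWave(center_week=106, width_weeks=4.0, height=250_000),
        ]
    )
    death_lag_weeks: int = Field(2, ge=0)
    death_ratio: float = Field(0.025, ge=0.0, le=1.0)
    noise_sigma: float = Field(0.15, ge=0.0)
    seed: int = 0


def _geometric_delay(rng: np.random.Generator, mean: float) -> int:
    """Geometric delay with support {0, 1, ...} and the given mean."""
    if mean <= 0:
        return 0
    return int(rng.geometric(1.0 / (mean + 1.0))) - 1


class _IntensityWarp:
    """Operational-time warp: calendar day d consumes ``multiplier[d]``
    demand-days, so a demand gap G stretches to ~G / multiplier."""

    def __init__(self, daily_multiplier: np.ndarray):
        self.cum = np.concatenate([[0.0], np.cumsum(daily_multiplier)])
        self.n = len(daily_multiplier)

    def advance(self, day: int, demand_days: float) -> int:
        """First calendar day at which ``demand_days`` of demand since
        ``day`` is exhausted; days past the array advance one-for-one."""
        if day >= self.n:
            return day + int(round(demand_days))
        target = self.cum[day] + demand_days
        if target > self.cum[-1]:
            return self.n + int(round(target - self.cum[-1]))
        return int(np.searchsorted(self.cum, target, side="left"))


def _daily_multipliers(
    window: StudyWindow,
    seasonal: dict[int, float],
    lockdown_mult: float,
    lockdown: LockdownCalendar,
    trend_per_week: float = 1.0,
) -> np.ndarray:
    days = window.n_days
    out = np.ones(days)
    d = window.start
    for i in range(days):
        iso = d.isocalendar()
        m = seasonal.get(iso[1], 1.0)
        if lockdown.is_lockdown((iso[0], iso[1])):
            m *= lockdown_mult
        if trend_per_week != 1.0:
            m *= trend_per_week ** (i / 7.0)
        out[i] = m
        d += timedelta(days=1)
    return out


def generate_cohort(
    params: CohortParams,
    window: StudyWindow = StudyWindow(),
) -> tuple[list[Patient], list[PrescriptionEvent], list[DispensationEvent]]:
    """Simulate the registry (patients, prescriptions, dispensations).

    Prevalent patients enter the window mid-cycle with carry-in supply from a
    pre-window fill (which is outside the registry and therefore not
    emitted); incident patients initiate at trend-weighted random dates.
    Fully reproducible from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    lockdown = LockdownCalendar(ranges=params.lockdown_ranges)
    end_day = window.n_days - 1

    warp_rx = _IntensityWarp(
        _daily_multipliers(window, params.seasonal_multipliers, 1.0, lockdown)
    )
    warp_disp = _IntensityWarp(
        _daily_multipliers(window, {}, params.lockdown_multiplier_disp, lockdown)
    )
    lock_day = np.zeros(window.n_days, dtype=bool)
    d = window.start
    for i in range(window.n_days):
        iso = d.isocalendar()
        lock_day[i] = lockdown.is_lockdown((iso[0], iso[1]))
        d += timedelta(days=1)

    def skip_lockdown_visit(day: int) -> bool:
        """True when an in-lockdown refill visit is thinned away."""
        return (
            0 <= day <= end_day
            and lock_day[day]
            and rng.random() >= params.lockdown_multiplier_rx
        )

    # accrual density for incident users: weekly growth applied daily
    accrual_w = params.trend_per_week ** (np.arange(window.n_days) / 7.0)
    accrual_p = accrual_w / accrual_w.sum()

    pack_sizes = np.array(sorted(params.pack_mix), dtype=int)
    pack_probs = np.array([params.pack_mix[s] for s in pack_sizes], dtype=float)
    pack_probs /= pack_probs.sum()
    atc_codes = sorted(params.atc_mix)
    atc_probs = np.array([params.atc_mix[c] for c in atc_codes], dtype=float)
    atc_probs /= atc_probs.sum()
    sex_codes = sorted(params.sex_probs)
    sex_probs = np.array([params.sex_probs[s] for s in sex_codes], dtype=float)
    sex_probs /= sex_probs.sum()

    gamma_shape = 1.0 / params.rx_interval_cv**2
    interval_ratio = params.rx_interval_mean / params.mean_pack_tablets
    death_rate_daily = (
        -math.log(1.0 - params.annual_death_prob) / 365.25
        if params.annual_death_prob > 0
        else 0.0
    )
    hazard = params.discontinuation_hazard_monthly

    patients: list[Patient] = []
    prescriptions: list[PrescriptionEvent] = []
    dispensations: list[DispensationEvent] = []
    rx_counter = 0

    n_prevalent = int(round(params.prevalent_frac * params.n_patients))
    for i in range(params.n_patients):
        pid = f"P{i:06d}"
        sex = str(rng.choice(sex_codes, p=sex_probs))
        age = float(np.clip(rng.normal(params.age_mean, params.age_sd), 18, 105))
        birth_year = window.end.year - int(round(age))
        prevalent = i < n_prevalent

        if prevalent:
            entry_day = 0
            # hazard-free burn-in from before the window so refill phases,
            # re-request states and carry-in supply are stationary at the
            # window start; pre-window events are outside the registry and
            # therefore not emitted
            day = -160 - int(rng.integers(0, 90))
            supply_end = day
            prev_issue = day
            next_issue = day
            while next_issue < 0:
                prev_issue = next_issue
                if rng.random() < 1.0 - params.p_primary_nonadherence:
                    t0 = int(rng.choice(pack_sizes, p=pack_probs))
                    disp = next_issue + _geometric_delay(rng, params.dispense_delay_mean)
                    supply_start = max(disp, supply_end)
                    supply_end = supply_start + t0
                    gap = rng.gamma(gamma_shape, (t0 * interval_ratio) / gamma_shape)
                    next_issue = disp + int(round(gap))
                else:
                    next_issue = next_issue + 1 + _geometric_delay(rng, params.rerequest_delay_mean)
            first_rx = False  # hazard applies from the first in-window refill
        else:
            entry_day = int(rng.choice(window.n_days, p=accrual_p))
            supply_end = entry_day
            next_issue = entry_day
            prev_issue = entry_day
            first_rx = True

        if death_rate_daily > 0:
            death_day = entry_day + rng.exponential(1.0 / death_rate_daily)
        else:
            death_day = math.inf
        death_date = (
            window.start + timedelta(days=int(death_day))
            if death_day <= end_day
            else None
        )

        while True:
            if next_issue > end_day or next_issue >= death_day:
                break
            if skip_lockdown_visit(next_issue):
                # forgone fill: the patient returns at the natural next
                # cadence point; prev_issue is not advanced, so the stopping
                # hazard at the next actual visit covers the whole gap
                t_skip = int(rng.choice(pack_sizes, p=pack_probs))
                gap = rng.gamma(gamma_shape, (t_skip * interval_ratio) / gamma_shape)
                next_issue = warp_rx.advance(next_issue, gap)
                continue
            if not first_rx and hazard > 0:
                gap_months = (next_issue - prev_issue) / DAYS_PER_MONTH
                if rng.random() > math.exp(-hazard * gap_months):
                    break  # therapy discontinued
            first_rx = False
            prev_issue = next_issue

            rx_counter += 1
            tablets = int(rng.choice(pack_sizes, p=pack_probs))
            atc = str(rng.choice(atc_codes, p=atc_probs))
            prescriptions.append(
                PrescriptionEvent(
                    prescription_id=f"R{rx_counter:08d}",
                    patient_id=pid,
                    issue_date=window.start + timedelta(days=next_issue),
                    atc_code=atc,
                    tablets=tablets,
                )
            )

            if rng.random() < 1.0 - params.p_primary_nonadherence:
                delay = _geometric_delay(rng, params.dispense_delay_mean)
                disp_day = warp_disp.advance(next_issue, delay) if delay else next_issue
                if disp_day <= end_day and disp_day < death_day:
                    dispensations.append(
                        DispensationEvent(
                            prescription_id=f"R{rx_counter:08d}",
                            patient_id=pid,
                            dispense_date=window.start + timedelta(days=disp_day),
                            tablets=tablets,
                        )
                    )
                supply_start = max(disp_day, supply_end)
                supply_end = supply_start + tablets
                gap = rng.gamma(gamma_shape, (tablets * interval_ratio) / gamma_shape)
                next_issue = warp_rx.advance(disp_day, gap)
            else:
                # prescription never filled: patient re-requests shortly
                rr = 1 + _geometric_delay(rng, params.rerequest_delay_mean)
                next_issue = warp_rx.advance(next_issue, rr)

        patients.append(
            Patient(patient_id=pid, sex=sex, birth_year=birth_year, death_date=death_date)
        )

    return patients, prescriptions, dispensations


def generate_covid_series(
    params: CovidParams,
    window: StudyWindow = StudyWindow(),
) -> pd.DataFrame:
    """Weekly COVID cases and deaths over the study calendar.

    Cases are a sum of Gaussian waves with multiplicative log-normal noise;
    deaths equal ``death_ratio`` times the cases ``death_lag_weeks`` earlier,
    with independent noise.  With ``noise_sigma = 0`` the relationship is the
    exact (rounded) closed form.
    """
    rng = np.random.default_rng(params.seed)
    keys = week_keys(window)
    n = len(keys)
    w = np.arange(n, dtype=float)
    base = np.zeros(n)
    for wave in params.waves:
        base += wave.height * np.exp(-0.5 * ((w - wave.center_week) / wave.width_weeks) ** 2)
    if params.noise_sigma > 0:
        cases = base * rng.lognormal(0.0, params.noise_sigma, size=n)
    else:
        cases = base
    cases = np.rint(cases).astype(np.int64)
    cases = np.maximum(cases, 0)

    lagged = np.zeros(n, dtype=np.int64)
    lag = params.death_lag_weeks
    if lag < n:
        lagged[lag:] = cases[: n - lag] if lag > 0 else cases
    deaths = lagged * params.death_ratio
    if params.noise_sigma > 0:
        deaths = deaths * rng.lognormal(0.0, params.noise_sigma, size=n)
    deaths = np.maximum(np.rint(deaths).astype(np.int64), 0)

    idx = pd.MultiIndex.from_tuples(keys, names=["iso_year", "iso_week"])
    return pd.DataFrame({"covid_cases": cases, "covid_deaths": deaths}, index=idx)


def simulate_to_dir(
    out_dir: str | Path,
    cohort_params: CohortParams | None = None,
    covid_params: CovidParams | None = None,
    window: StudyWindow = StudyWindow(),
    country: str = "Poland",
) -> dict[str, Path]:
    """Run both generators and write the registry CSVs plus the
    ECDC-dialect covid_weekly.csv; returns the written paths."""
    cohort_params = cohort_params or CohortParams()
    covid_params = covid_params or CovidParams(seed=cohort_params.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    patients, rx, disp = generate_cohort(cohort_params, window)
    paths = write_registry(rx, disp, patients, out_dir)
    covid = generate_covid_series(covid_params, window)
    covid_path = out_dir / "covid_weekly.csv"
    write_ecdc_weekly(
        covid["covid_cases"], covid["covid_deaths"], covid_path, country=country
    )
    paths["covid"] = covid_path
    return paths
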