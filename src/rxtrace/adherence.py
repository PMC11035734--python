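"""MPR adherence and grace-period persistence.

Adherence is quantified by the Medication Possession Ratio (MPR): covered
days divided by days in the patient's observation window, here running from
the first statin dispensation to the study end (or death).  The ratio is
capped at 1.0 by default, making it equivalent to a proportion-of-days-
covered under carryover; patients at or above a threshold (0.80 by
convention, 0.90 as a stricter variant) are classified adherent.

Persistence is the absence of a disqualifying refill gap: a patient is
non-persistent from the first supply exhaustion that is not followed by
renewed coverage within a grace period (30 days by default).  Durations are
expressed in months of 30.4375 days (365.25 / 12) and right-censored at
death or the end of the analysis window.  The discontinuation event is
timestamped at the exhaustion date, not at grace expiry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
from lifelines import KaplanMeierFitter

from .supply import SupplyTimeline, coverage_days

logger = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.4375  # 365.25 / 12
DEFAULT_GRACE_DAYS = 30
DEFAULT_MPR_THRESHOLD = 0.80


@dataclass(frozen=True)
class AdherenceRecord:
    patient_id: str
    window_start: date
    window_end: date  # inclusive last observed day
    mpr: float  # capped at 1.0
    mpr_uncapped: float  # diagnostic: raw supply / window ratio
    adherent: bool

    def __post_init__(self) -> None:
        if self.window_start > self.window_end:
            raise ValueError("window_start after window_end")
        if not 0.0 <= self.mpr <= 1.0:
            raise ValueError(f"capped MPR out of [0, 1]: {self.mpr}")


@dataclass(frozen=True)
class PersistenceOutcome:
    patient_id: str
    duration_months: float
    discontinued: bool  # True = event observed, False = censored

    def __post_init__(self) -> None:
        if self.duration_months < 0:
            raise ValueError("negative duration")


@dataclass(frozen=True)
class SurvivalCurve:
    """Step-function product-limit estimate."""

    times: tuple[float, ...]  # event times, months, ascending
    survival: tuple[float, ...]  # S(t) just after each event time
    at_risk: tuple[int, ...]

    def survival_at(self, t: float) -> float:
        """S(t): value of the step function at time t (S(0) = 1)."""
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


def compute_mpr(
    timeline: SupplyTimeline,
    window_start: date,
    window_end: date,
    cap: bool = True,
) -> float:
    """MPR over the inclusive day window [window_start, window_end].

    Denominator is the window length in days; numerator is covered days
    (capped implicitly at the window length).  With ``cap`` unset the raw
    supply ratio (total dispensed days / window days, possibly > 1) is
    returned for diagnostics.
    """
    n_days = (window_end - window_start).days + 1
    if n_days < 1:
        raise ValueError("degenerate observation window")
    if cap:
        covered = coverage_days(timeline, window_start, window_end + timedelta(days=1))
        return min(covered / n_days, 1.0)
    total = sum((e - s).days for s, e in timeline.intervals)
    return total / n_days


def classify_adherent(mpr: float, threshold: float = DEFAULT_MPR_THRESHOLD) -> bool:
    """Threshold comparison, boundary inclusive (MPR >= threshold)."""
    if not 0.0 <= mpr <= 1.0:
        raise ValueError(f"MPR out of [0, 1]: {mpr}")
    return mpr >= threshold


def cohort_adherence(
    records: Sequence[AdherenceRecord],
    thresholds: Iterable[float] = (0.80, 0.90),
) -> dict[float, float]:
    """Percentage of the cohort at or above each MPR threshold."""
    if not records:
        raise ValueError("empty cohort")
    n = len(records)
    return {
        thr: 100.0 * sum(r.mpr >= thr for r in records) / n
        for thr in thresholds
    }


def adherence_record(
    timeline: SupplyTimeline,
    study_end: date,
    death_date: date | None = None,
    threshold: float = DEFAULT_MPR_THRESHOLD,
) -> AdherenceRecord | None:
    """Per-patient adherence over first-dispensation → min(death, study end).

    Returns None (logged) for degenerate windows (no coverage, or death
    recorded before the first fill).
    """
    if not timeline.intervals:
        return None
    window_start = timeline.intervals[0][0]
    window_end = min(death_date, study_end) if death_date else study_end
    if window_end < window_start:
        logger.warning("patient %s: observation window empty, excluded", timeline.patient_id)
        return None
    mpr = compute_mpr(timeline, window_start, window_end, cap=True)
    raw = compute_mpr(timeline, window_start, window_end, cap=False)
    return AdherenceRecord(
        patient_id=timeline.patient_id,
        window_start=window_start,
        window_end=window_end,
        mpr=mpr,
        mpr_uncapped=raw,
        adherent=mpr >= threshold,
    )


def detect_discontinuation(
    timeline: SupplyTimeline,
    window_start: date,
    window_end: date,
    grace_days: int = DEFAULT_GRACE_DAYS,
    death_date: date | None = None,
) -> PersistenceOutcome:
    """Scan coverage from ``window_start`` for the first disqualifying gap.

    A discontinuation event occurs at the first supply-exhaustion date (on or
    after window start) not followed by renewed coverage within
    ``grace_days``.  Supply at window start includes carry-in from earlier
    dispensations.  A patient already out of supply beyond grace at window
    start scores an event of duration 0.  Otherwise the patient is censored
    at death or window end, whichever is first.
    """
    if grace_days < 0:
        raise ValueError("grace_days must be >= 0")
    censor = min(death_date, window_end) if death_date else window_end
    if censor < window_start:
        raise ValueError("censoring date before window start")
    pid = timeline.patient_id

    def months(d: date) -> float:
        return (d - window_start).days / DAYS_PER_MONTH

    intervals = timeline.intervals
    # walk exhaustion points (interval ends) and the refill that follows each
    for i, (start, end) in enumerate(intervals):
        if end > censor:
            # supply outlives observation
            return PersistenceOutcome(pid, months(censor), discontinued=False)
        next_start = intervals[i + 1][0] if i + 1 < len(intervals) else None
        if next_start is None:
            # no further coverage ever: event if the grace window closes
            # within observation, else unobservable -> censored
            if (censor - end).days > grace_days:
                event_date = max(end, window_start)
                return PersistenceOutcome(pid, months(event_date), discontinued=True)
            return PersistenceOutcome(pid, months(censor), discontinued=False)
        if next_start <= window_start:
            continue  # gap entirely before the analysis window
        if (next_start - end).days > grace_days:
            event_date = max(end, window_start)
            return PersistenceOutcome(pid, months(event_date), discontinued=True)
    # empty timeline: no coverage at all
    return PersistenceOutcome(pid, 0.0, discontinued=True)


def kaplan_meier(outcomes: Sequence[PersistenceOutcome]) -> SurvivalCurve:
    """Product-limit estimate of the persistence function."""
    if not outcomes:
        raise ValueError("no outcomes")
    durations = np.array([o.duration_months for o in outcomes], dtype=float)
    events = np.array([o.discontinued for o in outcomes], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    surv = kmf.survival_function_["KM_estimate"]
    event_table = kmf.event_table
    times, probs, at_risk = [], [], []
    for t, s in surv.items():
        if t == 0 and s == 1.0 and 0.0 not in set(durations[events]):
            continue  # implicit S(0)=1 anchor, not an event time
        times.append(float(t))
        probs.append(float(s))
        at_risk.append(int(event_table.loc[t, "at_risk"]))
    return SurvivalCurve(tuple(times), tuple(probs), tuple(at_risk))


def summarize_persistence(
    outcomes: Sequence[PersistenceOutcome],
    horizon_months: float = 12.0,
) -> tuple[float, float, float]:
    """(S at horizon, mean months of continuous therapy, SD of months).

    The mean is the arithmetic mean of observed durations over all patients,
    events and censored alike (window-truncated).
    """
    curve = kaplan_meier(outcomes)
    durations = np.array([o.duration_months for o in outcomes], dtype=float)
    return (
        curve.survival_at(horizon_months),
        float(durations.mean()),
        float(durations.std(ddof=1)) if len(durations) > 1 else 0.0,
    )


def sample_persistence_cohort(
    eligible: Iterable[str],
    n: int = 100_000,
    seed: int = 0,
) -> list[str]:
    """Uniform sample of patient ids without replacement, seed-reproducible.

    If fewer than ``n`` patients are eligible, all are returned (with a
    warning), mirroring a registry smaller than the requested sample.
    """
    pool = sorted(set(eligible))
    if n >= len(pool):
        if n > len(pool):
            logger.warning(
                "requested sample %d exceeds eligible %d; taking all", n, len(pool)
            )
        return pool
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return sorted(pool[i] for i in idx)


def persistence_outcomes(
    timelines: Mapping[str, SupplyTimeline],
    sample_ids: Sequence[str],
    window_start: date,
    window_end: date,
    grace_days: int = DEFAULT_GRACE_DAYS,
    death_dates: Mapping[str, date] | None = None,
) -> list[PersistenceOutcome]:
    """Discontinuation outcomes for a sampled subcohort."""
    death_dates = death_dates or {}
    out = []
    for pid in sample_ids:
        tl = timelines.get(pid, SupplyTimeline(patient_id=pid, intervals=[]))
        out.append(
            detect_discontinuation(
                tl,
                window_start,
                window_end,
                grace_days=grace_days,
                death_date=death_dates.get(pid),
            )
        )
    return out
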