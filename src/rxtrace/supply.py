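"""Medication-supply timelines and standard-pack arithmetic.

A patient's dispensations are converted into a per-patient timeline of
covered days under the convention of one tablet per day, all compounds
interchangeable.  The default semantics honours stockpiling (carryover): a
refill collected before the previous supply has run out starts covering when
that supply is exhausted, so early refills extend coverage contiguously and
only late refills leave uncovered gaps.

Days are handled at date resolution with half-open intervals
``[start, end)``; a dispensation of *t* tablets on day *d* covers days
``d .. d+t-1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Sequence

from .registry import DispensationEvent


def tablets_to_packs(tablets: int, pack_size: int = 30) -> int:
    """Convert a tablet count to standard-pack equivalents.

    Rounds half away from zero, which reproduces printed national pack
    counts from tablet totals.
    """
    if pack_size <= 0:
        raise ValueError(f"pack_size must be positive, got {pack_size}")
    if tablets < 0:
        raise ValueError(f"tablets must be non-negative, got {tablets}")
    # integer half-away-from-zero: avoids float error on 10-digit counts
    return (2 * tablets + pack_size) // (2 * pack_size)


@dataclass
class SupplyTimeline:
    """Ordered disjoint half-open coverage intervals for one patient."""

    patient_id: str
    intervals: list[tuple[date, date]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end: date | None = None
        for start, end in self.intervals:
            if start >= end:
                raise ValueError(f"empty or inverted interval [{start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValueError("intervals must be disjoint and sorted")
            prev_end = end

    @property
    def total_days(self) -> int:
        return sum((end - start).days for start, end in self.intervals)

    @property
    def coverage_end(self) -> date | None:
        """Day after the last covered day, or None for an empty timeline."""
        return self.intervals[-1][1] if self.intervals else None


def build_supply_timeline(
    dispensations: Sequence[DispensationEvent],
    dose_per_day: int = 1,
    carryover: bool = True,
) -> SupplyTimeline:
    """Union of coverage from one patient's dispensations.

    With ``carryover`` (default), each fill adds ``tablets // dose_per_day``
    days of coverage starting at the later of its dispense date and the
    current exhaustion date.  Without carryover, each fill covers from its own
    date and overlapping supply is forfeited (intervals merged).

    The result is invariant to the order of the input events (sorted by
    dispense date internally, ties broken by tablets then prescription id).
    """
    if dose_per_day < 1:
        raise ValueError("dose_per_day must be >= 1")
    if not dispensations:
        return SupplyTimeline(patient_id="", intervals=[])
    patient_ids = {d.patient_id for d in dispensations}
    if len(patient_ids) != 1:
        raise ValueError(f"events from multiple patients: {sorted(patient_ids)}")
    events = sorted(dispensations, key=lambda d: (d.dispense_date, d.tablets, d.prescription_id))

    intervals: list[tuple[date, date]] = []
    exhaustion: date | None = None
    for ev in events:
        days = ev.tablets // dose_per_day
        if days <= 0:
            continue
        if carryover:
            start = ev.dispense_date if exhaustion is None or ev.dispense_date > exhaustion else exhaustion
        else:
            start = ev.dispense_date
        end = start + timedelta(days=days)
        if carryover:
            if intervals and start == intervals[-1][1]:
                intervals[-1] = (intervals[-1][0], end)
            else:
                intervals.append((start, end))
            exhaustion = end
        else:
            if intervals and start <= intervals[-1][1]:
                if end > intervals[-1][1]:
                    intervals[-1] = (intervals[-1][0], end)
            else:
                intervals.append((start, end))
    return SupplyTimeline(patient_id=events[0].patient_id, intervals=intervals)


def coverage_days(timeline: SupplyTimeline, window_start: date, window_end: date) -> int:
    """Number of covered days inside the half-open window ``[start, end)``."""
    if window_start >= window_end:
        raise ValueError(f"window [{window_start}, {window_end}) is empty")
    total = 0
    for start, end in timeline.intervals:
        lo = max(start, window_start)
        hi = min(end, window_end)
        if lo < hi:
            total += (hi - lo).days
    return total


def timelines_by_patient(
    dispensations: Sequence[DispensationEvent],
    dose_per_day: int = 1,
    carryover: bool = True,
) -> dict[str, SupplyTimeline]:
    """Build one timeline per patient (events keyed by patient_id)."""
    grouped: dict[str, list[DispensationEvent]] = {}
    for d in dispensations:
        grouped.setdefault(d.patient_id, []).append(d)
    return {
        pid: build_supply_timeline(evs, dose_per_day=dose_per_day, carryover=carryover)
        for pid, evs in grouped.items()
    }


def write_timelines_csv(timelines: dict[str, SupplyTimeline], path) -> None:
    """Diagnostic export: one row per coverage interval."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "start", "end"])
        for pid in sorted(timelines):
            for start, end in timelines[pid].intervals:
                w.writerow([pid, start.isoformat(), end.isoformat()])
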