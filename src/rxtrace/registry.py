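"""Domain types and CSV I/O for e-prescription registries.

An e-prescription registry is modelled as three flat tables: issued
prescriptions, dispensations (fills) linked to prescriptions, and patients.
Quantities are expressed in tablets throughout; all retained drugs are treated
as interchangeable at one tablet per day, so no strength or compound
information is carried.

CSV schemas (ISO-8601 dates)::

    prescriptions.csv: prescription_id,patient_id,issue_date,atc_code,tablets
    dispensations.csv: prescription_id,patient_id,dispense_date,tablets
    patients.csv:      patient_id,sex,birth_year,death_date   (death_date may be empty)
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: ATC inclusion rule: plain statins are any code under C10AA; fixed-dose
#: combinations of statins with other lipid-modifying agents are the
#: enumerated C10BA codes.  Combinations with non-lipid-lowering drugs
#: (e.g. C10BX) and other lipid-lowering classes (C10AB fibrates,
#: C10AX ezetimibe) are excluded.
STATIN_ATC_PREFIX = "C10AA"
STATIN_COMBINATION_CODES = frozenset(
    {f"C10BA{i:02d}" for i in range(1, 10)} | {"C10BA11", "C10BA12"}
)


@dataclass(frozen=True)
class PrescriptionEvent:
    """One issued e-prescription line."""

    prescription_id: str
    patient_id: str
    issue_date: date
    atc_code: str
    tablets: int


@dataclass(frozen=True)
class DispensationEvent:
    """One fill of an e-prescription (partial fills allowed)."""

    prescription_id: str
    patient_id: str
    dispense_date: date
    tablets: int


@dataclass(frozen=True)
class Patient:
    patient_id: str
    sex: str  # "F", "M" or "missing"
    birth_year: int
    death_date: date | None = None


@dataclass(frozen=True)
class StudyWindow:
    """Half-open-by-day analysis window; both endpoints are included days."""

    start: date = date(2020, 1, 8)
    end: date = date(2022, 12, 31)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"study window start {self.start} not before end {self.end}")

    def contains(self, d: date) -> bool:
        return self.start <= d <= self.end

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1


DEFAULT_WINDOW = StudyWindow()

_VALID_SEX = {"F", "M", "missing"}


def _parse_date(text: str) -> date:
    return date.fromisoformat(text.strip())


def _read_rows(path: str | Path, required: Sequence[str]) -> Iterable[dict]:
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        extra = [c for c in header if c not in required]
        if extra:
            logger.warning("%s: ignoring unknown columns %s", path, extra)
        for row in reader:
            yield row


def read_prescriptions(path: str | Path) -> list[PrescriptionEvent]:
    """Read prescriptions.csv; malformed rows are dropped with a logged
    diagnostic, exact duplicate rows are dropped once."""
    out: list[PrescriptionEvent] = []
    seen: set[tuple] = set()
    n_bad = n_dup = 0
    for row in _read_rows(path, ["prescription_id", "patient_id", "issue_date", "atc_code", "tablets"]):
        try:
            rec = PrescriptionEvent(
                prescription_id=row["prescription_id"].strip(),
                patient_id=row["patient_id"].strip(),
                issue_date=_parse_date(row["issue_date"]),
                atc_code=row["atc_code"].strip(),
                tablets=int(row["tablets"]),
            )
            if rec.tablets < 1:
                raise ValueError(f"non-positive tablets {rec.tablets}")
        except (ValueError, KeyError) as exc:
            n_bad += 1
            logger.warning("prescriptions: rejected row %r (%s)", row, exc)
            continue
        key = (rec.prescription_id, rec.patient_id, rec.issue_date, rec.atc_code, rec.tablets)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        out.append(rec)
    if n_bad or n_dup:
        logger.info("prescriptions: %d rejected, %d exact duplicates dropped", n_bad, n_dup)
    return out


def read_dispensations(path: str | Path) -> list[DispensationEvent]:
    out: list[DispensationEvent] = []
    seen: set[tuple] = set()
    n_bad = n_dup = 0
    for row in _read_rows(path, ["prescription_id", "patient_id", "dispense_date", "tablets"]):
        try:
            rec = DispensationEvent(
                prescription_id=row["prescription_id"].strip(),
                patient_id=row["patient_id"].strip(),
                dispense_date=_parse_date(row["dispense_date"]),
                tablets=int(row["tablets"]),
            )
            if rec.tablets < 1:
                raise ValueError(f"non-positive tablets {rec.tablets}")
        except (ValueError, KeyError) as exc:
            n_bad += 1
            logger.warning("dispensations: rejected row %r (%s)", row, exc)
            continue
        key = (rec.prescription_id, rec.patient_id, rec.dispense_date, rec.tablets)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        out.append(rec)
    if n_bad or n_dup:
        logger.info("dispensations: %d rejected, %d exact duplicates dropped", n_bad, n_dup)
    return out


def read_patients(path: str | Path) -> list[Patient]:
    out: list[Patient] = []
    seen: set[tuple] = set()
    n_bad = n_dup = 0
    for row in _read_rows(path, ["patient_id", "sex", "birth_year", "death_date"]):
        try:
            death_raw = (row.get("death_date") or "").strip()
            sex = (row["sex"] or "missing").strip() or "missing"
            if sex not in _VALID_SEX:
                raise ValueError(f"unknown sex code {sex!r}")
            rec = Patient(
                patient_id=row["patient_id"].strip(),
                sex=sex,
                birth_year=int(row["birth_year"]),
                death_date=_parse_date(death_raw) if death_raw else None,
            )
        except (ValueError, KeyError) as exc:
            n_bad += 1
            logger.warning("patients: rejected row %r (%s)", row, exc)
            continue
        key = (rec.patient_id, rec.sex, rec.birth_year, rec.death_date)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        out.append(rec)
    if n_bad or n_dup:
        logger.info("patients: %d rejected, %d exact duplicates dropped", n_bad, n_dup)
    return out


def read_registry(
    prescriptions_path: str | Path,
    dispensations_path: str | Path,
    patients_path: str | Path,
) -> tuple[list[PrescriptionEvent], list[DispensationEvent], list[Patient]]:
    """Read the three registry CSVs into typed records."""
    return (
        read_prescriptions(prescriptions_path),
        read_dispensations(dispensations_path),
        read_patients(patients_path),
    )


def write_registry(
    prescriptions: Sequence[PrescriptionEvent],
    dispensations: Sequence[DispensationEvent],
    patients: Sequence[Patient],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the registry as the three documented CSVs; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "prescriptions": out_dir / "prescriptions.csv",
        "dispensations": out_dir / "dispensations.csv",
        "patients": out_dir / "patients.csv",
    }
    with paths["prescriptions"].open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["prescription_id", "patient_id", "issue_date", "atc_code", "tablets"])
        for p in prescriptions:
            w.writerow([p.prescription_id, p.patient_id, p.issue_date.isoformat(), p.atc_code, p.tablets])
    with paths["dispensations"].open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["prescription_id", "patient_id", "dispense_date", "tablets"])
        for d in dispensations:
            w.writerow([d.prescription_id, d.patient_id, d.dispense_date.isoformat(), d.tablets])
    with paths["patients"].open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "sex", "birth_year", "death_date"])
        for pat in patients:
            w.writerow([
                pat.patient_id,
                pat.sex,
                pat.birth_year,
                pat.death_date.isoformat() if pat.death_date else "",
            ])
    return paths


def is_statin_atc(atc_code: str) -> bool:
    """True for plain statins (C10AA*) and the retained statin+lipid-modifying
    fixed-dose combinations; False for everything else (incl. statin +
    non-lipid-lowering combinations, ezetimibe, fibrates)."""
    code = atc_code.strip().upper()
    return code.startswith(STATIN_ATC_PREFIX) or code in STATIN_COMBINATION_CODES


def filter_statin_atc(events: Sequence[PrescriptionEvent]) -> list[PrescriptionEvent]:
    """Keep prescription events for included statin ATC codes only.

    Idempotent; output is always a subset of the input.  Events with empty or
    too-short ATC strings are excluded with a warning.
    """
    kept: list[PrescriptionEvent] = []
    n_short = 0
    for ev in events:
        code = ev.atc_code.strip()
        if len(code) < 5:
            n_short += 1
            continue
        if is_statin_atc(code):
            kept.append(ev)
    if n_short:
        logger.warning("filter_statin_atc: %d events with empty/short ATC excluded", n_short)
    return kept


def link_dispensations(
    prescriptions: Sequence[PrescriptionEvent],
    dispensations: Sequence[DispensationEvent],
) -> list[DispensationEvent]:
    """Restrict dispensations to those whose prescription is in the given set
    (used to propagate the ATC filter, which lives on prescriptions)."""
    ids = {p.prescription_id for p in prescriptions}
    return [d for d in dispensations if d.prescription_id in ids]


def include_patients(
    prescriptions: Sequence[PrescriptionEvent],
    dispensations: Sequence[DispensationEvent],
    window: StudyWindow = DEFAULT_WINDOW,
) -> set[str]:
    """Cohort inclusion: patients with at least one (statin) dispensation
    inside the window.  Patients with prescriptions only are excluded.
    Assumes the statin filter has been applied upstream."""
    return {d.patient_id for d in dispensations if window.contains(d.dispense_date)}
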