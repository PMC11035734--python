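"""Shared fixtures: event builders and a session-scoped default simulation."""

from __future__ import annotations

import json
from datetime import date, timedelta

import pytest

from rxtrace import (
    CohortParams,
    CovidParams,
    DispensationEvent,
    PipelineConfig,
    PrescriptionEvent,
    StudyWindow,
    generate_cohort,
    run_pipeline,
    simulate_to_dir,
)

BASE = date(2022, 1, 1)


def day(offset: int) -> date:
    """Calendar date at a day offset from the 2022-01-01 reference."""
    return BASE + timedelta(days=offset)


def rx(rx_id: str, pid: str, issue_offset: int, tablets: int = 30, atc: str = "C10AA05") -> PrescriptionEvent:
    return PrescriptionEvent(rx_id, pid, day(issue_offset), atc, tablets)


def disp(rx_id: str, pid: str, disp_offset: int, tablets: int = 30) -> DispensationEvent:
    return DispensationEvent(rx_id, pid, day(disp_offset), tablets)


@pytest.fixture(scope="session")
def default_cohort():
    """Default-parameter cohort at the standard simulation scale."""
    params = CohortParams(n_patients=10_000, seed=1)
    patients, prescriptions, dispensations = generate_cohort(params, StudyWindow())
    return params, patients, prescriptions, dispensations


@pytest.fixture(scope="session")
def full_run(tmp_path_factory):
    """One end-to-end simulate + analyze at the default scale."""
    td = tmp_path_factory.mktemp("full_run")
    reg_dir, out_dir = td / "reg", td / "out"
    simulate_to_dir(reg_dir, CohortParams(n_patients=10_000, seed=1), CovidParams(seed=2))
    summary = run_pipeline(PipelineConfig(seed=3), reg_dir, out_dir)
    with (out_dir / "covid_report.json").open() as fh:
        covid_report = json.load(fh)
    return {
        "summary": summary,
        "covid_report": covid_report,
        "reg_dir": reg_dir,
        "out_dir": out_dir,
    }
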