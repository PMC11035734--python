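"""End-to-end orchestration: registry → supply → adherence/persistence →
weekly trends → COVID context → report files.

``run_pipeline`` reads a registry (three CSVs plus an optional ECDC-dialect
COVID CSV), applies the statin inclusion filter, and writes::

    weekly_series.csv   per-ISO-week tablets, pct dispensed, per-1000, lockdown flag
    adherence.csv       per-patient MPR and threshold classifications
    persistence.csv     per-patient duration (months) and event flag
    km_curve.csv        product-limit persistence curve
    covid_report.json   correlations, lockdown and matched-week comparisons
    summary.json        totals, pack equivalents, trends, adherence/persistence

Every reported number is produced by a module operation; the run log records
seed, config hash and record counts at each stage.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from datetime import date
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import adherence as adh
from . import covid as cov
from . import registry as reg
from . import supply as sup
from . import trends as trd
from .covid import DEFAULT_LOCKDOWN_RANGES, LockdownCalendar
from .registry import StudyWindow

logger = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    """Analysis configuration; all study constants are defaults here, never
    hard-coded at call sites."""

    schema_version: int = 1
    study_start: date = date(2020, 1, 8)
    study_end: date = date(2022, 12, 31)

    prescriptions_csv: str = "prescriptions.csv"
    dispensations_csv: str = "dispensations.csv"
    patients_csv: str = "patients.csv"
    covid_csv: str | None = "covid_weekly.csv"
    covid_country: str = "Poland"

    adherence_thresholds: tuple[float, ...] = (0.80, 0.90)
    grace_days: int = Field(30, ge=0)
    pack_size: int = Field(30, gt=0)

    persistence_start: date = date(2022, 1, 1)
    persistence_end: date = date(2022, 12, 31)
    persistence_sample_n: int = Field(100_000, ge=1)
    seed: int = 0

    correlation_method: str = "spearman"
    detrend_lockdown: bool = False
    lockdown_ranges: tuple[tuple[int, int, int], ...] = DEFAULT_LOCKDOWN_RANGES
    population_thousands: dict[int, float] = Field(
        default_factory=lambda: dict(trd.DEFAULT_POPULATION_THOUSANDS)
    )

    @field_validator("adherence_thresholds")
    @classmethod
    def _thresholds_valid(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if any(not 0.0 < t <= 1.0 for t in v):
            raise ValueError("thresholds must lie in (0, 1]")
        return v

    @property
    def window(self) -> StudyWindow:
        return StudyWindow(start=self.study_start, end=self.study_end)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw.get("analyze", raw))

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _round_floats(obj: Any, ndigits: int = 6) -> Any:
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _write_json(payload: dict, path: Path) -> None:
    with path.open("w") as fh:
        json.dump(_round_floats(payload), fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig, in_dir: str | Path, out_dir: str | Path) -> dict:
    """Run the full analysis; returns the summary dict (also written to
    ``summary.json``).  Any stage failure raises with a stage-labelled
    message."""
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    window = config.window
    logger.info(
        "pipeline start: seed=%d config=%s in=%s", config.seed, config.config_hash(), in_dir
    )

    # --- stage: registry -------------------------------------------------
    try:
        prescriptions, dispensations, patients = reg.read_registry(
            in_dir / config.prescriptions_csv,
            in_dir / config.dispensations_csv,
            in_dir / config.patients_csv,
        )
    except Exception as exc:
        raise RuntimeError(f"registry stage failed: {exc}") from exc
    n_rx_raw, n_disp_raw = len(prescriptions), len(dispensations)
    prescriptions = reg.filter_statin_atc(prescriptions)
    dispensations = reg.link_dispensations(prescriptions, dispensations)
    included = reg.include_patients(prescriptions, dispensations, window)
    death_dates = {p.patient_id: p.death_date for p in patients if p.death_date}
    n_deaths = sum(1 for p in patients if p.death_date)
    n_missing_sex = sum(1 for p in patients if p.sex == "missing")
    logger.info(
        "registry: %d/%d statin prescriptions, %d/%d linked dispensations, "
        "%d included patients, %d deaths, %d missing sex",
        len(prescriptions), n_rx_raw, len(dispensations), n_disp_raw,
        len(included), n_deaths, n_missing_sex,
    )

    # --- stage: supply ----------------------------------------------------
    try:
        timelines = sup.timelines_by_patient(dispensations)
    except Exception as exc:
        raise RuntimeError(f"supply stage failed: {exc}") from exc

    # --- stage: adherence -------------------------------------------------
    try:
        records = []
        for pid in sorted(included):
            rec = adh.adherence_record(
                timelines[pid],
                study_end=window.end,
                death_date=death_dates.get(pid),
                threshold=config.adherence_thresholds[0],
            )
            if rec is not None:
                records.append(rec)
        adherence_pct = adh.cohort_adherence(records, config.adherence_thresholds)
        mean_mpr = float(np.mean([r.mpr for r in records]))
        sd_mpr = float(np.std([r.mpr for r in records], ddof=1))
    except Exception as exc:
        raise RuntimeError(f"adherence stage failed: {exc}") from exc
    with (out_dir / "adherence.csv").open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "window_start", "window_end", "mpr", "adherent80", "adherent90"])
        for r in records:
            w.writerow([
                r.patient_id, r.window_start.isoformat(), r.window_end.isoformat(),
                f"{r.mpr:.6f}", int(r.mpr >= 0.80), int(r.mpr >= 0.90),
            ])

    # --- stage: persistence ----------------------------------------------
    try:
        # eligibility: a dispensation before the persistence window plus
        # supply (or grace) reaching the window start — i.e. current users
        eligible = []
        for pid in sorted(included):
            dd = death_dates.get(pid)
            if dd is not None and dd < config.persistence_start:
                continue
            tl = timelines[pid]
            if not tl.intervals or tl.intervals[0][0] >= config.persistence_start:
                continue
            cov_end = tl.coverage_end
            last_ok = (config.persistence_start - cov_end).days <= config.grace_days
            has_late = any(e > config.persistence_start for _, e in tl.intervals)
            if last_ok or has_late:
                eligible.append(pid)
        sample = adh.sample_persistence_cohort(
            eligible, n=config.persistence_sample_n, seed=config.seed
        )
        outcomes = adh.persistence_outcomes(
            timelines, sample, config.persistence_start, config.persistence_end,
            grace_days=config.grace_days, death_dates=death_dates,
        )
        curve = adh.kaplan_meier(outcomes)
        s12, mean_months, sd_months = adh.summarize_persistence(outcomes)
    except Exception as exc:
        raise RuntimeError(f"persistence stage failed: {exc}") from exc
    with (out_dir / "persistence.csv").open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "duration_months", "discontinued"])
        for o in outcomes:
            w.writerow([o.patient_id, f"{o.duration_months:.6f}", int(o.discontinued)])
    with (out_dir / "km_curve.csv").open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_months", "survival", "at_risk"])
        for t, s, n in zip(curve.times, curve.survival, curve.at_risk):
            w.writerow([f"{t:.6f}", f"{s:.6f}", n])

    # --- stage: weekly trends --------------------------------------------
    try:
        weekly = trd.aggregate_weekly(prescriptions, dispensations, window)
        weekly = trd.percent_dispensed(weekly)
        weekly = trd.per_capita_rate(weekly, config.population_thousands)
        calendar = LockdownCalendar(ranges=config.lockdown_ranges)
        flags, n_lockdown_weeks = cov.lockdown_flags(calendar, list(weekly.index))
        weekly["lockdown_flag"] = flags.astype(int)

        total_rx = int(weekly["prescribed_tablets"].sum())
        total_disp = int(weekly["dispensed_tablets"].sum())
        fill_pct = trd.overall_fill_percentage(total_disp, total_rx)
        fit_rx = trd.fit_linear_trend(weekly["prescribed_tablets"])
        fit_disp = trd.fit_linear_trend(weekly["dispensed_tablets"])
        fit_pct = trd.fit_linear_trend(weekly["pct_dispensed"])
        quarters = trd.aggregate_quarters(weekly["pct_dispensed"])
        quarter_tests = trd.compare_quarters(weekly["pct_dispensed"])
        years = trd.compare_years(weekly["pct_dispensed"])
    except Exception as exc:
        raise RuntimeError(f"trends stage failed: {exc}") from exc
    weekly_out = weekly.reset_index()
    weekly_out.to_csv(out_dir / "weekly_series.csv", index=False, float_format="%.6f")

    # --- stage: covid context --------------------------------------------
    covid_report: dict[str, Any] = {"available": False}
    if config.covid_csv is not None and (in_dir / config.covid_csv).exists():
        try:
            covid = cov.read_ecdc_weekly(
                in_dir / config.covid_csv, list(weekly.index), country=config.covid_country
            )
            method = config.correlation_method
            correlations = {}
            for covid_col in ("covid_cases", "covid_deaths"):
                for statin_col in ("prescribed_tablets", "dispensed_tablets", "pct_dispensed"):
                    vals = weekly[statin_col].to_numpy(dtype=float)
                    mask = ~np.isnan(vals)
                    rho, p = cov.correlate_series(
                        covid[covid_col].to_numpy(dtype=float)[mask], vals[mask], method=method
                    )
                    correlations[f"{covid_col}_vs_{statin_col}"] = {"rho": rho, "p": p}
            lock_rx = cov.compare_lockdown(
                weekly["prescribed_tablets"], flags, detrend=config.detrend_lockdown
            )
            lock_disp = cov.compare_lockdown(
                weekly["dispensed_tablets"], flags, detrend=config.detrend_lockdown
            )
            lock_pct = cov.compare_lockdown(weekly["pct_dispensed"], flags)
            pct_lock = weekly.loc[flags.to_numpy(dtype=bool), "pct_dispensed"]
            pct_open = weekly.loc[~flags.to_numpy(dtype=bool), "pct_dispensed"]
            matched = cov.matched_week_comparison(weekly["pct_dispensed"], calendar)

            def _regression(series: pd.Series) -> dict[str, float | None]:
                try:
                    d, p = cov.lockdown_effect_regression(series, flags)
                    return {"percent_deficit": d, "p_value": p}
                except ValueError as exc:  # e.g. zero-count weeks at tiny scale
                    logger.warning("lockdown regression skipped: %s", exc)
                    return {"percent_deficit": None, "p_value": None}

            reg_rx = _regression(weekly["prescribed_tablets"])
            reg_disp = _regression(weekly["dispensed_tablets"])
            covid_report = {
                "available": True,
                "method": method,
                "correlations": correlations,
                "lockdown_weeks": n_lockdown_weeks,
                "multiple_testing_correction": "none",
                "lockdown_comparison": {
                    "prescribed_tablets": vars(lock_rx),
                    "dispensed_tablets": vars(lock_disp),
                    "pct_dispensed": {
                        **vars(lock_pct),
                        "median_lockdown": float(pct_lock.median()),
                        "median_other": float(pct_open.median()),
                        "sd_lockdown": float(pct_lock.std(ddof=1)),
                        "sd_other": float(pct_open.std(ddof=1)),
                    },
                },
                "lockdown_regression": {
                    "prescribed_tablets": reg_rx,
                    "dispensed_tablets": reg_disp,
                },
                "matched_weeks_vs_2022": [vars(m) for m in matched],
            }
        except Exception as exc:
            raise RuntimeError(f"covid stage failed: {exc}") from exc
    _write_json(covid_report, out_dir / "covid_report.json")

    # --- summary ----------------------------------------------------------
    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "window": {"start": window.start.isoformat(), "end": window.end.isoformat()},
        "cohort": {
            "patients_included": len(included),
            "patients_in_registry": len(patients),
            "deaths": n_deaths,
            "missing_sex": n_missing_sex,
            "prescriptions": len(prescriptions),
            "dispensations": len(dispensations),
        },
        "totals": {
            "prescribed_tablets": total_rx,
            "dispensed_tablets": total_disp,
            "prescribed_packs": sup.tablets_to_packs(total_rx, config.pack_size),
            "dispensed_packs": sup.tablets_to_packs(total_disp, config.pack_size),
            "overall_fill_pct": fill_pct,
            "ever_filled_pct": trd.ever_filled_rate(prescriptions, dispensations),
        },
        "weeks": {
            "n_weeks": trd.count_weeks(window),
            "n_lockdown_weeks": n_lockdown_weeks,
        },
        "trends": {
            "prescribed": {
                "slope_per_week": fit_rx.slope_per_week,
                "first_fitted": fit_rx.first_fitted,
                "last_fitted": fit_rx.last_fitted,
                "pct_change": trd.percent_change_endpoints(fit_rx.first_fitted, fit_rx.last_fitted),
                "p_value": fit_rx.p_value,
            },
            "dispensed": {
                "slope_per_week": fit_disp.slope_per_week,
                "first_fitted": fit_disp.first_fitted,
                "last_fitted": fit_disp.last_fitted,
                "pct_change": trd.percent_change_endpoints(fit_disp.first_fitted, fit_disp.last_fitted),
                "p_value": fit_disp.p_value,
            },
            "pct_dispensed": {
                "slope_per_week": fit_pct.slope_per_week,
                "first_fitted": fit_pct.first_fitted,
                "last_fitted": fit_pct.last_fitted,
                "p_value": fit_pct.p_value,
            },
        },
        "quarters": {
            str(q): {"mean": row["mean"], "sd": row["std"], "n_weeks": int(row["count"])}
            for q, row in quarters.iterrows()
        },
        "quarter_tests": quarter_tests.to_dict(orient="records"),
        "years": {
            "kruskal_h": years.h_statistic,
            "p_value": years.p_value,
            "centers_are_means": years.centers_are_means,
            "center_by_year": {str(y): c for y, c in years.center_by_year.items()},
        },
        "adherence": {
            "n_patients": len(records),
            "mean_mpr_pct": 100.0 * mean_mpr,
            "sd_mpr_pct": 100.0 * sd_mpr,
            "pct_adherent": {f"{t:.2f}": v for t, v in adherence_pct.items()},
        },
        "persistence": {
            "window": {
                "start": config.persistence_start.isoformat(),
                "end": config.persistence_end.isoformat(),
            },
            "eligible": len(eligible),
            "sampled": len(sample),
            "survival_12mo_pct": 100.0 * s12,
            "mean_months": mean_months,
            "sd_months": sd_months,
            "n_events": sum(o.discontinued for o in outcomes),
        },
    }
    _write_json(summary, out_dir / "summary.json")
    logger.info("pipeline done: outputs in %s", out_dir)
    return summary


def render_report(out_dir: str | Path) -> str:
    """Human-readable tables from a completed analysis directory."""
    out_dir = Path(out_dir)
    with (out_dir / "summary.json").open() as fh:
        s = json.load(fh)
    with (out_dir / "covid_report.json").open() as fh:
        c = json.load(fh)
    lines = []
    add = lines.append
    add("=== Statin e-prescription analysis ===")
    add(f"Window: {s['window']['start']} .. {s['window']['end']} "
        f"({s['weeks']['n_weeks']} ISO weeks, {s['weeks']['n_lockdown_weeks']} lockdown)")
    add("")
    add("--- Cohort ---")
    co = s["cohort"]
    add(f"patients included: {co['patients_included']:,}  deaths: {co['deaths']:,}  "
        f"missing sex: {co['missing_sex']:,}")
    add(f"prescriptions: {co['prescriptions']:,}  dispensations: {co['dispensations']:,}")
    add("")
    add("--- Volumes (tablets / 30-tablet pack equivalents) ---")
    t = s["totals"]
    add(f"prescribed: {t['prescribed_tablets']:,} tablets = {t['prescribed_packs']:,} packs")
    add(f"dispensed:  {t['dispensed_tablets']:,} tablets = {t['dispensed_packs']:,} packs")
    add(f"overall fill: {t['overall_fill_pct']:.1f}%  (ever-filled: {t['ever_filled_pct']:.1f}%)")
    add("")
    add("--- Trends (OLS on week index) ---")
    for name in ("prescribed", "dispensed"):
        tr = s["trends"][name]
        add(f"{name}: {tr['first_fitted']:,.0f} -> {tr['last_fitted']:,.0f} tablets/week "
            f"({tr['pct_change']:+.1f}%, p={tr['p_value']:.3g})")
    tp = s["trends"]["pct_dispensed"]
    add(f"pct dispensed: slope {tp['slope_per_week']:+.4f}%/week "
        f"({tp['first_fitted']:.1f}% -> {tp['last_fitted']:.1f}%, p={tp['p_value']:.3g})")
    add("")
    add("--- Percentage dispensed by quarter (pooled across years) ---")
    for q, row in sorted(s["quarters"].items()):
        add(f"Q{q}: {row['mean']:.2f} ± {row['sd']:.2f}%  (n={row['n_weeks']} weeks)")
    yr = s["years"]
    kind = "means" if yr["centers_are_means"] else "medians"
    centers = ", ".join(f"{y}: {v:.1f}%" for y, v in sorted(yr["center_by_year"].items()))
    add(f"between-year Kruskal-Wallis H={yr['kruskal_h']:.2f}, p={yr['p_value']:.3g} ({kind}: {centers})")
    add("")
    add("--- Adherence (MPR from first dispensation to study end) ---")
    a = s["adherence"]
    add(f"mean MPR: {a['mean_mpr_pct']:.1f} ± {a['sd_mpr_pct']:.1f}%")
    for thr, pct in sorted(a["pct_adherent"].items()):
        add(f"adherent at MPR >= {thr}: {pct:.1f}%")
    add("")
    add("--- Persistence (30-day grace, Kaplan-Meier) ---")
    p = s["persistence"]
    add(f"sample: {p['sampled']:,} of {p['eligible']:,} eligible; events: {p['n_events']:,}")
    add(f"S(12 months) = {p['survival_12mo_pct']:.1f}%; "
        f"mean continuous therapy {p['mean_months']:.2f} ± {p['sd_months']:.2f} months")
    if c.get("available"):
        add("")
        add(f"--- COVID context ({c['method']} correlations) ---")
        for key, val in sorted(c["correlations"].items()):
            add(f"{key}: rho={val['rho']:+.3f}, p={val['p']:.3g}")
        for series, comp in sorted(c["lockdown_comparison"].items()):
            add(f"lockdown vs open [{series}]: deficit {comp['percent_deficit']:+.1f}% "
                f"(p={comp['p_value']:.3g}{', detrended' if comp.get('detrended') else ''})")
        for m in c["matched_weeks_vs_2022"]:
            add(f"matched weeks {m['lockdown_year']} w{m['week_from']}-{m['week_to']} vs 2022: "
                f"diff {m['difference']:+.2f} pct-points (p={m['p_value']:.3g})")
        add("note: no multiple-testing correction applied")
    return "\n".join(lines) + "\n"
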