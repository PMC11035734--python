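"""MPR computation, adherence classification, grace-period discontinuation
and Kaplan-Meier persistence."""

from __future__ import annotations

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rxtrace import (
    PersistenceOutcome,
    build_supply_timeline,
    classify_adherent,
    cohort_adherence,
    compute_mpr,
    detect_discontinuation,
    kaplan_meier,
    sample_persistence_cohort,
    summarize_persistence,
)
from rxtrace.adherence import DAYS_PER_MONTH, AdherenceRecord

from .conftest import day, disp


def product_limit_oracle(outcomes):
    """Hand-rolled product-limit estimator, independent of lifelines."""
    times = sorted({o.duration_months for o in outcomes if o.discontinued})
    s, curve = 1.0, {}
    for t in times:
        at_risk = sum(1 for o in outcomes if o.duration_months >= t)
        d = sum(1 for o in outcomes if o.discontinued and o.duration_months == t)
        s *= 1.0 - d / at_risk
        curve[t] = s
    return curve


class TestMPR:
    def test_proportion_of_days_covered(self):
        tl = build_supply_timeline([disp("R1", "P", 0, 60)])
        assert compute_mpr(tl, day(0), day(99)) == pytest.approx(0.60)

    def test_cap_at_one(self):
        tl = build_supply_timeline([disp("R1", "P", 0, 150)])
        assert compute_mpr(tl, day(0), day(99)) == 1.0
        assert compute_mpr(tl, day(0), day(99), cap=False) == pytest.approx(1.5)

    def test_degenerate_window_rejected(self):
        tl = build_supply_timeline([disp("R1", "P", 0, 30)])
        with pytest.raises(ValueError):
            compute_mpr(tl, day(10), day(5))

    @given(st.integers(1, 99), st.integers(0, 123))
    @settings(max_examples=50, derandomize=True)
    def test_invariant_to_splitting_a_fill(self, split, seed):
        rnd = random.Random(seed)
        d0 = rnd.randrange(0, 50)
        whole = build_supply_timeline([disp("R1", "P", d0, 100)])
        parts = build_supply_timeline(
            [disp("R1", "P", d0, split), disp("R1b", "P", d0, 100 - split)]
        )
        assert compute_mpr(whole, day(0), day(299)) == compute_mpr(parts, day(0), day(299))


class TestAdherenceClassification:
    def test_boundary_inclusive(self):
        assert classify_adherent(0.80) is True
        assert classify_adherent(0.799) is False

    def test_cohort_percentage(self):
        records = [
            AdherenceRecord(f"P{i}", day(0), day(99), m, m, m >= 0.8)
            for i, m in enumerate([0.9, 0.7, 0.85, 0.5])
        ]
        pct = cohort_adherence(records)
        assert pct[0.80] == pytest.approx(50.0)
        assert pct[0.90] == pytest.approx(25.0)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_adherence([])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=100, derandomize=True)
    def test_stricter_threshold_never_higher(self, mprs):
        records = [
            AdherenceRecord(f"P{i}", day(0), day(99), m, m, m >= 0.8)
            for i, m in enumerate(mprs)
        ]
        pct = cohort_adherence(records)
        assert pct[0.90] <= pct[0.80]


class TestDiscontinuation:
    def test_refill_within_grace_survives_the_gap(self):
        # supply ends day 30; refill day 55 is within the 30-day grace, so
        # the patient persists through that gap and the clock runs on to the
        # second supply's exhaustion (day 85)
        tl = build_supply_timeline([disp("R1", "P", 0, 30), disp("R2", "P", 55, 30)])
        out = detect_discontinuation(tl, day(0), day(364))
        assert out.duration_months == pytest.approx(85 / DAYS_PER_MONTH)

    def test_refill_one_day_past_grace_is_event(self):
        tl = build_supply_timeline([disp("R1", "P", 0, 30), disp("R2", "P", 61, 30)])
        out = detect_discontinuation(tl, day(0), day(364))
        assert out.discontinued
        assert out.duration_months == pytest.approx(30 / DAYS_PER_MONTH)

    def test_censored_when_supply_reaches_window_end(self):
        tl = build_supply_timeline([disp("R1", "P", 350, 60)])
        out = detect_discontinuation(tl, day(0), day(364))
        assert not out.discontinued
        assert out.duration_months == pytest.approx(364 / DAYS_PER_MONTH)

    def test_event_requires_observable_grace_window(self):
        # supply ends day 350; only 14 days of observation remain, so the
        # 30-day gap cannot be confirmed before censoring
        tl = build_supply_timeline([disp("R1", "P", 320, 30)])
        out = detect_discontinuation(tl, day(0), day(364))
        assert not out.discontinued

    def test_death_censors_before_window_end(self):
        tl = build_supply_timeline([disp("R1", "P", 0, 400)])
        out = detect_discontinuation(tl, day(0), day(364), death_date=day(100))
        assert not out.discontinued
        assert out.duration_months == pytest.approx(100 / DAYS_PER_MONTH)

    def test_exhausted_beyond_grace_before_window_scores_zero(self):
        tl = build_supply_timeline([disp("R1", "P", -90, 30)])
        out = detect_discontinuation(tl, day(0), day(364))
        assert out.discontinued
        assert out.duration_months == 0.0

    def test_carry_in_supply_counts(self):
        # a pre-window fill covers to day 10; the day-30 refill is within
        # grace, so the clock runs to the second supply's exhaustion (day 120)
        tl = build_supply_timeline([disp("R1", "P", -20, 30), disp("R2", "P", 30, 90)])
        out = detect_discontinuation(tl, day(0), day(364))
        assert out.discontinued
        assert out.duration_months == pytest.approx(120 / DAYS_PER_MONTH)

    @given(st.integers(0, 99999))
    @settings(max_examples=40, derandomize=True)
    def test_longer_grace_never_shortens_duration(self, seed):
        rnd = random.Random(seed)
        events = [
            disp(f"R{i}", "P", rnd.randrange(-60, 320), rnd.choice([28, 30, 60, 90]))
            for i in range(rnd.randrange(1, 7))
        ]
        tl = build_supply_timeline(events)
        short = detect_discontinuation(tl, day(0), day(364), grace_days=15)
        long = detect_discontinuation(tl, day(0), day(364), grace_days=45)
        assert long.duration_months >= short.duration_months


class TestKaplanMeier:
    def test_hand_product_limit(self):
        outcomes = [
            PersistenceOutcome("a", 2.0, True),
            PersistenceOutcome("b", 4.0, False),
            PersistenceOutcome("c", 6.0, True),
        ]
        curve = kaplan_meier(outcomes)
        assert curve.survival_at(2.0) == pytest.approx(2 / 3)
        assert curve.survival_at(6.0) == pytest.approx(0.0)

    def test_all_censored_stays_at_one(self):
        outcomes = [PersistenceOutcome(f"p{i}", 12.0, False) for i in range(5)]
        curve = kaplan_meier(outcomes)
        assert curve.survival_at(12.0) == 1.0
        s12, mean, _ = summarize_persistence(outcomes)
        assert s12 == 1.0 and mean == pytest.approx(12.0)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(5)
        durations = rng.exponential(8.0, size=400)
        outcomes = [PersistenceOutcome(f"p{i}", float(d), True) for i, d in enumerate(durations)]
        curve = kaplan_meier(outcomes)
        for t in (1.0, 4.0, 9.0, 15.0):
            empirical = np.mean(durations > t)
            assert curve.survival_at(t) == pytest.approx(empirical, abs=1e-12)

    def test_matches_lifelines_free_oracle(self):
        rng = np.random.default_rng(11)
        outcomes = [
            PersistenceOutcome(f"p{i}", float(rng.integers(1, 15)), bool(rng.random() < 0.7))
            for i in range(200)
        ]
        curve = kaplan_meier(outcomes)
        for t, s in product_limit_oracle(outcomes).items():
            assert curve.survival_at(t) == pytest.approx(s, abs=1e-12)

    def test_exponential_samples_track_closed_form(self):
        lam = 0.0764
        rng = np.random.default_rng(2)
        outcomes = []
        for i, d in enumerate(rng.exponential(1 / lam, size=1000)):
            censored = d > 12.0
            outcomes.append(PersistenceOutcome(f"p{i}", min(float(d), 12.0), not censored))
        curve = kaplan_meier(outcomes)
        sup = max(
            abs(curve.survival_at(t) - math.exp(-lam * t)) for t in np.arange(0.5, 12.0, 0.25)
        )
        assert sup < 0.05


class TestSampling:
    def test_full_pool_returned_when_n_covers_it(self):
        ids = [f"P{i}" for i in range(50)]
        assert sample_persistence_cohort(ids, n=50, seed=0) == sorted(ids)
        assert sample_persistence_cohort(ids, n=99, seed=0) == sorted(ids)

    def test_seed_reproducible(self):
        ids = [f"P{i}" for i in range(1000)]
        a = sample_persistence_cohort(ids, n=100, seed=7)
        b = sample_persistence_cohort(ids, n=100, seed=7)
        c = sample_persistence_cohort(ids, n=100, seed=8)
        assert a == b
        assert a != c
        assert len(set(a)) == 100

    def test_subcohort_km_close_to_full_cohort(self):
        lam = 0.0764
        rng = np.random.default_rng(3)
        outcomes = {
            f"p{i}": PersistenceOutcome(f"p{i}", min(float(d), 12.0), d <= 12.0)
            for i, d in enumerate(rng.exponential(1 / lam, size=50_000))
        }
        full = kaplan_meier(list(outcomes.values())).survival_at(12.0)
        sub_ids = sample_persistence_cohort(list(outcomes), n=5000, seed=4)
        sub = kaplan_meier([outcomes[i] for i in sub_ids]).survival_at(12.0)
        se = math.sqrt(full * (1 - full) / 5000)
        assert abs(sub - full) < 3 * se
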