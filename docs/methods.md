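# Methods

## Scope and data model

The package analyses e-prescription claims for statins: issued prescriptions
(`prescription_id, patient_id, issue_date, atc_code, tablets`), dispensations
linked to prescriptions (partial fills allowed; tablet sums drive all supply
arithmetic), and a patient table (sex, birth year, optional death date). The
inclusion filter keeps ATC codes starting `C10AA` (HMG-CoA reductase
inhibitors) plus the fixed-dose lipid-combination codes `C10BA01–C10BA09`,
`C10BA11`, `C10BA12`; combinations with non-lipid-lowering drugs (`C10BX`)
and other lipid agents (fibrates `C10AB`, ezetimibe `C10AX`) are excluded.
All retained products are treated as interchangeable at one tablet per day,
so strength and compound are ignored; pack counts are standardized to a
30-tablet unit with half-away-from-zero rounding (integer arithmetic, exact
at national magnitudes). The cohort is the set of patients with at least one
statin dispensation inside the study window (default 2020-01-08 to
2022-12-31: the 156 ISO weeks 2020-W02..W53, 2021-W01..W52, 2022-W01..W52).

## Supply timelines

Dispensations are merged per patient into disjoint half-open day intervals
under carryover: each fill contributes `tablets // dose_per_day` covered days
starting at the later of its dispense date and the current exhaustion date.
Stockpiling is uncapped; a no-carryover variant (each fill covers from its
own date, overlap forfeited) is available behind a flag for sensitivity
analyses. Total covered days equal total tablets dispensed whenever no
window truncation applies, and coverage is invariant to input order.
Oversupply at death is not truncated inside timelines; death enters only as
a censoring date at the analysis stage.

## Adherence

MPR is computed from the first dispensation to the study end or death
(inclusive day counts), capped at 1.0; the uncapped ratio is retained as a
diagnostic. Threshold classification is boundary-inclusive (`MPR >= 0.80`,
with 0.90 as the stricter variant), so the share of adherent patients at
0.90 can never exceed the share at 0.80. Because the observation window is
anchored at each patient's own first fill, cohort mean MPR and the adherent
percentage depend on the accrual pattern; they are reported as cohort
descriptions, not calibration targets.

## Persistence

Discontinuation is the first supply exhaustion on or after the persistence
window start that is not followed by renewed coverage within the grace
period (default 30 days; the comparison is strict, so a refill exactly at
`exhaustion + grace` still counts as persistent). The event is dated at the
exhaustion, not at grace expiry — the alternative convention would shift
every duration by a constant 30 days and is easy to apply downstream if
wanted. Durations are expressed in months of 30.4375 days (365.25/12),
censored at death or window end; a terminal gap is only called an event if
the full grace period is observable before censoring. Patients already out
of supply beyond grace at the window start score an event at duration zero.
Restarters after a qualifying gap are non-persistent from that first gap; no
re-initiation analytics are attempted.

The persistence analysis (default window: calendar year 2022) samples up to
100,000 patients uniformly without replacement (seed-reproducible) from the
eligible pool. Eligibility requires a dispensation before the window start
and supply coverage reaching at least `window_start - grace_days` — i.e.
*current* users at baseline. Requiring only a historical dispensation would
flood the sample with patients who quit months earlier and whose duration is
identically zero; the "current users" reading keeps the baseline cohort
well-defined and, for the synthetic registry, makes the Kaplan-Meier curve
directly comparable to the generator's stopping law. The curve itself is the
product-limit estimator (computed via lifelines; an independent hand-rolled
estimator serves as a test oracle), and the reported mean duration of
continuous therapy is the arithmetic mean over all sampled patients,
censored durations included — a window-truncated description, not a survival
mean.

## Utilization series and tests

Events aggregate into ISO-week tablet totals (each event counted in the week
of its own date). The weekly percent dispensed is the same-week ratio
`100 * dispensed / prescribed`; a prescription-linked ever-filled rate is
reported separately, since "share of issued tablets eventually filled"
answers a different question than the weekly flow ratio. Per-capita rates
divide by the population (in thousands) of the week's ISO year. Trends are
ordinary least squares on the week index, with endpoint percent change
computed from the fitted endpoints (raw-endpoint mode available); quarters
are ISO-week blocks 1–13, 14–26, 27–39, 40–end pooled across years and
compared with two-sided Mann-Whitney U tests; between-year comparisons use
Kruskal-Wallis with a Shapiro-Wilk pre-check deciding whether means or
medians are displayed. Correlations against weekly COVID cases and deaths
default to Spearman (weekly counts are heavy-tailed); Pearson is available
by flag. No multiple-testing correction is applied anywhere, and the report
says so.

Lockdown weeks are configuration, not derivation: the default calendar
(2020 weeks 12–22 and 46–52, 2021 weeks 12–16; 23 weeks) is taken as
printed because the underlying civil dates straddle ISO week boundaries.
Two lockdown contrasts are provided: the raw group-mean comparison
(`deficit = 100 * (mean_open - mean_lockdown) / mean_open`, Mann-Whitney
p-value), which is descriptive and confounded by secular growth and
seasonality; and a calendar-adjusted estimator — OLS of log weekly counts on
a linear trend, week-of-year fixed effects and a lockdown indicator, with
the indicator transformed to `100 * (1 - exp(delta))`. The adjusted
estimator recovers a multiplicative lockdown intensity exactly on noiseless
multiplicative data and is the one used for parameter-recovery checks.
A matched-week comparison sets each lockdown period against the
same-numbered weeks of 2022 (paired Wilcoxon; week 53 has no counterpart
and is dropped with a warning).

## Synthetic registry generator

The generator exists because national payer registries are not
redistributable; it emulates the structure the analysis assumes and is
calibrated so the pipeline recovers its parameters.

*Cohort composition.* `n_patients` split into a prevalent pool already on
therapy at the window start (`prevalent_frac = 0.285`) and incident users
whose initiation dates follow a weekly growth trend
(`trend_per_week = 1.189^(1/155)`, i.e. +18.9% across the window applied to
initiation intensity; realized series growth is damped by pool turnover).
The prevalent fraction was set by requiring the null weekly series (no
trend, no seasonality, no lockdown) to be flat: initiation inflow then
balances discontinuation and death outflow.

*Refill process.* Refills are exhaustion-anchored: after a fill of *q*
tablets, the gap to the next prescription is gamma distributed with mean
`q * rx_interval_mean / mean_pack_tablets` and CV `rx_interval_cv = 0.12`.
The default pack mix (28/30-tablet packs and their multiples, weighted
toward 3-month sizes; mean ≈ 75 tablets) makes the mean prescription
interval 75 days. An independent fixed-cadence renewal was rejected at the
design stage: combined with primary non-adherence it manufactures long
supply gaps, i.e. spurious discontinuations that no real refill behaviour
would produce. Prevalent patients run a hazard-free burn-in from before the
window so phases, re-request states and carry-in supply are stationary at
week one.

*Primary non-adherence.* Each prescription is never dispensed with
probability `p_primary_nonadherence = 0.14` (so the expected fill share is
86%); the patient re-requests a replacement after a short geometric delay
(mean 3 days). Dispense delays are geometric with mean 2 days.

*Discontinuation and death.* At every issuance the patient continues with
probability `exp(-hazard * gap_months)`, `hazard = 0.0764` per month; the
telescoping product makes time-to-last-exhaustion exponential with that
hazard at refill epochs (`exp(-12 * 0.0764) ≈ 0.40` 12-month persistence),
and because the decision straddling the analysis-window start covers its
whole elapsed gap, the backward age offsets the forward supply residual and
the pipeline Kaplan-Meier is approximately unbiased for the closed form.
The refill CV and re-request delay were sized so that spurious gap events
contribute about 1% per cycle — small against the 60%/year true stopping
rate. Deaths occur at a constant `annual_death_prob = 0.033`, truncating
refills and entering the registry as death dates.

*Calendar structure.* Seasonal week-of-year multipliers (default: 0.90
trough in weeks 51–53, 1.05 rebound in weeks 1–3) modulate refill timing
through an operational-time warp (each calendar day consumes
`multiplier` demand-days — the standard inhomogeneous-renewal
construction). Lockdown prescribing effects use per-visit thinning instead:
a refill visit falling in a lockdown week is skipped outright with
probability `1 - lockdown_multiplier_rx` (default multiplier 0.932) and the
patient returns at the natural next cadence point. Thinning acts on event
intensities, never on quantities per event; a clock-stretch mechanism was
rejected because lockdown blocks are about one refill cycle long, which
dilutes the measured weekly deficit, and postponement past the block was
rejected because it parks whole refill chains and roughly doubles it. The
dispensing-delay multiplier (`0.941`) stretches in-lockdown dispense delays
analogously.

*COVID series.* Weekly cases are a sum of Gaussian waves with multiplicative
log-normal noise; deaths are a lagged fraction of cases (default lag 2
weeks, ratio 0.025) with independent noise. Counts are non-negative
integers; shapes are phenomenological — there is no transmission mechanism.

*What the generator does not emulate:* covariate structure in adherence
(age/sex effects, co-payment, prescriber behaviour), re-initiation after
discontinuation, partial fills, strength switching, regional heterogeneity,
or any feedback from COVID burden onto prescribing. Tests passing on
synthetic data therefore validate the pipeline's arithmetic and the
generator's calibration contract, not claims about real-world cohorts.

## Numerical and reproducibility choices

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; no global state. Re-running simulation or
analysis with the same seed and config is byte-identical (JSON is written
with sorted keys and rounded floats). Weekly aggregation uses exact integer
tablet sums. Degenerate inputs are defined rather than silent: empty
adherence cohorts and zero-length observation windows raise; identical-group
rank tests return `H = 0, p = 1`; weeks with no prescriptions yield a
missing percent-dispensed that downstream fits skip; the calendar-adjusted
lockdown regression requires positive weekly counts and is skipped (with a
warning and null output) on registries too small to provide them.

## Default problem sizes

Unit and property tests run on hand-sized fixtures plus a shared
10,000-patient default simulation; the acceptance script uses the same
10,000-patient scale, at which the calibration targets are recovered with
comfortable margins (fill percentage SE ≈ 0.2 points; KM(12) SE ≈ 1 point;
calendar-adjusted lockdown deficit SD ≈ 1.4 points across seeds).

## Known limitations

The mean continuous-therapy duration includes censored durations, so it
understates a true survival mean and depends on the window length. The
persistence eligibility rule ("current users") is one defensible reading of
"users before the window start"; the strictly historical reading is
available by composing the lower-level operations directly. The
calendar-adjusted lockdown estimator assumes a log-linear trend and stable
week-of-year effects across three years; with only 23 lockdown weeks its
sampling SD at the default scale is ≈ 1.4 percentage points, so single-seed
recoveries scatter accordingly.
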