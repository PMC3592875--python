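# Methods

This note documents the model implemented in `markovcea`, the choices made
where the published description of the analysis leaves the design open, and
what the synthetic-data machinery does and does not show.

## Model structure

A cohort Markov model with three mutually exclusive states: progression-free
survival (PFS), disease progression (DP) and death (absorbing). The entire
cohort starts in PFS on one of two first-line strategies — erlotinib 150
mg/day until progression, or carboplatin–gemcitabine (CG) chemotherapy for up
to four cycles followed by best supportive care while progression-free.

Structural constants (all configurable):

| parameter | default | units | note |
|---|---|---|---|
| cycle length | 21 | days | 3-week treatment cycle |
| horizon | 10 | years | 174 cycles; doubling it moves discounted totals by <0.5% |
| discount rate | 0.03 | per year | applied to costs and effects as (1+r)^(−t) |
| month / year | 30.4375 / 365.25 | days | calendar-free conversions |

**Cycle-timing convention.** State membership is counted at cycle end (cycles
k ≥ 1) with no half-cycle correction, and new progressors join the DP at-risk
pool — and start accruing DP cost and DP death risk — at the start of the cycle
after they progress. This is one consistent convention chosen because
occupancy × per-cycle cost then reproduces the published lifetime DP cost
entries from the published DP person-years to within ~2%; the original
analysis does not state its convention.

## Survival

PFS is Weibull, S(t) = exp(−(t/λ)^γ). The default calibration is exponential
(γ = 1) per arm, anchored to each arm's trial median m via λ = m/ln 2 —
medians are the only published per-arm survival quantities, and the original
Weibull shapes are unpublished. The trial hazard ratio (0.16) is available as
a scenario (`fit(use_hazard_ratio=True)`) but is *not* used by default: it is
inconsistent with the ratio of median-implied exponential hazards
(4.6/13.1 ≈ 0.35), and the source analysis does not say which quantity
anchored its fits. Per-cycle exit probabilities are
p_k = 1 − S(k·u)/S((k−1)·u); their complement-product telescopes back to
S(k·u) exactly, which the tests assert at 1e−12. Direct PFS→death transitions
default to zero (a background-mortality hook exists in the transition
schedule) because pre-progression death is never quantified in the source.

**Post-progression mortality** is a constant per-cycle probability per arm,
back-calibrated by bisection so the discounted person-years in DP equal the
published 1.23 (erlotinib) and 3.65 (CG) years — the only printed anchor for
life after progression, as the trial released no overall-survival curve.
Discounted DP person-time is strictly decreasing in this probability, so
bisection on [0, 1] (xtol 1e−12, < 60 iterations, no randomness) is exact for
practical purposes; the round-trip test recovers a known probability to 1e−6.
Calibration matches *discounted* person-time because the published table is
discounted. The calibrated values at defaults are ≈0.0427/cycle (erlotinib)
and ≈0.0123/cycle (CG): later progression on erlotinib, shorter survival
after it.

**Consequence of the exponential default.** The model medians (13.10 / 4.61
months) match the published model medians (13.2 / 4.64) at cycle resolution,
but the PFS person-year split differs from the published one (1.48/0.52
discounted PFS years here vs 1.27/0.43 published), because the published
values come from steeper unpublished Weibull shapes. The package therefore
treats the published occupancy table as *input data* for the worked-example
identities and the utility tornado (`params.reference_base_case`,
`sensitivity.reference_icer`), while the full pipeline reports its own
internally consistent numbers (deterministic ICER ≈ $115k/QALY vs published
$85,927/QALY). All decision-level conclusions — erlotinib preferred at the
$13,527/QALY threshold, >90% of PSA draws in the northeast quadrant, CG's
acceptability reaching 50% only at a threshold several times the WTP — agree.

## Costs (2010 USD)

Per-cycle PFS aggregates: CG 1599.41 (cycles 1–4) then BSC 1415.4; erlotinib
1971.1 (cycles 1–7) then 0 (manufacturer donation after ~5 months of
continuous treatment). Differential blood tests (10.59 CG, 3.53 erlotinib)
are charged per PFS cycle on treatment and, by default, stop at the BSC
switch (BSC taken as all-inclusive); both behaviours are switches
(`include_blood_tests`, `blood_tests_stop_at_bsc`) because the source states
only that tests are more frequent under chemotherapy. The published CG
aggregate is treated as all-inclusive: the chemotherapy administration cost
(54.74) is a separately reported component, not added on top, so varying it
one-way has no ICER effect — visible as a zero-spread tornado row rather than
hidden. DP costs 1209.96 per *cycle* in both arms; the alternative per-month
reading is available via `dp_cost_basis="month"`. Adverse-event management
(neutropenia, thrombocytopenia, anaemia; CG only) is one expected one-off
charge at entry, Σ rateᵢ·costᵢ = 1620.951, matching the single published
lifetime figure exactly. The anaemia rate defaults to 0.13 (the
uncertainty-table value that makes this identity exact) over the 9% printed
elsewhere; 0.09 is a one-line config override. A dose-based chemotherapy
audit (BSA 1.72 m², gemcitabine 1000 mg/m² days 1+8) is provided for
inspection only; carboplatin is AUC-dosed via the Calvert formula, whose
renal-clearance input is not published, so its dose must be supplied
explicitly.

## Uncertainty analysis

**One-way (tornado).** Each of the 17 published parameter rows is set to its
low and high with everything else at base; the pipeline is re-run and both
ICERs recorded. Occupancy does not depend on any of these rows except the
discount rate, which re-weights the fixed traces; the DP death probabilities
stay at their base calibration throughout (they are structural, calibrated
once against the published discounted targets). An endpoint that flips the
sign of the QALY difference makes the ratio meaningless; such entries carry a
signed infinite sentinel and an `unstable` flag instead of a number.

**Probabilistic (PSA).** Every non-constant row is sampled independently per
iteration — costs from gamma/lognormal, rates and utilities from beta, as
published. The published table gives ranges but no dispersion convention, so
ranges are read as 95% intervals (sd = range/3.92) and distributions are
moment-matched: gamma shape (m/sd)², scale sd²/m; lognormal solved so the
distribution itself has mean m and sd; beta α = mν, β = (1−m)ν with
ν = m(1−m)/sd² − 1. Draws outside a parameter's domain are resampled (and
counted); with the published rows this never triggers. Survival medians and
DP mortality are not sampled (the published table does not list them);
`run_psa(..., specs=…, recalibrate=True)` supports exploratory runs that do.
Because the parameterisation convention is a declared choice, the published
CEAC landmarks ($96,884 at 50%; $10,264 and $420,000 at 95%) are treated as
soft checks only: the tests require the 50% crossing to lie within a
factor-of-2 band of the deterministic ICER, not to match those numbers.
Default 1000 iterations; a fixed explicit seed makes any run bit-reproducible.

Quadrants of the CE plane use the CG-minus-erlotinib orientation with exact
zeros assigned to the positive side. CEAC probabilities for the two
strategies are complements by construction.

## Synthetic trial data

`simulate.generate_ipd` draws per-arm Weibull event times by inverse
transform (t = λ(−ln U)^{1/γ}) with administrative censoring, defaults 500
patients/arm censored at 24 months and arm medians 13.1/4.6 months. Arm sizes
and censoring are generator parameters, not facts about the trial. It
emulates only what the survival-fitting code needs: independent,
identically-distributed event times with non-informative administrative
censoring. It does not emulate staggered accrual, dropout, interval-censored
assessment schedules, treatment crossover or overall survival — so passing
the parameter-recovery tests (shape and median within 5% at n = 5000 via
Kaplan–Meier + complementary-log-log least squares) demonstrates correctness
of the estimator chain, not robustness to real-trial artefacts. The
Kaplan–Meier estimator is implemented directly and cross-checked in the tests
against both a brute-force risk-set recomputation and lifelines.

## Numerical notes

- Trace conservation is asserted at 1e−9 every cycle; death occupancy is
  clamped at zero against ~1e−15 cancellation residue.
- The trace median is linear interpolation of occupancy between the two
  cycles bracketing 0.5, converted to months; a median not reached within the
  horizon is NaN with a `median_reached` flag.
- ICERs with a zero effect difference return a signed infinity, never raise;
  opposite-sign differences are reported as dominance with no ratio.
- Reports round to 2 decimals; all internal arithmetic is double precision.

## Limitations

- Post-progression mortality is memoryless and arm-constant; the published
  person-time anchor cannot identify anything richer.
- The exponential PFS default reproduces medians, not the full published
  occupancy path (see above).
- No correlation structure between sampled parameters; none is published.
- Single two-strategy comparison; no frontier analysis or value-of-information.
- Costs are fixed 2010 USD; no inflation or currency conversion.
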