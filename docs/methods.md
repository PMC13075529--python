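# Methods

## Model structure

The model is a deterministic Markov cohort simulation.  States are the four
SALT severity strata (≤ 10, 11–20, 21–49, ≥ 50) crossed with treatment
status (on ritlecitinib 50 mg / off treatment), plus absorbing Death.  The
cohort enters entirely in SALT ≥ 50 — the trial's inclusion threshold — on
treatment in the intervention arm and off treatment in the comparator arm.
Cycle length is 12 weeks; the horizon is lifetime, closed deterministically
at a cap age of 100 years where the life table forces qx = 1.

**Trial phase (weeks 0–48).**  The phase 2b/3 trial reports cross-sectional
SALT distributions, not transitions, so the engine imposes those marginals
directly at the cycle boundaries, scaled by cumulative survival: treated at
weeks 12/24/36/48 (the week-34 checkpoint is assigned to the week-36
boundary, the nearest grid point), untreated at weeks 12/24 with the
week-24 distribution held through week 48.  Two printed distributions sum
to 0.999/1.001 from rounding; the residual is absorbed into the largest
(≥ 50) share so occupancies stay on the simplex.

**Week-48 responder split.**  Patients at SALT ≤ 20 at week 48
(35.5% + 13.6% = 49.1% of the cohort) continue treatment; the rest
discontinue and worsen
one stratum (21–49 → ≥ 50).  The split is applied at the week-48 boundary,
so the on-treatment pool from cycle 4 onward is exactly
`0.491 · survival · (1 − d)^(t−4)`.

**Extrapolation (after week 48).**  Continuing responders keep their SALT
stratum while on treatment and leave at the constant per-cycle hazard
`d = 1 − (1 − 0.131)^(12/48) ≈ 0.0345`, worsening one stratum on exit.
This reproduces the roughly 30% retention at four years described for the
model.  Off-treatment patients in SALT 11–20 or 21–49 worsen one stratum
per *worsening interval*; untreated patients who reached SALT ≤ 10 by week
24 are in spontaneous remission and never worsen.  Discontinued responders
are not granted remission: after the one-step exit worsening they follow
the ordinary off-treatment dynamics, and the exit cycle itself counts as an
off-treatment cycle (they are exposed to the natural worsening step in the
same transition).

**Worsening interval (key calibration).**  The source publications state
the direction of off-treatment worsening but not its rate, and the numbers
they print are not mutually consistent about it: the two-year projections
(41.2% at SALT ≤ 20, 29.8% at ≤ 10) equal the continuing-responder pool
alone, which requires worsening of about one stratum per cycle, while the
lifetime incremental QALY (1.09) and both ICERs require a much slower rate.
The default is **one stratum per 52 weeks**, which reproduces the no-
treatment lifetime QALY to 0.8%, the incremental cost to 1%, and both
ICERs to ~4%, while placing the two-year SALT ≤ 20 share at 43.9% (2.7
points above the printed projection; the ≤ 10 share is rate-invariant and
matches to < 0.1 point).  Setting `worsening_interval_weeks: 12` instead
reproduces both two-year shares to < 0.01 point at the cost of an ~20%
higher ICER.  Both settings are exposed in the run settings;
`worsen_new_discontinuers_same_cycle` controls the exit-cycle exposure.

**Mortality.**  A single age/sex-mixed background hazard applies uniformly
to all alive states in both arms (no AA excess mortality).  The annual
probability `q = p_F·qx(age,F) + (1−p_F)·qx(age,M)` is converted per cycle
as `1 − (1−q)^(12/52.1786)`.  Because mortality is uniform across states,
among-alive SALT shares are invariant to the life table — the two-year
projections do not depend on it.  The cohort ages continuously from the
mean entry age (40.2 years); only the mean is modelled, not an age
distribution.

## Valuation

Half-cycle correction averages the occupancy at each cycle's two boundaries
and discounts the averaged accrual at the cycle midpoint,
`(1.02)^(−t_mid/52.1786 weeks)`.  Per cycle:

* **QALYs**: stratum utilities (TTO-derived: 0.919/0.853/0.703/0.554) ×
  years per cycle.  No adverse-event disutility.
* **Drug**: 5,584.30 JPY × 7 days × 12 weeks × adherence (97.4%) per
  on-treatment member-cycle (dispensed-dose proxy; adherence does not scale
  efficacy, which already reflects trial behaviour).
* **HCRU**: monthly stratum costs × 12·(12/52.1786) months per cycle.
* **Indirect**: employment (83.3%) × 36.8 h/week × 52.1786 weeks ×
  2,353 JPY/h × WPAI overall impairment `A + (1−A)·P` per stratum, accrued
  over the whole lifetime.  The employment rate already encodes the
  retirement-at-65 assumption through the cohort's age mix; a hard
  retirement-age cutoff is available (`retirement_age`) but off by default,
  because only lifetime accrual is consistent with the printed no-treatment
  indirect cost.  An additive WPAI variant (`wpai_additive`) differs by
  < 0.6 points at base values.
* **Adverse events**: Σ incidence × unit management cost, applied once,
  undiscounted, at model start (treated incidences are 48-week, untreated
  24-week cumulative).  The printed lifetime AE costs (3,968/3,918 JPY)
  are not derivable from a one-off product-sum (~126/59 JPY) and are most
  consistent with per-cycle recurrence over the lifetime; a recurring mode
  (`ae_cost_recurring`) is provided.  At < 0.1% of total costs the choice
  is immaterial to the ICER.

Payer perspective simply drops the indirect component, so payer totals
equal societal totals minus indirect costs exactly.  USD figures are a
constant-rate display conversion at 151.37 JPY/USD.

## Sensitivity analysis

**OWSA.**  Each parameter is swept to ±20% of base (proportions clipped at
1), rebuilding the whole model at each bound; perturbations that violate a
hard invariant (e.g. utility monotonicity across strata) are recorded as
failed entries rather than silently skipped.  The default sweep covers the
uncertain estimates — utilities, HCRU costs, adverse-event incidences and
unit costs, productivity inputs, the discontinuation rate, and cohort
demographics.  The administered NHI drug price and the adherence factor are
fixed administrative inputs, and the trial SALT distributions are
simplex-valued (their uncertainty is handled jointly by the Dirichlet PSA),
so both groups are excluded by default; flags re-include them.  Perturbing
one checkpoint share renormalizes the remaining shares proportionally.

**PSA.**  Per iteration all parameters are redrawn jointly: Beta for
probabilities and utilities, Gamma for costs, wages and hours, and one
Dirichlet per SALT checkpoint, with SE = 10% of the base value.  The
Dirichlet total concentration anchors the largest share's SD at 10% of that
share (the "10% of base" rule is ill-posed on a simplex); zero shares stay
degenerate at zero.  Fits are method-of-moments in closed form, so the
fitted mean/SD reproduce the inputs exactly.  Draw order is fixed and a
single seeded generator is used, making runs bit-reproducible.  Utility
monotonicity across strata is not enforced within joint draws.  The PSA
summary reports the expected ICER as the ratio of mean increments and the
CEAC as the fraction of draws with positive NMB per willingness-to-pay
point.

## Synthetic inputs

`make_life_table` produces a single-year Gompertz–Makeham table,
`qx_male = min(1, a + c·e^{b·age})` with female rates scaled down by a
constant; defaults (a = 2·10⁻⁴, b = 0.1033, c = 1.2·10⁻⁵, ratio 0.54) are
calibrated so remaining life expectancy at age 40 is ~42.5 years (male),
~48 years (female), ~45.6 for the 61.9%-female cohort — Japanese-like.  It
emulates the level and slope of official mortality but not cohort effects
or old-age plateau behaviour.  `make_claims` draws per-patient monthly
costs with right-skewed Gamma noise (default CV 1.0) around stratum means;
it emulates the stratified cost structure assumed by the weighted-average
back-calculation, not actual claims layouts, coding, or the severity
prediction used to label real claims.  Passing tests therefore demonstrate
correctness of the computations under these stylized inputs, not agreement
with proprietary data.

## Numerical conventions and problem sizes

Weeks per year is fixed at 365.25/7 = 52.1786 everywhere.  Simulation stops
when the alive fraction falls below 10⁻⁶ or the cap age is reached (~260
cycles from age 40.2).  The base-case run takes milliseconds; the test
suite runs the PSA at 2,000 iterations (Monte-Carlo SE of the
acceptability probability ≈ 1.1 points) and the claims-recovery check at
n = 10⁵ records.

## Known limitations

* Single mean-age cohort; the 7.4% adolescent share is recorded but does
  not alter utilities, wages or employment (no data to do so).
* Trial-phase occupancies are imposed marginals, not an estimated
  transition matrix; whether the printed distributions condition on
  treatment continuation is unknown.
* The post-48-week discontinuation hazard, the off-treatment worsening
  rate, and the AE-cost accrual mechanism are under-determined by the
  source material; each is a documented knob with the defaults above, and
  the residual inconsistency between the printed two-year shares and the
  printed lifetime increments cannot be removed by any single setting.
* Human-capital costing; no friction-cost method, no unpaid-activity
  impairment.
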