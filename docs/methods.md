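# Methods

## The decision problem

The package evaluates first-line rhTNFR:Fc (a recombinant TNF-receptor-Fc
fusion protein with the same amino-acid sequence as etanercept) against
first-line methotrexate (MTX) for adults with active rheumatoid arthritis in
China, from the healthcare-system perspective, over a lifetime horizon.  Both
arms follow the same guideline sequence after first-line failure:
adalimumab + MTX, then tocilizumab + MTX, then tofacitinib, then palliative
care.  Outcomes are lifetime discounted costs (CNY) and QALYs; the decision
statistic is the ICER against a willingness-to-pay threshold of CNY 95,749
per QALY (2024 per-capita GDP).

## Cohort model

A Markov cohort model with 6-month cycles runs from age 49 until death or
age 100 (102 cycles).  States are responder/non-responder per treatment
line, palliative care, and death.  The transition rules:

- The cohort enters line 1 at cycle 0 and is split once, at entry, by the
  line's landmark response probability (ACR20 at 24 weeks).  Trials report
  response at a single landmark, so response is not re-assessed afterwards.
- Non-responders spend exactly one on-drug trial cycle on the line (full
  line cost, baseline utility) and then enter the next line.
- Responders stay on the line; each cycle they face a per-cycle withdrawal
  probability.  Withdrawers pass directly to the next line's entry split —
  no standalone "discontinued" dwell state, which would double-count time.
- The last active line feeds palliative care, which absorbs until death.
- Death competes with all transitions: background mortality is applied
  first in each cycle, then withdrawal/response among survivors.  This
  fixed ordering makes the chain reproducible and testable.
- No half-cycle correction: each cycle accrues costs and utilities on
  start-of-cycle occupancy.  Discount weight at cycle k is
  (1.05)^(-k/2) (5% per year, so cycle 2 is weighted 1/1.05).

The engine has two implementations of the same chain: a vectorized kernel
(used for single runs and for batched PSA draws, guaranteeing that a
degenerate PSA reproduces the base case bit for bit) and an explicit dense
transition-matrix builder.  Tests iterate the matrices against the kernel
cycle by cycle, and a patient-level microsimulation replays the same rules
per patient as an independent oracle (agreement within 3 Monte-Carlo
standard errors at n = 200,000).

## Transition probabilities

Rates observed over a source-trial window are converted to 6-month cycle
probabilities under a constant hazard: p_cycle = 1 − (1 − p_window)^(6/w).
First-line response and withdrawal come from a 24-week head-to-head trial;
24 weeks is treated as one cycle, so those rates are used directly.
Response rates for later lines are 24-week landmarks (window 6).  The
follow-up windows behind the later-line withdrawal rates are not published;
the fixture records them as 24 months (long-term-extension follow-up,
editorial choice, editable per row).  This is one of the calibrated free
inputs: the published lifetime QALY totals (7.46 / 8.20) require multi-year
dwell times on the later biologic lines, which pins the withdrawal windows
at the long-extension scale.

## Mortality

Background mortality comes from an age-indexed life table and is adjusted
for disability on the hazard scale: q_adj = 1 − (1 − qx)^(HR^HAQ), then
converted to the cycle length.  The hazard ratio per HAQ unit is
configuration (code default 1.33, the most widely used RA mortality
coefficient); the shipped fixture uses the calibrated value 1.281804 (see
Calibration).  No public life table is bundled: a deterministic
Gompertz–Makeham generator stands in, with female
(A = 1.0e-4, B = 1.44e-5, C = 0.0997) and male
(A = 2.0e-4, B = 4.86e-5, C = 0.090) coefficients anchored to published
East-Asian all-cause schedules (qx ≈ 0.0024 at 49, ≈ 0.047 at 80 for the
15%-male blend; life expectancy at 49 ≈ 34 years).  The cohort table blends
the sexes at the 15% male fraction.

## Utilities and the HAQ floor

Utilities are linked to HAQ through a linear mapping u = a + b·HAQ (b < 0),
clamped to [0, 1].  The mapping coefficients are not published; they are
back-solved so that the baseline utility 0.193193 corresponds to the worst
HAQ score (3.0), leaving the slope as one free parameter:
a = 0.193193 − 3b.  During long-term extrapolation HAQ is floored at 1.5
(HAQ floor effect in treated RA populations), and the floor binds on
utility from above: any trial utility whose HAQ equivalent would fall below
1.5 is capped at u(1.5) = a + 1.5b; utilities below the cap are used as
printed.  This matters for the incremental result: the later-line
utilities of the two arms (0.737562 vs 0.64043) both sit near the cap, so
the floor compresses the between-arm utility gap — exactly the conservative
direction the floor is meant to enforce.  The shipped slope −0.318592 puts
the cap at 0.671.  Each state's HAQ (for the mortality adjustment) is the
mapping inverse of its utility, clipped to [1.5, 3.0]; non-responders and
palliative care carry the baseline utility and HAQ 3.0.

## Costs

Per-cycle state cost is Σ unit price × units-per-cycle over the line's cost
items, scaled by the perspective's fraction per cost category.  Unit prices
are fixed inputs; usage quantities are not published and are configuration.
The shipped schedule:

- rhTNFR:Fc 52 vials/cycle (25 mg twice weekly) + subcutaneous injection
  fees; MTX 156 tablets/cycle (15 mg weekly); adalimumab 13 pens/cycle
  (40 mg every 2 weeks); tocilizumab 16.9 vials/cycle (8 mg/kg every
  4 weeks); tofacitinib 365 tablets/cycle (5 mg twice daily).
- Outpatient monitoring and adverse-event medication at fixed per-cycle
  frequencies on every active line.
- Inpatient care carries the calibrated mass: 39.40 bed-days per cycle on
  every active line (bed fee plus 24 hourly nursing units per day), with
  19.98 additional days on the first-line MTX phase, reflecting poorer
  disease control on csDMARD monotherapy.  These two quantities were solved
  (linearly, given the calibrated traces) so the shipped schedule
  reproduces the published arm totals; the implied non-drug management cost
  of roughly CNY 27k per year per active patient is below the published
  average annual RA treatment cost in China (CNY 41,971) that anchors the
  palliative state.
- Palliative care costs CNY 41,971 per year, accrued half per cycle
  (interpreted as an annual average; configurable via units-per-cycle).

Three payer perspectives ship: healthcare system (every category in full),
patient out-of-pocket, and medical insurance; the latter two are
complementary category-wise splits, so their results sum to the
healthcare-system results exactly.  The split fractions are configuration
(reimbursement rules are not published).

## Calibration of free inputs

Four inputs the published analysis used but did not print were calibrated,
in this order, and then frozen into the fixture:

1. later-line withdrawal windows = 24 months (sets dwell-time scale),
2. HAQ-mapping slope (sets the utility cap, hence the QALY gap) and the
   HAQ mortality hazard ratio (sets the QALY level) — solved jointly so the
   two arm QALY totals match the published 7.46 and 8.20,
3. inpatient usage quantities — solved linearly so the two arm cost totals
   match the published CNY 762,092.34 and 771,540.30.

Printed inputs (all rates, prices, utilities, the discount rate, the age
cap, the HAQ floor) were never adjusted.  The calibration reproduces all
five published base-case quantities within 0.05%.

## Sensitivity analyses

One-way analysis re-runs the full model at each row's printed lower and
upper bound (probabilities varied at the source-window scale and then
converted), holding everything else at base, and reports ICER swings sorted
descending.  Varying the male fraction rebuilds the blended life table.
Scenario analysis supports value or multiplier overrides (probabilities
capped at 1), perspective switches, and an alternative first-line pathway;
the combination-therapy scenario (rhTNFR:Fc + MTX, efficacy proxied from
originator-plus-MTX trials) ships with editorial response/withdrawal/utility
rows marked as such, with ±20% treatment-effect variants.

The PSA draws every stochastic row independently: Beta for probabilities
(mean pinned to the printed base; concentration solved so the central 95%
interval width matches the printed bounds, falling back to moment matching
when no solution exists), Gamma for costs and utilities (moment matching
with sd = (upper − lower)/3.92), utility draws clamped to [0, 1].  The one
internally inconsistent printed row (first-line MTX response 70% with
bounds 48.02–63.83%) keeps its printed base deterministically; its bounds
set dispersion only.  Ten thousand iterations run in seconds through the
batched kernel; the CEAC reports the probability that the intervention has
the higher net monetary benefit, ties favouring the comparator.

## Synthetic data

The trial generator emulates the source trial's structure: two arms with
nested ACR20/50/70 indicators (drawn by conditional thinning, honouring the
logical nesting) plus withdrawal flags, at the published arm sizes and
rates.  Passing tests on these data show the pipeline recovers its
generating parameters and that the cohort engine matches patient-level
simulation; they cannot show anything about covariate-driven response,
time-varying withdrawal hazards, or real Chinese mortality, none of which
the generator emulates.

## Numerical choices

- ICERs are computed on unrounded totals; published-style rounding happens
  only at report time (the printed increments 9447.96/0.74 give 12,767.51
  when divided after rounding — the published 12,783.56 corresponds to the
  unrounded QALY gain ≈ 0.739).
- An ICER exactly at the threshold counts as cost-effective (inclusive).
- Zero QALY difference yields an "undefined" flag instead of a ratio and is
  not called cost-effective.
- Zero-width bounds produce point-mass distributions; a degenerate PSA
  equals the deterministic run exactly.
- Dead states accrue nothing; occupancy conservation is enforced to 1e-10
  per cycle and transition rows to 1e-12.

## Known limitations

- Published first-line attrition ("<1% remain on first-line rhTNFR:Fc
  after five years") is irreconcilable with the published lifetime QALY
  totals under any single per-cycle stay probability: retention low enough
  for the attrition claim caps the MTX arm near 5.7 QALYs, far below the
  published 7.46.  This package follows the QALY totals; its first-line
  retention after 10 cycles is ≈ 17%.
- The payer-perspective incremental costs published alongside the base case
  do not sum to the base-case increment, so the published perspectives
  differ by more than a reimbursement split; the shipped perspectives are
  exact complements instead, and the payer scenarios are validated by that
  additivity property rather than against the published payer ICERs.
- Independent PSA draws (no correlation between rows), single landmark
  response, no adverse-event disutility, no individual-level covariates,
  no half-cycle correction, and an editorial dosing/management schedule:
  absolute cost levels inherit the schedule's assumptions even though the
  incremental comparison is calibrated.
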