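# Methods

## The hierarchical composite kidney outcome

`hierwin` analyses a six-tier hierarchical kidney outcome for two-arm trials
with longitudinal eGFR measurements:

1. all-cause mortality;
2. ESKD or an observed eGFR < 15 ml/min/1.73 m² at a scheduled visit;
3. eGFR decline ≥ 57% from the randomisation value;
4. eGFR decline ≥ 50%;
5. eGFR decline ≥ 40%;
6. participant-level eGFR slope (continuous).

Decline events are detected at scheduled visits only, as the first visit at
which `(baseline − eGFR)/baseline` reaches the threshold; declines are not
required to be sustained, so visit-level measurement noise genuinely
produces events — as it does in trials that define decline endpoints this
way. The randomisation eGFR is the baseline; participants without one are
excluded and counted.

All time-to-event tiers are truncated at a fixed follow-up window (720 days
for the HFrEF-style design, 1,080 for the HFpEF-style design). A participant
censored earlier than the window is treated as followed to exactly the
window: this removes the dependence of win proportions on the censoring
distribution at the price of treating unobserved event-free time as
event-free. The window boundary is closed (an event on the window day
counts); the convention is symmetric in the arms, so estimates at the null
are insensitive to it.

## The win engine

Every treated participant is compared with every control participant within
the same stratum (diabetes status; diabetes × trial when trials are pooled).
Tiers are examined in ascending order. At a time-to-event tier, a pair is
settled in favour of the participant without an in-window event if exactly
one has an event, or in favour of the later event if both do; equal days
descend to the next tier. The continuous slope tier settles every remaining
pair unless the slopes are exactly equal (no epsilon tolerance — exact ties
only arise from degenerate inputs, e.g. two participants that both received
the fallback slope). Without the slope tier, unsettled pairs are ties.

With pooled win/loss/tie proportions `P_W`, `P_L`, `P_T` (strata pooled by
raw pair counts, `weight ∝ n_T,s · n_C,s`):

- win ratio `P_W/P_L`,
- net benefit `P_W − P_L`,
- win odds `(P_W + ½P_T)/(P_L + ½P_T)`,
- win probability `P_W + ½P_T`.

Variances use the two-sample U-statistic projection: for each subject, the
fraction of opposite-arm subjects in its stratum that it beats (and loses
to) is computed by the engine as a by-product; the empirical variances and
covariances of those per-subject fractions give `var(P_W)`, `var(P_L)` and
`cov(P_W, P_L)`, combined across strata with squared pooling weights (strata
are independent). The O(1/(n_T·n_C)) term is neglected — at trial scale it
is dominated, and the analytic CI is validated against a participant
bootstrap in the test suite (half-widths within 15% at 200/arm). CIs for the
ratio statistics are normal on the log scale via the delta method
(`d log WO/d NB = 2/(1 − NB²)` since `WO = (1+NB)/(1−NB)`); net benefit and
win probability use direct normal intervals. The reported p-value is the
two-sided Wald test on the log win ratio. If no losing pairs exist the win
ratio is +∞ and its lower CI bound is computed from a 0.5-corrected loss
count.

The engine is vectorised per stratum over blocks of the pair matrix and is
exactly equivalent (bit-for-bit on counts) to the naive double loop, which
the tests verify against an independently coded oracle. A 5,500 × 5,500
comparison runs in seconds on one CPU.

## Participant-level slope (tier 6)

The default tier-6 value is each participant's own least-squares fit on the
two-phase basis — level, fraction of the acute phase elapsed, and years
since the knot — restricted to visits within the fixed window, summarised as
the total slope over `[0, window]` (annualised secant of the fitted
piecewise line). Computing the slope from the participant's own data alone
keeps the slopes of different participants statistically independent, which
the all-pairs U-statistic inference requires: an alternative that anchors
each participant at the *estimated* arm mean (mixed-model BLUP plus fixed
effects) injects the arm-contrast sampling error into every pair, and
simulation shows the win-ratio test's type-I error then inflates severely
(≈ 0.33 instead of 0.05 at 100/arm) at any sample size. The BLUP-based
variant remains available (`SlopeModelFit.participant_slopes`) for
comparison. Participants whose slope is undetermined (fewer than two usable
visits) receive the pooled mean slope — an arm-neutral fallback that cannot
tilt any cross-arm comparison systematically.

## The two-slope mixed model

Arm-level slopes are estimated by the standard piecewise-linear
("two-slope") linear mixed model for drugs with an acute haemodynamic eGFR
dip: visit-level eGFR (including the randomisation visit) is regressed,
without an intercept, on baseline eGFR, randomised treatment, diabetes
status, visit time, a spline term for days since the acute phase, and the
treatment interactions with time and spline; pooled fits add a trial main
effect and use per-trial knots. Random effects are a per-participant
intercept and chronic slope with unstructured 2×2 covariance; estimation is
by REML. Arm slopes are annualised with 365.25 days/year:
control acute = time coefficient, treated acute adds treatment×time, chronic
slopes add the spline terms, and
`total = (knot·acute + (window − knot)·chronic)/window` exactly.

Numerical notes:

- The raw time and spline columns are nearly collinear (they differ only
  during the ≤30-day acute phase), which defeats generic optimisers.
  Internally the model uses an exactly equivalent orthogonalised basis —
  acute-phase fraction and years-since-knot — and transforms back.
- REML is maximised directly over the three log-Cholesky parameters of the
  relative random-effect covariance, with fixed effects and the residual
  variance profiled out in closed form through the Woodbury identity on
  cached per-participant cross-products. One fit takes milliseconds, which
  the 1,000-replicate calibration and power studies rely on. Nelder–Mead
  with box bounds and three starting points is used; invalid covariance
  parameters return a large finite penalty so the simplex can recover.
  Zero-variance boundaries (noiseless or homogeneous cohorts) are reached
  smoothly on the log scale.
- The fit is cross-checked against `statsmodels` MixedLM on the same design
  matrix in the test suite (coefficients within a fraction of a standard
  error; our restricted likelihood is never worse).
- Rows are sorted canonically before fitting, so the result is exactly
  invariant to input row order.

The arm-level slope significance test used by the power study is the Wald
test on the treatment×chronic-slope contrast.

## Wins and losses over time

The engine is re-run on a 10-day grid with all events truncated at each
grid time, using tiers 1–5 only (a slope over the whole window has no
interim value). At the horizon the construction coincides exactly with the
main engine on those tiers. Note that per-tier win/loss series need not be
monotone under this construction: a pair settled at a low tier early (say, a
decline event) can later be settled at a higher tier for the *other*
participant (say, a death), moving a win across arms and tiers. What is
provably monotone is the overall settled-pair proportion — once any tier
shows a strict within-tier difference it can never revert to equality as
events accrue — and the tier-1 series, which no later event can overturn.
The tests assert exactly those properties.

## Conventional comparators

For each composite or single endpoint, time-to-first-event is the minimum
of the component event days; non-events are censored at the fixed window
(the same censoring-extension rule, so person-time for rates runs to the
window). Rates per 100 patient-years carry exact Poisson (chi-squared)
intervals. Hazard ratios come from `lifelines` Cox models stratified by
diabetes (and trial when pooled) and are reported as 1/HR so that values
above 1 favour treatment, directionally aligned with the win ratio.
Kaplan–Meier curves per arm are available for plotting.

## The synthetic trial generator

Patient-level data from the source trials require a data-access request and
cannot ship with the package, so all studies run against a seeded generator
that emulates the structure the analysis assumes:

- baseline eGFR ~ truncated normal (mean 65, sd 19 ml/min/1.73 m²) at the
  trial eligibility floor (30 or 25);
- an acute dip realised linearly from randomisation to the knot (defaults
  −3.5 treated / −0.3 control, the characteristic SGLT2-inhibitor pattern),
  then a per-participant chronic slope ~ normal around the arm mean
  (between-participant sd 2.0/year);
- additive visit-level measurement noise (default sd 7–9 ≈ 11–14% CV at
  eGFR 65, the visit-to-visit variability of creatinine-based eGFR; the
  default 9.0 was calibrated once so that control-arm ≥40/≥50/≥57% decline
  rates land near the published per-100-patient-year rates);
- the randomisation eGFR itself is generated noise-free, reflecting an
  adjudicated baseline. This matters: with a noisy baseline serving as both
  covariate and day-0 response, the no-intercept two-slope model exhibits a
  regression-to-the-mean artifact that biases the control-arm acute dip
  (reproduced identically with statsmodels — a property of the model, not
  the solver);
- exponential death/ESKD/dropout hazards with arm-specific rate ratios;
  ESKD additionally triggers at the first visit with observed eGFR < 15,
  whichever comes first; visits stop at min(death, dropout, horizon) while
  vital status is assumed complete to the horizon;
- chronic-slope defaults (−1.0 vs −3.1 per year for the 720-day design;
  +0.15 vs −1.5 for the 1,080-day design) were chosen so the implied total
  slopes match published arm-level totals.

What the generator does **not** emulate: informative (outcome-dependent)
censoring, non-exponential hazards, covariate-rich case mix, and non-linear
trajectories beyond the two-phase line. Passing tests therefore demonstrate
the statistical machinery on data satisfying the model's assumptions, not
robustness to their violation on real trial data.

## Problem sizes used in the checks

Monte-Carlo studies are scaled to what one CPU handles comfortably: null
calibration uses 1,000 replicates at 100/arm; the bootstrap validation
1,000 resamples at 200/arm; slope recovery averages 5 fits at 1,000/arm plus
200 replicates at 150/arm; the power comparison 200 iterations at total
sample sizes 200/500/1,000; the acceptance script one pooled cohort of
1,000/arm per trial design. All are seeded and reproducible.

## Known limitations

- Exponential hazards make event rates time-constant; real heart-failure
  mortality accelerates.
- The win-ratio p-value and CI are asymptotic; at very small n (tens per
  arm) the normal approximation on the log scale is the binding assumption.
- The pooled analysis shares acute/chronic treatment effects across trials
  (trial enters as a main effect only).
- The "sustained" ESKD definitions of the original trials are simplified to
  first occurrence.
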