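# Methods

## Quantities and conventions

δ values are per-mil deviations from VSMOW and stay in ‰ everywhere in the
API; conversion to absolute ratio quotients happens only inside
`compute_alpha` and its inverse.  The fractionation factor
α = (δ_M/10³+1)/(δ_W/10³+1) is dimensionless; differences between α values
and all α-scale uncertainties are reported in ‰ (×10³), so an α calibration
stores `s_yx` and `u_pred` in ‰ of 10³·α.  The seasonal predictor is the
non-leap day number t ∈ 1..365 (1 January = 1); 29 February is rejected
rather than mapped, because the calibrations are defined on a 365-day
calendar.  A sample record may carry both a date and an explicit t; the
explicit t wins, since sampling campaigns sometimes report a nominal day
number that disagrees with the transcription of the date.

Default single-measurement uncertainties (‰): farm water 0.08 (O) / 1.0 (H),
milk water 0.15 (O) / 1.5 (H).

## Regression machinery

* **Water/milk lines** (δ²H on δ¹⁸O) are ordinary least squares with the
  classical closed-form standard errors and s(yx) = √(SSE/(n−2)).
* **Quartic seasonal calibrations** are least-squares fits of degree 4 in
  t/365 (for conditioning), re-expressed in raw powers of t;
  s(yx) = √(SSE/(n−5)) uses the residual degrees of freedom (5 fitted
  parameters), and R² is against the mean model.  Fits require ≥6 points and
  ≥5 distinct day numbers.  Tests verify agreement with an independent
  normal-equations oracle on fitted values; raw-power *coefficients* of a
  quartic over t ∈ 1..365 are conditioning-limited in any solver and are not
  the contract.
* **LOESS** is degree-1 locally weighted regression with tricube weights
  and no robustness iterations (statsmodels `lowess`), span 0.2 by default;
  a span leaving fewer than three points per window is an error.
* **Two-way ANOVA without replication** (rows = sampling times, columns =
  sheds) is the classical sum-of-squares decomposition; mean squares are
  reported as the variance components, and the residual absorbs
  time×shed interaction plus measurement noise.
* **Cold/warm period comparison**: cold = Nov–Apr, warm = May–Oct.  Records
  are averaged per shed within each period (each shed contributes one point
  per period), milk δ¹⁸O is regressed on farm-water δ¹⁸O per period, and
  slopes are compared with a two-sample t-test on the slope difference,
  pooling the two fits' standard errors, df = n₁+n₂−4.

## Prediction uncertainty of α̂

The exact prediction variance of a quartic depends on the design leverage
at each t.  The package uses the leverage-free approximation
u(α̂) = √(s(yx)² + s(yx)²/n), which understates the true value; with the
bundled calibrations it evaluates to 0.41 ‰·√(1+1/84) = 0.4124‰ (indoor)
and 0.5023‰ (all sheds).  The bundled calibrations pin `u_pred` to the
published rounded constants 0.42‰ and 0.51‰ so that the step-2 threshold
reproduces the reference decision rule exactly; a calibration refit from
new data has no override, and its threshold is recomputed from its own
s(yx) and n.  No t-multiplier is applied: the intent of the approximation
is a standard (coverage-1) uncertainty, and the two published constants are
reproduced only without it.

## The two-step decision rule

Step 1 passes iff |δ_M,measured − δ_M,calculated(t)| ≤ coverage·s(yx)
(coverage 1.645, significance 0.10 → 1.51‰ with the bundled milk
calibration).  Step 2 passes iff 10³|α_m − α̂(t)| ≤
√(u²(δ_M)+u²(δ_W)+u²(α̂)) (0.4531‰ with the defaults, i.e. the published
0.45‰ at reporting precision).  Equality passes — both conditions are ≤.
The overall verdict is pass only when both steps pass; if no water value is
available (neither farm water nor a user-supplied regional groundwater δ),
step 2 is *skipped* and the verdict is *undetermined*, never pass.  The
step-2 default calibration is the indoor-herd one; the all-sheds
calibration (with its larger 0.54‰ threshold) is the appropriate choice for
herds that graze outdoors.

## Synthetic herd-year generator

The generator emulates the structure of a one-year regional survey:

* **Farm waters**: per-shed δ¹⁸O means drawn from a normal distribution
  (mean −9.6‰, sd 0.9‰) truncated to the regional range −11.4…−7.8‰ —
  regional groundwater means cluster rather than spreading uniformly, and
  approximately Gaussian cross-shed scatter is also the premise under which
  a ±1.645·s(yx) band has its nominal ~90% coverage.  δ²H means sit on the
  slope-8.33/intercept-16.3‰ regional water line with 1.6‰ scatter.
  Month-to-month water scatter is at measurement level (0.08‰ O, 1.0‰ H).
* **Temperature**: a sinusoid (mean 13.5 °C, amplitude 10.5 °C, coldest
  mid-January — a Po-plain style cycle) plus 2 °C daily noise; the
  temperature attached to each record is the mean of the 14 days preceding
  sampling, matching the equilibration time of a cow's body water.
* **Fractionation**: α = A_i + B_i·T̄(t), per-shed slopes B_i uniform in
  5.7–9.0 ×10⁻⁵/°C for indoor sheds (the observed indoor range), with the
  regional mean α at mean temperature set to 1.0016.  Outdoor-grazing sheds
  switch to slopes of 11.8–13.3 ×10⁻⁵/°C in the warm months (May–Oct),
  reproducing the ~1‰ extra summer enrichment of outdoor herds.  A 0.15‰
  per-shed offset and 0.20‰ residual α noise (‰ of 10³·α) complete the
  model.  Alternatively, α(t) can be taken from a stored quartic
  calibration; combined with a stored milk-δ quartic and zero noise this
  pins the farm water so every record verifies with exactly zero
  discrepancy (a self-consistency configuration used in tests).
* **Milk values**: δ¹⁸O_M inverts the fractionation relation around the
  sampled water and adds 0.15‰ measurement noise.  δ²H_M follows the milk
  line (slope 6.30, intercept −5.6‰) with its deviation split into a
  temperature-correlated component (−0.35 ‰/°C — an evaporation-like ²H
  response beyond what δ¹⁸O carries) and 1.0‰ independent scatter, plus
  1.5‰ measurement noise; the total scatter around the milk line is ≈3.2‰.
  A purely independent 3.2‰ scatter would destroy the observed strong
  correlation (R ≈ 0.8) between the deuterium-excess gap d_ex,W − d_ex,M
  and temperature, so part of the deviation must be temperature-linked;
  the split keeps both the line geometry and the d_ex regime.
* **Seeding**: identical config + seed gives identical output.  A separate
  `noise_seed` regenerates month-level noise while keeping the herd (shed
  means, slopes, weather) fixed — this produces *held-out samples from the
  calibration herds*, the population for which the step-1 band's nominal
  ~10% rejection holds.  Verifying herds re-drawn from the whole region
  additionally carries a between-herd mean-shift term and rejects ~15%.

Fraud scenarios transform the authentic generator: `foreign_water` shifts
the declared water by +3‰ (milk unchanged), `foreign_milk` raises the
milk's fractionation regime by +1.5‰, `season_mislabel` declares milk
produced 180 days away from the stated date.  All records carry truth
labels for false-accept/false-reject estimation.

What the generator does **not** model: cow physiology (body-water pools,
methane ²H effects), within-shed month-to-month α autocorrelation beyond
the shared temperature, per-shed local weather, feed-water contributions,
and real groundwater hydrology.  Passing tests therefore show the
*machinery* is correct and the decision rule has the designed operating
characteristics under its own assumptions — not that those assumptions hold
for any particular real region.

## Problem sizes and numerical choices

Tests run herd-years of 9 sheds × 12 months (108 records) and Monte-Carlo
experiments of 200 replicates (power and false-reject rates) or 25
replicates (band-coverage), sizes at which the binomial tolerances quoted
in the tests are meaningful and the whole suite runs in seconds.
Degenerate inputs raise typed errors (`SingularFitError`,
`InsufficientDataError`, `IncompleteDesignError`, `WindowTooSmallError`,
…) rather than returning NaN; the one deliberate NaN is an undefined
correlation (zero variance), which is reported as not-computable.
Rounding is for display and reporting only (δ to 2 decimals, α to 6,
‰-differences to 2); all internal arithmetic is full precision.

## Known limitations

* Only oxygen defaults ship; the fitting machinery is isotope-agnostic, but
  no hydrogen seasonal calibration is bundled and the check is defined on
  δ¹⁸O.
* The u(α̂) approximation ignores design leverage and understates the true
  prediction uncertainty, so the step-2 threshold is anti-conservative near
  the edges of the sampled season; this is inherited from the reference
  decision rule and documented rather than silently corrected.
* The binary check attributes a sample to one region; it does not rank
  alternative regions or combine multiple samples.
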