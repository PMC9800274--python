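# Methods

This note documents the models and procedures implemented by `vilpa`, the
assumptions behind them, the defaults of the synthetic cohort generator,
and the numerical choices that matter.

## The exposure: VILPA bouts from 10-second epochs

Vigorous intermittent lifestyle physical activity (VILPA) is brief
(up to 1–2 min) vigorous-intensity movement embedded in daily living. The
measurement model assumes a wrist accelerometer record already classified,
per 10-second epoch, into an activity class (nonwear, sleep, sedentary,
standing, walking, running) with a mean acceleration in milli-gravity
(mg). Activity-class labelling (the random-forest classifier, sleep and
nonwear detection, device calibration) is upstream of this package:
epochs arrive labelled.

**Intensity assignment.** Activity class takes precedence over
acceleration: sedentary stays sedentary and standing maps to light
regardless of acceleration. Ambulatory epochs (walking/running) split by
mean acceleration: `<100 mg` light, `100–<400 mg` moderate, `>=400 mg`
vigorous.

**Bout detection.** A raw bout is a maximal run of consecutive vigorous
epochs within a calendar day. Runs of up to 6 epochs (<=1 min) and up to
12 epochs (<=2 min) are the short-bout categories — cumulative, so the
<=2-min exposure includes <=1-min bouts; runs of more than 12 consecutive
vigorous windows count as long VPA sessions and enter the models only as
adjustment covariates. Runs never cross midnight; a run spanning the day
boundary is split, since all accounting is per day.

**Length standardization.** Raw bout lengths are highly variable, so bout
*frequency* is expressed in length-standardized units: accumulate the raw
durations of a day's category-matching bouts in temporal order; each time
the running sum reaches or exceeds the standard length (60 s or 120 s),
count one analytic bout and reset the sum to zero, discarding any excess;
the terminal remainder counts fractionally (remainder / standard). Five
consecutive raw bouts of 20, 30, 20, 40 and 10 s therefore yield 1.83
one-minute standardized bouts: 20+30+20 completes one bout (the 10 s
excess is discarded), and 40+10 leaves 50/60 = 0.83. The discard-excess
rule is forced by that arithmetic. Full precision is retained internally;
rounding to 2 decimals is display only. The rolling sum runs within a
participant-day regardless of gap length and resets at day boundaries,
matching the per-day exposure construction. Fractional remainders are kept
on days with no completed bout.

**Wear validity.** A monitoring day is valid iff worn (non-nonwear) time
strictly exceeds 16 h; a participant enters the analysis with at least
three valid days of which at least one is a Saturday or Sunday (local
timestamps). Exposures — VILPA minutes/day, standardized bouts/day,
light and moderate minutes/day, sleep hours/day, long-VPA terms — are
computed within each valid day and averaged across valid days.

**Capping.** Each VILPA exposure column is winsorized at its empirical
97.5th percentile (linear-interpolation definition) to limit sparse-data
influence in the upper tail. Winsorization at a re-estimated interpolated
percentile is not exactly idempotent (re-capping can nudge the tied top
values down by a fraction of a percent); the capped values themselves are
of course stable once the threshold is fixed. Capping is skipped with a
warning below 40 records.

## Dose–response models

The exposure enters the log hazard through a restricted cubic spline with
three knots at the 10th, 50th and 90th percentiles of the capped analysis
exposure — computed after exclusions and capping, in that order (the
ordering of capping/exclusion/knot placement is a convention of this
package; results are insensitive at these sample sizes). With three knots
the spline contributes one nonlinear basis column (Harrell's construction,
scaled by the squared knot span), linear beyond the boundary knots and
exactly zero at and below the first knot, which makes exposure 0 the
natural referent.

**All-cause mortality** uses Cox proportional hazards with Efron tie
handling (delegated to `lifelines.CoxPHFitter`, Newton precision 1e-9);
the covariance is the inverse observed information.

**Cause-specific mortality** (CVD, cancer) uses the Fine–Gray
subdistribution-hazard model to account for competing deaths. The
implementation expands risk sets: a participant who dies of a competing
cause at time s remains at risk for the target cause afterwards with
weight `G(t-)/G(s-)`, where G is the Kaplan–Meier estimate of the
censoring distribution on the same analysis sample (one overall censoring
distribution, not cause-stratified). Weight intervals are cut at the
censoring times where G steps, weights are floored at 1e-8, and the
expanded weighted data are fitted as a start–stop Cox model
(`lifelines.CoxTimeVaryingFitter`). The expansion reproduces R
`survival::finegray` exactly (coefficient agreement to ~1e-7 on test
fixtures; this cross-check is part of the test suite). With no censoring
and no competing events the model coincides with Cox, and the test suite
asserts coefficient agreement to 1e-6. Reported standard errors are
model-based (weighted observed information), which is slightly
conservative relative to the Fine–Gray sandwich variance — a known
limitation; point estimates are unaffected.

**Exclusions.** All analyses drop participants whose *death* occurs within
the first 2 years of follow-up (landmark rule, reverse-causation guard);
participants censored early are retained — the rule is read literally as
applying to events. Cause-specific analyses additionally drop participants
with the corresponding prevalent disease at baseline. The adjustment set
mirrors the mutual-adjustment design: age, sex, smoking, a continuous
confounder, light/moderate minutes, sleep, long-VPA duration and
frequency, and the opposite prevalence flag; covariates that are constant
in a given cohort are dropped with a note in the report.

**Diagnostics.** Departure from linearity is a Wald chi-square on the
nonlinear spline coefficient(s) (1 df for three knots, where it equals the
squared z-score). Proportional hazards are checked with scaled Schoenfeld
residuals (Grambsch–Therneau): per-term statistics follow the classic
formulation (identical to lifelines' implementation, which serves as the
independent cross-check in the tests), the global statistic is the
quadratic form `(d / sum g*^2) u' V u` with `u = sum_k g*_k s_k`, and the
default time transform is the rank of event times within the full sample.
The global statistic matches R `cox.zph`'s GLOBAL closely on test data.

## Curve, minimal dose, E-values

The adjusted curve is `HR(x) = exp(b(x)'beta - b(0)'beta)` over a uniform
grid from 0 to the capped maximum (512 points by default), with pointwise
delta-method 95% bands. HRs at arbitrary exposures (sample median of the
nonzero exposures, maximum) interpolate linearly on the log scale.

The **minimal dose (ED50)** is the smallest exposure achieving half of the
optimal risk reduction, where "optimal" is `1 - min HR` over the observed
(capped) exposure range — for near-linear protective curves the minimum
sits at the maximum exposure. The crossing is refined by linear
interpolation between grid nodes, making the ED50 stable to grid
refinement beyond 1e-3 of the exposure range. The CI reported at the ED50
is the pointwise curve CI at that exposure, not a CI for the ED50 location
itself. A curve that never drops below HR 1 has no minimal dose and raises
a dedicated error.

**E-values** are computed on the hazard-ratio scale treated as a rate
ratio (rare-outcome setting): a protective HR is inverted to `RR = 1/HR`,
then `E = RR + sqrt(RR (RR - 1))`; the same transform applies to the CI
limit closer to the null, with intervals crossing 1 mapping to E = 1.

## The synthetic cohort generator

No public accession exists for the underlying cohort (access-controlled
biobank data), so every stage is exercised on seeded synthetic cohorts
generated at two tiers.

**Epoch tier.** Each of 7 days holds 8,640 ten-second epochs: contiguous
nonwear at the day edges (wear hours ~ Normal(23, 2) clipped to [4, 24],
exercising the 16-h rule), a sleep block (~ Normal(7.4, 0.8) h), and an
awake region evolving as a semi-Markov chain over sedentary / standing /
walking with exponential dwell times (means 20 / 3 / 3 min, i.i.d.
next-state probabilities 0.5 / 0.25 / 0.25). Vigorous runs are planted
into the awake region at a Poisson rate of 8/day with a length
distribution putting 92.3% of runs within 1 min, 97.7% within 2 min and
2.3% beyond 12 epochs, matching the reported bout-length mix; the rate is
set so the cohort's median daily VILPA duration sits near the reported
~4 min/day and ~3 standardized 1-min bouts/day. Planted runs never
overlap, are separated by at least one non-vigorous epoch, never occur in
sleep or nonwear, and never cross midnight. Acceleration draws are
state-conditional; ordinary ambulatory epochs stay strictly below 400 mg
and planted epochs draw from Uniform(420, 800) mg, so the bout engine
recovers the planted runs *exactly* — the generator's run log is the
ground truth for the oracle-equivalence tests. What this tier does not
emulate: autocorrelated acceleration noise, circadian structure of bout
timing (within-day bout spacing is not a calibrated target), classifier
error, or mid-day don/doff gaps; exact recovery therefore demonstrates
the correctness of the bout arithmetic, not robustness to classification
noise.

**Survival.** Cause-specific event times are exponential:
`h_c(t | x, z) = lambda_c exp(beta_c x + gamma' z)` for CVD, cancer and
other causes, with observed time the minimum over causes, random dropout
(0.01/yr) and a 6.9-year administrative horizon. Default baseline hazards
(0.0015 / 0.0032 / 0.0004 per year) reproduce the reported ~4.9 deaths
per 1,000 person-years split between CVD and cancer; default true effects
(log-HR per min/day of VILPA: −0.094 CVD, −0.071 cancer, 0 other) match
the reported median-exposure HRs. Covariates are a reduced schema — age,
sex, smoking (3-level), one standard-normal confounder, baseline
prevalence flags — with conventional effect sizes (e.g. 0.08/yr age, 0.4
male). One root seed drives everything through `SeedSequence` spawn keys
(one substream per participant), so identical seed + configuration is
reproducible bit-for-bit.

**Model tier.** Calibration studies (CI coverage, Wald type-I error) need
thousands of cohorts, so `simulate_analysis_cohort` draws the daily VILPA
exposure directly from a zero-inflated gamma (11.2% zeros, shape 2, scale
2.4 — median ~4 min/day among the non-zero) and reuses the survival
generator, skipping the epoch layer.

**Problem sizes used in the test suite** (chosen to make the statistical
assertions sharp at desk scale): exact-recovery runs on 200 participants
× 7 days; coverage of the spline-Cox CI uses 200 replicates of n = 5,000
with ~500 events each; Wald-test calibration uses 500 replicates of
n = 2,000; the Fine–Gray/Cox coincidence uses n = 400 with full follow-up;
proportional-hazards calibration uses 60 replicates of n = 400.

## Known limitations

* Fine–Gray standard errors are model-based rather than sandwich
  (conservative); point estimates match R's reference implementation.
* The Schoenfeld per-term test follows the classic (pre-2019) formulation;
  modern R `survival` uses a refined per-term statistic, though the global
  statistics agree closely.
* Complete-case analysis only; no frailty, time-varying covariates or
  interval censoring.
* The generator's semi-Markov day structure is a convenience; any
  mechanism producing sporadic short vigorous runs would serve, and none
  of the analytic results depend on it beyond the planted-run log.
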