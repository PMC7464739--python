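# Methods

## The decision problem

Patients with advanced hepatocellular carcinoma (HCC) — BCLC stage C, or
intermediate stage unfit for loco-regional therapy — receive a first-line
systemic agent until progression, then a second-line agent until death.
Head-to-head trials of full *sequences* do not exist: first-line trials
report progression-free survival (PFS) against Sorafenib, second-line trials
report overall survival (OS) in Sorafenib-experienced patients.  `hccseq`
joins these two bodies of evidence in a microsimulation so that all
first-line × second-line combinations can be compared on a common footing,
and weighs the survival gain of a sequence against its toxicity burden.

## Model structure

The model is a three-state semi-Markov process with monthly cycles:

1. **advanced HCC on first-line therapy** — sojourn time follows the
   first-line *PFS* law (PFS is a validated surrogate for OS in this disease
   and is not contaminated by post-progression treatment);
2. **first progression, on second-line therapy** — sojourn time follows the
   second-line *post-progression OS* law, clocked from state entry
   (the semi-Markov property: the hazard rises with time in state, not
   calendar time);
3. **death** (absorbing).

States are mutually exclusive per cycle.  Rather than converting the
parametric laws into per-cycle transition probabilities, the simulator draws
continuous event times from the laws, resolves orderings in continuous time,
and bins events to the end of the containing cycle.  This is exact where a
per-cycle probability formulation would approximate, and it is what makes
the time-inhomogeneous (Weibull) hazards cheap to simulate.

Three mechanisms compete for each simulated patient:

* the first-line event at `T1 ~ Weibull(scale1, shape1)`.  With probability
  `delta_death_first_line` (default 0.08) this event is a death — the
  patient never receives second-line therapy; otherwise it is a progression
  and a second-line time `T2 ~ Weibull(scale2, shape2)` runs from
  progression;
* background (non-cancer) mortality, drawn by piecewise-exponential
  inversion of an age-indexed life table from age 60, advancing along the
  simulation clock.  It competes as an independent time-to-event; whichever
  of disease death and background death comes first kills the patient;
* a lifetime horizon capped at 480 cycles (40 years), beyond which survival
  for this cohort is numerically negligible; the rare trajectory reaching it
  is censored there and flagged.

Risks and benefits are not discounted: median survival in every scenario is
under three years.

### The first-line death split

Trials report that some patients never reach second-line therapy because
they die during first-line treatment, but not the mechanism.  We model it as
a Bernoulli split applied to the first-line event.  The default
`delta_death_first_line = 0.08` is back-solved from the published
transition-weighted SAE rates, which imply that roughly 92% of simulated
patients transit to the second state; the parameter is exposed in the
configuration and in the sensitivity machinery rather than hard-coded.

### The life table

The packaged default is a **synthetic** male life table following a Gompertz
law with q(60) = 0.011 doubling every 8 years — a typical industrialized-
country male mortality schedule.  For a cohort with median OS around two
years, background mortality at age 60–63 removes about 2% of patients and
is a second-order effect; any national life table in the same TSV format
(`age`, `annual_death_prob`) can be substituted per run.

## Parameterizing the time-to-event laws

All laws are two-parameter Weibull, `S(t) = exp(-(t/scale)^shape)`, time in
months.  Three routes produce parameters:

* **Censored MLE** (`fit_weibull_mle`) on individual patient data, with
  standard errors from the observed information matrix (delegated to
  lifelines, which uses the identical parameterization).
* **Quantile inversion** (`weibull_from_quantiles`): the published
  per-treatment Weibull *median* and *IQR* determine the parameters
  uniquely, because IQR/median is scale-free and strictly decreasing in the
  shape; the shape is bracketed on [0.05, 50] and found by Brent's method,
  the scale recovered from the median, and a forward check enforces 1e-6
  relative reproduction of both inputs.  The packaged therapy profiles use
  this route.  Note these can differ in the third decimal from parameters
  fitted by MLE on the underlying reconstructed data; downstream medians are
  insensitive to this at the reported precision.
* **KM reconstruction** (`reconstruct_ipd`) for users who digitize published
  curves: within each interval between number-at-risk entries, censoring
  times are spread uniformly, event counts at each digitized drop follow
  from the running product-limit value (the rounding is self-correcting
  because the running KM tracks what was actually allocated), and the
  censoring total is iterated until the published number at risk is matched
  exactly.  Past the last risk entry no intra-interval censoring is assumed;
  survivors are censored at the curve's end.  Survival rises up to 0.005
  (digitization jitter) are clamped to the running minimum; larger rises are
  rejected as infeasible.  Round-trip accuracy (KM of the reconstruction vs
  the source curve) is within 0.02 absolute survival probability on
  synthetic fixtures of 50+ patients.

Only monotone-increasing hazards are clinically plausible for progressing
advanced cancer, so candidate families are screened by the sign pattern of
the fitted hazard on a grid (`classify_hazard_shape`): log-normal and
log-logistic hazards are dome-shaped, the exponential is constant, and gamma
fits in this setting decrease — all unsuitable; every packaged Weibull law
has shape > 1 and an increasing hazard, which the test suite asserts.  A
relative slope below 1e-3 counts as flat.

## Outcome measures

Let the reference sequence be the least effective one (lowest median OS).

* **Median OS**: Kaplan-Meier median of simulated death times (identical to
  the sample median here, as deaths inside the horizon are fully observed).
  Reported to the month — the model's native resolution; tables round, but
  derived measures below use the unrounded internal values.
* **36-month milestone survival**: percentage of patients alive beyond
  month 36.
* **LYG** — life-years gained: (median OS − reference median OS)/12.
* **NNT**: `round(1/|ΔS(36)|)`, with the absolute risk difference so the
  measure is defined for sequences below the reference; the nearest-integer
  rounding (not ceiling) reproduces the published values.
* **Weighted SAE rate**: trial-reported grade ≥ 3 adverse-event rates of the
  two lines, weighted by the simulated numbers of patients entering each
  state — every patient enters first line, only those progressing enter
  second line.
* **ISER** — incremental safety-effectiveness ratio:
  `(SAE_a − SAE_b) / (LYG_a − LYG_b)`, in percentage points of SAEs per
  life-year gained.  The toxicity price of choosing the more effective
  sequence; the analogue of an ICER with SAEs in place of cost.  When the
  LYG difference is zero, or one option is better on both axes, the result
  reports dominance instead of a ratio.
* **Minimum trial size**: at each candidate per-arm size, both cohorts are
  simulated repeatedly and the two-sided Wilcoxon rank-sum test applied to
  the OS samples; the smallest size with majority rejection is reported.

## Sensitivity analyses

**Covariate-to-survival link.**  Trial populations differ in HBV/HCV
etiology, macrovascular invasion and/or extrahepatic disease (MaVI/EHD) and
performance status; a sample-size-weighted linear meta-regression of
trial-level median PFS on these four prevalences is the model's only
covariate-to-survival link.  A covariate change moves the predicted median
PFS; the ratio of predicted to baseline median multiplies the first-line
Weibull scale (a proportional shift of every quantile — proportional
hazards is a property of the Weibull with fixed shape).  The shift applies
to the first-line laws of *all* sequences in a comparison, because the
population changed, not one arm.

**One-way tornado.**  Covariate prevalences vary by ±30 percentage points,
capped to [0, 1] (e.g. from a baseline MaVI/EHD prevalence of 0.88 only a
12-point increase is possible — capping is logged, never an error);
Weibull parameters vary by ±2 standard errors of their fit.  Bars are the
induced LYG range versus a reference sequence, sorted by width.  Covariates
outside the meta-regression (sex, ethnicity, BCLC stage) produce zero-width
bars by construction.

**Two-way ISER plane.**  Over a rectangle of (ΔSAE, ΔLYG) values, a point
favors the more effective option iff ΔSAE ≤ threshold × ΔLYG — the
net-benefit half-plane, equal to ΔSAE/ΔLYG ≤ threshold wherever ΔLYG > 0.
The default willingness-to-risk threshold is 30% of SAEs per LYG.  The zero
ΔLYG line is excluded (undefined ratio).  Reported: favored fraction overall
and within the four quadrants split at the midpoints of each axis (high/low
LYG × high/low SAE scenarios); the favored fraction is monotone
non-decreasing in the threshold.  Grid 201×201 by default.

**Probabilistic analysis.**  1000 draws of the four prevalences, uniform
over configurable ranges (default: the min-max across the trial catalog),
each translated into a shared first-line scale shift and pushed through a
fresh simulation of every strategy and the reference; the result is the
fraction of draws in which a strategy's median OS exceeds the reference's,
ties on the monthly grid counting one half (so a strategy against itself
scores 0.5 exactly in expectation).

## Baseline population and the synthetic trial catalog

The baseline prevalence profile (male 0.84, Asian 0.50, HBV 0.45, HCV 0.30,
MaVI/EHD 0.88, ECOG-PS1 0.37, BCLC-C 0.82) is typical of the first-line
trial populations feeding the model; only the four meta-regression
covariates propagate to survival.  No redistributable trial-level covariate
table exists, so the packaged catalog is **synthetic**, generated by
`gen_trial_catalog` with a fixed seed: prevalences uniform on [0, 1], median
PFS a linear predictor plus noise, per-trial sizes uniform on [100, 1000].
The default coefficients (intercept 10; HBV −3, HCV +2, MaVI/EHD −5,
ECOG-PS1 −3 months per unit prevalence) were chosen once for sign pattern
and realistic prediction range (4–9 months), not fitted to any published
regression.  The noise standard deviation scales as 1/√n, the sampling-error
structure of a trial-level median — which is exactly what justifies
weighting the regression by sample size.  Consequences: tornado orderings
and probabilistic exceedance fractions computed from the packaged catalog
are demonstrations of the machinery, not estimates of the published
appendix-level quantities; tests treat them qualitatively (signs, orderings,
calibration), while the base-case outcome table does not involve the catalog
at all.

## Numerical choices

* Cohort size 2000 for the base case; 400,000 for the ISER of the two
  leading sequences, because that ratio divides a ~7-point SAE difference by
  a month-quantized median-OS difference and needs a large cohort to pin
  down.  The tornado/PSA default to the base-case size.
* Per-sequence seeds are derived from the run seed by hashing the sequence
  label, so results are independent of strategy order and byte-identical
  under a rerun.
* Quantile-solver tolerance 1e-12 on the shape bracket; forward verification
  at 1e-6 relative.
* Censoring calibration in the IPD generator: censoring is uniform on
  [0, c] with c solved by bisection so the expected censored fraction equals
  the target (the pattern of staggered entry with a common cutoff).
* KM ties: events precede censorings at the same time (standard).
* Ranking ties in median OS are broken by 36-month survival, descending.

## What the synthetic generators do and do not emulate

The IPD generator produces exact Weibull data with independent uniform
censoring; real trial arms deviate from Weibull in early plateaus and
late-crossing tails (a known issue for immunotherapy), and censoring may be
informative.  The curve digitizer evaluates the true KM on a grid without
pixel noise beyond what the jitter tolerance models.  Passing tests
therefore demonstrate that the pipeline is *correct under its stated
assumptions*, not that the Weibull family is adequate for any particular
trial — that judgement is what the hazard-shape screen and the fit
diagnostics are for.

## Known limitations

* No carry-over effect of first-line therapy on second-line efficacy; the
  second-line laws come from Sorafenib-experienced populations regardless of
  the simulated first line.
* No liver-decompensation state, no treatment-discontinuation-without-
  progression state.
* No quality-of-life weighting (utilities are unavailable for most of the
  underlying trials), hence LYG rather than QALYs, and no costs.
* The SAE weighting assumes line-specific SAE rates are fixed trial
  constants, independent of time on treatment.
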