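# Methods

## IAUC geometry

The incremental area under a glucose curve is computed per segment on the
raw sampling grid (default 0/15/30/45/60/90/120 min) with the baseline fixed
at the 0-min value. Writing d₁, d₂ for the two endpoint excesses over
baseline and Δt for the segment width:

- d₁, d₂ ≥ 0: trapezoid (d₁+d₂)/2·Δt;
- one endpoint below baseline: the segment is split at the linearly
  interpolated crossing and only the triangle above baseline counts,
  d²/(|d₁|+|d₂|)·Δt/2 with d the non-negative endpoint;
- both below: zero.

This "cut at baseline" geometry is the standard choice in GI methodology
(alternatives exist, e.g. net AUC, which subtracts area below baseline). It
makes the result non-negative and invariant to adding a constant to all
glucose values; both properties are tested, and the engine is checked to
1e−6 relative against an independent numeric oracle that locates crossings
by root finding on the interpolated curve.

## GI, GL and aggregation

Each subject's reference IAUC is the arithmetic mean of their glucose-solution
tests only; steamed-rice reference tests are stored (reserved food id
`RICE_REF`) but never enter the GI denominator, since GI is defined against
glucose. Per-food GI is the mean of per-subject GI ratios — not the ratio of
mean IAUCs — because the study design reports per-food mean ± SD over the
8 subjects consuming each food, which implies per-subject values; SDs use
the n−1 denominator. GL per event applies the subject's GI to the serving's
available carbohydrate.

Class bands are inclusive at the published boundaries (GI low ≤ 55,
high ≥ 70; GL low ≤ 10, high ≥ 20) and configurable via
`GlycemicClassBands`; an alternative convention with a strict high bound
exists in the literature, and no bundled food sits exactly on a boundary
that would distinguish them. Displayed GI/GL/eGL values round half away from
zero; all internal computation is full precision.

## The eGL model and coefficient recovery

eGL = a + b·(carb − fiber) − c·fat − d·protein² − e·fiber². The equation is
linear in the transformed features, so `EstimatedGlycemicLoad.fit` solves
the 5-parameter OLS problem by `numpy.linalg.lstsq`, refusing rank-deficient
designs (< 5 foods, or collinear nutrient profiles). On noiseless synthetic
data generated from known constants, recovery is exact to 1e−8 (tested).

The original development-study constants are not public. The package's
default coefficients are therefore recovered from the bundled 24-food table
(fitted lazily on first use and cached; the CLI can persist them to a JSON
config and read them back). On that table the fit reproduces every published
integer eGL within ±0.41, comfortably inside the ±1.5 band that integer
rounding of the published scores permits. Fitted values:
a = 6.397, b = 0.396 per g, c = 0.217 per g, d = 0.00749 per g²,
e = 0.01043 per g².

## Validation statistics

**Transportability.** Cohorts are compared from summary statistics alone:
two-sample t-tests reconstructed from (mean, SD, n), pooled-variance by
default (the convention of the era's statistical packages; Welch via
`welch=True`), and a chi-square test on the 2×2 sex table. From the bundled
summaries this reproduces the published significance pattern — carbohydrate,
protein and fiber differ at p < 0.001 between cohorts; anthropometrics and
fat do not (height p ≈ 0.84). The published sex-split p-value (0.364) is not
reproducible from the printed 50%/50% proportions, which give p = 1; the
recomputed value is reported.

**Calibration and discrimination.** The study does not state how events were
dichotomized. This package's interpretation — flagged at warn level whenever
used — is event-level "observed high GL": measured GL ≥ 20, the high-GL
band boundary; the threshold is an argument everywhere. The outcome is
regressed on eGL by maximum-likelihood logistic regression (Newton/IRLS via
statsmodels, convergence required, complete separation raised as an error).
Hosmer–Lemeshow uses g = 10 deciles of predicted risk (near-equal bins of
the sorted probabilities), df = g − 2, with degenerate bins merged into a
neighbour; in strata too small for 10 bins, g shrinks to ⌊n/2⌋. Its null
behaviour is verified by simulation: on a well-calibrated *fitted* model the
type-I error at α = 0.05 sits in [0.03, 0.08] (the df = g − 2 reference
applies to fitted probabilities; against known true probabilities the
statistic is closer to χ²(g)). AUROC is the Mann–Whitney concordance with
midrank ties and a Hanley–McNeil normal-approximation 95% CI clipped to
[0, 1]; it is tested against exhaustive pairwise concordance and
scikit-learn. Because the published per-subject data are unavailable and the
dichotomization unstated, the published overall χ² = 11.607 and
AUROC = 0.571 are not reproduced numerically; the machinery is validated by
the property checks above instead. Note the synthetic events make eGL
strongly predictive by construction, so simulated AUROCs run far above the
published 0.571.

**Agreement.** Pearson r (two-sided t-distribution p) and the OLS line
measured = intercept + slope·eGL, with R² = r². On the 24 per-food means the
line is measured = −8.99 + 1.63·eGL (published: −9.27 + 1.64·eGL; published
inputs are integer-rounded).

## The synthetic generator

The generator emulates the study's *summary* statistics, not glucose
physiology:

- **Curves**: fasting baseline ~ Normal(92.8, 4.78) mg/dL; excess shape is a
  two-parameter gamma-like pulse (t/tₚ)^k·exp(k(1 − t/tₚ)), peak time
  tₚ = 35 min, shape k = 2 — a convention chosen to peak in the 30–45 min
  window and return near baseline by 120 min, since the study reports only
  the sampling grid. The pulse is non-negative and zero at t = 0, so the
  noiseless IAUC is exactly linear in amplitude and any target area is hit
  by direct scaling; Gaussian measurement noise (default SD 3 mg/dL) is then
  added. Per-subject glucose-reference IAUC targets are Normal(4500, 900)
  mg·min/dL truncated at 500, consistent with the IAUC/GI ratios in the
  bundled table.
- **Events**: for each food, n = 8 draws from Normal(GL mean, GL SD)
  truncated at 0 using the bundled per-food dispersion, paired with the
  food's eGL. Within-food dispersion mixes between-subject and measurement
  variance, which the study does not separate; the simulator treats it as a
  single Normal component. Truncation at 0 adds a small positive bias for
  low-GL foods (largest for mean 8, SD 4: ≈ +0.22); it is documented, not
  corrected, and the generator's large-sample means are tested against the
  analytic truncated-normal mean.
- **Cohort**: characteristics drawn independently from the validation
  cohort's printed means/SDs, sex balanced 10/10, BMI recomputed from the
  drawn height and weight (hence wider BMI dispersion than the printed SD,
  since real height and weight are correlated); fasting glucose truncated
  below 100 mg/dL to respect the study's inclusion screen.

All generators are driven by one `numpy` Generator seeded from
`SimulationConfig.seed` in a fixed order; a fixed config yields byte-identical
output.

**What passing tests show**: that the pipeline arithmetic, the attenuation
structure (event-level r ≈ 0.71 vs per-food r ≈ 0.90) and the validation
machinery behave correctly under the study's printed distributions. They do
not show that real glucose curves follow the pulse shape, that real GL
dispersion is Normal, or that eGL's discrimination of real events matches
the simulation.

The analytic event-level correlation used as a cross-check is the
attenuation formula r = cov(eGL, GL mean) / √(var(eGL)·(var(GL mean) +
mean within-food variance)) over foods; it ignores the truncation, so it
predicts a simulated replicate's r to within the replicate-to-replicate
spread (≈ 0.69–0.71 here).

## Problem sizes and determinism

The bundled tables drive all deterministic results (24 foods, two cohorts).
Stochastic checks use 500 seeded replicates of the 192-event simulation for
the correlation summaries, 1000 replicates at n = 500 for the
Hosmer–Lemeshow type-I error, and 1000 random 7-point curves for the IAUC
oracle comparison — sizes chosen so Monte-Carlo error is well inside each
assertion's tolerance. Seeds are fixed in tests; the acceptance script
derives replicate seeds from its `--seed` argument.

## Known limitations

- The eGL constants are recovered from integer-rounded published scores, not
  the development study's raw fit; they are correct to the precision those
  scores carry.
- The calibration/discrimination outcome definition is an interpretation
  (measured GL ≥ 20); published χ²/AUROC values are not reproducible without
  the per-subject data.
- The curve simulator is a sampling-grid emulation, not a
  glucose–insulin dynamics model; no meal-composition effects exist beyond
  the per-food summary statistics.
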