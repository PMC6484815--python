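# Methods

## The measurement model

The object of analysis is a fluorescence time–intensity curve: ROI-mean
intensity of a single-channel fluorescence frame sequence, sampled at the
frame rate, in arbitrary units (AU). The physiological signal is an
inflow front — baseline until dye arrival, a monotone rise to a maximum,
then a plateau (or slow washout, which the analysis deliberately
ignores: only inflow-phase factors are computed). Six parameters
summarize the front: F_MIN (baseline), ΔF (peak minus baseline), slope
(ΔF/T_MAX), and the times T_MAX, T_1/2MAX and TR = T_1/2MAX/T_MAX
measured *from the onset of the first fluorescence increase*, not from
injection — the absolute time origin of a recording is irrelevant.

Two structural facts drive every numerical choice below:

1. Intensity units are uncalibrated (camera, light source, working
   distance). All detection thresholds are therefore *relative* (to the
   baseline noise and to ΔF), making the time parameters invariant under
   affine intensity transforms α·I + β, α > 0. The test suite checks
   this invariance explicitly.
2. The landmarks are level crossings (half of ΔF; within ε of ΔF) on a
   monotone signal observed with additive noise. Naïve first crossings
   of a noisy trace are biased early; thresholded "time of maximum" is
   biased early by ε. The estimators below remove both biases while
   remaining sample-exact on noise-free input.

## The synthetic-data generator

The generator emulates a baseline–rise–plateau curve:

    I(t) = F0                                      t < t0
    I(t) = F0 + A·((t − t0)/R)^γ                   t0 ≤ t ≤ t0 + R
    I(t) = F0 + A·exp(−w·(t − t0 − R))             t > t0 + R

with i.i.d. Gaussian sample noise. The power-law rise is chosen because
it makes every landmark analytic — T_MAX = R, TR = 0.5^(1/γ), slope =
A/R — so parameter recovery can be verified against exact truth; γ < 1
gives a fast-start (concave) front, γ > 1 a sluggish (convex) one, and
γ = log 0.5/log 0.6 ≈ 1.357 puts TR exactly at the 0.6 slow-perfusion
boundary.

Two-group cohorts sample slope, T_MAX and TR per group from truncated
normal distributions calibrated to the published 86-patient cohort
(complication group n = 6: slope 0.7, T_MAX 64.0 s, TR 0.6;
no-complication n = 80: slope 2.5, T_MAX 30.3 s, TR 0.4). Published
dispersions are standard errors; the sampler converts SE → SD via
SD = SE·√n. The published TR standard errors round to 0.0, so TR
dispersion defaults to 0.05 — a configurable assumption, not a published
value. TR is sampled directly and converted to γ = log 0.5/log TR (so
group TR means are matched by construction); amplitude is slope·T_MAX
(so the slope identity holds by construction). Truncation: TR in
(0.05, 0.95), times > 1 s (and < 240 s), slope > 0.05 AU/s. Truncating
the complication-group T_MAX at 1 s shifts its mean up by about 1 s
relative to the nominal 64.0; the calibration test verifies the sampler
against the analytic truncated-normal mean for exactly this reason.

Defaults that define the simulated recording: onset at 10 s, 10
frames/s, additive noise SD 1.5 AU (2–4% of typical amplitudes), washout
0 (plateau), per-curve duration = onset + rise + max(10 s, 0.35·rise).

What the generator does **not** emulate — hence what passing tests do
not show about real data: motion of the bowel and camera, illumination
drift and vignetting, photobleaching, dye recirculation (second-pass
bumps), heteroscedastic or correlated sensor noise, and ROI placement
error. The affine-invariance tests cover static imaging-condition
differences only.

## Curve analysis

All detection runs on a 0.5 s centered moving-average of the curve
(truncated at the ends, length-preserving); the raw curve is kept for
plotting and for the statistical tests below that need independent
noise.

**Onset detection.** Candidate arrival is the first sample exceeding the
running baseline mean + k·SD (k = 3, statistics over all samples before
the candidate), sustained for 0.5 s (window mean above the threshold and
at least half its samples above). Baseline statistics are frozen at the
first raw exceedance: past that point the running statistics are
contaminated by the rise itself, and a threshold that chases the signal
can postpone detection indefinitely. For slow-starting fronts that still
outrun the threshold, a fallback compares each sample against the lowest
threshold seen so far. If no sustained exceedance occurs within the
analysis window (default 300 s, mirroring the intraoperative cap on
waiting for inflow), a no-perfusion error is raised.

On noise-free curves the crossing is frame-exact and the sample *before*
it is reported as onset (the last baseline sample). On noisy curves the
declared crossing necessarily lags the true first increase by however
long the signal needs to clear the noise band — ~2 s for a linear rise
at 2% noise — so the onset is refined by back-extrapolating the rising
edge: the raw samples from 12 s before the edge up to 90% of the rise
amplitude are fitted with f + a·max(t − t0, 0)^γ (γ ∈ [0.2, 8]), and the
fitted break point t0 is the onset. The baseline level f is itself a
free parameter (anchoring it to the contaminated running mean would bias
the onset late), and the flat pre-onset segment of the model is what
localizes the break. Because the objective is non-smooth in t0 and t0/γ
are strongly coupled, the fit is a coarse profile grid over (t0, γ) with
the closed-form (f, a) pair, polished by bounded least squares. F_MIN
and the baseline SD are then recomputed from the raw samples strictly
before the refined onset.

**Peak level.** On noise-free curves, the raw maximum. On noisy curves,
the median of the smoothed samples within the top 10% band of the range
("robust peak") — the raw maximum of a noisy plateau overestimates the
peak by the extreme of the noise, which would in turn displace every
threshold.

**T_1/2MAX.** First crossing of F_MIN + 0.5·ΔF, linearly interpolated,
located on the *monotone landmark trace*: the isotonic (non-decreasing
least-squares) regression of the smoothed curve over the analysis
window. For a monotone signal plus noise, isotonic regression is the
canonical monotonicity-restoring fit, and first crossings of it are far
more stable than first crossings of the noisy trace itself; on
noise-free input it is the identity over the rise. The trace is exposed
(`detection_series`) so the crossing can be checked against an
exhaustive scan of its upsampled linear interpolation.

**T_MAX.** Anchored at the first attainment of (1 − ε)·ΔF above
baseline (ε = 0.02) on the landmark trace, then extended to the full
peak level along the local tangent (least-squares slope over the 1 s
ending at the crossing). The ε-threshold alone is biased early by
ε·T_MAX/γ; tangent extrapolation cancels this to second order in ε for
smooth fronts. On noise-free curves T_MAX is instead the sample-exact
first attainment of the maximum.

**Censoring.** A curve still rising at the end of the analysis window
has its T_MAX censored there, with a warning and a flag; classification
treats a censored measurement as at least dangerous (clinically
conservative). "Still rising" is a regression test on the final stretch
(≥ 8 s) of *raw* samples — smoothed samples are autocorrelated and would
wildly overstate significance — requiring the end slope to be both
statistically positive (> 3 SE) and practically meaningful (projected
rise > 2% of ΔF across the stretch).

**No-measurable-inflow guard.** If the apparent rise amplitude is below
4 baseline SDs, the curve is reported as no-perfusion rather than
parameterized: a "rise" that small cannot be told apart from noise. In
cohort analysis such patients are flagged and ranked maximally abnormal
(TR 1, zero slope, every factor slow, critical zone) — the pipeline
analogue of observing no flow within the capped window.

**Slope.** ΔF/T_MAX by definition (so slope·T_MAX = ΔF exactly); a
fitted variant (least-squares line over the 20–80% rise) is available as
`slope_method="fit"` but non-default, since the ratio definition is the
published one.

**Noise-free fast path.** Baseline SD below 10⁻⁷ of the rise amplitude
switches the sample-exact rules on. The criterion is a *relative* one,
so the branch itself is affine-invariant.

## Classification

Strict published inequalities per factor; values equal to a cut-off are
moderate (the boundary is never defined as fast or slow in the source
tables). The two-factor risk zone uses T_1/2MAX (high sensitivity) as
step one and TR (high specificity) as step two: both fast → safe; both
slow → critical; exactly one slow → dangerous; anything else (no slow,
at least one moderate) → intermediate. The full nine-combination map
ships in the config and can be overridden — the source material names
only the corners, so the mixed-quadrant assignment is a documented
package choice, as is the severity ordering safe < intermediate <
dangerous < critical. Surgical guidance attached to zones is emitted as
informational text only.

## Cohort statistics

Diagnostic proportions are carried as exact numerator/denominator pairs;
zero denominators make a metric explicitly undefined (never silently 0);
percentages render to one decimal, half-up. ROC curves and tie-aware
AUC come from scikit-learn; the confidence interval uses a DeLong
midrank variance estimator written in-package (a seeded stratified
bootstrap is the alternative); the cut-off maximizes Youden's J and is
reported midway between the bracketing observed values. For protective
factors (slope: larger is safer) the AUC is reported in the raw
"larger ⇒ complication" orientation — below 0.5, matching how the source
prints it — with the flipped value alongside. The 2×2 odds ratio is
(tp·tn)/(fp·fn) with a Wald log-scale CI; a single zero cell triggers
the Haldane–Anscombe 0.5 correction (flagged), an empty margin leaves
the OR undefined. Logistic regression is a statsmodels Newton/IRLS fit;
rank-deficient designs raise, and perfect or quasi-separation (likely
with few events and strong predictors) is reported diagnostically, not
returned as silent estimates. No multiple-testing correction is applied
(single pre-specified α = 0.05, matching the source analysis).

## Problem sizes

The test suite and acceptance script use: noiseless recovery over
γ ∈ {0.5, 0.756, 1, 1.357, 2} × {5, 10, 30} fps; noisy recovery over 200
seeded curves (5% amplitude noise, 10 fps); onset accuracy over 200
seeded curves at 2% noise; ROC oracle checks on 50 random cohorts of up
to 200; null-coverage of the logistic CI over 100 permuted replicates;
and the end-to-end pipeline on 100 seeded 86-patient cohorts (20 in the
acceptance script). These sizes make the stochastic checks reproducible
in minutes on a single core while keeping estimator noise well below the
tolerances they assert.

## Known limitations

* The onset refinement assumes a locally power-law rising edge; fronts
  with inflection before half-max (e.g. biphasic inflow from collateral
  filling) would bias it.
* Isotonic landmark localization presumes a monotone inflow; strong
  recirculation bumps before the peak violate that.
* No motion correction or illumination compensation: the package
  measures the curve it is given.
* Censored T_MAX is a lower bound, and slope (ΔF/T_MAX) is
  correspondingly an upper bound on those curves.
* Cohort calibration reproduces published group means and standard
  errors, not patient-level covariate structure; multivariate
  adjustment on real covariates is out of reach by construction.
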