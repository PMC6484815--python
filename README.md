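# icgquant

Quantitative analysis of indocyanine green (ICG) fluorescence angiography
for intraoperative bowel-perfusion assessment.

During laparoscopic colorectal surgery, ICG injected intravenously binds
plasma proteins and stays intravascular, so near-infrared fluorescence of
the colon wall tracks its blood perfusion. Simply *seeing* fluorescence is
a poor predictor of anastomotic complications — delayed inflow still
lights up eventually. What discriminates is the *shape in time* of the
fluorescence inflow curve. `icgquant` turns a fluorescence frame sequence
(or a pre-extracted time–intensity curve) into the standard perfusion
parameters, classifies perfusion status against published cut-offs, and
evaluates predictive performance.

## The quantities

For an inflow curve I(t) with baseline F_MIN and onset (first fluorescence
increase) at t₀:

| symbol | definition | units |
|---|---|---|
| F_MIN | baseline fluorescence before dye arrival | AU |
| ΔF (F_MAX) | peak minus baseline fluorescence | AU |
| Slope | ΔF / T_MAX | AU/s |
| T_MAX | time from onset to maximum | s |
| T_1/2MAX | time from onset to half of ΔF | s |
| TR | T_1/2MAX / T_MAX | — |

TR is a dimensionless shape descriptor of the inflow front: values near 1
mean a sluggish early rise (slow perfusion). Because fluorescence
magnitudes depend on camera, light source and working distance (arbitrary
units), the time parameters — which are invariant to affine intensity
transforms α·I + β — are the clinically robust factors. Published
cut-offs trichotomize each factor (slope: fast > 1.0, slow < 0.7 AU/s;
T_1/2MAX: fast < 10 s, slow > 18 s; TR: fast < 0.4, slow > 0.6), and a
two-step flow chart (T_1/2MAX screens, TR refines) assigns a four-level
anastomotic risk zone: safe, intermediate, dangerous, critical.

No surgical videos ship with the package. A synthetic-data module
generates curves, frame stacks and two-group cohorts from a power-law
inflow model with *analytic* landmarks (TR = 0.5^(1/γ)), calibrated to
the published 86-patient cohort, so every stage is testable against known
ground truth.

## Worked example

```python
from icgquant import KineticTruth, generate_curve, PerfusionModel

truth = KineticTruth(baseline_f0=10.0, amplitude_a=50.0, onset_t0=8.0,
                     rise_duration=40.0, shape_gamma=1.357, noise_sd=1.5)
curve = generate_curve(truth, frame_rate=10.0, duration=70.0, seed=42)

res = PerfusionModel(curve).fit()
print(res.summary())
```

```
Perfusion curve quantification
====================================
F_MIN (baseline, AU)      10.00
dF (peak - baseline, AU)  49.82
slope (AU/s)              1.276
t_onset (s)               8.64
T_MAX (s, from onset)     39.06
T_1/2MAX (s, from onset)  23.26
TR = T_1/2MAX / T_MAX     0.596
```

The generative truth had T_MAX = 40 s, T_1/2MAX = 24 s, TR = 0.60 (the
slow-perfusion boundary); the analyzer recovers them from the noisy
sampled curve to a fraction of a second. Classification then reads:

```python
status = res.classify()
status.risk_zone.value      # 'dangerous'
status.categories           # slope: fast, t_half_max: slow, tr: moderate
```

T_1/2MAX of 23 s is slow (> 18 s) while TR 0.596 sits just under the 0.6
cut-off, so the two-step flow chart lands in the dangerous zone.

Cohort-level evaluation mirrors the published tables:

```python
from icgquant import ContingencyTable2x2, diagnostic_values, odds_ratio

table = ContingencyTable2x2(tp=5, fp=3, fn=1, tn=77)   # slow TR vs outcome
print(diagnostic_values(table).summary())
# sensitivity 83.3% (5/6), specificity 96.3% (77/80), ppv 62.5% (5/8),
# npv 98.7% (77/78), accuracy 95.3% (82/86)
odds_ratio(table).odds_ratio                            # 128.33
```

A command line mirrors the library:
`icgquant simulate curve|stack|cohort`, `icgquant extract`,
`icgquant analyze`, `icgquant classify`, `icgquant evaluate`.

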