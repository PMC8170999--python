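# cholspec

A simulation and analysis toolkit for **non-invasive skin-cholesterol
detection by transmission absorption spectroscopy**, written for
instrumentation and biostatistics work on point-of-care optical assays.

The measurement principle: a detection reagent binds skin cholesterol and,
via an HRP/TMB reaction, produces a blue colored product. A white-LED beam
passes through the reaction solution; the transmitted spectrum encodes the
product concentration through the Beer–Lambert law

```
I1(λ) = I0(λ) · exp(−α(λ) · c · l)
```

where `I0` is the incident spectrum, `I1` the transmitted spectrum, `α(λ)`
the extinction profile of the colored product, `l` the path length (1 mm)
and `c` the relative cholesterol concentration. Absorbance
`A(λ) = ln[I0(λ)/I1(λ)]` is linear in `c`, so `c` is retrieved by ordinary
least squares over the characteristic band 475–780 nm:

```
c* = Σ α(λ)·l·A(λ) / Σ (α(λ)·l)²
```

Raw spectrometer traces (2048 samples, 330–850 nm) are first resampled by
piecewise-linear interpolation onto the 400-point integer-wavelength grid
{380, …, 779} nm. Because the enzymatic color response saturates, the
concentration–signal relation is calibrated with a four-parameter logistic
(4PL) in log10 concentration, which is monotone and closed-form invertible.

The package provides:

- `cholspec.spectral` — resampling, absorbance, Beer–Lambert forward model
  and least-squares retrieval;
- `cholspec.calibration` — 4PL standard-curve fitting, prediction, inversion;
- `cholspec.simulate` — a synthetic instrument and study generator (LED
  source with bounded ≤1% exposure jitter, blue chromogen, PI source-control
  loop, dilution ladders, extraction time courses, repeatability studies,
  three-group clinical cohorts with a paired noisy reference method);
- `cholspec.stats` — Pearson correlation, Bland–Altman agreement
  (bias ± 1.96·SD limits), coefficient of variation, Mann–Whitney AUC with
  DeLong 95% CI, one-way ANOVA — all implemented from first principles and
  cross-checked against scipy/scikit-learn/pROC in the test suite;
- `cholspec.pipeline` — end-to-end measurement, accuracy and screening
  studies with provenance-stamped JSON reports;
- a thin `cholspec` CLI (`simulate`, `measure`, `calibrate`, `validate`)
  over YAML configs, and narrative scripts under `examples/`.

## Worked example

Simulate a screening cohort (115 normal / 117 at-risk / 110 disease
subjects, log-normal skin cholesterol, elevated groups 1.5× normal) and run
the screening analysis (`examples/06_screening_study.py`):

```
normal  : n=115  mean= 158.00  sd= 38.30
risk    : n=117  mean= 242.64  sd= 76.60
disease : n=110  mean= 233.94  sd= 61.96

ANOVA: F=66.65, p=3.87e-25
normal vs disease: AUC 0.8732 (95% CI 0.8283-0.9181)
normal vs risk   : AUC 0.8641 (95% CI 0.8193-0.9088)
```

The ANOVA F confirms the groups differ; the AUC is the probability that a
randomly chosen elevated-group subject has higher skin cholesterol than a
randomly chosen normal subject (≈0.86 at the default effect size), and the
normal-vs-risk comparison is near-identical to normal-vs-disease because
the generator draws the two elevated groups from the same distribution.

The accuracy study (`examples/05_accuracy_study.py`) pairs 73 device
measurements with a noisy linear reference and reports Pearson r ≈ 0.83–0.94
across seeds with a Bland–Altman bias near −72.8 (device − reference) and
limits of agreement near −112 to −33; the repeatability study
(`examples/04_repeatability.py`) keeps the CV of retrieved concentration
within 5% at all three levels under 1% source jitter:

```
level 0.25: mean 0.2532, CV 1.79%
level  1.0: mean 0.9975, CV 0.63%
level  4.0: mean 4.0037, CV 0.16%
```

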