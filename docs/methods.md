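# Methods

## Measurement model

The instrument is modeled as a transmission spectrometer: an incident
spectrum `I0(λ)` and a transmitted spectrum `I1(λ)` related by the
Beer–Lambert law `I1 = I0·exp(−α(λ)·c·l)` with path length `l = 1 mm`.
Absorbance `A(λ) = ln(I0/I1)` is linear in the relative concentration `c`,
and `c` is estimated by unweighted least squares over the characteristic
band 475–780 nm (inclusive), where the blue colored product absorbs. The
estimator has the closed form `c* = Σ xA / Σ x²` with `x = α·l`; it is
linear in `A`, invariant to common rescaling of both spectra, and exactly
recovers `c` on noiseless same-grid data (tested to 1e−10). Negative
estimates are legitimate under noise and are returned unclamped; the
reporting layer clamps to zero and sets a `negative-retrieval` flag, so
downstream statistics remain unbiased while reported values stay physical.

### Wavelength grid

Raw traces carry 2048 uniform samples over 330–850 nm (the spectrometer's
range); processing restricts to 380–780 nm. An integer-wavelength grid on
that window has 401 inclusive points; the processing chain is specified to
use 400, so the default grid adopts the half-open convention
{380, …, 779}. The inclusive 401-point variant is one flag away
(`WavelengthGrid(include_endpoint=True)`); nothing downstream depends on
the choice beyond the point count.

### Resampling accuracy

Resampling is piecewise linear. Because the 2048-point raw grid is not
aligned with the integer grid and the simulated spectra are smoothly
curved, interpolation leaves a relative error of order `h²·(curvature)` —
measured at ~1e−6 to ~1e−5 of the retrieved concentration across the
0.25–4 relative-unit range. Tests of the raw-grid round trip therefore
assert a 5e−5 relative floor; this is an intrinsic property of linear
interpolation on an unaligned grid, not an implementation artifact. The
logarithm in the absorbance is guarded by flooring transmitted intensities
at 1e−9 of the peak incident intensity.

## Calibration

The enzymatic color response saturates, so concentration→signal is modeled
as a four-parameter logistic in log10 concentration:
`f(c) = lower + (upper−lower)/(1 + 10^(slope·(mid − log10 c)))`, the
standard form for HRP/TMB-type assays. Monotonicity is enforced by
construction (span ≥ 0, slope ≥ 0 in the optimizer's parameterization);
fitting is `scipy.optimize.curve_fit` (TRF, tolerances 1e−15) with
self-starting values: asymptotes from the signal extremes, midpoint from
the concentration nearest mid-signal, unit slope. On exact 4PL data the
six-point 2-fold dilution ladder (5 → 0.15625 µg/ml) is enough to recover
all four parameters to machine precision. The inverse is closed-form and
restricted to the open asymptote interval; near-flat fits (span below
1e−10 of the signal scale) are flagged non-invertible and a
`FitQualityWarning` is emitted, as it is when the residual exceeds 20% of
the signal variance. Device units are carried as an `a.u.` tag: the
instrument's clinical values are relative, and the pipeline labels whether
an output is raw signal or a calibrated concentration.

## Synthetic instrument and studies

The generator emulates the study conditions rather than any particular
dataset; every generator is a pure function of config + seed
(bit-reproducible, `numpy.random.default_rng` seeded with
`[seed, stage-offset]`).

- **Source**: white LED as two Gaussian bands (blue die 450 ± 18 nm,
  phosphor 560 ± 60 nm, power ratio 1 : 1.8) plus a 0.5% broadband pedestal
  so incident light is strictly positive across the window. The shape only
  enters through band integrals; it is a modeling choice.
- **Chromogen**: one Gaussian absorption band at 652 nm (σ = 40 nm)
  emulating oxidized TMB's blue product. The peak extinction, 2.0 per unit
  concentration per mm, is a design choice sized by error analysis: a
  bounded ±1% exposure jitter on two independent exposures shifts the
  absorbance by `ln(f0/f1)`, which propagates to an additive concentration
  error of SD ≈ 0.006 units, keeping the CV at the lowest repeatability
  level (0.25 units) near 2–3% — inside the instrument's ≤5% repeatability
  design target with margin.
- **Noise**: one multiplicative uniform draw in [1−j, 1+j] per exposure
  (default j = 0.01, matching a source stabilized to <1%), optional
  additive detector noise and an optional multiplicative blotting
  (sample-prep) term, both off by default. A uniform bounded draw was
  chosen over a Gaussian so "varies by at most 1%" holds for every
  realization, not just in SD.
- **Control loop**: discrete PI on an integrating plant,
  `I[k+1] = I[k] + dt·(kp·e + ki·∫e)`, dt = 0.1 s, gains kp = 8, ki = 16 —
  a critically damped design (ωn = 4 rad/s) chosen analytically so all
  five start fractions {0.5, 0.75, 1.0, 1.25, 1.5}× target settle into the
  1% band within 4 s (measured: ≤1.3 s). Settling time is the first time
  after which the trajectory never leaves the band; divergence (|I| > 10×
  target) is reported as non-settling rather than raised.
- **Dilution series**: reagent concentration maps through a Hill response
  `smax/(1+(k/c)^hill)` (smax = 4, k = 1.25 µg/ml, hill = 1.2) — exactly a
  4PL with zero lower asymptote — to an effective chromogen concentration,
  which is then measured optically. This makes 4PL recovery on noiseless
  simulated ladders a self-consistent oracle (recovered to ~1e−5, the
  resampling floor).
- **Extraction time course**: remaining cholesterol decays exponentially
  (default rate 0.5 /min from baseline 2.0 over 0–4 min), giving strictly
  decreasing noiseless measurements.
- **Cohorts**: skin cholesterol is log-normal per group — a standard choice
  for a positive biomarker — with group sizes 115/117/110
  (normal/risk/disease). The elevated groups share one distribution whose
  median is 1.5× normal (the risk and disease groups are deliberately not
  separable). Log-scale SD 0.27 puts the design normal-vs-disease AUC at
  `Φ(ln 1.5/(σ√2)) ≈ 0.856`. The reference method is linear with a fixed
  offset: reference = device + 72.78 with difference SD 20.03 (device −
  reference differences center on −72.78); difference order is
  configurable, device − reference by default. The normal-group median of
  150 a.u. is back-solved from those two anchors so the design
  device–reference correlation `σ_d/√(σ_d²+σ_n²) ≈ 0.906`. The accuracy
  study draws 73 volunteers from the normal-group distribution.

### What the generator does not emulate

Radiometric detail (quantum efficiency, integration time, shot noise),
source drift within a session, reagent/binding kinetics, operator
technique beyond a single optional multiplicative term, covariate
structure (age, lipids) and any real-subject variation beyond a two-group
log-normal shift. Passing tests therefore demonstrate that the processing
and statistics are correct and that the instrument design targets are
attainable under the stated noise model — not that a physical device
meets them.

## Statistics

All validation statistics are first-principles implementations with
independent oracles in the test suite:

- Pearson r from centered sums (vs `scipy.stats.pearsonr`).
- Bland–Altman: bias = mean difference, SD with n−1 denominator, limits at
  bias ± 1.96·SD. The multiplier is fixed at 1.96 (not 2, not t-based),
  which reproduces published-style limits from a printed bias/SD to within
  rounding (±0.02 when bias/SD are printed to two decimals).
- CV = 100·SD/mean (n−1 denominator), undefined at zero mean.
- AUC by the Mann–Whitney pairwise formulation via midranks, ties counted
  ½ (equal to exhaustive pair counting, tested on all instances with
  n_pos·n_neg ≤ 1e4); 95% CI by DeLong's structural-components method
  (variance from placement values, ddof = 1), verified to 1e−9 against R's
  pROC `ci.auc(method="delong")` on a frozen dataset. The positive class
  is the elevated-cholesterol group; direction is a flag.
- One-way ANOVA from the SSB/SSW decomposition with the F distribution
  (vs `scipy.stats.f_oneway`; the two-group case equals the squared pooled
  t). Under null cohorts the empirical type-I error at α = 0.05 is ≈4–5%
  over 1000 seeded simulations — the mild lognormal skew is absorbed by
  n ≈ 115 per group. Post-hoc pairwise testing is out of scope.

## Numerical and design notes

- Noise-robustness of the calibration midpoint is assessed on the mean of
  100 seeded replicates (within 5% of truth); a single six-point replicate
  at 1% noise has midpoint scatter of ~5% SD, so a per-replicate bound
  would mostly measure that scatter.
- Problem sizes used in the shipped checks — 10 replicates per
  repeatability level, 200 seeded cohorts for AUC summaries, 1000 for the
  ANOVA type-I rate — were chosen to put Monte-Carlo error well below the
  asserted margins.
- CSV writers format floats with `repr` (shortest exact decimal), so
  write→read round trips are bit-exact; readers validate monotone
  wavelengths, non-negative intensities and closed-set group labels, and
  name the offending line.
- Reports embed a SHA-256 of the canonical-JSON config plus the seed;
  identical config + seed yields byte-identical report JSON.

## Known limitations

Single-component retrieval only (no spectral unmixing, no
scattering/diffuse-reflectance model); wavelength calibration of real
spectrometer files is out of scope; the clinical-scale correlation and AUC
values depend on generator anchors (effect size 1.5×, σ_log 0.27, offset
72.78/SD 20.03) and are design points, not measurements of a physical
device.
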