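# Methods

This note documents the models, numerical choices and limitations of
`pmevalkit`. The package implements a laboratory evaluation-and-correction
workflow for low-cost optical PM2.5 monitors: synthetic chamber experiments,
reference-instrument processing, rollover screening, mixed-effects
correction modelling with three-criterion variable selection, and bin-wise
accuracy verification.

## Synthetic chamber generator

The generator produces the data structure the analysis assumes; it is
first-class, tested code, not a fixture.

**Concentration profiles.** Stable exposures hold plateaus of ≥ 15 min at
333/666/1000/2500/5000 µg/m³ joined by linear ramps (10% of the plateau
duration by default); plateaus are built sample-wise so within-plateau means
equal the requested levels exactly. Transient exposures are three
0 → 5000 → 0 µg/m³ excursions of 30 min each; the ramp shape is linear
(triangular) by default with an exponential alternative, since the true
shape of a chamber peak is not well constrained. Sampling cadence is 15 s,
the APS setting; other cadences are emulated by block-averaging.

**Sensor model.** All condition effects act on the log gain:

    log G = log(base_gain · material_gain)
          + temp_slope·(T−20) + rh_slope·(RH−50)
          + power_shift·1{battery} + pattern_shift·1{transient}
          + drift_slope·session_time + u,   u ~ N(0, device_sd²)

and a reading is `true · G` times mean-one **log-normal** noise with
coefficient of variation `noise_cv`. The log-normal law keeps readings
positive (the data are log-transformed downstream) at the cost of a small
positive Jensen bias in ratio statistics (see *Verification* below). The
per-unit effect `u` is keyed on the unit label and the root seed, so the
same physical unit carries the same deviation in every experiment — without
this the between-device random effect would be undetectable. The reference
instrument reads `true · (1+ε)` with ε i.i.d. mean-zero, relative SD 0.10
(the manufacturer-stated APS uncertainty), also log-normal. Gravimetric
values are the time-averaged true concentration with 3% relative noise.

**Rollover.** Above a true-concentration limit L the expected reading
declines linearly with slope equal to the pre-rollover slope (a symmetric
tent), clipped at zero; through the reference noise this produces the
half-circle monitor-vs-reference scatter of a saturating optical sensor.
The decline slope is configurable.

**Default effect sizes** are chosen to emulate a realistic device family:
material gains {1.0, 1.3, 0.7} (the dominant effect — different refractive
indices and densities at identical size distribution), pattern shift 0.08
(the second-largest effect), device SD 0.02, drift 0.0002/h, temperature
0.002/°C, humidity 0.0005/%RH, power 0.01, reading noise CV 0.05. These
magnitudes put the per-variable MAE fold improvements in the range observed
for commercial devices of this class (≈2–3-fold for material, ≈1.2 for
pattern, ≈1.01–1.05 for the minor variables).

**Designs.** `build_design` expands either a one-variable-at-a-time
screening design (each variable varied over its levels — materials ARD,
quartz, alumina; 15/20/25 °C; 25/50/75% RH; battery/wired;
transient/stable; sessions at 0/24/48 h — with all others at the defaults
battery, 20 °C, 50% RH, transient, plus shared default-arm repeats) or a
full factorial (default materials × temperatures × humidities, 27
experiments) used for verification. All randomness flows from one root seed
through named substreams per experiment, so inserting a design point does
not perturb the others.

**What the generator does not emulate:** aerosol physics (coagulation,
settling, hygroscopic growth), spatial chamber gradients beyond a location
tag, sensor response lag (readings track the chamber instantaneously — the
responsiveness check therefore measures the profile ramp, not device lag),
firmware quirks of specific devices, and non-multiplicative error (zero
offsets, quantization). Passing tests show the *statistical machinery*
recovers known structure under these idealized conditions; they do not
certify any physical device.

## Reference processing

Counts per aerodynamic-diameter bin are converted to mass with
`d_ve = d_aero·sqrt(χ·ρ₀/ρ)` (ρ₀ = 1 g/cm³) and per-particle mass
ρ·(π/6)·d_ve³; with diameters in µm, density in g/cm³ and sample volume in
cm³ the units collapse to µg/m³ directly. Whether the shape factor enters
through the diameter (default) or multiplies the mass after a χ=1
conversion is ambiguous in practice, so both are implemented behind
`shape_mode`; they differ by χ^1/2. Shape factor 1.5 and densities 2.6
(ARD, quartz) and 3.95 g/cm³ (alumina) are the package defaults. The
respirable convention is the cumulative log-normal form (median 4.25 µm,
GSD 1.5), evaluated as a normal survival function.

Calibration fits `aps = a + b·grav` by OLS on time-averaged pairs and
corrects real-time readings with the inverse mapping `(r−a)/b`, which makes
the corrected residual mean exactly zero on the fitting data. The
environmental-invariance check regresses varied-condition APS values on the
default-condition expectation; a slope near 1 with high R² indicates the
reference itself is insensitive to the evaluation variables.

## Screening

**Loess.** The smoother is a hand-written tricube local-polynomial
regression, default span 0.5 and **degree 2** (local quadratic, the base-R
default). Degree matters: local-linear fits systematically undershoot curve
maxima — the exact point where the rollover limit is read off — by 15–20%
under these noise conditions, while local quadratic keeps the apex within a
few percent. The implementation is cross-checked against R's `loess` in the
test suite.

**Detection and pooling.** A curve is flagged when the fitted value falls
more than 5% of its maximum after the maximum (the tolerance separates
rollover from smoothing wiggle; it is configurable). The per-experiment
limit is the apex of the fitted curve when flagged, otherwise the maximum
observed reading — in monitor-output units, because the true concentration
is unknown before correction. With ≥ 10% of experiments flagged, the cutoff
is the 10th percentile (type-7, linear interpolation) of all pooled
per-experiment limits; pooling is per unit by default. Note two systematic
conservatisms: the fitted curve estimates E[monitor | noisy reference],
whose apex sits below the true limit when the reference carries noise
(≈ 4% at 5% effective x-noise), and p10 pooling sits below the typical
limit by construction. Recovered cutoffs therefore average ≈ 0.91·(true
monitor-unit limit) under the default conditions.

**Truncation** removes readings above the cutoff. For a rolled-over sensor
the descending branch re-enters the retained range at high true
concentrations; this contamination is unavoidable when truncating by
monitor output (the only scale available pre-correction) and is why
saturating monitors verify terribly above their first bins.

**Transform selection** scores six candidates (identity, log10, sqrt,
Box-Cox, Yeo-Johnson, ordered-quantile) by a 10-fold cross-validated
Pearson χ²/df normality statistic (classes ⌈2n^0.4⌉, df = classes − 3) and
keeps the lowest, ties broken in candidate order. Cross-validation is
essential: the rank-based ordered-quantile map is perfectly normal
in-sample by construction and only out-of-fold scoring compares candidates
fairly. On log-normal concentration data log10 (or Box-Cox with λ ≈ 0, its
affine equivalent) wins; the pipeline default is log10. Non-positive values
under log/Box-Cox get an offset of half the smallest positive value,
recorded in the transform parameters.

## Correction modelling

The model predicts transformed reference from transformed monitor output.
Every evaluation-variable effect is coded **as a slope on the monitor
predictor**: fixed terms x·session_time, x·(T−20), x·(RH−50),
x·1{transient}, x·1{battery}; random slope deviations per unit and per
material with no random intercept. Units and materials are random because
the deployed population of devices and workplace aerosols is sampled rather
than enumerated. Estimation is maximum likelihood (never REML) so
likelihood-ratio tests and AIC comparisons across nested structures are
valid; with no random terms the fit collapses to OLS, which equals the
normal-equations solution to numerical precision.

Crossed random slopes are expressed as variance components within a single
enclosing group (the standard statsmodels idiom); AIC is computed uniformly
as −2ℓ + 2k with k = fixed coefficients + variance components + residual
scale, because the OLS and mixed-model conventions in the underlying
library count parameters differently. If the default BFGS optimizer stalls
near a variance boundary, derivative-free optimizers (Powell, CG,
Nelder–Mead) are tried before a random term is declared singular and
dropped (logged in `fit_log_`). Fixed terms whose code is constant in a
subset (e.g. session time in the material arm of a one-variable-at-a-time
design) are inestimable there and dropped with a log note.

**Variable testing** compares nested ML fits with and without the variable:
LRT p-value (χ², 1 df for a fixed slope; the 50:50 χ²₀/χ²₁ boundary mixture
for a random slope, i.e. half the 1-df tail), ΔAIC, and MAE evaluated on
the back-transformed µg/m³ scale. A variable passes only if p < 0.05, AIC
decreases and MAE shrinks. Variables are tested in priority order —
between-device, drift, material, then temperature, humidity, pattern,
power — and structural terms that pass are carried into the baseline of
later tests. The final model contains all passed terms and is fitted on the
pooled screening experiments.

**Prediction** is the naive back-transform (10^ŷ for log10), mirroring how
such corrections are reported; a median-type estimate that under lognormal
residuals carries a small (≈ +σ²ln10/2) mean bias. A smearing-type
correction was deliberately not applied by default. Unseen random-effect
levels get the population-level (zero-deviation) prediction and are
flagged.

Because the generator's material and condition effects are intercept shifts
on the log scale while the model codes them as slopes on x, the correction
is structurally partial: a slope term b·x approximates a constant shift
well in the middle of the x-range and less well at its edges. This is a
property of the slope-coded model family, and it is why corrected low-bin
uncertainties carry a few extra points of bias spread.

## Verification

Binning is on the reference-derived concentration, half-open [lower,
upper), default uppers 500/1000/1500/2000/3000/5000 µg/m³; pairs beyond the
last edge are excluded with a count. Within a bin, relative bias
B = mean(pred/ref − 1) and precision S = sqrt(max(SD(pred/ref)² − s_ref² −
s_extra², 0)) with s_ref = 0.10; s_extra (additional exposure-instability
variance) defaults to 0. The reported accuracy is U = (|B| + 1.96·S)·100%,
a symmetric band containing ≈95% of readings when B = 0 and errors are
normal; the formula is isolated in `relative_uncertainty` so an alternative
(e.g. an exact non-central coverage solve) can be swapped in, and a
Monte-Carlo coverage test validates whichever is active. Bins with fewer
than 30 pairs report "insufficient_data" (NA). Verification runs at the
instruments' native cadence: the quadrature removal of the *stated
per-reading* reference uncertainty is only consistent with unaveraged
pairs (averaging would shrink the realized reference noise below the
deconvolved constant and floor the precision term).

Two statistical fine points, both documented rather than corrected away:
the ratio of two mean-one log-normals has SD slightly above the normal
quadrature value (0.1432 vs 0.1414 at 10%/10%) and mean e^{σ_r²} ≈ 1.01, so
the generative value of U for a "good" monitor (gain 1 under all
conditions, noise CV 0.10) is ≈21.1%, not the normal-law 19.6%; and the
per-run bias estimate fluctuates with the finite training set, adding
E|bias-noise| ≈ 1–2 points. The end-to-end pipeline reproduces the
law-consistent value within the expected band.

The "average correction" comparator is the base regression (transformed
reference ~ transformed monitor only) fitted on the same screening data;
the fold for a bin is U_reduced/U_full, averaged over bins defined in both.

## Pipeline

`run_pipeline` executes simulate → screen → fit → verify per monitor from a
`RunConfig` (YAML-loadable, schema-validated with unknown fields rejected).
Instruments are aligned to a common 1-minute block-average grid before
screening and modelling; relative errors are undefined at zero
concentration, so verification pairs below 1 µg/m³ reference (the practical
detection floor) are excluded. All stage outputs are plain CSV/JSON,
content-hashed into `summary.json`; identical seeds give bit-identical
artifacts. Responsiveness is the time from the series minimum to 80% of its
maximum, judged against a 60 s target; in the synthetic setting it reflects
the exposure ramp because sensor lag is not modelled.

Problem sizes used by the test suite and the acceptance script — e.g. 50
seeds × 10 experiments for cutoff recovery, 500/200 replicates for the
selection operating characteristics, 100 seeds at n = 2000 for parameter
recovery, and 27-experiment factorials per pipeline run — were chosen so
every Monte-Carlo tolerance is comfortably resolved while a full run stays
in the minutes range on a single CPU.

## Known limitations

- Rollover contamination below the cutoff is inherent to output-unit
  truncation; no attempt is made to "unfold" the descending branch.
- Slope-coded condition effects correct log-scale intercept shifts only
  approximately (see above).
- The LRT for a random slope uses the 50:50 boundary mixture, an asymptotic
  approximation; a parametric-bootstrap cross-check is included in the
  tests for small instances.
- The naive back-transform is median-type, slightly conservative on the
  mean scale.
- Long-term drift, field/workplace re-evaluation, instrument-specific
  firmware corrections and machine-learning correction variants are out of
  scope.
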