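# Methods

## Single-rod optics

Scattering is evaluated at the fixed 90° geometry of the instrument.  The
rod form factor `E²(z) = Si(2z)/z − (sin z/z)²` uses the library sine
integral (`scipy.special.sici`); below z = 10⁻³ the series
`E² = 1 − z²/9 + O(z⁴)` avoids the 0/0 and makes `E²(0) = 1` exact.  The
radius factor `F(r)` of the full shape factor `P(90°) = F(r)²E(l)²` is
taken as 1: for intermediate filaments (r < 10 nm ≪ λ/10) it is
indistinguishable from unity, and a warning — not a correction — is
issued if a geometry violates the thin-rod condition.  Wavelengths are
used as their nominal vacuum values (405/594 nm) with no refractive-index
correction; that convention reproduces the quoted asymptote
λ₅₉₄/λ₄₀₅ = 1.4667 ("1.46") and is therefore what the published analysis
used.  ULF counts map to contour length by `l = 60 + 43(n−1)` nm
(annealing partners overlap, so each ULF past the first adds 43 nm).

The 594/405 single-length ratio rises monotonically with length through
the 7-ULF length (318 nm) and attains its first local maximum at
l ≈ 348 nm, i.e. at 7.7 ULF equivalents, between the 7- and 8-ULF
lengths.  Because filaments contain whole ULFs, `ratio_peak` reports
alongside the continuous location the number of *complete* ULFs at the
peak (7): the monotone, length-sensitive regime of the assay extends
through 7 annealed ULFs.

## Length distributions and the σ convention

Filament lengths are modelled as log-normal; the width is tied to the
geometric mean by the empirical law σ = 0.053·l_fil + 0.115.  Throughout
the package **σ is the standard deviation of log₁₀(length)** (lengths in
ULF units; the geometric mean is base-independent).  The alternatives are
untenable: a multiplicative geometric SD is ≥ 1, inconsistent with values
of 0.115–0.4, and reading σ as the SD of the natural log makes the rate
calibration come out near 3.4 instead of the published 2.32 ULFs.  Under
the log₁₀ reading the calibration reproduces 2.32 directly (see below),
which identifies it as the convention of the source data.  `fit_lognormal`
accepts a `base` argument for interoperability.

Sub-ULF lengths arising in distribution tails are mapped to nanometres by
the same affine relation extended below n = 1; they carry negligible
weight in any ensemble average but keep integrands defined.

## Ensemble averaging: two deliberate conventions

Two population-level 594/405 ratios exist side by side:

* **`average="intensity"`** — the physical detector ratio.  A filament of
  length l scatters ∝ (mass)²·P with mass ∝ l; at fixed total protein
  mass the filament number density scales as 1/⟨l⟩, so the per-channel
  ensemble intensity is I ∝ ⟨l²P(λ)⟩/⟨l⟩ (this saturates for long
  filaments, which is why late-time intensities plateau) and the measured
  ratio is ⟨l²P₅₉₄⟩/⟨l²P₄₀₅⟩.  The synthetic generator and the
  cross-condition intensity comparisons use this convention.
* **`average="filament"`** — the expectation over filaments of the
  per-filament ratio, ⟨P₅₉₄/P₄₀₅⟩: the single-length curve blurred by the
  length distribution.  Calibrating the exponential time constant on
  these curves (growth from 1 ULF, σ from the law above, curves evaluated
  on a log-spaced 1–600 s grid — the span of a recording — and regressed
  through the origin over rates 0.5–5 ULFs/min) yields a factor of
  2.31–2.35 depending on sampling, reproducing the published
  r_la = 2.32/τ rule; this identifies the convention behind that rule,
  so it is the calibration default.

Expectations are computed by 64-node Gauss–Hermite quadrature in
log-length, cross-checked against Monte Carlo (they agree to ≪ 1%; a
dedicated test enforces < 1%).  Intensity-weighted quadrature refuses
σ > 3, beyond which the l² weight probes the log-normal tail past the
node range; the bounded per-filament integrand needs no cap.  Monte Carlo
curves reuse one set of standard-normal draws across time points (common
random numbers), so they are smooth and inherit the exact time-rescaling
property of linear growth: curve(k·rate, t/k) = curve(rate, t).

## The trace pipeline and its calibration offset

Stages are state-checked and run in a fixed order: affine calibration
against water baseline and buffer reference, per-channel normalization
over [dead time, 50 ms] (when scatterers are still optically point-like,
making the analysis exactly invariant to per-channel gain), pointwise
ratio with masking of non-positive denominators (flagged above 1%), and a
least-squares fit of r(t) = 1 + A(1 − e^(−t/τ)) on log-spaced time bins
(default 12 per decade, arithmetic bin-mean abscissa) starting at 1 s —
equal weight per decade keeps the 600 s tail from dominating a rise that
happens over seconds, and earlier samples are ratio ≈ 1 lateral-phase
transients.  The asymptote is fixed at 1; A is free (plausible range
0.3–0.5; A > 0.5 raises the "too short" flag).  A initializes at 0.46, τ
at the half-rise time.  Artifact screening compares each channel's
residual about a centred rolling median with 8 × robust SD
(1.4826 × MAD) and flags runs of ≥ 5 exceedances from 0.5 s on (the
deterministic mixing-phase rise would otherwise trip the detector);
flagged traces are excluded, never repaired.

Two conventions meet in reciprocal-rule rate estimation and do not quite
agree.  The published 2.32 factor derives from *unnormalized*
filament-averaged curves, whereas the pipeline fits *normalized*
intensity-ratio data; fitting such curves yields rate·τ ≈ 2.6, so rates
computed with 2.32 run ~10% low (still inside the pipeline's ±15%
recovery contract).  `calibrate_for_pipeline()` recalibrates under the
pipeline's own conventions (factor ≈ 2.62) and removes the offset; the
default remains the published 2.32 so that results are comparable with
the literature.  Separately, at 0.5 ULFs/min a 600 s recording covers too
little of the rise for A and τ to separate: estimates bias low by ~30%
and the A > 0.5 flag fires — the correct reading is "measurement too
short", which is exactly how the experimental protocol treats such fits.

## Synthetic stopped-flow data

The generator multiplies three terms per channel — a saturating
double-exponential lateral ramp (time constants 30 ms and 2 s, weights
0.7/0.3, reproducing a knee near 100 ms), a mass-per-cross-section factor,
and the normalized ensemble shape term ⟨l²P⟩/⟨l⟩ for the growing
population (evaluated on a 400-point log-time grid and interpolated; the
term is smooth, and the interpolation error is far below the noise) —
then applies a first-order 1 ms low-pass, 1 kHz sampling, 3 ms dead-time
blanking, additive white Gaussian noise (default SD 0.01 of the lateral
plateau, matching the visual SNR of published recordings), and optional
bubble transients (Gaussian bumps in both channels).  All randomness
flows from one seed through named substreams, so noise, bubbles and
length sampling are independently reproducible; with noise off the
output is seed-independent.

Condition folds are encoded so that each comparison window isolates its
parameter: `lateral_factor` multiplies the early signal and relaxes away
over the slow lateral timescale (a condition with faster lateral kinetics
shows proportionally more signal while ULF formation is underway — the
quantity the 20–40 ms window reads); the mass-per-cross-section fold
builds in over ~2 s (so it does not contaminate the early window) and
carries a log-normal compaction pulse peaking at 30 s with 30% default
excess, mirroring the transient diameter excess seen by electron
microscopy.  The lateral ramp and pulse shapes are conventions of the
generator — no functional forms for them are established — so passing
recovery tests demonstrates the *analysis* is consistent, not that real
traces follow these forms.  Real data also differ in noise structure
(photon counting, drift) and may bundle or fragment filaments; none of
that is modelled.

## Cross-condition windows

Condition ratios are ratios of replicate-mean intensities (ratio of
means — means of ratios would be unstable where the denominator is small
and noisy), with bootstrap-over-replicates standard errors (seeded,
default 1000 resamples).  Windows: early 20–40 ms (after the 3 ms dead
time); plateau 500–600 s; the 40 s peak window is centred on the maximum
of the 5 s moving-average-smoothed ratio series, searched between 1 s and
the plateau.  The elongation-only prediction divides the ensemble
intensities of two growth models at one wavelength; with a 3-vs-1
ULFs/min contrast at 405 nm it peaks near 1.15–1.2 at ~30–40 s and
relaxes toward 1, and the measured-over-predicted quotient converts
window averages into mass-per-cross-section folds.  For the plateau the
predicted ratio is ≈ 1 (both conditions past 405 nm shape saturation);
when the rate contrast is large and the slower condition is still a few
percent short of saturation, supplying the computed plateau prediction
instead of 1 removes that residual (the recovery tests do this).

## Morphometry

Log-normal fits use the maximum-likelihood estimators: geometric mean =
exp of the mean log, σ = population (1/n) SD of logs.  Growth rate is an
unweighted OLS line through per-time geometric means versus time in
minutes; the σ–length law is an unweighted OLS of per-time (l_fil, σ)
pairs — no error bars feed either fit.  Diameter summaries report
per-time mean, population SD and n, plus the peak-time mean and its
percent excess over the final time point (the compaction signature).
Lengths supplied in nm are converted to ULF units before fitting so the
σ-law coefficients keep their published units.

## Problem sizes

Default analyses run in seconds: calibration uses 20 000 filaments per
curve and 150 time points per rate; simulated traces are 600 s at 1 kHz;
the replicated-recovery test suite uses 50 traces per rate at 50 Hz and
three replicates per salt condition at 1 kHz, sizes at which the Monte
Carlo error is far below the tolerances being tested.

## Known limitations

* The rate calibration assumes the σ–length law measured for one
  condition holds for all; the law's slope may vary with salt and protein
  concentration, and `GrowthModel` exposes both coefficients.
* Rates ≲ 0.5 ULFs/min are not reliably measurable from a 600 s
  recording (flagged, see above); rates ≳ 5 ULFs/min exhaust the
  length-sensitive regime (~7 ULFs) within seconds of the lateral phase.
* Flexible-chain (worm-like) corrections, Mie scattering, arbitrary
  scattering angles, polarization, and absolute photometric calibration
  are out of scope; intensities are meaningful only as ratios.
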