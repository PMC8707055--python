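# Methods

This note documents the models implemented in `organoidphasor`, the
defaults and why they were chosen, what the synthetic phantom generator
does and does not emulate, and the numerical conventions that matter for
reproducing results.

## Decay model and phasor transform

Fluorescence decays are modeled as periodic (pulse-train-wrapped)
mono-exponentials. For lifetime τ and repetition period T, the emission
within one period is proportional to `exp(-t/τ) / (1 - exp(-T/τ))`, and
the simulator integrates this analytically over each of the `n_bins` time
bins — no instrument response function is convolved in. IRF effects are
represented solely by the distortion injectable into the reference decay
(below), which is exactly what reference-compound calibration removes; a
measured IRF would be redundant with that scheme.

The phasor transform uses **bin centers** `t_k = (k + ½)·Δ` as timestamps.
This choice is load-bearing: with center timestamps the leading
discretization error of the discrete Fourier sums cancels, and the phase
lifetime recovered from a noiseless simulated decay agrees with the
nominal lifetime to ≲ 5·10⁻⁴ ns at 256 bins for lifetimes in the 0.4–3.4 ns
range (edge timestamps would bias it by half a bin width, ~0.02 ns).
Zero-intensity pixels carry NaN phasor coordinates and are excluded from
every statistic; mapping them to (0, 0) would disguise them as
infinite-lifetime pixels.

Defaults, with units:

| parameter | default | meaning |
|---|---|---|
| `rep_period` | 12.5 ns | laser repetition period (80 MHz pulse train); ω = 2π/T |
| `n_bins` | 256 | time bins per period |
| `tau_free` | 0.4 ns | free-NADH lifetime (trajectory endpoint) |
| `tau_bound` | 3.4 ns | LDH-bound-NADH lifetime (trajectory endpoint) |
| `tau_ref` | 2.5 ns | coumarin 6 reference lifetime for calibration |
| `photons_per_pixel` | 10⁴ | expected photon budget per foreground pixel |
| `harmonic` | 1 | only the first harmonic is analyzed; higher harmonics are plumbed through but unused |

The photon budget is chosen for adequate phasor signal-to-noise at a
single pixel (relative phasor noise ~ 1/√N), not to mimic any particular
detector; real acquisitions vary widely.

## Calibration

The calibration statistic is the **intensity-weighted mean phasor** of the
reference field, which is robust to per-pixel shot noise; per-pixel
correction would add noise without benefit for a uniform reference. The
derived correction is the rotation and scaling that move that mean onto
the universal-circle point of the known reference lifetime, applied
identically to every sample pixel. Double application is an error, and
fields carry a `calibrated` flag to enforce the order of operations.

The reference generator can inject a known instrument distortion for
round-trip testing. The phase component is realized as a circular shift by
the **nearest whole number of time bins**, because an integer roll rotates
the discrete first harmonic exactly (a fractional, Fourier-interpolated
shift rings at the wrap discontinuity of the decay and can drive bins
negative). The offset actually applied — the request rounded to the bin
phase granularity 2π/`n_bins` — is recorded in the cube metadata, and
tests assert recovery of the *applied* values. The modulation component
scales the histogram's AC part about its mean, which multiplies the phasor
modulus exactly and preserves positivity for scales ≤ 1.

## Metabolic trajectory projection

Pixels are projected **orthogonally** onto the chord between the free and
bound NADH circle points. Projections that land outside the segment
(possible under noise) are clamped to the nearest endpoint and counted in
`clamped_mask`, because F1 is a fraction by definition; clamping is never
silent. F1 and F2 are intensity-weighted fractional contributions — the
native phasor quantity — with no quantum-yield correction, so the
generator programs free fractions as *intensity* fractions and recovery is
exact in expectation.

Two ratio routes coexist deliberately. Per-pixel F1 maps feed images and
per-region medians; the scalar f/b ratio reported in summaries is computed
from the region's intensity-weighted phasor **center of mass** projected
onto the axis. The two agree only when all pixels are collinear along the
chord; the center-of-mass route is the one summaries use, and tests pin
that choice.

Spatial noise reduction is a median filter applied to the g and s planes
independently (window 3 by default), never to the photon histograms;
missing pixels are excluded from each window and stay missing.

## Outer-rim analysis and longitudinal summaries

Only the outer surface of an organoid is analyzed for the metabolic
readout (interior signal in thick samples is unreliable, and the
photoreceptor layer of interest is the outermost). The rim mask is: Otsu
threshold, keep the largest connected component, subtract its erosion by
`rim_width` (default 10 px at 1.66 µm/px ≈ 17 µm).

Age-series summaries bin records into configurable (min, max) day windows
— monthly bins from day 30 to 180 by default, since group boundaries are
study design, not something the pipeline infers. Each bin reports n,
linear-interpolation quartiles, and a whisker half-width of 1.5 × the
population standard deviation (ddof = 0; the SD convention matters only
for tiny groups and is stated here for that reason).

## Spectral phasor

The Fourier phase runs over the **channel index** 0…C−1, not wavelength —
the standard convention for a fixed 32-channel detector; channel center
wavelengths are display metadata. Harmonic 1 maps the full 410–690 nm
range onto one period. Pixels dimmer than 1% of the 99th-percentile
intensity are excluded from the phasor plane so background cannot smear
the fingerprint clusters. Cursors are circles (center, radius) supplied by
configuration; `endmember_phasor` seeds a cursor from a pure spectrum's
fingerprint. No least-squares unmixing or clustering is performed — cursor
selection is the method.

Default endmember spectra are Gaussians on the channel grid (bound NADH
445 nm, free NADH 465 nm, retinol 490 nm, FAD 530 nm). Only linearity and
phasor-plane separability matter to the analysis; the shapes are not
fitted to measured spectra, and users analyzing real data should supply
their own cursor coordinates.

## ΔΔCt

Replicate Ct values are averaged per (group, gene) **before** the ΔCt
subtraction (the conventional order; the alternative — subtracting per
replicate then averaging — differs only when replicate counts are
unbalanced across genes). Amplification efficiency is fixed at 2 (perfect
doubling); no efficiency correction is applied. Non-detected wells are
assigned Ct = 40, the protocol's cycle count, before analysis; the
imputation count is carried through to the output provenance. The reported
matrix is log₂(fold expression) = −ΔΔCt, so the control column is
identically zero by construction.

## What the phantom generator does and does not emulate

It emulates: a laminated ring-shaped cross-section with a glycolytic outer
rim (high free-NADH fraction) and a more oxidative interior; two-component
exponential decays with Poisson photon noise; per-layer emission spectra
with a retinol-like component concentrated in the rim; and qPCR plates
with group-level shifts, replicate noise, programmed log₂ effects, and
non-detected wells.

It does **not** emulate: optical blur or scattering, depth attenuation,
photobleaching, autofluorescence species beyond the four endmembers,
intra-layer biological heterogeneity, or intensity variation within a
layer. Consequently, passing tests demonstrate that the *analysis* is
correct and self-consistent — that programmed parameters are recovered
through the full pipeline — not that real organoids will behave like the
phantoms. Trend-level results (e.g. the decreasing-then-plateau f/b
trajectory test) assert only that the pipeline faithfully summarizes a
programmed trajectory.

## Numerical conventions and degenerate inputs

- Image origin top-left; arrays indexed (y, x), 0-based; stated in all
  JSON sidecars.
- Circle-membership and lifetime-roundtrip tolerances: calibrated
  noiseless mono-exponentials lie on the universal circle within 1e-3 for
  ≥ 256 bins; the closed-form inversion round-trip is exact to 1e-9.
- `fb_ratio(1.0)` is reported as NaN (undefined), never infinity;
  `tau_phase` with g ≤ 0 and `tau_mod` with |phasor| > 1 likewise.
- An all-zero decay cube produces an all-missing phasor field with a
  warning, not an exception, so batch runs survive empty frames.
- Abundance-sum and similar invariants use a 1e-6 tolerance so that
  float32 TIFF round-trips of exact values do not trip them.
- All generators are deterministic: identical parameters + seed give
  bit-identical arrays (`numpy.random.default_rng(seed)` throughout).

## Problem sizes

Tests and the acceptance script run on reduced geometries chosen to keep
the statistical properties intact: 48–128 px frames with proportionally
scaled organoid radii, 64–256 time bins, 8×8 to 4×4 uniform reference
fields, and 10–12-seed replications for noise-statistics checks. The
defaults in `RunConfig` (256 × 256 at 1.66 µm/px, 256 bins, 32 channels)
reflect a realistic acquisition and are used when the package is run as a
tool.

## Known limitations

- Single-harmonic analysis only; two-component mixtures are resolvable,
  three or more are not identifiable from one harmonic.
- The calibration assumes a spatially uniform instrument distortion; no
  per-pixel IRF variation is modeled or corrected.
- Cursor segmentation is geometric; overlapping fingerprints (e.g.
  retinol vs retinoic acid) are separable only as far as their phasor
  positions differ by more than the cursor radius.
- Raw vendor formats (.lsm/.czi, FLIMbox streams) are out of scope; inputs
  are plain multi-page TIFF with JSON sidecars.
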