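# Methods

This document describes the models, parameters, and numerical choices
used by the `midzone` package.

## 1. Axial intensity profile models

All profiles are 1-D intensity traces along the pole-to-pole axis, with
x = 0 at the spindle centre and lengths in µm. For a Gaussian,
FWHM = 2·√(2·ln 2)·σ ≈ 2.35482·σ (`midzone.profiles.FWHM_FACTOR`).

**Metaphase (single Gaussian).** I(x) = A·G(x; m, σ) + b. The spindle
length is reported as the FWHM.

**Anaphase (constrained three-Gaussian).** A central peak at position m
with amplitude A_c and width σ_c plus two side peaks constrained to be
symmetric: equal amplitudes A_s, equal widths σ_s, centres at m ± d.
Six free parameters: (A_c, m, σ_c, A_s, d, σ_s), plus a baseline. Two
derived lengths:

- overlap length L = 2√(2 ln 2)·σ_c (central-peak FWHM);
- total width W = 2d + 2√(2 ln 2)·σ_s (side-peak separation plus one
  side-peak FWHM).

`AnaphaseProfileModel.from_widths(L, W, …)` inverts these relations to
construct a model from the two published lengths. The fit
(`fit_anaphase_profile`) uses bounded nonlinear least squares
(`scipy.optimize.least_squares`) from six deterministic multi-starts;
a fit is flagged `degenerate` when the side peaks collapse onto the
centre and `reliable` only when the geometry is physically sensible
(d > 0, W ≥ L, peaks inside the window). On symmetric noiseless data
the constrained fit agrees with a free 9-parameter three-Gaussian fit
(oracle-checked in the tests).

**DNA (two Gaussians).** Two equal-width Gaussians at m ± s/2 model the
separating chromosome masses; the separation is 2·(s/2) = s. A frame is
`resolved` only when (a) the separation exceeds the component width
(s ≥ σ), (b) both component centres lie inside the data window, and
(c) the two-Gaussian fit beats a single-Gaussian fit in residual sum of
squares. Without (b) and (c), converged-but-degenerate fits on
unseparated metaphase DNA masquerade as resolved pairs and corrupt
onset detection.

## 2. Kymographs and cross-cell averaging

Each movie frame is rotated/translated (bilinear interpolation,
`skimage.transform.warp`) so the centrosome axis is horizontal and
centred; out-of-image samples are masked, not zero-filled. A band of
configurable width (default 8 µm for spindle channels, 0.3 µm for comet
work) centred on the axis is averaged column-wise to one kymograph row.
A row at distance |row − centre| ≤ half-width (+1 px tolerance ×1e−9)
belongs to the band; bands extending past the image edge are clipped
with a warning.

**Anaphase onset** is detected from the DNA kymograph: the per-frame
two-Gaussian separation series, restricted to resolved frames, is
thresholded at 20% of the metaphase pole distance with a 3-frame
sustain requirement, then refined by back-extrapolating a line through
the early resolved separations to its zero crossing. On synthetic
movies the detected onset equals the generator's configured onset
frame.

**Averaging** (used for the 17-cell ensemble): each cell's kymograph is
rescaled along x by (mean metaphase pole distance / its own) via linear
interpolation onto a common grid, rows are shifted so anaphase onset is
time zero, and per-bin mean, n, and SEM are accumulated. Averaging is
permutation-invariant.

**Bleaching correction** fits C·e^(−kt) to background-subtracted row
sums and divides it out; the background per frame is the median of the
outer 10% of columns.

## 3. FRAP kinetics

Curves are normalized by the mean of the last four pre-bleach points.
With a reference region available, bleaching is corrected by dividing
by the reference series (itself normalized to its pre-bleach mean)
before renormalizing. Normalized curves for one stage are averaged
pointwise (interpolating onto the first curve's time grid), then fitted
with

I(t) = I₀ + Iₐ·(1 − e^(−t/τ)),

where t = 0 at the bleach frame and the bleach frame itself is excluded.
Bounds: τ ∈ [Δt, 10·window], I₀ ∈ [0, 1], Iₐ ∈ [0, 1.5]. The mobile
fraction is mf = Iₐ/(1 − I₀). When τ exceeds half the observation
window the fit is flagged `window_limited`: the plateau is extrapolated
rather than observed, and τ is correspondingly less certain. The
least-squares fit agrees with a dense τ-grid search plus linear
least-squares to ≤1e−3 (oracle-checked).

Sampling matters for fast kinetics: τ ≈ 1.3 s (CLASP1) is not
identifiable from 2 s sampling — the first post-bleach point is already
~78% recovered — so sub-second sampling (0.5 s) is used for CLASP1.

## 4. Comet statistics

Tracks shorter than 3 consecutive frames are discarded. Speed is total
path length divided by elapsed time. A comet is *internal* when the
majority of its samples lie between the pole positions, *external*
otherwise. Per-stage summaries report median, mean, SEM, MAD, and
quartiles. The survival curve is the exact empirical survivor function
S(t) = fraction of tracks with duration ≥ t (identically 1 − ECDF at
t⁻), reported in both seconds and frames. The position histogram bins
each track's mean axial position on the normalized [0, 1] pole-to-pole
axis (20 bins by default), so counts sum to the number of tracks.

## 5. Synthetic generator

`SpindleSimConfig` defaults (chosen to match the published geometry and
kinetics):

| parameter | default |
|---|---|
| duration / frame interval | 15 min / 30 s |
| pixel size, frame shape | 0.2 µm, 48 × 160 px |
| pole distance | 8 µm metaphase → 20 µm plateau over 5 min |
| anaphase onset | 3 min |
| overlap FWHM | 6 µm → 1.7 µm, exponential τ = 2 min |
| metaphase protein FWHM | 8 µm |
| midzone mass fraction | 0.5 → 0.85, τ = 3 min |
| side-peak σ | 0.9 µm |
| background, bleach rate | 0.05, 1e−4 s⁻¹ |
| noise | Gaussian SD 0.02 (Poisson optional) |

Realism choices: total profile intensity is conserved as the overlap
compacts (so the central peak brightens as it narrows, producing the
rising I_max); poles jitter across ensemble cells (±10% length scale,
±1 frame onset); photobleaching decays all channels exponentially;
noise is additive Gaussian by default with an optional Poisson shot
model. Frame-by-frame ground truth (pole positions, overlap FWHM,
total width, model parameters) is exported alongside every movie.

FRAP stage kinetics used as simulation truth: PRC1 τ = 6/11/11/44/124 s
with mf 0.55/0.48/0.41/0.34/0.27 across
metaphase/early/mid/late-anaphase/telophase; KIF4A 5.9 s (mf 0.95) late
anaphase and 30 s (mf 0.71) telophase; CLASP1 1.3 s (0.79) early
anaphase and 2.9 s (0.64) telophase. Comet stage speeds:
0.30/0.28/0.25/0.20/0.18 µm/s.

All randomness derives from a single integer seed via
`numpy.random.SeedSequence`; child seeds are kept below 2³¹. Identical
config + seed gives bit-identical output.

## 6. Numerical choices

- Nonlinear fits use `scipy.optimize.least_squares` with analytic-free
  numerical Jacobians, bounded parameters, and deterministic
  multi-starts; parameter SEs come from the Jacobian at the optimum.
- Image alignment uses bilinear interpolation with an explicit validity
  mask (threshold 0.999 after warping) so out-of-field pixels never
  dilute band averages.
- Cross-cell averaging uses single-pass mean/variance accumulation.
- CSV storage: decimal point, UTF-8, mandatory header; lengths in µm,
  times in s (minutes only at the presentation layer). Result JSON
  includes provenance (software name/version, config hash, seed) and is
  byte-identical for identical inputs.

## 7. Limitations

- The generator renders straight, symmetric spindles; bent or tilted
  midzones and asymmetric overlaps are out of scope.
- The FRAP model is a single-exponential; two-component recoveries will
  be summarized by an effective τ.
- τ values beyond half the observation window (e.g. 124 s in a 180 s
  window) are window-limited: reported, flagged, and only accurate to
  ~20%.
- Onset detection requires a DNA channel with resolvable separating
  masses; it returns "not detected" rather than guessing otherwise.
- Comet simulation uses constant per-track speed with Gaussian
  positional noise; pausing and catastrophe dynamics are not modeled.
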