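# Methods

This note records the models, parameter choices and numerical decisions
behind `ccvtrack`, and what the synthetic validation does and does not
establish about real microscopy data.

## Scope and data model

The package analyses 2-D grayscale image data in two regimes: time-lapse
movies of diffraction-limited moving spots (clathrin-coated vesicles,
CCVs), and fixed two-channel scenes for colocalization and radial
quantification. Internally time is measured in frames and space in pixels;
physical units enter only through the calibration pair
(`pixel_size_um`, `frame_interval_s`, default 1 s per frame, matching
1-frame-per-second live-cell acquisition). Coordinates are 0-based
pixel-center, x = column, y = row, and every CSV written by the package
uses that convention.

## Synthetic-data generator

The simulator provides the ground truth that all recovery tests are scored
against.

* **Motion.** Particles are stationary, Brownian, or directed. Brownian
  steps are isotropic Gaussian with per-axis variance 2D per frame, so the
  2-D ensemble MSD is 4Dτ; directed motion adds a constant drift
  (v·cos θ, v·sin θ) per frame, giving MSD = 4Dτ + (vτ)². Disappearance
  (`p_off`) is permanent; blinking (`p_blink`) opens gaps whose lengths
  are geometric with parameter 1 − p_blink, so small rates give mostly
  single-frame gaps — long enough tails to exercise the 5-frame
  gap-closing rule.
* **Optics.** Spots render as isotropic 2-D Gaussians evaluated at pixel
  centers (no sub-pixel area integration; adequate for σ ≥ 1 px and
  identical to the detector's fit model, so recovery tests measure
  estimation error, not model mismatch). Optional Poisson noise is applied
  to expected counts, then additive Gaussian read noise. Default scene:
  σ_PSF = 2 px, amplitude 100 a.u. on background 10 a.u., read noise
  5 a.u. — amplitude ≈ 17× the background noise, a bright-spot regime
  comparable to GFP-clathrin imaging.
* **Scenes.** Colocalization pairs share `round(f·n)` spot positions, the
  rest placed ≥ 4σ apart so "disjoint" truly means product-zero.
  Cell scenes are filled disks with vesicles placed either area-uniformly
  (mean radius 2R/3) or on a fixed ring; the truth records exact
  per-vesicle distances and flags border-touching cells.
* **Determinism.** One `numpy` Generator seeded per call: identical seeds
  give bit-identical truth and pixels.

What the generator does **not** emulate: photobleaching, motion blur
within the exposure, EM-gain statistics, anisotropic PSFs, cell-shaped
(non-disk) masks, or spatially varying background. Passing the recovery
tests therefore demonstrates correctness of the estimators under the
stated noise model, not performance on arbitrary real data.

## Spot detection

Candidates are local maxima of a Gaussian-smoothed copy of the frame
(smoothing σ = 2 px) whose smoothed value exceeds the frame background
plus the intensity threshold; the background is the frame median, which is
robust while spots are sparse. Smoothing attenuates a spot of width σ by
σ²/(σ²+σ_s²) (half, at the defaults) but suppresses shot-noise maxima
~7-fold, which keeps the number of fitted candidates proportional to the
number of real spots; a `candidate_gate="raw"` variant gates on the raw
pixel value instead. Each candidate window (half-width ⌈3σ_s⌉ = 6 px) is
fitted with an isotropic Gaussian (amplitude, x, y, σ, offset) by weighted
least squares with weights 1/max(counts, 1) — the inverse expected
variance under Poisson statistics, floored to keep dark pixels finite —
using an analytic Jacobian. Accepted fits must satisfy
σ ∈ [σ_min, σ_max] = [1, 15] px and amplitude ≥ threshold (default
5 a.u.); both the candidate pre-filter and the fitted-amplitude gate are
applied, since a bare "5 a.u. above background" rule does not say which
value it refers to. Non-converging fits are tallied in a diagnostics dict, never raised.
Fits closer than 1 px are duplicates; the lower-residual one is kept.
Measured on the default benchmark scene (100 frames × 20 spots,
256² px): recall and precision ≈ 1.00, localization RMSE ≈ 0.16 px.

## Linking

Frame-by-frame greedy nearest-neighbour assignment: all (active track,
detection) pairs within the 3-px radius are sorted by distance (ties:
lower track id, then lower detection row) and claimed greedily — a
faithful reading of "nearest-neighbour linking"; Hungarian assignment is
available behind `assignment="optimal"` for sensitivity analysis.
Unmatched tracks stay eligible until more than `max_gap` = 5 consecutive
frames are missing, so a 5-frame hole is bridged and a 6-frame hole is
not. The search radius stays fixed during gap closing (a √gap scaling is
available, off by default). The minimum-length cut (5) counts *observed*
frames, not span. Gap-bridged frames receive no interpolated positions.

## Motion statistics

* **MSD** averages squared displacements over *all* observed frame pairs
  at each lag, recording the pair count; on a contiguous track this is
  exactly the (1/(N−τ))Σ estimator, and lags with no pairs (gaps) are
  omitted rather than imputed. The implementation is verified against an
  independent brute-force double loop at 1e-12 relative error.
* **Apparent D** is slope/4 of an unweighted straight-line fit through
  lags 1–4 with a free intercept: the intercept absorbs the static
  localization-error offset that would otherwise bias short-track slopes.
  A through-origin variant (`fit_diffusion_origin`) exists because the
  relation MSD = 4Dτ is literally origin-constrained. D may be negative
  for noisy short tracks and is reported as-is.
* **Turning angles** use α = |atan2(det(v₁,v₂), v₁·v₂)| ∈ [0°, 180°] —
  the two-argument arctangent, since the single-argument arctangent of
  det/dot cannot distinguish persistence (0°) from reversal (180°).
  Triples must be consecutive observed frames; zero-length displacements
  skip the triple.
* **Asymmetry coefficient** (default) is the frequency ratio
  frac(α ≥ 150°)/frac(α ≤ 30°), pooled over all displacements of a field
  (per-cell aggregation). With this orientation Brownian motion — whose
  turning angle is uniform on [0°, 180°] — gives AC = 1 and directed
  motion drives AC → 0, satisfying "the lower the AC, the more
  directionality". An alternative definition seen in the field
  (frac(α ≥ 15°)/frac(α ≤ 30°), overlapping bins) is implemented as
  `method="overlapping"` but is not the default, as the 150°/30° bins are the
  form whose limiting behaviour is testable. A zero denominator yields
  NaN with a diagnostic, never infinity.

A known effect worth noting: on tracks reconstructed from noisy images,
static localization error anti-correlates consecutive displacements and
inflates the reversal bin, so a purely Brownian field measured through
the full pipeline shows AC slightly above 1 (≈ 1.3–1.6 at the default
SNR). Condition *ordering* (drifted < non-drifted) is unaffected, which
is how the statistic is used.

## Colocalization and intensity readouts

Rolling-ball background subtraction uses the Sternberg ball (scikit-image
`rolling_ball`) with no pre-smoothing and output clipped at zero; a radius
exceeding the image degenerates to subtracting the minimum. The Manders
overlap coefficient is computed over mask pixels where *either* channel
exceeds its threshold — the union keeps the disjoint-channel case well
defined (MOC = 0) and matches the behaviour of the ImageJ tool the
coefficient is usually quoted from; with an intersection rule the
disjoint case would be an empty set. Thresholds default to (0, 0);
`auto_threshold=True` runs the Costes procedure (largest threshold pair,
taken along the green-on-red regression line, for which the
below-threshold pixels are uncorrelated), falling back to channel minima
for degenerate perfectly correlated inputs. Z-stacks are averaged
per-slice by default (pooled-voxel mode available). The live-cell dye
readout is the mean intensity over the Otsu-thresholded (or fixed-
threshold) cell area.

## Radial distribution

The cell mask is built as rolling-ball subtraction (radius 50) → linear
rescale of the intensity window [3, 30] onto [0, 1] with clipping (the
window is read as a display-rescale-with-clip; a hard clip alone would
not normalize the Otsu input) → Gaussian blur σ = 5. Segmentation is
global two-class Otsu plus connected components — per-object
re-thresholding is unnecessary for well-separated cells and is noted as a
variant — with border-touching objects flagged and excluded from
statistics. Speckle enhancement is a white top-hat with a disk of
diameter 20 px. Vesicles are identified inside the retained-cell union at
a threshold of 2 × the mode of the masked nonzero-intensity histogram
(the classic "background" strategy; multiplier configurable); objects
smaller than 15 px² are rejected as sub-diffraction noise specks (the
size-acceptance step of the standard object-identification module), and
clumps are split by watershed on inverted intensity seeded at local
maxima ≥ 2 px apart. Each object is shrunk to its intensity-weighted
centroid (binary centroid available) and related to the cell whose mask
contains it.

Distances are Euclidean child-to-parent-centroid in pixels. The
area-corrected distance defaults to mean distance / √area — the only
scale-removing reading that preserves radial information; the literal
normalization "multiply the mean distance by α = √area / mean distance"
algebraically collapses to √area and is kept as `mode="literal"`
with a warning. Fraction-at-distance uses 4 equal-width annuli from the
centroid to the farthest mask pixel, so an area-uniform distribution
yields fractions (1, 3, 5, 7)/16.

## Problem sizes and tolerances

The validation suite uses: 100 random tracks (lengths 5–200, half with
gaps) for the MSD oracle at 1e-12 relative error; 500 Brownian tracks ×
100 frames for diffusion recovery (median within 10%); ≥ 10⁴ pooled
displacements for the AC limits (1.0 ± 0.1 Brownian, < 0.2 at drift = 2
step-σ); 100 frames × 20 spots for detection (recall, precision ≥ 0.95 at
2 px matching, RMSE ≤ 0.2 px); 30 particles on 512² px for link-identity
recovery (≥ 95%); five overlap fractions for MOC monotonicity; 160²–320²
px cell scenes for the radial recoveries (ring mean within 5%, corrected
distance within 1% under ×2 rescale). These sizes keep the whole suite
around a minute while leaving comfortable Monte-Carlo margins.

## Known limitations

Greedy linking can swap identities at high density or large steps; no
Kalman prediction or merge/split handling is attempted. The diffusion fit
assumes free diffusion over the first four lags and reports an *apparent*
D that drift inflates by design. The Costes threshold search walks 256
levels of the red channel and assumes an approximately linear
inter-channel relation. Cell segmentation assumes one Otsu class
separates cells from background, which holds for well-stained, sparse
cells but not confluent fields. All analysis is strictly 2-D.
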