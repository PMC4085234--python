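# Methods

## Model and processing order

A 2-DE gel or immunoblot image is modeled as a flat background `μ_bg`
plus a sum of circular 2-D Gaussian spots plus i.i.d. read noise of SD
`σ_ns`. The pipeline runs in a fixed order:

1. **Noise estimation.** The image is covered with sliding `w × w`
   windows (full support only, so a border of `w−1` pixels is ignored);
   per window the mean and the sample SD of its pixels are computed.
   Windows whose mean lies strictly below the mean of all window means
   are taken as background — most of a gel is background, so spot
   windows pull the global mean up — and `σ_ns` is the average SD over
   those windows. A constant image yields `σ_ns = 0`. A tiled
   (non-overlapping) variant is available via `tiled=True`.
   Caveat: a *sharp* intensity step produces straddling windows with
   intermediate means and large SDs that pass the low-mean rule and
   inflate `σ_ns`; real gel backgrounds vary smoothly, where the rule
   behaves as intended (verified on spot-on-noise scenes).
2. **Restoration.** The image is convolved with the zero-sum kernel
   `K = G − U` on support `[−w, w]²`, where `G` is a 2-D Gaussian of SD
   2 (configurable) normalized to unit sum and `U` the unit-sum boxcar.
   One pass therefore smooths read noise and subtracts a boxcar
   local-background estimate. Because the kernel annihilates constants
   and detection compares the restored image only with its own
   dilation, detections are invariant to any positive kernel scale; we
   fix the scale at 1. Boundaries use reflect padding (configurable to
   zero padding).
3. **Peak detection.** A pixel is a peak iff (a) its restored value
   equals the grayscale dilation of the restored image with a flat disk
   of radius `w` — i.e. it is the brightest restored pixel within
   distance `w` — and (b) its *original* intensity exceeds
   `μ_w + t·σ_ns`, with `μ_w` the original-image mean over the same
   disk (center pixel included). Connected plateaus of equal maximal
   value emit one peak at the first pixel in row-major order. `t = 10`
   is the default: detection then fires at ten noise SDs above the
   local mean, which silences pure-noise images essentially always.
4. **Compounding.** Peaks P, Q with `|Δx| ≤ d` and `|Δy| ≤ d` must be
   fitted together; connectivity is closed transitively by squaring and
   re-binarizing the peak adjacency matrix until a fixpoint (the
   reachability matrix) — at most `⌈log₂ N⌉ + 1` squarings. A
   graph-traversal implementation exists only as a test oracle. Each
   compound's area is the union of edge-`d` squares centered on its
   peaks, clipped to the image; the fusion rule guarantees areas of
   distinct compounds are disjoint, so compounds can be fitted
   independently. For even `d` the square extends `⌊d/2⌋` pixels
   left/up and `d−1−⌊d/2⌋` right/down; odd `d` is recommended.
5. **Background.** `μ_bg` = mean intensity over all pixels outside
   every compound area, computed before fitting and held fixed (a flag
   allows co-fitting it per compound).
6. **Compound fitting.** Per compound, bounded nonlinear least squares
   (scipy `least_squares`, trust-region reflective, ftol = xtol = 1e−8,
   max `200·4k` evaluations for `k` spots) minimizes the squared
   residual of the Gaussian-sum model over the compound-area pixels of
   the **original** image (the restored image is used for detection
   only). Initialization: centers at the detected peak pixels,
   amplitudes at peak-above-background, `σ₀ = max(1.5, w/2)`. Bounds:
   `I ≥ 0`, `σ ∈ (0.1, d]`, centers inside the compound bounding box
   expanded by `w`. If the image has a known saturation level,
   saturated pixels are censored from the residual (no saturated-spot
   shape model). Optimizer failure is reported via `converged=False`,
   never raised — a single-pixel impulse, for example, pins σ at its
   floor and exhausts the evaluation budget while still yielding a
   usable (flagged) fit.
7. **False-positive discrimination.** Fits with `σ ≤ 1` pixel are
   flagged (boundary inclusive), not removed: single-pixel camera noise
   forms peaks without a broad base, narrower than any real spot.

Spot signal is `VUS = 2π I σ²`, the closed-form volume under the fitted
surface.

## Parameter guide

| parameter | meaning | default | rationale |
|---|---|---|---|
| `w` (px) | dilation radius / window scale | from `⌊IPD/2⌋` | largest radius that cannot merge the closest resolvable pair |
| `t` (–) | noise multiples in condition (b) | 10 | silences pure noise; smaller values admit false positives |
| `d` (px) | compound square edge | `6·w` | σ is typically below `w`, and a ±3σ support holds >99 % of a spot's volume; a fitted σ above `d/6` triggers a warning |
| smoothing SD (px) | Gaussian part of the restoration kernel | 2 | suppresses pixel noise without erasing spot-scale structure |
| area threshold | comparator's fixed intensity cut | `μ_bg + t·σ_ns` | deterministic reuse of detection quantities; any absolute value may be supplied |

## Comparator methods

**Optical density** is the intensity of the peak pixel (optionally
background-subtracted). It depicts height ratios of equal-width spots
perfectly, ignores width entirely, and reports the clip level for any
saturated spot.

**Threshold-area volume** sums intensities over the pixels above a
fixed threshold assigned to each spot (8-connected components;
peakless components dropped). A component shared by two peaks is split
by the perpendicular to the inter-peak line through the minimum of the
bilinearly interpolated line profile (unit spacing, endpoints on the
peaks). When the profile decreases monotonically from P to Q the
minimum sits on Q and the split passes through Q — the scheme's
documented failure mode, which produces the large-|α| blow-up for
strongly overlapping pairs. With more than two peaks in a component the
pairwise rule is applied in increasing inter-peak-distance order with
nearest-split-cell assignment; pixels exactly on a split line go to the
nearer peak. Volumes are raw sums by default (background subtraction
behind a flag).

## Synthetic scenes

The simulator renders spot surfaces at pixel centers (no within-pixel
integration; spots at gel scales are smooth), adds seeded i.i.d.
Gaussian noise, and optionally clips at a saturation level.
`(spec, seed)` determines the image bit-for-bit.

* **Gaussian** spots have exact truth `2π I σ²`.
* **Lorentz** spots `I / (1 + r²/s²)` have a divergent 2-D integral, so
  their *true signal is defined as the noiseless rendered sum over the
  image support*; truth ratios are meaningful for spots rendered on the
  same support. This is a declared convention of this package.
* **Diffusion-model** spots are a uniform disk of radius `R` blurred by
  a Gaussian of SD `D` (computed by stable radial quadrature using the
  exponentially scaled Bessel function, 2048-point trapezoid, then
  radial interpolation), scaled to peak amplitude `I`; peak value
  `1 − exp(−R²/2D²)` and total volume `πR²` (unit height) serve as
  closed-form cross-checks. Truth is again the rendered sum.

SNR means peak amplitude over noise SD throughout. The simulator does
not model gel warping, streaks, dust, spatially correlated background,
or any camera nonlinearity beyond clipping — so green tests demonstrate
correctness of the algorithms under the stated noise model, not
robustness to every artifact of real gels.

## Evaluation metrics

`α = ((signal_P/signal_Q)/(true_P/true_Q) − 1)·100` is returned signed;
aggregations across replicates use |α|. For many spots,
`α_mean` = mean over spots of `|rel_signal_i / rel_truth_i − 1|·100`
with relative values as fractions of the totals (scale-invariant; a
package convention, as is the greedy nearest-center truth matching).
Exposure-series precision is the per-spot coefficient of variation
(sample SD / mean) of the relative spot signal across the series.

## Problem sizes used in tests

The shipped test- and acceptance-suites run the experiments at desk
scale, chosen so every property is decided with margin: 50 random
8-spot 256² fields (σ ∈ [2, 4], SNR ≥ 50, IPD ≥ 4σ_max) for detection;
100 pure-noise 128² images; 20 seeded replicates per condition for the
overlapping-pair comparisons (σ = 4, I_P:I_Q = 100:60, SNR 100, IPD =
2σ and 3.5σ); a 7-point noiseless intensity sweep (20× down to 1.5× the
area threshold) for all three spot shapes; a 4-image 1×–8× exposure
series of a fixed 5-spot scene, unsaturated and clipped; and 20
impulse-plus-spot scenes for the discrimination rule.

Because the restored image of an exactly-2σ-spaced 100:60 pair carries
a single maximum under this kernel (the two-maxima window extends from
about 2.1σ to 2.5σ, below which even restoration cannot split the
pair), the pair-comparison experiments seed the peak list from the
rounded true centers — the seed-list equivalent of the interactive peak
marking the method supports on real data — so that all three
quantification methods receive identical peak inputs and the comparison
isolates quantification error.

## Known limitations

* Circular Gaussians only; elliptical or skewed spots are fitted by
  their best circular approximation.
* Non-Gaussian spot shapes (Lorentz, diffusion) are simulated but never
  fitted; fitting them with Gaussians biases absolute volumes while
  leaving relative comparisons largely intact.
* The noise estimator assumes a smoothly varying background (see the
  sharp-step caveat above).
* No cross-gel registration or spot matching between different gels.
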