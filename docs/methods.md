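# Methods

This note documents the models behind `duospot`, the defaults and their
units, the numerical choices, and what the synthetic-data generator does and
does not emulate.

## Dispersion model (optics)

A thin prism in the imaging path shifts each spot laterally by an amount
proportional to the refractive index of the prism material at the emission
wavelength. We model the PMMA index with a two-term Cauchy law
*n*(λ) = *A* + *B*/λ², pinned to datasheet values *n*(486 nm) = 1.497 and
*n*(589 nm) = 1.492, giving *A* = 1.4813, *B* = 3698 nm². The model is
valid over 400–900 nm (out-of-band wavelengths raise an error).

All geometry — apex angle, the 60 mm prism-to-sensor distance, the 6.5 µm
pixel pitch — is folded into a single **gain** (px per unit index
difference), calibrated from one measured pair separation:
gain = sep / (*n*(λ_short) − *n*(λ_long)). By construction the calibrated
model reproduces its anchor exactly, separations are symmetric, zero for
equal wavelengths, and additive over intermediate wavelengths (linearity in
*n*). No ray tracing or chromatic PSF modeling is attempted.

Anchored on the Tm pair (450/802 nm → 30.2 px) the model predicts 6.61 px
for the 660/802 nm cluster pair — inside the measured 6.5 ± 0.6 px — but
8.6 px for the Er 554/660 nm pair where 9.4 ± 0.5 px is measured. The Er
"green" emission is a multi-line band (the 512–556 nm region), so a single
effective wavelength under-determines its centroid. Consequence: **the
simulator takes measured separations as species defaults** (Tm 30.2 px,
Er 9.4 px, cluster 6.5 px) and the optics module serves wavelength
assignment and what-if geometry questions.

## Synthetic frames (simulate)

The generator emulates wide-field frames of freely diffusing UCNP
bioconjugates behind the prism:

* **Emitter counts.** Per species, Poisson with mean *c·N_A·V*, where *V*
  is the detection volume — a disc of the field diameter (111 µm at full
  geometry) times a 0.7 µm effective slab, treated as binary in/out. At
  10 pmol/L this is ~6 particles per 1000 fL, ~40 per full-size frame.
* **Positions.** Uniform in the field disc, sub-pixel.
* **Spot patterns.** Filter-dependent per species: under the 600 nm
  long-pass, singles (Tm at 802 nm, Er at 660 nm) are one spot and the
  Tm–Er cluster is the 6.5 px double spot; in full spectrum Tm/Er are
  double spots (30.2/9.4 px) and the cluster the 4-spot union.
* **Brightness.** Integrated photons per unit-intensity spot are lognormal
  with mean 2000 and CV 0.25 per 10 ms exposure, scaled by relative spot
  intensity and aggregate multiplicity. Spots are pixel-integrated
  Gaussians (σ = 1.3 px default); the truth table records the photons
  actually deposited, so the truth sum equals the pre-noise signal sum
  exactly even when patterns clip at the frame edge.
* **Aggregation.** n-mer multiplicity sampled so the monomer fraction
  matches the species default (0.77 Tm, 0.81 Er); the aggregated remainder
  splits 0.7/0.2/0.1 over dimers/trimers/tetramers. Brightness scales
  linearly with n-mer.
* **Noise.** Poisson shot noise on signal + background (100 counts/px
  default), additive Gaussian read noise (σ = 2 counts), clipped to 16 bit.
  Background level, read noise and the photon budget are free parameters —
  the source experiments do not constrain them — so detector-performance
  results are properties of these stated conditions, not instrument
  reproductions.
* **Seeding.** One master seed; each (stack, frame) gets an independent
  substream via `SeedSequence([seed, stack_id, frame])`, so stacks are
  bit-reproducible and stable under partial regeneration.

Not emulated: upconversion photophysics (power-dependent spectra, decay
kinetics), diffusion blur within the 10 ms exposure (negligible at these
diffusion constants), axial intensity roll-off (slab is binary), camera
fixed-pattern noise, and cross-frame correlation of slow-moving particles
(frames are independent draws, matching the per-frame counting convention).
Passing tests therefore demonstrate correctness of the algorithms under
these conditions, not performance on real camera data.

The competitive-assay generator converts a fraction of Tm/Er particle pairs
into cluster species by a 4PL-shaped suppression in free biotin
(p_max = 0.9, p_bg = 0.05, IC50 = 17 nmol/L, S = 1.5 by default), rendering
the remainder as singles. A count-level generator (no frames) produces
dose–response tables with multiplicative Gaussian noise for statistical
studies of the 4PL fit.

## Classical detector (detect)

Deterministic pipeline, a pure function of (frame, parameters):

1. **Background**: median filter with a 21 px window (≫ PSF). For speed
   the frame is reduced 4× by block medians, filtered, and bilinearly
   interpolated back; a bright spot on a background ramp can shift the
   local median by a few counts (order-statistic effect), which is far
   below the detection threshold.
2. **Spots**: difference-of-Gaussians (σ 1.0/2.5 px), local maxima above
   5 robust SDs (1.4826·MAD of the DoG response), 5×5 intensity-centroid
   refinement, 5 px edge margin.
3. **Pairing**: candidate pairs must match the expected separation
   (6.5 ± 3 px default; the ±3 px tolerance is ~5× the measured 0.6 px SD,
   loosened for centroid noise) and the dispersion-axis orientation
   (±10°). Conflicts are resolved per connected component of the candidate
   graph: components of ≤ 10 spots are matched **exactly** (maximum pair
   count, then maximum combined intensity, deterministic tie-breaks);
   larger components fall back to greedy. Pure greedy was rejected because
   a chain of spots A–B–C–D whose middle pair is brightest makes greedy
   return one pair where two exist; exact small-component matching keeps
   the count equal to the true maximum matching wherever it is feasible to
   compute.

Matching to ground truth is greedy nearest-neighbour on pair midpoints
within a radius (2 px default); with no detections, precision is reported
as 1.0 with an explicit `precision_defined = False` flag.

## U-net backend (unet)

A compact encoder–decoder network implemented directly on numpy (im2col
3×3 convolutions, ReLU, 2×2 max-pool, nearest-neighbour upsampling, skip
concatenation, explicit backpropagation, Adam, weighted binary
cross-entropy with positive-class weight 4). Defaults — depth 3, 8 base
channels, 64 px patches, batch 8, 8 epochs, lr 2·10⁻³ — are sized so that
training on 200 patches takes a couple of minutes on one CPU core while
the receptive field still spans several pair separations. Training is
deterministic for a fixed seed.

**Labels** come from simulator ground truth: a radius-3 px *capsule* (the
two spot disks joined along the pair axis) over each true double spot;
single spots are left unlabeled so the network learns to suppress them.
A capsule rather than two separate disks is used because disks at
sub-pixel centers 6.5 px apart frequently fail to touch after
rasterization, which would break the mask-then-count identity (one
connected component per pair). Half of the training patches are centered
on a random emitter — pairs for positives, singles as hard negatives — and
half are uniform crops.

**Counting**: full frames are normalized (median/MAD), tiled into
overlapping patches with logit averaging, thresholded at probability 0.5,
and 8-connected components with area ≥ 25 px are counted. The area
threshold is ~40% of the nominal capsule area (2·r·sep + πr² ≈ 67 px),
rejecting fragments and partially activated singles.

## Quantification (quantify)

* **Calibration**: weighted least squares of mean counts/frame vs molar
  concentration; weights 1/SD² across replicate (slide-level) means where
  available, with the smallest positive SD as a floor so all-zero blanks
  cannot dominate. The **linear range** is chosen by dropping the highest
  levels one at a time until the weighted R² reaches 0.995 (configurable);
  at least three nonblank levels must remain, otherwise the series is
  flagged — a two-point line is trivially perfect and would mask a
  hopeless series. Saturation enters from the top because overlapping
  double-spot patterns cause undercounting at high densities.
* **LOD** = 3.3 · SD(blank replicate means) / slope.
* **Volumes**: V = count/(c·N_A) from counts, or π(d/2)²·t for the disc
  geometry; µm³ ≡ fL. These are exact inverses of the expected-count
  relation.
* **Monomer fraction**: the spot-intensity histogram is fitted by maximum
  likelihood (binned, Nelder–Mead) with a mixture of up to K = 4
  components at means k·µ1 and shared fractional width. A pure k-mer
  population is equally well explained by µ1/k with all weight shifted one
  component up, so among near-equal likelihoods (within 2 nats) the
  solution with the largest µ1 — fewest implied aggregates — is preferred.
* **Scan budget**: ceil(depth/step) steps × (exposure + transit).

## Assay statistics (assay)

4PL on linear concentration so that [B] = 0 evaluates exactly to DSC_max;
fitting by bounded nonlinear least squares (positivity enforced),
initialized at DSC_max = max mean, DSC_bg = min mean, IC50 = level nearest
the midpoint response, S = 1, with 1/SD² weighting where replicate SDs are
present. The inverse 4PL is algebraic and round-trips with the forward
model to 1e−9 relative over at least four decades.

**DSC_LOD** is defined as DSC_max − k·SD(DSC at zero analyte) with k = 3.3,
consistent with the 3.3·SD blank convention used for the dilution-series
LOD; the multiplier is configurable. Whether the SD should come from
zero-analyte replicates or pooled residuals is a genuinely open choice; we
use the zero-analyte replicates and fall back to the fit's residual SD when
they are absent. If DSC_LOD leaves the open response interval the assay is
flagged nonresponsive rather than reporting an extrapolated LOD.

## Problem sizes in tests

End-to-end tests and examples run on reduced fields (256–512 px instead of
1024 px) at the **same areal spot-pair density** as the full-size
experiment, with the detection volume scaled by field area accordingly
(e.g. 1691 fL for a 512 px field vs 6774 fL at full size). All
concentration ↔ count arithmetic is invariant under this scaling; the
package defaults remain the full 1024 px geometry. The dilution-series
test uses 5 levels over 4 decades with 50 frames/level and two replicate
"slides" per level; the U-net test trains on 200 patches from 20 frames
and evaluates on 10 held-out frames.

## Known limitations

* The dispersion model is single-wavelength-per-line; multi-line bands
  (Er green) need an effective centroid that the model cannot supply.
* Counting is per frame; slow-moving particles appearing in consecutive
  frames are counted each time, as in the per-frame DSC convention.
* The monomer-fraction mixture assumes strictly linear brightness in
  n-mer and a shared fractional width; K is capped at 4.
* The numpy U-net is intentionally small; it is a working reference of the
  mask-then-count scheme, not a tuned segmentation model.
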