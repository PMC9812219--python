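# Methods

This note documents the models, algorithms and numerical choices behind
`cryotarget`, and what the synthetic validation does and does not show.

## Coordinate and data conventions

All coordinates are `(row, col)`, 0-based, with pixel centers at integer
positions and half-open image bounds `[0, H) × [0, W)`.  Angles are degrees.
Images travel as 2-D float arrays; MRC/CCP4, PNG and TIFF are accepted on
disk.  Every stochastic component takes an explicit integer seed, and a
fixed seed reproduces scenes, training runs and rankings bit for bit on the
same CPU architecture.

## Square localization

**Poisson mixture.**  Low-magnification pixel counts are modeled as a
two-component Poisson mixture: thick grid bars emit few counts, thin foil
squares many.  EM runs on the histogram of unique count values (not on raw
pixels), which makes iterations O(#distinct values).  Initialization splits
the empirical distribution at its median; components are ordered
`rate_low ≤ rate_high` to resolve label-swap symmetry.  Convergence is an
absolute log-likelihood change below `tol` (default 1e-6, max 200
iterations).  Non-integer images are affinely rescaled to counts in
[0, 255]; integer-valued floats are used as is.  A constant image yields a
*degenerate* fit (`rate_low == rate_high`) that segmentation refuses with a
specific error — an image with no contrast has no squares to find.
Segmentation assigns a pixel to the square class when its posterior under
the bright component is ≥ 0.5; the tie at exactly 0.5 goes to the bright
class, favouring recall at the localization stage (classification later
filters false positives; missing a square cannot be repaired downstream).

**Components and hulls.**  Square-class pixels are grouped by 4-connected
flood fill.  Components smaller than `min_pixels` are dropped; the default
is a quarter of the median component size, which removes speck noise without
a fixed absolute scale that could delete genuinely small squares.  Each kept
component is bounded by the convex hull of its pixel centers (degenerate
single-pixel or collinear components fall back to their extreme points).

**Shared angle.**  The mesh rotation is one global θ per image.  The total
aligned-bounding-rectangle area Σᵢ Aᵢ(θ) is 90°-periodic and piecewise
smooth with kinks at optimal angles, and can be multimodal.  Minimization
runs Brent-style bounded search from 8 evenly spaced brackets over [0°, 90°)
followed by a golden-section polish in a ±1e-4° window: SciPy's bounded
Brent stops at a relative tolerance of about `sqrt(eps)·|θ|`, which at a
V-shaped minimum leaves ~1e-7° (and ~1e-7 of objective) on the table; the
polish removes it.  Crops resample the image bilinearly along the rotated
box axes at unit pixel spacing, optionally padded by `pad_fraction`, and are
standardized by the mean/sd of all pixels in all boxes of the image so that
per-square brightness differences survive normalization (they carry signal)
while electron-dose differences between images do not.  An sd floor of 1e-8
maps contrast-free crops to zeros.

## Hole localization

**Heatmap network.**  A U-Net (two 3×3 convolutions + ReLU per level, 2×
max-pool down, nearest-neighbour up with skip concatenation, 1×1 sigmoid
head) maps the normalized image to per-pixel hole-center probabilities.  The
library default is depth 5 / 16 base channels; the validation suite trains a
depth 3 / 8 channel configuration on 128 px scenes, whose 32 px bottleneck
receptive field covers the 16 px synthetic hole diameter — the configured
`max_hole_diameter_px` is checked against the receptive field at
construction.  The engine underneath is a small reverse-mode autodiff over
numpy arrays written for this package (im2col convolutions, Adam); gradient
correctness is tested against central differences at 1e-7.

**Training.**  Targets are binary maps with 1 at operator click pixels.
Because clicks are near, not at, hole centers, the model *output* is blurred
with a Gaussian (truncated at radius ⌈3σ⌉, renormalized, zero-padded
borders) before the per-pixel binary cross-entropy; σ starts at 2 px — the
synthetic click jitter has sd r/4 = 2 px — and descends its own gradient in
the same loop, with a squared-cosine annealed step so the learned smoothing
settles as training converges (weights use Adam, lr 5e-3, batch 4; a
parameter whose optimal value the loss pins down only weakly is better
served by gradient-proportional steps than by Adam's normalized ones, which
keep oscillating at convergence).  Two further choices matter under the
extreme class imbalance of point targets (~0.1% positive pixels): the head
bias is initialized to the logit of the positive-pixel base rate, so
training starts calibrated instead of being driven into deep sigmoid
saturation during the first epochs, and the cross-entropy keeps a bounded
nonzero slope in its clipping region so saturated predictions can recover.
Augmentation applies a random quarter-turn to image and target jointly and
inverts the image sign with probability 1/2 (target untouched), which makes
one model serve both contrast polarities — on carbon grids holes are darker
than the substrate.

**Lattice fitting.**  Holes lie on a regular square lattice, so detection is
finished by fitting one: centroids of 4-connected regions above
`region_threshold` (default 0.5) are paired with their K = 6 nearest
neighbours; each pair `(a, b)` generates the lattice with basis `v = b − a`
and its exact 90° rotation (oblique lattices from tilted collection are out
of scope), rasterized as disks of radius 0.25·pitch (recomputed per pair so
the covered-area fraction π/16 is pitch-invariant and costs are comparable
across candidates).  The pixelwise cost `λ₁·L·(1−O) + λ₂·(1−L)·O` averaged
over pixels weighs lattice-without-evidence against evidence-without-lattice;
defaults λ₁ = 1, λ₂ = 4 prioritize recall — the stage's job is to recover
every hole.  Ties keep the earlier candidate.  Two guards make the search
robust: anchor pairs closer than a minimum pitch are inadmissible, with the
minimum derived from the detected region sizes (twice the median
region-equivalent radius — holes cannot overlap, so no genuine lattice is
tighter than its own hole diameter), and an optional `auto_balance` mode
rescales λ₂ by (π/16)/mean(O) so that on low-mass maps — early-training
network output concentrates probability in narrow spikes — the missed-mass
penalty stays commensurate with the lattice-area term.  Without this, all
candidate lattices pay a nearly identical area penalty and the choice
degenerates to border-clipping artifacts that favour sparse lattices.  The
pipeline enables auto-balancing and additionally calibrates the map to unit
peak and halves the centroid threshold (down to 0.02) until at least four
anchor candidates exist; library calls use the literal cost by default.

**Tile scoring.**  Each lattice point yields a crop of side round(pitch)
(clamped at borders) scored by the summed in-tile probability; setting
`tile_prob_threshold` drops low-evidence tiles, trading recall for
precision.

## Target ranking

Square features are the seven statistics mean, max, min, variance, kurtosis,
skew (Fisher convention, population denominators; a constant crop has
skew = kurtosis = 0 by convention) and crop area; a 5-feature variant
without the higher moments is also constructible.  Logistic regression
(standardized inputs) and a 200-tree random forest are the baselines;
permutation importance uses average precision over 10 repeats.  The square
CNN resamples crops to a fixed side (the area signal stays with the
baselines, where it is explicit).  The hole CNNs share every hyperparameter
except their size handling: the padded variant zero-pads to a fixed canvas
and flattens, the average-pool variant runs stride-1 convolutions only and
averages the final map over space, making the score independent of where a
feature sits in the crop — contamination matters by presence and proportion,
not position.  Class imbalance is handled by inverse-frequency loss weights.
The summed in-tile U-Net probability, rescaled per image to [0, 1], is
itself a hole classifier and is the pipeline default.

## Matching metrics

A predicted point inside exactly one ground-truth hole that contains no
other prediction is a true positive; holes with zero or multiple predictions
are false negatives, and predictions outside all holes or sharing a hole are
false positives — so tp + fn always equals the number of holes, and flooding
an image with predictions cannot inflate recall.  Containment is a distance
test against per-hole radii (checked against all holes, not the nearest
center, since radii may differ); overlapping ground-truth holes are
rejected as ambiguous.  Session reports pool counts within a session, then
macro-average across sessions; sessions with no predictions have undefined
precision and are excluded from the macro mean with a warning.  Micro
(pooled) metrics are also emitted.  Square detection quality uses rotated-box
IoU with Hungarian one-to-one assignment.

## What the simulator does and does not show

Grid scenes draw Poisson counts at two rates on a rotated mesh (defaults:
256 px image, 64 px pitch, 40 px squares, rates 4/40), with a configurable
fraction of squares "cracked" by erasing a random half-plane; cracked
squares stay in the ground truth as unselectable.  Hole scenes place disks
on an axis-aligned lattice (128 px image, 32 px pitch, 8 px radius) with
signed contrast, Gaussian intensity noise (sd 0.15), irregular dark
contamination blobs, hole dropout, and operator points jittered by sd r/4
and truncated inside the hole; operators select 85% of the good holes,
emulating incomplete labeling.  These scenes exercise every code path with
exact ground truth, but they are not physically accurate TEM images: no
contrast-transfer function, detector response, ice-thickness gradients,
lacey or sprayed geometries, or tilted (oblique) lattices.  Passing the
validation suite therefore demonstrates algorithmic correctness and
robustness to the modeled nuisances (noise, dropout, contamination, contrast
inversion, mesh rotation), not performance on any particular real facility's
data.

## Validation problem sizes

The validation suite (also run by `scripts/acceptance.py`) uses: 3 polygon
sets per angle for angle recovery; 10⁴ pixels for mixture recovery; 20
atlases for square detection; 3 maps for the exhaustive-search oracle; 10
maps at 30% dropout with 5 spurious blobs for robustness; 6 maps for the
tile-threshold trade; and one training run of 200 scenes × 10 epochs
evaluated on 2 × 10 held-out scenes for the end-to-end hole stage.  Square
detection recall is measured over intact squares (a cracked square
legitimately yields a part-sized box), while spurious boxes are those
overlapping no real square at IoU 0.1.

## Known limitations

Tilted collection (oblique lattices), multi-lattice fields of view and lacey
grids are out of scope.  Training determinism is guaranteed per seed on a
single device class; BLAS differences across architectures can change
low-order bits.  The pipeline emits per-image ranked target lists; combining
them into a session-level collection queue is left to the caller.
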