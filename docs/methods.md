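# Methods

This note documents the models and procedures implemented in `wormalign`,
the choices made where the design was genuinely open, and what the
synthetic phantoms do and do not establish about real data.

## Problem setting

Whole-brain imaging in freely moving animals (the motivating case is the
*C. elegans* head, with extensions to jellyfish recordings and to
cross-animal atlases) produces long sequences of 3-D fluorescence volumes
in which a few hundred nuclei translate, rotate, and bend non-rigidly from
frame to frame. Extracting single-cell activity traces requires three
capabilities, which map onto the package's three pipelines:

1. **Registration** — find, for a pair of volumes, a dense displacement
   field (DDF) mapping fixed-image coordinates to moving-image
   coordinates, so that ROIs can be carried across time.
2. **Tracking** — convert many pairwise registrations into consistent cell
   identities by clustering an ROI similarity matrix.
3. **Annotation** — assign cell-type labels to ROIs from multi-spectral
   (NeuroPAL-style) color volumes, and estimate how accurate those labels
   are.

## Conventions

Volumes are indexed `(x, y, z[, c])`, 0-based, voxel centers; the
canonical full-scale registration shape is `(284, 120, 64)` and the
desk-scale shape used throughout the tests is `(64, 32, 16)`. A DDF `D` is
an `(X, Y, Z, 3)` voxel-displacement field with pull semantics: the warped
(predicted fixed) image reads the moving image at `p + D[p]`, trilinearly
interpolated, zero outside the volume. ROI volumes are integer grids
(0 = background). Matched centroid tables are `(200, 3)`, padded with the
sentinel `(-1, -1, -1)`; row order is the correspondence key.

## Rigid (Euler) pre-alignment

Networks learn small non-rigid deformations much more readily than large
rotations/translations, so pairs are first rigidly aligned by brute-force
NCC maximization. The transform convention is
`out[p] = moving[R(p - c) + c + t]` (rotation about the image center,
zero fill), which coincides exactly with warping by the rigid DDF
`d[p] = R(p - c) + c + t - p`.

The search runs in three stages: (i) an exhaustive scan of
(rotation, integer-pixel translation) on factor-4-downsampled z-MIPs —
for each rotation, the NCC of *every* shift is evaluated exactly from
overlap sums, since the global mean and variance of a zero-filled shifted
image are functions of the overlap; (ii) a translation refinement on the
full-resolution MIP at the configured step (default 2 voxels) around the
coarse optimum; (iii) a 1-D scan of the z-shift maximizing the full 3-D
NCC. Ties break toward the first candidate in scan order. Default grid:
rotation ±180° in 2° steps, in-plane translation ±40 voxels in 2-voxel
steps, z-shift ±10 in 1-voxel steps; these ranges cover the motion seen
between posture-matched frames while keeping the search desk-scale. The
grid was not stated in full by the source pipelines; the ranges are this
package's defaults and are configurable.

## Registration network

The backbone is a LocalNet-style 3-D U-Net: three encoder levels with
`b·2^i` channels (conv block → residual conv block → 2×2×2 max-pool), a
bottom conv block, and three decoder levels (transposed-conv upsampling
plus a resized split-channel-sum branch, skip concatenation with the
mirrored encoder's pre-pool features, conv + residual conv). A 3-channel
head is applied to the bottom block and to every decoder output, each head
is trilinearly resized to the input shape, and the four head images are
averaged into the DDF. Odd input dims are handled by −∞-padded pooling and
resize-to-skip-shape in the decoder, so the output spatial shape always
equals the input's. Displacement heads are zero-initialized so the
untrained network produces the identity warp — training refines from
identity rather than from a random field.

Channel bookkeeping in the written description of the original
architecture is not self-consistent (the skip tensors carry the pre-pool
channel counts `b, 2b, 4b`, not the decoder-level counts); we concatenate
the actual pre-pool features and let the following conv block reduce to
the level width. The full-scale width is `b = 16`; the desk-scale spec
used in tests is `b = 4` on `(64, 32, 16)` volumes, chosen so a complete
training experiment runs in minutes on one CPU core.

Variants: the *jellyfish* configuration zeroes the z-component of the DDF
after the final average (deformation stays within z-slices), drops
centroid supervision, and restricts the gradient-norm regularizer to x/y
derivatives; the *discovery* configuration takes 4-channel image pairs
concatenated along the existing channel axis (8 input channels), trains
unsupervised with a squared channel-averaged global NCC image loss, and
applies the DDF to each channel independently.

The annotation architecture contract (`LabelerUNet`) is a 4-level
group-normalized 3-D U-Net (GroupNorm group size 16, size 1 for the first
block; interpolation upsampling; 1×1×1 head with K = 185 channels).
Training it at full scale is out of scope; the architecture, loss, and
metric are implemented and exercised at reduced width.

### Losses

`Loss = w_I·L_I + w_C·L_C + w_R·(0.02·L_Grad + 0.005·L_Diff + 0.001·L_AxisDiff + 0.02·L_Nonrigid)`
with `w_I = 1`, `w_C = 0.1`, `w_R = 1`.

* **Image loss** `L_I`: negative local squared zero-normalized
  cross-correlation in a sliding cube of side `n = 16`
  (`L_I = −mean[(E(FP) − E(F)E(P))² / (V(F)V(P) + ε)]`). Windows are
  dense (stride 1) over valid positions only; `ε = 1e−5` stabilizes
  flat windows. Both choices (window stride, ε) are unstated in the
  source description and fixed here once. Desk-scale experiments use
  `n = 8` so that a `(64, 32, 16)` volume contains a meaningful number of
  windows along z.
* **Centroid alignment loss** `L_C`: mean Euclidean distance between the
  predicted moving centroids (fixed centroid + DDF sampled trilinearly at
  the fractional centroid) and the true moving centroids. Padding rows
  are excluded from numerator and denominator — sentinels are not
  physical points. The written description calls the loss a "negative"
  of the distance sum but prints a positive formula; minimizing distance
  is the only reading consistent with the optimizer, so the printed
  positive form is implemented.
* **Regularizers**: mean squared central-difference gradient over interior
  voxels (`L_Grad`; 2-D variant omits z-derivatives); mean squared
  displacement (`L_Diff`); mean squared z-displacement (`L_AxisDiff`);
  and the rigidity-aware penalty `L_Nonrigid`: with
  `D_ref[p] = −p`, the per-component gradient magnitude
  `M = Σ_axes (∂(D − D_ref)/∂axis)²` equals 1 under any rigid-body
  transform, and the penalty is the interior mean of `|M + 1/M − 2|`.
  `M` is floored at `1e−8` before inversion (the printed formula divides
  by `M`).

The discovery preset replaces `L_I` with
`−(1/C)·Σ_c NCC_c²` (global, per channel) and uses regularizer weights
(0.05, 0.0025, 0, 0.05).

### Training

Adam, full-scale learning rate 1e−4. Desk-scale experiments use 1e−3 —
with a 100-epoch budget on 30 problems, the smaller network needs the
larger step; this is a configuration default of the reduced setup, not of
the architecture. Batches are assembled by shuffling problems each epoch
(seeded); augmentation, when enabled, draws one random affine transform
per sample from perturbed cube corners (least-squares fit), pull-warps
both images with it, and moves both centroid sets by the inverse map; the
jellyfish toggle adds a random multiple of 90° in-plane rotation.
Validation loss is tracked when a validation set is configured, and the
best-validation parameters are restored at the end. A non-finite loss
aborts immediately with diagnostics.

All network compute runs on an in-package reverse-mode autodiff core
(`wormalign.nn`) written on numpy: im2col-based 3-D convolutions (BLAS
matmuls, float32), transposed convolutions as the exact adjoint of the
stride-2 convolution, fused batch normalization, separable trilinear
resizing, a spatial-transformer warp whose gradient with respect to the
field is the analytic derivative of the trilinear interpolant, and a
box-filter sliding-window mean whose adjoint is again a box filter. Every
operation is verified against central finite differences in the test
suite; the differentiable losses are additionally required to agree with
the plain-numpy reference implementations to ~1e−9.

## Tracking (ROI linkage)

For two ROIs *i* (moving, time `t_i`) and *j* (fixed, time `t_j`) with a
solved registration, the similarity entry is

`M_ij = R · 1/(1 + w1·d_i) · q^w2 · r^w3 · exp(−(w4·a + w5·c + w6·n))`

with `R` the registered indicator, `d_i` the DDF displacement magnitude at
the warped ROI's centroid, `q` the global NCC of warped-moving vs fixed
image (clamped to [0, 1] before the `w2 = 25` power: a negative NCC
carries no linkage confidence), `r` the fractional overlap
(intersection / larger size) of warped-moving and fixed ROI, `a` the
brightness dissimilarity, `c` the residual centroid distance, and `n` the
unweighted nonrigid penalty of the DDF. Weights default to
`(w1..w6) = (2, 25, 1, 3, 1, 1)`, merge floor `w7 = 1e−4`, collision cap
`w8 = 0.05`. The matrix is symmetrized by copying `M_ij` into empty
`M_ji` slots.

`a` is implemented as `|F_i/μ(t_i) − F_j/μ(t_j)|` where `F` is the mean
in-ROI marker brightness and `μ(t)` the mean over ROIs at that timepoint —
one concrete reading of "normalized to mean activity at the corresponding
timepoints". `q` uses the global NCC (whether the original uses global or
local is unstated).

Clustering: the source pipeline's "custom hierarchical clustering" is not
published in detail. Implemented here as greedy agglomeration: repeatedly
merge the most similar cluster pair (average linkage via Lance–Williams
update), refuse merges below `w7`, and reject (and bar) a merge whenever
the merged cluster's collision fraction — the fraction of its timepoints
contributing more than one ROI — would exceed `w8`. Each surviving
cluster is one cell identity; traces are the per-timepoint ratio of mean
in-ROI green to mean in-ROI red, with missing timepoints left missing.

The cross-animal variant replaces `a` with the L1
distance between 4-channel color vectors (per-channel mean brightness
normalized to mean 1 over channels), sets `w4 = 7`, forbids collisions
(`w8 = 0`), lowers the floor to `w7 = 1e−9`, and reports only clusters
present in more than half of the animals. Its accuracy metric is, over
clusters with more than two known labels, the fraction of labels equal to
the cluster's most frequent label (L/R subclass ignored on request).

## Annotation utilities

Training weights: background pixels weigh 1; pixels of an ROI labeled `l`
with human confidence `c ∈ {2..5}` weigh `(130/N(l))·f(c)` with
`f = {2: 50, 3: 600, 4: 900, 5: 1000}` and `N(l)` the corpus count of the
label (130 is the corpus count of the most frequent neuronal label, so
the rarity factor is ≤ 1 only for labels at least that common); pixels of
unlabeled ROIs get `1e−3` (the original states "extremely low" without a
number). The loss is pixel-wise weighted cross-entropy with a `1/(XYZK)`
normalization — note the extra `1/K` relative to the usual convention.
The evaluation metric is a weighted mean IoU of the argmax map against
the one-hot target; channels with an empty weighted union score 1 by
default (vacuous truth; configurable to be skipped).

For training annotation networks an augmentation battery is provided
(`LabelerAugmentSpec`): a smooth B-spline-style worm bend in the xy
plane, random affine, 180° rotations about a random axis, and —
image-only — per-channel contrast adjustment, a z-gradient Gaussian blur
mimicking depth-dependent optics, and Gaussian plus Poisson noise.
Images interpolate linearly with median fill; label and weight volumes
use nearest-neighbor interpolation with zero fill. The magnitudes are
package defaults (the originals live in unpublished configuration files)
and every term can be disabled.

ROI label extraction: each ROI is averaged over a mask that is 0 outside,
0.01 on face-adjacent boundary voxels, and 1 in the interior (neighbors
beyond the volume faces do not exist and are ignored), giving a V×K row
per ROI that sums to 1; the argmax is the label, its probability the
confidence. Postprocessing iterates ROIs by descending confidence:
duplicate labels within 3 voxels (a value the original leaves at "small
enough") are treated as over-segmentation and share the label, farther
duplicates lose the lower-confidence copy; an ROI with a foreign class
above 0.75 probability on ≥10 voxels or ≥20 % of its voxels is dropped as
under-segmented; if both L and R subclasses exceed 10 % probability the
class-level label is emitted with summed confidence; rare classes, 'glia'
and 'granule', background argmaxes, and labels below 0.75 confidence are
removed. Argmax ties break toward the lower label index.

## Evaluation statistics

* **Centroid distance** — mean Euclidean distance between per-index
  centroids of two ROI volumes sharing indices.
* **Sparse-GFP error rate** — with traces `F` and threshold 1.5: a neuron
  is GFP-positive iff `median(F) > 1.5`; a sample is a mismatch iff it
  deviates from the neuron's median by more than 1.5 *and* exactly one of
  {sample, median} exceeds 1.5; the rate is
  `mismatches / (samples · 2·Frac·(1 − Frac))`, correcting for
  same-polarity errors the assay cannot see. Undefined when the
  GFP-positive fraction is 0 or 1 (flagged).
* **Simulation-based label accuracy** — for candidate accuracies
  `p_sim ∈ {0..100} %`, each label of a consistently encoding class is
  reassigned (per trial) to a random same-class reference neuron with
  probability `p_sim`, else to a random neuron of the same animal; the
  estimate is the `p_sim` whose mean simulated expected-encoding fraction
  (1000 trials by default, averaged per label) is closest to the observed
  fraction, ties toward the lower value.

## Synthetic phantoms

`make_phantom` scatters `n_cells` (default 110, the typical matched-ROI
count in a head recording) non-overlapping Gaussian-blob nuclei along a
curved midline; ROIs are the blob balls, centroids the analytic centers.
Bends displace `y` by `A·sin(2πx/λ + φ)` — a function of `x` only —
optionally composed with a rigid transform. Because the bend leaves `x`
unchanged, the maps invert and compose in closed form, so ground-truth
DDFs between any two frames or animals are exact, not numerically
inverted. Desk-scale bend amplitudes (4–7 voxels on a 32-voxel y-extent)
are chosen to mimic the residual deformation left after rigid
pre-alignment. `make_timeseries` adds a per-cell green/red ratio (bright
for planted GFP-positive cells, dim otherwise), can inject identity
swaps between a GFP-positive and a GFP-negative cell for error-rate
validation, and can plant step-like activity events (a cell's green
ratio doubles from a known frame) to validate trace extraction. `make_cohort` gives each of `n_types` cell types a fixed
4-channel color signature (mean-1 normalized, multiplicative noise 5 %)
and a stereotyped position perturbed per animal (jitter σ = 0.5 voxels)
under a per-animal bend.

What the phantoms do *not* emulate: optical PSF and depth-dependent blur,
autofluorescence and background structure, segmentation errors (ROIs are
exact balls), cell-density inhomogeneity, intensity bleaching, and
deformations with out-of-plane twist. Passing the synthetic experiments
therefore demonstrates that the machinery is implemented correctly and
can recover known structure under realistic geometry and noise scales —
not that the full-scale networks reach their published accuracy on real
recordings, which requires the original data and GPU-scale training.

## Problem sizes used by the test suite

Unit tests run on volumes up to 24³. The end-to-end experiments use:
Euler recovery on 20 seeded phantoms at `(64, 32, 16)`; network training
on 30 bent pairs at `(64, 32, 16)` for 100 epochs (base width 2, batch 5,
LNCC window 8, learning rate 1e−3) with 6 held-out pairs — the smallest
width at which the architecture's channel bookkeeping stays integral, and
ample for the sinusoidal-bend family (measured held-out error 0.63
voxels); tracking on a 10-frame, ~25-cell series with exact DDFs;
discovery on a 6-animal, 15-type cohort. These sizes are the package's
desk-scale choices.

## Known limitations

* The clustering algorithm and the brightness normalization in the
  linkage heuristic are this package's concrete readings of briefly
  described components; both are flagged in the API documentation.
* The autodiff core is single-threaded numpy; full-scale `(284, 120, 64)`
  training is functional but impractically slow without accelerator
  hardware — the full-scale configuration is provided for completeness.
* `estimate_label_accuracy` averages the expected-encoding fraction per
  label (whether the original averages per label or per animal is
  unstated).
* Volume I/O covers HDF5 and TIFF.
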