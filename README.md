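# wormalign

Non-rigid registration, cell tracking, and multi-spectral cell-type
annotation for volumetric fluorescence recordings of moving, deforming
nervous systems — the *C. elegans* head is the motivating case, with
variants for jellyfish recordings (planar deformation) and for
cross-animal cell-type discovery.

It is aimed at researchers processing whole-brain calcium-imaging data:
people who have a time series of 3-D volumes (plus segmented ROI label
volumes) and need per-neuron activity traces, or who have multi-spectral
(NeuroPAL-style) volumes and need cell-type labels.

## What it computes

**Registration.** Image pairs are rigidly pre-aligned by a brute-force
NCC grid search over in-plane rotation/translation (on downsampled
maximum-intensity projections) plus a z-shift. A LocalNet-style 3-D U-Net
then predicts a dense displacement field (DDF) `D` mapping fixed-image
coordinates to moving-image coordinates; the warped moving image reads
`moving[p + D[p]]`. Training minimizes

```
Loss = w_I·L_I + w_C·L_C + w_R·(0.02·L_Grad + 0.005·L_Diff + 0.001·L_AxisDiff + 0.02·L_Nonrigid)
```

where `L_I` is a negative local squared zero-normalized cross-correlation
in 16³ sliding cubes, `L_C` the mean distance between predicted and true
matched centroids, and the regularizers penalize rough, large, out-of-plane
and — via the rigidity statistic `M`, which equals 1 for any rigid-body
transform — non-rigid fields. The network stack (convolutions, autodiff,
Adam) is implemented in-package on numpy; see `wormalign/nn/`.

**Tracking.** ROIs from all registered frame pairs are linked by the
similarity heuristic

```
M_ij = R · 1/(1 + w1·d) · q^w2 · r^w3 · exp(−(w4·a + w5·c + w6·n))
```

(`d` centroid displacement, `q` registration NCC, `r` ROI overlap, `a`
brightness/color dissimilarity, `c` residual centroid distance, `n`
nonrigid penalty; defaults `w1..w8 = 2, 25, 1, 3, 1, 1, 1e-4, 0.05`) and
clustered agglomeratively — `w7` is the merge floor, `w8` the acceptable
fraction of timepoints contributing more than one ROI. Each cluster is
one neuron; traces are per-frame green/red ratios. A cross-animal mode
swaps the brightness heuristic for a 4-channel color distance
(`w4 = 7, w7 = 1e-9, w8 = 0`) to discover cell types across animals
without supervision.

**Annotation.** Utilities for label networks: confidence- and
rarity-weighted training pixels (`W = (130/N(l))·f(c)`), pixel-weighted
cross-entropy and weighted MeanIoU, mask-weighted per-ROI label
extraction from probability maps, and the postprocessing rules
(over/under-segmentation handling, L/R ambiguity, rare-class deletion,
confidence floor). Label accuracy in strains no human can annotate is
estimated by a behavior-encoding simulation.

**Synthetic ground truth.** `wormalign.synthetic` generates worm-like
blob phantoms, bending deformations with *exact* displacement fields
(bends displace y as a function of x only, so maps compose and invert in
closed form), GFP-patterned time series with injectable identity swaps,
and multi-animal 4-channel cohorts with per-type color signatures. Every
pipeline stage is testable against known truth without any downloads.

## Worked example

Registration and tracking on a synthetic deforming recording
(25 nuclei, 8 frames, one injected identity swap):

```python
import itertools
from collections import Counter
from wormalign import synthetic, euler, losses, tracking, evaluation
from wormalign import ddf as ddfmod

phantom = synthetic.make_phantom(synthetic.PhantomSpec(dims=(64, 32, 16), n_cells=25, seed=0))
series = synthetic.make_timeseries(phantom, n_frames=8, gfp_fraction=0.4,
                                   n_swaps=1, swap_duration=2, seed=0)

d = series.true_ddf(0, 3)                      # exact DDF of frames 0 -> 3
warped = ddfmod.warp_image(series.frames[3].red, d)
print(euler.ncc(series.frames[0].red, series.frames[3].red))  # before
print(euler.ncc(series.frames[0].red, warped))                # after
print(losses.nonrigid_penalty(d))

rois = {t: f.rois for t, f in enumerate(series.frames)}
reds = {t: f.red for t, f in enumerate(series.frames)}
regs = [tracking.Registration(moving=i, fixed=j, ddf=series.true_ddf(j, i))
        for i, j in itertools.combinations(range(8), 2)]
w = tracking.LinkageWeights.within_animal()
sim = tracking.build_similarity_matrix(regs, rois, reds, w)
clusters = tracking.cluster_rois(sim, w.w7, w.w8)
```

Output:

```
NCC before registration: 0.567
NCC after warping:       0.997
nonrigid penalty of DDF: 0.0001
clusters: 25 (25 cells planted); correctly linked ROIs: 200/200
GFP-positive fraction: 0.40; mismatch error rate: 0.0417
```

Reading the numbers: warping by the true field raises the frame-pair NCC
from 0.567 to 0.997 (1.0 would be pixel-identical), and the field's
nonrigid penalty is near zero because the bend is smooth. Clustering the
similarity matrix recovers exactly the 25 planted cells with all 200
ROI-timepoints linked to the right identity. The injected two-frame
identity swap between a GFP-positive and a GFP-negative cell surfaces in
the trace-consistency check: 4 mismatched samples out of 200, divided by
the detectability correction `2·Frac·(1−Frac) = 0.48`, gives the 0.0417
mis-registration rate — recovering the planted error level.

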