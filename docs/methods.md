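# Methods

## Problem and pipeline

`gliounet` segments intra-tumoral sub-regions of gliomas — peritumoral
edema, enhancing tumor and necrotic/non-enhancing core — from four
co-registered, skull-stripped MR channels (FLAIR, T1, T2, T1ce) at 1 mm
isotropic resolution on BraTS-style 240×240×155 grids. The pipeline is:

1. **Preprocessing** — derive the brain mask as the support of nonzero
   voxels (skull-stripped data has exact-zero background), then z-score
   each channel over in-mask voxels.
2. **Weighted patch extraction** — an equidistant lattice of 64³ seed
   patches over the zero-padded volume, filtered to patches with more than
   60% brain content, plus extra patches centred on a random 30% of
   whole-tumor boundary voxels.
3. **3-level 3D U-Net** with 48/96/192 feature maps, trained with
   multi-class soft Dice loss.
4. **Tile-based inference** — non-overlapping 64³ tiles of the padded
   volume, reassembled and cropped back to the input shape.
5. **Post-processing** — keep the largest 3D connected component of the
   whole-tumor mask (26-connectivity) and AND with the brain mask.
6. **Evaluation** — Dice, sensitivity, specificity and HD95 for the nested
   regions ET ⊆ TC ⊆ WT, with cohort aggregation
   (mean / SD / median / quartiles).

## Model

The network is a conventional encoder–decoder U-Net restricted to three
levels with an unusually wide feature progression (48, 96, 192). Each level
applies two zero-padded 3³ convolutions with ReLU; 2³ max-pooling
downsamples between levels; the decoder upsamples by nearest-neighbour ×2
followed by a 3³ convolution, concatenates the same-level encoder features,
and applies the same double-convolution block. A final 1×1×1 convolution
produces four logit maps fused by per-voxel softmax; the predicted label is
the argmax (ties resolve to the lowest class index). Dropout 0.25 follows
each encoder block during training. Batch normalisation is available behind
a config flag but off by default.

Intra-block layer count (2), the pooling operator and the upsampling
operator are deliberate defaults following the conventional U-Net design;
they are exposed in `UNetConfig` rather than hard-coded.

The layers are implemented directly on numpy (see `gliounet/nn.py`): a
deliberately dependency-light, fully deterministic CPU implementation.
Convolution is evaluated as one accumulating BLAS `sgemm` per kernel
offset on a flat position-major view of the zero-padded batch, which avoids
im2col buffers and keeps peak memory bounded on full-size inputs. Forward
passes with fixed weights are bit-reproducible on a fixed machine.

## Training

Loss: smoothed multi-class soft Dice, macro-averaged over the four classes,

    L = 1 − (1/4) Σ_c (2 Σ_v p_cv t_cv + ε) / (Σ_v p_cv + Σ_v t_cv + ε),

with ε = 1e-5 in numerator and denominator. Macro-averaging keeps the
~99%-background class from swamping the rare tumor classes; the smoothing
makes absent classes score 1 rather than 0/0. The exact smoothed form is a
design choice pinned here for reproducibility.

Optimizer: mini-batch SGD with momentum 0.9 (the momentum coefficient is a
conventional default, exposed in `TrainConfig`), batch size 8. The
learning rate starts at 0.001, is held through epoch 60 (inclusive), and is
stepped down once by ×0.1 for the remaining epochs of the 100-epoch
schedule — implemented as a single step because the schedule's rationale
(loss plateau at epoch 60) describes a step event. All shuffling and
dropout randomness flows from one seed in `TrainConfig`; two runs with the
same inputs produce identical loss histories on the same machine.

## Patch sampling choices

* 240 and 155 are not multiples of 64, so volumes are zero-padded on the
  high side to the next multiple of the patch size (240×240×155 →
  256×256×192, i.e. 4×4×3 = 48 tiles) before tiling, and predictions are
  cropped back. Zero is the semantically neutral fill for skull-stripped
  data. Extract-then-assemble is exactly the identity.
* The brain-fraction filter is strict (> 0.6): a patch at exactly 60% brain
  is rejected.
* The whole-tumor boundary is the "thick" 6-connected interface (voxels on
  both sides), computed with `skimage.segmentation.find_boundaries`; a
  brute-force neighbour scan in the test suite pins the semantics,
  including the in-bounds-only edge handling of that function.
* Boundary patches are centred on the drawn voxels (corner = centre −
  size/2) and clipped — not padded — into the padded grid. The draw is
  `round(0.3·|boundary|)` voxels, uniform without replacement, fully
  determined by the seed.
* The training inventory is the union of filtered grid seeds (default
  stride = patch size, configurable) and boundary patches; duplicate
  corners are kept on purpose — oversampling the boundary is the point.
  The 60% filter is not applied to boundary patches by default
  (configurable), since they exist precisely to represent boundary-heavy,
  sometimes background-heavy context.

## Post-processing

Connected components are computed on the binary whole-tumor mask rather
than per class, so a necrotic core disconnected from its enhancing rim
survives pruning. Connectivity is 26 (standard for 3D lesion analysis;
6/18/26 configurable). Size ties break to the first component in scan
order. The rule is known to be wrong for genuinely multifocal disease; a
`min_size_fraction` option keeps all components above a size fraction of
the largest instead, and the bifocal phantom demonstrates the default
behaviour (the smaller focus is erased in full).

## Metrics

Dice, sensitivity and specificity follow the standard voxel-count
definitions; Dice is exactly the F1 score, which the test suite verifies
against an independent implementation. Undefined cases (empty denominator
sets) return NaN sentinels; cohort aggregation scores them as 0 for the
overlap metrics by default (the challenge convention for a region predicted
but absent, or present but missed) with an exclusion policy behind a flag.
Undefined HD95 values are always excluded — no meaningful zero exists for
an absent surface.

HD95 extracts surface voxels (mask voxels with a 6-adjacent voxel outside
the mask; the array border counts as outside), computes directed
nearest-surface distances both ways via a KD-tree, and returns the maximum
of the two 95th percentiles (the challenge-tooling convention; a pooled
percentile variant is available). Distances honour anisotropic spacing.
Percentiles use linear interpolation; the cohort SD is the sample (n−1)
estimator, defined as 0 for a single case.

## Phantom generator

The phantom emulates the data regime the pipeline targets: four aligned
channels, exact-zero background outside a brain ellipsoid, nested tumor
topology (necrosis ⊂ enhancing rim ⊂ edema, so ET ⊆ TC ⊆ WT holds by
construction), qualitative MR contrasts (edema bright on FLAIR/T2,
enhancing rim bright and necrosis dark on T1ce), additive Gaussian noise
(σ = 0.03 against tissue contrasts of order 0.1–0.5) inside the brain, and
severe class imbalance — the full-size default (radii 11/18/27 voxels on a
240×240×155 grid) leaves ~99% of voxels non-tumor, matching real cohorts.
Interfaces are deformed by a smooth low-order directional perturbation
(±12% of the radius) so the network cannot learn a perfect-sphere prior;
the same field scales all interfaces of a focus, preserving nesting
exactly. A second focus (mirrored through the brain centre at 0.45 scale)
exercises the multifocal post-processing limitation.

What the phantom does **not** model: MR physics, bias fields, scanner and
protocol variation, anatomical texture, infiltrative margins, or
inter-rater label noise. Passing the desk-scale experiments therefore shows
that the pipeline's machinery is correct and that the weighted sampling
scheme behaves as intended under controlled conditions — not that the
reported BraTS-level accuracy transfers; that requires the real data and
full-scale training.

## Desk-scale experiment sizes

The validation experiments (`gliounet/experiments.py`) shrink every cost
axis while keeping the pipeline's structure: 96³ phantoms, 32³ patches, a
2-level U-Net with 8/16 features, ~194 training patches pooled from two
phantoms (a stride-16 seed grid — which contains every offset the
non-overlapping inference tiling uses — plus the 30% boundary draw
subsampled to 40 patches per phantom; an uncapped draw on a 96³ phantom
yields thousands), 10 training epochs, and a learning rate of 0.01 — with
only ~25 mini-batches per epoch the full-size rate of 0.001 would need far
more epochs, so the rate is scaled up and the single ×0.1 step decay is
kept near the end. The reduced net trains without dropout: the full-scale
rate of 0.25 removes too much of its small capacity. The boundary-sampling
comparison trains matched runs (same phantom, stride-16 seed grid,
architecture, optimizer, 4 epochs) with and without the boundary-weighted
patches and scores whole-tumor Dice inside a ±2-voxel band around the true
boundary, median over three seeds.

### Rare-class stabilizer

Pure soft-Dice interacts badly with softmax at small capacity: the
gradient reaching a class's logits is proportional to that class's
predicted probability, so a rare class whose probability collapses in the
first epochs receives vanishing updates and never recovers — on some seeds
the reduced net gets stuck predicting background only. `TrainConfig`
therefore exposes `ce_weight`, a small admixture of voxel-mean
cross-entropy whose logit gradient (p − t) does not vanish. The default is
0 (pure Dice, the reference behaviour); the desk-scale experiments use
0.3, which reliably un-sticks every class while Dice remains the dominant
objective. Larger admixtures (≥0.5) over-weight the background class and
destabilise training; 0.3 sits comfortably between the failure modes.

## Known limitations

* Training at the full 64³/48-feature scale on real cohorts is out of reach
  for a CPU-bound numpy implementation; the full configuration is exercised
  at forward-pass scale only.
* N4 bias-field correction is an optional pre-hook that shells out to an
  external executable when configured; it is never re-implemented.
* No data augmentation, overlapping-tile averaging, ensembling or
  validation-based early stopping — all deliberately out of scope.
* Checkpoints store raw float32 arrays with a JSON architecture sidecar;
  they are not portable to other frameworks.
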