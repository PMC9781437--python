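# Methods

## Problem setting

En-face OCTA projections of the retina show two vascular layers with very
different annotation regimes: the superficial vascular complex (SVC) is
annotated pixel by pixel, while the deep vascular complex (DVC) — thin,
dim, capillary-scale — is annotated only along 1-px centerlines.  Both
layers are heavily class-imbalanced (vessels are a small fraction of the
image), and thin deep vessels tend to come out of segmentation networks
with breakpoints.  The package implements a three-stage method for this
setting: a two-branch split-attention encoder–decoder trained with a
mean-squared-error plus global pixel-contrastive objective, and a
local-propagation refinement stage trained with Dice loss.

## Model

**Backbone.** A U-shaped encoder–decoder whose basic block is a
split-attention residual block: the input passes through `G = K x R`
grouped conv paths (`K` cardinal groups, `R` splits, each split a 1x1
conv+BN+ReLU followed by a 3x3 conv+BN+ReLU); within a cardinal group the
`R` split maps are fused by per-channel soft attention.  The attention
weights come from global average pooling of the fused map (`S_c`, the
spatial mean per channel), a two-layer bottleneck, and a per-channel
softmax across the `R` splits (`R > 1`) or a sigmoid gate (`R = 1`); a
residual shortcut (identity, or a 1x1 projection when shapes change)
closes the block.  Defaults are `K = 1, R = 2` as in standard
split-attention networks.

The SVC branch has five encoder/decoder levels, the DVC branch three.
The first three encoder levels are shared — the DVC branch's entire
encoder — which is the configuration that lets one encoder serve both
label regimes; decoders are private.  Downsampling is 2x2 average
pooling, upsampling nearest-neighbour, so each branch ends at full
resolution.  Each branch carries two heads: a 1x1-conv segmentation head
with a sigmoid (the task is binary), and a two-layer MLP projection head
(1x1 convs, `2D -> D`, ReLU between) on the penultimate decoder feature
at half resolution, followed by L2 normalisation.  Normalisation makes
the contrastive inner products cosine similarities, which is what a
temperature of 0.07 presupposes.

**Segmentation objective.** Per branch,

    L_obj = L_MSE + lambda_NCE * L_NCE,
    L_total = lambda_SVC * L_SVC + lambda_DVC * L_DVC.

MSE rather than cross-entropy/Dice because the regression form amplifies
small prediction errors on thin structures.  `lambda_NCE = 0.1`,
`lambda_SVC = lambda_DVC = 1` by default; none of the three is dictated
by theory, all are configurable.

**Global pixel contrastive loss.** For an anchor embedding `i` with
positive set `P_i` and negative set `N_i`,

    L_i = (1/|P_i|) * sum_{i+ in P_i} -log[ exp(i.i+/t) /
            (exp(i.i+/t) + sum_{i- in N_i} exp(i.i-/t)) ],

averaged over anchors, with temperature `t = 0.07`, computed with
max-subtraction for stability.  Anchors come from the current batch's
embedding maps; positives and negatives come from a memory bank, so the
loss sees same-class pixels from the whole dataset rather than one image.

**Memory bank.** Per class: a FIFO queue of at most `T = 400` sampled
pixel embeddings, plus one mean-pooled (re-normalised) class embedding
per training image.  Total capacity is `(N + T) x C x D` scalars for `N`
training images, `C = 2` classes per branch, embedding dimension `D`.
Each branch keeps its own pair of banks because the two branches label
different things (pixels vs centerlines).  Stored vectors are constants:
no gradient flows into the bank.  Per image and class, 32 pixels are
enqueued per step; the contrastive term is disabled for the first epoch
while the bank fills.

**Hybrid sampling.** Per anchor, 64 positives and 64 negatives: half are
the hardest available (negatives most similar to the anchor, positives
least similar, ranked by inner product at sampling time), half uniform
random from the remainder.  Pure hard mining over-focuses on degenerate
pairs; pure random sampling under-weights the confusable thin-vessel
pixels.

**Embedding-grid labels.** Embeddings live at half resolution, so mask
labels must be downsampled.  We use occupancy pooling — a cell is vessel
if any of its four pixels is vessel — rather than nearest-neighbour
subsampling: for a 1-px centerline, subsampling discards about half the
positive anchors and labels cells that do contain centerline pixels as
background, which feeds the contrastive term contradictory supervision
on the deep branch.  With occupancy labels the term's cost at desk scale
drops to about one Dice point (see the acceptance protocol).

**Refinement stage.** The two confidence maps and the original image are
fused into a 3-channel input.  The SVC path applies three 3x3 conv
layers, the DVC path two; the final layer emits `m^2 = 9` logits per
pixel which a per-pixel softmax turns into a normalised propagation field
`omega`.  The refined value is the convex combination of the pixel's 3x3
neighbourhood confidences, `Pred_i = sum_P omega_i^P f_i^P` (reflect
padding at borders, no edge repetition), so refined values never leave
the input range.  Training minimises Dice loss, `1 - (2*sum(PG)+s) /
(sum(P^2)+sum(G^2)+s)` with `s = 1e-6`, against the clean masks, with
the backbone frozen.  The refined branch maps are merged by pixelwise
max and thresholded at 0.5 into one binary vessel image.

**Metrics.** ACC, G-mean, Kappa, Dice and FDR from confusion counts, and
AUC as the fraction of correctly ranked (positive, negative) score pairs
with ties counting one half — the Wilcoxon–Mann–Whitney statistic; a
strict-inequality mode is available.  Predictions against centerline
ground truth are evaluated inside a 2-px tolerance band (a predicted
pixel within 2 px of the centerline is a true positive; a centerline
pixel with no prediction within 2 px is a false negative), because exact
overlay against a 1-px medial axis is ill-posed.  Metrics with a zero
denominator are reported as `nan`, never silently as zero.

## Synthetic phantoms

The generator emulates the features of en-face OCTA acquisitions that
the method depends on, at arbitrary size:

* **Vessel geometry.** Each tree is a random recursive branching walk:
  a border start heading inward, unit steps with Gaussian heading jitter,
  1–3 branch events forking at 20–60 degrees.  The rasterised walk gives
  an exact 1-px, 8-connected centerline by construction (staircase
  corners pruned), so deep-layer ground truth needs no skeletonisation.
* **Two depth layers.** Superficial trees are rendered 2–6 px wide and
  bright (0.7–1.0); deep trees 1–2 px wide and dim (0.3–0.6) over a
  smooth background around 0.12, giving the contrast ordering
  SVC > DVC > background that the method assumes.  The SVC mask is the
  full rendered ribbon (pixel-level); the DVC mask is only the
  centerline.
* **Artifacts.** Multiplicative Gaussian speckle (sigma 0.1) and
  row-wise sinusoidal gain stripes (amplitude 0.15, random period 8–24
  rows) mimicking motion/projection artifacts.  Artifacts apply to the
  image only, never to masks.

Datasets are split 7:3 into train/validation, deterministic per seed.

What the phantoms do *not* model: 3-D volumes and projection, real OCTA
intensity statistics (the contrast levels are design choices, not
calibrated to any instrument), pathology (drusen, non-perfusion), vessel
caliber tapering, and inter-image intensity variation.  Passing the
desk-scale protocols therefore shows that the implementation learns and
refines two-layer curvilinear structure under speckle and stripe noise —
not that it reaches any particular accuracy on clinical data.

## Training configuration

Full-scale defaults mirror the reference configuration: Adam with
learning rate 5e-4, weight decay 1e-4, batch 16, 200 epochs each for the
segmentation and refinement stages, temperature 0.07, bank length 400.
The *tiny preset* used by the tests and the acceptance script scales the
problem to one CPU: 8 base channels, embedding dimension 16, batch 4,
30 epochs, learning rate 2e-3.  The higher step size is deliberate: from
random initialisation at batch 4, the deep branch needs roughly 45
epochs at 5e-4 to leave the all-background regime of the imbalanced MSE
objective; at 2e-3 both branches converge within the 30-epoch budget.
Segmentation heads are initialised with down-scaled weights so the
initial sigmoid output sits near 0.5 — a saturated head at
initialisation can trap training in the all-background minimum.

All randomness (weight init, shuffling, augmentation, pixel sampling)
derives from one root seed through independent generator streams, so a
fixed seed reproduces every logged number on the same hardware.

## Desk-scale protocols

* **Segmentation protocol** (`experiments.segmentation_experiment`):
  40 phantoms at 64x64, tiny preset, 30 epochs; reports held-out Dice
  per branch (pixel-level SVC, tolerance-band DVC) at the best-validation
  epoch — the epoch whose checkpoint the trainer retains, matching the
  record-the-highest-score convention.  Run with the contrastive weight
  at 0.1 and 0, the same protocol measures the term's marginal effect.
* **Gap-refinement protocol** (`experiments.gap_refinement_experiment`):
  24 phantoms; ground-truth masks corrupted with twenty 1–3 px gaps per
  image stand in for an imperfect segmentation; the refinement stage is
  trained for 200 epochs (the full-scale stage length) to restore the
  clean masks and is evaluated on held-out images by pixel-exact Dice
  (the tolerance band would hide exactly the damage being repaired) and
  by the skeleton-endpoint count of the deep map.  A 3x3 one-step
  propagation can only bridge gaps adjacent to surviving vessel pixels,
  so wide gaps shrink rather than close; the expected effect is a
  modest Dice gain and a reduction, not elimination, of endpoints.

## Numerical choices

* Engine: reverse-mode autodiff over numpy in float32, with fused
  batch-norm gradients and numba direct kernels for 3x3 convolutions
  (generic im2col fallback, cross-checked in tests).  Loss oracles and
  all reported metrics are computed in float64.
* Softmaxes (attention, propagation, contrastive loss) use
  max-subtraction.
* AUC ties count 0.5; the strict mode implements the literal
  strict-inequality count.
* Binarisation threshold 0.5 everywhere a binary map is needed; AUC uses
  raw probabilities.
* Rotations restricted to multiples of 90 degrees and flips, so
  augmented masks stay exactly binary; crops are joint across image and
  masks.
* CLAHE is applied to a fixed region of interest only (default: the
  central 50% x 50% window, where deep-layer detail concentrates) and
  computed on the crop alone; a constant crop is returned unchanged.
  The clip limit accepts the common 8-bit convention (values > 1 are
  mapped onto the normalised clip fraction).
* Inputs whose sides are not multiples of 16 are reflect-padded for the
  forward pass and cropped back; sizes >= 32 never error.
* Degenerate cases: an anchor with an empty positive set is excluded
  from the contrastive loss (all excluded -> loss 0); an empty vessel
  class makes AUC undefined (signalled), not 0.

## Known limitations

* One aggregation step with m = 3 bounds what refinement can repair;
  gaps wider than ~2 px persist (visible in the gap protocol's
  endpoint counts).
* Centerline-level supervision at half-resolution embeddings remains
  approximate even with occupancy labels; the contrastive term still
  costs ~1 Dice point at desk scale, consistent with it being a
  regulariser whose benefit the full-scale setting (longer schedules,
  pretrained encoders, real data) is designed to realise.
* The engine is single-CPU and float32; it is not a general-purpose
  deep-learning framework and implements exactly the ops this
  architecture needs.
* Checkpoints serialise with pickle and are not portable across package
  versions (a version tag guards against silent mismatch).
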