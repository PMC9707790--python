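# Methods

`colonyseg` implements a complete, headless workflow for instance
segmentation of microbial microcolonies in 2-D microscopy frames: synthetic
training data, two trainable label representations, encoder–decoder
networks, seeded-watershed instance recovery, AJI+ evaluation with
automatic threshold selection, and result export with per-frame cell
statistics.  This note documents the models, the defaults and why they were
chosen, the numerical choices, and the limits of what the synthetic tests
demonstrate.

## Segmentation methods

Two methods share a U-Net backbone and differ in what the network predicts
and how instances are recovered.

**Boundary method.** The network predicts a 3-class semantic map —
background, cell interior, cell boundary — with a softmax head.  A
foreground pixel of the training target is *boundary* iff its
8-neighborhood contains background or a different instance id, so touching
instances are separated by a two-pixel-wide boundary band.  Instances are
recovered by flooding interior components over the boundary-probability
map (seeded watershed restricted to the predicted foreground).  Trained
with cross entropy + channel-wise Dice (weights 1:1, Dice smoothing 1.0).

**Distance method (default).** Two decoders regress

* the *cell distance*: per-instance Euclidean distance to the nearest
  pixel outside the instance, normalized per instance to (0, 1] (every
  cell peaks at 1, independent of its size);
* the *inverse neighbor distance*: for a pixel at distance `d` from the
  nearest pixel of a *different* instance,
  `clip(1 - d/cutoff, 0, 1) ** gamma` — a ridge that is high exactly where
  cells meet.

Trained with a smooth-L1 loss (transition `beta = 1`), summed over the two
maps.  Instances are recovered by thresholding the cell distance at
`th_cell` (foreground), extracting seeds as connected components of
`cell - alpha * neigh > th_seed` (`alpha = 1`, minimum seed area 4 px), and
growing seeds by watershed on `-cell` inside the foreground;
foreground components that received no seed become instances on their own
when at least `min_cell_area = 2` px.  Defaults `th_cell = 0.09`,
`th_seed = 0.45` are used for models that have not been evaluated yet.

### Neighbor-map shape: cutoff and gamma

The defaults are `gamma = 3` and `cutoff = 1.0 x` the median instance
minor-axis length of the training set (recomputed once per training set,
`labelrep.default_cutoff_radius`).  The cutoff choice is load-bearing: for
thin rods, a cutoff much larger than the cell width leaks neighbor signal
onto the cell midline (a rod's skeleton is only ~w/2 from a side contact),
the seed map `cell - neigh` dips below `th_seed` inside single cells, and
the watershed over-segments.  With the cutoff at about one cell width the
ideal-target round trip (targets computed from ground truth, then
post-processed) recovers the exact cell count in 20/20 dense synthetic
colonies with mean per-object IoU > 0.99; at `3 x` the median minor axis it
recovers only 3/20.  Both parameters are exposed in the API.

## Network

U-Net with `depth = 5` resolution levels, two 3x3 convolution + batch norm
+ ReLU layers per level, channel doubling, 2x2 max pooling, 3x3 stride-2
transposed-convolution upsampling, skip concatenation, He initialization.
The boundary network has one decoder (3-channel softmax head); the distance
network has two independent decoders (1-channel linear heads) sharing the
encoder.  At the full width of 64 first-level filters this is 34.5 M
trainable parameters (single decoder) and 50.2 M (double).  Given a
parameter budget, the first-level width is walked down 64 → 48 → 32 → 24 →
16 until the exact parameter count fits; 16 is the floor, corresponding to
2.16 M / 3.14 M parameters.  Budgets below the floor (2 M single, 3 M
double) are rejected.

Inputs are normalized per image by percentile scaling (1st percentile → 0,
99th → 1, clipped), which is agnostic to intensity polarity (dark cells in
phase contrast vs bright cells in fluorescence).  Spatial dimensions must
be divisible by `2^(depth-1) = 16`; inference reflection-pads and crops
back.

The network engine (`colonyseg.nn`) is a compact NumPy implementation:
convolutions are evaluated as k² channel-mixing matrix products on shifted
views of the padded input, so the heavy lifting stays in BLAS; backward
passes are hand-derived and verified against finite differences in the test
suite.  Transposed convolution is implemented as zero-stuffing followed by
a valid correlation with the flipped kernel.

### Batch-norm statistics ("precise BN")

With few, small batches per epoch, momentum-averaged running statistics lag
badly: early in training eval mode still sees near-initialization statistics,
the outputs collapse toward zero, and — because the regression targets are
mostly zero — the validation loss of this degenerate predictor is *lower*
than that of a genuinely learning network.  Best-weight selection, the
plateau scheduler and early stopping then all lock onto that phantom
optimum.  The trainer therefore replaces the running statistics after every
epoch by the average of the batch statistics actually seen in that epoch
before computing the validation loss.

## Training

Defaults: distance method, Ranger optimizer (RAdam + Lookahead, k=6,
alpha=0.5), five models per run, batch size four.  Optimizer presets:
Adam with start learning rate 8e-4, Ranger with 6e-3; both use
reduce-on-plateau (factor 0.25, patience `max(5, epochs_max // 12)`, floor
6e-5) and early stopping once the best validation loss has not improved by
more than 1e-4 for `max(10, epochs_max // 8)` epochs.  The best-validation
weights are kept.  The epoch budget adapts to the data:
`clip(round(1120 / n_train_crops), 40, 200)`, scaled by `128 / crop_size`
and floored at 20.  All of these constants are configuration fields.

Augmentations per draw: horizontal/vertical flip (p = 0.5 each), rotation
by k·90°, scaling in [0.85, 1.15] (nearest-neighbor on the mask, with the
training target recomputed from the transformed mask so distance maps stay
geometrically valid), multiplicative contrast in [0.7, 1.3], Gaussian blur
σ ∈ [0, 1.5] px, additive Gaussian noise up to 5 % of the intensity range
(photometric transforms touch the image only).

New crops are assigned to train/validation/test by a deterministic greedy
largest-deficit rule with target fractions 0.600 / 0.225 / 0.175 (ties:
train > val > test), which yields an 8/3/2 split after 13 crops and 13/5/4
after 22; an explicit assignment override exists.

## Evaluation and model selection

AJI+ compares instance masks by matching predicted and true objects
one-to-one so that the total IoU is maximal (Hungarian assignment on the
pairwise IoU table; zero-IoU pairs are never matched), then divides the
aggregated matched intersection by the aggregated matched union plus all
unmatched object areas.  Conventions pinned here: both masks empty scores
1.0 (perfect agreement on "no cells"); exactly one side empty scores 0.0;
the reported standard deviation over test images is the population (N)
form.  For distance models the evaluation sweeps
`th_cell ∈ {0.05, 0.07, 0.09, 0.11, 0.13}` ×
`th_seed ∈ {0.35, ..., 0.60}` on the internal test split and keeps the pair
with the highest mean AJI+ (ties: lower `th_cell`, then lower `th_seed`).
The best model is the one with the highest mean AJI+ (ties: lower std, then
lexicographic id); a manual override is supported.

## Synthetic data

The generator emulates dense microcolonies of rod-shaped bacteria: cells
are spherocylinders (optionally bent along a circular arc), rasterized at
4x supersampling, placed by rejection sampling against an occupancy mask so
instances may touch but never overlap (half of colony placements are
allowed direct contact; the rest keep a 1-px gap).  `phase` renders dark
cells with a bright halo on a mid-gray textured background; `fluor`
renders bright, roundish nucleus-like blobs on a dark background.  Both
apply Gaussian PSF blur then additive Gaussian noise, and write 16-bit
images.  Time-lapse mode elongates cells per frame (growing toward a free
end when symmetric elongation is blocked) and divides them into two
daughters once the midline exceeds 1.6x the maximum sampled length, so
counts are non-decreasing and masks stay overlap-free.

Defaults (256² px, 30 cells, length 12–22 px, width 5–8 px, curvature 0.25,
PSF σ = 1 px, noise 3 % of range) are sized to a 100x-objective view of a
young colony.  What the generator does *not* emulate: halo physics and
shade-off of real phase contrast, debris and microfluidic-device structures
in the background, focus drift, cell motility, overlap, and annotation
noise.  Passing the synthetic end-to-end tests therefore demonstrates that
the pipeline is self-consistent and trainable, not that real-data accuracy
figures transfer.

## Scaled-down study sizes

The test suite trains one budget-reduced distance model (3 M parameter
budget → 3.14 M parameters) on 24 synthetic 128-px crops (14 train / 6 val
/ 4 test by the automatic split) for at most 30 epochs with early stopping
disabled inside that small budget, then grid-searches thresholds on 8
held-out colonies.  This configuration reaches mean AJI+ well above 0.5,
which is the smoke bar used in the tests; full-size training on real data
is out of scope here.

## Known limitations

* No overlapping objects: the representations and the watershed assign each
  pixel to at most one instance.
* 2-D only.
* The NumPy engine trains small networks on CPU in minutes but is not meant
  for full-size (34–50 M parameter) training runs.
* Boundary-method accuracy trails the distance method on touching rods,
  matching its role as the simpler baseline.
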