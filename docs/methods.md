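# Methods

## Setting and model

The package operates on square RGB tiles cut from H&E-stained tissue
images. Five classes are fixed throughout, in this canonical order: HLN
(healthy lymph node), HP (healthy pancreas), PDAC (pancreatic ductal
adenocarcinoma), ADI (adipose), BG (background/glass). Every score vector
and confusion-matrix axis uses this order; argmax ties resolve to the
lowest class index and are logged.

The core procedure is label purification of one "new" class at a time by
two cross-trained classifiers against a reference dataset that supplies the
contaminant classes. The reference must contain ADI and, in this
implementation, also BG: the final sweep emits both labels, so some model
must know both. Per cycle, Communicator 1 (trained on reference ∪ current
Data A tiles labeled as the target class) filters the tiles of a disjoint
B-image subset by plain argmax; Communicator 2 (trained on reference ∪ the
filtered Data B) filters Data A. Filtering never adds tiles, so the Data A
tile set shrinks monotonically. The A-image subset is fixed when the loop
starts (this is what makes the monotonicity invariant meaningful); the
B-image subset is redrawn each cycle from the class's remaining images by
default, with a fixed-subset ablation mode. Subset size is k = 20 images
per side, falling back to floor(n/2) with a warning on small cohorts.

The 0.55 softmax threshold applies only to the final sweep, not to
per-cycle filtering: for every tile of a parenchymal image, the class's
final communicator either discards it (top softmax below threshold,
status `discarded_unclassifiable`), moves it (predicted ADI/BG, status
`moved_to_ADI`/`moved_to_BG`, label rewritten), or keeps it. Kept + moved +
discarded counts equal the input count per image; the audit is exposed as
`conservation_check`. Discarded tiles are excluded from downstream training
by default (a flagged alternative keeps them under their original label).

## Preprocessing conventions

- 40x images are resized to 50% linear size with floor dimensions and
  bilinear interpolation; 20x images pass through.
- Tiling is a non-overlapping grid of full tiles; partial edge remainders
  are discarded, never padded. Coordinates are 0-based, half-open, (row,
  col) grid order, recorded in every manifest.
- The bright-tile cutoff (default 239) removes a tile when its mean
  intensity over all pixels and channels exceeds the cutoff; a
  fraction-of-bright-pixels statistic is available behind the same flag.
  The mean convention makes the filter monotone in the cutoff.
- Cross-size transfer: a 299 px tile is labeled through its 224 px center
  crop at offset floor((299−224)/2) = 37 on both axes; label and status
  propagate back to the parent by grid coordinates.
- Stain normalization is Macenko-style: optical density OD = −log((I+1)/256),
  tissue pixels selected by an L2-norm mask whose threshold adapts to the
  stained-pixel distribution (max(0.15, 0.2·P90 of OD norms) — the adaptive
  part makes the estimator stable under global stain-intensity scaling and
  near-idempotent), stain plane from the top two eigenvectors of the OD
  scatter, stain vectors at the 1st/99th angle percentiles, non-negative
  concentrations by least squares, 99th-percentile concentration rescaling
  to a fixed published H&E reference matrix. Tiles with fewer than 30
  tissue pixels (glass, fat) are returned unchanged with a logged warning.
  Both per-tile and whole-image ("in toto") normalization are supported and
  mapped one-to-one by grid coordinates, so statuses decided on one
  representation transfer to the other.

## Classifiers

Training runs on CPU with a transfer-learning structure authored in
numpy/scipy: a frozen convolutional stem — a deterministic bank of
zero-mean unit-norm 3×3 filters plus pooled color, gradient and
bright/dark-fraction statistics — feeding a small fully connected softmax
head. Only the last `layers_to_retrain` dense blocks (default 3 = the whole
head) are updated; the stem is a pure function of the backbone spec and is
bit-identical before and after fitting. Global pooling makes the stem
input-size agnostic; each fitted model records the tile size it saw and
refuses differently sized inputs. The registry ships `small_cnn` (default),
`wide_cnn` (twice the filters and hidden width, for backbone-pluggability
checks) and `inception_small` (299-native, for cross-size transfer). The
loop's bookkeeping is identical under any backbone.

Optimization is minibatch cross-entropy with Adam (default), SGD with
momentum, or RMSprop; the learning rate decays by 5% every five epochs
(epoch e uses lr·0.95^⌊e/5⌋, 1-indexed); training stops when validation
loss fails to improve for `early_stop_patience` epochs (default 5) and the
best-validation-loss checkpoint is returned. Class balancing upsamples
minority classes to the majority count by sampling with replacement
("random doubling"; a strict-doubling mode exists) — applied after
splitting, to the training set only, so duplication never leaks across
splits. Gaussian-blur augmentation (σ ∈ [0.1, 2], applied with probability
0.5 per sample per epoch) is on by default. `TrainConfig` defaults keep the
classic fine-tuning values (lr 1e-4, batch 150, 100 epochs); the desk
profile used by the communicators and experiments (`DESK_CONFIG`: lr 3e-3,
batch 64, ≤ 40 epochs) is the standard regime for a small MLP head — the
1e-4 protocol is tuned to fine-tuning large pretrained CNNs, which is not
what runs here.

Splits are subject-level (a subject never appears in two splits),
stratified per class at 80/10/10 within ±1 subject; a single-subject class
goes entirely to train with a warning.

## Scores

One-vs-rest confusion metrics per class: precision TP/(TP+FP), recall
TP/(TP+FN), F1 = 2TP/(2TP+FP+FN), Jaccard = TP/(TP+FP+FN); accuracy =
trace/total; macro = unweighted mean, weighted = support-weighted mean.
Zero-denominator cases score 0 and are flagged. The identities
F1 = 2PR/(P+R), J = PR/(P+R−PR) = F1/(2−F1) are exposed as helpers and hold
to 1e-9 on count data.

The classification score vector of an image with M patches is
c_i = (#patches predicted i)/M; the image label is argmax(c). The
three-score averages c_true-class over the test images of each parenchymal
class and then over the three classes; a class without images is excluded
with a warning. The four-score compares model and expert average fractions
over four validation groups (HLN, HP, PDAC, LNPM); the LNPM group is scored
on its PDAC fraction (detection of metastases in lymph nodes). The gap
m_i is computed from the *mean* over the group's N_i images: summing c_i
over images without dividing would let m_i exceed 1 for N_i > 1 and make
the score meaningless, while the mean keeps m_i commensurable with the
expert fraction p_i regardless of group size. An explicit exclusion list
drops insufficiently annotated images before averaging; an empty group is
an error naming the group.

## Synthetic cohorts

The generator emulates the *structure* of a TMA tile study, not its
appearance: each class is a parametric texture (noise + geometric
primitives) — dense dark nuclei for HLN, acinar blob clusters for HP,
irregular duct rings with pale lumens for PDAC, near-white vacuoles with
thin rims for ADI, near-white noise (channel means > 230) for BG. Identical
(spec, seed) pairs render bit-identical tiles. Parenchymal mosaics carry
exactly round(rate · n_positions) contaminant positions drawn uniformly
from {ADI, BG}; every tile's true class is emitted as a sidecar CSV
manifest, never embedded in pixels. One subject per image by default
(mirroring one spot per patient). A separate validation generator produces
grouped images — including LNPM mosaics, lymph-node fields with a planted
PDAC fraction in [0.25, 0.6] — whose expert annotation is the exact tile
fraction table.

Desk-scale study conditions, used by the test suite and the reproduction
script: 32 px tiles on 128 px mosaics (16 positions/image), 16 images per
class, contamination rate 0.25, 3 purification cycles, 5 seeds, `small_cnn`
backbone; validation groups sized HP 3 / PDAC 15 / HLN 5 / LNPM 6 with 10%
contamination. The standalone tile renderer defaults to 224 px, and the
cross-size experiment runs at the real 299/224 sizes.

What passing on this generator does and does not show: the textures are
linearly separable on simple pooled features by design, so the tests verify
the *mechanics* of purification — bookkeeping, monotone enrichment,
threshold semantics, conservation, the structural advantage of learning the
contaminant vocabulary — under conditions where classifier capacity is not
the bottleneck. They do not certify performance on real H&E tiles, where
class boundaries are soft, staining varies beyond a global profile, and
contaminants are not texture-pure. The cleaned-vs-raw comparison in
particular reflects a vocabulary gap (the raw baseline has no
ADI/BG classes and cannot be right on contaminated positions); with
trivially separable textures, a baseline *given* clean ADI/BG training
classes would absorb the label noise and show no gap.

## Numerical choices and degenerate inputs

- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; a master seed drives subset selection,
  initialization and data order, and reruns reproduce manifests and metric
  files byte-identically.
- Early stopping uses a 1e-9 improvement tolerance; a constant-loss run
  stops after patience + 1 epochs.
- Empty training/validation sets, single-class training pools, images
  smaller than the tile size, grid mismatches in tile mapping, thresholds
  outside (0, 1), and missing four-score groups are all hard errors with
  the offending object named; an image yielding zero tiles is logged, not
  fatal.
- The purification loop raises if filtering empties Data A entirely, with
  advice to review threshold/backbone.
- Softmax rows are validated to sum to 1 within 1e-6 in tests; argmax uses
  numpy's first-maximum convention, which implements the lowest-class-index
  tie rule.

## Limitations

- Backbones are small frozen-stem + MLP-head models built for CPU
  determinism; no GPU-scale pretrained CNNs are bundled, and absolute
  accuracies are not comparable to fine-tuned ImageNet networks on real
  slides.
- The contaminant vocabulary is fixed by the reference dataset; the loop
  cannot discover new contaminant classes.
- Stain normalization assumes a two-stain (H&E) model; it passes
  non-tissue tiles through unchanged rather than attempting correction.
- Proprietary whole-slide formats are out of scope; inputs are
  pre-exported PNG/TIFF-like arrays.
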