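# Methods

This note documents the models, the synthetic data they are exercised
on, the numerical choices, and what the package's tests do and do not
establish.

## Diagnosis pipeline

**Classes and class logic.** Four diagnostic classes in severity order
MMD < MIS < T1a < T1b (MPATH-Dx categories with the two lowest-risk
classes merged). The pipeline leans on one clinical fact throughout:
melanoma dermal nests (DMN-M) occur only in invasive cases — any DMN-M
would move a case to T1a/T1b — so every dermal nest on an MMD or MIS
case is a nevus nest (DMN-N).

**Mask fusion.** Integer-coded tissue masks (code table BG=0, COR=1,
EP=2, DE=3, EPN=4, DMN-N=5, DMN-M=6; DMN is the derived union {5,6})
are binarized per tissue and appended to the RGB raster as extra
channels. Mask channels enter the network as floats in {0,1} with no
mean/sd normalization — binary semantics are preserved — while RGB is
standardized per channel with training-split statistics. Nest codes are
exclusive of the stratum codes (a nest pixel is coded nest, not
epidermis/dermis); the six exclusive code sets partition every pixel.
Coordinates are 0-based row-major, origin top-left; rectangles half-open.

**Dermal-nest typing.** 100×100 windows (at the nominal 20× base) slide
over the slice at a configurable stride; a window with at least 5% DMN
coverage (configurable; the window must contain at least one nest
pixel) is emitted with all non-nest pixels zeroed. The training pool is
rebalanced by relabeling segmented DMN on benign-class cases as DMN-N
and sampling from that pool without replacement until the label counts
match; if the pool is too small the majority class is subsampled down
and the shortfall logged. The classifier is a small CNN (two strided
3×3 convolutions, global average pooling, linear head) trained 20
epochs with Adam at lr 0.001 and cross-entropy, with random 90°
rotation, horizontal flip, pad-and-crop shifts and per-channel
normalization. Melanoma is the positive class in the binary metrics.
The large pretrained backbones of full-scale studies (DenseNet,
ShuffleNet, ResNet) are named in the API but require pretrained weights
that are not bundled, so they raise; the self-contained `tiny` backbone
is the supported path. At inference, `split_dmn` labels 100×100 tiles
(stride 100, final tiles anchored to the borders so all pixels are
covered) and assigns DMN pixels of melanoma tiles to DMN-M; **nevus is
the complement**, so the two output masks partition the input exactly,
and rasters smaller than one window default entirely to DMN-N —
melanoma must be positively detected.

**Multi-scale features.** Slices are declared 20×; working scales are
produced by resizing with factors 7.5/20, 10/20, 12.5/20 (bilinear for
RGB, nearest-neighbour + re-threshold for mask channels, so binarity
survives the pyramid). Each scale is cut into a fixed grid — 5×5 at
7.5×, 7×7 at 10×, 9×9 at 12.5×. Only the 5×5 and 9×9 grids are fixed by
the published description; 7×7 follows the evident arithmetic
progression and is recorded here as an inference. Tiles are near-equal:
remainder pixels go to the last rows/columns, sizes differ by at most
one pixel, and reassembling the tiles reproduces the image exactly
(exact tiling was preferred over padding because it makes the
reassembly property testable). The patch encoder maps a C-channel patch
(C ≥ 3) to a 1280-d vector by global average pooling over its final
feature map. The package's encoder is a compact randomly initialized
CNN honouring that contract; when 3-channel pretrained first-layer
kernels are supplied, extra channels receive the mean of the RGB
kernels, so an all-ones mask channel perturbs activations at the scale
of an average colour channel.

**Embedding standardization.** Patch embeddings are standardized per
dimension and per scale with training-half statistics before entering
the aggregator. A large pretrained backbone yields well-conditioned
features out of the box; the compact random-init encoder does not, and
the aggregator's optimization stalls on raw features. This is numerical
conditioning of the feature store, not part of the model.

**Aggregator.** A shared linear projection takes 1280 → 128. Per scale:
learned positional embeddings are added, a learned scale token is
prepended, and the sequence passes through a stack of two transformer
units, each with 4-head self-attention and feed-forward width 512
(post-norm residual blocks). The scale summary is the token output. The
cross-scale stage adds learned scale embeddings and reuses the same
2-unit/4-head/512 geometry with its own weights (whether the published
model shares weights across the two stages is not stated; separate
weights are the package's choice), then mean-pools and applies a linear
head. Test mode can disable the positional signal, making the forward
pass permutation-invariant over patches.

**Soft labels.** Cases hold several slices but carry one diagnosis, and
only one slice bears the expert ROI; the others may show milder
histology. The ROI slice is labeled one-hot at the case class. Each
other slice gets `α·onehot(case class) + (1−α)·onehot(MMD)` where α
compares the slice to the ROI slice along the first singular direction
of the centered slice-feature matrix: equal-sign projections give α=1,
opposite sign α=0, a vanishing projection α=1/2 (two vanishing
projections: α=1, the slices being indistinguishable along that
direction). The cosine of two 1-D projections is their sign, so α is
discrete — a deliberate, degenerate-safe stand-in for the published
SVD scheme whose exact construction is external to this package; it is
pluggable (`strategy="svd" | "onehot"`).

**Training.** Adam minimizes cross-entropy against the soft label
distributions for 200 epochs at full scale; the learning rate warms up
linearly over 5% of the epochs (epoch 0 at lr_max/warmup) and halves
every 25% of the epochs after warmup (the schedule *shape* is
published; these constants are package defaults). After every epoch a
checkpoint is scored by case-level validation micro F; the final model
is the elementwise mean of the best five checkpoints, ties broken
toward the later epoch (more-trained weights).

**Evaluation.** Max-voting takes the most severe slice prediction as
the case diagnosis (implemented as severity-argmax per the rule "one
invasive slice makes the case invasive"; a majority-with-severity-
tiebreak variant exists for sensitivity analysis). Micro metrics follow
the five aggregate formulas; zero denominators report 0 with a flag.
Specificity aggregates one-vs-rest true negatives (TN_sum + FP_sum =
(K−1)·N), the reading under which the formula is well defined for
multi-class data. Multi-seed experiments vary only the training seed —
the case-level data split and the fit/validation subsplit are fixed —
and report average/min/max/median micro F plus mean sensitivity and
specificity.

## Synthetic data generator

The generator emulates the *statistical structure* the pipeline
assumes, not histology appearance: horizontal strata (10% background,
10% stratum corneum, 22% epidermis, 58% dermis of the slice height),
disk-shaped nests (radius 8–11 px) placed uniformly inside their
stratum, per-tissue mean RGB colours with Gaussian noise (sd 8), and
exact integer ground-truth masks. Defaults (per 192×192 reference
area): epidermal nests 2/8/5/5 for MMD/MIS/T1a/T1b, total dermal nests
8 for every class, of which 0/0/2/6 are DMN-M. Choices of note:

* **MIS > MMD in EPN density** and **T1b > T1a in DMN-M density** give
  every adjacent class pair a learnable signal.
* **Total dermal-nest count is class-constant.** With
  `decoy_contrast = 0` the two nest types share one RGB appearance, so
  the RGB image carries *no* T1a/T1b signal at all — the DMN-M mask
  channel is the only route. This turns the mask-benefit claim into a
  controlled, falsifiable property. The default `decoy_contrast` is
  0.25 (mildly visible), 1.0 makes nest type fully visible in RGB.
* Cases have 1–4 slices (uniform; real per-case slice counts are not
  published — this is a recorded guess). Exactly one slice is rendered
  at the case severity and carries the ROI (the bounding box of its
  nest pixels); other slices draw a severity at or below the case's,
  exercising soft labels and max-voting.
* Class proportions default to the study cohort's distribution after
  the class merge (61/60/72/47 of 240); counts use largest-remainder
  rounding, and the 50/50 case split preserves per-class counts to
  within one case.
* Everything is deterministic in (config seed, case seed): identical
  inputs give bit-identical rasters.

What passing tests on this data do **not** show: robustness to stain
variation, scanner artefacts, imperfect segmentation masks, realistic
nest morphology, or the absolute accuracy levels attainable on real
cohorts. The synthetic study establishes that the pipeline's machinery
— fusion, class-logic relabeling, aggregation, voting, metrics — is
correct and that mask channels are used when they carry signal.

## Profiles and problem sizes

The full-scale profile (200 epochs, multi-scale) mirrors the published
training budget and is available but not exercised by the test suite.
The desk profile — identical geometry, 30 epochs, single 7.5× scale,
60-case cohorts, the `tiny` encoders — is the package's own CPU-scale
study size used in tests and in `scripts/acceptance.py`. Under it the
mask-benefit experiment (3 seeds, `decoy_contrast = 0`) yields mean
test micro F ≈ 0.91 with EPN + DMN-M channels versus ≈ 0.56 for RGB
alone, reproducing the direction of the published full-scale gap from a
much easier, fully separable task.

## Numerical choices and degenerate inputs

* All tensors float32; computation is single-threaded NumPy, so seeded
  runs are bit-reproducible.
* Masks with codes outside the declared table are rejected listing the
  offending codes; non-grayscale PNGs are rejected as masks.
* Nest sampling on rasters smaller than one window warns and returns an
  empty list (not an error); `split_dmn` on such rasters returns
  all-nevus.
* Largest-remainder ties break toward the lower class index; odd
  per-class counts alternate which split half receives the extra case.
* Checkpoint-score ties prefer the later epoch; fewer than five
  checkpoints average all with a logged note.
* Zero metric denominators report 0 and set a flag rather than raising.
* The embedding-standardization floor (sd clipped at 1e-6) can leave a
  near-constant dimension with sub-unit variance; this is harmless.

## Known limitations

* The soft-label α is sign-discrete (see above); a continuous scheme
  would need the exact external construction.
* The random-init encoders are contracts-faithful stand-ins; absolute
  activations of pretrained backbones are out of scope.
* Slide-to-slice extraction from scanner files, stain normalization and
  the production of segmentation masks from RGB are out of scope: masks
  are inputs here.
* The 10× grid side (7×7) is inferred, not published.
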