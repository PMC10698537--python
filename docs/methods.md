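# Methods

This note documents the models and procedures implemented in `phccsurv`, the
parameters that matter, the design decisions taken where the design was
genuinely open, and what the synthetic-data experiments do and do not show.

## Synthetic slide generator

A slide is a procedural stand-in for a scanned H&E section with
pathologist-annotated tumor nests. Region layout thresholds smoothed Gaussian
noise fields at quantiles, which produces irregular blob shapes while pinning
realized area fractions to the requested ones (the tumor-mask mean is within
a fraction of a percent of `tumor_fraction`): the brightest
`background_fraction` of a low-frequency field becomes near-white background
(luminance > 0.9), and the top `tumor_fraction` (rescaled to tissue area) of
a second field — biased by `n_tumor_blobs` Gaussian bumps that seed nest
locations — becomes tumor. Textures: non-tumor tissue is a smooth eosin-pink
stroma (mean luminance ~0.63); tumor tissue is darker (a drop scaling with
`texture_contrast` in [0,1]) and carries a high-frequency nuclei-like speckle
(~25% of tumor pixels darkened by `0.35 * texture_contrast`). The stroma is
kept well below the background brightness so that Otsu's dominant
between-class split on a slide that actually contains background is
tissue-vs-background, not tumor-vs-stroma.

What the generator emulates: two visually distinct tissue classes with
irregular interlocking geometry, a bright background phase, exact masks, and
a controllable difficulty dial (`texture_contrast`). What it does not:
stain-physics variation, scanner artifacts, nuclear morphology, pyramidal
multi-resolution detail, or the ambiguity of real tumor-nest annotation.
Passing segmentation tests therefore demonstrate that the training loop,
cross-validation plumbing, and stitching are correct and that the network can
learn a learnable texture — not that the architecture would reach any
particular accuracy on clinical WSIs.

Patch embeddings are drawn from a mixture of `n_latent_clusters` Gaussians
whose centers sit at pairwise distance `cluster_separation` in units of the
unit within-cluster standard deviation (per-coordinate noise is scaled by
`1/sqrt(dim)` so separability does not decay with dimensionality); per-slide
Dirichlet(1) mixture weights make bag-of-words histograms differ across
slides. Cohorts follow a proportional-hazards model: event times exponential
with rate `baseline_hazard * exp(x' beta)` (Weibull behind a
`weibull_shape` flag, implemented as the exponential draw raised to `1/k`),
censoring independent exponential at `censor_rate`. The exponential choice
makes every downstream estimator checkable in closed form. A master seed can
be split into independent substreams (`split_seed`) so stages regenerate
independently; all generators are bit-identical under a fixed seed.

## Preprocessing

Otsu's threshold is computed per slide on the grayscale image (channel mean),
never per patch; pixels strictly brighter than the threshold are background.
A constant image has no defined threshold and falls back to an all-tissue
mask with a warning. Tiling is row-major and 0-based over half-open pixel
intervals with stride = patch size (non-overlapping) by default; partial edge
tiles are dropped. A tile is kept iff the background fraction of its focus
patch is strictly below `background_max_fraction` (default 0.5); the context
patch is never filtered separately, so focus and context counts are always
equal. The default patch size is 256 px at the focus magnification
(a standard WSI tiling size; 32 px in the desk-scale experiments so that
grids divide the 128-px synthetic slides).

The context patch covers a `focus_mag/context_mag`-times wider field (20x/5x
= 4x) centered on the focus tile, padded with white where it overruns the
slide, and block-averaged down to the patch size — the wide field is the
default because the low-magnification pathway exists to capture surrounding
structures. A strict same-field mode (`context_mode="same"`), in which the
context patch is the focus field degraded to context-magnification detail,
is available since the two readings are both defensible.

## Segmentation network and training

Two independent convolutional pathways (3x3 conv -> ReLU -> 3x3 conv -> ReLU)
encode focus and context patches into per-pixel feature maps; their
channel-wise concatenation feeds a 1x1-convolution decoder head with a
sigmoid, so each output pixel depends on both pathways' local features. The
spatially pooled concatenated map is the *concatenation-layer embedding*
(2 x `per_pathway_embed_dim`), the feature vector tapped for survival
modelling. Two width presets exist: `wide` (embedding 1280 per pathway, 2560
concatenated — the canonical width) and `tiny` (16 per pathway) for
desk-scale runs. The decoder is deliberately minimal: the survival stage
consumes the concatenation layer, and per-pixel probabilities only need to be
good enough to segment the synthetic textures; no skip connections or
transposed convolutions are warranted at this scale. The network and its
backpropagation are implemented directly on numpy (im2col convolutions,
Adam), which keeps the artifact free of any deep-learning-framework
dependency and bit-reproducible under a fixed seed with single-threaded BLAS.

Training: pixel-weighted binary cross-entropy with inverse-frequency class
weights normalized to mean 1 (with 80% non-tumor pixels the tumor class
weighs 4x); Adam at `learning_rate` (1e-4 canonical, 0.02 in the scaled-down
runs where the tiny network tolerates and needs it) with exponential decay
0.95/epoch; an optional two-stage schedule — `transfer_epochs` (canonical 11)
with encoders frozen, then `finetune_epochs` (canonical 120) end to end —
mirroring transfer learning followed by fine-tuning; early stopping on
validation loss with configurable patience, restoring the best weights.
Cross-validation is slide-level: the validation sets partition the slide set
and no slide contributes pixels to both sides of a fold. Augmentation applies
the same geometric transform (flips, 90-degree rotation multiples — exact on
masks; free-angle rotation is intentionally excluded by default) to focus,
context, and mask, and brightness/contrast jitter (0.85–1.15) to the images
only. Prediction re-tiles the slide with the training grid, stitches
probabilities back to the slide frame (unvisited pixels are NaN and excluded
from every metric), and binarizes at `prob_threshold` = 0.5 with ties
classified tumor.

## Evaluation

Pixel metrics are the standard confusion-matrix ratios; a metric with an
empty denominator is reported as missing (NaN), never clamped, so a slide
with no predicted positives has undefined precision rather than 0 (and the
worst-case F1 = 0 remains representable when denominators are defined).
Confidence intervals are Clopper–Pearson exact beta-quantile intervals on the
pooled pixel counts of each proportion, with the conventional endpoints
low = 0 at s = 0 and high = 1 at s = n. ROC pools all evaluated pixels across
slides and integrates trapezoidally over the unique thresholds; a
single-class pooled truth raises rather than returning a vacuous value.
Heatmaps map probability linearly from white to red (red channel saturated,
green/blue = 1 - p), render unvisited pixels light gray, and contour the
ground truth in green.

## Bag-of-visual-words slide features

Embeddings are extracted per CV model from the tumor-annotated patches of a
slide and quantized against that model's own k-means codebook — clustering
each model's embedding space separately and concatenating afterwards, rather
than clustering the cross-model concatenation, because the per-model spaces
are not commensurable. k-means uses k-means++ initialization with 10
restarts and a fixed seed; nearest-centroid ties break to the lowest centroid
index. The cluster-count default is k = 500, adopted from an elbow trade-off
between inertia and cost; `elbow_scan` reproduces the scan for any k list and
skips k > n with a warning.

TF-IDF treats slides as documents and clusters as terms, using the smooth-IDF
variant `ln((1+N)/(1+df)) + 1` with L2 row normalization (a widely used
default; the exact variant is configurable through the underlying
transformer). TF-IDF is applied per model and the per-model vectors
concatenated (5 x 500 = 2500 canonical); document frequencies come from
training slides only. NMF (Frobenius loss, coordinate descent, `nndsvd`
initialization, fixed seed) reduces the slide-by-2500 matrix to r = 5
features; the component matrix is frozen at fit time and held-out slides are
transformed against it, never refitted. Tests assert the leakage guard
directly: transforming held-out slides mutates neither codebooks, IDF
weights, nor NMF components. A slide with zero tumor patches encodes to the
zero vector and is flagged by its empty histogram.

## Survival analysis

Clinical preprocessing: MELD = `9.57 ln(creatinine) + 3.78 ln(bilirubin) +
11.2 ln(INR) + 6.43` (mg/dL, mg/dL, dimensionless), with creatinine replaced
by 4.0 when the patient was dialyzed within the preceding week; non-positive
labs are a domain error. The ISGLS post-hepatectomy liver-failure flag is a
boolean: elevated INR with concomitant hyperbilirubinemia on/after
postoperative day 5. Imputation fills continuous fields (CA19-9, LDH, weight,
height, days from diagnosis to surgery) with the column median — computed on
training rows only when a split is given — and categorical staging fields
(biliary stent, perineural invasion, UICC stage, V, L, T) with 0, G with 2
(the modal grade); every fill is recorded in a `<col>_imputed` flag. Patients
who died in hospital or had an R2 resection are excluded before regression.

Classical screening fits one univariable Cox proportional-hazards model per
covariate and flags those with P < .05 (strict) for the multivariable stage,
which performs conditional backward selection: iteratively refit and drop the
covariate with the largest P >= .05 until all retained covariates are
significant; an empty final model is a valid outcome. Exactly or
near-exactly collinear covariates (|r| > 0.999) are reduced to their first
representative before fitting, because the partial likelihood is
unidentifiable under exact collinearity.

The machine-learning stage trains gradient-boosted regression trees with Cox
partial-likelihood loss. The resampling unit is the patient. Test patients
(by id, or a seeded fraction) are fixed up front; each bootstrap round
resamples the remaining training pool with replacement, fits, and scores that
round's out-of-bag patients (the "validation" measurement) and the fixed test
set; per-patient risks are averaged across rounds and per-round concordance
indices and normalized impurity importances are recorded. Hyperparameter
search (trees 50–500, depth 1–4, learning rate 0.01–0.3 log-uniform,
subsample 0.5–1.0) draws random configurations and selects by mean
out-of-bag concordance before the final bootstrap pass. Evaluation splits the
averaged risks strictly at the median — ties to the low-risk group —
into two Kaplan–Meier curves compared by the two-sample log-rank test, plus
the concordance index of the averaged risks. Degenerate cases raise
explicitly: all-censored training outcomes, all-identical risks, or a split
leaving fewer than two patients per group.

## Problem sizes and tolerances in the tests

The test and analysis runs use deliberately small configurations chosen as
the package's study conditions: 128-px slides with 32-px patches; 8–24 slides
for training experiments (20 slides, 5 folds, 15 epochs in the acceptance
segmentation run, where the out-of-fold pooled pixel F1 must reach 0.8);
cohorts of 120–150 patients with 50–200 bootstrap rounds. Brute-force oracle
comparisons are exact to 1e-6 (Clopper–Pearson vs tail-sum bisection over all
s, n <= 30) or 1e-9/1e-12 (log-rank, concordance, AUC on small instances).
Null-calibration bands are Monte-Carlo: the log-rank type-I error over 500
replicates must fall in [0.02, 0.08]; pure-noise boosted-Cox held-out
concordance over 200 rounds in [0.45, 0.55]. For the strong-signal recovery
bound (>= 0.70) the stable held-out estimator is the mean per-round
out-of-bag concordance; the small (~25-patient) fixed test split is required
to sit clearly above chance, since its concordance fluctuates by several
points across cohort draws at that size.

## Known limitations

- The synthetic textures are far easier than clinical histology; segmentation
  metrics on them say nothing quantitative about WSI performance.
- The numpy CNN is CPU-bound and meant for the tiny/wide presets at small
  patch counts, not for gigapixel-scale training.
- Pretrained-weight initialization is not bundled; the transfer/fine-tune
  schedule is retained (frozen encoders during transfer epochs) but starts
  from random weights.
- The exponential cohort model has proportional hazards by construction;
  violations of proportionality are out of scope.
- Bootstrap validation concordance is an out-of-bag estimate and is known to
  be slightly pessimistic relative to a fixed validation split.
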