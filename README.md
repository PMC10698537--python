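# phccsurv

Digital-pathology survival analysis for perihilar cholangiocarcinoma
(Klatskin tumor), built as a tested, fully synthetic-data-driven pipeline.
Perihilar cholangiocarcinoma is a rare bile-duct cancer with dismal and
hard-to-predict prognosis; the pipeline combines whole-slide-image (WSI)
analysis by a convolutional network with classical and machine-learning
survival modelling of clinical covariates, and asks whether slide-derived
features improve individual risk prediction over clinical factors alone.

The package is aimed at computational-pathology and clinical-statistics
researchers who want each stage of such a pipeline as a reusable, separately
testable component, with a synthetic slide/cohort generator supplying ground
truth in place of (undeposited) patient data.

## Pipeline

1. **Synthetic data** (`phccsurv.synthetic`) — procedural H&E-like slides with
   pixel-exact tumor masks, patch-embedding matrices with latent cluster
   structure, and survival cohorts drawn from a proportional-hazards model
   with event rate `h0 * exp(x' beta)` and independent exponential censoring.
2. **Preprocessing** (`phccsurv.preprocess`) — Otsu thresholding flags bright
   background; the slide is tiled on a non-overlapping grid into co-centered
   dual-resolution patch pairs (high-magnification *focus*, 4x-wider *context*
   resampled to the same size); tiles with >= 50% background are dropped.
3. **Segmentation** (`phccsurv.segmentation`) — a dual-pathway CNN encodes
   focus and context patches separately, concatenates the pooled embeddings
   (the *concatenation layer*, 2 x 1280 = 2560 features at canonical width),
   and decodes per-pixel tumor probabilities, binarized at 0.5. Training uses
   slide-level 5-fold cross-validation, inverse-frequency class weights,
   flip/rotation/photometric augmentation, Adam with decaying learning rate,
   and early stopping.
4. **Evaluation** (`phccsurv.segeval`) — per-slide accuracy / specificity /
   sensitivity / precision / F1 with Clopper–Pearson exact binomial CIs,
   pooled ROC-AUC, and white-to-red probability heatmaps with the ground
   truth contoured in green.
5. **Slide features** (`phccsurv.features`) — bag of visual words: each CV
   model's patch embeddings are quantized against that model's k-means
   codebook (canonical k = 500), TF-IDF normalized over the slide corpus
   (slides are documents, clusters are terms), concatenated across the 5
   models into a 2500-entry vector, and NMF-reduced to 5 features per slide.
   All statistics are fitted on training slides only.
6. **Survival** (`phccsurv.survival`) — MELD scoring
   (`9.57 ln(crea) + 3.78 ln(bili) + 11.2 ln(INR) + 6.43`, creatinine set to
   4.0 under recent dialysis), the cohort imputation rules, univariable Cox
   screening feeding conditional backward selection (P < .05), and a
   gradient-boosted Cox model whose per-patient risk scores are averaged over
   bootstrap rounds (canonically 1000), evaluated by median-split
   Kaplan–Meier / log-rank and the concordance index, with per-round impurity
   feature importances.

## Worked example

The `analysis/` directory is a numbered end-to-end study over synthetic data
(run the scripts in order; tables land in `results/`, large intermediates in
`scratch/`):

```sh
python analysis/01_simulate_slides.py     # 24 slides with ground-truth masks
python analysis/02_preprocess.py          # dual-resolution patch pairs
python analysis/03_train_segmentation.py  # 5-fold CV training
python analysis/04_evaluate_segmentation.py
python analysis/05_slide_features.py      # codebooks -> TF-IDF -> NMF
python analysis/06_survival_analysis.py   # Cox screen + boosted-Cox bootstrap
```

A run with the committed seeds prints, at the key steps:

```
356 of 384 tiles kept (<50% background), focus and context counts equal by construction
pooled: acc 1.000, spec 1.000, sens 1.000, prec 1.000, F1 1.000, ROC-AUC 1.000
TF-IDF vector length 250 (5 models x 50 clusters); reduced to 5 NMF features per slide
univariable screen: ['transfusion'] significant at P<.05
backward selection retained: ['transfusion']
clinical: validation c=0.558 (log-rank P=0.88), test c=0.449 (log-rank P=0.23)
clinical+slide: validation c=0.724 (log-rank P=1.3e-05), test c=0.624 (log-rank P=0.064)
adding slide features moves test concordance by +0.175
```

Reading: the synthetic tumor texture is easy for the scaled-down CNN (F1 near
1.0 out-of-fold — deliberately high-contrast so the downstream stages get
clean features); the clinical-only boosted-Cox model is barely better than
chance because most of the simulated hazard loads on slide composition, and
adding the 5 NMF slide features recovers that signal, raising held-out
concordance substantially — the directional behaviour the pipeline is
designed to measure.

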