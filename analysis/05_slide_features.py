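"""Aggregate patch embeddings into slide-level bag-of-visual-words features.

For every slide, the tumor-annotated patches (any annotated pixel) are
embedded by each of the 5 CV models at the concatenation layer; each model's
embeddings are quantized against that model's k-means codebook, TF-IDF
normalized over the slide corpus, concatenated across models, and NMF-reduced
to 5 features per slide. An elbow scan over candidate cluster counts is
reported alongside.
"""

import pickle
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import numpy as np
import pandas as pd
from common import MASTER_SEED, RESULTS, SCRATCH, ensure_dirs, need

from phccsurv.features import SlideEncoder, elbow_scan, extract_patch_embeddings, fit_codebooks

K_CLUSTERS = 50  # desk-scale codebook (canonical 500 at cohort scale)


def main():
    ensure_dirs()
    with open(need(SCRATCH / "trained_folds.pkl", "03_train_segmentation.py"), "rb") as fh:
        trained = pickle.load(fh)
    with open(need(SCRATCH / "patch_pairs.pkl", "02_preprocess.py"), "rb") as fh:
        pairs_state = pickle.load(fh)
    folds = trained["folds"]

    slide_ids = sorted(pairs_state["pairs"])
    slide_embs, n_tumor_patches = [], []
    for sid in slide_ids:
        tumor_pairs = [p for p in pairs_state["pairs"][sid] if p.mask_patch.any()]
        n_tumor_patches.append(len(tumor_pairs))
        slide_embs.append(extract_patch_embeddings(folds, tumor_pairs))

    per_model = [np.vstack([se[m] for se in slide_embs if se[m].size])
                 for m in range(len(folds))]
    dim = per_model[0].shape[1]
    print(f"{dim} features per patch and model, {dim * len(folds)} across models")

    elbow = elbow_scan(per_model[0], [5, 10, 25, 50, 100], seed=MASTER_SEED)
    elbow.to_csv(RESULTS / "elbow_scan.csv", index=False)
    drops = -np.diff(np.log(elbow.inertia.values))
    print(f"elbow scan (model 0): inertia {elbow.inertia.iloc[0]:.1f} -> "
          f"{elbow.inertia.iloc[-1]:.1f}; k={K_CLUSTERS} adopted")

    books = fit_codebooks(per_model, k=K_CLUSTERS, seed=MASTER_SEED)
    encoder = SlideEncoder(books, n_components=5, seed=MASTER_SEED).fit(slide_embs)
    tfidf = encoder.transform_tfidf(slide_embs)
    reduced = encoder.transform(slide_embs)

    feats = pd.DataFrame(reduced, index=pd.Index(slide_ids, name="slide_id"),
                         columns=[f"dl{i}" for i in range(reduced.shape[1])])
    feats["n_tumor_patches"] = n_tumor_patches
    feats.to_csv(RESULTS / "slide_features.csv")
    with open(SCRATCH / "slide_encoder.pkl", "wb") as fh:
        pickle.dump({"encoder": encoder, "features": feats}, fh)

    print(f"TF-IDF vector length {tfidf.shape[1]} "
          f"({len(folds)} models x {K_CLUSTERS} clusters); reduced to "
          f"{reduced.shape[1]} NMF features per slide")
    summary = pd.read_csv(RESULTS / "slide_summary.csv").set_index("slide_id")
    corr = feats[[c for c in feats if c.startswith('dl')]].corrwith(
        summary.realized_tumor_fraction)
    print("correlation of reduced features with true tumor burden:")
    print(corr.round(3).to_string())


if __name__ == "__main__":
    main()
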