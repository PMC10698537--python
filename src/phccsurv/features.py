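"""Slide-level features: per-model k-means codebooks, TF-IDF bag of visual words, NMF.

Per-patch embeddings tapped at each cross-validation model's concatenation
layer are quantized against that model's own codebook (k-means, canonically
k = 500), giving a per-slide count histogram per model (slides are documents,
clusters are terms). Each model's histograms are TF-IDF normalized (smooth
IDF ln((1+N)/(1+df)) + 1 with L2 row normalization) and the per-model vectors
are concatenated, canonically 5 x 500 = 2500 entries per slide. Non-negative
matrix factorization then reduces the slide-by-2500 matrix to a handful of
final features (canonically 5).

Codebooks, IDF statistics and NMF components are fitted on training slides
only; held-out slides are transformed against the frozen statistics, never
refitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import NMF
from sklearn.feature_extraction.text import TfidfTransformer

from .preprocess import PatchPair
from .segmentation import TrainedFold

__all__ = [
    "Codebook",
    "SlideEncoder",
    "extract_patch_embeddings",
    "elbow_scan",
    "fit_codebooks",
    "reduce_features",
]


@dataclass
class Codebook:
    """k-means centroids quantizing one CV model's embedding space."""

    model_index: int
    centroids: np.ndarray  # (k, dim)
    inertia: float

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def assign(self, embeddings: np.ndarray) -> np.ndarray:
        """Nearest-centroid assignment; ties break to the lowest centroid index."""
        emb = np.atleast_2d(embeddings)
        if emb.shape[1] != self.centroids.shape[1]:
            raise ValueError(
                f"embedding dim {emb.shape[1]} != codebook dim {self.centroids.shape[1]}"
            )
        d2 = (
            (emb**2).sum(1)[:, None]
            - 2 * emb @ self.centroids.T
            + (self.centroids**2).sum(1)[None, :]
        )
        return np.argmin(d2, axis=1)  # argmin returns the first (lowest) index on ties


def extract_patch_embeddings(
    fold_models: list[TrainedFold],
    tumor_pairs: list[PatchPair],
    batch_size: int = 64,
) -> list[np.ndarray]:
    """Concatenation-layer embeddings of annotated-tumor patches, per CV model.

    Returns one (n_patches, 2*embed) matrix per fold model; with the canonical
    backbone that is 2560 columns per model, 5 x 2560 = 12 800 features per
    patch across models. An empty patch list yields empty (0, dim) matrices.
    """
    out = []
    for fold in fold_models:
        model = fold.model
        if not hasattr(model, "embed"):
            raise RuntimeError("model lacks an embedding hook")
        rows = []
        for i in range(0, len(tumor_pairs), batch_size):
            batch = tumor_pairs[i : i + batch_size]
            f = np.stack([p.focus for p in batch])
            c = np.stack([p.context for p in batch])
            rows.append(model.embed(f, c))
        dim = model.embedding_dim
        out.append(np.vstack(rows) if rows else np.empty((0, dim)))
    return out


def elbow_scan(embeddings: np.ndarray, k_list: list[int], seed: int = 0,
               n_init: int = 3, max_iter: int = 100) -> pd.DataFrame:
    """k-means inertia over a sorted list of candidate cluster counts.

    Values of k exceeding the sample count are skipped with a warning.
    Returns a DataFrame with columns (k, inertia); inertia is non-increasing
    in k up to k-means local-optimum noise and exactly 0 at k = n.
    """
    X = np.asarray(embeddings, dtype=float)
    if sorted(k_list) != list(k_list):
        raise ValueError("k_list must be sorted ascending")
    rows = []
    for k in k_list:
        if k > X.shape[0]:
            warnings.warn(f"k={k} exceeds n={X.shape[0]} samples; skipped")
            continue
        km = KMeans(n_clusters=k, n_init=n_init, max_iter=max_iter, random_state=seed).fit(X)
        rows.append({"k": k, "inertia": float(km.inertia_)})
    return pd.DataFrame(rows)


def fit_codebooks(per_model_embeddings: list[np.ndarray], k: int = 500, seed: int = 0,
                  n_init: int = 10, max_iter: int = 300) -> list[Codebook]:
    """Fit one k-means codebook per CV model on pooled training-slide embeddings."""
    books = []
    for m, X in enumerate(per_model_embeddings):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < k:
            raise ValueError(f"model {m}: {X.shape[0]} embeddings < k={k}")
        km = KMeans(n_clusters=k, n_init=n_init, max_iter=max_iter,
                    random_state=seed + m).fit(X)
        books.append(Codebook(model_index=m, centroids=km.cluster_centers_.copy(),
                              inertia=float(km.inertia_)))
    return books


class SlideEncoder:
    """Bag-of-visual-words slide encoder with frozen training-corpus statistics.

    ``fit`` learns per-model IDF weights from the training slides' cluster
    histograms and the NMF components from the training TF-IDF matrix;
    ``transform`` encodes any slides (training or held-out) against those
    frozen statistics without mutating them.
    """

    def __init__(self, codebooks: list[Codebook], n_components: int = 5, seed: int = 0):
        self.codebooks = codebooks
        self.n_components = n_components
        self.seed = seed
        self._tfidf: list[TfidfTransformer] | None = None
        self._nmf: NMF | None = None
        self.fitted = False

    # -- histograms ---------------------------------------------------------
    def counts(self, slide_embeddings: list[list[np.ndarray]]) -> list[np.ndarray]:
        """Per-model (n_slides, k) cluster-count histograms.

        ``slide_embeddings[s][m]`` is slide s's embedding matrix under model m.
        A slide with zero tumor patches yields an all-zero histogram row.
        The row sum of each histogram equals the slide's tumor-patch count.
        """
        n_models = len(self.codebooks)
        out = []
        for m, book in enumerate(self.codebooks):
            H = np.zeros((len(slide_embeddings), book.k))
            for s, per_model in enumerate(slide_embeddings):
                emb = per_model[m]
                if emb.shape[0] == 0:
                    continue
                idx = book.assign(emb)
                H[s] = np.bincount(idx, minlength=book.k)
            out.append(H)
        return out

    def fit(self, train_slide_embeddings: list[list[np.ndarray]]) -> "SlideEncoder":
        counts = self.counts(train_slide_embeddings)
        self._tfidf = []
        blocks = []
        for H in counts:
            tf = TfidfTransformer(smooth_idf=True, sublinear_tf=False, norm="l2")
            blocks.append(tf.fit_transform(H).toarray())
            self._tfidf.append(tf)
        tfidf = np.hstack(blocks)
        r = min(self.n_components, *tfidf.shape)
        self._nmf = NMF(n_components=r, init="nndsvd", random_state=self.seed,
                        max_iter=500)
        self._nmf.fit(tfidf)
        self.fitted = True
        return self

    def transform_tfidf(self, slide_embeddings: list[list[np.ndarray]]) -> np.ndarray:
        """TF-IDF bag-of-visual-words vectors, length folds x k per slide."""
        if not self.fitted:
            raise RuntimeError("encoder not fitted")
        counts = self.counts(slide_embeddings)
        blocks = [tf.transform(H).toarray() for tf, H in zip(self._tfidf, counts)]
        return np.hstack(blocks)

    def transform(self, slide_embeddings: list[list[np.ndarray]]) -> np.ndarray:
        """Reduced slide features (slides x n_components, non-negative)."""
        tfidf = self.transform_tfidf(slide_embeddings)
        return self._nmf.transform(tfidf)

    @property
    def tfidf_dim(self) -> int:
        return sum(b.k for b in self.codebooks)


def reduce_features(tfidf: np.ndarray, r: int = 5, seed: int = 0,
                    max_iter: int = 500) -> tuple[np.ndarray, NMF]:
    """NMF-reduce a non-negative slides x features matrix to r columns.

    Returns (W, fitted NMF). The component matrix H is kept inside the
    returned NMF object so held-out slides can be transformed against the
    frozen components rather than refitted.
    """
    X = np.asarray(tfidf, dtype=float)
    if (X < 0).any():
        raise ValueError("NMF requires non-negative input")
    if not 1 <= r <= min(X.shape):
        raise ValueError(f"r={r} must be in [1, min(slides, features)={min(X.shape)}]")
    nmf = NMF(n_components=r, init="nndsvd", random_state=seed, max_iter=max_iter)
    W = nmf.fit_transform(X)
    return W, nmf
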