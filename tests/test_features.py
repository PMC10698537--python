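"""Codebooks, TF-IDF bag of visual words, NMF reduction — oracles and leakage guards."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from phccsurv.features import (
    Codebook,
    SlideEncoder,
    elbow_scan,
    extract_patch_embeddings,
    fit_codebooks,
    reduce_features,
)
from phccsurv.synthetic import generate_patch_embeddings


def _slide_embeddings(n_slides=10, pps=40, dim=16, k=4, sep=8.0, seed=0, n_models=3):
    """Per-slide, per-model embedding lists as the encoder expects."""
    per_model_pooled, slide_embs = [], [[None] * n_models for _ in range(n_slides)]
    for m in range(n_models):
        emb, _ = generate_patch_embeddings(n_slides, pps, dim, k, sep, seed=seed + m)
        per_model_pooled.append(np.vstack(emb))
        for s in range(n_slides):
            slide_embs[s][m] = emb[s]
    return per_model_pooled, slide_embs


class TestElbowScan:
    def test_inertia_non_increasing_and_zero_at_n(self):
        X = np.random.default_rng(0).normal(size=(20, 4))
        tab = elbow_scan(X, [2, 5, 10, 20], seed=0)
        assert (np.diff(tab.inertia) <= 1e-9).all()
        assert tab.inertia.iloc[-1] == pytest.approx(0.0, abs=1e-9)

    def test_k_above_n_skipped_with_warning(self):
        X = np.random.default_rng(1).normal(size=(5, 3))
        with pytest.warns(UserWarning):
            tab = elbow_scan(X, [2, 10], seed=0)
        assert tab.k.tolist() == [2]

    def test_largest_relative_drop_at_true_k(self):
        emb, _ = generate_patch_embeddings(4, 60, 8, 3, 10.0, seed=5)
        tab = elbow_scan(np.vstack(emb), [1, 2, 3, 4, 5, 6], seed=0)
        drops = -np.diff(np.log(tab.inertia.values + 1e-12))
        assert tab.k.iloc[np.argmax(drops) + 1] == 3


class TestCodebooks:
    def test_duplicate_points_k1(self):
        X = np.tile([1.0, 2.0], (10, 1))
        books = fit_codebooks([X], k=1, seed=0)
        assert np.allclose(books[0].centroids, [1.0, 2.0])
        assert books[0].inertia == pytest.approx(0.0, abs=1e-12)

    def test_assignments_match_latent_labels(self):
        emb, lab = generate_patch_embeddings(5, 60, 16, 4, 10.0, seed=1)
        books = fit_codebooks([np.vstack(emb)], k=4, seed=0)
        assign = books[0].assign(np.vstack(emb))
        assert adjusted_rand_score(np.concatenate(lab), assign) > 0.99

    def test_refit_same_seed_identical(self):
        X = np.random.default_rng(2).normal(size=(50, 6))
        a = fit_codebooks([X], k=5, seed=3)[0]
        b = fit_codebooks([X], k=5, seed=3)[0]
        assert np.array_equal(a.centroids, b.centroids)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            fit_codebooks([np.zeros((3, 2))], k=5)

    def test_tie_breaks_to_lowest_index(self):
        book = Codebook(0, np.array([[0.0], [2.0]]), 0.0)
        assert book.assign(np.array([[1.0]]))[0] == 0  # equidistant -> lowest index


class TestEncoder:
    def test_histogram_conserves_patch_count(self):
        _, slide_embs = _slide_embeddings(n_slides=6)
        per_model, _ = _slide_embeddings(n_slides=6)
        books = fit_codebooks(per_model, k=5, seed=0)
        enc = SlideEncoder(books, n_components=2, seed=0)
        counts = enc.counts(slide_embs)
        for H in counts:
            assert np.allclose(H.sum(axis=1), 40)

    def test_tfidf_matches_hand_computation(self):
        """Two-slide toy with hand-assigned clusters reproduces the smooth-IDF
        formula ln((1+N)/(1+df)) + 1 with L2 row normalization."""
        book = Codebook(0, np.eye(3) * 10, 0.0)
        e = np.eye(3) * 10
        slide_embs = [
            [np.array([e[0], e[0], e[1]])],  # counts [2, 1, 0]
            [np.array([e[1], e[2], e[2], e[2]])],  # counts [0, 1, 3]
        ]
        enc = SlideEncoder([book], n_components=1, seed=0).fit(slide_embs)
        got = enc.transform_tfidf(slide_embs)
        counts = np.array([[2.0, 1, 0], [0, 1, 3]])
        df = np.array([1, 2, 1])
        idf = np.log((1 + 2) / (1 + df)) + 1
        expect = counts * idf
        expect /= np.linalg.norm(expect, axis=1, keepdims=True)
        assert np.allclose(got, expect, atol=1e-9)

    def test_single_cluster_slide_has_one_nonzero_block_entry_per_model(self):
        per_model, slide_embs = _slide_embeddings(n_slides=6, k=4, sep=10.0)
        books = fit_codebooks(per_model, k=4, seed=0)
        enc = SlideEncoder(books, n_components=2, seed=0)
        one = [[pm[:1] for pm in slide_embs[0]]]  # one patch -> one cluster/model
        counts = enc.counts(one)
        assert all((H > 0).sum() == 1 for H in counts)

    def test_empty_slide_zero_vector(self):
        per_model, slide_embs = _slide_embeddings(n_slides=5)
        books = fit_codebooks(per_model, k=4, seed=0)
        enc = SlideEncoder(books, n_components=2, seed=0).fit(slide_embs)
        empty = [[np.empty((0, 16)) for _ in range(3)]]
        assert enc.transform_tfidf(empty).sum() == 0.0

    def test_heldout_transform_never_mutates_fitted_state(self):
        per_model, slide_embs = _slide_embeddings(n_slides=8)
        books = fit_codebooks([p[:200] for p in per_model], k=4, seed=0)
        enc = SlideEncoder(books, n_components=2, seed=0).fit(slide_embs[:5])
        idf_before = [tf.idf_.copy() for tf in enc._tfidf]
        comp_before = enc._nmf.components_.copy()
        cents_before = [b.centroids.copy() for b in enc.codebooks]
        enc.transform(slide_embs[5:])
        assert all(np.array_equal(a, t.idf_) for a, t in zip(idf_before, enc._tfidf))
        assert np.array_equal(comp_before, enc._nmf.components_)
        assert all(np.array_equal(a, b.centroids) for a, b in zip(cents_before, enc.codebooks))

    def test_reduced_features_separate_distinct_mixtures(self):
        """Slides drawn from two very different mixture-weight profiles stay
        separable in the reduced feature space (silhouette > 0.3)."""
        rng = np.random.default_rng(7)
        k, dim, pps = 3, 12, 60
        centers = np.eye(k, dim) * 8
        slide_embs, group = [], []
        for s in range(12):
            g = s % 2
            w = np.array([0.8, 0.1, 0.1]) if g == 0 else np.array([0.1, 0.1, 0.8])
            lab = rng.choice(k, size=pps, p=w)
            emb = centers[lab] + rng.normal(size=(pps, dim)) / np.sqrt(dim)
            slide_embs.append([emb])
            group.append(g)
        books = fit_codebooks([np.vstack([se[0] for se in slide_embs])], k=k, seed=0)
        enc = SlideEncoder(books, n_components=2, seed=0).fit(slide_embs)
        red = enc.transform(slide_embs)
        assert silhouette_score(red, group) > 0.3


class TestNMF:
    def test_output_width_and_nonnegativity(self):
        X = np.abs(np.random.default_rng(0).normal(size=(12, 30)))
        W, _ = reduce_features(X, r=5, seed=0)
        assert W.shape == (12, 5)
        assert (W >= 0).all()

    def test_rank_one_exact(self):
        u = np.abs(np.random.default_rng(1).normal(size=(10, 1)))
        v = np.abs(np.random.default_rng(2).normal(size=(1, 8)))
        X = u @ v
        W, nmf = reduce_features(X, r=1, seed=0)
        assert np.linalg.norm(X - W @ nmf.components_) < 1e-6

    def test_reconstruction_error_non_increasing_in_r(self):
        X = np.abs(np.random.default_rng(3).normal(size=(15, 20)))
        errs = []
        for r in (1, 2, 5, 10):
            W, nmf = reduce_features(X, r=r, seed=0)
            errs.append(np.linalg.norm(X - W @ nmf.components_))
        assert errs == sorted(errs, reverse=True)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            reduce_features(np.array([[1.0, -0.5]]), r=1)


class TestPatchEmbeddingExtraction:
    def test_dims_scale_with_models(self, small_pairs):
        from phccsurv.segmentation import DualPathwaySegNet, SegModelConfig, TrainedFold

        cfg = SegModelConfig(backbone="tiny", per_pathway_embed_dim=32)
        folds = [
            TrainedFold(model=DualPathwaySegNet(cfg), fold_index=i,
                        train_slides=[], val_slides=[])
            for i in range(3)
        ]
        pairs = small_pairs["s0"][:4]
        mats = extract_patch_embeddings(folds, pairs)
        assert len(mats) == 3
        assert all(m.shape == (4, 64) for m in mats)  # 2 pathways x 32

    def test_zero_patches_gives_empty_matrices(self):
        from phccsurv.segmentation import DualPathwaySegNet, SegModelConfig, TrainedFold

        cfg = SegModelConfig(backbone="tiny", per_pathway_embed_dim=8)
        folds = [TrainedFold(model=DualPathwaySegNet(cfg), fold_index=0,
                             train_slides=[], val_slides=[])]
        mats = extract_patch_embeddings(folds, [])
        assert mats[0].shape == (0, 16)
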