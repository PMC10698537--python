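"""Dual-pathway convolutional tumor segmentation and its training protocol.

The model mirrors how a pathologist reads a slide: a *focus* patch at high
magnification (cell morphology) and a co-centered *context* patch at low
magnification (surrounding structures) are encoded by two independent
convolutional pathways; their pooled embeddings are concatenated (this
concatenation layer is also the feature tap for the downstream survival
stage) and a per-pixel decoder head emits tumor probabilities at focus-patch
resolution, binarized at 0.5.

Training follows the protocol of the pipeline: slide-level k-fold
cross-validation (no slide contributes patches to both train and validation
of a fold), pixel-weighted cross-entropy with inverse-frequency class
weights, flip/rotation/brightness/contrast augmentation, Adam with an
exponentially decaying learning rate, an optional two-stage schedule
(frozen-encoder transfer epochs then fine-tuning), and early stopping on
validation loss.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .nn import Adam, Conv2D, relu, sigmoid, weighted_bce
from .preprocess import PatchGridConfig, PatchPair, extract_patch_pairs, stitch_patches
from .synthetic import SyntheticSlide

__all__ = [
    "SegModelConfig",
    "DualPathwaySegNet",
    "TrainedFold",
    "SlideProbabilityMap",
    "build_model",
    "apply_augment",
    "augment_pair",
    "class_weights",
    "assign_folds",
    "train_cv",
    "predict_slide",
]

_BACKBONE_HIDDEN = {"tiny": 8, "wide": 32}
_BACKBONE_EMBED = {"tiny": 16, "wide": 1280}


@dataclass(frozen=True)
class SegModelConfig:
    """Architecture and training hyperparameters of the segmentation network.

    Canonical values follow the full-scale protocol (per-pathway embedding
    1280 -> 2560 concatenated, Adam lr 1e-4 decaying over time, 11 transfer +
    120 fine-tuning epochs, probability threshold 0.5, 5 folds); the ``tiny``
    backbone scales the network to desk-size experiments.
    """

    backbone: str = "tiny"
    per_pathway_embed_dim: int | None = None  # None -> backbone preset
    learning_rate: float = 1e-4
    lr_decay: float = 0.95  # multiplicative per-epoch factor
    transfer_epochs: int = 11
    finetune_epochs: int = 120
    early_stopping_patience: int = 10
    class_weight_mode: str = "inverse_frequency"
    fixed_class_weights: tuple[float, float] = (1.0, 1.0)
    prob_threshold: float = 0.5
    folds: int = 5
    seed: int = 0
    batch_size: int = 16
    augment: bool = True

    def __post_init__(self):
        if self.backbone not in _BACKBONE_HIDDEN:
            raise ValueError(f"unknown backbone {self.backbone!r}; choose from {sorted(_BACKBONE_HIDDEN)}")
        if not 0 < self.prob_threshold < 1:
            raise ValueError("prob_threshold must be in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.embed_dim <= 0:
            raise ValueError("per_pathway_embed_dim must be > 0")
        if self.class_weight_mode not in ("inverse_frequency", "fixed"):
            raise ValueError("class_weight_mode must be 'inverse_frequency' or 'fixed'")

    @property
    def embed_dim(self) -> int:
        if self.per_pathway_embed_dim is None:
            return _BACKBONE_EMBED[self.backbone]
        return self.per_pathway_embed_dim

    @property
    def hidden(self) -> int:
        return _BACKBONE_HIDDEN[self.backbone]


class DualPathwaySegNet:
    """Two convolutional encoders + concatenation + 1x1 decoder head.

    Each pathway: Conv3x3(3->hidden)-ReLU-Conv3x3(hidden->embed)-ReLU giving a
    per-pixel feature map; the two maps are concatenated channel-wise
    (2*embed channels). The decoder is a 1x1 convolution over the
    concatenated map followed by a sigmoid, so every pixel's probability is a
    function of both pathways' local features. The slide-feature hook
    :meth:`embed` returns the spatially pooled concatenated embedding
    (length 2*embed), the vector tapped for survival modelling.
    """

    def __init__(self, config: SegModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        h, e = config.hidden, config.embed_dim
        self.enc_focus = [Conv2D.create(rng, 3, 3, h), Conv2D.create(rng, 3, h, e)]
        self.enc_context = [Conv2D.create(rng, 3, 3, h), Conv2D.create(rng, 3, h, e)]
        self.head = Conv2D.create(rng, 1, 2 * e, 1)
        self.trained = False
        self._cache: dict | None = None

    # -- parameter plumbing -------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        layers = self.enc_focus + self.enc_context + [self.head]
        return [p for layer in layers for p in layer.params]

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state):
            p[...] = s

    @property
    def embedding_dim(self) -> int:
        return 2 * self.config.embed_dim

    # -- forward / backward -------------------------------------------------
    @staticmethod
    def _prep(images: np.ndarray) -> np.ndarray:
        return images.astype(np.float64) / 255.0 - 0.5

    def _encode(self, enc, x):
        z1 = enc[0].forward(x)
        a1 = relu(z1)
        z2 = enc[1].forward(a1)
        return z1, z2, relu(z2)

    def forward(self, focus: np.ndarray, context: np.ndarray) -> np.ndarray:
        """Per-pixel tumor probabilities for a batch of (N, p, p, 3) uint8 pairs."""
        xf, xc = self._prep(focus), self._prep(context)
        z1f, z2f, a2f = self._encode(self.enc_focus, xf)
        z1c, z2c, a2c = self._encode(self.enc_context, xc)
        feat = np.concatenate([a2f, a2c], axis=-1)
        logits = self.head.forward(feat)[..., 0]
        prob = sigmoid(logits)
        self._cache = {"z1f": z1f, "z2f": z2f, "z1c": z1c, "z2c": z2c, "prob": prob}
        return prob

    def embed(self, focus: np.ndarray, context: np.ndarray) -> np.ndarray:
        """Concatenation-layer embedding: spatial mean of the 2*embed feature map."""
        xf, xc = self._prep(focus), self._prep(context)
        *_, a2f = self._encode(self.enc_focus, xf)
        *_, a2c = self._encode(self.enc_context, xc)
        return np.concatenate([a2f, a2c], axis=-1).mean(axis=(1, 2))

    def backward(self, dlogits: np.ndarray) -> list[np.ndarray]:
        """Gradients for all params given dL/dlogits of shape (N, p, p)."""
        c = self._cache
        if c is None:
            raise RuntimeError("forward must be called before backward")
        e = self.config.embed_dim
        dwh, dbh, dfeat = self.head.backward(dlogits[..., None])
        grads_path = []
        for enc, z1, z2, dslice in (
            (self.enc_focus, c["z1f"], c["z2f"], dfeat[..., :e]),
            (self.enc_context, c["z1c"], c["z2c"], dfeat[..., e:]),
        ):
            dz2 = dslice * (z2 > 0)
            dw2, db2, da1 = enc[1].backward(dz2)
            dz1 = da1 * (z1 > 0)
            dw1, db1, _ = enc[0].backward(dz1, need_dx=False)
            grads_path.extend([dw1, db1, dw2, db2])
        return grads_path + [dwh, dbh]


def build_model(config: SegModelConfig) -> DualPathwaySegNet:
    """Construct an untrained dual-pathway segmentation network."""
    return DualPathwaySegNet(config)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def apply_augment(
    pair: PatchPair,
    flip_h: bool = False,
    flip_v: bool = False,
    rot90: int = 0,
    brightness: float = 1.0,
    contrast: float = 1.0,
) -> PatchPair:
    """Apply one explicit augmentation draw.

    The geometric transform (flips, rotation in 90-degree multiples) is shared
    by focus, context, and mask; the photometric jitter touches the images
    only, so the mask stays strictly binary.
    """

    def geom(a):
        if flip_h:
            a = a[:, ::-1]
        if flip_v:
            a = a[::-1]
        return np.rot90(a, k=rot90 % 4)

    def photo(img):
        x = img.astype(np.float64) / 255.0
        x = ((x - 0.5) * contrast + 0.5) * brightness
        return np.clip(np.rint(x * 255.0), 0, 255).astype(np.uint8)

    return PatchPair(
        focus=photo(np.ascontiguousarray(geom(pair.focus))),
        context=photo(np.ascontiguousarray(geom(pair.context))),
        mask_patch=np.ascontiguousarray(geom(pair.mask_patch)),
        grid_row=pair.grid_row,
        grid_col=pair.grid_col,
        slide_id=pair.slide_id,
        background_fraction=pair.background_fraction,
    )


def augment_pair(pair: PatchPair, seed: int | np.random.Generator) -> PatchPair:
    """Random flip/90-degree-rotation + brightness/contrast jitter."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return apply_augment(
        pair,
        flip_h=bool(rng.random() < 0.5),
        flip_v=bool(rng.random() < 0.5),
        rot90=int(rng.integers(4)),
        brightness=float(rng.uniform(0.85, 1.15)),
        contrast=float(rng.uniform(0.85, 1.15)),
    )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def class_weights(mask_pixels: np.ndarray, mode: str = "inverse_frequency",
                  fixed: tuple[float, float] = (1.0, 1.0)) -> np.ndarray:
    """Per-class pixel weights (non-tumor, tumor) normalized to mean 1.

    Inverse-frequency weights are proportional to 1/class-frequency, so with
    80% non-tumor pixels the tumor class weighs 4x the non-tumor class.
    """
    if mode == "fixed":
        w = np.asarray(fixed, dtype=float)
        return w / w.mean()
    n = mask_pixels.size
    n_tumor = int(mask_pixels.sum())
    n_non = n - n_tumor
    if n_tumor == 0 or n_non == 0:
        raise ValueError(
            "degenerate class weights: training fold has a single pixel class "
            f"(tumor pixels = {n_tumor} of {n})"
        )
    w = np.array([n / (2.0 * n_non), n / (2.0 * n_tumor)])
    return w / w.mean()


@dataclass
class TrainedFold:
    """One cross-validation fold: the trained model and its slide-level split."""

    model: DualPathwaySegNet
    fold_index: int
    train_slides: list[str]
    val_slides: list[str]
    history: list[dict] = field(default_factory=list)


def assign_folds(slide_ids: list[str], folds: int, seed: int) -> list[list[str]]:
    """Deterministic slide-level partition into ``folds`` validation sets."""
    ids = sorted(slide_ids)
    if len(ids) < folds:
        raise ValueError(f"need at least {folds} slides, got {len(ids)}")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    return [perm[i::folds] for i in range(folds)]


def _stack(pairs: list[PatchPair]):
    focus = np.stack([p.focus for p in pairs])
    context = np.stack([p.context for p in pairs])
    y = np.stack([p.mask_patch for p in pairs]).astype(np.float64)
    return focus, context, y


def _epoch_loss(model, pairs, weights, batch_size):
    total, wtot = 0.0, 0.0
    for i in range(0, len(pairs), batch_size):
        f, c, y = _stack(pairs[i : i + batch_size])
        p = model.forward(f, c)
        w = weights[y.astype(int)]
        loss, _ = weighted_bce(p, y, w)
        total += loss * w.sum()
        wtot += w.sum()
    return total / wtot


def train_fold(
    model: DualPathwaySegNet,
    train_pairs: list[PatchPair],
    val_pairs: list[PatchPair],
    config: SegModelConfig,
    rng: np.random.Generator,
) -> list[dict]:
    """Train one model on one fold; returns the per-epoch loss history.

    Stage 1 (``transfer_epochs``): encoders frozen, only the decoder head
    updates. Stage 2 (``finetune_epochs``): all parameters update. Early
    stopping monitors validation loss with the configured patience and
    restores the best weights.
    """
    weights = class_weights(
        np.concatenate([p.mask_patch.ravel() for p in train_pairs]),
        config.class_weight_mode,
        config.fixed_class_weights,
    )
    opt = Adam(model.params, lr=config.learning_rate)
    n_params = len(model.params)
    head_only = [False] * (n_params - 2) + [True, True]

    best_val, best_state, since_best = np.inf, model.get_state(), 0
    history: list[dict] = []
    total_epochs = config.transfer_epochs + config.finetune_epochs
    order = np.arange(len(train_pairs))
    for epoch in range(total_epochs):
        frozen = epoch < config.transfer_epochs
        opt.lr = config.learning_rate * (config.lr_decay**epoch)
        rng.shuffle(order)
        run_loss, run_w = 0.0, 0.0
        for i in range(0, len(order), config.batch_size):
            batch = [train_pairs[j] for j in order[i : i + config.batch_size]]
            if config.augment:
                batch = [augment_pair(p, rng) for p in batch]
            f, c, y = _stack(batch)
            p = model.forward(f, c)
            w = weights[y.astype(int)]
            loss, dlogits = weighted_bce(p, y, w)
            grads = model.backward(dlogits)
            opt.step(grads, mask=head_only if frozen else None)
            run_loss += loss * w.sum()
            run_w += w.sum()
        val_loss = _epoch_loss(model, val_pairs, weights, config.batch_size) if val_pairs else np.nan
        history.append({"epoch": epoch, "train_loss": run_loss / run_w, "val_loss": val_loss})
        if val_pairs:
            if val_loss < best_val - 1e-9:
                best_val, best_state, since_best = val_loss, model.get_state(), 0
            else:
                since_best += 1
                if since_best >= config.early_stopping_patience:
                    break
    if val_pairs:
        model.set_state(best_state)
    model.trained = True
    return history


def train_cv(
    pairs_by_slide: dict[str, list[PatchPair]],
    config: SegModelConfig,
) -> list[TrainedFold]:
    """Slide-level k-fold cross-validated training.

    Each slide's patches are assigned wholly to one fold (the validation sets
    partition the slide set), so no slide contributes pixels to both sides of
    a split. Returns one trained model per fold.
    """
    val_sets = assign_folds(list(pairs_by_slide), config.folds, config.seed)
    all_ids = sorted(pairs_by_slide)
    fold_results = []
    for k, val_ids in enumerate(val_sets):
        train_ids = [s for s in all_ids if s not in set(val_ids)]
        train_pairs = [p for s in train_ids for p in pairs_by_slide[s]]
        val_pairs = [p for s in val_ids for p in pairs_by_slide[s]]
        model = DualPathwaySegNet(replace(config, seed=config.seed + 1000 + k))
        rng = np.random.default_rng(config.seed + 2000 + k)
        history = train_fold(model, train_pairs, val_pairs, config, rng)
        fold_results.append(
            TrainedFold(model=model, fold_index=k, train_slides=train_ids,
                        val_slides=sorted(val_ids), history=history)
        )
    return fold_results


# ---------------------------------------------------------------------------
# Slide-level prediction
# ---------------------------------------------------------------------------

@dataclass
class SlideProbabilityMap:
    """Per-pixel tumor probabilities stitched back to the slide frame.

    Pixels of dropped tiles (background-heavy or partial-edge) carry NaN and
    are flagged unvisited; the binary mask classifies visited pixels with
    probability >= threshold as tumor (ties go to tumor).
    """

    prob: np.ndarray  # (H, W) float, NaN where unvisited
    threshold: float = 0.5

    @property
    def visited(self) -> np.ndarray:
        return ~np.isnan(self.prob)

    @property
    def binary(self) -> np.ndarray:
        out = np.zeros(self.prob.shape, dtype=np.uint8)
        v = self.visited
        out[v] = (self.prob[v] >= self.threshold).astype(np.uint8)
        return out


def predict_slide(
    model: DualPathwaySegNet,
    slide: SyntheticSlide | np.ndarray,
    grid_config: PatchGridConfig,
    batch_size: int = 16,
) -> SlideProbabilityMap:
    """Tile a slide with the training grid, predict, and stitch probabilities."""
    if not model.trained:
        raise RuntimeError("model has not been trained; call train_cv/train_fold first")
    image = slide.image if isinstance(slide, SyntheticSlide) else np.asarray(slide)
    pairs = extract_patch_pairs(slide, grid_config)
    probs, coords = [], []
    for i in range(0, len(pairs), batch_size):
        batch = pairs[i : i + batch_size]
        f, c, _ = _stack(batch)
        p = model.forward(f, c)
        probs.extend(list(p))
        coords.extend([(q.grid_row, q.grid_col) for q in batch])
    prob = stitch_patches(probs, coords, image.shape[:2], grid_config.stride)
    return SlideProbabilityMap(prob=prob, threshold=model.config.prob_threshold)
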