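"""Synthetic slides, patch embeddings, and survival cohorts with known ground truth.

Every downstream stage of the pipeline (patching, segmentation, bag-of-visual-words
aggregation, boosted-Cox survival) is exercised on data from this module, so each
generator exposes the latent truth it was built from: the slide generator returns
the pixel-exact tumor mask, the embedding generator returns the latent cluster
labels, and the cohort generator draws event times from a proportional-hazards
model with user-chosen log-hazard coefficients.

All generators are deterministic under a fixed seed (bit-identical outputs).
A master seed can be split into independent per-component substreams with
:func:`split_seed` so stages can be regenerated independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "SlideGenParams",
    "SyntheticSlide",
    "CohortSpec",
    "split_seed",
    "generate_slide",
    "generate_patch_embeddings",
    "generate_cohort",
    "save_slide",
    "load_slide",
]


def split_seed(master_seed: int, n: int) -> list[int]:
    """Split a master seed into ``n`` independent substream seeds (< 2**31)."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# Slides
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SlideGenParams:
    """Parameters of a procedural H&E-like slide.

    ``tumor_fraction`` and ``background_fraction`` are fractions of the whole
    slide area; the remainder is non-tumor tissue. ``texture_contrast`` in [0,1]
    scales how strongly the tumor texture (dark, high-frequency nuclei-like
    speckle) differs from the smoother non-tumor stroma.
    """

    width_px: int = 512
    height_px: int = 512
    tumor_fraction: float = 0.2
    n_tumor_blobs: int = 4
    texture_contrast: float = 0.7
    background_fraction: float = 0.3
    seed: int = 0

    def validate(self, min_side: int = 16) -> None:
        if self.width_px < min_side or self.height_px < min_side:
            raise ValueError(f"slide dimensions must be >= {min_side} px")
        for name in ("tumor_fraction", "background_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.tumor_fraction + self.background_fraction > 1.0 + 1e-12:
            raise ValueError("tumor_fraction + background_fraction must be <= 1")
        if not 0.0 <= self.texture_contrast <= 1.0:
            raise ValueError("texture_contrast must be in [0, 1]")
        if self.n_tumor_blobs < 0:
            raise ValueError("n_tumor_blobs must be >= 0")


@dataclass(frozen=True)
class SyntheticSlide:
    """An RGB slide image with its ground-truth binary tumor mask."""

    image: np.ndarray  # (H, W, 3) uint8
    tumor_mask: np.ndarray  # (H, W) uint8 in {0, 1}
    params: SlideGenParams

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]


def _smooth_field(rng: np.random.Generator, h: int, w: int, sigma: float) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal((h, w)), sigma=sigma, mode="wrap")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_slide(params: SlideGenParams) -> SyntheticSlide:
    """Generate a textured tissue slide with irregular tumor nests.

    Regions are laid out by thresholding smoothed Gaussian noise fields at
    quantiles, which yields irregular blob shapes while pinning the realized
    area fractions close to the requested ones: background is the brightest
    ``background_fraction`` of a low-frequency field; tumor is the top
    ``tumor_fraction`` (rescaled to tissue area) of a second field restricted
    to tissue, with ``n_tumor_blobs`` Gaussian bumps seeding nest locations.

    Non-tumor tissue is a smooth eosin-pink stroma; tumor tissue is darker and
    carries a high-frequency nuclei-like speckle whose amplitude scales with
    ``texture_contrast``; background is near-white (luminance > 0.9 of max).
    """
    params.validate()
    h, w = params.height_px, params.width_px
    rng = np.random.default_rng(params.seed)
    sigma = max(h, w) / 24.0

    # --- region layout -----------------------------------------------------
    bg_field = _smooth_field(rng, h, w, sigma)
    if params.background_fraction > 0:
        thr = np.quantile(bg_field, 1.0 - params.background_fraction)
        background = bg_field > thr
    else:
        background = np.zeros((h, w), dtype=bool)

    tissue = ~background
    tumor = np.zeros((h, w), dtype=bool)
    if params.tumor_fraction > 0 and tissue.any():
        tfield = _smooth_field(rng, h, w, sigma * 0.6)
        # Gaussian bumps bias where nests form without changing total area.
        yy, xx = np.mgrid[0:h, 0:w]
        for _ in range(params.n_tumor_blobs):
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
            r = 0.6 * sigma + rng.uniform(0, sigma)
            tfield = tfield + 2.0 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * r**2))
        frac_in_tissue = min(1.0, params.tumor_fraction / max(tissue.mean(), 1e-12))
        vals = tfield[tissue]
        thr = np.quantile(vals, 1.0 - frac_in_tissue) if frac_in_tissue < 1 else -np.inf
        tumor[tissue] = tfield[tissue] > thr

    # --- textures ----------------------------------------------------------
    c = params.texture_contrast
    img = np.empty((h, w, 3), dtype=np.float64)

    # stroma: smooth pink with gentle low-frequency variation; kept well below
    # the near-white background so Otsu's dominant split is tissue-vs-background
    lowf = _smooth_field(rng, h, w, sigma / 2.0) * 0.04
    stroma = np.stack(
        [0.72 + lowf, 0.52 + lowf, 0.64 + lowf], axis=-1
    )
    img[:] = stroma

    # tumor: darker purple base + dense dark speckle ("nuclei")
    speckle = rng.random((h, w))
    nuclei = (speckle < 0.25).astype(np.float64)  # ~25% of tumor pixels are nuclei dots
    tumor_base = np.stack(
        [0.72 - 0.28 * c + lowf, 0.52 - 0.22 * c + lowf, 0.64 - 0.12 * c + lowf],
        axis=-1,
    )
    tumor_tex = tumor_base - (0.35 * c) * nuclei[..., None]
    img[tumor] = tumor_tex[tumor]

    # mild fine-grained noise everywhere in tissue
    img += (rng.random((h, w, 1)) - 0.5) * 0.03
    img = np.clip(img, 0.0, 1.0)

    # background: near-white, luminance kept > 0.9
    bg_tex = 0.94 + rng.random((h, w, 1)) * 0.05
    img[background] = np.broadcast_to(bg_tex, (h, w, 3))[background]

    image = np.clip(np.rint(img * 255), 0, 255).astype(np.uint8)
    mask = tumor.astype(np.uint8)
    return SyntheticSlide(image=image, tumor_mask=mask, params=params)


def save_slide(slide: SyntheticSlide, directory: str | Path, basename: str) -> None:
    """Write a slide as paired PNGs (image, mask) plus a JSON parameter sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    Image.fromarray(slide.image).save(directory / f"{basename}.png")
    Image.fromarray(slide.tumor_mask * 255).save(directory / f"{basename}_mask.png")
    with open(directory / f"{basename}_params.json", "w") as fh:
        json.dump(asdict(slide.params), fh, indent=1)


def load_slide(directory: str | Path, basename: str) -> SyntheticSlide:
    directory = Path(directory)
    image = np.asarray(Image.open(directory / f"{basename}.png").convert("RGB"))
    mask = (np.asarray(Image.open(directory / f"{basename}_mask.png")) > 127).astype(np.uint8)
    with open(directory / f"{basename}_params.json") as fh:
        params = SlideGenParams(**json.load(fh))
    return SyntheticSlide(image=image, tumor_mask=mask, params=params)


# ---------------------------------------------------------------------------
# Patch embeddings
# ---------------------------------------------------------------------------

def generate_patch_embeddings(
    n_slides: int,
    patches_per_slide: int,
    dim: int,
    n_latent_clusters: int,
    cluster_separation: float,
    seed: int,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Draw per-slide patch-embedding matrices from a Gaussian mixture.

    Stands in for the pooled concatenation-layer features of the segmentation
    network. Cluster centers sit at pairwise distance ``cluster_separation``
    in units of the (unit) within-cluster standard deviation; per-coordinate
    noise is scaled by 1/sqrt(dim) so separability does not degrade with
    dimensionality. Slide-level mixture weights are Dirichlet(1) draws, so
    bag-of-visual-words histograms differ between slides.

    Returns
    -------
    embeddings : list of (patches_per_slide, dim) arrays, one per slide
    labels : list of (patches_per_slide,) integer latent-cluster labels
    """
    if n_latent_clusters < 1 or dim < 1 or n_slides < 1 or patches_per_slide < 1:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)

    dirs = rng.standard_normal((n_latent_clusters, dim))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    # pairwise distance between two random unit vectors is ~sqrt(2); rescale
    centers = dirs * (cluster_separation / np.sqrt(2.0))

    embeddings, labels = [], []
    for _ in range(n_slides):
        weights = rng.dirichlet(np.ones(n_latent_clusters))
        lab = rng.choice(n_latent_clusters, size=patches_per_slide, p=weights)
        noise = rng.standard_normal((patches_per_slide, dim)) / np.sqrt(dim)
        embeddings.append(centers[lab] + noise)
        labels.append(lab)
    return embeddings, labels


# ---------------------------------------------------------------------------
# Survival cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Proportional-hazards cohort: rate = baseline_hazard * exp(X @ beta)."""

    n_patients: int
    beta: tuple = ()
    baseline_hazard: float = 0.01
    censor_rate: float = 0.005
    seed: int = 0
    weibull_shape: float | None = None  # None -> exponential times

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")
        if self.weibull_shape is not None and self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be > 0")


def generate_cohort(spec: CohortSpec, covariates: np.ndarray) -> pd.DataFrame:
    """Simulate observed survival times under a proportional-hazards model.

    Event times are exponential with rate ``baseline_hazard * exp(X @ beta)``
    (or Weibull with the given shape when ``weibull_shape`` is set), censoring
    times independent exponential at ``censor_rate``; the observed time is the
    minimum and ``event`` flags whether the event preceded censoring.

    Returns a DataFrame with columns ``patient_id``, ``time``, ``event``.
    """
    spec.validate()
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] != spec.n_patients:
        raise ValueError(
            f"covariates has {X.shape[0]} rows, expected {spec.n_patients}"
        )
    beta = np.asarray(spec.beta, dtype=float)
    if beta.size != X.shape[1]:
        raise ValueError(f"beta has length {beta.size}, expected {X.shape[1]}")

    rng = np.random.default_rng(spec.seed)
    rate = spec.baseline_hazard * np.exp(X @ beta)
    u = rng.random(spec.n_patients)
    if spec.weibull_shape is None:
        t_event = -np.log(u) / rate
    else:
        k = spec.weibull_shape
        t_event = (-np.log(u) / rate) ** (1.0 / k)
    if spec.censor_rate > 0:
        t_cens = rng.exponential(1.0 / spec.censor_rate, spec.n_patients)
    else:
        t_cens = np.full(spec.n_patients, np.inf)

    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(spec.n_patients)],
            "time": time,
            "event": event.astype(int),
        }
    )
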