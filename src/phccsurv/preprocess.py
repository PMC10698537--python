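"""Slide preprocessing: Otsu background exclusion and dual-resolution patching.

A slide is tiled on a non-overlapping grid at the focus magnification
(canonically 20x). Each kept tile yields a *patch pair*: the focus patch
itself and a co-centered *context* patch sampled from a wider field
(focus_mag / context_mag times wider, canonically 4x, emulating a 5x view)
resampled to the same pixel size. Tiles whose Otsu-background fraction is at
or above ``background_max_fraction`` (canonically 0.5) are dropped, as are
partial edge tiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .synthetic import SyntheticSlide

__all__ = [
    "PatchGridConfig",
    "PatchPair",
    "compute_background_mask",
    "binarize_annotation",
    "extract_patch_pairs",
    "patch_manifest",
    "stitch_patches",
]


@dataclass(frozen=True)
class PatchGridConfig:
    """Grid and filtering rules for dual-resolution patch extraction.

    ``context_mode`` selects how the low-magnification patch relates to the
    focus patch: ``"wide"`` (default) covers a focus_mag/context_mag-times
    wider field centered identically, capturing surrounding structures;
    ``"same"`` covers exactly the focus field but at context-magnification
    detail (downsampled then upsampled back).
    """

    patch_px: int = 256
    focus_mag: float = 20.0
    context_mag: float = 5.0
    background_max_fraction: float = 0.5
    stride_px: int | None = None  # None -> patch_px (non-overlapping)
    context_mode: str = "wide"

    def __post_init__(self):
        if not self.focus_mag > self.context_mag > 0:
            raise ValueError("require focus_mag > context_mag > 0")
        if not 0 < self.background_max_fraction <= 1:
            raise ValueError("background_max_fraction must be in (0, 1]")
        if self.stride_px is not None and self.stride_px < 1:
            raise ValueError("stride_px must be >= 1")
        if self.patch_px < 1:
            raise ValueError("patch_px must be >= 1")
        if self.context_mode not in ("wide", "same"):
            raise ValueError("context_mode must be 'wide' or 'same'")

    @property
    def stride(self) -> int:
        return self.patch_px if self.stride_px is None else self.stride_px

    @property
    def scale(self) -> float:
        return self.focus_mag / self.context_mag


@dataclass
class PatchPair:
    """Co-centered focus/context patches with the aligned mask patch."""

    focus: np.ndarray  # (p, p, 3) uint8
    context: np.ndarray  # (p, p, 3) uint8, resampled from the wider field
    mask_patch: np.ndarray  # (p, p) uint8 in {0, 1}
    grid_row: int
    grid_col: int
    slide_id: str = ""
    background_fraction: float = 0.0


def compute_background_mask(image: np.ndarray) -> np.ndarray:
    """Flag background pixels (1) by Otsu thresholding the grayscale image.

    Luminance is the channel mean; pixels strictly brighter than the Otsu
    threshold are background. A constant image has no defined threshold: an
    all-tissue mask is returned with a warning.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    gray = image.mean(axis=-1) if image.ndim == 3 else image.astype(float)
    if np.ptp(gray) == 0:
        warnings.warn("constant image: Otsu threshold undefined, treating all pixels as tissue")
        return np.zeros(gray.shape, dtype=np.uint8)
    thr = threshold_otsu(gray.astype(np.uint8) if image.dtype == np.uint8 else gray)
    return (gray > thr).astype(np.uint8)


def binarize_annotation(annotation_mask: np.ndarray, slide_shape: tuple | None = None) -> np.ndarray:
    """Collapse a labeled annotation mask to binary tumor/non-tumor."""
    mask = np.asarray(annotation_mask)
    if slide_shape is not None and mask.shape != tuple(slide_shape):
        raise ValueError(f"mask shape {mask.shape} does not match slide {tuple(slide_shape)}")
    return (mask != 0).astype(np.uint8)


def _context_window(image: np.ndarray, r0: int, c0: int, p: int, scale: int,
                    fill: float) -> np.ndarray:
    """Extract the scale*p wide window centered on the focus tile, padding
    out-of-slide area with ``fill``, and block-average down to p x p."""
    h, w = image.shape[:2]
    half_extra = (scale - 1) * p // 2
    top, left = r0 - half_extra, c0 - half_extra
    size = scale * p
    out = np.full((size, size) + image.shape[2:], fill, dtype=np.float64)
    ys, xs = max(top, 0), max(left, 0)
    ye, xe = min(top + size, h), min(left + size, w)
    out[ys - top : ye - top, xs - left : xe - left] = image[ys:ye, xs:xe]
    # block mean over scale x scale blocks
    out = out.reshape(p, scale, p, scale, -1).mean(axis=(1, 3))
    return out.squeeze(-1) if out.shape[-1] == 1 else out


def extract_patch_pairs(
    slide: SyntheticSlide | np.ndarray,
    config: PatchGridConfig,
    mask: np.ndarray | None = None,
    slide_id: str = "",
    background_mask: np.ndarray | None = None,
) -> list[PatchPair]:
    """Tile a slide into filtered dual-resolution patch pairs.

    The grid is row-major and 0-based over the focus frame with half-open
    pixel intervals; partial edge tiles are dropped. A tile is kept iff the
    background fraction of its *focus* patch is strictly below
    ``config.background_max_fraction`` (the context patch is never filtered
    separately). One context patch is produced per kept focus patch, always.
    """
    if isinstance(slide, SyntheticSlide):
        image = slide.image
        if mask is None:
            mask = slide.tumor_mask
    else:
        image = np.asarray(slide)
    h, w = image.shape[:2]
    p = config.patch_px
    if p > h or p > w:
        warnings.warn(f"patch_px={p} exceeds slide dimensions ({h}x{w}); no patches")
        return []
    if mask is None:
        mask = np.zeros((h, w), dtype=np.uint8)
    mask = binarize_annotation(mask, (h, w))
    if background_mask is None:
        background_mask = compute_background_mask(image)

    scale = config.scale
    if config.context_mode == "wide" and abs(scale - round(scale)) > 1e-9:
        raise ValueError("focus_mag/context_mag must be an integer in 'wide' mode")
    scale = int(round(scale))

    pairs: list[PatchPair] = []
    stride = config.stride
    for gi, r0 in enumerate(range(0, h - p + 1, stride)):
        for gj, c0 in enumerate(range(0, w - p + 1, stride)):
            bg_frac = float(background_mask[r0 : r0 + p, c0 : c0 + p].mean())
            if bg_frac >= config.background_max_fraction:
                continue
            focus = image[r0 : r0 + p, c0 : c0 + p]
            if config.context_mode == "wide":
                ctx = _context_window(image, r0, c0, p, scale, fill=255.0)
            else:
                # same field at context-magnification detail: block-average by
                # scale then repeat back up to p x p
                small = focus.reshape(p // scale, scale, p // scale, scale, -1).mean(axis=(1, 3))
                ctx = np.repeat(np.repeat(small, scale, axis=0), scale, axis=1)
            pairs.append(
                PatchPair(
                    focus=focus.copy(),
                    context=np.clip(np.rint(ctx), 0, 255).astype(np.uint8),
                    mask_patch=mask[r0 : r0 + p, c0 : c0 + p].copy(),
                    grid_row=gi,
                    grid_col=gj,
                    slide_id=slide_id,
                    background_fraction=bg_frac,
                )
            )
    return pairs


def patch_manifest(
    slide: SyntheticSlide | np.ndarray,
    config: PatchGridConfig,
    slide_id: str = "",
) -> pd.DataFrame:
    """Per-tile manifest (slide_id, row, col, kept, background_fraction) for a slide."""
    image = slide.image if isinstance(slide, SyntheticSlide) else np.asarray(slide)
    h, w = image.shape[:2]
    p, stride = config.patch_px, config.stride
    bg = compute_background_mask(image)
    rows = []
    for gi, r0 in enumerate(range(0, h - p + 1, stride)):
        for gj, c0 in enumerate(range(0, w - p + 1, stride)):
            frac = float(bg[r0 : r0 + p, c0 : c0 + p].mean())
            rows.append(
                {
                    "slide_id": slide_id,
                    "row": gi,
                    "col": gj,
                    "kept": frac < config.background_max_fraction,
                    "background_fraction": frac,
                }
            )
    return pd.DataFrame(rows)


def stitch_patches(
    patches: list[np.ndarray],
    coords: list[tuple[int, int]],
    shape: tuple[int, int],
    stride: int,
    fill=np.nan,
) -> np.ndarray:
    """Re-stitch per-tile arrays into the slide frame; unvisited pixels get ``fill``.

    ``coords`` are (grid_row, grid_col) indices; pixel origin of a tile is
    (grid_row * stride, grid_col * stride).
    """
    if not patches:
        return np.full(shape, fill, dtype=float)
    p = patches[0].shape[0]
    dtype = np.promote_types(patches[0].dtype, np.min_scalar_type(fill))
    out = np.full(shape + patches[0].shape[2:], fill, dtype=dtype)
    for patch, (gi, gj) in zip(patches, coords):
        r0, c0 = gi * stride, gj * stride
        out[r0 : r0 + p, c0 : c0 + p] = patch
    return out
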