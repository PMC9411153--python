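"""Tissue masking, patch-grid extraction and dataset augmentation.

Cores are scanned H&E images on a glass (near-white) background. The mask
pipeline is fixed: greyscale -> Otsu threshold (tissue = darker side) ->
morphological closing -> keep the main tissue contour, filling interior
holes smaller than a physical area threshold (~1470 µm², i.e. 23,520 px²
at 0.25 µm/pixel); larger holes are genuine background and are preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from skimage.color import rgb2gray, rgb2hsv, hsv2rgb
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import closing, disk

__all__ = [
    "CoreImage",
    "TissueMask",
    "PatchGrid",
    "compute_tissue_mask",
    "extract_patch_grid",
    "augment_cohort",
    "AUGMENTATIONS_GEO4",
    "AUGMENTATIONS_GEOCOLOUR13",
    "DEFAULT_HOLE_AREA_UM2",
]

DEFAULT_HOLE_AREA_UM2 = 1470.0
_CLOSING_RADIUS_PX_AT_QUARTER_MICRON = 5


@dataclass(frozen=True)
class CoreImage:
    """RGB (or greyscale) raster of one TMA core with its physical scale."""

    pixels: np.ndarray
    resolution: float  # µm per pixel
    core_id: str = ""

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution (µm/pixel) must be positive")
        if self.pixels.size == 0:
            raise ValueError("empty raster")

    @property
    def shape_2d(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class TissueMask:
    mask: np.ndarray  # bool, same height/width as the image
    min_suppressed_hole_um2: float = DEFAULT_HOLE_AREA_UM2

    def tissue_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass(frozen=True)
class PatchGrid:
    """Non-overlapping patch grid, origins 0-based on multiples of the size."""

    patch_size_px: int
    origins: tuple[tuple[int, int], ...]
    tissue_fraction: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.origins)

    def to_frame(self, core_id: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "core_id": core_id,
                "row": [r for r, _ in self.origins],
                "col": [c for _, c in self.origins],
                "patch_size_px": self.patch_size_px,
                "tissue_fraction": self.tissue_fraction,
            }
        )


def _to_grey(pixels: np.ndarray) -> np.ndarray:
    if pixels.ndim == 3:
        return rgb2gray(pixels)
    return pixels.astype(float) / (255.0 if pixels.dtype == np.uint8 else 1.0)


def compute_tissue_mask(
    image: CoreImage, hole_area_um2: float = DEFAULT_HOLE_AREA_UM2
) -> TissueMask:
    """Binary tissue mask of a core image.

    The area threshold is physical: holes below ``hole_area_um2`` are stain
    gaps and are filled; larger interior holes (damaged/missing tissue) stay
    background. The closing kernel is a disc of 5 px at 0.25 µm/px, scaled
    inversely with resolution.
    """
    grey = _to_grey(image.pixels)
    if np.ptp(grey) == 0:
        warnings.warn(
            f"core {image.core_id!r}: constant-intensity image, Otsu degenerate; empty mask",
            stacklevel=2,
        )
        return TissueMask(np.zeros(grey.shape, dtype=bool), hole_area_um2)
    thr = threshold_otsu(grey)
    tissue = grey < thr  # H&E tissue is darker than glass
    radius = max(1, round(_CLOSING_RADIUS_PX_AT_QUARTER_MICRON * 0.25 / image.resolution))
    tissue = closing(tissue, disk(radius))
    labels = cc_label(tissue, connectivity=2)
    if labels.max() > 0:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        tissue = labels == sizes.argmax()
    hole_area_px = hole_area_um2 / image.resolution**2
    # fill enclosed holes strictly smaller than the physical threshold;
    # background touching the image border is never a hole
    bg_labels = cc_label(~tissue, connectivity=1)
    border = np.unique(
        np.concatenate(
            [bg_labels[0, :], bg_labels[-1, :], bg_labels[:, 0], bg_labels[:, -1]]
        )
    )
    sizes = np.bincount(bg_labels.ravel())
    for comp in range(1, bg_labels.max() + 1):
        if comp not in border and sizes[comp] < hole_area_px:
            tissue[bg_labels == comp] = True
    return TissueMask(tissue, hole_area_um2)


def extract_patch_grid(
    mask: TissueMask, patch_size_px: int, min_tissue_fraction: float = 0.5
) -> PatchGrid:
    """Grid of non-overlapping ``patch_size_px`` patches covering the mask.

    The grid starts at (0, 0); partial boundary patches are discarded. A
    patch is retained when its share of mask-positive pixels is at least
    ``min_tissue_fraction``.
    """
    if patch_size_px < 1:
        raise ValueError("patch_size_px must be >= 1")
    h, w = mask.mask.shape
    n_rows = h // patch_size_px
    n_cols = w // patch_size_px
    if n_rows == 0 or n_cols == 0:
        return PatchGrid(patch_size_px, (), ())
    cropped = mask.mask[: n_rows * patch_size_px, : n_cols * patch_size_px]
    fractions = cropped.reshape(n_rows, patch_size_px, n_cols, patch_size_px).mean(axis=(1, 3))
    origins, fracs = [], []
    for i in range(n_rows):
        for j in range(n_cols):
            if fractions[i, j] >= min_tissue_fraction:
                origins.append((i * patch_size_px, j * patch_size_px))
                fracs.append(float(fractions[i, j]))
    return PatchGrid(patch_size_px, tuple(origins), tuple(fracs))


# --- augmentation -----------------------------------------------------------

def _rot(k: int) -> Callable[[np.ndarray], np.ndarray]:
    return lambda im: np.rot90(im, k=k, axes=(0, 1)).copy()


def _hflip(im: np.ndarray) -> np.ndarray:
    return np.flip(im, axis=1).copy()


def _vflip(im: np.ndarray) -> np.ndarray:
    return np.flip(im, axis=0).copy()


def _hflip_rot90(im: np.ndarray) -> np.ndarray:
    return _rot(1)(_hflip(im))


def _colour_jitter(im: np.ndarray) -> np.ndarray:
    """Fixed-strength brightness/saturation jitter (deterministic)."""
    if im.ndim != 3:
        return np.clip(im.astype(float) * 1.08, 0, 255).astype(im.dtype)
    hsv = rgb2hsv(im)
    hsv[..., 1] = np.clip(hsv[..., 1] * 0.85, 0, 1)  # desaturate
    hsv[..., 2] = np.clip(hsv[..., 2] * 1.08, 0, 1)  # brighten
    out = hsv2rgb(hsv)
    if im.dtype == np.uint8:
        return (out * 255).round().astype(np.uint8)
    return out


AUGMENTATIONS_GEO4: tuple[tuple[str, Callable[[np.ndarray], np.ndarray]], ...] = (
    ("identity", lambda im: im.copy()),
    ("hflip", _hflip),
    ("vflip", _vflip),
    ("rot90", _rot(1)),
)

_GEO6 = (
    ("rot90", _rot(1)),
    ("rot180", _rot(2)),
    ("rot270", _rot(3)),
    ("hflip", _hflip),
    ("vflip", _vflip),
    ("hflip_rot90", _hflip_rot90),
)

AUGMENTATIONS_GEOCOLOUR13: tuple[tuple[str, Callable[[np.ndarray], np.ndarray]], ...] = (
    ("identity", lambda im: im.copy()),
    *[(name, fn) for name, fn in _GEO6],
    *[(f"{name}+jitter", (lambda f: (lambda im: _colour_jitter(f(im))))(fn)) for name, fn in _GEO6],
)


@dataclass(frozen=True)
class AugmentedItem:
    """One augmented copy of a patient's image set (or feature bag)."""

    patient_id: str
    source_patient_id: str
    transform: str
    payload: object  # list of images, or the original bag untouched
    label: object


def augment_cohort(items: Sequence, mode: str) -> list[AugmentedItem]:
    """Expand a cohort by deterministic geometric/colour transforms.

    ``mode='geo4'`` emits the original plus 3 geometric transforms (4x);
    ``mode='geocolour13'`` emits the original plus 12 transforms (13x).
    Each item is ``(patient_id, images, label)`` (images: list of HxWx3
    arrays) or any object with ``patient_id``/``label`` attributes, in which
    case the payload is carried over unchanged and only provenance is added.
    Augmented copies share the source patient's survival label.
    """
    if mode == "geo4":
        transforms = AUGMENTATIONS_GEO4
    elif mode == "geocolour13":
        transforms = AUGMENTATIONS_GEOCOLOUR13
    else:
        raise ValueError(f"unknown augmentation mode {mode!r}; use 'geo4' or 'geocolour13'")
    out: list[AugmentedItem] = []
    for item in items:
        if isinstance(item, tuple) and len(item) == 3:
            pid, images, lab = item
            for name, fn in transforms:
                payload = [fn(np.asarray(im)) for im in images]
                out.append(
                    AugmentedItem(
                        patient_id=f"{pid}#{name}",
                        source_patient_id=pid,
                        transform=name,
                        payload=payload,
                        label=lab,
                    )
                )
        else:
            pid = item.patient_id
            for name, _ in transforms:
                out.append(
                    AugmentedItem(
                        patient_id=f"{pid}#{name}",
                        source_patient_id=pid,
                        transform=name,
                        payload=item,
                        label=item.label,
                    )
                )
    return out
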