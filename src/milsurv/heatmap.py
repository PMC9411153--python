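"""Attention heatmap overlays for the instance-level model.

Per-patch attention weights are rescaled to [0, 1] against the global
minimum/maximum over the whole dataset, placed on the core's patch grid,
bilinearly interpolated to pixel resolution, colour-mapped and alpha-
blended over the H&E image. Non-tissue regions are left untinted when a
mask is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
import pandas as pd
from matplotlib import colormaps
from skimage.transform import resize

from .preprocess import CoreImage, TissueMask

__all__ = ["AttentionMap", "scale_attention", "render_heatmap", "attention_to_frame"]


def scale_attention(weights, global_min: float, global_max: float) -> np.ndarray:
    """Affine rescale of raw attention weights to [0, 1] (clipped).

    The bounds are the dataset-wide minimum and maximum attention weight so
    that maps of different cores are comparable. Degenerate bounds
    (max == min) map every weight to 0.5. Rescaling preserves ranking.
    """
    if global_max < global_min:
        raise ValueError("global_max must be >= global_min")
    w = np.asarray(weights, dtype=float)
    if global_max == global_min:
        return np.full_like(w, 0.5)
    return np.clip((w - global_min) / (global_max - global_min), 0.0, 1.0)


@dataclass(frozen=True)
class AttentionMap:
    """Scaled per-patch attention weights on one core's patch grid."""

    core_id: str
    origins: tuple[tuple[int, int], ...]  # top-left (row, col) per patch
    raw: np.ndarray
    patch_size_px: int
    global_min: float
    global_max: float

    @property
    def scaled(self) -> np.ndarray:
        return scale_attention(self.raw, self.global_min, self.global_max)


def attention_to_frame(amap: AttentionMap) -> pd.DataFrame:
    """Side-car table of raw and scaled weights per patch."""
    scaled = amap.scaled
    return pd.DataFrame(
        {
            "core_id": amap.core_id,
            "row": [r for r, _ in amap.origins],
            "col": [c for _, c in amap.origins],
            "attention_raw": amap.raw,
            "attention_scaled": scaled,
        }
    )


def render_heatmap(
    core: CoreImage,
    amap: AttentionMap,
    mask: TissueMask | None = None,
    cmap: str = "jet",
    alpha: float = 0.4,
) -> np.ndarray:
    """Overlay an attention heatmap on a core image (same height/width).

    The scaled weights are laid out on the patch grid, bilinearly upsampled
    to pixel resolution and blended over the image with opacity ``alpha``.
    """
    h, w = core.shape_2d
    s = amap.patch_size_px
    for (r, c) in amap.origins:
        if r + s > h or c + s > w:
            raise ValueError(f"patch at ({r}, {c}) exceeds the {h}x{w} core raster")
    n_rows, n_cols = h // s, w // s
    coarse = np.zeros((n_rows, n_cols))
    covered = np.zeros((n_rows, n_cols), dtype=bool)
    for (r, c), val in zip(amap.origins, amap.scaled):
        coarse[r // s, c // s] = val
        covered[r // s, c // s] = True
    field = resize(coarse, (h, w), order=1, mode="edge", anti_aliasing=False)
    img = np.asarray(core.pixels, dtype=float)
    if img.ndim == 2:
        img = img[:, :, None].repeat(3, axis=2)
    if img.max() > 1.0:
        img = img / 255.0
    colours = colormaps[cmap](field)[..., :3]
    blend_region = resize(covered.astype(float), (h, w), order=0) > 0.5
    if mask is not None:
        blend_region &= mask.mask
    out = img.copy()
    out[blend_region] = (1 - alpha) * img[blend_region] + alpha * colours[blend_region]
    return (out * 255).round().astype(np.uint8)
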