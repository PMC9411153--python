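"""Patch encoder contract, super-patch assembly and per-patient feature bags.

The survival pipeline consumes fixed patch embeddings rather than raw
pixels: each 256x256 px patch at 0.25 µm/px is downsampled by 2 (to the
encoder's native 128x128 @ 0.5 µm/px) and mapped to a 128-dimensional
vector. Four adjacent 256-px vectors form one 2x2x128 "super-patch"
instance representing a 512x512 px tissue area.

Training the compression encoder itself is out of scope: any object
satisfying :class:`EncoderContract` can be plugged in, and the package
ships a deterministic synthetic stand-in (a seeded random projection of
block-averaged pixel content) so every downstream stage is exercisable
without external weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Protocol, Sequence, runtime_checkable

import numpy as np

from .cohort import PatientRecord, SurvivalLabel
from .preprocess import PatchGrid

__all__ = [
    "InstanceFeature",
    "PatientBag",
    "EncoderContract",
    "SyntheticEncoder",
    "downsample_by_two",
    "encode_patch",
    "assemble_superpatches",
    "build_bags",
]


@dataclass(frozen=True)
class InstanceFeature:
    """One MIL instance: a d-vector (optionally a g x g x d super-patch grid).

    ``vector`` is stored flattened (length g*g*d); ``grid_shape`` records the
    spatial layout, None for plain 1x1xd patch vectors. ``source`` locates
    the instance as (core_id, row, col) of its top-left patch.
    """

    vector: np.ndarray
    source: tuple[str, int, int] = ("", 0, 0)
    grid_shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float)
        if v.ndim != 1 or not np.all(np.isfinite(v)):
            raise ValueError("instance vector must be 1-D and finite")
        object.__setattr__(self, "vector", v)
        if self.grid_shape is not None:
            g0, g1, d = self.grid_shape
            if g0 * g1 * d != v.size:
                raise ValueError(f"grid_shape {self.grid_shape} inconsistent with vector of size {v.size}")

    @property
    def d(self) -> int:
        return self.vector.size if self.grid_shape is None else self.grid_shape[2]


@dataclass(frozen=True)
class PatientBag:
    """A patient's set of instances plus the single survival label they share."""

    patient_id: str
    instances: tuple[InstanceFeature, ...]
    label: SurvivalLabel

    def __post_init__(self) -> None:
        inst = tuple(self.instances)
        if len(inst) == 0:
            raise ValueError(f"patient {self.patient_id!r}: a bag must hold at least one instance")
        sizes = {i.vector.size for i in inst}
        shapes = {i.grid_shape for i in inst}
        if len(sizes) > 1 or len(shapes) > 1:
            raise ValueError(f"patient {self.patient_id!r}: instances disagree on shape")
        object.__setattr__(self, "instances", inst)

    def __len__(self) -> int:
        return len(self.instances)

    def feature_matrix(self) -> np.ndarray:
        """(n_instances, p) matrix of flattened instance vectors."""
        return np.stack([i.vector for i in self.instances])


@runtime_checkable
class EncoderContract(Protocol):
    """Maps one 128x128 RGB tile to a fixed-length feature vector."""

    d: int

    def encode(self, tile: np.ndarray) -> np.ndarray: ...


class SyntheticEncoder:
    """Deterministic stand-in for the pretrained compression encoder.

    Block-averages the 128x128 RGB tile to a 16x16x3 summary, then applies a
    seeded Gaussian random projection to ``d`` dimensions followed by tanh.
    Identical tiles map to identical vectors; a single-pixel change perturbs
    one block mean and hence the output. This is a synthetic surrogate: it
    preserves pixel-content differences but carries no histology semantics.
    """

    tile_px = 128
    _block = 8  # 128 / 16

    def __init__(self, d: int = 128, seed: int = 0):
        self.d = d
        rng = np.random.default_rng(seed)
        n_in = (self.tile_px // self._block) ** 2 * 3
        self._projection = rng.standard_normal((d, n_in)) / np.sqrt(n_in)

    def encode(self, tile: np.ndarray) -> np.ndarray:
        tile = np.asarray(tile, dtype=float)
        if tile.ndim == 2:
            tile = tile[:, :, None].repeat(3, axis=2)
        if tile.shape[:2] != (self.tile_px, self.tile_px) or tile.shape[2] != 3:
            raise ValueError(f"encoder expects a {self.tile_px}x{self.tile_px} RGB tile, got {tile.shape}")
        b = self._block
        g = self.tile_px // b
        summary = tile.reshape(g, b, g, b, 3).mean(axis=(1, 3)) / 255.0
        return np.tanh(self._projection @ (summary.ravel() - 0.5))


def downsample_by_two(patch: np.ndarray) -> np.ndarray:
    """2x2 block-mean downsampling (256 px @ 0.25 µm -> 128 px @ 0.5 µm)."""
    h, w = patch.shape[:2]
    if h % 2 or w % 2:
        raise ValueError("patch dimensions must be even")
    p = np.asarray(patch, dtype=float)
    if p.ndim == 2:
        return p.reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))
    return p.reshape(h // 2, 2, w // 2, 2, p.shape[2]).mean(axis=(1, 3))


def encode_patch(patch: np.ndarray, encoder: EncoderContract) -> np.ndarray:
    """Encode one 256x256 px patch: downsample by 2, then apply the encoder."""
    patch = np.asarray(patch)
    if patch.shape[:2] != (2 * encoder.tile_px, 2 * encoder.tile_px):
        raise ValueError(
            f"expected a {2 * encoder.tile_px}x{2 * encoder.tile_px} patch, got {patch.shape[:2]}"
        )
    vec = encoder.encode(downsample_by_two(patch))
    if vec.shape != (encoder.d,):
        raise ValueError("encoder returned a vector of unexpected length")
    return vec


def assemble_superpatches(
    grid: PatchGrid,
    features: Mapping[tuple[int, int], np.ndarray],
    core_id: str = "",
) -> list[InstanceFeature]:
    """Group four adjacent 256-px patch vectors into 2x2xd instances.

    A 512-px block aligned to even multiples of the patch size becomes one
    instance iff all four children survived tissue filtering; incomplete
    blocks are dropped. Children are concatenated row-major: (0,0), (0,1),
    (1,0), (1,1).
    """
    s = grid.patch_size_px
    available = set(grid.origins)
    out: list[InstanceFeature] = []
    for (r, c) in grid.origins:
        if (r // s) % 2 or (c // s) % 2:
            continue  # only top-left children anchor a block
        children = [(r, c), (r, c + s), (r + s, c), (r + s, c + s)]
        if not all(ch in available for ch in children):
            continue
        vecs = [np.asarray(features[ch], dtype=float) for ch in children]
        d = vecs[0].size
        out.append(
            InstanceFeature(
                vector=np.concatenate(vecs),
                source=(core_id, r, c),
                grid_shape=(2, 2, d),
            )
        )
    return out


def build_bags(
    cohort: Sequence[PatientRecord],
    features_by_core: Mapping[str, Sequence[InstanceFeature]],
) -> list[PatientBag]:
    """Pool instances across each patient's cores into one bag per patient.

    Every core in ``features_by_core`` must belong to exactly one patient of
    the cohort; a patient whose cores yielded no instances is an error (a
    bag may not be empty).
    """
    core_to_patient: dict[str, str] = {}
    for rec in cohort:
        for core in rec.core_ids:
            core_to_patient[core] = rec.patient_id
    orphans = sorted(set(features_by_core) - set(core_to_patient))
    if orphans:
        raise ValueError(f"feature store contains cores not in the cohort: {orphans}")
    bags = []
    for rec in cohort:
        instances: list[InstanceFeature] = []
        for core in rec.core_ids:
            instances.extend(features_by_core.get(core, ()))
        if not instances:
            raise ValueError(f"patient {rec.patient_id!r} has no surviving instances")
        bags.append(PatientBag(rec.patient_id, tuple(instances), rec.label))
    return bags
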