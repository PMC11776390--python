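"""Cube patch extraction, foreground filtering, train/val split, reconstruction.

Volumes are tiled with cube-shaped sub-volumes on a regular stride grid; the
last origin along each axis is clamped inward so the final cube touches the
boundary (full coverage, no zero padding).  Patches with less than the
minimum foreground fraction (default 5%, inclusive) are discarded before
training; the survivors are split 75/25 into train/val by a seeded uniform
permutation.  Full-volume predictions are rebuilt by averaging class scores
over all cubes covering a voxel and taking the argmax (ties go to the lowest
class index); voxels covered by no selected cube are background.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import PatchingError
from .mri_io import CLASS_MAP, DixonVolume, LabelVolume


@dataclass
class Patch:
    origin: tuple[int, int, int]
    size: int
    image_data: np.ndarray  # (4, size, size, size) float32
    label_data: np.ndarray | None = None  # (size,)*3 int
    foreground_fraction: float | None = None
    split: str | None = None  # 'train' | 'val' | None

    def __post_init__(self):
        if self.image_data.ndim != 4 or self.image_data.shape[1:] != (self.size,) * 3:
            raise PatchingError(
                f"patch image shape {self.image_data.shape} does not match cube {self.size}"
            )


@dataclass
class PatchSet:
    patches: list[Patch]
    source_shape: tuple[int, int, int]
    cube: int
    stride: int
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __len__(self):
        return len(self.patches)

    def __iter__(self):
        return iter(self.patches)

    def subset(self, split: str) -> list[Patch]:
        return [p for p in self.patches if p.split == split]

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "origin_x": [p.origin[0] for p in self.patches],
                "origin_y": [p.origin[1] for p in self.patches],
                "origin_z": [p.origin[2] for p in self.patches],
                "foreground_fraction": [p.foreground_fraction for p in self.patches],
                "split": [p.split for p in self.patches],
            }
        )


def axis_origins(extent: int, cube: int, stride: int) -> list[int]:
    """Regular origins with the final one clamped so the last cube touches
    the boundary."""
    if cube > extent:
        raise PatchingError(f"cube {cube} exceeds axis extent {extent}")
    origins = list(range(0, extent - cube + 1, stride))
    if origins[-1] != extent - cube:
        origins.append(extent - cube)
    return origins


def extract_patches(
    vol: DixonVolume,
    labels: LabelVolume | None,
    cube: int = 32,
    stride: int = 16,
) -> PatchSet:
    """Tile ``vol`` (and, when given, ``labels``) into cube patches."""
    shape = vol.shape
    if labels is not None and labels.shape != shape:
        raise PatchingError(f"label grid {labels.shape} does not match volume {shape}")
    if not 1 <= stride <= cube:
        raise PatchingError(f"stride must satisfy 1 <= stride <= cube, got {stride}")
    for extent in shape:
        if cube > extent:
            raise PatchingError(f"cube {cube} larger than volume extent {extent}")
    channels = vol.stacked().astype(np.float32)
    lab = labels.labels if labels is not None else None
    patches = []
    for ox in axis_origins(shape[0], cube, stride):
        for oy in axis_origins(shape[1], cube, stride):
            for oz in axis_origins(shape[2], cube, stride):
                sl = np.s_[ox : ox + cube, oy : oy + cube, oz : oz + cube]
                patch_labels = None
                frac = None
                if lab is not None:
                    patch_labels = lab[sl].copy()
                    frac = float(np.count_nonzero(patch_labels)) / patch_labels.size
                patches.append(
                    Patch(
                        origin=(ox, oy, oz),
                        size=cube,
                        image_data=channels[(slice(None),) + sl].copy(),
                        label_data=patch_labels,
                        foreground_fraction=frac,
                    )
                )
    return PatchSet(
        patches=patches,
        source_shape=shape,
        cube=cube,
        stride=stride,
        voxel_spacing=vol.voxel_spacing,
    )


def filter_foreground(ps: PatchSet, min_fraction: float = 0.05) -> PatchSet:
    """Keep patches whose foreground fraction is >= ``min_fraction``."""
    if any(p.foreground_fraction is None for p in ps.patches):
        raise PatchingError("filter_foreground requires patches extracted with labels")
    kept = [p for p in ps.patches if p.foreground_fraction >= min_fraction]
    return replace(ps, patches=kept)


def split_train_val(ps: PatchSet, train_fraction: float = 0.75, seed: int = 0) -> PatchSet:
    """Assign floor(train_fraction*n) patches to train, the rest to val,
    by a seeded uniform permutation."""
    n = len(ps.patches)
    if n < 2:
        raise PatchingError(f"need at least 2 patches to split, got {n}")
    if not 0.0 < train_fraction < 1.0:
        raise PatchingError("train_fraction must be in (0, 1)")
    n_train = int(np.floor(train_fraction * n))
    perm = np.random.default_rng(seed).permutation(n)
    assigned = []
    train_idx = set(perm[:n_train].tolist())
    for i, p in enumerate(ps.patches):
        assigned.append(replace(p, split="train" if i in train_idx else "val"))
    return replace(ps, patches=assigned)


def reconstruct(
    predictions: Sequence[np.ndarray],
    ps: PatchSet,
    background_class: int = 0,
    n_classes: int = 4,
) -> LabelVolume:
    """Assemble per-patch class-score cubes into a full label volume.

    ``predictions[i]`` must be a ``(n_classes, cube, cube, cube)`` score
    array for ``ps.patches[i]``.  Scores are averaged over covering patches,
    the per-voxel argmax taken (ties -> lowest class index), and uncovered
    voxels set to ``background_class``.
    """
    if len(predictions) != len(ps.patches):
        raise PatchingError(
            f"got {len(predictions)} predictions for {len(ps.patches)} patches"
        )
    c = ps.cube
    score_sum = np.zeros((n_classes,) + tuple(ps.source_shape), dtype=np.float64)
    cover = np.zeros(ps.source_shape, dtype=np.int32)
    for pred, patch in zip(predictions, ps.patches):
        pred = np.asarray(pred)
        if pred.shape != (n_classes, c, c, c):
            raise PatchingError(
                f"prediction shape {pred.shape} does not match ({n_classes}, {c}, {c}, {c})"
            )
        ox, oy, oz = patch.origin
        sl = np.s_[ox : ox + c, oy : oy + c, oz : oz + c]
        score_sum[(slice(None),) + sl] += pred
        cover[sl] += 1
    covered = cover > 0
    mean = np.zeros_like(score_sum)
    np.divide(score_sum, cover[None], out=mean, where=covered[None])
    labels = np.argmax(mean, axis=0).astype(np.int16)
    labels[~covered] = background_class
    return LabelVolume(
        labels=labels, voxel_spacing=ps.voxel_spacing, class_map=dict(CLASS_MAP)
    )


def one_hot_labels(labels: np.ndarray, n_classes: int = 4) -> np.ndarray:
    """(n_classes, *labels.shape) one-hot float32 encoding."""
    out = np.zeros((n_classes,) + labels.shape, dtype=np.float32)
    for cls in range(n_classes):
        out[cls] = labels == cls
    return out


def save_patchset(ps: PatchSet, out_dir) -> Path:
    """Persist a patch set as one .npz per patch plus a CSV manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, p in enumerate(ps.patches):
        payload = {"image": p.image_data, "origin": np.array(p.origin)}
        if p.label_data is not None:
            payload["labels"] = p.label_data
        np.savez_compressed(out_dir / f"patch_{i:05d}.npz", **payload)
    manifest = ps.manifest()
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return out_dir
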