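"""Per-class tissue volumetry and segmentation overlap scoring."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, SlabError, StatsError
from .mri_io import LabelVolume


@dataclass
class VolumeReport:
    """Exact voxel counts and physical volumes per tissue class."""

    voxel_counts: dict[int, int]
    volume_cm3: dict[int, float]
    voxel_volume_mm3: float
    slab: tuple[int, int] | None  # (anchor, n_slices), None = whole volume
    class_map: dict[int, str]

    def as_dict(self) -> dict[str, float]:
        return {self.class_map[c]: self.volume_cm3[c] for c in sorted(self.volume_cm3)}


def compute_volumes(labels: LabelVolume, slab: tuple[int, int] | None = None) -> VolumeReport:
    """Count voxels per class over ``slab`` and convert via the voxel volume.

    ``slab`` is a half-open (anchor, n_slices) interval on the slice axis;
    ``None`` uses the whole volume.
    """
    arr = labels.labels
    if slab is not None:
        anchor, n_slices = slab
        if n_slices <= 0:
            raise SlabError(f"empty slab requested: n_slices={n_slices}")
        if anchor < 0 or anchor + n_slices > arr.shape[2]:
            raise SlabError(
                f"slab [{anchor}, {anchor + n_slices}) out of range for "
                f"{arr.shape[2]} slices"
            )
        arr = arr[:, :, anchor : anchor + n_slices]
    vv = labels.voxel_volume_mm3
    classes = sorted(labels.class_map)
    counts = np.bincount(arr.ravel(), minlength=max(classes) + 1)
    voxel_counts = {c: int(counts[c]) for c in classes}
    volume_cm3 = {c: voxel_counts[c] * vv / 1000.0 for c in classes}
    return VolumeReport(
        voxel_counts=voxel_counts,
        volume_cm3=volume_cm3,
        voxel_volume_mm3=vv,
        slab=slab,
        class_map=dict(labels.class_map),
    )


def dice_coefficient(pred: LabelVolume, truth: LabelVolume, class_id: int) -> float:
    """Dice similarity 2|P∩T| / (|P|+|T|) of one class; 1.0 when both empty."""
    if pred.shape != truth.shape:
        raise AlignmentError(
            f"prediction grid {pred.shape} does not match truth {truth.shape}"
        )
    p = pred.labels == class_id
    t = truth.labels == class_id
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.count_nonzero(p & t)) / denom


def dice_per_class(pred: LabelVolume, truth: LabelVolume, classes=(1, 2, 3)) -> dict[int, float]:
    return {c: dice_coefficient(pred, truth, c) for c in classes}


def percent_change(pre_cm3: float, post_cm3: float) -> float:
    """100 * (post - pre) / pre; full precision (round only for display)."""
    if pre_cm3 <= 0:
        raise StatsError(f"baseline volume must be positive, got {pre_cm3}")
    return 100.0 * (post_cm3 - pre_cm3) / pre_cm3
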