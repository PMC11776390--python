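"""Volume containers and NIfTI I/O with a single grid contract.

Every pipeline stage consumes either a :class:`DixonVolume` (the four
co-registered Dixon contrasts: in-phase, opposed-phase, water, fat) or a
:class:`LabelVolume` (integer tissue map on the same grid).  Axis order is
(x, y, slice); voxel indices are 0-based and slab intervals are half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np

from .errors import AlignmentError, SlabError

log = logging.getLogger("dixonseg.mri_io")

CONTRAST_NAMES = ("in_phase", "opposed_phase", "water", "fat")

#: Tissue classes used throughout the package.
CLASS_MAP = {0: "background", 1: "muscle", 2: "sat", 3: "bone"}
TISSUE_CLASSES = (1, 2, 3)


def affine_from_spacing(voxel_spacing: Sequence[float]) -> np.ndarray:
    """RAS-aligned affine with the grid origin at world (0, 0, 0)."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_spacing
    return aff


def _check_spacing(voxel_spacing):
    spacing = tuple(float(s) for s in voxel_spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"voxel_spacing must be 3 positive floats, got {voxel_spacing}")
    return spacing


@dataclass
class DixonVolume:
    """Four aligned 3D intensity grids plus voxel geometry."""

    in_phase: np.ndarray
    opposed_phase: np.ndarray
    water: np.ndarray
    fat: np.ndarray
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.voxel_spacing = _check_spacing(self.voxel_spacing)
        shapes = {name: getattr(self, name).shape for name in CONTRAST_NAMES}
        ref = self.in_phase.shape
        for name, shp in shapes.items():
            if len(shp) != 3 or shp != ref:
                raise AlignmentError(f"contrast {name!r} has shape {shp}, expected {ref}")
        for name in CONTRAST_NAMES:
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"contrast {name!r} contains non-finite intensities")
            if arr.min() < 0:
                raise ValueError(f"contrast {name!r} contains negative intensities")
            setattr(self, name, arr)
        if self.affine is None:
            self.affine = affine_from_spacing(self.voxel_spacing)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.in_phase.shape

    @property
    def n_slices(self) -> int:
        return self.shape[2]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_spacing))

    def contrasts(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in CONTRAST_NAMES}

    def stacked(self) -> np.ndarray:
        """Channel-first array of shape (4, nx, ny, nz)."""
        return np.stack([getattr(self, name) for name in CONTRAST_NAMES], axis=0)


@dataclass
class LabelVolume:
    """Integer tissue map: 0 background, 1 muscle, 2 SAT, 3 bone."""

    labels: np.ndarray
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    class_map: Mapping[int, str] = field(default_factory=lambda: dict(CLASS_MAP))
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.voxel_spacing = _check_spacing(self.voxel_spacing)
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got shape {labels.shape}")
        if not np.issubdtype(labels.dtype, np.integer):
            rounded = np.rint(labels)
            if not np.allclose(labels, rounded):
                raise ValueError("labels must be integer-valued")
            labels = rounded.astype(np.int16)
        extra = set(np.unique(labels)) - set(self.class_map)
        if extra:
            raise ValueError(f"labels contain values outside class_map: {sorted(extra)}")
        self.labels = labels
        if self.affine is None:
            self.affine = affine_from_spacing(self.voxel_spacing)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def n_slices(self) -> int:
        return self.labels.shape[2]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_spacing))


# ---------------------------------------------------------------------------
# NIfTI round trips


def _spacing_from_affine(affine: np.ndarray) -> tuple[float, float, float]:
    return tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))


def write_dixon(vol: DixonVolume, out_dir, stem: str = "dixon") -> dict[str, Path]:
    """Write one NIfTI file per contrast; returns the path map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, arr in vol.contrasts().items():
        path = out_dir / f"{stem}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr), vol.affine), path)
        paths[name] = path
    return paths


def read_dixon(paths: Mapping[str, Path] | Sequence[Path], atol: float = 1e-4) -> DixonVolume:
    """Load four contrast files into an aligned :class:`DixonVolume`.

    ``paths`` maps contrast name -> file, or is a sequence ordered as
    ``CONTRAST_NAMES``.  Grids or affines differing beyond ``atol`` are
    rejected with an :class:`AlignmentError` naming the offending contrast.
    """
    if not isinstance(paths, Mapping):
        if len(paths) != 4:
            raise ValueError("expected four contrast paths")
        paths = dict(zip(CONTRAST_NAMES, paths))
    missing = set(CONTRAST_NAMES) - set(paths)
    if missing:
        raise ValueError(f"missing contrasts: {sorted(missing)}")
    imgs = {}
    for name in CONTRAST_NAMES:
        p = Path(paths[name])
        if not p.exists():
            raise FileNotFoundError(p)
        imgs[name] = nib.load(str(p))
    ref_name = CONTRAST_NAMES[0]
    ref = imgs[ref_name]
    for name, img in imgs.items():
        if img.shape != ref.shape:
            raise AlignmentError(
                f"contrast {name!r} grid {img.shape} does not match {ref_name!r} {ref.shape}"
            )
        if not np.allclose(img.affine, ref.affine, atol=atol):
            raise AlignmentError(f"contrast {name!r} affine deviates from {ref_name!r}")
    data = {name: np.asarray(img.get_fdata(), dtype=np.float64) for name, img in imgs.items()}
    return DixonVolume(
        **data, voxel_spacing=_spacing_from_affine(ref.affine), affine=np.asarray(ref.affine)
    )


def write_labels(labels: LabelVolume, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(labels.labels.astype(np.uint8), labels.affine), path)
    return path


def read_labels(path) -> LabelVolume:
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int16)
    return LabelVolume(
        labels=labels,
        voxel_spacing=_spacing_from_affine(img.affine),
        affine=np.asarray(img.affine),
    )


# ---------------------------------------------------------------------------
# Slab selection


def select_slab(vol, n_slices: int, anchor_slice: int = 0):
    """Crop ``n_slices`` contiguous slices starting at ``anchor_slice``.

    The interval is half-open: slices ``anchor_slice .. anchor_slice+n_slices-1``
    are retained.  Works for both :class:`DixonVolume` and :class:`LabelVolume`;
    the affine origin is shifted so world coordinates are preserved.
    """
    if n_slices <= 0:
        raise SlabError(f"n_slices must be positive, got {n_slices}")
    if anchor_slice < 0 or anchor_slice + n_slices > vol.n_slices:
        raise SlabError(
            f"slab [{anchor_slice}, {anchor_slice + n_slices}) out of range "
            f"for {vol.n_slices} slices"
        )
    log.info(
        "select_slab: keeping slices [%d, %d) of %d (%s)",
        anchor_slice, anchor_slice + n_slices, vol.n_slices, type(vol).__name__,
    )
    new_affine = vol.affine.copy()
    new_affine[:3, 3] += vol.affine[:3, 2] * anchor_slice
    sl = np.s_[:, :, anchor_slice : anchor_slice + n_slices]
    if isinstance(vol, DixonVolume):
        return DixonVolume(
            **{name: arr[sl].copy() for name, arr in vol.contrasts().items()},
            voxel_spacing=vol.voxel_spacing,
            affine=new_affine,
        )
    if isinstance(vol, LabelVolume):
        return LabelVolume(
            labels=vol.labels[sl].copy(),
            voxel_spacing=vol.voxel_spacing,
            class_map=dict(vol.class_map),
            affine=new_affine,
        )
    raise TypeError(f"unsupported volume type {type(vol)!r}")
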