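"""Synthetic Dixon thigh phantoms and pre/post training cohorts.

The anatomy is a single-thigh stack of concentric discs per axial slice:
an outer subcutaneous-fat (SAT) ring, a muscle bulk, and a central bone
consisting of a cortical shell around fatty marrow.  Slice centers wobble
smoothly along the stack so the cylinder is not perfectly straight.

Signal synthesis follows the two-point Dixon decomposition: each tissue has
a reference signal ``S`` and a fat fraction ``ff``; the water image is
``S*(1-ff)``, the fat image ``S*ff``, the in-phase image their sum and the
opposed-phase image the absolute difference.  Rician noise and a smooth
multiplicative bias field are applied identically (same seeded draws) to
all four contrasts.

Cohorts emulate a two-group (intervention IG / control CG) pre/post design:
a prescribed percent muscle gain in IG only, a common percent SAT drift over
time, no systematic bone change, and multiplicative log-normal
within-subject measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import GeometryError
from .mri_io import CLASS_MAP, DixonVolume, LabelVolume

# internal tissue codes; marrow is folded into the bone label (3)
T_BACKGROUND, T_MUSCLE, T_SAT, T_CORTICAL, T_MARROW = 0, 1, 2, 3, 4
_TISSUE_TO_LABEL = np.array([0, 1, 2, 3, 3], dtype=np.int16)

DEFAULT_FAT_FRACTION = {
    "background": 0.0,
    "muscle": 0.05,
    "sat": 0.90,
    "bone": 0.02,
    "marrow": 0.80,
}
#: Reference (proton-density-like) signal per tissue, arbitrary units.
DEFAULT_TISSUE_SIGNAL = {
    "background": 0.0,
    "muscle": 1.0,
    "sat": 1.0,
    "bone": 0.15,
    "marrow": 0.90,
}
_TISSUE_NAMES = ("background", "muscle", "sat", "bone", "marrow")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and degradation parameters of one phantom."""

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    thigh_radius_mm: float = 50.0
    sat_thickness_mm: float = 10.0
    bone_radius_mm: float = 8.0
    marrow_radius_mm: float = 5.0
    center_offset_mm: tuple[float, float] = (2.0, 2.0)
    noise_sigma: float = 0.05
    bias_amplitude: float = 0.10
    tissue_fat_fraction: dict = field(default_factory=lambda: dict(DEFAULT_FAT_FRACTION))
    tissue_signal: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_SIGNAL))
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacings must be strictly positive")
        if self.sat_thickness_mm <= 0:
            raise ValueError("sat_thickness_mm must be > 0")
        if not (self.marrow_radius_mm < self.bone_radius_mm < self.thigh_radius_mm):
            raise ValueError(
                "radii must satisfy marrow < bone < thigh, got "
                f"{self.marrow_radius_mm}, {self.bone_radius_mm}, {self.thigh_radius_mm}"
            )
        if self.muscle_outer_radius_mm <= self.bone_radius_mm:
            raise ValueError(
                "thigh_radius_mm - sat_thickness_mm must exceed bone_radius_mm"
            )
        for name in _TISSUE_NAMES:
            ff = self.tissue_fat_fraction.get(name, 0.0)
            if not 0.0 <= ff <= 1.0:
                raise ValueError(f"fat fraction for {name!r} must be in [0,1], got {ff}")
        if not 0.0 <= self.bias_amplitude < 1.0:
            raise ValueError("bias_amplitude must be in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        self.validate_fit()

    @property
    def muscle_outer_radius_mm(self) -> float:
        return self.thigh_radius_mm - self.sat_thickness_mm

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_spacing))

    def half_extent_mm(self) -> tuple[float, float]:
        return (
            self.grid_shape[0] * self.voxel_spacing[0] / 2.0,
            self.grid_shape[1] * self.voxel_spacing[1] / 2.0,
        )

    def validate_fit(self):
        """The thigh plus its jitter must fit inside the in-plane grid."""
        hx, hy = self.half_extent_mm()
        for axis, half in zip("xy", (hx, hy)):
            reach = self.thigh_radius_mm + abs(
                self.center_offset_mm[0 if axis == "x" else 1]
            )
            if reach > half:
                raise GeometryError(
                    f"thigh_radius_mm={self.thigh_radius_mm} (+ jitter) exceeds the "
                    f"{axis} half-extent {half:.1f} mm of the grid"
                )


def _seed_streams(seed: int, *labels: str) -> dict[str, np.random.Generator]:
    """Independent, named, deterministic RNG streams derived from one seed."""
    import zlib

    return {
        lab: np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF,
                                                           zlib.crc32(lab.encode())]))
        for lab in labels
    }


def _slice_center_offsets(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth per-slice in-plane center offsets, shape (2, nz), in mm."""
    nz = spec.grid_shape[2]
    k = np.arange(nz)
    offsets = np.zeros((2, nz))
    for ax in range(2):
        amp = spec.center_offset_mm[ax]
        if amp == 0:
            continue
        freq = rng.integers(1, 3)
        phase = rng.uniform(0, 2 * np.pi)
        offsets[ax] = amp * np.sin(2 * np.pi * freq * k / max(nz, 1) + phase)
    return offsets


def _radial_distance_mm(spec: PhantomSpec, offsets: np.ndarray) -> np.ndarray:
    """In-plane distance of every voxel center to its slice's thigh axis."""
    nx, ny, nz = spec.grid_shape
    sx, sy, _ = spec.voxel_spacing
    # voxel centers relative to the grid center, mm
    x = (np.arange(nx) + 0.5) * sx - nx * sx / 2.0
    y = (np.arange(ny) + 0.5) * sy - ny * sy / 2.0
    dx = x[:, None, None] - offsets[0][None, None, :]
    dy = y[None, :, None] - offsets[1][None, None, :]
    return np.sqrt(dx**2 + dy**2)


def _tissue_from_radii(r: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    tissue = np.full(r.shape, T_BACKGROUND, dtype=np.int16)
    tissue[r < spec.thigh_radius_mm] = T_SAT
    tissue[r < spec.muscle_outer_radius_mm] = T_MUSCLE
    tissue[r < spec.bone_radius_mm] = T_CORTICAL
    tissue[r < spec.marrow_radius_mm] = T_MARROW
    return tissue


def _bias_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field in [1-a, 1+a], from a random quadratic."""
    if spec.bias_amplitude == 0:
        return np.ones(spec.grid_shape)
    nx, ny, nz = spec.grid_shape
    u = np.linspace(-1, 1, nx)[:, None, None]
    v = np.linspace(-1, 1, ny)[None, :, None]
    w = np.linspace(-1, 1, nz)[None, None, :]
    basis = [u, v, w, u * v, u * w, v * w, u**2, v**2, w**2]
    coeff = rng.standard_normal(len(basis))
    f = sum(c * b for c, b in zip(coeff, basis))
    f = f - f.mean()
    peak = np.abs(f).max()
    if peak > 0:
        f = f / peak
    return 1.0 + spec.bias_amplitude * f


def _dixon_from_tissue(tissue: np.ndarray, spec: PhantomSpec,
                       rng_bias: np.random.Generator,
                       rng_noise: np.random.Generator) -> DixonVolume:
    sig = np.array([spec.tissue_signal[n] for n in _TISSUE_NAMES])
    ff = np.array([spec.tissue_fat_fraction.get(n, 0.0) for n in _TISSUE_NAMES])
    water = (sig * (1.0 - ff))[tissue]
    fat = (sig * ff)[tissue]
    in_phase = water + fat
    opposed = np.abs(water - fat)

    bias = _bias_field(spec, rng_bias)
    contrasts = {"in_phase": in_phase, "opposed_phase": opposed, "water": water, "fat": fat}
    if spec.noise_sigma > 0:
        foreground = tissue != T_BACKGROUND
        mean_signal = in_phase[foreground].mean() if foreground.any() else 1.0
        sigma = spec.noise_sigma * mean_signal
        # one draw pair, reused for every contrast channel
        real = rng_noise.normal(0.0, sigma, size=tissue.shape)
        imag = rng_noise.normal(0.0, sigma, size=tissue.shape)
        contrasts = {
            name: np.sqrt((arr * bias + real) ** 2 + imag**2)
            for name, arr in contrasts.items()
        }
    else:
        contrasts = {name: arr * bias for name, arr in contrasts.items()}
    return DixonVolume(**contrasts, voxel_spacing=spec.voxel_spacing)


def simulate_dixon_phantom(spec: PhantomSpec) -> tuple[DixonVolume, LabelVolume]:
    """Generate one four-contrast phantom and its ground-truth label map."""
    streams = _seed_streams(spec.seed, "geometry", "bias", "noise")
    offsets = _slice_center_offsets(spec, streams["geometry"])
    r = _radial_distance_mm(spec, offsets)
    tissue = _tissue_from_radii(r, spec)
    labels = LabelVolume(
        labels=_TISSUE_TO_LABEL[tissue],
        voxel_spacing=spec.voxel_spacing,
        class_map=dict(CLASS_MAP),
    )
    vol = _dixon_from_tissue(tissue, spec, streams["bias"], streams["noise"])
    return vol, labels


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass(frozen=True)
class CohortSpec:
    """Two-group pre/post cohort with prescribed percent effects.

    Baselines are (mean, between-subject SD) pairs in cm^3.  Muscle changes
    by ``ig_muscle_effect_pct`` in the intervention group and
    ``cg_muscle_effect_pct`` in the control group; SAT drifts by
    ``time_sat_effect_pct`` in both groups; bone has no systematic change.
    ``within_subject_noise_pct`` is the coefficient of variation of the
    multiplicative log-normal measurement error applied per scan.
    """

    n_per_group: int = 9
    baseline_muscle_cm3: tuple[float, float] = (2600.0, 250.0)
    baseline_sat_cm3: tuple[float, float] = (1195.0, 250.0)
    baseline_bone_cm3: tuple[float, float] = (300.0, 30.0)
    ig_muscle_effect_pct: float = 2.93
    cg_muscle_effect_pct: float = -0.62
    time_sat_effect_pct: float = 2.8
    within_subject_noise_pct: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for name in ("baseline_muscle_cm3", "baseline_sat_cm3", "baseline_bone_cm3"):
            mean, sd = getattr(self, name)
            if mean <= 0 or sd < 0:
                raise ValueError(f"{name} needs mean > 0 and SD >= 0, got {(mean, sd)}")
        if self.within_subject_noise_pct < 0:
            raise ValueError("within_subject_noise_pct must be >= 0")

    def desk_scaled_to(self, base: PhantomSpec) -> "CohortSpec":
        """Rescale baselines to the class volumes of ``base`` so every
        subject is renderable inside its grid; percent effects, relative
        SDs and noise are preserved."""
        _, labels = simulate_dixon_phantom(replace(base, noise_sigma=0.0))
        vv = base.voxel_volume_mm3 / 1000.0
        counts = np.bincount(labels.labels.ravel(), minlength=4)
        new = {}
        for name, cls in (
            ("baseline_muscle_cm3", 1),
            ("baseline_sat_cm3", 2),
            ("baseline_bone_cm3", 3),
        ):
            mean, sd = getattr(self, name)
            target = counts[cls] * vv
            new[name] = (target, sd / mean * target)
        return replace(self, **new)


def simulate_cohort(cspec: CohortSpec) -> pd.DataFrame:
    """One row per subject x time with group label and tissue volumes (cm^3)."""
    rng = np.random.default_rng(np.random.SeedSequence(int(cspec.seed) & 0x7FFFFFFF))
    sigma = np.log1p(cspec.within_subject_noise_pct / 100.0)

    def meas_noise():
        if sigma == 0:
            return 1.0
        return np.exp(rng.normal(-0.5 * sigma**2, sigma))

    def draw_baseline(mean, sd):
        if sd == 0:
            return mean
        for _ in range(100):
            v = rng.normal(mean, sd)
            if v > 0:
                return v
        raise ValueError(f"baseline distribution ({mean}, {sd}) yields no positive draws")

    rows = []
    for group, muscle_eff in (("IG", cspec.ig_muscle_effect_pct),
                              ("CG", cspec.cg_muscle_effect_pct)):
        for i in range(cspec.n_per_group):
            sid = f"{group}{i + 1:02d}"
            muscle0 = draw_baseline(*cspec.baseline_muscle_cm3)
            sat0 = draw_baseline(*cspec.baseline_sat_cm3)
            bone0 = draw_baseline(*cspec.baseline_bone_cm3)
            true = {
                "pre": (muscle0, sat0, bone0),
                "post": (
                    muscle0 * (1.0 + muscle_eff / 100.0),
                    sat0 * (1.0 + cspec.time_sat_effect_pct / 100.0),
                    bone0,
                ),
            }
            for time in ("pre", "post"):
                m, s, b = true[time]
                rows.append(
                    {
                        "subject_id": sid,
                        "group": group,
                        "time": time,
                        "muscle_cm3": m * meas_noise(),
                        "sat_cm3": s * meas_noise(),
                        "bone_cm3": b * meas_noise(),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rendering cohort entries as phantoms


def render_phantom_with_volumes(
    base: PhantomSpec,
    muscle_cm3: float,
    sat_cm3: float,
    bone_cm3: float,
    geometry_seed: int | None = None,
    noise_seed: int | None = None,
) -> tuple[DixonVolume, LabelVolume]:
    """Phantom whose voxel-counted class volumes match the targets.

    The class radii are chosen as order statistics of the per-voxel radial
    distances: sorting voxels by distance to the slice axis and cutting the
    ranking at the target voxel counts picks exactly the radii whose
    voxelized discs contain those counts, so each class volume matches its
    target to within half a voxel volume.
    """
    gseed = base.seed if geometry_seed is None else geometry_seed
    nseed = gseed if noise_seed is None else noise_seed
    gstreams = _seed_streams(gseed, "geometry")
    nstreams = _seed_streams(nseed, "bias", "noise")

    offsets = _slice_center_offsets(base, gstreams["geometry"])
    r = _radial_distance_mm(base, offsets)
    vv = base.voxel_volume_mm3
    n_bone = int(round(bone_cm3 * 1000.0 / vv))
    n_muscle = int(round(muscle_cm3 * 1000.0 / vv))
    n_sat = int(round(sat_cm3 * 1000.0 / vv))
    for name, n in (("bone", n_bone), ("muscle", n_muscle), ("sat", n_sat)):
        if n < 1:
            raise GeometryError(f"target {name} volume smaller than one voxel")
    n_total = n_bone + n_muscle + n_sat
    flat_order = np.argsort(r, axis=None, kind="stable")
    if n_total > flat_order.size:
        raise GeometryError("target volumes exceed the grid volume")
    hx, hy = base.half_extent_mm()
    max_jit = max(abs(o) for o in base.center_offset_mm)
    fit_radius = min(hx, hy) - max_jit
    outer_r = r.ravel()[flat_order[n_total - 1]]
    if outer_r > fit_radius:
        raise GeometryError(
            f"target volumes imply an outer radius of {outer_r:.1f} mm which does "
            f"not fit the grid (limit {fit_radius:.1f} mm)"
        )

    marrow_share = (base.marrow_radius_mm / base.bone_radius_mm) ** 2
    n_marrow = int(round(n_bone * marrow_share))
    tissue = np.full(r.size, T_BACKGROUND, dtype=np.int16)
    tissue[flat_order[:n_marrow]] = T_MARROW
    tissue[flat_order[n_marrow:n_bone]] = T_CORTICAL
    tissue[flat_order[n_bone : n_bone + n_muscle]] = T_MUSCLE
    tissue[flat_order[n_bone + n_muscle : n_total]] = T_SAT
    tissue = tissue.reshape(r.shape)

    labels = LabelVolume(
        labels=_TISSUE_TO_LABEL[tissue],
        voxel_spacing=base.voxel_spacing,
        class_map=dict(CLASS_MAP),
    )
    vol = _dixon_from_tissue(tissue, base, nstreams["bias"], nstreams["noise"])
    return vol, labels


def render_cohort_phantoms(
    cspec: CohortSpec,
    base: PhantomSpec,
    table: pd.DataFrame | None = None,
) -> list[tuple[str, str, DixonVolume, LabelVolume]]:
    """Render each cohort row as a phantom with matching class volumes.

    Pre and post scans of a subject share thigh geometry (same jitter) but
    get independent noise realizations.  Pass ``table`` to reuse an already
    simulated cohort; otherwise one is simulated from ``cspec``.
    """
    if table is None:
        table = simulate_cohort(cspec)
    out = []
    subject_ids = list(dict.fromkeys(table["subject_id"]))
    for idx, sid in enumerate(subject_ids):
        gseed = int(
            np.random.SeedSequence([int(cspec.seed) & 0x7FFFFFFF, base.seed, idx]).generate_state(1)[0]
        )
        for t_idx, time in enumerate(("pre", "post")):
            row = table[(table.subject_id == sid) & (table.time == time)]
            if len(row) != 1:
                raise ValueError(f"cohort table must have one {time!r} row for {sid!r}")
            row = row.iloc[0]
            vol, labels = render_phantom_with_volumes(
                base,
                muscle_cm3=row.muscle_cm3,
                sat_cm3=row.sat_cm3,
                bone_cm3=row.bone_cm3,
                geometry_seed=gseed,
                noise_seed=gseed + t_idx + 1,
            )
            out.append((sid, time, vol, labels))
    return out
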