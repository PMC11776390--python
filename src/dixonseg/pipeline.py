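"""End-to-end orchestration: cohort simulation -> phantom rendering ->
patching -> training -> prediction -> volumetry -> statistics.

Every stage writes its artifacts under the run's output directory and the
run closes with a JSON manifest listing per-stage outputs, their SHA-256
hashes and summary numbers, so identical configurations reproduce
identical manifests at a fixed thread count.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DixonSegError
from .evaluation import segment_volume
from .mri_io import select_slab, write_dixon, write_labels
from .patching import extract_patches, filter_foreground, split_train_val
from .phantom import CohortSpec, PhantomSpec, render_cohort_phantoms, simulate_cohort, simulate_dixon_phantom
from .segnet import SegmenterConfig, build_segmenter, train_segmenter
from .stats import mixed_anova_2x2
from .volumetrics import compute_volumes, dice_per_class

log = logging.getLogger("dixonseg.pipeline")

OUTCOMES = ("muscle_cm3", "sat_cm3", "bone_cm3")


@dataclass
class RunConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    segmenter: SegmenterConfig = field(default_factory=SegmenterConfig)
    cube: int = 32
    stride: int = 16
    min_foreground: float = 0.05
    train_fraction: float = 0.75
    n_training_phantoms: int = 8
    slab: tuple[int, int] | None = None  # (anchor_slice, n_slices)
    use_ground_truth: bool = False  # bypass the network with true labels
    desk_scale_cohort: bool = True  # rescale cohort baselines into the grid
    out_dir: str = "dixonseg_run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, value in raw.items():
            if key == "phantom":
                value = phantom_spec_from_dict(value)
            elif key == "cohort":
                value = cohort_spec_from_dict(value)
            elif key == "segmenter":
                value = SegmenterConfig(**value)
            elif key == "slab" and value is not None:
                value = tuple(value)
            kwargs[key] = value
        return cls(**kwargs)


def phantom_spec_from_dict(d: dict) -> PhantomSpec:
    d = dict(d)
    for key in ("grid_shape", "voxel_spacing", "center_offset_mm"):
        if key in d:
            d[key] = tuple(d[key])
    return PhantomSpec(**d)


def cohort_spec_from_dict(d: dict) -> CohortSpec:
    d = dict(d)
    for key in ("baseline_muscle_cm3", "baseline_sat_cm3", "baseline_bone_cm3"):
        if key in d:
            d[key] = tuple(d[key])
    return CohortSpec(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _child_seed(seed: int, label: str) -> int:
    import zlib

    return int(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(label.encode())]).generate_state(1)[0]
        % (2**31)
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return (and write) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "config": _config_dict(config)}

    def record(stage: str, paths: dict, summary: dict | None = None):
        manifest["stages"][stage] = {
            "artifacts": {k: str(p) for k, p in paths.items()},
            "hashes": {k: _sha256(Path(p)) for k, p in paths.items()},
            "summary": summary or {},
        }
        log.info("stage %s done: %s", stage, sorted(paths))

    stage = "cohort"
    try:
        cohort_spec = replace(config.cohort, seed=_child_seed(config.seed, "cohort"))
        if config.desk_scale_cohort:
            cohort_spec = cohort_spec.desk_scaled_to(config.phantom)
        table = simulate_cohort(cohort_spec)
        cohort_csv = out / "cohort_true.csv"
        table.to_csv(cohort_csv, index=False)
        record(stage, {"cohort_true": cohort_csv}, {"n_rows": len(table)})

        stage = "render"
        rendered = render_cohort_phantoms(cohort_spec, config.phantom, table)
        phantom_dir = out / "phantoms"
        paths = {}
        for sid, time, vol, labels in rendered:
            stem = f"{sid}_{time}"
            write_dixon(vol, phantom_dir, stem=stem)
            paths[stem] = write_labels(labels, phantom_dir / f"{stem}_labels.nii.gz")
        record(stage, paths, {"n_phantoms": len(rendered)})

        model = None
        if not config.use_ground_truth:
            stage = "train"
            tr_patches = []
            ps_ref = None
            for i in range(config.n_training_phantoms):
                spec = replace(config.phantom, seed=_child_seed(config.seed, f"train_phantom_{i}"))
                vol, labels = simulate_dixon_phantom(spec)
                ps = filter_foreground(
                    extract_patches(vol, labels, config.cube, config.stride),
                    config.min_foreground,
                )
                tr_patches.extend(ps.patches)
                ps_ref = ps
            ps = replace(ps_ref, patches=tr_patches)
            ps = split_train_val(ps, config.train_fraction, seed=_child_seed(config.seed, "split"))
            model = build_segmenter(
                replace(config.segmenter, seed=_child_seed(config.seed, "net"))
            )
            train_segmenter(model, ps)
            ckpt = out / "segmenter.npz"
            model.save(ckpt)
            hist_csv = out / "training_history.csv"
            model.history_frame().to_csv(hist_csv, index=False)
            record(stage, {"checkpoint": ckpt, "history": hist_csv},
                   {"final_val_dice": model.history[-1]["val_dice"]})

        stage = "segment"
        rows = []
        dice_rows = []
        for sid, time, vol, labels in rendered:
            if config.use_ground_truth:
                pred = labels
            else:
                pred = segment_volume(model, vol, config.cube, config.stride)
                dice_rows.append(
                    {"subject_id": sid, "time": time,
                     **{f"dice_{n}": d for n, d in zip(
                         ("muscle", "sat", "bone"), dice_per_class(pred, labels).values())}}
                )
            report = compute_volumes(pred, slab=config.slab)
            rows.append(
                {
                    "subject_id": sid,
                    "group": sid[:2],
                    "time": time,
                    "muscle_cm3": report.volume_cm3[1],
                    "sat_cm3": report.volume_cm3[2],
                    "bone_cm3": report.volume_cm3[3],
                }
            )
        measured = pd.DataFrame(rows)
        measured_csv = out / "cohort_measured.csv"
        measured.to_csv(measured_csv, index=False)
        seg_paths = {"cohort_measured": measured_csv}
        seg_summary = {}
        if dice_rows:
            dice_df = pd.DataFrame(dice_rows)
            dice_csv = out / "dice_scores.csv"
            dice_df.to_csv(dice_csv, index=False)
            seg_paths["dice_scores"] = dice_csv
            seg_summary = {
                k: float(dice_df[k].mean()) for k in ("dice_muscle", "dice_sat", "dice_bone")
            }
        record(stage, seg_paths, seg_summary)

        stage = "anova"
        anova_paths = {}
        anova_summary = {}
        for outcome in OUTCOMES:
            res = mixed_anova_2x2(measured, outcome=outcome)
            a_csv = out / f"anova_{outcome}.csv"
            res.anova_table.to_csv(a_csv, index=False)
            t_csv = out / f"tukey_{outcome}.csv"
            res.tukey().to_csv(t_csv, index=False)
            anova_paths[f"anova_{outcome}"] = a_csv
            anova_paths[f"tukey_{outcome}"] = t_csv
            inter = res.effects["TIME×GROUP"]
            anova_summary[outcome] = {
                "interaction_F": inter.F,
                "interaction_p": inter.p,
                "interaction_eta_p2": inter.partial_eta_sq,
            }
        record(stage, anova_paths, anova_summary)
    except DixonSegError as err:
        raise DixonSegError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _config_dict(config: RunConfig) -> dict:
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [encode(v) for v in obj]
        if isinstance(obj, dict):
            return {k: encode(v) for k, v in obj.items()}
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    return {f.name: encode(getattr(config, f.name)) for f in dataclasses.fields(config)}
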