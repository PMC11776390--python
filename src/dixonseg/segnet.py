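"""Attention-gated 3D U-Net voxel classifier: configuration, training,
prediction and checkpointing.

The classifier consumes 4-channel Dixon cubes and emits per-voxel class
scores for background/muscle/SAT/bone.  Training minimizes a soft-Dice +
cross-entropy compound loss with Adam; inputs are z-scored per channel with
statistics estimated on the training patches.  The default architecture
(depth 3, 8 base filters, 32-voxel cubes) is sized for CPU training.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ArchitectureError, TrainingError
from .nn.autograd import softmax as _softmax
from .nn.layers import LOSSES, Adam, UNet3D
from .patching import PatchSet, one_hot_labels


@dataclass(frozen=True)
class SegmenterConfig:
    in_channels: int = 4
    n_classes: int = 4
    depth: int = 3
    base_filters: int = 8
    use_attention_gates: bool = True
    use_dense_skip_connections: bool = True
    loss_name: str = "dice+ce"
    learning_rate: float = 1e-3
    epochs: int = 2
    batch_size: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_filters < 4:
            raise ValueError("base_filters must be >= 4")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.loss_name not in LOSSES:
            raise ValueError(f"unknown loss {self.loss_name!r}; options: {sorted(LOSSES)}")


class SegmenterModel:
    """A (possibly trained) voxel classifier with its normalization state
    and per-epoch training history."""

    def __init__(self, config: SegmenterConfig):
        self.config = config
        self.net = UNet3D(
            in_channels=config.in_channels,
            n_classes=config.n_classes,
            depth=config.depth,
            base_filters=config.base_filters,
            attention=config.use_attention_gates,
            dense_skips=config.use_dense_skip_connections,
            seed=config.seed,
        )
        self.norm_mean: np.ndarray | None = None  # (channels,)
        self.norm_std: np.ndarray | None = None
        self.history: list[dict] = []

    # -- normalization ------------------------------------------------------

    def fit_normalization(self, patches):
        stack = np.stack([p.image_data for p in patches])  # (n, C, c, c, c)
        self.norm_mean = stack.mean(axis=(0, 2, 3, 4)).astype(np.float32)
        std = stack.std(axis=(0, 2, 3, 4)).astype(np.float32)
        std[std == 0] = 1.0
        self.norm_std = std

    def normalize(self, images: np.ndarray) -> np.ndarray:
        if self.norm_mean is None:
            return images.astype(np.float32)
        shape = (1, -1, 1, 1, 1) if images.ndim == 5 else (-1, 1, 1, 1)
        return ((images - self.norm_mean.reshape(shape)) /
                self.norm_std.reshape(shape)).astype(np.float32)

    # -- inference ----------------------------------------------------------

    def forward_scores(self, batch: np.ndarray) -> np.ndarray:
        """Softmax class scores for a normalized (N, C, c, c, c) batch."""
        logits = self.net(batch)
        return _softmax(logits, axis=1).data

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history)

    # -- persistence --------------------------------------------------------

    def save(self, path):
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = dict(self.net.state_dict())
        payload["config_json"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8
        )
        if self.norm_mean is not None:
            payload["norm_mean"] = self.norm_mean
            payload["norm_std"] = self.norm_std
        np.savez(path, **payload)

    @classmethod
    def load(cls, path) -> "SegmenterModel":
        with np.load(path) as data:
            cfg = SegmenterConfig(**json.loads(bytes(data["config_json"]).decode()))
            model = cls(cfg)
            state = {k: data[k] for k in data.files if k.startswith("param_")}
            model.net.load_state_dict(state)
            if "norm_mean" in data:
                model.norm_mean = data["norm_mean"]
                model.norm_std = data["norm_std"]
        return model


def build_segmenter(config: SegmenterConfig) -> SegmenterModel:
    """Instantiate a seeded, untrained segmenter."""
    return SegmenterModel(config)


def _soft_dice_from_argmax(pred_labels, true_labels, n_classes):
    scores = []
    for cls in range(1, n_classes):
        p = pred_labels == cls
        t = true_labels == cls
        denom = p.sum() + t.sum()
        if denom == 0:
            scores.append(1.0)
        else:
            scores.append(2.0 * np.count_nonzero(p & t) / denom)
    return float(np.mean(scores))


def train_segmenter(model: SegmenterModel, ps: PatchSet,
                    log=None) -> SegmenterModel:
    """Train in place on the patch set's train split, tracking validation
    loss and Dice each epoch.  Reproducible for a fixed seed and thread
    count."""
    cfg = model.config
    train = ps.subset("train")
    val = ps.subset("val")
    if not train or not val:
        raise TrainingError(
            f"need non-empty train and val splits, got {len(train)}/{len(val)}"
        )
    if any(p.label_data is None for p in train + val):
        raise TrainingError("training requires patches with labels")
    model.net.check_cube(ps.cube)
    if train[0].image_data.shape[0] != cfg.in_channels:
        raise TrainingError(
            f"patches have {train[0].image_data.shape[0]} channels, "
            f"config expects {cfg.in_channels}"
        )
    model.fit_normalization(train)
    loss_fn = LOSSES[cfg.loss_name]
    opt = Adam(model.net.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 0x5EED]))

    x_train = model.normalize(np.stack([p.image_data for p in train]))
    y_train = np.stack([one_hot_labels(p.label_data, cfg.n_classes) for p in train])
    x_val = model.normalize(np.stack([p.image_data for p in val]))
    y_val = np.stack([one_hot_labels(p.label_data, cfg.n_classes) for p in val])
    true_val = np.stack([p.label_data for p in val])

    def eval_val():
        losses, dices = [], []
        for start in range(0, len(val), cfg.batch_size):
            xb = x_val[start : start + cfg.batch_size]
            yb = y_val[start : start + cfg.batch_size]
            logits = model.net(xb)
            losses.append(float(loss_fn(logits, yb).item()) * len(xb))
            pred = logits.data.argmax(axis=1)
            dices.append(
                _soft_dice_from_argmax(pred, true_val[start : start + len(xb)],
                                       cfg.n_classes) * len(xb)
            )
        return sum(losses) / len(val), sum(dices) / len(val)

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train))
        epoch_loss = 0.0
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            logits = model.net(x_train[sel])
            loss = loss_fn(logits, y_train[sel])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(sel)
        val_loss, val_dice = eval_val()
        record = {
            "epoch": epoch,
            "train_loss": epoch_loss / len(train),
            "val_loss": val_loss,
            "val_dice": val_dice,
        }
        model.history.append(record)
        if log is not None:
            log(record)
    return model


def predict_patches(model: SegmenterModel, ps: PatchSet) -> list[np.ndarray]:
    """Softmax-normalized class-score cubes, one per patch in ``ps``."""
    if not ps.patches:
        return []
    if ps.patches[0].image_data.shape[0] != model.config.in_channels:
        raise ArchitectureError(
            f"patches have {ps.patches[0].image_data.shape[0]} channels, "
            f"model expects {model.config.in_channels}"
        )
    model.net.check_cube(ps.cube)
    x = model.normalize(np.stack([p.image_data for p in ps.patches]))
    out: list[np.ndarray] = []
    bs = model.config.batch_size
    for start in range(0, len(ps.patches), bs):
        scores = model.forward_scores(x[start : start + bs])
        out.extend(np.ascontiguousarray(s) for s in scores)
    return out
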