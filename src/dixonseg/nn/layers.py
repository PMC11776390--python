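"""Network building blocks: convolutions, attention gates, the 3D U-Net,
losses and the Adam optimizer.

Weight initialization is seeded per named parameter (seed mixed with a CRC
of the parameter path), so two networks built from the same seed share the
weights of every layer they have in common regardless of which optional
blocks (attention gates, dense skips) are present.
"""

from __future__ import annotations

import zlib

import numpy as np

from ..errors import ArchitectureError
from . import autograd as A
from .autograd import Tensor


def _param_rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


class Conv3d:
    """Same-padded stride-1 3D convolution with He-normal initialization."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, *, seed: int,
                 name: str, dtype=np.float32):
        rng = _param_rng(seed, name)
        fan_in = in_ch * kernel**3
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel, kernel)).astype(dtype),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True)
        self.name = name

    def __call__(self, x: Tensor) -> Tensor:
        return A.conv3d(x, self.weight, self.bias)

    def parameters(self):
        return [self.weight, self.bias]


class ConvBlock:
    """Two conv+ReLU stages at one resolution level."""

    def __init__(self, in_ch, out_ch, *, seed, name, dtype=np.float32):
        self.c1 = Conv3d(in_ch, out_ch, seed=seed, name=f"{name}.c1", dtype=dtype)
        self.c2 = Conv3d(out_ch, out_ch, seed=seed, name=f"{name}.c2", dtype=dtype)

    def __call__(self, x):
        return A.relu(self.c2(A.relu(self.c1(x))))

    def parameters(self):
        return self.c1.parameters() + self.c2.parameters()


class AttentionGate:
    """Additive attention on a skip connection.

    The skip tensor ``x`` and the (already upsampled) gating signal ``g``
    are projected to an intermediate channel count, summed, passed through
    ReLU and a single-channel projection, and squashed with a sigmoid into
    per-voxel weights in [0, 1] that multiply the skip tensor.  When
    ``pinned`` the weights are forced to 1 and the gate is an identity.
    """

    def __init__(self, skip_ch, gate_ch, *, seed, name, reduction: int = 2,
                 dtype=np.float32):
        inter = max(skip_ch // reduction, 1)
        self.theta = Conv3d(skip_ch, inter, kernel=1, seed=seed, name=f"{name}.theta",
                            dtype=dtype)
        self.phi = Conv3d(gate_ch, inter, kernel=1, seed=seed, name=f"{name}.phi",
                          dtype=dtype)
        self.psi = Conv3d(inter, 1, kernel=1, seed=seed, name=f"{name}.psi", dtype=dtype)
        self._last_weights: np.ndarray | None = None

    def __call__(self, x: Tensor, g: Tensor, pinned: bool = False) -> Tensor:
        if pinned:
            self._last_weights = None
            return x
        a = A.relu(A.add(self.theta(x), self.phi(g)))
        alpha = A.sigmoid(self.psi(a))
        self._last_weights = alpha.data
        return A.mul(x, alpha)

    @property
    def last_attention(self) -> np.ndarray | None:
        """Attention map of the most recent forward pass, (N,1,D,H,W)."""
        return self._last_weights

    def parameters(self):
        return self.theta.parameters() + self.phi.parameters() + self.psi.parameters()


class UNet3D:
    """Encoder-decoder voxel classifier with optional attention-gated skips
    and optional dense (multi-scale) decoder inputs.

    ``depth`` resolution levels with channel doubling; mirrored skip
    connections; when ``dense_skips`` each decoder level additionally
    receives 1x1-projected, repeatedly upsampled features from all coarser
    decoder levels.
    """

    def __init__(self, in_channels=4, n_classes=4, depth=3, base_filters=8,
                 attention=True, dense_skips=True, seed=0, dtype=np.float32):
        if depth < 2:
            raise ArchitectureError("depth must be >= 2")
        self.depth = depth
        self.in_channels = in_channels
        self.n_classes = n_classes
        self.attention = attention
        self.dense_skips = dense_skips
        self.pin_attention = False  # force all gates open (diagnostics)

        ch = [base_filters * 2**level for level in range(depth)]
        self.enc = []
        prev = in_channels
        for level in range(depth):
            self.enc.append(
                ConvBlock(prev, ch[level], seed=seed, name=f"enc{level}", dtype=dtype)
            )
            prev = ch[level]
        self.dec = []
        self.gates = []
        self.dense_proj = {}  # (src_level, dst_level) -> 1x1 Conv3d
        for level in range(depth - 2, -1, -1):
            in_ch = ch[level + 1] + ch[level]
            if dense_skips:
                for src in range(level + 2, depth):
                    proj = Conv3d(ch[src], base_filters, kernel=1, seed=seed,
                                  name=f"dense{src}to{level}", dtype=dtype)
                    self.dense_proj[(src, level)] = proj
                    in_ch += base_filters
            self.dec.append(ConvBlock(in_ch, ch[level], seed=seed, name=f"dec{level}",
                                      dtype=dtype))
            if attention:
                self.gates.append(
                    AttentionGate(ch[level], ch[level + 1], seed=seed,
                                  name=f"gate{level}", dtype=dtype)
                )
        self.head = Conv3d(ch[0], n_classes, kernel=1, seed=seed, name="head",
                           dtype=dtype)

    def check_cube(self, cube: int):
        div = 2 ** (self.depth - 1)
        if cube % div:
            raise ArchitectureError(
                f"cube size {cube} is not divisible by 2^(depth-1) = {div}"
            )

    def forward(self, x) -> Tensor:
        x = A.as_tensor(x)
        self.check_cube(x.shape[2])
        for d in (2, 3, 4):
            if x.shape[d] != x.shape[2]:
                raise ArchitectureError(f"input must be cubic, got {x.shape[2:]}")
        if x.shape[1] != self.in_channels:
            raise ArchitectureError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}"
            )
        skips = []
        h = x
        for level in range(self.depth):
            h = self.enc[level](h)
            if level < self.depth - 1:
                skips.append(h)
                h = A.maxpool2(h)
        # decoder outputs per level, for dense connections
        dec_out = {self.depth - 1: h}
        for i, level in enumerate(range(self.depth - 2, -1, -1)):
            g = dec_out[level + 1]
            up = A.upsample2(g)
            skip = skips[level]
            if self.attention:
                skip = self.gates[i](skip, up, pinned=self.pin_attention)
            cat = [up, skip]
            if self.dense_skips:
                for src in range(level + 2, self.depth):
                    feat = self.dense_proj[(src, level)](dec_out[src])
                    for _ in range(src - level):
                        feat = A.upsample2(feat)
                    cat.append(feat)
            h = self.dec[i](A.concat(cat, axis=1))
            dec_out[level] = h
        return self.head(h)

    __call__ = forward

    def parameters(self):
        params = []
        for block in self.enc + self.dec:
            params += block.parameters()
        for gate in self.gates:
            params += gate.parameters()
        for proj in self.dense_proj.values():
            params += proj.parameters()
        params += self.head.parameters()
        return params

    def attention_maps(self):
        """Per-gate attention weights from the last forward pass."""
        return [g.last_attention for g in self.gates]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"param_{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.parameters()
        if len(state) != len(params):
            raise ArchitectureError(
                f"checkpoint has {len(state)} arrays, model needs {len(params)}"
            )
        for i, p in enumerate(params):
            arr = state[f"param_{i}"]
            if arr.shape != p.data.shape:
                raise ArchitectureError(f"parameter {i} shape mismatch: {arr.shape}")
            p.data = arr.astype(p.data.dtype)


# ---------------------------------------------------------------------------
# losses and optimization


def dice_ce_loss(logits: Tensor, onehot: np.ndarray, eps: float = 1e-6) -> Tensor:
    """Soft-Dice + cross-entropy sum, the standard compound loss for
    class-imbalanced volumetric segmentation."""
    y = A.as_tensor(onehot)
    n_vox = logits.data.size / logits.shape[1]
    lsm = A.log_softmax(logits, axis=1)
    ce = A.scale(A.tsum(A.mul(y, lsm)), -1.0 / n_vox)
    p = A.softmax(logits, axis=1)
    axes = (0, 2, 3, 4)
    inter = A.tsum(A.mul(p, y), axis=axes)
    denom = A.add(A.add(A.tsum(p, axis=axes), A.tsum(y, axis=axes)), Tensor(eps))
    dice = A.tmean(A.div(A.scale(inter, 2.0), denom))
    return A.add(ce, A.sub(Tensor(1.0), dice))


def ce_loss(logits: Tensor, onehot: np.ndarray) -> Tensor:
    y = A.as_tensor(onehot)
    n_vox = logits.data.size / logits.shape[1]
    return A.scale(A.tsum(A.mul(y, A.log_softmax(logits, axis=1))), -1.0 / n_vox)


LOSSES = {"dice+ce": dice_ce_loss, "ce": ce_loss}


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype, copy=False)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
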