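"""The grid-transformer classifier.

Architecture, front to back:

1. **Convolutional front-end** — two 3x3 convolutions (stride 1, padding 1,
   channels C -> 32 -> C, ReLU after each) over the C x 9 x 9 feature stack;
   spatial dimensions are preserved.
2. **Reshape** — each of the C planes is flattened row-major into a token of
   width d = H*W, giving a C x d token matrix.
3. **Token augmentation** — two trainable rows are prepended, giving
   (C+2) x d tokens.
4. **Encoder stack** — L (default 15) pre-norm transformer encoders using
   either the efficient element-wise attention (``isa``) or standard
   softmax attention (``original``); see :mod:`eegemotion.nn`.
5. **Head** — a trainable token-mixing vector collapses the tokens to a
   single d-vector, followed by an affine map to the class logits and a
   softmax.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn

__all__ = [
    "ModelConfig",
    "GridTransformerNet",
    "reshape_tokens",
    "unreshape_tokens",
    "audit",
    "format_audit",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``ffn_hidden`` defaults to 4*d (the usual transformer expansion);
    ``conv_hidden`` is the width of the middle convolution layer.
    """

    n_classes: int
    C: int = 8
    H: int = 9
    W: int = 9
    L: int = 15
    conv_hidden: int = 32
    ffn_hidden: int | None = None
    n_extra_tokens: int = 2
    encoder_variant: str = "isa"
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("need at least one encoder block")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.encoder_variant not in ("isa", "original"):
            raise ValueError(f"unknown encoder variant {self.encoder_variant!r}")
        if self.ffn_hidden is None:
            self.ffn_hidden = 4 * self.d

    @property
    def d(self) -> int:
        return self.H * self.W

    @property
    def n_tokens(self) -> int:
        return self.C + self.n_extra_tokens


def reshape_tokens(x: np.ndarray) -> np.ndarray:
    """(..., C, H, W) -> (..., C, H*W), row-major per plane.  Invertible."""
    return x.reshape(x.shape[:-2] + (x.shape[-2] * x.shape[-1],))


def unreshape_tokens(z: np.ndarray, H: int, W: int) -> np.ndarray:
    if z.shape[-1] != H * W:
        raise ValueError(f"token width {z.shape[-1]} != {H}*{W}")
    return z.reshape(z.shape[:-1] + (H, W))


class _TokenMix(nn.Layer):
    """z_D = w^T z: collapse n tokens to one d-vector (init: mean pooling)."""

    def __init__(self, n, name="head.mix", dtype=np.float32):
        self.w = self._register(name, np.full(n, 1.0 / n, dtype=dtype))

    def forward(self, z):
        self._z = z
        return np.einsum("n,bnd->bd", self.w.value, z, optimize=True)

    def backward(self, dzd):
        self.w.grad += np.einsum("bnd,bd->n", self._z, dzd, optimize=True)
        return self.w.value[None, :, None] * dzd[:, None, :]


class GridTransformerNet:
    """Forward/backward network over C x H x W feature tensors."""

    def __init__(self, config: ModelConfig):
        self.config = config
        dtype = np.dtype(config.dtype).type
        rng = np.random.default_rng(config.seed)
        C, d, n = config.C, config.d, config.n_tokens
        self.conv1 = nn.Conv3x3(C, config.conv_hidden, rng, name="conv1", dtype=dtype)
        self.act1 = nn.ReLU()
        self.conv2 = nn.Conv3x3(config.conv_hidden, C, rng, name="conv2", dtype=dtype)
        self.act2 = nn.ReLU()
        self.tokens = nn.TokenAugment(config.n_extra_tokens, d, rng, dtype=dtype)
        self.blocks = [
            nn.EncoderBlock(n, d, config.ffn_hidden, rng,
                            variant=config.encoder_variant, name=f"enc{l}",
                            dtype=dtype)
            for l in range(config.L)
        ]
        self.head_mix = _TokenMix(n, dtype=dtype)
        self.head_fc = nn.Dense(d, config.n_classes, rng, name="head.fc", dtype=dtype)
        self._dtype = dtype

    # -- spec-level stages -------------------------------------------------
    def conv_frontend(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self._dtype)
        if x.ndim == 3:
            x = x[None]
        cfg = self.config
        if x.shape[1:] != (cfg.C, cfg.H, cfg.W):
            raise ValueError(f"expected input {cfg.C}x{cfg.H}x{cfg.W}, "
                             f"got {x.shape[1:]}")
        return self.act2.forward(self.conv2.forward(
            self.act1.forward(self.conv1.forward(x))))

    def token_augment(self, z0: np.ndarray) -> np.ndarray:
        return self.tokens.forward(z0)

    def encode(self, z: np.ndarray) -> np.ndarray:
        for blk in self.blocks:
            z = blk.forward(z)
        return z

    def classify(self, zL: np.ndarray) -> np.ndarray:
        """Token mixing + affine head + softmax -> class probabilities."""
        return nn.softmax(self.head_fc.forward(self.head_mix.forward(zL)))

    # -- training interface ------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits for a batch of feature tensors."""
        h = self.conv_frontend(x)
        z = self.token_augment(reshape_tokens(h))
        z = self.encode(z)
        return self.head_fc.forward(self.head_mix.forward(z))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dz = self.head_mix.backward(self.head_fc.backward(dlogits))
        for blk in reversed(self.blocks):
            dz = blk.backward(dz)
        dz0 = self.tokens.backward(dz)
        cfg = self.config
        dh = unreshape_tokens(dz0, cfg.H, cfg.W)
        dh = self.conv1.backward(self.act1.backward(
            self.conv2.backward(self.act2.backward(dh))))
        return dh

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.forward(x))

    def parameters(self) -> list[nn.Parameter]:
        out = []
        for layer in [self.conv1, self.conv2, self.tokens, *self.blocks,
                      self.head_mix, self.head_fc]:
            out += layer.parameters()
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())


# ---------------------------------------------------------------------------
# efficiency audit

def _layer_groups(net: GridTransformerNet):
    groups = [("conv_frontend", net.conv1.parameters() + net.conv2.parameters()),
              ("tokens", net.tokens.parameters())]
    for i, blk in enumerate(net.blocks):
        groups.append((f"encoder_{i}.attention", blk.attn.parameters()))
        groups.append((f"encoder_{i}.norm_ffn",
                       blk.ln1.parameters() + blk.ln2.parameters()
                       + blk.fc1.parameters() + blk.fc2.parameters()))
    groups.append(("head", net.head_mix.parameters() + net.head_fc.parameters()))
    return groups


def _mac_count(net: GridTransformerNet) -> int:
    cfg = net.config
    macs = net.conv1.mac_count(cfg.H, cfg.W) + net.conv2.mac_count(cfg.H, cfg.W)
    macs += sum(blk.mac_count() for blk in net.blocks)
    macs += cfg.n_tokens * cfg.d          # token mixing
    macs += cfg.d * cfg.n_classes         # output affine
    return macs


def audit(config: ModelConfig, flop_factor: int = 1) -> dict:
    """Exact trainable-parameter and forward-MAC counts for both variants.

    ``flop_factor=1`` counts one FLOP per multiply-accumulate (the
    convention used throughout the package); pass 2 for the
    multiply-plus-add convention.  Element-wise work (activations, norms,
    Hadamard products) is excluded in both variants alike.
    """
    out = {}
    for variant in ("isa", "original"):
        cfg = ModelConfig(**{**asdict(config), "encoder_variant": variant})
        net = GridTransformerNet(cfg)
        groups = _layer_groups(net)
        attn_params = sum(sum(p.size for p in ps) for name, ps in groups
                          if name.endswith(".attention"))
        out[variant] = {
            "params": net.n_parameters(),
            "flops": _mac_count(net) * flop_factor,
            "attention_params_per_layer": attn_params // cfg.L,
            "attention_macs_per_layer": net.blocks[0].attn.mac_count() * flop_factor,
            "per_layer": [(name, sum(p.size for p in ps)) for name, ps in groups],
        }
    for key in ("params", "flops"):
        orig, isa = out["original"][key], out["isa"][key]
        out[f"{key}_reduction_pct"] = 100.0 * (orig - isa) / orig
    return out


def format_audit(report: dict) -> str:
    """Human-readable audit: both variants plus percentage difference."""

    def _m(x):
        return f"{x / 1e6:.2f}M"

    lines = [f"{'layer':<28}{'isa params':>12}{'original params':>18}"]
    orig = dict(report["original"]["per_layer"])
    for name, n in report["isa"]["per_layer"]:
        lines.append(f"{name:<28}{n:>12,}{orig.get(name, 0):>18,}")
    lines.append("")
    lines.append(f"Params: {_m(report['isa']['params'])} (isa) vs "
                 f"{_m(report['original']['params'])} (original); "
                 f"reduction {report['params_reduction_pct']:.2f}%")
    lines.append(f"FLOPs:  {_m(report['isa']['flops'])} (isa) vs "
                 f"{_m(report['original']['flops'])} (original); "
                 f"reduction {report['flops_reduction_pct']:.2f}%")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(path, net: GridTransformerNet) -> None:
    """Single-file npz checkpoint with the config embedded as JSON."""
    arrays = {f"param_{i}": p.value for i, p in enumerate(net.parameters())}
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(net.config)).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> GridTransformerNet:
    with np.load(path) as data:
        cfg = ModelConfig(**json.loads(bytes(data["config_json"]).decode()))
        net = GridTransformerNet(cfg)
        for i, p in enumerate(net.parameters()):
            val = data[f"param_{i}"]
            if val.shape != p.value.shape:
                raise ValueError(f"checkpoint mismatch at {p.name}")
            p.value[...] = val
    return net
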