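"""Minimal NumPy neural-network layers with explicit backpropagation.

Every layer caches what its backward pass needs during ``forward`` and
returns the input gradient from ``backward``, accumulating parameter
gradients into :class:`Parameter.grad`.  All layers are deterministic given
their initialisation RNG, and dtype-polymorphic (float32 for training speed,
float64 for finite-difference checks).

The attention layers implement the two encoder variants of the classifier:

* :class:`ISAAttention` — the efficient element-wise attention.  With token
  matrix ``z`` (n x d):

  ``[Q,K,V] = z @ U_qkv``;  keys and values are scaled by the L2 norm of
  their feature axis (eps-guarded), combined by a Hadamard product, mixed
  across tokens by ``U_copy`` (n x n, initialised to 1/n, i.e. an
  aggregate-and-broadcast) and across features by ``U_sum`` (d x d), then
  gated element-wise by the trainable all-ones matrix ``D`` and the queries,
  and projected by ``U_proj``.  No softmax is involved, so cost is linear in
  the token count.
* :class:`SoftmaxAttention` — single-head scaled-dot-product self-attention
  with a fused qkv projection, the standard encoder baseline.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

__all__ = [
    "Parameter",
    "Layer",
    "Dense",
    "LayerNorm",
    "ReLU",
    "GELU",
    "Conv3x3",
    "TokenAugment",
    "ISAAttention",
    "SoftmaxAttention",
    "EncoderBlock",
    "softmax",
    "softmax_cross_entropy",
    "AdamW",
]


class Parameter:
    """A trainable array and its accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def parameters(self) -> list[Parameter]:
        return list(getattr(self, "_params", []))

    def _register(self, name: str, value: np.ndarray) -> Parameter:
        if not hasattr(self, "_params"):
            self._params: list[Parameter] = []
        p = Parameter(name, value)
        self._params.append(p)
        return p


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int, shape, dtype):
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Dense(Layer):
    """Affine map over the last axis: y = x @ W (+ b)."""

    def __init__(self, d_in, d_out, rng, bias=True, name="dense", dtype=np.float32):
        self.W = self._register(f"{name}.W",
                                _xavier(rng, d_in, d_out, (d_in, d_out), dtype))
        self.b = self._register(f"{name}.b", np.zeros(d_out, dtype=dtype)) if bias else None

    def forward(self, x):
        self._x = x
        y = x @ self.W.value
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, dy):
        x = self._x
        self.W.grad += np.einsum("...i,...j->ij", x, dy, optimize=True)
        if self.b is not None:
            self.b.grad += dy.reshape(-1, dy.shape[-1]).sum(axis=0)
        return dy @ self.W.value.T

    def mac_count(self, n_positions: int) -> int:
        return n_positions * self.W.value.shape[0] * self.W.value.shape[1]


class LayerNorm(Layer):
    def __init__(self, dim, name="ln", eps=1e-5, dtype=np.float32):
        self.eps = eps
        self.g = self._register(f"{name}.gamma", np.ones(dim, dtype=dtype))
        self.b = self._register(f"{name}.beta", np.zeros(dim, dtype=dtype))

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat, self._inv = xc * inv, inv
        return self.g.value * self._xhat + self.b.value

    def backward(self, dy):
        xhat, inv = self._xhat, self._inv
        d = xhat.shape[-1]
        self.g.grad += (dy * xhat).reshape(-1, d).sum(axis=0)
        self.b.grad += dy.reshape(-1, d).sum(axis=0)
        dxhat = dy * self.g.value
        return inv / d * (d * dxhat - dxhat.sum(-1, keepdims=True)
                          - xhat * (dxhat * xhat).sum(-1, keepdims=True))


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


class GELU(Layer):
    """Exact (erf-based) Gaussian error linear unit."""

    def forward(self, x):
        from scipy.special import erf
        self._x = x
        self._cdf = 0.5 * (1.0 + erf(x / _SQRT2))
        return x * self._cdf

    def backward(self, dy):
        x = self._x
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
        return dy * (self._cdf + x * pdf)


class Conv3x3(Layer):
    """3x3 convolution, stride 1, padding 1, via im2col."""

    def __init__(self, c_in, c_out, rng, name="conv", dtype=np.float32):
        fan_in, fan_out = c_in * 9, c_out * 9
        self.c_in, self.c_out = c_in, c_out
        self.W = self._register(f"{name}.W",
                                _xavier(rng, fan_in, fan_out, (c_in * 9, c_out), dtype))
        self.b = self._register(f"{name}.b", np.zeros(c_out, dtype=dtype))

    def forward(self, x):
        B, C, H, W = x.shape
        if C != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {C}")
        self._shape = (B, C, H, W)
        cols = self._im2col_reordered(x)
        self._cols = cols
        y = cols @ self.W.value + self.b.value  # B x HW x c_out
        return y.transpose(0, 2, 1).reshape(B, self.c_out, H, W)

    def _im2col_reordered(self, x):
        # weight rows ordered as (c_in, ki, kj) flattened: c*9 + (ki*3+kj)
        B, C, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = np.empty((B, H * W, C * 9), dtype=x.dtype)
        for di in range(3):
            for dj in range(3):
                patch = xp[:, :, di:di + H, dj:dj + W].reshape(B, C, H * W)
                cols[:, :, (di * 3 + dj)::9] = patch.transpose(0, 2, 1)
        return cols

    def backward(self, dy):
        B, C, H, W = self._shape
        dyf = dy.reshape(B, self.c_out, H * W).transpose(0, 2, 1)  # B x HW x c_out
        self.W.grad += np.einsum("bpi,bpo->io", self._cols, dyf, optimize=True)
        self.b.grad += dyf.sum(axis=(0, 1))
        dcols = dyf @ self.W.value.T  # B x HW x C*9
        dxp = np.zeros((B, C, H + 2, W + 2), dtype=dy.dtype)
        for di in range(3):
            for dj in range(3):
                patch = dcols[:, :, (di * 3 + dj)::9].transpose(0, 2, 1).reshape(B, C, H, W)
                dxp[:, :, di:di + H, dj:dj + W] += patch
        return dxp[:, :, 1:-1, 1:-1]

    def mac_count(self, h, w) -> int:
        return h * w * self.c_in * 9 * self.c_out


class TokenAugment(Layer):
    """Prepend trainable token rows (init N(0, 0.02^2)) to the sequence."""

    def __init__(self, n_extra, d, rng, name="tokens", dtype=np.float32):
        self.n_extra = n_extra
        init = (0.02 * rng.standard_normal((n_extra, d))).astype(dtype)
        self.tokens = self._register(f"{name}.rows", init)

    def forward(self, z0):
        B = z0.shape[0]
        t = np.broadcast_to(self.tokens.value, (B,) + self.tokens.value.shape)
        return np.concatenate([t, z0], axis=1)

    def backward(self, dz):
        self.tokens.grad += dz[:, :self.n_extra].sum(axis=0)
        return dz[:, self.n_extra:]


class ISAAttention(Layer):
    """Efficient element-wise self-attention (see module docstring)."""

    def __init__(self, n, d, rng, name="isa", eps=1e-6, dtype=np.float32):
        self.n, self.d, self.eps = n, d, eps
        self.U_qkv = self._register(f"{name}.U_qkv",
                                    _xavier(rng, d, 3 * d, (d, 3 * d), dtype))
        self.U_copy = self._register(f"{name}.U_copy",
                                     np.full((n, n), 1.0 / n, dtype=dtype))
        self.U_sum = self._register(f"{name}.U_sum", _xavier(rng, d, d, (d, d), dtype))
        self.U_proj = self._register(f"{name}.U_proj", _xavier(rng, d, d, (d, d), dtype))
        self.D = self._register(f"{name}.D", np.ones((n, d), dtype=dtype))

    def forward(self, z):
        if z.shape[-2:] != (self.n, self.d):
            raise ValueError(f"expected tokens of shape ({self.n},{self.d}), "
                             f"got {z.shape[-2:]}")
        d = self.d
        P = z @ self.U_qkv.value
        Q, K, V = P[..., :d], P[..., d:2 * d], P[..., 2 * d:]
        nk = np.linalg.norm(K, axis=-1, keepdims=True)
        nv = np.linalg.norm(V, axis=-1, keepdims=True)
        sk = np.maximum(nk, self.eps)
        sv = np.maximum(nv, self.eps)
        Kh, Vh = K / sk, V / sv
        A = Kh * Vh
        M = np.einsum("ij,bjd->bid", self.U_copy.value, A, optimize=True)
        S = M @ self.U_sum.value
        G = self.D.value * Q * S
        self._cache = (z, Q, Kh, Vh, sk, sv, nk, nv, A, M, S, G)
        return G @ self.U_proj.value

    def backward(self, dy):
        z, Q, Kh, Vh, sk, sv, nk, nv, A, M, S, G = self._cache
        self.U_proj.grad += np.einsum("bnd,bne->de", G, dy, optimize=True)
        dG = dy @ self.U_proj.value.T
        self.D.grad += (dG * Q * S).sum(axis=0)
        dQ = dG * self.D.value * S
        dS = dG * self.D.value * Q
        self.U_sum.grad += np.einsum("bnd,bne->de", M, dS, optimize=True)
        dM = dS @ self.U_sum.value.T
        self.U_copy.grad += np.einsum("bid,bjd->ij", dM, A, optimize=True)
        dA = np.einsum("ij,bid->bjd", self.U_copy.value, dM, optimize=True)
        dKh, dVh = dA * Vh, dA * Kh
        dK = self._norm_backward(dKh, Kh, sk, nk)
        dV = self._norm_backward(dVh, Vh, sv, nv)
        dP = np.concatenate([dQ, dK, dV], axis=-1)
        self.U_qkv.grad += np.einsum("bnd,bne->de", z, dP, optimize=True)
        return dP @ self.U_qkv.value.T

    def _norm_backward(self, dyh, yh, s, n_raw):
        # y_hat = y / max(||y||, eps); two regimes
        proj = (dyh * yh).sum(axis=-1, keepdims=True)
        grad = (dyh - yh * proj) / s
        return np.where(n_raw > self.eps, grad, dyh / self.eps)

    def mac_count(self) -> int:
        n, d = self.n, self.d
        return 3 * n * d * d + n * n * d + 2 * n * d * d  # qkv, copy, sum+proj

    def attention_param_count(self) -> int:
        return sum(p.size for p in self.parameters())


class SoftmaxAttention(Layer):
    """Single-head scaled dot-product self-attention (pre-norm baseline)."""

    def __init__(self, n, d, rng, name="mhsa", dtype=np.float32):
        self.n, self.d = n, d
        self.U_qkv = self._register(f"{name}.U_qkv",
                                    _xavier(rng, d, 3 * d, (d, 3 * d), dtype))
        self.U_proj = self._register(f"{name}.U_proj", _xavier(rng, d, d, (d, d), dtype))

    def forward(self, z):
        d = self.d
        P = z @ self.U_qkv.value
        Q, K, V = P[..., :d], P[..., d:2 * d], P[..., 2 * d:]
        scores = Q @ K.swapaxes(-1, -2) / math.sqrt(d)
        scores -= scores.max(axis=-1, keepdims=True)
        e = np.exp(scores)
        attn = e / e.sum(axis=-1, keepdims=True)
        O = attn @ V
        self._cache = (z, Q, K, V, attn, O)
        return O @ self.U_proj.value

    def backward(self, dy):
        z, Q, K, V, attn, O = self._cache
        d = self.d
        self.U_proj.grad += np.einsum("bnd,bne->de", O, dy, optimize=True)
        dO = dy @ self.U_proj.value.T
        dattn = dO @ V.swapaxes(-1, -2)
        dV = attn.swapaxes(-1, -2) @ dO
        dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        dscores /= math.sqrt(d)
        dQ = dscores @ K
        dK = dscores.swapaxes(-1, -2) @ Q
        dP = np.concatenate([dQ, dK, dV], axis=-1)
        self.U_qkv.grad += np.einsum("bnd,bne->de", z, dP, optimize=True)
        return dP @ self.U_qkv.value.T

    def mac_count(self) -> int:
        n, d = self.n, self.d
        return 3 * n * d * d + 2 * n * n * d + n * d * d

    def attention_param_count(self) -> int:
        return sum(p.size for p in self.parameters())


class EncoderBlock(Layer):
    """Pre-norm encoder: attention residual, then an FFN whose residual adds
    the *normalised* intermediate (``z = FFN(LN(z')) + LN(z')``)."""

    def __init__(self, n, d, ffn_hidden, rng, variant="isa", name="enc",
                 dtype=np.float32):
        if variant == "isa":
            self.attn = ISAAttention(n, d, rng, name=f"{name}.isa", dtype=dtype)
        elif variant == "original":
            self.attn = SoftmaxAttention(n, d, rng, name=f"{name}.attn", dtype=dtype)
        else:
            raise ValueError(f"unknown encoder variant {variant!r}")
        self.variant = variant
        self.ln1 = LayerNorm(d, name=f"{name}.ln1", dtype=dtype)
        self.ln2 = LayerNorm(d, name=f"{name}.ln2", dtype=dtype)
        self.fc1 = Dense(d, ffn_hidden, rng, name=f"{name}.fc1", dtype=dtype)
        self.gelu = GELU()
        self.fc2 = Dense(ffn_hidden, d, rng, name=f"{name}.fc2", dtype=dtype)

    def parameters(self):
        out = []
        for sub in (self.attn, self.ln1, self.ln2, self.fc1, self.fc2):
            out += sub.parameters()
        return out

    def forward(self, z):
        zp = self.attn.forward(self.ln1.forward(z)) + z          # z'
        h = self.ln2.forward(zp)                                  # LN(z')
        f = self.fc2.forward(self.gelu.forward(self.fc1.forward(h)))
        return f + h

    def backward(self, dout):
        dh = dout + self.fc1.backward(self.gelu.backward(self.fc2.backward(dout)))
        dzp = self.ln2.backward(dh)
        dz = dzp + self.ln1.backward(self.attn.backward(dzp))
        return dz

    def mac_count(self) -> int:
        n = self.attn.n
        ffn = self.fc1.W.value.shape[1]
        d = self.fc1.W.value.shape[0]
        return self.attn.mac_count() + n * d * ffn + n * ffn * d


def softmax(logits):
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits, labels):
    """Mean cross-entropy; returns (loss, dlogits)."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = np.finfo(p.dtype).tiny
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), (dlogits / n).astype(logits.dtype)


class AdamW:
    """Decoupled weight-decay Adam (the framework-default settings)."""

    def __init__(self, params: Sequence[Parameter], lr=1e-3, betas=(0.9, 0.999),
                 eps=1e-8, weight_decay=0.01):
        self.params = list(params)
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.t = 0
        # moments in float64: squared float32 gradients can overflow
        self.m = [np.zeros(p.value.shape, dtype=np.float64) for p in self.params]
        self.v = [np.zeros(p.value.shape, dtype=np.float64) for p in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad.astype(np.float64)
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            new = p.value.astype(np.float64) * (1.0 - self.lr * self.weight_decay)
            new -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.value[...] = new.astype(p.value.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
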