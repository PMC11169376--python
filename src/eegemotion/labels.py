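"""Label construction from affective ratings.

Ratings on the valence / arousal / dominance dimensions become class labels
under one of four schemes:

* ``binary`` — low/high around a threshold (5 for 1-9 float ratings,
  3 for 1-5 integer ratings), one dimension at a time;
* ``multiclass`` — fine-grained: 1-9 ratings are cut into the eight bins
  [1,2], (2,3], ..., (8,9]; 1-5 integer ratings map directly to 5 classes;
* ``composite_va`` / ``composite_vad`` — the per-dimension binary labels are
  combined into a bit code ((V,A) -> 4 classes, (V,A,D) -> 8 classes,
  valence as the most significant bit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["LabelScheme", "binarize", "bin8", "composite_label"]

DIMS = ("valence", "arousal", "dominance")


def binarize(rating: float, threshold: float,
             rating_range: tuple[float, float] = (1.0, 9.0)) -> int:
    """0 (low) if rating < threshold, 1 (high) if rating >= threshold."""
    lo, hi = rating_range
    if not lo <= rating <= hi:
        raise ValueError(f"rating {rating} outside [{lo}, {hi}]")
    return int(rating >= threshold)


def bin8(rating: float) -> int:
    """Fine-grained class 1..8 for a rating in [1, 9].

    Intervals are [1,2] for class 1 and (k, k+1] for class k = 2..8.
    """
    if not 1.0 <= rating <= 9.0:
        raise ValueError(f"rating {rating} outside [1, 9]")
    return max(1, math.ceil(rating) - 1)


def composite_label(binary: dict[str, int], mode: str) -> int:
    """Big-endian bit code over (valence, arousal[, dominance])."""
    dims = ("valence", "arousal") if mode == "composite_va" else DIMS
    if mode not in ("composite_va", "composite_vad"):
        raise ValueError(f"unknown composite mode {mode!r}")
    missing = [d for d in dims if d not in binary]
    if missing:
        raise KeyError(f"missing dimension(s): {', '.join(missing)}")
    code = 0
    for d in dims:
        code = (code << 1) | int(binary[d])
    return code


@dataclass(frozen=True)
class LabelScheme:
    """A labelling rule plus the rating dialect it applies to."""

    mode: str  # binary | multiclass | composite_va | composite_vad
    dimensions: tuple[str, ...]
    binary_threshold: float
    rating_range: tuple[float, float]
    multiclass_bins: int  # 8 for 1-9 float ratings, 5 for 1-5 integers

    @classmethod
    def binary(cls, dimension: str, dialect: str = "deap") -> "LabelScheme":
        thr, rng, bins = _dialect_params(dialect)
        if dimension not in DIMS:
            raise ValueError(f"unknown dimension {dimension!r}")
        return cls("binary", (dimension,), thr, rng, bins)

    @classmethod
    def multiclass(cls, dimension: str, dialect: str = "deap") -> "LabelScheme":
        thr, rng, bins = _dialect_params(dialect)
        if dimension not in DIMS:
            raise ValueError(f"unknown dimension {dimension!r}")
        return cls("multiclass", (dimension,), thr, rng, bins)

    @classmethod
    def composite(cls, mode: str, dialect: str = "deap") -> "LabelScheme":
        thr, rng, bins = _dialect_params(dialect)
        dims = DIMS[:2] if mode == "composite_va" else DIMS
        return cls(mode, tuple(dims), thr, rng, bins)

    @property
    def n_classes(self) -> int:
        if self.mode == "binary":
            return 2
        if self.mode == "multiclass":
            return self.multiclass_bins
        return 2 ** len(self.dimensions)

    def label(self, ratings: dict[str, float]) -> int:
        """0-based class index for one trial's ratings."""
        if self.mode == "binary":
            return binarize(ratings[self.dimensions[0]], self.binary_threshold,
                            self.rating_range)
        if self.mode == "multiclass":
            r = ratings[self.dimensions[0]]
            if self.multiclass_bins == 8:
                return bin8(r) - 1
            if r != int(r) or not 1 <= r <= 5:
                raise ValueError(f"rating {r} is not an integer in 1..5")
            return int(r) - 1
        bits = {d: binarize(ratings[d], self.binary_threshold, self.rating_range)
                for d in self.dimensions}
        return composite_label(bits, self.mode)

    def labels(self, ratings_array: np.ndarray) -> np.ndarray:
        """Vectorised labelling of an (n, 3) valence/arousal/dominance array."""
        out = np.empty(len(ratings_array), dtype=np.int64)
        for i, row in enumerate(ratings_array):
            out[i] = self.label(dict(zip(DIMS, map(float, row))))
        return out


def _dialect_params(dialect: str):
    if dialect == "deap":
        return 5.0, (1.0, 9.0), 8
    if dialect == "dreamer":
        return 3.0, (1.0, 5.0), 5
    raise ValueError(f"no labelling convention for dialect {dialect!r}")
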