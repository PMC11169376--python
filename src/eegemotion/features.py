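"""Differential-entropy grid features.

Each one-second segment is band-pass filtered into the four classical EEG
rhythms (theta 4-8, alpha 8-13, beta 13-31, gamma 31-45 Hz), the differential
entropy (DE) of every channel x band slice is computed under a Gaussian
approximation,

    DE(x) = 1/2 * ln(2 * pi * e * sigma^2),

min-max normalised per subject x channel x band, scattered onto a sparse
9 x 9 scalp grid (unmapped cells stay 0), and optionally passed through the
dynamic-range log enhancement ``ln(1 + 255 * M)``.  Stacking the four DE
planes and the four enhanced planes yields the 8 x 9 x 9 input tensor of the
classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence  # noqa: F401

import numpy as np
from scipy import signal as sps

from .io import EEGRecording, Segment, segment_trials

__all__ = [
    "BandSpec",
    "CANONICAL_BANDS",
    "ChannelLayout",
    "FeatureTensor",
    "bandpass",
    "band_sos",
    "differential_entropy",
    "minmax_normalize",
    "spatial_map",
    "enhance",
    "compute_de_features",
    "build_feature_tensors",
    "save_feature_tensors",
    "load_feature_tensors",
]

FEATURE_SETS = ("de_only", "enhanced_only", "both")


@dataclass(frozen=True)
class BandSpec:
    """A frequency band with edges in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def validate(self, fs: float) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(f"band {self.name}: need 0 < low < high, "
                             f"got ({self.low_hz}, {self.high_hz})")
        if self.high_hz >= fs / 2:
            raise ValueError(f"band {self.name}: high edge {self.high_hz} Hz "
                             f"reaches Nyquist ({fs / 2} Hz)")


#: theta, alpha, beta, gamma — the plane order of every feature tensor.
CANONICAL_BANDS = (
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 13.0),
    BandSpec("beta", 13.0, 31.0),
    BandSpec("gamma", 31.0, 45.0),
)


def band_sos(band: BandSpec, fs: float) -> np.ndarray:
    """Second-order sections of the 4th-order Butterworth band-pass."""
    band.validate(fs)
    return sps.butter(4, [band.low_hz, band.high_hz], btype="bandpass",
                      fs=fs, output="sos")


def bandpass(segment_signal: np.ndarray, band: BandSpec, fs: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass, channel by channel."""
    sos = band_sos(band, fs)
    return sps.sosfiltfilt(sos, np.asarray(segment_signal, dtype=np.float64), axis=-1)


def differential_entropy(x: np.ndarray) -> float:
    """Gaussian differential entropy of one channel, 1/2*ln(2*pi*e*sigma^2).

    ``sigma`` is the sample standard deviation; a constant input has no
    defined DE and raises.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size < 2:
        raise ValueError("differential entropy needs at least 2 samples")
    var = float(np.var(x))
    if var <= 0.0:
        raise ValueError("zero-variance segment: differential entropy undefined")
    return 0.5 * math.log(2.0 * math.pi * math.e * var)


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Map a sequence to [0, 1] by (x - min) / (max - min).

    A constant sequence maps to all zeros (guarded division).
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("cannot normalise an empty sequence")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


@dataclass(frozen=True)
class ChannelLayout:
    """Injective channel -> (row, col) placement on a grid (default 9 x 9)."""

    cells: Mapping[str, tuple[int, int]]
    grid_h: int = 9
    grid_w: int = 9

    def __post_init__(self) -> None:
        seen: dict[tuple[int, int], str] = {}
        for name, (r, c) in self.cells.items():
            if not (0 <= r < self.grid_h and 0 <= c < self.grid_w):
                raise ValueError(f"channel {name} at ({r},{c}) is off the "
                                 f"{self.grid_h}x{self.grid_w} grid")
            if (r, c) in seen:
                raise ValueError(f"channels {seen[r, c]} and {name} collide at ({r},{c})")
            seen[r, c] = name

    def __len__(self) -> int:
        return len(self.cells)

    def require(self, channel_names: Iterable[str]) -> None:
        missing = [n for n in channel_names if n not in self.cells]
        if missing:
            raise KeyError(f"layout lacks channels: {', '.join(missing)}")

    @classmethod
    def from_file(cls, path) -> "ChannelLayout":
        """Read a plain-text ``channel,row,col`` table ('#' starts a comment)."""
        cells = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            name, r, c = (tok.strip() for tok in line.split(","))
            cells[name] = (int(r), int(c))
        return cls(cells=cells)

    def to_file(self, path) -> None:
        lines = ["# channel,row,col"]
        lines += [f"{name},{r},{c}" for name, (r, c) in self.cells.items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def builtin(cls, name: str) -> "ChannelLayout":
        """A layout shipped with the package: ``deap`` or ``dreamer``."""
        here = Path(__file__).parent / "layouts" / f"{name}.txt"
        if not here.exists():
            raise KeyError(f"no builtin layout {name!r}")
        return cls.from_file(here)


def spatial_map(channel_values: Mapping[str, float], layout: ChannelLayout) -> np.ndarray:
    """Scatter per-channel scalars onto the grid; unmapped cells are 0."""
    unknown = [n for n in channel_values if n not in layout.cells]
    if unknown:
        raise KeyError(f"channels not in layout: {', '.join(unknown)}")
    grid = np.zeros((layout.grid_h, layout.grid_w), dtype=np.float64)
    for name, val in channel_values.items():
        r, c = layout.cells[name]
        grid[r, c] = val
    return grid


def enhance(M: np.ndarray, mode: str = "inside") -> np.ndarray:
    """Log dynamic-range enhancement of a normalised grid.

    ``inside`` (default): ln(1 + 255*M); ``outside``: 255*ln(1 + M).  Both
    leave zeros at zero, so structurally empty grid cells stay empty.
    """
    M = np.asarray(M, dtype=np.float64)
    if mode == "inside":
        return np.log1p(255.0 * M)
    if mode == "outside":
        return 255.0 * np.log1p(M)
    raise ValueError(f"unknown enhancement mode {mode!r}")


# ---------------------------------------------------------------------------
# end-to-end extraction

@dataclass(frozen=True)
class FeatureTensor:
    """One segment's stacked grid planes plus labels and provenance."""

    values: np.ndarray  # C x H x W
    band_order: tuple[str, ...]
    plane_order: tuple[str, ...]
    label_payload: Mapping[str, float]
    subject_id: str
    trial_id: int
    second_index: int


def compute_de_features(
    rec: EEGRecording,
    bands: Sequence[BandSpec] = CANONICAL_BANDS,
    window_s: int = 1,
) -> tuple[np.ndarray, list[Segment]]:
    """Raw (un-normalised) DE values for every segment.

    Returns ``(de, segments)`` with ``de`` of shape
    ``n_segments x n_channels x n_bands``.  Filtering is applied per trial
    (not per segment) so the zero-phase filter sees full-length context, then
    the filtered trial is sliced into the same windows as the segments.
    """
    for b in bands:
        b.validate(rec.fs)
    segments = segment_trials(rec, window_s=window_s)
    win = window_s * rec.fs
    de = np.empty((len(segments), rec.n_channels, len(bands)), dtype=np.float64)
    row = 0
    for t in rec.trials:
        n_win = t.signal.shape[1] // win
        if n_win == 0:
            continue
        for bi, band in enumerate(bands):
            filt = bandpass(t.signal, band, rec.fs)
            # slice the filtered trial into windows: n_win x channels x win
            sliced = filt[:, :n_win * win].reshape(rec.n_channels, n_win, win)
            var = sliced.var(axis=-1)
            if np.any(var <= 0):
                ch, wi = np.argwhere(var <= 0)[0]
                raise ValueError(
                    f"zero-variance segment (subject {rec.subject_id}, trial "
                    f"{t.trial_id}, channel {rec.channel_names[ch]}, second {wi})"
                )
            de[row:row + n_win, :, bi] = (0.5 * np.log(2 * np.pi * np.e * var)).T
        row += n_win
    assert row == len(segments)
    return de, segments


def normalize_de(de: np.ndarray, stats_de: np.ndarray | None = None) -> np.ndarray:
    """Per channel x band min-max of DE values across segments.

    ``stats_de`` optionally supplies the array from which min/max are taken
    (the training folds under the strict protocol); results are clipped to
    [0, 1] so held-out segments cannot leave the unit range.
    """
    ref = de if stats_de is None else stats_de
    lo = ref.min(axis=0, keepdims=True)
    hi = ref.max(axis=0, keepdims=True)
    span = hi - lo
    out = np.where(span > 0, (de - lo) / np.where(span > 0, span, 1.0), 0.0)
    return np.clip(out, 0.0, 1.0)


def assemble_tensors(
    norm_de: np.ndarray,
    segments: Sequence[Segment],
    channel_names: Sequence[str],
    layout: ChannelLayout,
    bands: Sequence[BandSpec] = CANONICAL_BANDS,
    feature_set: str = "both",
    enhancement: str = "inside",
) -> list[FeatureTensor]:
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
    layout.require(channel_names)
    rows = np.array([layout.cells[n][0] for n in channel_names])
    cols = np.array([layout.cells[n][1] for n in channel_names])
    band_names = tuple(b.name for b in bands)
    n_seg, n_ch, n_band = norm_de.shape

    de_planes = np.zeros((n_seg, n_band, layout.grid_h, layout.grid_w))
    for ci in range(n_ch):
        de_planes[:, :, rows[ci], cols[ci]] = norm_de[:, ci, :]

    if feature_set == "de_only":
        stacks = de_planes
        plane_order = tuple(f"DE_{b}" for b in band_names)
    else:
        en_planes = enhance(de_planes, mode=enhancement)
        if feature_set == "enhanced_only":
            stacks = en_planes
            plane_order = tuple(f"EN_{b}" for b in band_names)
        else:
            stacks = np.concatenate([de_planes, en_planes], axis=1)
            plane_order = tuple(f"DE_{b}" for b in band_names) + \
                tuple(f"EN_{b}" for b in band_names)

    tensors = []
    for i, seg in enumerate(segments):
        tensors.append(FeatureTensor(
            values=stacks[i], band_order=band_names, plane_order=plane_order,
            label_payload=dict(seg.ratings), subject_id=seg.subject_id,
            trial_id=seg.trial_id, second_index=seg.second_index,
        ))
    return tensors


def build_feature_tensors(
    rec: EEGRecording,
    layout: ChannelLayout,
    feature_set: str = "both",
    bands: Sequence[BandSpec] = CANONICAL_BANDS,
    enhancement: str = "inside",
    window_s: int = 1,
) -> list[FeatureTensor]:
    """Recording -> per-segment grid tensors.

    Normalisation statistics are the subject's own per channel x band min and
    max over *all* segments (the default, whole-session protocol; see
    :class:`eegemotion.pipeline.EmotionClassifier` for the fold-strict
    alternative).
    """
    de, segments = compute_de_features(rec, bands=bands, window_s=window_s)
    norm = normalize_de(de)
    return assemble_tensors(norm, segments, rec.channel_names, layout,
                            bands=bands, feature_set=feature_set,
                            enhancement=enhancement)


# ---------------------------------------------------------------------------
# HDF5 feature store

def save_feature_tensors(path, tensors: Sequence[FeatureTensor]) -> None:
    """Write tensors + ratings + provenance for one subject to HDF5."""
    import h5py

    if not tensors:
        raise ValueError("nothing to save")
    feats = np.stack([t.values for t in tensors]).astype(np.float32)
    dims = ("valence", "arousal", "dominance")
    ratings = np.array([[t.label_payload.get(d, np.nan) for d in dims]
                        for t in tensors], dtype=np.float64)
    prov = np.array([[t.trial_id, t.second_index, 0] for t in tensors], dtype=np.int64)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("features", data=feats)
        fh.create_dataset("ratings", data=ratings)
        fh.create_dataset("provenance", data=prov)
        fh.attrs["subject_id"] = tensors[0].subject_id
        fh.attrs["band_order"] = ",".join(tensors[0].band_order)
        fh.attrs["plane_order"] = ",".join(tensors[0].plane_order)
        fh.attrs["rating_dims"] = ",".join(dims)


def load_feature_tensors(path):
    """Read a feature store; returns (features, ratings, provenance, meta)."""
    import h5py

    with h5py.File(path, "r") as fh:
        feats = fh["features"][()].astype(np.float64)
        ratings = fh["ratings"][()]
        prov = fh["provenance"][()]
        meta = {k: fh.attrs[k] for k in fh.attrs}
    meta["plane_order"] = tuple(str(meta.get("plane_order", "")).split(","))
    meta["band_order"] = tuple(str(meta.get("band_order", "")).split(","))
    return feats, ratings, prov, meta
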