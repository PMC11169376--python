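"""EEG recording containers and dataset loaders.

The package works on a single in-memory representation, :class:`EEGRecording`:
one subject's worth of trials, each a ``channels x samples`` array with
per-trial affective ratings on the valence / arousal / dominance dimensions.

Four on-disk dialects are supported:

``deap``
    The preprocessed per-subject python pickle distributed with the DEAP
    benchmark (``data`` of shape 40 x 40 x 8064 at 128 Hz, ``labels`` of
    shape 40 x 4).  Only the first 32 rows of the channel axis (the EEG
    electrodes) are kept; the peripheral-physiology rows are dropped.  Each
    trial retains its leading 3 s baseline; use :func:`strip_baseline` to
    remove it.
``dreamer``
    The all-subjects MATLAB container of the DREAMER benchmark.  The
    stimulus-period EEG is loaded; the per-trial baseline recordings are
    discarded (no baseline correction is part of this pipeline).
``generic``
    EDF files plus a sidecar ratings table (CSV with columns
    ``trial_id, valence, arousal, dominance`` and optionally ``file``).
``synthetic``
    The HDF5 layout written by :mod:`eegemotion.synthetic`.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "EEGRecording",
    "Trial",
    "Segment",
    "DialectError",
    "DEAP_CHANNELS",
    "DREAMER_CHANNELS",
    "load_recording",
    "strip_baseline",
    "segment_trials",
]

#: Electrode order of the preprocessed DEAP EEG rows (Geneva ordering).
DEAP_CHANNELS = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)

#: Emotiv EPOC electrode order used by DREAMER.
DREAMER_CHANNELS = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

RATING_DIMENSIONS = ("valence", "arousal", "dominance")

_DIALECTS = ("deap", "dreamer", "generic", "synthetic")


class DialectError(ValueError):
    """The file on disk does not match the declared dataset dialect."""


@dataclass
class Trial:
    """One stimulus presentation: a multichannel signal plus its ratings."""

    trial_id: int
    signal: np.ndarray  # channels x samples
    ratings: dict[str, float]

    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass
class EEGRecording:
    """One subject's trials at a common sampling rate."""

    subject_id: str
    fs: int
    channel_names: tuple[str, ...]
    trials: list[Trial]
    dialect: str = "generic"

    def __post_init__(self) -> None:
        self.channel_names = tuple(self.channel_names)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        for t in self.trials:
            if t.signal.ndim != 2 or t.signal.shape[0] != len(self.channel_names):
                raise ValueError(
                    f"trial {t.trial_id}: signal shape {t.signal.shape} does not "
                    f"match {len(self.channel_names)} channels"
                )
            if t.signal.shape[1] < self.fs:
                raise ValueError(f"trial {t.trial_id}: shorter than one second")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)


@dataclass(frozen=True)
class Segment:
    """Exactly one second of one trial, carrying provenance and ratings."""

    subject_id: str
    trial_id: int
    second_index: int
    signal: np.ndarray  # channels x fs
    ratings: Mapping[str, float]


# ---------------------------------------------------------------------------
# loaders

def load_recording(path, dialect: str, subject: int | str | None = None) -> EEGRecording:
    """Load one subject's recording from *path* in the given dialect.

    For the DREAMER dialect (one file holds every subject) *subject* selects
    the 0-based subject index, defaulting to 0.
    """
    path = Path(path)
    if dialect not in _DIALECTS:
        raise DialectError(f"unsupported dialect {dialect!r}; expected one of {_DIALECTS}")
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "deap":
        return _load_deap(path)
    if dialect == "dreamer":
        return _load_dreamer(path, 0 if subject is None else int(subject))
    if dialect == "synthetic":
        return _load_synthetic(path)
    return _load_generic(path)


def _load_deap(path: Path) -> EEGRecording:
    with open(path, "rb") as fh:
        try:
            payload = pickle.load(fh, encoding="latin1")
        except Exception as exc:  # pragma: no cover - corrupt file
            raise IOError(f"could not unpickle DEAP file {path}: {exc}") from exc
    try:
        data = np.asarray(payload["data"])
        labels = np.asarray(payload["labels"], dtype=float)
    except (TypeError, KeyError) as exc:
        raise DialectError(f"{path} lacks DEAP 'data'/'labels' arrays") from exc
    if data.ndim != 3 or data.shape[1] < 32:
        raise DialectError(
            f"{path}: expected >=32 channel rows in a trials x channels x samples "
            f"array, got shape {data.shape}"
        )
    trials = []
    for i in range(data.shape[0]):
        ratings = {dim: float(labels[i, j]) for j, dim in enumerate(RATING_DIMENSIONS)}
        _check_rating_range(ratings, 1.0, 9.0, f"{path} trial {i}")
        trials.append(Trial(trial_id=i, signal=np.asarray(data[i, :32], dtype=np.float64),
                            ratings=ratings))
    return EEGRecording(subject_id=path.stem, fs=128, channel_names=DEAP_CHANNELS,
                        trials=trials, dialect="deap")


def _load_dreamer(path: Path, subject: int) -> EEGRecording:
    from scipy.io import loadmat

    try:
        mat = loadmat(path, squeeze_me=True, struct_as_record=False)
    except Exception as exc:
        raise IOError(f"could not read MATLAB container {path}: {exc}") from exc
    if "DREAMER" not in mat:
        raise DialectError(f"{path} has no top-level 'DREAMER' struct")
    root = mat["DREAMER"]
    subjects = np.atleast_1d(root.Data)
    if not 0 <= subject < len(subjects):
        raise DialectError(f"subject index {subject} out of range (n={len(subjects)})")
    rec = subjects[subject]
    stimuli = np.atleast_1d(rec.EEG.stimuli)
    valence = np.atleast_1d(rec.ScoreValence).astype(float)
    arousal = np.atleast_1d(rec.ScoreArousal).astype(float)
    dominance = np.atleast_1d(rec.ScoreDominance).astype(float)
    trials = []
    for i, sig in enumerate(stimuli):
        sig = np.asarray(sig, dtype=np.float64)
        if sig.ndim != 2:
            raise DialectError(f"{path}: stimulus {i} is not a 2-D array")
        if sig.shape[0] != 14 and sig.shape[1] == 14:
            sig = sig.T  # DREAMER stores samples x channels
        if sig.shape[0] != 14:
            raise DialectError(
                f"{path}: stimulus {i} has {sig.shape[0]} channels, expected 14"
            )
        ratings = {"valence": float(valence[i]), "arousal": float(arousal[i]),
                   "dominance": float(dominance[i])}
        for dim, r in ratings.items():
            if r != int(r) or not 1 <= r <= 5:
                raise DialectError(
                    f"{path} trial {i}: {dim} rating {r} not an integer in 1..5"
                )
        trials.append(Trial(trial_id=i, signal=sig, ratings=ratings))
    return EEGRecording(subject_id=f"dreamer_s{subject:02d}", fs=128,
                        channel_names=DREAMER_CHANNELS, trials=trials,
                        dialect="dreamer")


def _load_generic(path: Path) -> EEGRecording:
    """EDF trial files plus a ratings CSV.

    *path* may be a directory containing ``ratings.csv`` and one EDF per
    trial, or a single EDF whose sidecar ``<stem>.csv`` holds one row.
    """
    import pandas as pd

    if path.is_dir():
        table = pd.read_csv(path / "ratings.csv")
        edf_dir = path
    else:
        table = pd.read_csv(path.with_suffix(".csv"))
        if len(table) != 1:
            raise DialectError(
                f"single EDF {path} needs a one-row sidecar, got {len(table)} rows"
            )
        edf_dir = path.parent
    trials = []
    fs = None
    names: tuple[str, ...] | None = None
    for _, row in table.iterrows():
        tid = int(row["trial_id"])
        fname = row["file"] if "file" in table.columns else f"trial_{tid:03d}.edf"
        sig, ch_names, sfreq = _read_edf(edf_dir / fname if path.is_dir() else path)
        if fs is None:
            fs, names = int(round(sfreq)), tuple(ch_names)
        elif int(round(sfreq)) != fs or tuple(ch_names) != names:
            raise DialectError(f"{fname}: sampling rate or montage differs across trials")
        ratings = {dim: float(row[dim]) for dim in RATING_DIMENSIONS if dim in table.columns}
        trials.append(Trial(trial_id=tid, signal=sig, ratings=ratings))
    assert fs is not None and names is not None
    return EEGRecording(subject_id=path.stem, fs=fs, channel_names=names,
                        trials=trials, dialect="generic")


def _read_edf(path: Path):
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return raw.get_data(), raw.ch_names, raw.info["sfreq"]


def _load_synthetic(path: Path) -> EEGRecording:
    import h5py

    with h5py.File(path, "r") as fh:
        names = tuple(n.decode() if isinstance(n, bytes) else str(n)
                      for n in fh["channel_names"][()])
        fs = int(fh.attrs["fs"])
        subject_id = str(fh.attrs["subject_id"])
        trials = []
        grp = fh["trials"]
        for key in sorted(grp):
            ds = grp[key]
            ratings = {dim: float(ds.attrs[dim]) for dim in RATING_DIMENSIONS
                       if dim in ds.attrs}
            trials.append(Trial(trial_id=int(ds.attrs["trial_id"]),
                                signal=ds[()].astype(np.float64), ratings=ratings))
    return EEGRecording(subject_id=subject_id, fs=fs, channel_names=names,
                        trials=trials, dialect="synthetic")


def _check_rating_range(ratings, lo, hi, ctx):
    for dim, r in ratings.items():
        if not lo <= r <= hi:
            raise DialectError(f"{ctx}: {dim} rating {r} outside [{lo}, {hi}]")


# ---------------------------------------------------------------------------
# trial surgery

def strip_baseline(rec: EEGRecording, baseline_s: int) -> EEGRecording:
    """Drop the first *baseline_s* seconds of every trial (ratings kept)."""
    if baseline_s < 0:
        raise ValueError("baseline_s must be non-negative")
    if baseline_s == 0:
        return rec
    cut = baseline_s * rec.fs
    trials = []
    for t in rec.trials:
        if t.n_samples() <= cut:
            raise ValueError(
                f"trial {t.trial_id} ({t.n_samples() / rec.fs:.1f} s) is not longer "
                f"than the {baseline_s} s baseline"
            )
        trials.append(Trial(trial_id=t.trial_id, signal=t.signal[:, cut:],
                            ratings=dict(t.ratings)))
    return EEGRecording(subject_id=rec.subject_id, fs=rec.fs,
                        channel_names=rec.channel_names, trials=trials,
                        dialect=rec.dialect)


def segment_trials(rec: EEGRecording, window_s: int = 1) -> list[Segment]:
    """Cut every trial into non-overlapping ``window_s``-second segments.

    Segments are emitted in (trial, time) order; a trailing remainder shorter
    than one window is dropped.  Each segment inherits its trial's ratings.
    """
    if window_s < 1:
        raise ValueError("window_s must be >= 1")
    win = window_s * rec.fs
    segments: list[Segment] = []
    for t in rec.trials:
        n_win = t.n_samples() // win
        for i in range(n_win):
            segments.append(Segment(
                subject_id=rec.subject_id, trial_id=t.trial_id, second_index=i,
                signal=t.signal[:, i * win:(i + 1) * win], ratings=dict(t.ratings),
            ))
    return segments
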