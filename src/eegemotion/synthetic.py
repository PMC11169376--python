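"""Synthetic EEG with known class-dependent spectral structure.

Each trial belongs to a latent emotion class assigned round-robin; its
signal is broadband Gaussian noise plus band-limited noise in the class's
target rhythm, amplified by the class gain, independently per channel.  The
band-limited component is produced with the same 4th-order Butterworth bank
the feature extractor uses, so a class's extra power lands exactly in one DE
plane.  Trial ratings are placed at fine-grained bin centres so both the
binary and the 8-bin labelling rules separate the classes unambiguously.

This generator emulates only the power structure the feature extractor
measures — not 1/f spectra, artifacts or inter-channel covariance of real
EEG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .features import CANONICAL_BANDS, BandSpec, band_sos
from .io import EEGRecording, Trial

__all__ = ["SynthSpec", "generate_recording", "generate_dataset",
           "save_recording", "synthetic_layout"]

_BANDS = {b.name: b for b in CANONICAL_BANDS}

#: default 4-class map: one class per rhythm, power gain 4 over the floor
DEFAULT_CLASS_MAP = {
    0: ("theta", 4.0),
    1: ("alpha", 4.0),
    2: ("beta", 4.0),
    3: ("gamma", 4.0),
}

#: ratings at 8-bin centres (bins 1, 3, 5, 8): classes 0,1 are "low" and
#: 2,3 "high" under the threshold-5 binary rule
DEFAULT_RATING_MAP = {
    0: (1.5, 1.5, 1.5),
    1: (3.5, 3.5, 3.5),
    2: (5.5, 5.5, 5.5),
    3: (8.5, 8.5, 8.5),
}


@dataclass
class SynthSpec:
    """Generator settings; the defaults are the package's study conditions."""

    n_channels: int = 32
    fs: int = 128
    n_trials: int = 40
    trial_s: int = 60
    class_map: dict[int, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MAP))
    rating_map: dict[int, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RATING_MAP))
    noise_floor: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_channels < 1 or self.n_trials < 1 or self.trial_s < 1:
            raise ValueError("channels, trials and trial length must be positive")
        if self.noise_floor <= 0:
            raise ValueError("noise_floor must be positive")
        for cls, (band, gain) in self.class_map.items():
            if band not in _BANDS:
                raise ValueError(f"class {cls}: unknown band {band!r}")
            if gain <= 1:
                raise ValueError(f"class {cls}: gain must exceed 1, got {gain}")
            _BANDS[band].validate(self.fs)
            if cls not in self.rating_map:
                raise ValueError(f"class {cls} has no ratings")


def _band_noise(rng: np.random.Generator, band: BandSpec, fs: int,
                shape: tuple[int, int]) -> np.ndarray:
    white = rng.standard_normal(shape)
    return sps.sosfilt(band_sos(band, fs), white, axis=-1)


def generate_recording(spec: SynthSpec, subject_id: str = "synthetic_s00",
                       seed: int | None = None) -> tuple[EEGRecording, list[int]]:
    """One subject's recording plus the per-trial class assignment."""
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    classes = sorted(spec.class_map)
    n_samp = spec.trial_s * spec.fs
    trials = []
    assignment = []
    for i in range(spec.n_trials):
        cls = classes[i % len(classes)]  # balanced round-robin
        band, gain = spec.class_map[cls]
        sig = spec.noise_floor * rng.standard_normal((spec.n_channels, n_samp))
        sig += gain * _band_noise(rng, _BANDS[band], spec.fs,
                                  (spec.n_channels, n_samp))
        v, a, d = spec.rating_map[cls]
        trials.append(Trial(trial_id=i, signal=sig,
                            ratings={"valence": v, "arousal": a, "dominance": d}))
        assignment.append(cls)
    rec = EEGRecording(subject_id=subject_id, fs=spec.fs,
                       channel_names=tuple(f"ch{i:02d}" for i in range(spec.n_channels)),
                       trials=trials, dialect="synthetic")
    return rec, assignment


def generate_dataset(spec: SynthSpec, n_subjects: int):
    """Independent per-subject recordings plus a manifest.

    Per-subject seeds are drawn from a seed sequence spawned off the master
    seed, so subjects differ in signal but share the trial structure.
    """
    ss = np.random.SeedSequence(spec.seed)
    recordings = []
    manifest = {"master_seed": spec.seed, "subjects": []}
    for s, child in enumerate(ss.spawn(n_subjects)):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        rec, classes = generate_recording(spec, subject_id=f"synthetic_s{s:02d}",
                                          seed=sub_seed)
        recordings.append(rec)
        manifest["subjects"].append({
            "subject_id": rec.subject_id,
            "seed": sub_seed,
            "classes": classes,
            "ratings": [dict(t.ratings) for t in rec.trials],
        })
    return recordings, manifest


def synthetic_layout(n_channels: int):
    """Grid placement for the generator's ``chNN`` channel names.

    Reuses the cells of the builtin 32-channel 10-20 layout in order, so up
    to 32 synthetic channels land on plausible scalp positions.
    """
    from .features import ChannelLayout

    base = ChannelLayout.builtin("deap")
    if n_channels > len(base.cells):
        raise ValueError(f"at most {len(base.cells)} synthetic channels supported")
    coords = list(base.cells.values())[:n_channels]
    return ChannelLayout(cells={f"ch{i:02d}": coords[i] for i in range(n_channels)})


def save_recording(path, rec: EEGRecording) -> None:
    """Write a recording in the HDF5 layout of the ``synthetic`` dialect."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["subject_id"] = rec.subject_id
        fh.attrs["fs"] = rec.fs
        fh.attrs["dialect"] = rec.dialect
        fh.create_dataset("channel_names",
                          data=np.array(rec.channel_names, dtype="S"))
        grp = fh.create_group("trials")
        for t in rec.trials:
            ds = grp.create_dataset(f"trial_{t.trial_id:04d}",
                                    data=t.signal.astype(np.float64))
            ds.attrs["trial_id"] = t.trial_id
            for dim, val in t.ratings.items():
                ds.attrs[dim] = val
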