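import numpy as np
import pytest

from eegemotion.synthetic import SynthSpec, generate_recording, synthetic_layout


@pytest.fixture(scope="session")
def small_spec():
    """A fast 8-channel, 8-trial generator spec for unit tests."""
    return SynthSpec(n_channels=8, n_trials=8, trial_s=10, seed=7)


@pytest.fixture(scope="session")
def small_recording(small_spec):
    rec, classes = generate_recording(small_spec)
    return rec, classes


@pytest.fixture(scope="session")
def small_layout(small_spec):
    return synthetic_layout(small_spec.n_channels)


def write_minimal_edf(path, signals, fs, channel_names):
    """Synthetic EDF fixture writer (test utility, not a production encoder).

    Writes an EDF with one data record per second, int16 samples, physical
    range chosen per channel to cover the signal.
    """
    signals = np.asarray(signals, dtype=np.float64)
    n_ch, n_samp = signals.shape
    assert n_samp % fs == 0
    n_rec = n_samp // fs

    def pad(s, width):
        b = str(s).encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b""
    header += pad("0", 8)
    header += pad("X X X X", 80)          # patient
    header += pad("Startdate 01-JAN-2024 X X X", 80)
    header += pad("01.01.24", 8) + pad("00.00.00", 8)
    header += pad(256 * (1 + n_ch), 8)
    header += pad("", 44)
    header += pad(n_rec, 8)
    header += pad("1", 8)                 # record duration in seconds
    header += pad(n_ch, 4)

    phys_min = signals.min(axis=1) - 1.0
    phys_max = signals.max(axis=1) + 1.0
    fields = [
        [pad(name, 16) for name in channel_names],
        [pad("", 80)] * n_ch,
        [pad("uV", 8)] * n_ch,
        [pad(f"{phys_min[i]:.2f}", 8) for i in range(n_ch)],
        [pad(f"{phys_max[i]:.2f}", 8) for i in range(n_ch)],
        [pad(-32768, 8)] * n_ch,
        [pad(32767, 8)] * n_ch,
        [pad("", 80)] * n_ch,
        [pad(fs, 8)] * n_ch,
        [pad("", 32)] * n_ch,
    ]
    for f in fields:
        header += b"".join(f)

    body = b""
    for r in range(n_rec):
        for i in range(n_ch):
            chunk = signals[i, r * fs:(r + 1) * fs]
            digital = np.round(
                (chunk - phys_min[i]) / (phys_max[i] - phys_min[i])
                * 65535.0 - 32768.0).astype("<i2")
            body += digital.tobytes()
    with open(path, "wb") as fh:
        fh.write(header + body)
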