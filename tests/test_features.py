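"""Filter bank, differential entropy, normalisation, grid mapping, tensors."""

import math

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from eegemotion.features import (CANONICAL_BANDS, BandSpec, ChannelLayout,
                                 bandpass, build_feature_tensors,
                                 compute_de_features, differential_entropy,
                                 enhance, load_feature_tensors,
                                 minmax_normalize, save_feature_tensors,
                                 spatial_map)
from eegemotion.synthetic import SynthSpec, generate_recording, synthetic_layout

ALPHA = CANONICAL_BANDS[1]


def _sine(freq, fs=128, seconds=4):
    t = np.arange(seconds * fs) / fs
    return np.sin(2 * np.pi * freq * t)[None, :]


def test_bandpass_passes_in_band_and_rejects_out_of_band():
    fs = 128
    in_band = bandpass(_sine(10, fs), ALPHA, fs)
    out_band = bandpass(_sine(40, fs), ALPHA, fs)
    rms = lambda x: np.sqrt(np.mean(x ** 2))
    assert rms(in_band) >= 0.9 * rms(_sine(10, fs))
    assert rms(out_band) <= 0.1 * rms(_sine(40, fs))


def test_band_validation():
    with pytest.raises(ValueError):
        bandpass(_sine(10), BandSpec("bad", 20, 10), 128)
    with pytest.raises(ValueError):
        bandpass(_sine(10), BandSpec("bad", 30, 64), 128)  # reaches Nyquist


@pytest.mark.parametrize("sigma", [0.5, 1.0, 2.0])
def test_differential_entropy_matches_gaussian_closed_form(sigma):
    rng = np.random.default_rng(42)
    x = sigma * rng.standard_normal(4096)
    analytic = 0.5 * math.log(2 * math.pi * math.e * sigma ** 2)
    assert differential_entropy(x) == pytest.approx(analytic, abs=0.05)


def test_differential_entropy_scaling_shift():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(1024)
    assert differential_entropy(2 * x) - differential_entropy(x) == \
        pytest.approx(math.log(2), abs=1e-12)


def test_differential_entropy_degenerate():
    with pytest.raises(ValueError):
        differential_entropy(np.full(100, 3.3))
    with pytest.raises(ValueError):
        differential_entropy(np.array([1.0]))


def test_minmax_normalize():
    np.testing.assert_allclose(minmax_normalize([2, 4, 6]), [0, 0.5, 1])
    np.testing.assert_array_equal(minmax_normalize([5, 5, 5]), [0, 0, 0])
    rng = np.random.default_rng(1)
    v = minmax_normalize(rng.normal(size=50))
    assert v.min() == 0 and v.max() == 1 and ((0 <= v) & (v <= 1)).all()
    with pytest.raises(ValueError):
        minmax_normalize([])


def test_spatial_map_conservation_and_counts():
    deap = ChannelLayout.builtin("deap")
    dreamer = ChannelLayout.builtin("dreamer")
    assert len(deap) == 32 and len(dreamer) == 14
    values = {name: float(i + 1) for i, name in enumerate(deap.cells)}
    grid = spatial_map(values, deap)
    assert grid.shape == (9, 9)
    assert grid.sum() == pytest.approx(sum(values.values()))
    assert np.count_nonzero(grid) == 32  # 49 structurally-zero cells remain
    with pytest.raises(KeyError, match="NoSuchChannel"):
        spatial_map({"NoSuchChannel": 1.0}, deap)


def test_layout_injectivity_and_file_roundtrip(tmp_path):
    with pytest.raises(ValueError, match="collide"):
        ChannelLayout(cells={"a": (0, 0), "b": (0, 0)})
    with pytest.raises(ValueError, match="off the"):
        ChannelLayout(cells={"a": (9, 0)})
    layout = ChannelLayout.builtin("dreamer")
    layout.to_file(tmp_path / "l.txt")
    assert ChannelLayout.from_file(tmp_path / "l.txt").cells == dict(layout.cells)


def test_enhance():
    np.testing.assert_array_equal(enhance(np.zeros((9, 9))), np.zeros((9, 9)))
    assert enhance(np.array([1.0]))[0] == pytest.approx(math.log(256), abs=1e-12)
    m = np.linspace(0, 1, 11)
    assert (np.diff(enhance(m)) > 0).all()  # strictly increasing
    assert enhance(np.array([1.0]), mode="outside")[0] == \
        pytest.approx(255 * math.log(2))


@pytest.mark.parametrize("feature_set,planes", [("both", 8), ("de_only", 4),
                                                ("enhanced_only", 4)])
def test_tensor_shapes_and_plane_order(small_recording, small_layout,
                                       feature_set, planes):
    rec, _ = small_recording
    tensors = build_feature_tensors(rec, small_layout, feature_set=feature_set)
    expected_n = sum(t.signal.shape[1] // rec.fs for t in rec.trials)
    assert len(tensors) == expected_n
    t0 = tensors[0]
    assert t0.values.shape == (planes, 9, 9)
    assert t0.band_order == ("theta", "alpha", "beta", "gamma")
    if feature_set == "both":
        assert t0.plane_order[:4] == ("DE_theta", "DE_alpha", "DE_beta", "DE_gamma")
        assert t0.plane_order[4:] == ("EN_theta", "EN_alpha", "EN_beta", "EN_gamma")


def test_normalized_planes_attain_extremes_and_zeros(small_recording, small_layout):
    rec, _ = small_recording
    tensors = build_feature_tensors(rec, small_layout, feature_set="both")
    stack = np.stack([t.values for t in tensors])  # n x 8 x 9 x 9
    mapped = np.zeros((9, 9), dtype=bool)
    for r, c in small_layout.cells.values():
        mapped[r, c] = True
    # unmapped cells are exactly 0 on every plane
    assert np.all(stack[:, :, ~mapped] == 0)
    # DE planes lie in [0,1] and attain both extremes per channel x band
    de = stack[:, :4]
    assert de.min() >= 0 and de.max() <= 1
    for r, c in small_layout.cells.values():
        for b in range(4):
            col = de[:, b, r, c]
            assert col.min() == 0.0 and col.max() == 1.0


def test_feature_extraction_deterministic(small_recording, small_layout):
    rec, _ = small_recording
    a = np.stack([t.values for t in build_feature_tensors(rec, small_layout)])
    b = np.stack([t.values for t in build_feature_tensors(rec, small_layout)])
    np.testing.assert_array_equal(a, b)


def test_band_power_classes_separate_in_de():
    """The class's target-band DE plane is stochastically larger (rank test)."""
    spec = SynthSpec(n_channels=8, n_trials=20, trial_s=40, seed=3)
    rec, classes = generate_recording(spec)
    de, segments = compute_de_features(rec)
    seg_class = np.array([classes[s.trial_id] for s in segments])
    alpha_de = de[:, :, 1].mean(axis=1)  # mean over channels, alpha band
    a = alpha_de[seg_class == 1]  # alpha-boosted class
    b = alpha_de[seg_class == 0]  # theta-boosted class
    assert len(a) == len(b) == 200
    stat, p = mannwhitneyu(a, b, alternative="greater")
    assert p < 0.01


def test_hdf5_feature_store_roundtrip(tmp_path, small_recording, small_layout):
    rec, _ = small_recording
    tensors = build_feature_tensors(rec, small_layout)
    path = tmp_path / "feat.h5"
    save_feature_tensors(path, tensors)
    feats, ratings, prov, meta = load_feature_tensors(path)
    assert feats.shape == (len(tensors), 8, 9, 9)
    assert ratings.shape == (len(tensors), 3)
    np.testing.assert_allclose(feats[5], tensors[5].values, rtol=1e-6)
    assert meta["subject_id"] == rec.subject_id
    assert prov[0].tolist()[:2] == [tensors[0].trial_id, tensors[0].second_index]
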