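"""Network stages: conv front-end, tokens, attention, encoder, head, audit."""

import numpy as np
import pytest

from eegemotion import nn
from eegemotion.network import (GridTransformerNet, ModelConfig, audit,
                                format_audit, load_checkpoint, reshape_tokens,
                                save_checkpoint, unreshape_tokens)


def small_cfg(**kw):
    base = dict(n_classes=8, L=2, dtype="float64")
    base.update(kw)
    return ModelConfig(**base)


def isa_reference(z, U_qkv, U_copy, U_sum, U_proj, D, eps=1e-6):
    """Literal per-index evaluation of the element-wise attention map."""
    n, d = z.shape
    P = np.zeros((n, 3 * d))
    for i in range(n):
        for j in range(3 * d):
            for k in range(d):
                P[i, j] += z[i, k] * U_qkv[k, j]
    Q, K, V = P[:, :d], P[:, d:2 * d], P[:, 2 * d:]
    A = np.zeros((n, d))
    for i in range(n):
        sk = max(np.sqrt(sum(K[i, k] ** 2 for k in range(d))), eps)
        sv = max(np.sqrt(sum(V[i, k] ** 2 for k in range(d))), eps)
        for k in range(d):
            A[i, k] = (K[i, k] / sk) * (V[i, k] / sv)
    M = np.zeros((n, d))
    for i in range(n):
        for j in range(n):
            for k in range(d):
                M[i, k] += U_copy[i, j] * A[j, k]
    S = M @ U_sum
    G = D * Q * S
    return G @ U_proj


# -- conv front-end --------------------------------------------------------

def test_conv_frontend_preserves_shape():
    net = GridTransformerNet(small_cfg())
    x = np.random.default_rng(0).standard_normal((3, 8, 9, 9))
    assert net.conv_frontend(x).shape == (3, 8, 9, 9)
    with pytest.raises(ValueError):
        net.conv_frontend(np.zeros((3, 5, 9, 9)))


def test_conv_zero_weights_give_zero_output():
    net = GridTransformerNet(small_cfg())
    for p in net.conv1.parameters() + net.conv2.parameters():
        p.value[...] = 0.0
    x = np.random.default_rng(1).standard_normal((2, 8, 9, 9))
    np.testing.assert_array_equal(net.conv_frontend(x), np.zeros((2, 8, 9, 9)))


def test_closed_form_parameter_counts():
    net = GridTransformerNet(small_cfg())
    assert sum(p.size for p in net.conv1.parameters()) == 32 * 8 * 3 * 3 + 32  # 2336
    conv_total = sum(p.size for p in net.conv1.parameters() + net.conv2.parameters())
    assert conv_total == 2336 + (8 * 32 * 3 * 3 + 8)  # 4648
    dense = nn.Dense(81, 8, np.random.default_rng(0))
    assert sum(p.size for p in dense.parameters()) == 81 * 8 + 8  # 656


# -- reshape / tokens ------------------------------------------------------

def test_reshape_tokens_row_major_and_invertible():
    x = np.random.default_rng(2).standard_normal((5, 8, 9, 9))
    z = reshape_tokens(x)
    assert z.shape == (5, 8, 81)
    np.testing.assert_array_equal(unreshape_tokens(z, 9, 9), x)
    const = np.full((1, 9, 9), 3.5)
    np.testing.assert_array_equal(reshape_tokens(const), np.full((1, 81), 3.5))


def test_token_augment_shape_and_seed_determinism():
    net1 = GridTransformerNet(small_cfg(seed=5))
    net2 = GridTransformerNet(small_cfg(seed=5))
    z0 = np.zeros((4, 8, 81))
    z = net1.token_augment(z0)
    assert z.shape == (4, 10, 81)
    np.testing.assert_array_equal(net1.tokens.tokens.value, net2.tokens.tokens.value)


def test_augmented_tokens_receive_gradient():
    net = GridTransformerNet(small_cfg())
    x = np.random.default_rng(3).standard_normal((4, 8, 9, 9))
    logits = net.forward(x)
    _, dl = nn.softmax_cross_entropy(logits, np.array([0, 1, 2, 3]))
    net.backward(dl)
    assert np.abs(net.tokens.tokens.grad).max() > 0


# -- attention -------------------------------------------------------------

@pytest.mark.parametrize("n,d", [(2, 4), (10, 81), (32, 4)])
def test_isa_matches_loop_reference(n, d):
    rng = np.random.default_rng(n * 100 + d)
    layer = nn.ISAAttention(n, d, rng, dtype=np.float64)
    for p in layer.parameters():
        p.value[...] = rng.standard_normal(p.value.shape)
    for _ in range(5):
        z = rng.standard_normal((1, n, d))
        ref = isa_reference(z[0], layer.U_qkv.value, layer.U_copy.value,
                            layer.U_sum.value, layer.U_proj.value, layer.D.value)
        assert np.abs(layer.forward(z)[0] - ref).max() < 1e-5


def test_isa_zero_scaling_matrix_annihilates():
    rng = np.random.default_rng(0)
    layer = nn.ISAAttention(6, 10, rng, dtype=np.float64)
    layer.D.value[...] = 0.0
    z = rng.standard_normal((3, 6, 10))
    np.testing.assert_array_equal(layer.forward(z), np.zeros((3, 6, 10)))


def test_attention_shape_checks():
    layer = nn.ISAAttention(6, 10, np.random.default_rng(0))
    with pytest.raises(ValueError):
        layer.forward(np.zeros((2, 5, 10)))


# -- encoder block ---------------------------------------------------------

@pytest.mark.parametrize("variant", ["isa", "original"])
def test_encoder_block_preserves_shape(variant):
    rng = np.random.default_rng(1)
    blk = nn.EncoderBlock(10, 81, 324, rng, variant=variant, dtype=np.float64)
    z = rng.standard_normal((2, 10, 81))
    assert blk.forward(z).shape == (2, 10, 81)


def test_encoder_zero_ffn_returns_normalised_intermediate():
    rng = np.random.default_rng(2)
    blk = nn.EncoderBlock(5, 12, 24, rng, dtype=np.float64)
    for p in blk.fc1.parameters() + blk.fc2.parameters():
        p.value[...] = 0.0
    z = rng.standard_normal((3, 5, 12))
    zp = blk.attn.forward(blk.ln1.forward(z)) + z
    expected = blk.ln2.forward(zp)
    np.testing.assert_array_equal(blk.forward(z), expected)


def test_fifteen_block_stack_composes():
    net = GridTransformerNet(ModelConfig(n_classes=8, L=15, dtype="float64"))
    z = np.random.default_rng(3).standard_normal((2, 10, 81))
    assert net.encode(z).shape == (2, 10, 81)


# -- gradients -------------------------------------------------------------

@pytest.mark.parametrize("pname", ["D", "U_sum", "U_copy"])
def test_isa_finite_difference_gradients(pname):
    rng = np.random.default_rng(7)
    layer = nn.ISAAttention(4, 6, rng, dtype=np.float64)
    z = rng.standard_normal((2, 4, 6))
    w = rng.standard_normal((2, 4, 6))  # fixed projection -> scalar loss

    def loss():
        return float((layer.forward(z) * w).sum())

    base = loss()
    for p in layer.parameters():
        p.zero_grad()
    layer.backward(w)
    p = getattr(layer, pname)
    eps = 1e-6
    for idx in [(0, 0), (1, 2), (3, 1) if p.value.shape[0] > 3 else (2, 1)]:
        old = p.value[idx]
        p.value[idx] = old + eps
        lp = loss()
        p.value[idx] = old - eps
        lm = loss()
        p.value[idx] = old
        fd = (lp - lm) / (2 * eps)
        assert abs(fd - p.grad[idx]) <= 1e-3 * max(1.0, abs(fd))


def test_end_to_end_gradient_check():
    cfg = ModelConfig(n_classes=3, C=2, H=3, W=3, L=2, conv_hidden=4,
                      ffn_hidden=7, dtype="float64")
    net = GridTransformerNet(cfg)
    rng = np.random.default_rng(0)
    x = rng.standard_normal((3, 2, 3, 3))
    y = np.array([0, 1, 2])

    def loss():
        l, _ = nn.softmax_cross_entropy(net.forward(x), y)
        return l

    for p in net.parameters():
        p.zero_grad()
    _, dl = nn.softmax_cross_entropy(net.forward(x), y)
    net.backward(dl)
    eps = 1e-6
    for p in net.parameters()[::4]:
        idx = tuple(rng.integers(0, s) for s in p.value.shape)
        old = p.value[idx]
        p.value[idx] = old + eps
        lp = loss()
        p.value[idx] = old - eps
        lm = loss()
        p.value[idx] = old
        fd = (lp - lm) / (2 * eps)
        assert abs(fd - p.grad[idx]) <= 1e-3 * max(1e-4, abs(fd)), p.name


# -- head / forward --------------------------------------------------------

@pytest.mark.parametrize("variant", ["isa", "original"])
@pytest.mark.parametrize("n_classes", [8, 5])
def test_end_to_end_probability_contract(variant, n_classes):
    net = GridTransformerNet(small_cfg(n_classes=n_classes,
                                       encoder_variant=variant))
    x = np.random.default_rng(4).standard_normal((6, 8, 9, 9))
    proba = net.predict_proba(x)
    assert proba.shape == (6, n_classes)
    assert (proba > 0).all()
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)


def test_forward_deterministic():
    net = GridTransformerNet(small_cfg())
    x = np.random.default_rng(5).standard_normal((2, 8, 9, 9))
    np.testing.assert_array_equal(net.forward(x), net.forward(x))


def test_de_only_config_four_planes():
    net = GridTransformerNet(small_cfg(C=4))
    x = np.random.default_rng(6).standard_normal((2, 4, 9, 9))
    assert net.predict_proba(x).shape == (2, 8)
    assert net.config.n_tokens == 6


# -- audit / checkpoints ---------------------------------------------------

def test_audit_variants_differ_only_in_attention():
    report = audit(ModelConfig(n_classes=8))
    isa = dict(report["isa"]["per_layer"])
    orig = dict(report["original"]["per_layer"])
    assert isa.keys() == orig.keys()
    for name in isa:
        if name.endswith(".attention"):
            assert isa[name] != orig[name]
        else:
            assert isa[name] == orig[name]
    # reductions must be consistent with the raw counts
    for key in ("params", "flops"):
        expect = 100.0 * (report["original"][key] - report["isa"][key]) \
            / report["original"][key]
        assert report[f"{key}_reduction_pct"] == pytest.approx(expect)
    text = format_audit(report)
    assert "Params" in text and "FLOPs" in text and "%" in text


def test_audit_flop_convention_switch():
    r1 = audit(ModelConfig(n_classes=8), flop_factor=1)
    r2 = audit(ModelConfig(n_classes=8), flop_factor=2)
    assert r2["isa"]["flops"] == 2 * r1["isa"]["flops"]


def test_checkpoint_roundtrip(tmp_path):
    net = GridTransformerNet(small_cfg(seed=9))
    x = np.random.default_rng(7).standard_normal((2, 8, 9, 9))
    ref = net.forward(x)
    save_checkpoint(tmp_path / "m.npz", net)
    back = load_checkpoint(tmp_path / "m.npz")
    np.testing.assert_array_equal(back.forward(x), ref)
    assert back.config == net.config
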