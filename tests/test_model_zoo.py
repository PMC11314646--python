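"""Forward operators vs hand/brute-force oracles; architecture contracts."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from attnaf import _layers as L
from attnaf.core import ValidationError
from attnaf.model_zoo import (ConvSpec, ModelConfig, activation, atac_forward, build_model,
                              compression_percent, conv1d_forward, count_learnables, se_forward)


def naive_conv(x, w, b):
    """Literal double-loop evaluation of the neural-convolution sum."""
    c_out, c_in, m = w.shape
    _, length = x.shape
    y = np.zeros((c_out, length))
    for o in range(c_out):
        for n in range(length):
            acc = b[o]
            for c in range(c_in):
                for k in range(m):
                    if 0 <= n - k < length:
                        acc += x[c, n - k] * w[o, c, m - 1 - k]
            y[o, n] = acc
    return y


# -- activation --------------------------------------------------------------

@pytest.mark.parametrize("kind,x,expected", [
    ("relu", -2.0, 0.0), ("relu", 3.0, 3.0),
    ("swish", 0.0, 0.0), ("sine", 0.0, 0.0),
    ("swish", 1.0, 0.731059), ("sine", np.pi / 2, 1.0),
])
def test_activation_values(kind, x, expected):
    assert activation(kind, np.array(x)) == pytest.approx(expected, abs=1e-6)


def test_unknown_activation_rejected():
    with pytest.raises(ValueError):
        activation("tanh", np.array(0.0))


# -- convolution -------------------------------------------------------------

def test_identity_kernel():
    x = np.array([[1.0, -2.0, 3.0, 0.5]])
    spec = ConvSpec(1, 1, filter_length=1)
    out = conv1d_forward(x, spec, np.ones((1, 1, 1)), np.zeros(1))
    assert np.array_equal(out, x)


def test_two_tap_kernel_hand_values():
    x = np.array([[1.0, 2.0, 3.0]])
    spec = ConvSpec(1, 1, filter_length=2)
    out = conv1d_forward(x, spec, np.ones((1, 1, 2)), np.zeros(1))
    assert np.allclose(out, [[1.0, 3.0, 5.0]])


def test_bias_only_with_relu():
    x = np.zeros((3, 8))
    spec = ConvSpec(3, 2, filter_length=5)
    out = activation("relu", conv1d_forward(x, spec, np.zeros((2, 3, 5)), np.full(2, 2.0)))
    assert np.all(out == 2.0)


def test_weight_shape_mismatch_rejected():
    with pytest.raises(ValidationError):
        conv1d_forward(np.zeros((1, 4)), ConvSpec(1, 1, 5), np.zeros((1, 1, 3)), np.zeros(1))


@settings(deadline=None, derandomize=True, max_examples=30)
@given(c_in=st.integers(1, 8), c_out=st.integers(1, 8), length=st.integers(1, 8),
       m=st.integers(1, 8), seed=st.integers(0, 10_000))
def test_conv_matches_naive_oracle(c_in, c_out, length, m, seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(c_in, length))
    w = rng.normal(size=(c_out, c_in, m))
    b = rng.normal(size=c_out)
    out = conv1d_forward(x, ConvSpec(c_in, c_out, m), w, b)
    assert np.max(np.abs(out - naive_conv(x, w, b))) < 1e-6


# -- squeeze-excitation ------------------------------------------------------

def test_se_zero_weights_halve_input(rng):
    x = rng.normal(size=(3, 7))
    out = se_forward(x, np.zeros((1, 3)), np.zeros(1), np.zeros((3, 1)), np.zeros(3))
    assert np.allclose(out, 0.5 * x)


def test_se_hand_example():
    x = np.array([[2.0, 2.0], [0.0, 4.0]])
    out = se_forward(x, np.array([[0.5, 0.5]]), np.zeros(1),
                     np.array([[1.0], [-1.0]]), np.zeros(2))
    s = np.array([1 / (1 + np.exp(-2.0)), 1 / (1 + np.exp(2.0))])
    assert s == pytest.approx([0.88080, 0.11920], abs=1e-5)
    assert np.allclose(out, x * s[:, None])


def test_se_gate_is_scalar_per_channel(rng):
    c = 5
    layer = L.SEAttention(c, 3, rng=rng)
    x = rng.normal(size=(2, c, 9))
    out = layer.forward(x)
    ratio = out / np.where(x == 0, np.nan, x)
    for n in range(2):
        for ch in range(c):
            vals = ratio[n, ch][np.isfinite(ratio[n, ch])]
            assert np.ptp(vals) < 1e-12
            assert 0 < vals[0] < 1


# -- attention-as-activation -------------------------------------------------

def _identity_bn(bn):
    bn.eps = 0.0
    return bn


def test_atac_zero_weights_halve_input(rng):
    module = L.ATACAttention(3, 3)
    _identity_bn(module.bn1), _identity_bn(module.bn2)
    x = rng.normal(size=(3, 6))
    assert np.allclose(atac_forward(x, module), 0.5 * x)


def test_atac_hand_example():
    module = L.ATACAttention(1, 1)
    module.conv1.w[...] = 1.0
    module.conv2.w[...] = 1.0
    _identity_bn(module.bn1), _identity_bn(module.bn2)
    assert atac_forward(np.array([[0.0]]), module) == pytest.approx(0.0)
    out = atac_forward(np.array([[2.0]]), module)
    assert out[0, 0] == pytest.approx(1.76159, abs=1e-5)


def test_atac_gate_bounds_and_locality(rng):
    module = L.ATACAttention(4, 3, rng=rng)
    x = rng.normal(size=(2, 4, 10))
    out = atac_forward(x, module)
    assert out.shape == x.shape
    assert np.all(np.abs(out) <= np.abs(x) + 1e-15)
    assert np.all((module.last_gate > 0) & (module.last_gate < 1))


# -- build_model -------------------------------------------------------------

def test_softmax_head_is_probability_simplex(rng):
    for variant, attention in [("baseline", "none"), ("compressed", "se"), ("compressed", "atac")]:
        model = build_model(ModelConfig(variant=variant, attention=attention), seed=0)
        p = model.predict_proba(rng.normal(0.8, 0.2, size=(4, 30)))
        assert p.shape == (4, 2)
        assert np.all(p > 0)
        assert np.allclose(p.sum(axis=1), 1.0)


def test_compressed_se_shape_trace(rng):
    model = build_model(ModelConfig(variant="compressed", attention="se"), seed=0)
    x = rng.normal(0.8, 0.2, size=(1, 1, 30))
    expected = {1: (1, 20, 30), 2: (1, 10, 30), 3: (1, 5, 15)}
    for block, shape in expected.items():
        _, fmap = model.forward_capture(x, model.conv_block_ends[block - 1])
        assert fmap.shape == shape


def test_same_seed_same_parameters():
    cfg = ModelConfig(variant="compressed", attention="atac", activation="sine")
    a = build_model(cfg, seed=42).get_flat_params()
    b = build_model(cfg, seed=42).get_flat_params()
    assert np.array_equal(a, b)
    c = build_model(cfg, seed=43).get_flat_params()
    assert not np.array_equal(a, c)


def test_invalid_config_rejected():
    with pytest.raises(ValidationError):
        ModelConfig(variant="tiny")
    with pytest.raises(ValidationError):
        ModelConfig(attention="se", attention_layer_index=9)


# -- parameter counting ------------------------------------------------------

def test_dense_toy_count():
    assert L.Dense(2, 2).n_params() == 6


PER_LAYER_BASELINE = [360, 120, 12040, 80, 4020, 40, 1010, 20, 302]


def test_baseline_budget_matches_per_layer_sum():
    exact, truncated = count_learnables(ModelConfig(variant="baseline"))
    assert exact == sum(PER_LAYER_BASELINE) == 17992
    assert truncated == 17900


@pytest.mark.parametrize("attention,extra,exact,truncated", [
    ("none", 0, 1607, 1600),
    ("se", 73, 1680, 1600),
    ("atac", 99, 1706, 1700),
])
def test_compressed_budgets(attention, extra, exact, truncated):
    got_exact, got_trunc = count_learnables(ModelConfig(variant="compressed", attention=attention))
    assert got_exact == 1607 + extra == exact
    assert got_trunc == truncated


@pytest.mark.parametrize("variant,attention", [
    ("baseline", "none"), ("compressed", "none"), ("compressed", "se"), ("compressed", "atac"),
])
def test_closed_form_count_matches_built_arrays(variant, attention):
    cfg = ModelConfig(variant=variant, attention=attention)
    exact, _ = count_learnables(cfg)
    assert build_model(cfg, seed=0).n_params() == exact


@pytest.mark.parametrize("attention", ["none", "se", "atac"])
def test_compression_below_ten_percent(attention):
    cfg = ModelConfig(variant="compressed", attention=attention)
    exact_c, _ = count_learnables(cfg)
    exact_b, _ = count_learnables(ModelConfig(variant="baseline"))
    assert exact_c / exact_b < 0.10
    assert round(compression_percent(cfg)) == 91


# -- full-model gradient check ----------------------------------------------

@pytest.mark.parametrize("attention,activation_kind", [
    ("none", "relu"), ("se", "swish"), ("atac", "sine"),
])
def test_gradients_match_finite_differences(attention, activation_kind, rng):
    from attnaf.train import cross_entropy, cross_entropy_grad

    cfg = ModelConfig(variant="compressed", attention=attention, activation=activation_kind,
                      conv_channels=(4, 3, 2), input_length=8, dropout=0.0)
    model = build_model(cfg, seed=1)
    X = rng.normal(0.8, 0.1, size=(5, 1, 8))
    y = rng.integers(0, 2, size=5)

    def loss():
        return cross_entropy(model.forward(X, training=False), y)

    logits = model.forward(X, training=False)
    model.backward(cross_entropy_grad(logits, y))
    eps = 1e-6
    for layer in model.layers:
        params, grads = layer.params(), layer.grads()
        for name, arr in params.items():
            flat = arr.ravel()
            for idx in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                old = flat[idx]
                flat[idx] = old + eps
                lp = loss()
                flat[idx] = old - eps
                lm = loss()
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                ana = grads[name].ravel()[idx]
                assert num == pytest.approx(ana, abs=1e-4), f"{name}[{idx}]"
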