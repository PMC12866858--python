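"""Architecture contracts: shapes, parameter counts, determinism, gradients."""

import numpy as np
import pytest

from msifuse.losses import EdgeKernel, edge_loss_gradient, edge_perceptual_loss, mse_loss
from msifuse.network import (
    CNNBaseline,
    Conv2d,
    NetworkSpec,
    ResidualBlock,
    build_cnn_baseline,
    build_network,
    forward,
)


def conv_params(c_in, c_out, k):
    """Closed-form parameter count of one convolution (weights + biases)."""
    return k * k * c_in * c_out + c_out


def lcrn_param_count():
    """init 3->64, blocks (64->32, 32->32, skip 64->32), (32->1, 1->1, skip 32->1)."""
    return (
        conv_params(3, 64, 3)
        + conv_params(64, 32, 3) + conv_params(32, 32, 3) + conv_params(64, 32, 1)
        + conv_params(32, 1, 3) + conv_params(1, 1, 3) + conv_params(32, 1, 1)
    )


def cnn_param_count():
    return conv_params(3, 64, 3) + conv_params(64, 32, 3) + conv_params(32, 1, 3)


class TestNetworkSpec:
    def test_defaults_match_channel_plan(self):
        spec = NetworkSpec()
        assert spec.in_channels == 3
        assert spec.block_channels == (64, 32, 1)
        assert spec.kernel_size == 3 and spec.skip_kernel_size == 1

    @pytest.mark.parametrize("kwargs", [
        {"in_channels": 1},
        {"block_channels": (64, 32, 2)},
        {"kernel_size": 4},
        {"activation": "tanh"},
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            NetworkSpec(**kwargs)


class TestResidualFusionNet:
    @pytest.mark.parametrize("hw", [(8, 8), (37, 23), (64, 37)])
    def test_same_padding_shape_contract(self, rng, hw):
        model = build_network(seed=0)
        x = rng.uniform(0, 1, (3, *hw))
        assert model.forward(x).shape == hw

    def test_parameter_count_closed_form(self):
        assert build_network(seed=0).n_params == lcrn_param_count()

    def test_seeded_determinism(self, rng):
        x = rng.uniform(0, 1, (3, 12, 12))
        a, b = build_network(seed=5), build_network(seed=5)
        for pa, pb in zip(a.parameters(), b.parameters(), strict=True):
            np.testing.assert_array_equal(pa, pb)
        np.testing.assert_array_equal(a.forward(x), b.forward(x))
        c = build_network(seed=6)
        assert not np.array_equal(a.forward(x), c.forward(x))

    def test_zeroed_model_outputs_zero(self, rng):
        model = build_network(seed=0)
        model.set_state([np.zeros_like(p) for p in model.parameters()])
        out = model.forward(rng.uniform(0, 1, (3, 9, 9)))
        np.testing.assert_array_equal(out, 0.0)

    def test_state_roundtrip(self, rng):
        model = build_network(seed=1)
        state = model.get_state()
        other = build_network(seed=2)
        other.set_state(state)
        x = rng.uniform(0, 1, (3, 10, 10))
        np.testing.assert_array_equal(model.forward(x), other.forward(x))


class TestCNNBaseline:
    def test_shape_contract(self, rng):
        model = build_cnn_baseline(seed=0)
        assert model.forward(rng.uniform(0, 1, (3, 15, 9))).shape == (15, 9)

    def test_parameter_count_closed_form(self):
        assert build_cnn_baseline(seed=0).n_params == cnn_param_count()
        # the baseline drops both residual second-convs and both 1x1 skips
        extra = (conv_params(32, 32, 3) + conv_params(1, 1, 3)
                 + conv_params(64, 32, 1) + conv_params(32, 1, 1))
        assert build_network(seed=0).n_params == cnn_param_count() + extra

    def test_seeded_determinism(self, rng):
        x = rng.uniform(0, 1, (3, 8, 8))
        np.testing.assert_array_equal(
            build_cnn_baseline(seed=3).forward(x), build_cnn_baseline(seed=3).forward(x)
        )


class TestConv2d:
    def test_hand_set_1x1_weights(self):
        # y = 2 R - 1 G + 0.5 B + 0.25 per pixel, verified by hand
        conv = Conv2d(3, 1, 1, np.random.default_rng(0))
        conv.W[...] = np.array([2.0, -1.0, 0.5]).reshape(1, 3, 1, 1)
        conv.b[...] = 0.25
        x = np.arange(12, dtype=float).reshape(3, 2, 2)
        expected = 2 * x[0] - 1 * x[1] + 0.5 * x[2] + 0.25
        np.testing.assert_allclose(conv.forward(x)[0], expected, atol=1e-12)

    def test_replicate_padding_constant_input(self):
        # a constant field stays constant under same-padded convolution
        conv = Conv2d(1, 1, 3, np.random.default_rng(4))
        x = np.full((1, 6, 6), 2.0)
        y = conv.forward(x)
        np.testing.assert_allclose(y, y[0, 0, 0], atol=1e-12)


class TestResidualBlock:
    def test_identity_skip_passes_input_through(self, rng):
        block = ResidualBlock(2, 2, 3, 1, np.random.default_rng(0), final_relu=False)
        for conv in (block.conv1, block.conv2):
            conv.W[...] = 0.0
            conv.b[...] = 0.0
        block.skip.W[...] = np.eye(2).reshape(2, 2, 1, 1)
        block.skip.b[...] = 0.0
        x = rng.normal(size=(2, 7, 7))
        np.testing.assert_allclose(block.forward(x), x, atol=1e-12)

    def test_identity_skip_with_final_relu(self, rng):
        block = ResidualBlock(2, 2, 3, 1, np.random.default_rng(0), final_relu=True)
        for conv in (block.conv1, block.conv2):
            conv.W[...] = 0.0
            conv.b[...] = 0.0
        block.skip.W[...] = np.eye(2).reshape(2, 2, 1, 1)
        block.skip.b[...] = 0.0
        x = rng.normal(size=(2, 5, 5))
        np.testing.assert_allclose(block.forward(x), np.maximum(x, 0.0), atol=1e-12)


@pytest.mark.parametrize("builder", ["lcrn", "cnn"])
def test_backward_matches_finite_differences(rng, builder):
    """The hand-written backward pass agrees with central differences."""
    if builder == "lcrn":
        model = build_network(NetworkSpec(block_channels=(5, 4, 1)), seed=2)
    else:
        model = build_cnn_baseline(seed=2)
    x = rng.uniform(0, 1, (3, 7, 6))
    target = rng.uniform(0, 1, (7, 6))
    lum = rng.uniform(0, 1, (7, 6))
    k = EdgeKernel()
    w1, w2 = 1.3, 0.7

    def loss():
        y = model.forward(x)
        return w1 * mse_loss(y, target) + w2 * edge_perceptual_loss(y, lum, k)

    y = model.forward(x)
    dldy = w1 * (2.0 / target.size) * (y - target) + w2 * edge_loss_gradient(y, lum, k)
    model.backward(dldy)
    grads = [g.copy() for g in model.gradients()]
    eps = 1e-6
    for p, g in zip(model.parameters(), grads, strict=True):
        flat, gflat = p.ravel(), g.ravel()
        for i in rng.choice(flat.size, size=min(8, flat.size), replace=False):
            orig = flat[i]
            flat[i] = orig + eps
            lp = loss()
            flat[i] = orig - eps
            lm = loss()
            flat[i] = orig
            num = (lp - lm) / (2 * eps)
            assert gflat[i] == pytest.approx(num, rel=1e-4, abs=1e-8)


def test_forward_wrapper_contract(small_pair, small_phantom):
    model = build_network(seed=0)
    fused = forward(model, small_pair, config_hash="abc", epoch=3)
    assert fused.values.shape == small_pair.microscopy.spatial_shape
    assert np.isfinite(fused.values).all()
    assert fused.config_hash == "abc" and fused.epoch_of_best == 3
    clipped = fused.clipped()
    assert clipped.min() >= 0.0 and clipped.max() <= 1.0
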