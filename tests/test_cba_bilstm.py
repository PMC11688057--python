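import math

import numpy as np
import pytest

from gaitfreeze import autodiff as ad
from gaitfreeze.autodiff import Tensor
from gaitfreeze.cba_bilstm import (
    CbaBilstmConfig,
    _apply_attention_t,
    apply_attention,
    bilstm_sequence,
    build_model,
    channel_attention,
    forward,
    fuse_attention,
    global_average_pool,
    load_model,
    lstm_step,
    make_attention_params,
    make_lstm_params,
    save_model,
    spatial_attention,
)
from gaitfreeze.signal_io import ValidationError

rng = np.random.default_rng(7)


# ---------------------------------------------------------------------------
# Independent oracles (explicit scalar loops)
# ---------------------------------------------------------------------------

def lstm_step_oracle(x, h, c, p):
    d, hh = len(x), len(h)
    xh = list(x) + list(h)

    def affine(w, b, j):
        return b.value[j] + sum(xh[i] * w.value[i, j] for i in range(d + hh))

    sig = lambda v: 1.0 / (1.0 + math.exp(-v))  # noqa: E731
    h_t, c_t = [], []
    for j in range(hh):
        i_g = sig(affine(p.w_i, p.b_i, j))
        o_g = sig(affine(p.w_o, p.b_o, j))
        f_g = sig(affine(p.w_f, p.b_f, j))
        cand = math.tanh(affine(p.w_c, p.b_c, j))
        cj = f_g * c[j] + i_g * cand
        c_t.append(cj)
        h_t.append(o_g * math.tanh(cj))
    return np.array(h_t), np.array(c_t)


def _zero_lstm_params(d, h):
    p = make_lstm_params(d, h, np.random.default_rng(0))
    for t in p.tensors():
        t.value[:] = 0.0
    return p


class TestLstmStep:
    def test_all_zero_weights_and_state(self):
        p = _zero_lstm_params(3, 4)
        h, c = lstm_step(np.ones(3), np.zeros(4), np.zeros(4), p)
        np.testing.assert_array_equal(c, np.zeros(4))
        np.testing.assert_array_equal(h, np.zeros(4))

    def test_zero_weights_halve_cell_state(self):
        p = _zero_lstm_params(3, 4)
        v = np.array([1.0, -2.0, 0.5, 4.0])
        h, c = lstm_step(np.zeros(3), np.zeros(4), v, p)
        np.testing.assert_allclose(c, 0.5 * v)  # forget gate at sigma(0) = 0.5
        np.testing.assert_allclose(h, 0.5 * np.tanh(0.5 * v))

    def test_matches_scalar_oracle_on_random_instance(self):
        p = make_lstm_params(3, 5, np.random.default_rng(1))
        x, h0, c0 = rng.normal(size=3), rng.normal(size=5), rng.normal(size=5)
        h, c = lstm_step(x, h0, c0, p)
        h_ref, c_ref = lstm_step_oracle(x, h0, c0, p)
        np.testing.assert_allclose(h, h_ref, atol=1e-10)
        np.testing.assert_allclose(c, c_ref, atol=1e-10)

    def test_shape_mismatch_rejected(self):
        p = make_lstm_params(3, 4, np.random.default_rng(0))
        with pytest.raises(ValidationError):
            lstm_step(np.ones(2), np.zeros(4), np.zeros(4), p)


class TestBilstmSequence:
    def test_length_one_is_two_single_steps(self):
        fwd = make_lstm_params(2, 3, np.random.default_rng(2))
        bwd = make_lstm_params(2, 3, np.random.default_rng(3))
        x = rng.normal(size=(1, 2))
        out = bilstm_sequence(x, fwd, bwd)
        hf, _ = lstm_step(x[0], np.zeros(3), np.zeros(3), fwd)
        hb, _ = lstm_step(x[0], np.zeros(3), np.zeros(3), bwd)
        np.testing.assert_allclose(out[0], np.concatenate([hf, hb]), atol=1e-12)

    def test_time_reversal_symmetry(self):
        fwd = make_lstm_params(2, 3, np.random.default_rng(4))
        bwd = make_lstm_params(2, 3, np.random.default_rng(5))
        x = rng.normal(size=(5, 2))
        out = bilstm_sequence(x, fwd, bwd)
        rev = bilstm_sequence(x[::-1], bwd, fwd)
        h = 3
        np.testing.assert_allclose(out[:, :h], rev[::-1, h:], atol=1e-12)
        np.testing.assert_allclose(out[:, h:], rev[::-1, :h], atol=1e-12)

    def test_matches_loop_oracle(self):
        fwd = make_lstm_params(2, 3, np.random.default_rng(6))
        bwd = make_lstm_params(2, 3, np.random.default_rng(7))
        x = rng.normal(size=(3, 2))
        out = bilstm_sequence(x, fwd, bwd)
        h = np.zeros(3)
        c = np.zeros(3)
        hf = []
        for t in range(3):
            h, c = lstm_step_oracle(x[t], h, c, fwd)
            hf.append(h)
        h, c = np.zeros(3), np.zeros(3)
        hb = [None] * 3
        for t in (2, 1, 0):
            h, c = lstm_step_oracle(x[t], h, c, bwd)
            hb[t] = h
        ref = np.stack([np.concatenate([hf[t], hb[t]]) for t in range(3)])
        np.testing.assert_allclose(out, ref, atol=1e-10)

    def test_empty_sequence_rejected(self):
        p = make_lstm_params(2, 3, np.random.default_rng(0))
        with pytest.raises(ValidationError):
            bilstm_sequence(np.empty((0, 2)), p, p)


def _identity_bn(bn):
    bn.eps = 0.0  # exact identity at running stats (0, 1)
    return bn


class TestChannelAttention:
    def test_gap_of_constant_map_is_constant(self):
        f = np.stack([np.full((2, 2), 3.5), np.full((2, 2), -1.25)])
        np.testing.assert_array_equal(global_average_pool(f), [3.5, -1.25])

    def test_zero_weights_identity_bn_gives_zero_map(self):
        p = make_attention_params(4, reduction_ratio=2, rng=np.random.default_rng(0))
        p.w1.value[:] = 0.0
        p.w2.value[:] = 0.0
        _identity_bn(p.bn_channel)
        mc = channel_attention(rng.normal(size=(4, 3, 2)), p)
        np.testing.assert_array_equal(mc, np.zeros((4, 1, 1)))

    def test_hand_traced_two_channel_case(self):
        p = make_attention_params(2, reduction_ratio=2, rng=np.random.default_rng(0))
        p.w1.value[:] = np.array([[1.0], [2.0]])  # (C=2, C/r=1)
        p.w2.value[:] = np.array([[0.5, -1.0]])  # (1, 2)
        _identity_bn(p.bn_channel)
        f = np.array([[[1.0, 2.0], [3.0, 4.0]], [[0.0, 1.0], [1.0, 2.0]]])
        # GAP: [2.5, 1.0]; z = relu(2.5*1 + 1.0*2) = 4.5; s = [2.25, -4.5]
        mc = channel_attention(f, p)
        np.testing.assert_allclose(mc.ravel(), [2.25, -4.5], atol=1e-12)

    def test_reduction_larger_than_channels_needs_padding(self):
        with pytest.raises(ValidationError):
            make_attention_params(4, reduction_ratio=16, allow_padding=False)
        p = make_attention_params(4, reduction_ratio=16, allow_padding=True)
        assert p.w1.shape == (4, 1)


class TestSpatialAttention:
    def test_zero_kernels_identity_bn_gives_zero_map(self):
        p = make_attention_params(3, reduction_ratio=3, dilation=1,
                                  rng=np.random.default_rng(1))
        for t in (p.conv_reduce, p.conv_dil1, p.conv_dil2, p.conv_collapse):
            t.value[:] = 0.0
        _identity_bn(p.bn_spatial)
        ms = spatial_attention(rng.normal(size=(3, 4, 4)), p)
        np.testing.assert_array_equal(ms, np.zeros((1, 4, 4)))

    def test_output_shape_contract(self):
        p = make_attention_params(6, reduction_ratio=2, dilation=2,
                                  rng=np.random.default_rng(2))
        for n, m in ((3, 3), (5, 1), (1, 4)):
            ms = spatial_attention(rng.normal(size=(6, n, m)), p)
            assert ms.shape == (1, n, m)

    def test_one_hot_dilated_kernel_shifts_input(self):
        # C=1, r=1: 1x1 convs set to identity, first 3x3 kernel one-hot at
        # (0, 0), second at center -> output equals input shifted by (+1, +1)
        p = make_attention_params(1, reduction_ratio=1, dilation=1,
                                  rng=np.random.default_rng(3))
        p.conv_reduce.value[:] = 1.0
        p.conv_collapse.value[:] = 1.0
        p.conv_dil1.value[:] = 0.0
        p.conv_dil1.value[0, 0, 0, 0] = 1.0
        p.conv_dil2.value[:] = 0.0
        p.conv_dil2.value[1, 1, 0, 0] = 1.0
        _identity_bn(p.bn_spatial)
        x = np.abs(rng.normal(size=(1, 3, 3)))  # nonnegative: ReLU transparent
        ms = spatial_attention(x, p)
        expected = np.zeros((3, 3))
        expected[1:, 1:] = x[0, :2, :2]
        np.testing.assert_allclose(ms[0], expected, atol=1e-12)


class TestFuseAndApply:
    def test_zero_maps_fuse_to_half(self):
        fused = fuse_attention(np.zeros((3, 1, 1)), np.zeros((1, 2, 2)))
        np.testing.assert_array_equal(fused, np.full((3, 2, 2), 0.5))

    def test_monotone_in_spatial_map(self):
        mc = rng.normal(size=(3, 1, 1))
        ms = rng.normal(size=(1, 2, 2))
        base = fuse_attention(mc, ms)
        bumped = ms.copy()
        bumped[0, 1, 0] += 0.3
        out = fuse_attention(mc, bumped)
        assert (out[:, 1, 0] > base[:, 1, 0]).all()
        mask = np.ones((1, 2, 2), bool)
        mask[0, 1, 0] = False
        np.testing.assert_array_equal(out[:, mask[0]], base[:, mask[0]])

    def test_fuse_matches_elementwise_oracle(self):
        mc = rng.normal(size=(2, 1, 1))
        ms = rng.normal(size=(1, 2, 2))
        fused = fuse_attention(mc, ms)
        for c in range(2):
            for i in range(2):
                for j in range(2):
                    z = mc[c, 0, 0] + ms[0, i, j]
                    assert fused[c, i, j] == pytest.approx(1 / (1 + math.exp(-z)))

    def test_apply_identity_and_doubling(self):
        f = rng.normal(size=(2, 3, 2))
        np.testing.assert_array_equal(apply_attention(f, np.zeros_like(f)), f)
        np.testing.assert_allclose(apply_attention(f, np.ones_like(f)), 2 * f)

    def test_apply_matches_loop_oracle(self):
        f = rng.normal(size=(2, 2, 2))
        m = rng.uniform(0, 1, size=(2, 2, 2))
        out = apply_attention(f, m)
        for idx in np.ndindex(2, 2, 2):
            assert out[idx] == pytest.approx(f[idx] * (1 + m[idx]))

    def test_residual_keeps_gradient_alive_when_map_saturates(self):
        """With F' = F + F*M, dLoss/dF is nonzero even at M ~ 0."""
        f = Tensor(rng.normal(size=(1, 2, 2, 3)), requires_grad=True)
        m = Tensor(np.zeros((1, 2, 2, 3)))  # fully saturated-off attention
        out = _apply_attention_t(f, m).sum()
        out.backward()
        assert np.abs(f.grad).min() > 0


class TestBuildModelForward:
    def test_default_config_parameter_budget(self):
        model = build_model(CbaBilstmConfig(n_channels=9, sequence_length=128))
        assert model.parameter_count <= 3_000_000

    def test_head_width_matches_classes(self):
        model = build_model(CbaBilstmConfig(n_channels=9, sequence_length=128, n_classes=2))
        assert model.head_w.shape[1] == 2

    def test_halving_units_reduces_parameters(self):
        big = build_model(CbaBilstmConfig(bilstm_units=64))
        small = build_model(CbaBilstmConfig(bilstm_units=32))
        assert small.parameter_count < big.parameter_count

    def test_sequence_too_short_for_pooling_rejected(self):
        with pytest.raises(ValidationError):
            CbaBilstmConfig(sequence_length=4)

    def test_forward_rows_are_probabilities(self):
        model = build_model(CbaBilstmConfig(n_channels=2, sequence_length=16, seed=1))
        probs = forward(model, rng.normal(size=(5, 16, 2)))
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), np.ones(5), atol=1e-6)

    def test_duplicate_inputs_identical_outputs(self):
        model = build_model(CbaBilstmConfig(n_channels=2, sequence_length=16, seed=1))
        x = rng.normal(size=(16, 2))
        batch = np.stack([x, x, x])
        probs = forward(model, batch)
        np.testing.assert_array_equal(probs[0], probs[1])
        np.testing.assert_array_equal(probs[0], probs[2])

    def test_inference_is_batch_independent(self):
        model = build_model(CbaBilstmConfig(n_channels=2, sequence_length=16, seed=2))
        batch = rng.normal(size=(6, 16, 2))
        alone = forward(model, batch[:1])
        together = forward(model, batch)
        np.testing.assert_allclose(alone[0], together[0], atol=1e-12)

    def test_checkpoint_round_trip(self, tmp_path):
        model = build_model(CbaBilstmConfig(n_channels=2, sequence_length=16, seed=3))
        model.input_norm = (np.array([-1.0, -2.0]), np.array([1.0, 2.0]))
        x = rng.normal(size=(4, 16, 2))
        before = forward(model, x)
        path = tmp_path / "model.h5"
        save_model(model, path)
        restored = load_model(path)
        np.testing.assert_array_equal(forward(restored, x), before)
        assert restored.config == model.config
        np.testing.assert_array_equal(restored.input_norm[0], model.input_norm[0])

    def test_input_norm_applied_at_inference(self):
        model = build_model(CbaBilstmConfig(n_channels=2, sequence_length=16, seed=4))
        x = rng.normal(size=(3, 16, 2))
        lo, hi = x.min(axis=(0, 1)), x.max(axis=(0, 1))
        span = hi - lo
        raw_scaled = forward(model, (x - lo) / span)
        model.input_norm = (lo, hi)
        np.testing.assert_allclose(forward(model, x), raw_scaled, atol=1e-12)
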