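"""Layer operations vs sliding-window and composition oracles."""

import numpy as np
import pytest

from deepcac.attention_core import MHAParams, multi_head_attention
from deepcac.cac_layers import (
    AAConvConfig,
    CACLayerConfig,
    ChannelAccountingError,
    ConvParams,
    PoolConfig,
    attention_augmented_conv,
    cac_layer_forward,
    conv1d_same,
    default_attention_width,
    max_pool,
)


# ---------------------------------------------------------------- oracles
def conv1d_same_oracle(x, kernels, bias):
    """Direct sliding-window triple loop with explicit zero padding."""
    L, d_in = x.shape
    k, _, d_out = kernels.shape
    pad = k // 2
    out = np.zeros((L, d_out))
    for t in range(L):
        for j in range(k):
            src = t + j - pad
            if 0 <= src < L:
                for c in range(d_out):
                    out[t, c] += np.dot(x[src], kernels[j, :, c])
    return out + bias


def random_branch(rng, d_in=4, d_out=8, d_v=4, n_heads=2, kernel_size=3):
    cfg = AAConvConfig(d_out=d_out, d_v=d_v, kernel_size=kernel_size,
                       n_heads=n_heads, input_channels=d_in)
    conv = ConvParams(kernels=rng.normal(size=(kernel_size, d_in, cfg.d_conv)),
                      bias=rng.normal(size=cfg.d_conv))
    mha = MHAParams.random(d_in, n_heads, cfg.d_head, rng=rng, scale=0.5)
    return cfg, conv, mha


# ---------------------------------------------------------------- conv
class TestConv1dSame:
    def test_1x1_identity_kernel(self, rng):
        x = rng.normal(size=(10, 4))
        kernels = np.eye(4)[None]  # (1, 4, 4)
        np.testing.assert_allclose(conv1d_same(x, kernels, np.zeros(4)), x)

    def test_zero_input_broadcasts_bias(self, rng):
        kernels = rng.normal(size=(3, 4, 5))
        bias = rng.normal(size=5)
        out = conv1d_same(np.zeros((8, 4)), kernels, bias)
        np.testing.assert_allclose(out, np.tile(bias, (8, 1)))

    def test_matches_loop_oracle(self, rng):
        x = rng.normal(size=(10, 4))
        kernels = rng.normal(size=(3, 4, 6))
        bias = rng.normal(size=6)
        np.testing.assert_allclose(conv1d_same(x, kernels, bias),
                                   conv1d_same_oracle(x, kernels, bias), atol=1e-6)

    @pytest.mark.parametrize("k", [1, 5, 9])
    def test_oracle_agreement_across_kernel_sizes(self, rng, k):
        x = rng.normal(size=(12, 3))
        kernels = rng.normal(size=(k, 3, 2))
        bias = rng.normal(size=2)
        np.testing.assert_allclose(conv1d_same(x, kernels, bias),
                                   conv1d_same_oracle(x, kernels, bias), atol=1e-10)

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ValueError, match="odd"):
            conv1d_same(rng.normal(size=(5, 4)), rng.normal(size=(2, 4, 3)),
                        np.zeros(3))

    def test_length_preserved(self, rng):
        out = conv1d_same(rng.normal(size=(17, 4)), rng.normal(size=(5, 4, 3)),
                          np.zeros(3))
        assert out.shape == (17, 3)


# ---------------------------------------------------------------- configs
class TestConfigs:
    def test_channel_arithmetic_64_16(self):
        cfg = AAConvConfig(d_out=64, d_v=16, kernel_size=7, n_heads=8,
                           input_channels=4)
        assert cfg.d_conv == 48

    def test_dv_not_below_one_conv_channel(self):
        with pytest.raises(ChannelAccountingError):
            AAConvConfig(d_out=4, d_v=4, kernel_size=3, n_heads=2, input_channels=4)

    def test_dv_head_divisibility(self):
        with pytest.raises(ChannelAccountingError, match="divisible"):
            AAConvConfig(d_out=16, d_v=6, kernel_size=3, n_heads=4, input_channels=4)

    def test_layer_divided_equally(self):
        cfg = CACLayerConfig.default(D=192, i=3, input_channels=4, n_heads=8)
        assert [b.d_out for b in cfg.branches] == [64, 64, 64]
        assert sum(b.d_out for b in cfg.branches) == 192

    def test_layer_indivisible_rejected(self):
        with pytest.raises(ChannelAccountingError):
            CACLayerConfig.default(D=100, i=3, input_channels=4)

    def test_unequal_branch_rejected(self):
        a = AAConvConfig(d_out=8, d_v=2, kernel_size=3, n_heads=2, input_channels=4)
        b = AAConvConfig(d_out=16, d_v=4, kernel_size=3, n_heads=2, input_channels=4)
        with pytest.raises(ChannelAccountingError, match="divided equally"):
            CACLayerConfig(D=24, branches=(a, b, a))

    def test_default_attention_width(self):
        assert default_attention_width(64, 8) == 16
        assert default_attention_width(16, 4) == 4
        # floor to multiple of heads, but never below one per head
        assert default_attention_width(10, 4) == 4

    def test_branch_kernel_sizes_differ(self):
        cfg = CACLayerConfig.default(D=48, i=3, input_channels=4, n_heads=4)
        assert len({b.kernel_size for b in cfg.branches}) == 3


# ---------------------------------------------------------------- aaconv
class TestAttentionAugmentedConv:
    def test_zero_conv_exposes_attention_channels(self, rng):
        cfg, conv, mha = random_branch(rng)
        conv0 = ConvParams(kernels=np.zeros_like(conv.kernels),
                           bias=np.zeros_like(conv.bias))
        x = rng.normal(size=(9, 4))
        out = attention_augmented_conv(x, cfg, conv0, mha)
        np.testing.assert_allclose(out[:, :cfg.d_conv], 0.0)
        np.testing.assert_allclose(out[:, cfg.d_conv:], multi_head_attention(x, mha))

    def test_matches_composition_oracle(self, rng):
        cfg, conv, mha = random_branch(rng, d_out=10, d_v=4)
        x = rng.normal(size=(7, 4))
        out = attention_augmented_conv(x, cfg, conv, mha)
        expected = np.concatenate(
            [conv1d_same_oracle(x, conv.kernels, conv.bias),
             multi_head_attention(x, mha)], axis=1)
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_channel_accounting_violation_reports_numbers(self, rng):
        cfg, conv, mha = random_branch(rng)
        bad_conv = ConvParams(kernels=rng.normal(size=(3, 4, cfg.d_conv + 1)),
                              bias=rng.normal(size=cfg.d_conv + 1))
        with pytest.raises(ChannelAccountingError, match="d_conv"):
            attention_augmented_conv(rng.normal(size=(5, 4)), cfg, bad_conv, mha)

    def test_length_preserved(self, rng):
        cfg, conv, mha = random_branch(rng)
        out = attention_augmented_conv(rng.normal(size=(13, 4)), cfg, conv, mha)
        assert out.shape == (13, cfg.d_out)


# ---------------------------------------------------------------- cac layer
class TestCacLayerForward:
    def _layer(self, rng, D=24, i=3, d_in=4, n_heads=2):
        cfg = CACLayerConfig.default(D=D, i=i, input_channels=d_in,
                                     n_heads=n_heads, kernel_sizes=(3, 5, 7))
        params = []
        for br in cfg.branches:
            conv = ConvParams(
                kernels=rng.normal(size=(br.kernel_size, d_in, br.d_conv)),
                bias=rng.normal(size=br.d_conv))
            mha = MHAParams.random(d_in, br.n_heads, br.d_head, rng=rng, scale=0.5)
            params.append((conv, mha))
        return cfg, params

    def test_192_over_3_gives_64_channel_branches(self):
        cfg = CACLayerConfig.default(D=192, i=3, input_channels=4, n_heads=8)
        assert all(b.d_out == 64 for b in cfg.branches)

    def test_single_branch_reduces_to_activated_aaconv(self, rng):
        cfg = CACLayerConfig.default(D=8, i=1, input_channels=4, n_heads=2,
                                     kernel_sizes=(3,))
        br = cfg.branches[0]
        conv = ConvParams(kernels=rng.normal(size=(3, 4, br.d_conv)),
                          bias=rng.normal(size=br.d_conv))
        mha = MHAParams.random(4, br.n_heads, br.d_head, rng=rng, scale=0.5)
        x = rng.normal(size=(6, 4))
        out = cac_layer_forward(x, cfg, [(conv, mha)])
        expected = np.maximum(attention_augmented_conv(x, br, conv, mha), 0.0)
        np.testing.assert_allclose(out, expected)

    def test_matches_branchwise_oracle(self, rng):
        cfg, params = self._layer(rng)
        x = rng.normal(size=(10, 4))
        out = cac_layer_forward(x, cfg, params)
        oracle = np.concatenate(
            [np.maximum(attention_augmented_conv(x, br, cp, mp), 0.0)
             for br, (cp, mp) in zip(cfg.branches, params)], axis=1)
        np.testing.assert_array_equal(out, oracle)

    def test_every_branch_sees_same_input(self, rng):
        # duplicating a branch's parameters duplicates its output block
        cfg = CACLayerConfig.default(D=16, i=2, input_channels=4, n_heads=2,
                                     kernel_sizes=(3, 3))
        br = cfg.branches[0]
        conv = ConvParams(kernels=rng.normal(size=(3, 4, br.d_conv)),
                          bias=rng.normal(size=br.d_conv))
        mha = MHAParams.random(4, br.n_heads, br.d_head, rng=rng, scale=0.5)
        x = rng.normal(size=(5, 4))
        out = cac_layer_forward(x, cfg, [(conv, mha), (conv, mha)])
        np.testing.assert_array_equal(out[:, :8], out[:, 8:])

    def test_length_invariant(self, rng):
        cfg, params = self._layer(rng)
        out = cac_layer_forward(rng.normal(size=(21, 4)), cfg, params)
        assert out.shape == (21, cfg.D)


# ---------------------------------------------------------------- pooling
class TestMaxPool:
    def test_1000_to_250(self, rng):
        out = max_pool(rng.normal(size=(1000, 3)), PoolConfig(4, 4))
        assert out.shape == (250, 3)

    def test_hand_checked_windows(self):
        x = np.array([1, 3, 2, 0, 5, 5, 0, 1], dtype=float)[:, None]
        np.testing.assert_array_equal(max_pool(x, PoolConfig(4, 4)).ravel(), [3, 5])

    def test_constant_input(self):
        out = max_pool(np.full((12, 2), 7.0), PoolConfig(4, 4))
        np.testing.assert_array_equal(out, np.full((3, 2), 7.0))

    def test_floor_length_formula(self, rng):
        for L, size, stride in [(10, 4, 4), (11, 4, 4), (9, 3, 2), (7, 7, 1)]:
            out = max_pool(rng.normal(size=(L, 2)), PoolConfig(size, stride))
            assert out.shape[0] == (L - size) // stride + 1

    def test_too_short_rejected(self, rng):
        with pytest.raises(ValueError):
            max_pool(rng.normal(size=(3, 2)), PoolConfig(4, 4))
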