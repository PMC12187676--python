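"""HFEF block: shuffle permutation arithmetic, gate closed forms, a
straight-line channel-attention oracle, shape preservation and gradient flow."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.special import expit

from conftest import numeric_gradient
from hasaseg.config import HfefConfig
from hasaseg.hfef import (HFEF, ChannelAttention, SpatialAttention,
                          channel_shuffle, shuffle_permutation)
from hasaseg.nn import Tensor
from hasaseg.nn.tensor import using_dtype


class TestChannelShuffle:
    def test_interleaving_order_c8_g4(self):
        x = np.arange(8, dtype=float).reshape(8, 1, 1) * np.ones((8, 2, 2))
        out = channel_shuffle(x, groups=4)
        order = out.data[:, 0, 0].astype(int).tolist()
        assert order == [0, 2, 4, 6, 1, 3, 5, 7]
        assert np.array_equal(shuffle_permutation(8, 4), [0, 2, 4, 6, 1, 3, 5, 7])

    @pytest.mark.parametrize("groups", [1, 8])
    def test_degenerate_grouping_is_identity(self, groups, rng):
        x = rng.normal(size=(8, 3, 3))
        np.testing.assert_array_equal(channel_shuffle(x, groups).data,
                                      x.astype(np.float32))

    @pytest.mark.parametrize("c", [4, 8, 12, 16])
    def test_inverse_shuffle_restores_input(self, c, rng):
        for g in [g for g in (2, 4) if c % g == 0]:
            x = rng.normal(size=(c, 2, 2)).astype(np.float32)
            back = channel_shuffle(channel_shuffle(x, g), c // g)
            np.testing.assert_array_equal(back.data, x)

    @given(st.sampled_from([4, 8, 12, 16]), st.integers(0, 10 ** 6))
    def test_channel_energy_multiset_invariant(self, c, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(c, 3, 3))
        out = channel_shuffle(x, 4).data
        energies = lambda a: np.sort((a ** 2).sum(axis=(1, 2)))
        np.testing.assert_allclose(energies(out),
                                   energies(x.astype(np.float32)), rtol=1e-6)

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            channel_shuffle(np.zeros((6, 2, 2)), groups=4)


class TestChannelAttention:
    def test_zero_weights_gate_at_half(self, rng):
        cab = ChannelAttention(8)
        for p in cab.parameters():
            p.data[...] = 0.0
        x = rng.normal(size=(8, 5, 5)).astype(np.float32)
        np.testing.assert_allclose(cab(x).data, 0.5 * x, rtol=1e-6)

    def test_shape_preserved(self, rng):
        cab = ChannelAttention(16, rng=rng)
        assert cab(rng.normal(size=(16, 8, 8))).shape == (16, 8, 8)

    def test_single_pixel_matches_straightline_oracle(self, rng):
        """On a 1x1 grid the block is exactly: sigmoid(W2 relu(W1 x + b1) + b2) * x."""
        with using_dtype(np.float64):
            cab = ChannelAttention(4, rng=rng)
            w1 = rng.normal(size=(1, 4)) * 0.5
            b1 = rng.normal(size=1) * 0.1
            w2 = rng.normal(size=(4, 1)) * 0.5
            b2 = rng.normal(size=4) * 0.1
            cab.fc1.weight.data[...] = w1[:, :, None, None]
            cab.fc1.bias.data[...] = b1
            cab.fc2.weight.data[...] = w2[:, :, None, None]
            cab.fc2.bias.data[...] = b2
            x = np.array([1.0, 2.0, 3.0, 4.0])
            z = w2 @ np.maximum(w1 @ x + b1, 0.0) + b2
            expected = expit(z) * x
            got = cab(x.reshape(4, 1, 1)).data.ravel()
            np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_gate_strictly_inside_unit_interval(self, rng):
        cab = ChannelAttention(8, rng=rng)
        m = cab.gate(rng.normal(size=(8, 6, 6))).data
        assert np.all(m > 0) and np.all(m < 1)

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ValueError):
            ChannelAttention(6)


class TestSpatialAttention:
    def test_zero_weights_gate_at_half_in_eval_mode(self, rng):
        sab = SpatialAttention(8, kernel_size=5, rng=rng)
        for name, p in sab.named_parameters():
            if "conv" in name:
                p.data[...] = 0.0
        sab.eval()
        x = rng.normal(size=(8, 6, 6)).astype(np.float32)
        np.testing.assert_allclose(sab(x).data, 0.5 * x, rtol=1e-6)

    @pytest.mark.parametrize("k", [3, 5, 7, 9])
    def test_padding_preserves_dims(self, k, rng):
        sab = SpatialAttention(16, kernel_size=k, rng=rng)
        sab.eval()
        assert sab(rng.normal(size=(16, 12, 12))).shape == (16, 12, 12)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            SpatialAttention(8, kernel_size=4)

    def test_gate_strictly_inside_unit_interval(self, rng):
        sab = SpatialAttention(8, kernel_size=3, rng=rng)
        m = sab.gate(rng.normal(size=(2, 8, 6, 6))).data
        assert np.all(m > 0) and np.all(m < 1)


class TestHFEF:
    @pytest.mark.parametrize("level", [1, 2, 3, 4])
    def test_shape_preserved_at_every_level(self, level, rng):
        block = HFEF(32, level, rng=rng)
        block.eval()
        assert block.kernel_size == 2 * level + 1
        assert block(rng.normal(size=(32, 16, 16))).shape == (32, 16, 16)

    def test_zero_weights_reduce_to_quarter_of_shuffled_input(self, rng):
        block = HFEF(8, level=1, rng=rng)
        for name, p in block.named_parameters():
            if "bn" not in name:
                p.data[...] = 0.0
        block.eval()
        x = rng.normal(size=(8, 4, 4)).astype(np.float32)
        expected = 0.25 * channel_shuffle(x, 4).data
        np.testing.assert_allclose(block(x).data, expected, rtol=1e-5)

    def test_gate_attenuates_never_amplifies(self, rng):
        cab = ChannelAttention(8, rng=rng)
        x = rng.normal(size=(8, 5, 5))
        assert np.all(np.abs(cab(x).data) <= np.abs(x).astype(np.float32) + 1e-7)

    def test_deterministic_in_eval_mode(self, rng):
        block = HFEF(8, level=2, rng=rng)
        block.eval()
        x = rng.normal(size=(8, 6, 6))
        assert np.array_equal(block(x).data, block(x).data)

    def test_every_parameter_gets_gradient(self, rng):
        with using_dtype(np.float64):
            block = HFEF(8, level=1, rng=rng)
            out = block(Tensor(rng.normal(size=(2, 8, 4, 4)), requires_grad=True))
            (out * Tensor(rng.normal(size=out.shape))).sum().backward()
            for name, p in block.named_parameters():
                assert p.grad is not None and np.any(p.grad != 0), name

    def test_cab_weight_gradient_matches_finite_differences(self, rng):
        with using_dtype(np.float64):
            block = HFEF(4, level=1, rng=rng)
            x = Tensor(rng.normal(size=(1, 4, 4, 4)))
            w = block.cab.fc1.weight
            err = numeric_gradient(lambda w_: block(x), [w], rng=rng)
            assert err < 1e-3
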