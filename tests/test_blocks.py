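"""Oracle equivalence and invariants of FIFConv, CFRM and MBGM."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from defifnet.autodiff import Tensor
from defifnet.blocks import CFRM, FIFConv, MBGM, channel_shuffle, \
    shuffle_permutation

import oracles

SIGMOID_1 = 0.7310585786300049  # closed-form sigmoid(1)


def make_rng(seed=0):
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# FIFConv
# ---------------------------------------------------------------------------


class TestFIFConv:
    def test_shape_preserved(self):
        block = FIFConv(8, make_rng())
        x = make_rng(1).normal(size=(2, 8, 16, 16)).astype(np.float32)
        assert block(Tensor(x)).shape == (2, 8, 16, 16)

    def test_zero_input_is_fixed_point(self):
        block = FIFConv(8, make_rng())
        for conv in (block.conv1_left, block.conv1_right, block.group_conv,
                     block.inner_left, block.inner_right):
            conv.bias.data[...] = 0.0
        out = block(Tensor(np.zeros((1, 8, 4, 4), dtype=np.float32)))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_matches_straight_line_oracle_with_unit_kernels(self):
        block = FIFConv(4, make_rng())
        for conv in (block.conv1_left, block.conv1_right, block.group_conv,
                     block.inner_left, block.inner_right):
            conv.weight.data[...] = 1.0
            conv.bias.data[...] = 0.0
        x = np.arange(16, dtype=np.float32).reshape(1, 4, 2, 2) / 8.0
        out = block(Tensor(x)).data
        ref = oracles.fifconv_oracle(x.astype(np.float64),
                                     oracles.fif_params(block))
        np.testing.assert_allclose(out, ref, atol=1e-5)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_straight_line_oracle_random(self, seed):
        rng = make_rng(seed)
        C = int(rng.choice([2, 4, 8]))
        block = FIFConv(C, rng)
        x = rng.normal(size=(2, C, 5, 5)).astype(np.float32)
        out = block(Tensor(x)).data
        ref = oracles.fifconv_oracle(x.astype(np.float64),
                                     oracles.fif_params(block))
        np.testing.assert_allclose(out, ref, atol=1e-5)

    @pytest.mark.parametrize("C", [2, 4, 8, 16, 32])
    def test_shape_preservation_across_widths(self, C):
        block = FIFConv(C, make_rng(C))
        x = make_rng(C + 1).normal(size=(1, C, 8, 8)).astype(np.float32)
        assert block(Tensor(x)).shape == (1, C, 8, 8)

    def test_gate_strictly_inside_unit_interval(self):
        block = FIFConv(8, make_rng(7))
        x = make_rng(8).normal(size=(3, 8, 6, 6)).astype(np.float32) * 10
        gate = block.gate_values(Tensor(x))
        assert (gate > 0.0).all() and (gate < 1.0).all()

    def test_odd_channel_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            FIFConv(5, make_rng())

    def test_wrong_input_channels_rejected(self):
        block = FIFConv(4, make_rng())
        with pytest.raises(ValueError, match="channels"):
            block(Tensor(np.zeros((1, 6, 4, 4), dtype=np.float32)))


# ---------------------------------------------------------------------------
# channel shuffle
# ---------------------------------------------------------------------------


class TestChannelShuffle:
    def test_identity_for_single_group(self):
        x = make_rng().normal(size=(1, 6, 2, 2))
        out = channel_shuffle(Tensor(x), 1)
        np.testing.assert_array_equal(out.data, x)

    def test_interleaving_order_c6_g2(self):
        """Channels [0..5] with 2 groups shuffle to [0, 3, 1, 4, 2, 5]."""
        assert shuffle_permutation(6, 2).tolist() == [0, 3, 1, 4, 2, 5]
        x = np.zeros((1, 6, 1, 1))
        x[0, :, 0, 0] = np.arange(6)
        out = channel_shuffle(Tensor(x), 2)
        assert out.data[0, :, 0, 0].tolist() == [0, 3, 1, 4, 2, 5]

    def test_c4_g2_matches_reshape_permute_enumeration(self):
        assert shuffle_permutation(4, 2).tolist() == oracles.ref_shuffle_perm(4, 2)

    @given(st.sampled_from([2, 4, 6, 8, 12, 24]), st.sampled_from([1, 2, 3, 4]))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_inverse_permutation_restores_input(self, C, groups):
        if C % groups:
            return
        x = np.random.default_rng(C * 7 + groups).normal(size=(1, C, 2, 2))
        perm = shuffle_permutation(C, groups)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(C)
        shuffled = channel_shuffle(Tensor(x), groups).data
        np.testing.assert_array_equal(shuffled[:, inv], x)
        # multiset of channel slices preserved
        orig = {x[0, c].tobytes() for c in range(C)}
        assert {shuffled[0, c].tobytes() for c in range(C)} == orig

    def test_nondividing_group_count_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            channel_shuffle(Tensor(np.zeros((1, 6, 2, 2))), 4)


# ---------------------------------------------------------------------------
# CFRM
# ---------------------------------------------------------------------------


class TestCFRM:
    def test_shape_preserved(self):
        block = CFRM(8, make_rng())
        x = make_rng(2).normal(size=(1, 8, 8, 8)).astype(np.float32)
        assert block(Tensor(x)).shape == (1, 8, 8, 8)

    def test_initial_gate_is_sigmoid_of_one(self):
        """Zero scales and unit shifts force both gates to sigmoid(1)."""
        block = CFRM(8, make_rng(3))
        x = make_rng(4).normal(size=(2, 8, 4, 4)).astype(np.float32)
        x1 = x[:, :4]
        out = block(Tensor(x)).data
        # undo the shuffle to recover branch-1 channels
        perm = shuffle_permutation(8, 2)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(8)
        branch1 = out[:, inv][:, :4]
        np.testing.assert_allclose(branch1, x1 * SIGMOID_1, atol=1e-6)

    def test_branch1_with_identity_branch2_reduces_to_scaled_input(self):
        block = CFRM(4, make_rng(5))
        # identity 3x3 grouped conv: delta kernel
        block.branch2_conv.weight.data[...] = 0.0
        for c in range(2):
            block.branch2_conv.weight.data[c, 0, 1, 1] = 1.0
        block.branch2_conv.bias.data[...] = 0.0
        x = make_rng(6).normal(size=(1, 4, 3, 3)).astype(np.float32)
        out = block(Tensor(x)).data
        ref = oracles.cfrm_oracle(x.astype(np.float64), oracles.cfrm_params(block))
        np.testing.assert_allclose(out, ref, atol=1e-6)
        perm = shuffle_permutation(4, 2)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(4)
        np.testing.assert_allclose(out[:, inv][:, :2], x[:, :2] * SIGMOID_1,
                                   atol=1e-6)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_straight_line_oracle_random(self, seed):
        rng = make_rng(100 + seed)
        C = int(rng.choice([4, 8, 16]))
        block = CFRM(C, rng)
        # random learnable gates (not the zero/one init) for a real test
        block.w_gap.data[...] = rng.normal(size=block.w_gap.data.shape)
        block.w_gn.data[...] = rng.normal(size=block.w_gn.data.shape)
        x = rng.normal(size=(2, C, 4, 4)).astype(np.float32)
        out = block(Tensor(x)).data
        ref = oracles.cfrm_oracle(x.astype(np.float64), oracles.cfrm_params(block))
        np.testing.assert_allclose(out, ref, atol=1e-5)

    @pytest.mark.parametrize("C", [4, 8, 16, 32])
    def test_shape_preservation_across_widths(self, C):
        block = CFRM(C, make_rng(C))
        x = make_rng(C).normal(size=(1, C, 4, 4)).astype(np.float32)
        assert block(Tensor(x)).shape == (1, C, 4, 4)

    def test_invalid_configurations_rejected(self):
        with pytest.raises(ValueError, match="even"):
            CFRM(5, make_rng())
        with pytest.raises(ValueError, match="gn_groups"):
            CFRM(6, make_rng(), gn_groups=2)  # half = 3 not divisible


# ---------------------------------------------------------------------------
# MBGM
# ---------------------------------------------------------------------------


class TestMBGM:
    def test_shape_contract(self):
        block = MBGM(32, 32, 32, make_rng())
        x = make_rng(1).normal(size=(1, 32, 8, 8)).astype(np.float32)
        assert block(Tensor(x)).shape == (1, 32, 8, 8)

    def test_zero_input_is_fixed_point(self):
        block = MBGM(8, 8, 8, make_rng(2))
        for unit in (block.entry, block.primary, block.secondary,
                     block.branch, block.exit):
            unit.conv.bias.data[...] = 0.0
            unit.bn.beta.data[...] = 0.0
        out = block(Tensor(np.zeros((2, 8, 4, 4), dtype=np.float32)))
        np.testing.assert_array_equal(out.data, 0.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_straight_line_oracle_random(self, seed):
        rng = make_rng(200 + seed)
        cin, mid = int(rng.choice([2, 4, 8])), int(rng.choice([2, 4, 8]))
        cout = int(rng.choice([2, 4, 8]))
        block = MBGM(cin, mid, cout, rng)
        x = rng.normal(size=(3, cin, 4, 4)).astype(np.float32)
        out = block(Tensor(x)).data  # training mode: batch statistics
        ref = oracles.mbgm_oracle(x.astype(np.float64), oracles.mbgm_params(block))
        np.testing.assert_allclose(out, ref, atol=1e-5)

    def test_hand_set_kernels_with_identity_normalization(self):
        """Integer input + delta kernels, BN in identity mode: Eq-by-Eq check."""
        block = MBGM(2, 2, 2, make_rng(9))
        for unit in (block.entry, block.primary, block.secondary,
                     block.branch, block.exit):
            w = unit.conv.weight.data
            w[...] = 0.0
            k = w.shape[-1]
            for o in range(w.shape[0]):
                w[o, o % w.shape[1], k // 2, k // 2] = 1.0
            unit.conv.bias.data[...] = 0.0
        block.eval()  # identity normalization via running stats (0, 1)
        x = np.arange(2 * 3 * 3, dtype=np.float32).reshape(1, 2, 3, 3)
        out = block(Tensor(x)).data
        # entry/primary/secondary/branch are per-channel identities, so
        # Q = x, P + R = 2x and the exit conv (identity over the first two
        # input channels of the concatenation) returns Q = x after ReLU.
        # eval-mode BN with stats (0, 1) scales by 1/sqrt(1 + eps) per stage.
        np.testing.assert_allclose(out, np.maximum(x, 0.0), atol=1e-2)

    def test_channel_mismatch_rejected(self):
        block = MBGM(4, 4, 4, make_rng())
        with pytest.raises(ValueError, match="channels"):
            block(Tensor(np.zeros((1, 6, 4, 4), dtype=np.float32)))
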