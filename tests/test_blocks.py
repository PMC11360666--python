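"""Building-block contracts: split/shuffle algebra, RepVGG branch-sum and
reparameterization equivalence, RepNCSPELAN4/ADown/SPPELAN shapes and
identities, CBLinear/CBFuse fusion."""

import numpy as np
import pytest

from ecgdet import nnops
from ecgdet.autodiff import Tensor, no_grad
from ecgdet.blocks import (ADown, CBFuse, CBLinear, RepNCSPELAN4, RepVGGBlock,
                           RepVGGStage, SPPELAN, Silence, cbfuse,
                           channel_shuffle, channel_split,
                           shuffle_permutation, silence)


def fmap(rng, shape):
    return Tensor(rng.standard_normal(shape).astype(np.float32))


class TestChannelSplitShuffle:
    def test_split_halves_and_reconstruct(self, rng):
        x = fmap(rng, (2, 64, 5, 5))
        a, b = channel_split(x)
        assert a.shape[1] == b.shape[1] == 32
        from ecgdet import autodiff as ad
        back = ad.concat([a, b], axis=1)
        assert np.array_equal(back.data, x.data)

    def test_split_rejects_odd_channels(self, rng):
        with pytest.raises(ValueError):
            channel_split(fmap(rng, (1, 3, 4, 4)))

    def test_split_concat_identity_many_random_maps(self, rng):
        from ecgdet import autodiff as ad
        for _ in range(1000):
            x = fmap(rng, (1, 4, 2, 2))
            a, b = channel_split(x)
            assert np.array_equal(ad.concat([a, b], axis=1).data, x.data)

    def test_shuffle_matches_permutation_oracle(self, rng):
        x = fmap(rng, (1, 6, 2, 2))
        y = channel_shuffle(x, 2)
        perm = shuffle_permutation(6, 2)
        assert list(perm) == [0, 3, 1, 4, 2, 5]
        assert np.array_equal(y.data, x.data[:, perm])

    def test_shuffle_is_bijection_consistent_with_reshape_oracle(self):
        for c, g in [(8, 2), (12, 3), (16, 4)]:
            perm = shuffle_permutation(c, g)
            assert sorted(perm) == list(range(c))
            oracle = np.arange(c).reshape(g, c // g).T.ravel()
            assert np.array_equal(perm, oracle)

    def test_shuffle_groups_one_is_identity(self, rng):
        x = fmap(rng, (1, 6, 3, 3))
        assert np.array_equal(channel_shuffle(x, 1).data, x.data)

    def test_shuffle_inverse_roundtrip(self, rng):
        x = fmap(rng, (1, 8, 2, 2))
        y = channel_shuffle(x, 2).data
        inv = np.argsort(shuffle_permutation(8, 2))
        assert np.array_equal(y[:, inv], x.data)

    def test_shuffle_rejects_nondivisible(self, rng):
        with pytest.raises(ValueError):
            channel_shuffle(fmap(rng, (1, 6, 2, 2)), 4)


def _randomize_repvgg(rng, blk):
    for _, p in blk.named_parameters():
        p.data = rng.standard_normal(p.data.shape).astype(np.float32) * 0.5
    for bn in (blk.conv3.bn, blk.conv1.bn, blk.id_bn):
        bn.running_mean[:] = rng.standard_normal(bn.running_mean.shape) * 0.3
        bn.running_var[:] = rng.uniform(0.5, 2.0, bn.running_var.shape)


class TestRepVGG:
    def test_shape_preserving(self, rng):
        blk = RepVGGBlock(rng, 64).eval()
        x = fmap(rng, (1, 64, 10, 10))
        assert blk(x).shape == (1, 64, 10, 10)

    def test_odd_channels_rejected(self, rng):
        with pytest.raises(ValueError):
            RepVGGBlock(rng, 3)

    def test_zero_branches_identity_activation(self, rng):
        """With zero conv weights and fresh norm stats the branch sum is the
        identity on the right half, so the block is shuffle(concat(x))."""
        blk = RepVGGBlock(rng, 8, activation="identity").eval()
        blk.conv3.weight.data[:] = 0
        blk.conv1.weight.data[:] = 0
        x = fmap(rng, (1, 8, 4, 4))
        out, tr = blk(x, return_trace=True)
        assert np.allclose(tr.y_repvgg, tr.x_right, atol=1e-5)
        expected = channel_shuffle(x, 2).data
        assert np.allclose(out.data, expected, atol=1e-5)

    def test_trace_sum_identity(self, rng):
        blk = RepVGGBlock(rng, 16).eval()
        _randomize_repvgg(rng, blk)
        x = fmap(rng, (2, 16, 6, 6))
        _, tr = blk(x, return_trace=True)
        assert np.allclose(tr.y_repvgg, tr.y_3x3 + tr.y_1x1 + tr.y_id, atol=1e-5)

    def test_merged_kernel_zero_branches_is_centered_identity(self, rng):
        blk = RepVGGBlock(rng, 8)
        blk.conv3.weight.data[:] = 0
        blk.conv1.weight.data[:] = 0
        w, b = blk.merged_kernel()
        expect = np.zeros_like(w)
        expect[np.arange(4), np.arange(4), 1, 1] = 1.0 / np.sqrt(1 + 1e-5)
        assert np.allclose(w, expect, atol=1e-6)
        assert np.allclose(b, 0, atol=1e-6)

    def test_norm_folding_identity(self, rng):
        """Folded conv+BN equals the unfolded pair at inference."""
        from ecgdet.modules import ConvBN
        conv = ConvBN(rng, 4, 6, 3).eval()
        conv.bn.running_mean[:] = rng.standard_normal(6) * 0.2
        conv.bn.running_var[:] = rng.uniform(0.5, 2.0, 6)
        conv.bn.beta.data[:] = rng.standard_normal(6).astype(np.float32)
        fused = conv.fuse().eval()
        x = fmap(rng, (1, 4, 5, 5))
        assert np.allclose(conv(x).data, fused(x).data, atol=1e-5)

    def test_reparameterization_equivalence_many_draws(self, rng):
        """Merged single-conv forward equals the three-branch forward for
        random weights, norm stats and inputs."""
        for i in range(200):
            c = int(rng.choice([8, 16, 32]))
            blk = RepVGGBlock(rng, c).eval()
            _randomize_repvgg(rng, blk)
            merged = blk.reparameterize().eval()
            b = int(rng.integers(1, 3))
            hw = int(rng.integers(4, 17))
            x = fmap(rng, (b, c, hw, hw))
            with no_grad():
                y0, y1 = blk(x).data, merged(x).data
            err = np.max(np.abs(y0 - y1)) / (np.max(np.abs(y0)) + 1e-9)
            assert err < 1e-5, f"draw {i}: rel err {err:.2g}"

    def test_merged_mode_missing_weights_error(self, rng):
        blk = RepVGGBlock(rng, 8)
        blk.conv3 = None  # simulate a merged-mode block without merged weights
        x = fmap(rng, (1, 8, 4, 4))
        with pytest.raises((AttributeError, TypeError)):
            blk(x)


class TestRepNCSPELAN4:
    def test_output_channels_and_spatial_preserved(self, rng):
        m = RepNCSPELAN4(rng, 128, 96).eval()
        y = m(fmap(rng, (1, 128, 10, 10)))
        assert y.shape == (1, 96, 10, 10)

    def test_zero_branch2_passthrough(self, rng):
        """With branch-2 convs zeroed and identity activations, the first
        half of the concat equals the branch-1 passthrough."""
        m = RepNCSPELAN4(rng, 8, 8, activation="identity").eval()
        m.b2a.weight.data[:] = 0
        m.b2b.weight.data[:] = 0
        # make the final conv pick out the first half unchanged
        m.cv2.weight.data[:] = 0
        for i in range(4):
            m.cv2.weight.data[i, i, 0, 0] = 1.0
        x = fmap(rng, (1, 8, 5, 5))
        y1 = m.cv1(x)
        first_half = y1.data[:, :4]
        out = m(x)
        assert np.allclose(out.data[:, :4], first_half, atol=1e-5)

    def test_odd_hidden_rejected(self, rng):
        with pytest.raises(ValueError):
            RepNCSPELAN4(rng, 8, 8, hidden=7)


class TestADown:
    def test_halves_spatial_sets_channels(self, rng):
        m = ADown(rng, 32, 48).eval()
        y = m(fmap(rng, (1, 32, 12, 12)))
        assert y.shape == (1, 48, 6, 6)

    def test_odd_spatial_rejected(self, rng):
        m = ADown(rng, 8, 8)
        with pytest.raises(ValueError):
            m(fmap(rng, (1, 8, 9, 9)))

    def test_constant_input_constant_pool_branches(self, rng):
        x = Tensor(np.full((1, 4, 8, 8), 2.5, np.float32))
        pooled = nnops.avgpool2d(x, 2, 1, 0)
        assert np.allclose(pooled.data, 2.5)
        mp = nnops.maxpool2d(pooled, 3, 2, 1)
        assert np.allclose(mp.data, 2.5)


class TestSPPELAN:
    def test_spatial_preserved_and_channels(self, rng):
        m = SPPELAN(rng, 64, 64).eval()
        y = m(fmap(rng, (1, 64, 9, 9)))
        assert y.shape == (1, 64, 9, 9)

    def test_pool_branches_preserve_hw_and_dominate_input(self, rng):
        x = fmap(rng, (1, 4, 11, 11))
        for k, p in [(5, 2), (9, 4), (13, 6)]:
            y = nnops.maxpool2d(x, k, 1, p)
            assert y.shape == x.shape
            assert np.all(y.data >= x.data)  # window includes the center

    def test_k9_pool_equals_two_k5_pools(self, rng):
        x = fmap(rng, (1, 3, 12, 12))
        once = nnops.maxpool2d(x, 9, 1, 4).data
        twice = nnops.maxpool2d(nnops.maxpool2d(x, 5, 1, 2), 5, 1, 2).data
        assert np.array_equal(once, twice)

    def test_constant_input_equal_branches(self, rng):
        m = SPPELAN(rng, 8, 8).eval()
        x = Tensor(np.full((1, 8, 6, 6), 1.5, np.float32))
        xt = m.cv1(x)
        pools = [nnops.maxpool2d(xt, k, 1, p).data
                 for k, p in [(5, 2), (9, 4), (13, 6)]]
        for pmap in pools:
            assert np.allclose(pmap, xt.data, atol=1e-6)


class TestSilence:
    def test_identity_bitwise_and_involution(self, rng):
        x = fmap(rng, (1, 3, 4, 4))
        y = silence(x)
        assert y.shape == x.shape
        assert np.array_equal(y.data, x.data)
        assert np.array_equal(silence(silence(x)).data, x.data)


class TestCBLinearFuse:
    def test_split_sizes_and_reconstruction(self, rng):
        m = CBLinear(rng, 256, [64, 128]).eval()
        x = fmap(rng, (1, 256, 4, 4))
        outs = m(x)
        assert [o.shape[1] for o in outs] == [64, 128]
        assert all(o.shape[2:] == (4, 4) for o in outs)
        from ecgdet import autodiff as ad
        full = m.conv(x)
        assert np.array_equal(ad.concat(outs, axis=1).data, full.data)

    def test_zero_projection_zero_outputs(self, rng):
        m = CBLinear(rng, 8, [4, 4]).eval()
        m.conv.weight.data[:] = 0
        m.conv.bias.data[:] = 0
        outs = m(fmap(rng, (1, 8, 3, 3)))
        assert all(np.allclose(o.data, 0) for o in outs)

    def test_empty_list_rejected(self, rng):
        with pytest.raises(ValueError):
            CBLinear(rng, 8, [])

    def test_cbfuse_identity_sum_and_permutation_invariance(self, rng):
        a = fmap(rng, (1, 4, 4, 4))
        assert np.array_equal(cbfuse([a]).data, a.data)
        c1 = Tensor(np.full((1, 4, 8, 8), 1.0, np.float32))
        c2 = Tensor(np.full((1, 4, 4, 4), 2.0, np.float32))
        fused = cbfuse([c1, c2])
        assert fused.shape == (1, 4, 4, 4)
        assert np.allclose(fused.data, 3.0)
        b = fmap(rng, (1, 4, 4, 4))
        assert np.allclose(cbfuse([a, b]).data, cbfuse([b, a]).data, atol=1e-6)

    def test_cbfuse_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            cbfuse([fmap(rng, (1, 4, 4, 4)), fmap(rng, (1, 6, 4, 4))])


def test_stride1_blocks_preserve_spatial(rng):
    x = fmap(rng, (1, 16, 14, 14))
    for m in (RepVGGBlock(rng, 16).eval(), RepNCSPELAN4(rng, 16, 16).eval(),
              SPPELAN(rng, 16, 16).eval(), Silence()):
        assert m(x).shape[2:] == (14, 14)
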