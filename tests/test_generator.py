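"""Generator architecture: DR blocks, channel attention, fusion, U-net."""

import numpy as np
import pytest

from csmri import (ChannelAttention, DRBlock, DRBlockConfig, Generator,
                   GeneratorConfig, MultiScaleFusion, Tensor)
from csmri.autodiff import upsample_bilinear


def _positive_block(channels: int, dilation: int, seed: int = 0) -> DRBlock:
    """DR block rigged so no ReLU is dead: positive weights, identity BN."""
    rng = np.random.default_rng(seed)
    block = DRBlock(DRBlockConfig(channels, dilation), rng)
    for conv in (block.conv1, block.conv2):
        conv.weight.data = np.abs(conv.weight.data) + 0.01
        conv.bias.data[:] = 0.1
    block.eval()
    return block


def gradient_footprint(forward, shape, out_pixel):
    """Span of the input region with nonzero gradient for one output pixel."""
    x = Tensor(np.full(shape, 0.5), requires_grad=True)
    y = forward(x)
    g = np.zeros(y.shape)
    g[(0, 0) + out_pixel] = 1.0
    y.backward(g)
    footprint = np.abs(x.grad).sum(axis=(0, 1)) > 0
    rows = np.flatnonzero(footprint.any(axis=1))
    cols = np.flatnonzero(footprint.any(axis=0))
    return rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1


class TestDRBlock:
    def test_zero_convolutions_reduce_to_activation(self, rng):
        block = DRBlock(DRBlockConfig(4, 2), rng)
        for conv in (block.conv1, block.conv2):
            conv.weight.data[:] = 0
            conv.bias.data[:] = 0
        block.eval()
        x = Tensor(rng.normal(size=(1, 4, 8, 8)))
        out = block(x)
        np.testing.assert_allclose(out.data, np.maximum(x.data, 0), atol=1e-12)

    def test_parameter_count_independent_of_dilation(self, rng):
        counts = {r: DRBlock(DRBlockConfig(8, r), rng).num_parameters()
                  for r in (1, 2, 3)}
        assert counts[1] == counts[2] == counts[3]

    def test_shape_preserved(self, rng):
        for r in (1, 2, 3):
            block = DRBlock(DRBlockConfig(4, r), rng)
            x = Tensor(rng.normal(size=(2, 4, 16, 16)))
            assert block(x).shape == x.shape

    def test_channel_mismatch_rejected(self, rng):
        block = DRBlock(DRBlockConfig(4, 1), rng)
        with pytest.raises(ValueError):
            block(Tensor(rng.normal(size=(1, 3, 8, 8))))

    @pytest.mark.parametrize("dilation", [1, 2, 3])
    def test_receptive_field_of_single_block(self, dilation):
        # two 3x3 convs, second dilated by r: span 2*(1+r)+1 per axis
        expected = 2 * (1 + dilation) + 1
        block = _positive_block(3, dilation)
        span = gradient_footprint(block, (1, 3, 16, 16), (8, 8))
        assert span == (expected, expected)

    def test_invalid_dilation_rejected(self):
        with pytest.raises(ValueError):
            DRBlockConfig(4, 4)


class TestChannelAttention:
    def test_weights_strictly_in_unit_interval(self, rng):
        cam = ChannelAttention(8, rng=rng)
        w = cam.channel_weights(Tensor(rng.normal(size=(3, 8, 6, 6)))).data
        assert np.all(w > 0) and np.all(w < 1)

    def test_zero_transform_halves_input(self, rng):
        cam = ChannelAttention(8, rng=rng)
        for p in cam.parameters():
            p.data[:] = 0
        x = Tensor(rng.normal(size=(2, 8, 5, 5)))
        out = cam(x)
        np.testing.assert_allclose(out.data, 0.5 * x.data, atol=1e-12)

    def test_duplicated_channels_get_identical_weights(self, rng):
        cam = ChannelAttention(16, rng=rng)
        x = rng.normal(size=(2, 16, 8, 8))
        x[:, 5] = x[:, 11]
        w = cam.channel_weights(Tensor(x)).data
        assert np.abs(w[:, 5] - w[:, 11]).max() <= 1e-6

    def test_concat_combine_mode(self, rng):
        cam = ChannelAttention(8, combine="concat", rng=rng)
        x = rng.normal(size=(1, 8, 4, 4))
        x[:, 1] = x[:, 6]
        w = cam.channel_weights(Tensor(x)).data
        assert w.shape == (1, 8)
        assert np.abs(w[:, 1] - w[:, 6]).max() <= 1e-6

    def test_narrow_input_warns_and_clamps(self, rng):
        with pytest.warns(UserWarning):
            ChannelAttention(4, reduction=8, rng=rng)

    def test_single_channel_rejected(self, rng):
        cam = ChannelAttention(2, rng=rng)
        with pytest.raises(ValueError):
            cam.channel_weights(Tensor(rng.normal(size=(1, 1, 4, 4))))


class TestMultiScaleFusion:
    def test_single_level_reduces_to_projection_and_fusion(self, rng):
        fusion = MultiScaleFusion([4], 4, rng)
        x = Tensor(rng.normal(size=(1, 4, 8, 8)))
        expected = fusion.fuse(fusion.projections[0](x).relu())
        np.testing.assert_allclose(fusion([x]).data, expected.data, atol=1e-12)

    def test_mixed_strides_upsampled_to_finest(self, rng):
        fusion = MultiScaleFusion([8, 4, 2], 4, rng)
        feats = [Tensor(rng.normal(size=(2, 8, 4, 4))),
                 Tensor(rng.normal(size=(2, 4, 8, 8))),
                 Tensor(rng.normal(size=(2, 2, 16, 16)))]
        out = fusion(feats)
        assert out.shape == (2, 4, 16, 16)

    def test_inconsistent_batch_rejected(self, rng):
        fusion = MultiScaleFusion([2, 2], 2, rng)
        with pytest.raises(ValueError):
            fusion([Tensor(rng.normal(size=(1, 2, 8, 8))),
                    Tensor(rng.normal(size=(2, 2, 4, 4)))])


class TestGenerator:
    def test_identity_with_zero_initialized_head(self, rng):
        gen = Generator(GeneratorConfig(depth=3, base_channels=4), seed=0)
        x = rng.random((2, 1, 32, 32))
        out = gen(Tensor(x))
        np.testing.assert_array_equal(out.data, x)

    @pytest.mark.parametrize("size", [64, 128])
    def test_output_shape_matches_input(self, rng, size):
        gen = Generator(GeneratorConfig(depth=3, base_channels=4), seed=0)
        x = rng.random((1, 1, size, size))
        assert gen(Tensor(x)).shape == x.shape

    def test_indivisible_size_rejected_with_named_divisor(self, rng):
        gen = Generator(GeneratorConfig(depth=4, base_channels=4), seed=0)
        with pytest.raises(ValueError, match="divisible by 8"):
            gen(Tensor(rng.random((1, 1, 36, 36))))

    def test_dr_stack_receptive_field_is_19(self):
        # three DR blocks with dilations 1,2,3: 1 + sum(2*(1+r)) = 19
        blocks = [_positive_block(3, r, seed=r) for r in (1, 2, 3)]

        def stack(x):
            for b in blocks:
                x = b(x)
            return x

        span = gradient_footprint(stack, (1, 3, 32, 32), (16, 16))
        assert span == (19, 19)

    def test_dilation_toggle_preserves_parameter_count(self):
        cfg_on = GeneratorConfig(depth=3, base_channels=4, use_dilation=True)
        cfg_off = GeneratorConfig(depth=3, base_channels=4, use_dilation=False)
        assert (Generator(cfg_on, seed=0).num_parameters()
                == Generator(cfg_off, seed=0).num_parameters())

    def test_cam_toggle_strictly_decreases_parameter_count(self):
        with_cam = Generator(GeneratorConfig(depth=3, base_channels=4,
                                             use_cam=True), seed=0)
        without = Generator(GeneratorConfig(depth=3, base_channels=4,
                                            use_cam=False), seed=0)
        assert without.num_parameters() < with_cam.num_parameters()

    @pytest.mark.parametrize("kwargs", [
        {"use_dilation": False}, {"use_cam": False}, {"use_fusion": False},
    ])
    def test_ablation_toggles_preserve_output_shape(self, rng, kwargs):
        gen = Generator(GeneratorConfig(depth=3, base_channels=4, **kwargs),
                        seed=0)
        x = rng.random((1, 1, 32, 32))
        assert gen(Tensor(x)).shape == x.shape

    def test_inference_deterministic(self, rng):
        gen = Generator(GeneratorConfig(depth=3, base_channels=4), seed=3)
        # give the head nonzero weights so the output is nontrivial
        gen.head.weight.data = np.random.default_rng(0).normal(
            size=gen.head.weight.shape) * 0.1
        x = rng.random((2, 32, 32))
        np.testing.assert_array_equal(gen.reconstruct(x), gen.reconstruct(x))

    def test_gradient_reaches_every_parameter(self, rng):
        gen = Generator(GeneratorConfig(depth=3, base_channels=4), seed=1)
        x = Tensor(rng.random((2, 1, 16, 16)))
        target = Tensor(rng.random((2, 1, 16, 16)))
        loss = ((gen(x) - target) ** 2).mean()
        loss.backward()
        missing = [name for name, p in gen.named_parameters() if p.grad is None]
        assert not missing, f"no gradient for {missing}"
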