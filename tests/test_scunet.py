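"""SC-UNet architecture contracts: block structure, attention, shapes."""

import numpy as np
import pytest

from xfctdn.nn import Tensor, SwinBlock, WindowAttention, window_partition
from xfctdn.scunet import (ModelConfig, RConvBlock, SCBlock, SCUNet,
                           TINY_CONFIG, build_model, count_parameters,
                           load_checkpoint, save_checkpoint)

from conftest import dense_attention_oracle


def make_sc_block(dim, window=4, rng_seed=0):
    return SCBlock(dim, window, 32, 2.0, 0, np.random.default_rng(rng_seed))


class TestSCBlock:
    @pytest.mark.parametrize("c,hw", [(8, 16), (8, 64), (64, 16)])
    def test_residual_identity_with_zeroed_fusion(self, rng, c, hw):
        blk = make_sc_block(c)
        blk.conv_out.weight.data[:] = 0.0
        blk.conv_out.bias.data[:] = 0.0
        x = rng.random((1, c, hw, hw))
        out = blk(Tensor(x))
        assert np.array_equal(out.data, x)       # bit-exact residual path

    @pytest.mark.parametrize("c,hw", [(8, 16), (64, 64)])
    def test_shape_preserved(self, rng, c, hw):
        blk = make_sc_block(c)
        assert blk(Tensor(rng.random((2, c, hw, hw)))).shape == (2, c, hw, hw)

    def test_split_halves_channels(self, rng):
        blk = make_sc_block(16)
        t = blk.conv_in(Tensor(rng.random((1, 16, 8, 8))))
        assert t[:, :8].shape == (1, 8, 8, 8)
        assert t[:, 8:].shape == (1, 8, 8, 8)

    def test_odd_channels_rejected(self):
        with pytest.raises(ValueError):
            make_sc_block(7)


class TestSwinAttention:
    def test_attention_rows_sum_to_one(self, rng):
        blk = SwinBlock(8, 4, 4, 2.0, shift=2, rng=np.random.default_rng(3))
        blk(Tensor(rng.random((1, 8, 8, 8))))
        rows = blk.attn.last_attn.sum(axis=-1)
        assert np.abs(rows - 1.0).max() < 1e-6

    def test_single_window_equals_dense_attention(self, rng):
        # one window covering the whole input, no shift
        dim, ws, head_dim = 8, 4, 4
        attn = WindowAttention(dim, head_dim, np.random.default_rng(5))
        tokens = rng.normal(size=(ws * ws, dim))
        got = attn(Tensor(tokens[None])).data[0]
        wqkv = attn.qkv.weight.data
        bqkv = attn.qkv.bias.data
        want = dense_attention_oracle(
            tokens,
            wqkv[:, :dim], bqkv[:dim],
            wqkv[:, dim:2 * dim], bqkv[dim:2 * dim],
            wqkv[:, 2 * dim:], bqkv[2 * dim:],
            attn.proj.weight.data, attn.proj.bias.data,
            n_heads=dim // head_dim)
        assert np.abs(got - want).max() <= 1e-5

    def test_shifted_path_is_deterministic(self, rng):
        blk = SwinBlock(8, 4, 4, 2.0, shift=2, rng=np.random.default_rng(7))
        x = np.full((1, 8, 8, 8), 0.3)
        a = blk(Tensor(x)).data
        b = blk(Tensor(x)).data
        assert np.array_equal(a, b)

    def test_window_partition_counts(self, rng):
        x = Tensor(rng.random((2, 3, 8, 8)))
        wins = window_partition(x, 4)
        assert wins.shape == (2 * 4, 16, 3)

    def test_invalid_window_size_rejected(self):
        with pytest.raises(ValueError):
            SwinBlock(8, 0, 4, 2.0, 0, np.random.default_rng(0))


class TestRConvBlock:
    def test_zeroed_second_conv_is_identity(self, rng):
        blk = RConvBlock(6, np.random.default_rng(0))
        blk.conv2.weight.data[:] = 0.0
        blk.conv2.bias.data[:] = 0.0
        x = rng.random((1, 6, 12, 12))
        assert np.array_equal(blk(Tensor(x)).data, x)

    @pytest.mark.parametrize("hw", [8, 17, 32])
    def test_shape_preserved(self, rng, hw):
        blk = RConvBlock(4, np.random.default_rng(0))
        assert blk(Tensor(rng.random((1, 4, hw, hw)))).shape == (1, 4, hw, hw)

    def test_residual_branch_linear_without_relu(self, rng):
        blk = RConvBlock(4, np.random.default_rng(0))
        blk.use_relu = False          # test hook
        x = rng.normal(size=(1, 4, 8, 8))
        r1 = blk(Tensor(x)).data - x
        r2 = blk(Tensor(2 * x)).data - 2 * x
        bias_resp = blk(Tensor(0 * x)).data - 0 * x
        # affine branch: response to 2x minus bias is twice (x minus bias)
        assert np.allclose(r2 - bias_resp, 2 * (r1 - bias_resp), atol=1e-10)


class TestSCUNet:
    def test_default_config_channels(self):
        assert ModelConfig().scale_channels == (64, 128, 256, 512)

    def test_tiny_forward_shape_256(self):
        m = build_model("tiny")
        img = np.random.default_rng(0).random((256, 256))
        assert m.denoise(img).shape == (256, 256)

    def test_pad_and_crop_arbitrary_size(self):
        m = build_model("tiny")
        img = np.random.default_rng(0).random((70, 70))
        assert m.denoise(img).shape == (70, 70)

    def test_multi_channel_input_rejected(self):
        m = build_model("tiny")
        with pytest.raises(ValueError):
            m.denoise(np.zeros((2, 3, 64, 64)))

    def test_parameter_count_matches_analytic(self):
        m = build_model("tiny")
        assert count_parameters(m) == TINY_CONFIG.parameter_count()

    def test_halving_channels_roughly_quarters_parameters(self):
        big = ModelConfig(scale_channels=(32, 64, 128, 256),
                          blocks_per_scale=1, window_size=4)
        small = ModelConfig(scale_channels=(16, 32, 64, 128),
                            blocks_per_scale=1, window_size=4)
        ratio = big.parameter_count() / small.parameter_count()
        assert 3.3 <= ratio <= 4.2

    def test_forward_deterministic(self):
        m = build_model("tiny")
        x = np.random.default_rng(1).random((64, 64))
        assert np.array_equal(m.denoise(x), m.denoise(x))

    def test_gradient_reaches_every_parameter(self, rng):
        m = build_model("tiny", seed=2)
        x = rng.random((1, 1, 32, 32))
        out = m(Tensor(x))
        (out * out).mean().backward()
        for name, p in m.named_parameters():
            assert p.grad is not None, name
            assert np.all(np.isfinite(p.grad)), name
        total = sum(np.abs(p.grad).sum() for p in m.parameters())
        assert total > 0

    def test_checkpoint_roundtrip(self, tmp_path):
        m = build_model("tiny", seed=3)
        path = tmp_path / "m.ckpt"
        save_checkpoint(path, m, m.config, {"note": "test"})
        m2, cfg, meta = load_checkpoint(path)
        assert cfg == m.config
        assert meta["note"] == "test"
        x = np.random.default_rng(0).random((64, 64))
        assert np.array_equal(m.denoise(x), m2.denoise(x))

    def test_odd_scale_channels_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(scale_channels=(63, 128, 256, 512))
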