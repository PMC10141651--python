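"""Architecture contracts: shapes, channel plans, parameter accounting."""

import numpy as np
import pytest

from fusionseg.backbone import (
    ASPP,
    ConvBlock,
    Encoder,
    HybridFusionNet,
    NetworkConfig,
    ResConv,
    count_parameters,
    layer_plan,
)
from fusionseg.nn import Tensor


def _rng():
    return np.random.default_rng(0)


class TestBlocks:
    def test_conv_block_parameter_count(self):
        """1->32 channels: 3*3*1*32 kernel values + 2*32 batch-norm values."""
        block = ConvBlock(1, 32, _rng())
        assert block.num_parameters() == 3 * 3 * 1 * 32 + 2 * 32 == 352

    def test_conv_block_zero_input_zero_output_in_eval(self):
        block = ConvBlock(2, 5, _rng()).eval()
        out = block(Tensor(np.zeros((1, 2, 12, 12), dtype=np.float32)))
        np.testing.assert_allclose(out.data, 0.0)
        assert out.shape == (1, 5, 12, 12)

    def test_conv_block_preserves_224(self):
        block = ConvBlock(1, 2, _rng()).eval()
        out = block(Tensor(np.zeros((1, 1, 224, 224), dtype=np.float32)))
        assert out.shape[2:] == (224, 224)

    def test_res_conv_zero_input_zero_output_in_eval(self):
        rc = ResConv(3, 6, 0.2, _rng()).eval()
        out = rc(Tensor(np.zeros((1, 3, 8, 8), dtype=np.float32)))
        np.testing.assert_allclose(out.data, 0.0)

    def test_res_conv_residual_path_isolation(self):
        """With conv weights zeroed, only the 1x1 projection passes through."""
        rc = ResConv(2, 2, 0.0, _rng()).eval()
        for name, p in rc.named_parameters():
            p.data[...] = 0.0
        # identity-like projection: each output channel copies its input channel
        rc.proj.weight.data[...] = 0.0
        for c in range(2):
            rc.proj.weight.data[c, c, 0, 0] = 1.0
        x = np.random.default_rng(1).standard_normal((1, 2, 8, 8)).astype(np.float32)
        out = rc(Tensor(x))
        np.testing.assert_allclose(out.data, x, atol=1e-6)

    def test_res_conv_default_doubling(self):
        cfg = NetworkConfig(base_filters=4)
        plan = layer_plan(cfg)
        assert plan.encoder_out == [4, 8, 16, 32]  # each layer doubles


class TestEncoder:
    def test_four_layer_encoder_downscales_by_16(self):
        cfg = NetworkConfig(n_modalities=1, base_filters=2, multi_modal=False)
        enc = Encoder(1, cfg, _rng()).eval()
        pooled, skips = enc(Tensor(np.zeros((1, 1, 224, 224), dtype=np.float32)))
        assert pooled.shape[2:] == (14, 14)  # 224 / 2^4
        assert [s.shape[2] for s in skips] == [224, 112, 56, 28]

    def test_indivisible_input_rejected(self):
        cfg = NetworkConfig(base_filters=2)
        enc = Encoder(1, cfg, _rng())
        with pytest.raises(ValueError, match="not divisible"):
            enc(Tensor(np.zeros((1, 1, 36, 36), dtype=np.float32)))

    def test_inference_is_deterministic(self):
        cfg = NetworkConfig(base_filters=2, n_layers=2)
        enc = Encoder(1, cfg, _rng()).eval()
        x = Tensor(np.random.default_rng(2).standard_normal((1, 1, 16, 16)).astype(np.float32))
        a, _ = enc(x)
        b, _ = enc(x)
        np.testing.assert_array_equal(a.data, b.data)


class TestASPP:
    @pytest.mark.parametrize("dilations", [(1, 6, 12, 18), (1,), (2, 4)])
    def test_spatial_size_and_channels_preserved(self, dilations):
        aspp = ASPP(6, dilations, _rng()).eval()
        out = aspp(Tensor(np.random.default_rng(0).standard_normal((2, 6, 14, 14)).astype(np.float32)))
        assert out.shape == (2, 6, 14, 14)


class TestNetwork:
    def test_end_to_end_shape_law(self, tiny_cfg, tiny_net):
        x = np.random.default_rng(0).standard_normal((2, 4, 32, 32)).astype(np.float32)
        out = tiny_net(Tensor(x))
        assert out.shape == (2, tiny_cfg.n_classes, 32, 32)

    def test_decoder_restores_16x_at_224(self):
        cfg = NetworkConfig(n_modalities=2, base_filters=2, seed=0)
        net = HybridFusionNet(cfg).eval()
        x = np.zeros((1, 2, 224, 224), dtype=np.float32)
        pyramid = net.encode(Tensor(x))
        assert pyramid.bottleneck[0].shape[2:] == (14, 14)
        out = net.decode(pyramid)
        assert out.shape == (1, 4, 224, 224)

    def test_zero_input_zero_logits_with_zero_end_bias(self, tiny_net):
        tiny_net.end_conv.bias.data[...] = 0.0
        out = tiny_net(Tensor(np.zeros((1, 4, 32, 32), dtype=np.float32)))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-6)

    def test_bottleneck_merge_is_order_sensitive(self):
        """Concatenation is ordered, so modality order changes the output."""
        cfg = NetworkConfig(n_modalities=2, n_layers=2, base_filters=2, seed=3)
        net = HybridFusionNet(cfg).eval()
        rng = np.random.default_rng(4)
        x = rng.standard_normal((1, 2, 16, 16)).astype(np.float32)
        out1 = net(Tensor(x)).data
        out2 = net(Tensor(x[:, ::-1].copy())).data
        assert not np.allclose(out1, out2)

    def test_wrong_modality_count_rejected(self, tiny_net):
        with pytest.raises(ValueError, match="modalities"):
            tiny_net(Tensor(np.zeros((1, 3, 32, 32), dtype=np.float32)))


class TestParameterAccounting:
    @pytest.mark.parametrize("use_hafb", [True, False])
    @pytest.mark.parametrize("multi", [True, False])
    def test_analytic_count_matches_assembled_network(self, use_hafb, multi):
        cfg = NetworkConfig(
            n_modalities=3, n_layers=3, base_filters=4, use_hafb=use_hafb, multi_modal=multi
        )
        assert count_parameters(cfg) == HybridFusionNet(cfg).num_parameters()

    def test_multi_modal_with_fusion_scales_affinely(self):
        """Constant first differences of the count over 1..6 modalities."""
        counts = [
            count_parameters(NetworkConfig(n_modalities=n, use_hafb=True)) for n in range(1, 7)
        ]
        diffs = np.diff(counts)
        assert len(set(diffs.tolist())) == 1

    def test_multi_modal_without_fusion_scales_quadratically(self):
        """Constant second differences (and growing first differences)."""
        counts = [
            count_parameters(NetworkConfig(n_modalities=n, use_hafb=False)) for n in range(1, 7)
        ]
        d1 = np.diff(counts)
        d2 = np.diff(d1)
        assert len(set(d2.tolist())) == 1
        assert (d1[1:] > d1[:-1]).all()

    def test_fusion_parameter_crossover(self):
        """Fusion costs parameters at few modalities, saves them at many."""
        for n in (1, 2):
            plain = count_parameters(NetworkConfig(n_modalities=n, use_hafb=False))
            fused = count_parameters(NetworkConfig(n_modalities=n, use_hafb=True))
            assert fused > plain
        for n in (4, 5, 6):
            plain = count_parameters(NetworkConfig(n_modalities=n, use_hafb=False))
            fused = count_parameters(NetworkConfig(n_modalities=n, use_hafb=True))
            assert fused < plain

    def test_single_modal_count_nearly_constant_in_modalities(self):
        counts = [
            count_parameters(NetworkConfig(n_modalities=n, multi_modal=False))
            for n in range(1, 7)
        ]
        spread = max(counts) - min(counts)
        assert spread / counts[0] < 1e-3  # only the first conv widens


def test_config_validation_and_yaml_roundtrip(tmp_path):
    with pytest.raises(ValueError, match="distinct"):
        NetworkConfig(aspp_dilations=(1, 1, 6))
    with pytest.raises(ValueError, match="n_layers"):
        NetworkConfig(n_layers=0)
    cfg = NetworkConfig(base_filters=8, use_hafb=False)
    path = tmp_path / "net.yaml"
    cfg.to_yaml(path)
    assert NetworkConfig.from_yaml(path) == cfg
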