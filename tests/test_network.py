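"""Assembled network: stage-shape conformance, patch expansion, scaling,
determinism and gradient flow."""

import numpy as np
import pytest

from mambaseg.config import NetworkConfig, tiny_network
from mambaseg.network import (
    PatchExpand,
    SegmentationNetwork,
    build_network,
    count_parameters,
    summary,
)
from mambaseg.nn import Conv2d, Tensor, no_grad


@pytest.fixture(scope="module")
def tiny_net():
    return build_network(tiny_network())


class TestPatchExpand:
    @pytest.mark.parametrize("h,w,c,exp_c", [(28, 28, 128, 64), (7, 7, 192, 96), (4, 4, 10, 5)])
    def test_shapes(self, h, w, c, exp_c, rng):
        pe = PatchExpand(c, rng)
        with no_grad():
            out = pe(Tensor(rng.standard_normal((1, c, h, w)).astype(np.float32)))
        assert out.shape == (1, exp_c, 2 * h, 2 * w)

    def test_odd_channels_rejected(self, rng):
        with pytest.raises(ValueError):
            PatchExpand(5, rng)

    def test_expand_inverts_merge_shapes(self, rng):
        from mambaseg.vss import PatchMerge
        x = Tensor(rng.standard_normal((1, 8, 6, 6)).astype(np.float32))
        with no_grad():
            merged = PatchMerge(8, rng)(x)          # (1, 16, 3, 3)... needs even
            back = PatchExpand(16, rng)(merged)
        assert back.shape == x.shape


class TestAssembly:
    def test_tiny_stage_table(self, tiny_net):
        rows = summary(tiny_net)
        assert rows == [
            ("input", "64x64", 3), ("enc1", "32x32", 8), ("enc2", "16x16", 12),
            ("enc3", "8x8", 20), ("enc4", "4x4", 28), ("bridge", "2x2", 48),
            ("D4", "4x4", 28), ("D3", "8x8", 20), ("D2", "16x16", 12),
            ("D1", "32x32", 8), ("output", "64x64", 2),
        ]

    def test_n_classes_head_contract(self, rng):
        cfg = tiny_network()
        cfg.n_classes = 3
        net = build_network(cfg)
        x = np.random.default_rng(0).uniform(0, 1, (1, 3, 64, 64)).astype(np.float32)
        res = net.predict_batch(x)
        assert res.probabilities.shape == (1, 64, 64, 3)
        assert res.labels.max() < 3

    def test_fully_convolutional_input_scaling(self, tiny_net):
        x = np.random.default_rng(0).uniform(0, 1, (1, 3, 96, 96)).astype(np.float32)
        res = tiny_net.predict_batch(x)
        assert res.probabilities.shape == (1, 96, 96, 2)
        n_before = count_parameters(tiny_net)
        summary(tiny_net, input_size=96)
        assert count_parameters(tiny_net) == n_before

    def test_probabilities_sum_to_one_and_determinism(self, tiny_net):
        x = np.random.default_rng(1).uniform(0, 1, (2, 3, 64, 64)).astype(np.float32)
        r1 = tiny_net.predict_batch(x)
        r2 = tiny_net.predict_batch(x)
        np.testing.assert_allclose(r1.probabilities.sum(-1), 1.0, atol=1e-5)
        np.testing.assert_array_equal(r1.probabilities, r2.probabilities)
        np.testing.assert_array_equal(r1.labels, r2.labels)

    def test_channel_mismatch_rejected(self, tiny_net):
        with pytest.raises(ValueError, match="channels"):
            tiny_net.predict_batch(np.zeros((1, 5, 64, 64), dtype=np.float32))

    def test_invalid_config_rejected_before_build(self):
        with pytest.raises(ValueError):
            NetworkConfig(input_size=100)
        with pytest.raises(ValueError):
            NetworkConfig(n_classes=1)


class TestStructure:
    def test_attention_only_in_bridge_and_decoder(self, tiny_net):
        """SAB/CAB sit in the bottleneck and decoder stages, not the encoder."""
        from mambaseg.attention import AttentionBridge
        assert isinstance(tiny_net.bridge_attn, AttentionBridge)
        for stage in tiny_net.decoder:
            assert isinstance(stage.attn, AttentionBridge)
        encoder_mods = list(tiny_net.encoder.modules())
        for stack in tiny_net.encoder_vss:
            encoder_mods.extend(stack.modules())
        assert not any(isinstance(m, AttentionBridge) for m in encoder_mods)

    def test_decoder_concatenates_skip_first(self, rng):
        """The fusion input is [skip, upsampled] in that channel order."""
        from mambaseg.config import tiny_network
        from mambaseg.network import DecoderStage
        cfg = tiny_network()
        stage = DecoderStage(up_channels=8, skip_channels=8, out_channels=8, cfg=cfg, rng=rng)
        stage.expand.proj.weight.data[...] = 0.0   # upsampled branch -> all zeros
        captured = {}
        orig_fuse = stage.fuse

        def capture(t):
            captured["x"] = t.data.copy()
            return orig_fuse(t)

        stage.fuse = capture
        up = Tensor(rng.standard_normal((1, 8, 2, 2)).astype(np.float32))
        skip = Tensor(np.full((1, 8, 4, 4), 7.0, dtype=np.float32))
        with no_grad():
            stage.forward(up, skip)
        np.testing.assert_array_equal(captured["x"][:, :8], 7.0)   # skip first
        np.testing.assert_array_equal(captured["x"][:, 8:], 0.0)   # upsampled second

    def test_decoder_spatial_mismatch_rejected(self, rng):
        from mambaseg.config import tiny_network
        from mambaseg.network import DecoderStage
        stage = DecoderStage(8, 8, 8, tiny_network(), rng)
        with pytest.raises(ValueError, match="mismatch"):
            with no_grad():
                stage.forward(Tensor(np.zeros((1, 8, 2, 2), np.float32)),
                              Tensor(np.zeros((1, 8, 8, 8), np.float32)))


class TestParameters:
    def test_hand_counted_1x1_conv(self, rng):
        conv = Conv2d(4, 2, 1, rng)
        assert sum(p.size for p in conv.parameters()) == 4 * 2 + 2

    def test_freezing_all_weights_counts_zero(self, tiny_net):
        for p in tiny_net.parameters():
            p.requires_grad = False
        try:
            assert count_parameters(tiny_net) == 0
        finally:
            for p in tiny_net.parameters():
                p.requires_grad = True

    def test_seed_reproducible_initialization(self):
        a = build_network(tiny_network())
        b = build_network(tiny_network())
        for (n1, p1), (n2, p2) in zip(a.named_parameters(), b.named_parameters()):
            assert n1 == n2
            np.testing.assert_array_equal(p1.data, p2.data)


class TestGradientFlow:
    def test_every_parameter_receives_gradient_after_one_step(self):
        """After one optimization step on a toy batch, a second backward pass
        reaches every trainable array (residual branches start zero-initialized,
        so the first step is what opens them)."""
        from mambaseg.losses import LossConfig, hybrid_loss_tensor
        from mambaseg.nn import AdamW
        net = build_network(tiny_network())
        net.train()
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, (2, 3, 64, 64)).astype(np.float32)
        g = (rng.random((2, 64, 64)) > 0.9).astype(np.uint8)
        opt = AdamW(net.parameters(), lr=1e-3)
        for _ in range(2):
            phi = net.foreground_probability(Tensor(x))
            total, _, _ = hybrid_loss_tensor(phi, g, LossConfig())
            opt.zero_grad()
            total.backward()
            opt.step()
        missing = [n for n, p in net.named_parameters()
                   if p.grad is None or not np.any(p.grad)]
        assert missing == []
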