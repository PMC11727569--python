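"""Architecture contracts: shapes, attention ranges, residual shortcut."""

import numpy as np
import pytest

from myogest.nn import Tensor
from myogest.network import (
    BIG_SCALE, SMALL_SCALE, AttentionCNNClassifier, ChannelAttention,
    ModelConfig, MultiScaleAttentionCNN, MultiScaleBlock, MultiScaleConvLSTM,
    ResidualCBAM, SpatialAttention, StackedBiLSTMClassifier, TemporalFuse,
)

rng = np.random.default_rng(0)
CFG = ModelConfig(n_classes=4, seed=0)


def test_scale_params_table_constants():
    assert (SMALL_SCALE.k_time_a, SMALL_SCALE.k_time_b, SMALL_SCALE.k_chan) == (5, 8, 2)
    assert (BIG_SCALE.k_time_a, BIG_SCALE.k_time_b, BIG_SCALE.k_chan) == (10, 20, 4)
    assert SMALL_SCALE.pool == (2, 2) and SMALL_SCALE.n_kernels == 8
    assert CFG.ms_out_channels == 32


@pytest.mark.parametrize("scale", [SMALL_SCALE, BIG_SCALE])
def test_ms_block_output_geometry(scale):
    block = MultiScaleBlock(1, scale, np.random.default_rng(1))
    x = Tensor(rng.standard_normal((1, 400, 12, 1)))
    out = block(x)
    assert out.shape == (1, 400, 12, 32)  # 4 branches x 8 kernels, spatial preserved


def test_ms_block_zero_input_zero_output():
    block = MultiScaleBlock(1, SMALL_SCALE, np.random.default_rng(1))
    out = block(Tensor(np.zeros((2, 30, 8, 1))))
    np.testing.assert_allclose(out.data, 0.0)  # biases init to zero, ReLU(0)=0


def test_ms_block_rejects_too_small_input():
    block = MultiScaleBlock(1, BIG_SCALE, np.random.default_rng(1))
    with pytest.raises(ValueError):
        block(Tensor(np.zeros((1, 10, 2, 1))))


def test_channel_attention_range_and_zero_weights():
    attn = ChannelAttention(32, 8, np.random.default_rng(2))
    x = Tensor(rng.standard_normal((3, 10, 4, 32)))
    w = attn(x).data
    assert w.shape == (3, 32)
    assert np.all((w > 0) & (w < 1))

    for p in attn.parameters():
        p.data = np.zeros_like(p.data)
    np.testing.assert_allclose(attn(x).data, 0.5)


def test_channel_attention_constant_input_pools_agree():
    x = np.full((2, 6, 4, 32), 3.7)
    t = Tensor(x)
    avg = t.mean(axis=(1, 2)).data
    mx = t.max(axis=1).max(axis=1).data
    np.testing.assert_allclose(avg, mx)


def test_channel_attention_reduction_contract():
    with pytest.raises(ValueError):
        ChannelAttention(4, 8, np.random.default_rng(0))


def test_spatial_attention_shape_and_zero_kernel():
    attn = SpatialAttention(2, np.random.default_rng(3))
    x = Tensor(rng.standard_normal((1, 400, 12, 32)))
    m = attn(x).data
    assert m.shape == (1, 400, 12, 1)  # 2x2 kernel, size preserved
    assert np.all((m > 0) & (m < 1))

    attn.conv.weight.data = np.zeros_like(attn.conv.weight.data)
    attn.conv.bias.data = np.zeros_like(attn.conv.bias.data)
    np.testing.assert_allclose(attn(x).data, 0.5)


def test_spatial_attention_channel_constant_input():
    x = Tensor(np.broadcast_to(rng.standard_normal((1, 8, 4, 1)), (1, 8, 4, 32)).copy())
    avg = x.mean(axis=3, keepdims=True).data
    mx = x.max(axis=3, keepdims=True).data
    np.testing.assert_allclose(avg, mx)


def _zero_residual(block: ResidualCBAM) -> None:
    for conv in (block.residual.conv1, block.residual.conv2):
        conv.weight.data = np.zeros_like(conv.weight.data)
        conv.bias.data = np.zeros_like(conv.bias.data)
    for bn in (block.residual.bn1, block.residual.bn2):
        bn.beta.data = np.zeros_like(bn.beta.data)


def test_rescbam_identity_shortcut():
    """Residual branch zeroed + attention forced to 1 -> output = ReLU(x)."""
    block = ResidualCBAM(32, CFG, np.random.default_rng(4)).eval()
    _zero_residual(block)
    block.apply_attention = lambda x: x  # force both attention maps to 1
    x = rng.standard_normal((2, 20, 6, 32))
    out = block(Tensor(x))
    np.testing.assert_allclose(out.data, np.maximum(x, 0.0))


def test_rescbam_attention_oracle():
    """With the residual branch zeroed, output equals the element-wise
    attention-scaled input (recomputed from the two attention maps)."""
    block = ResidualCBAM(32, CFG, np.random.default_rng(4)).eval()
    _zero_residual(block)
    x = np.abs(rng.standard_normal((2, 20, 6, 32)))  # non-negative input
    t = Tensor(x)
    cw = block.channel_attn(t).data            # (B, C)
    y = x * cw[:, None, None, :]
    sm = block.spatial_attn(Tensor(y)).data    # (B, L, T, 1)
    expected = np.maximum(y * sm, 0.0)
    np.testing.assert_allclose(block(t).data, expected, atol=1e-12)


def test_rescbam_preserves_shape():
    block = ResidualCBAM(32, CFG, np.random.default_rng(4)).eval()
    x = Tensor(rng.standard_normal((3, 24, 8, 32)))
    assert block(x).shape == x.shape


def test_rescbam_shortcut_gradient_transparency():
    """With the residual unit zeroed and attention bypassed, the input
    gradient equals the output gradient masked by the ReLU derivative."""
    block = ResidualCBAM(32, CFG, np.random.default_rng(4)).eval()
    _zero_residual(block)
    block.apply_attention = lambda x: x
    x = rng.standard_normal((1, 8, 4, 32))
    t = Tensor(x, requires_grad=True)
    coef = rng.standard_normal(x.shape)
    (block(t) * Tensor(coef)).sum().backward()
    np.testing.assert_allclose(t.grad, coef * (x > 0), atol=1e-12)


def test_temporal_fuse_step_width():
    fuse = TemporalFuse(32, CFG, np.random.default_rng(5))
    small = Tensor(rng.standard_normal((2, 400, 12, 32)))
    big = Tensor(rng.standard_normal((2, 400, 12, 32)))
    out = fuse(small, big)
    assert out.shape == (2, CFG.tau, 128)  # every step vector has 128 entries

    zeros = Tensor(np.zeros((1, 40, 4, 32)))
    np.testing.assert_allclose(fuse(zeros, zeros).data, 0.0)


def test_temporal_fuse_time_mismatch():
    fuse = TemporalFuse(32, CFG, np.random.default_rng(5))
    with pytest.raises(ValueError):
        fuse(Tensor(np.zeros((1, 40, 4, 32))), Tensor(np.zeros((1, 32, 4, 32))))


def test_full_forward_probabilities():
    model = MultiScaleConvLSTM(ModelConfig(n_classes=5, seed=1)).eval()
    x = rng.standard_normal((3, 64, 8, 1))
    probs = model.predict_proba(x)
    assert probs.shape == (3, 5)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(probs >= 0)


def test_identical_images_identical_rows():
    model = MultiScaleConvLSTM(ModelConfig(n_classes=4, seed=1)).eval()
    img = rng.standard_normal((1, 64, 8, 1))
    batch = np.repeat(img, 4, axis=0)
    probs = model.predict_proba(batch)
    np.testing.assert_allclose(probs, np.tile(probs[0], (4, 1)), atol=1e-12)


def test_output_unit_permutation_permutes_probs():
    model = MultiScaleConvLSTM(ModelConfig(n_classes=4, seed=1)).eval()
    x = rng.standard_normal((2, 64, 8, 1))
    base = model.predict_proba(x)
    perm = np.array([2, 0, 3, 1])
    model.classifier.weight.data = model.classifier.weight.data[:, perm]
    model.classifier.bias.data = model.classifier.bias.data[perm]
    permuted = model.predict_proba(x)
    np.testing.assert_allclose(permuted, base[:, perm], atol=1e-12)


def test_architecture_constants_audit():
    """Default-mode audit: 128-dim fused steps, 256-dim recurrent output."""
    model = MultiScaleConvLSTM(ModelConfig(n_classes=4, seed=0)).eval()
    inter = {}
    model.forward_logits(Tensor(rng.standard_normal((1, 64, 8, 1))), intermediates=inter)
    assert inter["fused"].shape[2] == 128
    assert inter["recurrent"].shape[1] == 256


def test_dropout_zero_recurrent_head_train_eval_identical():
    """With dropout_p = 0 the Bi-LSTM head + classifier (which carry no
    batch statistics) produce identical outputs in train and eval mode."""
    cfg = ModelConfig(n_classes=3, dropout_p=0.0, seed=2)
    model = MultiScaleConvLSTM(cfg)
    seq = Tensor(rng.standard_normal((2, cfg.tau, cfg.fused_dim)))
    model.train()
    _, feat = model.bilstm(seq)
    a = model.classifier(model.dropout(feat)).data
    model.eval()
    _, feat = model.bilstm(seq)
    b = model.classifier(model.dropout(feat)).data
    np.testing.assert_allclose(a, b)


def test_stacked_bilstm_has_no_conv_parameters():
    model = StackedBiLSTMClassifier(ModelConfig(n_classes=4, seed=0), n_channels=8)
    from myogest.nn.layers import Conv2d
    assert not any(isinstance(m, Conv2d) for m in _walk(model))


def _walk(module):
    yield module
    for sub in module._modules():
        yield from _walk(sub)


def test_ablation_parameter_ordering():
    cfg = ModelConfig(n_classes=4, seed=0)
    m3 = MultiScaleAttentionCNN(cfg)
    m4 = MultiScaleConvLSTM(cfg)
    assert m3.n_parameters() < m4.n_parameters()


def test_all_ones_attention_is_noop():
    x = rng.standard_normal((2, 8, 4, 32))
    t = Tensor(x)
    np.testing.assert_array_equal((t * Tensor(np.ones((2, 1, 1, 32)))).data, x)
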