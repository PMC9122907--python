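"""Architecture family: configs, blocks, presets, prediction."""

import numpy as np
import pytest

from fazseg.engine import ChannelAttention, Conv2D
from fazseg.models import (
    PRESETS, ArchitectureConfig, ConvBlock, NarrowingMidblock,
    SegmentationModel, attention_block, build_model, conv_block,
    count_parameters, narrowing_midblock, predict,
)

PUBLISHED_TOTALS = {
    "Unet": 28_340_931,
    "Unet_AB": 29_830_275,
    "Unet_AB_Upsampling": 24_466_627,
    "Unet_AB_Upsampling_Add": 12_259_523,
    "Unet_AB_128_Upsampling_Add": 2_673_795,
    "Unet_AB_64_Upsampling_Add": 673_347,
    "LWBNA_Unet": 2_958_819,
}


# ---------------------------------------------------------------- config

def test_config_invariants_rejected():
    with pytest.raises(ValueError):
        ArchitectureConfig(base_or_fixed_width=48)       # not a power of two
    with pytest.raises(ValueError):
        ArchitectureConfig(input_height=100)             # not divisible by 16
    with pytest.raises(ValueError):                      # midblock needs attention
        ArchitectureConfig(attention_enabled=False, midblock_min_channels=16)
    with pytest.raises(ValueError):                      # min must divide width
        ArchitectureConfig(width_policy="fixed", base_or_fixed_width=128,
                           attention_enabled=True, skip_mode="add",
                           up_mode="upsample", midblock_min_channels=256)
    with pytest.raises(ValueError):
        ArchitectureConfig(dropout_rate=1.0)


def test_config_json_roundtrip():
    cfg = ArchitectureConfig(width_policy="fixed", base_or_fixed_width=64,
                             attention_enabled=True, skip_mode="add",
                             up_mode="upsample", midblock_min_channels=8)
    again = ArchitectureConfig.from_json(cfg.to_json())
    assert again == cfg


# ---------------------------------------------------------------- blocks

def test_conv_block_zero_weights_give_zero_output(rng):
    x = rng.random((1, 8, 8, 1), dtype=np.float32)
    block = ConvBlock(1, 1, rng=rng, batch_norm=False)
    block.conv.W[...] = 0.0
    block.conv.b[...] = 0.0
    assert np.all(conv_block(x, 1, block=block) == 0.0)


def test_conv_block_parameter_handcounts(rng):
    # 3x3 conv 1->1 with bias: 3*3*1*1 + 1 = 10 weights
    assert Conv2D(1, 1, k=3, rng=rng).n_params == 10
    # single 1x1 conv 1->1 with bias: 2 parameters
    assert Conv2D(1, 1, k=1, rng=rng).n_params == 2


def test_conv_block_same_padding_preserves_shape(rng):
    x = rng.random((1, 16, 16, 4), dtype=np.float32)
    y = conv_block(x, 12, rng=rng)
    assert y.shape == (1, 16, 16, 12)
    assert (y >= 0).all()                                # rectified
    with pytest.raises(ValueError):
        ConvBlock(4, 0, rng=rng)


def test_attention_zero_weights_halve_input(rng):
    x = rng.random((2, 5, 5, 4), dtype=np.float32)
    att = ChannelAttention(4, rng=rng)
    att.W[...] = 0.0
    att.b[...] = 0.0
    np.testing.assert_allclose(attention_block(x, att=att), x / 2, rtol=1e-6)


def test_attention_weights_bounded_below_and_above(rng):
    att = ChannelAttention(8, rng=rng)
    att.W[...] = rng.standard_normal(att.W.shape).astype(np.float32)
    att.b[...] = rng.standard_normal(8).astype(np.float32)
    x = rng.standard_normal((64, 4, 4, 8)).astype(np.float32)
    wts = att.weights_for(x)
    assert wts.min() >= 0.5
    assert wts.max() < 1.0          # strict in exact arithmetic; float32
    # saturation can only ever reach 1.0 from below
    att.W[...] *= 50
    assert att.weights_for(x * 50).max() <= 1.0


def test_attention_permutation_equivariance(rng):
    att = ChannelAttention(5, rng=rng)
    x = rng.random((1, 3, 3, 5), dtype=np.float32)
    w = att.weights_for(x)
    perm = np.array([3, 0, 4, 1, 2])
    att2 = ChannelAttention(5, rng=rng)
    att2.W[...] = att.W[np.ix_(perm, perm)]
    att2.b[...] = att.b[perm]
    w2 = att2.weights_for(x[..., perm])
    np.testing.assert_allclose(w2, w[:, perm], rtol=1e-5)


def test_midblock_channel_sequence_and_shapes(rng):
    mid = NarrowingMidblock(128, 16, rng=rng)
    assert mid.channel_sequence == [128, 128, 64, 32, 16]
    mid8 = NarrowingMidblock(128, 8, rng=rng)
    assert len(mid8.stages) == len(mid.stages) + 1       # one more halving
    x = rng.random((1, 4, 4, 16), dtype=np.float32)
    y = narrowing_midblock(x, 4, rng=rng)
    assert y.shape == x.shape                            # no pooling inside
    with pytest.raises(ValueError):
        NarrowingMidblock(64, 128, rng=rng)


# ---------------------------------------------------------------- presets

@pytest.mark.parametrize("name", list(PRESETS))
def test_preset_parameter_counts_match_published_totals(name):
    model = build_model(name, seed=0, input_size=(64, 64))
    assert count_parameters(model) == PUBLISHED_TOTALS[name]


def test_parameter_count_invariant_to_input_size():
    for name in ("LWBNA_Unet", "Unet_AB_64_Upsampling_Add"):
        a = build_model(name, seed=0, input_size=(64, 64))
        b = build_model(name, seed=0, input_size=(96, 96))
        assert a.parameter_count == b.parameter_count


def test_preset_ordering_matches_published_table():
    counts = [build_model(n, seed=0, input_size=(64, 64)).parameter_count
              for n in PRESETS]
    published = [PUBLISHED_TOTALS[n] for n in PRESETS]
    assert np.argsort(counts).tolist() == np.argsort(published).tolist()


def test_unknown_preset_error_lists_valid_names():
    with pytest.raises(ValueError, match="LWBNA_Unet"):
        build_model("NotAModel")


# ---------------------------------------------------------------- predict

def test_predict_output_range_shape_and_determinism(tiny_model, rng):
    x = rng.random((3, 32, 32, 3), dtype=np.float32)
    p1 = predict(tiny_model, x)
    assert p1.shape == (3, 32, 32, 1)
    assert (p1 > 0).all() and (p1 < 1).all()
    p2 = tiny_model.predict(x)
    np.testing.assert_array_equal(p1, p2)                # bitwise determinism


def test_predict_batch_order_and_duplicates(tiny_model, rng):
    x = rng.random((2, 32, 32, 3), dtype=np.float32)
    batch = np.stack([x[0], x[1], x[0]])
    p = tiny_model.predict(batch)
    np.testing.assert_array_equal(p[0], p[2])            # duplicates identical
    np.testing.assert_array_equal(p[1], tiny_model.predict(x[1:2])[0])


def test_predict_shape_mismatch_is_reported(tiny_model, rng):
    with pytest.raises(ValueError, match="32"):
        tiny_model.predict(rng.random((1, 16, 16, 3), dtype=np.float32))


def test_same_seed_builds_identical_models(tiny_arch, rng):
    x = rng.random((1, 32, 32, 3), dtype=np.float32)
    a = build_model(tiny_arch, seed=11)
    b = build_model(tiny_arch, seed=11)
    np.testing.assert_array_equal(a.predict(x), b.predict(x))
    c = build_model(tiny_arch, seed=12)
    assert not np.array_equal(a.predict(x), c.predict(x))
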