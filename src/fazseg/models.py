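"""The lightweight attention U-Net family for en-face OCTA segmentation.

The family covers the conventional U-Net, its channel-attention variants,
the parameter-trimmed fixed-width variants (upsampling + additive skips)
and the bottleneck-narrowing-with-attention network (``LWBNA_Unet``).
Architectural details that the published description leaves implicit
(decoder width schedule, attention placement, merge order, the exact
make-up of the narrowing midblock) were reconstructed so that every
preset reproduces its published total parameter count exactly; see
``docs/methods.md`` for the resolved layout.

Key structural facts:

* A convolutional block is a 3x3 same-padding convolution with bias,
  batch normalization and ReLU; two blocks per resolution level.
* Channel attention is a single dense C -> C map on globally averaged
  channels, rectified then passed through the logistic function, so all
  attention weights lie in [0.5, 1).
* Decoder conv widths are half the incoming skip width (floored at the
  base width) in the doubling models, and the fixed width otherwise.
* Transposed convolutions are 3x3, stride 2, mapped to the skip width,
  with bias but no batch normalization.
* In additive-skip models the bottleneck keeps the deepest encoder
  width; in concatenating models it doubles.
* The output head is a 3x3 convolution to three sigmoid channels (masks
  are handled as RGB images); ``predict`` averages them into a single
  probability map.
* The narrowing midblock (when enabled) sits after the two bottleneck
  conv blocks: a plain W -> W convolution, successive channel-halving
  convolutions down to ``midblock_min_channels`` each followed by
  attention, a restoring convolution back to W, an additive skip from
  the midblock input, and a final attention block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .engine import (
    Adam, BatchNorm, ChannelAttention, Conv2D, ConvTranspose2D, Dropout,
    MaxPool2, ReLU, Sigmoid, UpSample2,
)

__all__ = [
    "ArchitectureConfig", "SegmentationModel", "PRESETS", "build_model",
    "count_parameters", "predict", "ConvBlock", "conv_block",
    "attention_block", "narrowing_midblock", "NarrowingMidblock",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class ArchitectureConfig:
    """Declarative description of one member of the model family."""

    input_height: int = 320
    input_width: int = 320
    input_channels: int = 3
    width_policy: str = "doubling"          # {"doubling", "fixed"}
    base_or_fixed_width: int = 64
    depth: int = 4                           # pooling levels
    attention_enabled: bool = False
    skip_mode: str = "concatenate"           # {"concatenate", "add"}
    up_mode: str = "transpose"               # {"transpose", "upsample"}
    midblock_min_channels: Optional[int] = None
    dropout_rate: float = 0.2
    output_channels: int = 1
    output_activation: str = "logistic"
    # attention placement flags reconstructed from the published totals;
    # None means "derive from the other fields" (see __post_init__).
    att_bottleneck: Optional[bool] = None
    att_final: Optional[bool] = None

    def __post_init__(self):
        if self.width_policy not in ("doubling", "fixed"):
            raise ValueError(f"unknown width_policy {self.width_policy!r}")
        if self.skip_mode not in ("concatenate", "add"):
            raise ValueError(f"unknown skip_mode {self.skip_mode!r}")
        if self.up_mode not in ("transpose", "upsample"):
            raise ValueError(f"unknown up_mode {self.up_mode!r}")
        w = self.base_or_fixed_width
        if w < 1 or (w & (w - 1)):
            raise ValueError("base_or_fixed_width must be a power of two")
        m = self.midblock_min_channels
        if m is not None:
            if not self.attention_enabled:
                raise ValueError(
                    "midblock (narrowing of channels with attention) requires "
                    "attention_enabled")
            if m < 1 or (m & (m - 1)) or m > w or w % m:
                raise ValueError(
                    "midblock_min_channels must be a power of two dividing "
                    "the bottleneck width")
        d = self.depth
        if self.input_height % (1 << d) or self.input_width % (1 << d):
            raise ValueError(
                f"input dims must be divisible by 2^depth = {1 << d}")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.att_bottleneck is None:
            # attention at the (widened) bottleneck only in the
            # transposed-convolution family
            self.att_bottleneck = (
                self.attention_enabled and self.up_mode == "transpose")
        if self.att_final is None:
            # the fixed-width (lightweight) family carries one extra
            # attention block before the output head
            self.att_final = (
                self.attention_enabled and self.width_policy == "fixed")

    # ---- derived width schedule ------------------------------------
    @property
    def encoder_widths(self):
        if self.width_policy == "fixed":
            return [self.base_or_fixed_width] * self.depth
        return [self.base_or_fixed_width * (1 << i) for i in range(self.depth)]

    @property
    def bottleneck_width(self):
        last = self.encoder_widths[-1]
        if self.width_policy == "fixed" or self.skip_mode == "add":
            return last
        return 2 * last

    @property
    def decoder_widths(self):
        """Decoder conv width per level, deepest first."""
        if self.width_policy == "fixed":
            return [self.base_or_fixed_width] * self.depth
        base = self.base_or_fixed_width
        return [max(w // 2, base) for w in reversed(self.encoder_widths)]

    # ---- (de)serialisation ------------------------------------------
    def to_dict(self):
        return asdict(self)

    @classmethod
    def from_dict(cls, d):
        return cls(**d)

    def to_json(self):
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s):
        return cls.from_dict(json.loads(s))


def _preset_configs(h=320, w=320):
    common = dict(input_height=h, input_width=w)
    return {
        "Unet": ArchitectureConfig(
            width_policy="doubling", attention_enabled=False,
            skip_mode="concatenate", up_mode="transpose", **common),
        "Unet_AB": ArchitectureConfig(
            width_policy="doubling", attention_enabled=True,
            skip_mode="concatenate", up_mode="transpose", **common),
        "Unet_AB_Upsampling": ArchitectureConfig(
            width_policy="doubling", attention_enabled=True,
            skip_mode="concatenate", up_mode="upsample", **common),
        "Unet_AB_Upsampling_Add": ArchitectureConfig(
            width_policy="doubling", attention_enabled=True,
            skip_mode="add", up_mode="upsample", **common),
        "Unet_AB_128_Upsampling_Add": ArchitectureConfig(
            width_policy="fixed", base_or_fixed_width=128,
            attention_enabled=True, skip_mode="add", up_mode="upsample",
            **common),
        "Unet_AB_64_Upsampling_Add": ArchitectureConfig(
            width_policy="fixed", base_or_fixed_width=64,
            attention_enabled=True, skip_mode="add", up_mode="upsample",
            **common),
        "LWBNA_Unet": ArchitectureConfig(
            width_policy="fixed", base_or_fixed_width=128,
            attention_enabled=True, skip_mode="add", up_mode="upsample",
            midblock_min_channels=16, **common),
    }


PRESETS = tuple(_preset_configs())


# --------------------------------------------------------------------------
# building blocks
# --------------------------------------------------------------------------

class ConvBlock:
    """3x3 conv (same padding, bias) + batch normalization + ReLU."""

    def __init__(self, cin, cout, rng=None, batch_norm=True):
        if cout < 1:
            raise ValueError("filters must be >= 1")
        self.conv = Conv2D(cin, cout, k=3, rng=rng)
        self.bn = BatchNorm(cout) if batch_norm else None
        self.relu = ReLU()

    def forward(self, x, training=False):
        y = self.conv.forward(x, training)
        if self.bn is not None:
            y = self.bn.forward(y, training)
        return self.relu.forward(y, training)

    def backward(self, dy):
        dy = self.relu.backward(dy)
        if self.bn is not None:
            dy = self.bn.backward(dy)
        return self.conv.backward(dy)

    def layers(self):
        return [self.conv] + ([self.bn] if self.bn else []) + [self.relu]


class NarrowingMidblock:
    """Bottleneck narrowing of channels with attention.

    A plain W -> W convolution, then channel-halving convolutions down to
    ``min_channels`` (attention after each halving), a restoring
    convolution back to W, an additive skip connection from the midblock
    input, and a final attention block.  The narrowing/restore convs use
    bias + ReLU without batch normalization.
    """

    def __init__(self, width, min_channels, rng=None):
        if min_channels > width:
            raise ValueError("min_channels must not exceed the bottleneck width")
        if min_channels < 1 or (min_channels & (min_channels - 1)):
            raise ValueError("min_channels must be a power of two")
        self.width, self.min_channels = width, min_channels
        self.entry = Conv2D(width, width, k=3, rng=rng)
        self.entry_relu = ReLU()
        self.stages = []
        c = width
        while c > min_channels:
            conv = Conv2D(c, c // 2, k=3, rng=rng)
            c //= 2
            self.stages.append((conv, ReLU(), ChannelAttention(c, rng=rng)))
        self.restore = Conv2D(c, width, k=3, rng=rng)
        self.restore_relu = ReLU()
        self.final_att = ChannelAttention(width, rng=rng)

    @property
    def channel_sequence(self):
        seq = [self.width, self.width]
        c = self.width
        while c > self.min_channels:
            c //= 2
            seq.append(c)
        return seq

    def forward(self, x, training=False):
        y = self.entry_relu.forward(self.entry.forward(x, training), training)
        for conv, relu, att in self.stages:
            y = att.forward(relu.forward(conv.forward(y, training), training),
                            training)
        y = self.restore_relu.forward(self.restore.forward(y, training),
                                      training)
        y = y + x                              # skip connection
        return self.final_att.forward(y, training)

    def backward(self, dy):
        dy = self.final_att.backward(dy)
        dskip = dy
        dy = self.restore.backward(self.restore_relu.backward(dy))
        for conv, relu, att in reversed(self.stages):
            dy = conv.backward(relu.backward(att.backward(dy)))
        dy = self.entry.backward(self.entry_relu.backward(dy))
        return dy + dskip

    def layers(self):
        out = [self.entry, self.entry_relu]
        for conv, relu, att in self.stages:
            out += [conv, relu, att]
        out += [self.restore, self.restore_relu, self.final_att]
        return out


# --------------------------------------------------------------------------
# the model
# --------------------------------------------------------------------------

class SegmentationModel:
    """An encoder–decoder segmentation network built from a config.

    The object owns its weights (NumPy arrays) and exposes forward,
    backward, prediction and (de)serialisation.  Repeated construction
    with the same seed yields bitwise-identical weights.
    """

    def __init__(self, config: ArchitectureConfig, seed: int = 0):
        self.config = config
        self.rng = np.random.default_rng(seed)
        self.dropout_rng = np.random.default_rng(
            np.random.SeedSequence(seed).spawn(1)[0])
        self._build()

    # ---- construction ------------------------------------------------
    def _build(self):
        cfg = self.config
        rng = self.rng
        enc_w = cfg.encoder_widths
        dec_w = cfg.decoder_widths
        wb = cfg.bottleneck_width
        drop = cfg.dropout_rate

        self.enc = []
        cin = cfg.input_channels
        for w in enc_w:
            level = {
                "b1": ConvBlock(cin, w, rng),
                "b2": ConvBlock(w, w, rng),
                "att": ChannelAttention(w, rng=rng) if cfg.attention_enabled else None,
                "pool": MaxPool2(),
                "drop": Dropout(drop, rng=self.dropout_rng),
            }
            self.enc.append(level)
            cin = w

        self.bneck = {
            "b1": ConvBlock(cin, wb, rng),
            "b2": ConvBlock(wb, wb, rng),
            "att": ChannelAttention(wb, rng=rng) if cfg.att_bottleneck else None,
            "mid": (NarrowingMidblock(wb, cfg.midblock_min_channels, rng=rng)
                    if cfg.midblock_min_channels else None),
        }
        cin = wb

        self.dec = []
        for skip_w, dw in zip(reversed(enc_w), dec_w):
            if cfg.up_mode == "transpose":
                up = ConvTranspose2D(cin, skip_w, k=3, rng=rng)
                up_relu = ReLU()
                cin = skip_w
            else:
                up, up_relu = UpSample2(), None
            if cfg.skip_mode == "concatenate":
                merged = cin + skip_w
            else:
                if cin != skip_w:
                    raise ValueError(
                        "additive skip requires matching channel counts; "
                        f"got {cin} vs {skip_w}")
                merged = cin
            level = {
                "up": up, "up_relu": up_relu,
                "drop": Dropout(drop, rng=self.dropout_rng),
                "b1": ConvBlock(merged, dw, rng),
                "b2": ConvBlock(dw, dw, rng),
                "att": ChannelAttention(dw, rng=rng) if cfg.attention_enabled else None,
            }
            self.dec.append(level)
            cin = dw

        self.final_att = (ChannelAttention(cin, rng=rng)
                          if cfg.att_final else None)
        self.head = Conv2D(cin, 3, k=3, rng=rng)
        self.head_sigmoid = Sigmoid()

    def layers(self):
        out = []
        for lv in self.enc:
            out += lv["b1"].layers() + lv["b2"].layers()
            if lv["att"]:
                out.append(lv["att"])
            out += [lv["pool"], lv["drop"]]
        out += self.bneck["b1"].layers() + self.bneck["b2"].layers()
        if self.bneck["att"]:
            out.append(self.bneck["att"])
        if self.bneck["mid"]:
            out += self.bneck["mid"].layers()
        for lv in self.dec:
            out.append(lv["up"])
            if lv["up_relu"]:
                out.append(lv["up_relu"])
            out.append(lv["drop"])
            out += lv["b1"].layers() + lv["b2"].layers()
            if lv["att"]:
                out.append(lv["att"])
        if self.final_att:
            out.append(self.final_att)
        out += [self.head, self.head_sigmoid]
        return out

    # ---- forward / backward -----------------------------------------
    def forward(self, x, training=False):
        cfg = self.config
        x = np.asarray(x, dtype=np.float32)
        skips = []
        for lv in self.enc:
            x = lv["b1"].forward(x, training)
            x = lv["b2"].forward(x, training)
            if lv["att"]:
                x = lv["att"].forward(x, training)
            skips.append(x)
            x = lv["pool"].forward(x, training)
            x = lv["drop"].forward(x, training)
        x = self.bneck["b1"].forward(x, training)
        x = self.bneck["b2"].forward(x, training)
        if self.bneck["att"]:
            x = self.bneck["att"].forward(x, training)
        if self.bneck["mid"]:
            x = self.bneck["mid"].forward(x, training)
        self._concat_splits = []
        for lv, skip in zip(self.dec, reversed(skips)):
            x = lv["up"].forward(x, training)
            if lv["up_relu"]:
                x = lv["up_relu"].forward(x, training)
            x = lv["drop"].forward(x, training)
            if cfg.skip_mode == "concatenate":
                self._concat_splits.append(x.shape[-1])
                x = np.concatenate([x, skip], axis=-1)
            else:
                x = x + skip
            x = lv["b1"].forward(x, training)
            x = lv["b2"].forward(x, training)
            if lv["att"]:
                x = lv["att"].forward(x, training)
        if self.final_att:
            x = self.final_att.forward(x, training)
        x = self.head.forward(x, training)
        return self.head_sigmoid.forward(x, training)

    def backward(self, dy):
        cfg = self.config
        dy = self.head_sigmoid.backward(dy)
        dy = self.head.backward(dy)
        if self.final_att:
            dy = self.final_att.backward(dy)
        dskips = []
        splits = list(self._concat_splits)
        for lv in reversed(self.dec):
            if lv["att"]:
                dy = lv["att"].backward(dy)
            dy = lv["b2"].backward(dy)
            dy = lv["b1"].backward(dy)
            if cfg.skip_mode == "concatenate":
                s = splits.pop()
                dy, dskip = dy[..., :s], dy[..., s:]
            else:
                dskip = dy
            dskips.append(dskip)
            dy = lv["drop"].backward(dy)
            if lv["up_relu"]:
                dy = lv["up_relu"].backward(dy)
            dy = lv["up"].backward(dy)
        if self.bneck["mid"]:
            dy = self.bneck["mid"].backward(dy)
        if self.bneck["att"]:
            dy = self.bneck["att"].backward(dy)
        dy = self.bneck["b2"].backward(dy)
        dy = self.bneck["b1"].backward(dy)
        for lv, dskip in zip(reversed(self.enc), reversed(dskips)):
            dy = lv["drop"].backward(dy)
            dy = lv["pool"].backward(dy)
            dy = dy + dskip
            if lv["att"]:
                dy = lv["att"].backward(dy)
            dy = lv["b2"].backward(dy)
            dy = lv["b1"].backward(dy)
        return dy

    # ---- public API --------------------------------------------------
    @property
    def parameter_count(self) -> int:
        return int(sum(l.n_params for l in self.layers()))

    def predict(self, images) -> np.ndarray:
        """Probability maps for a batch of images.

        Parameters
        ----------
        images : array (N, H, W, C) scaled to [0, 1]

        Returns
        -------
        (N, H, W, 1) array of probabilities in (0, 1); the three sigmoid
        output channels are averaged into a single map.
        """
        images = np.asarray(images, dtype=np.float32)
        if images.ndim == 3:
            images = images[None]
        cfg = self.config
        expected = (cfg.input_height, cfg.input_width, cfg.input_channels)
        if images.shape[1:] != expected:
            raise ValueError(
                f"expected images of shape (N, {expected[0]}, {expected[1]}, "
                f"{expected[2]}), got {images.shape}")
        y = self.forward(images, training=False)
        return y.mean(axis=-1, keepdims=True)

    def reseed_dropout(self, seed: int):
        """Give every dropout layer a fresh generator derived from ``seed``."""
        gen = np.random.default_rng(np.random.SeedSequence([seed, 0xD0]))
        for layer in self.layers():
            if isinstance(layer, Dropout):
                layer.rng = gen

    # ---- weights -----------------------------------------------------
    def state_dict(self):
        state = {}
        for i, layer in enumerate(self.layers()):
            for name, p in zip(layer.param_names, layer.params):
                state[f"{i}:{type(layer).__name__}:{name}"] = p
            if isinstance(layer, BatchNorm):
                state[f"{i}:BatchNorm:moving_mean"] = layer.moving_mean
                state[f"{i}:BatchNorm:moving_var"] = layer.moving_var
        return state

    def get_weights(self):
        return [p.copy() for p in self.state_dict().values()]

    def set_weights(self, weights):
        targets = list(self.state_dict().values())
        if len(weights) != len(targets):
            raise ValueError("weight list length mismatch")
        for tgt, src in zip(targets, weights):
            if tgt.shape != src.shape:
                raise ValueError("weight shape mismatch")
            tgt[...] = src


def build_model(config_or_preset, seed: int = 0,
                input_size: Optional[tuple] = None) -> SegmentationModel:
    """Construct an untrained network from a config or preset name.

    ``input_size`` (height, width) optionally overrides the preset's
    320x320 canvas; parameter counts are unaffected (the networks are
    fully convolutional and attention pools over space).
    """
    if isinstance(config_or_preset, str):
        presets = _preset_configs(*(input_size or (320, 320)))
        if config_or_preset not in presets:
            raise ValueError(
                f"unknown preset {config_or_preset!r}; valid presets: "
                f"{', '.join(presets)}")
        config = presets[config_or_preset]
    else:
        config = config_or_preset
        if input_size is not None:
            d = config.to_dict()
            d["input_height"], d["input_width"] = input_size
            config = ArchitectureConfig.from_dict(d)
    return SegmentationModel(config, seed=seed)


def count_parameters(model: SegmentationModel) -> int:
    """Total parameter count (trainable + normalization statistics)."""
    return model.parameter_count


def predict(model: SegmentationModel, images) -> np.ndarray:
    return model.predict(images)


# --------------------------------------------------------------------------
# functional op surface (thin wrappers used in tests and exploration)
# --------------------------------------------------------------------------

def conv_block(x, filters, *, block: Optional[ConvBlock] = None,
               rng=None, training=False):
    """Apply one convolutional block (3x3 conv + BN + ReLU) to ``x``."""
    x = np.asarray(x, dtype=np.float32)
    if block is None:
        block = ConvBlock(x.shape[-1], filters,
                          rng or np.random.default_rng(0))
    return block.forward(x, training=training)


def attention_block(x, *, att: Optional[ChannelAttention] = None, rng=None):
    """Apply a channel-attention block; weights are bounded to [0.5, 1)."""
    x = np.asarray(x, dtype=np.float32)
    if att is None:
        att = ChannelAttention(x.shape[-1], rng=rng or np.random.default_rng(0))
    return att.forward(x, training=False)


def narrowing_midblock(x, min_channels, *, mid: Optional[NarrowingMidblock] = None,
                       rng=None):
    """Apply the bottleneck-narrowing midblock to ``x``."""
    x = np.asarray(x, dtype=np.float32)
    if mid is None:
        mid = NarrowingMidblock(x.shape[-1], min_channels,
                                rng=rng or np.random.default_rng(0))
    return mid.forward(x, training=False)
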