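"""The cascaded fusion + segmentation network.

Two sub-networks are chained end-to-end:

* **Fusion sub-network** — a small U-Net encoder ``E_theta`` takes the
  channel-stacked (CT, MRI) pair and emits a single fused image through a
  sigmoid; during training a mirror decoder ``D_phi`` reconstructs the
  2-channel input from the fused image (reconstruction + structural-
  similarity losses keep the fused image faithful to both modalities).
  ``D_phi`` is skipped at inference.

* **Segmentation sub-network** — a U-Net whose encoder is doubled (Dual
  Encoder Structure, DES): path A uses two 3x3 convolutions per stage, path
  B uses four 2x2 convolutions with alternating padding 0101 (or 1010; the
  -1/+1 size changes telescope so each stage preserves spatial size).  The
  deepest features of the two paths are concatenated and reduced 1x1 before
  the shared bottleneck.  Each decoder stage up-samples by a stride-2
  transposed convolution and merges the two encoder features through a
  CSAB-equipped skip connection (four variants a-d of the ordering of
  CSAB+up-sampling, 1x1 reduction and concatenation; d is the default).
  Every variant hands the decoder a 2C-channel tensor, so the decoder is the
  standard U-Net double 3x3 convolution stack ending in a 1x1 convolution
  and sigmoid.

Channel plans: "(32)" = 1-32-64-128-256-512-256-128-64-32-1 (default) and
"(16)" = 1-16-32-64-128-256-128-64-32-16-1; arbitrary width tuples are
accepted for scaled-down experiments.

Ablation flags ``use_fusion_subnet``, ``use_dual_encoder`` and ``use_csab``
each remove exactly their sub-graph; with all three off the model is a plain
U-Net.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .csab import CSAB
from .nn import Tensor

PRESET_PLANS = {
    "(16)": (16, 32, 64, 128, 256),
    "(32)": (32, 64, 128, 256, 512),
}

ENCODER_B_KERNELS = ("3x3", "5x5", "2x2-0101", "2x2-1010")
SKIP_VARIANTS = ("a", "b", "c", "d")


@dataclass(frozen=True)
class ChannelPlan:
    """Encoder stage widths plus bottleneck width (last entry)."""

    widths: tuple[int, ...] = PRESET_PLANS["(32)"]

    def __post_init__(self):
        if len(self.widths) < 2:
            raise ValueError("need at least one stage plus a bottleneck")
        for a, b in zip(self.widths, self.widths[1:]):
            if b != 2 * a:
                raise ValueError(f"widths must double per stage, got {self.widths}")

    @classmethod
    def from_spec(cls, spec) -> "ChannelPlan":
        if isinstance(spec, ChannelPlan):
            return spec
        if isinstance(spec, str):
            if spec not in PRESET_PLANS:
                raise ValueError(f"unknown plan {spec!r}; presets: {list(PRESET_PLANS)}")
            return cls(PRESET_PLANS[spec])
        return cls(tuple(spec))

    @property
    def stages(self) -> tuple[int, ...]:
        return self.widths[:-1]

    @property
    def bottleneck(self) -> int:
        return self.widths[-1]

    def sequence(self) -> tuple[int, ...]:
        """Full 1-...-1 channel sequence through encoder and decoder."""
        return (1,) + self.widths + tuple(reversed(self.stages)) + (1,)


@dataclass
class FsNetConfig:
    channel_plan: object = "(32)"
    skip_variant: str = "d"
    encoder_b_kernel: str = "2x2-0101"
    use_fusion_subnet: bool = True
    use_csab: bool = True
    use_dual_encoder: bool = True
    input_size: int = 256
    fusion_widths: tuple[int, ...] = (32, 64, 128, 256)
    csab_final_relu: bool = True
    dtype: object = np.float32

    def __post_init__(self):
        self.channel_plan = ChannelPlan.from_spec(self.channel_plan)
        if self.skip_variant not in SKIP_VARIANTS:
            raise ValueError(f"skip_variant must be one of {SKIP_VARIANTS}")
        if self.encoder_b_kernel not in ENCODER_B_KERNELS:
            raise ValueError(f"encoder_b_kernel must be one of {ENCODER_B_KERNELS}")
        n_pool = len(self.channel_plan.stages)
        if self.input_size % (2 ** n_pool):
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^{n_pool}")

    def to_dict(self) -> dict:
        return {
            "channel_plan": list(self.channel_plan.widths),
            "skip_variant": self.skip_variant,
            "encoder_b_kernel": self.encoder_b_kernel,
            "use_fusion_subnet": self.use_fusion_subnet,
            "use_csab": self.use_csab,
            "use_dual_encoder": self.use_dual_encoder,
            "input_size": self.input_size,
            "fusion_widths": list(self.fusion_widths),
            "csab_final_relu": self.csab_final_relu,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FsNetConfig":
        d = dict(d)
        if "channel_plan" in d:
            d["channel_plan"] = tuple(d["channel_plan"]) \
                if not isinstance(d["channel_plan"], str) else d["channel_plan"]
        if "fusion_widths" in d:
            d["fusion_widths"] = tuple(d["fusion_widths"])
        return cls(**d)


# --------------------------------------------------------------------------
# building blocks
# --------------------------------------------------------------------------

class DoubleConv3x3(nn.Module):
    """Two 3x3 conv + BN + ReLU; the classic U-Net stage."""

    def __init__(self, in_ch: int, out_ch: int, dtype=np.float32):
        super().__init__()
        self.block = nn.Sequential(
            nn.Conv2d(in_ch, out_ch, 3, padding=1, dtype=dtype),
            nn.BatchNorm2d(out_ch, dtype=dtype), nn.ReLU(),
            nn.Conv2d(out_ch, out_ch, 3, padding=1, dtype=dtype),
            nn.BatchNorm2d(out_ch, dtype=dtype), nn.ReLU(),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.block(x)


class EncoderBStage(nn.Module):
    """Second-encoder stage: kernel grid {3x3, 5x5, 2x2(0101), 2x2(1010)}.

    The 2x2 options chain four convolutions whose alternating padding makes
    the per-conv size changes (-1/+1 or +1/-1) cancel over the stage.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: str, dtype=np.float32):
        super().__init__()
        layers: list[nn.Module] = []
        if kernel in ("3x3", "5x5"):
            k = 3 if kernel == "3x3" else 5
            chans = [(in_ch, out_ch), (out_ch, out_ch)]
            pads = [k // 2, k // 2]
            ks = [k, k]
        else:
            pads = [0, 1, 0, 1] if kernel.endswith("0101") else [1, 0, 1, 0]
            chans = [(in_ch, out_ch)] + [(out_ch, out_ch)] * 3
            ks = [2] * 4
        for (ci, co), k_, p in zip(chans, ks, pads):
            layers += [nn.Conv2d(ci, co, k_, padding=p, dtype=dtype),
                       nn.BatchNorm2d(co, dtype=dtype), nn.ReLU()]
        self.block = nn.Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        return self.block(x)


class Encoder(nn.Module):
    """Stage stack returning per-stage (pre-pool) features and the pooled
    deepest feature."""

    def __init__(self, in_ch: int, stages: tuple[int, ...], make_stage, dtype=np.float32):
        super().__init__()
        self.stages = []
        prev = in_ch
        for width in stages:
            self.stages.append(make_stage(prev, width, dtype))
            prev = width

    def forward(self, x: Tensor) -> tuple[list[Tensor], Tensor]:
        feats = []
        for i, stage in enumerate(self.stages):
            if i > 0:
                x = nn.maxpool2d(x, 2)
            x = stage(x)
            feats.append(x)
        return feats, nn.maxpool2d(x, 2)


class SkipFusion(nn.Module):
    """One skip connection of the dual-encoder decoder.

    ``C`` is the stage width; the deeper decoder feature (``deep_ch``
    channels) is up-sampled inside the block.  Variants order the three
    primitives (Cu) = CSAB + up-sampling, (1x1) reduction, (Cat):

    * ``a`` — per-path 1x1, concatenate, CSAB at 2C;
    * ``b`` — concatenate, 1x1 mix at 2C, CSAB at 2C;
    * ``c`` — CSAB per path at C, concatenate [F1, F2, u], 1x1 to 2C;
    * ``d`` — CSAB per path at C, per-path 1x1 of [F_i, u] to C,
      concatenate (the published equations).

    Output always has 2C channels.  Without the dual encoder the second path
    vanishes and the output is the plain U-Net concatenation [x1', u]; with
    attention disabled CSAB degenerates to the identity on the skip feature.
    """

    def __init__(self, channels: int, deep_ch: int, variant: str = "d",
                 use_csab: bool = True, dual: bool = True,
                 final_relu: bool = True, dtype=np.float32):
        super().__init__()
        c = channels
        self.variant = variant
        self.use_csab = use_csab
        self.dual = dual
        wide = variant in ("a", "b") and dual
        self.up = nn.ConvTranspose2d(deep_ch, 2 * c if wide else c, dtype=dtype)
        if not dual:
            if use_csab:
                self.csab1 = CSAB(c, final_relu=final_relu, dtype=dtype)
            return
        if variant == "d":
            if use_csab:
                self.csab1 = CSAB(c, final_relu=final_relu, dtype=dtype)
                self.csab2 = CSAB(c, final_relu=final_relu, dtype=dtype)
            self.reduce1 = nn.Conv2d(2 * c, c, 1, dtype=dtype)
            self.reduce2 = nn.Conv2d(2 * c, c, 1, dtype=dtype)
        elif variant == "c":
            if use_csab:
                self.csab1 = CSAB(c, final_relu=final_relu, dtype=dtype)
                self.csab2 = CSAB(c, final_relu=final_relu, dtype=dtype)
            self.reduce = nn.Conv2d(3 * c, 2 * c, 1, dtype=dtype)
        elif variant == "a":
            self.reduce1 = nn.Conv2d(c, c, 1, dtype=dtype)
            self.reduce2 = nn.Conv2d(c, c, 1, dtype=dtype)
            if use_csab:
                self.csab1 = CSAB(2 * c, final_relu=final_relu, dtype=dtype)
        else:  # b
            self.reduce = nn.Conv2d(2 * c, 2 * c, 1, dtype=dtype)
            if use_csab:
                self.csab1 = CSAB(2 * c, final_relu=final_relu, dtype=dtype)

    def _att(self, block_name: str, x: Tensor, g: Tensor) -> Tensor:
        if not self.use_csab:
            return x
        return getattr(self, block_name)(x, g)

    def forward(self, x1: Tensor, x2: Tensor | None, deep: Tensor) -> Tensor:
        u = self.up(deep)
        if not self.dual:
            return nn.concat([self._att("csab1", x1, u), u], axis=1)
        if x2 is None:
            raise ValueError("dual-encoder skip needs both encoder features")
        if x1.shape != x2.shape:
            raise ValueError(f"stage mismatch: {x1.shape} vs {x2.shape}")
        v = self.variant
        if v == "d":
            f1 = self._att("csab1", x1, u)
            f2 = self._att("csab2", x2, u)
            x13 = self.reduce1(nn.concat([f1, u], axis=1))
            x23 = self.reduce2(nn.concat([f2, u], axis=1))
            return nn.concat([x13, x23], axis=1)
        if v == "c":
            f1 = self._att("csab1", x1, u)
            f2 = self._att("csab2", x2, u)
            return self.reduce(nn.concat([f1, f2, u], axis=1))
        if v == "a":
            merged = nn.concat([self.reduce1(x1), self.reduce2(x2)], axis=1)
        else:  # b
            merged = self.reduce(nn.concat([x1, x2], axis=1))
        return self._att("csab1", merged, u)


class SegmentationSubNet(nn.Module):
    """Dual-encoder U-Net mapping a 1-channel image to a probability map."""

    def __init__(self, config: FsNetConfig):
        super().__init__()
        plan = config.channel_plan
        dtype = config.dtype
        self.config = config
        self.encoder_a = Encoder(1, plan.stages,
                                 lambda i, o, dt: DoubleConv3x3(i, o, dt), dtype)
        if config.use_dual_encoder:
            kern = config.encoder_b_kernel
            self.encoder_b = Encoder(
                1, plan.stages,
                lambda i, o, dt: EncoderBStage(i, o, kern, dt), dtype)
            self.bottleneck_merge = nn.Conv2d(2 * plan.stages[-1], plan.stages[-1],
                                              1, dtype=dtype)
        self.bottleneck = DoubleConv3x3(plan.stages[-1], plan.bottleneck, dtype)
        self.skips = []
        self.decoders = []
        deep = plan.bottleneck
        for width in reversed(plan.stages):
            self.skips.append(SkipFusion(
                width, deep, config.skip_variant, config.use_csab,
                config.use_dual_encoder, config.csab_final_relu, dtype))
            self.decoders.append(DoubleConv3x3(2 * width, width, dtype))
            deep = width
        self.head = nn.Conv2d(plan.stages[0], 1, 1, dtype=dtype)

    def dual_encode(self, fused: Tensor):
        """Run both encoder paths; returns (features_a, features_b, bottleneck)."""
        h = fused.shape[2]
        n_pool = len(self.config.channel_plan.stages)
        if h % (2 ** n_pool) or fused.shape[3] % (2 ** n_pool):
            raise ValueError(f"spatial size {fused.shape[2:]} not divisible by "
                             f"2^{n_pool}")
        feats_a, pooled_a = self.encoder_a(fused)
        if self.config.use_dual_encoder:
            feats_b, pooled_b = self.encoder_b(fused)
            merged = self.bottleneck_merge(nn.concat([pooled_a, pooled_b], axis=1))
            bottleneck = self.bottleneck(merged)
        else:
            feats_b = [None] * len(feats_a)
            bottleneck = self.bottleneck(pooled_a)
        return feats_a, feats_b, bottleneck

    def forward(self, fused: Tensor) -> Tensor:
        feats_a, feats_b, deep = self.dual_encode(fused)
        for skip, dec, fa, fb in zip(self.skips, self.decoders,
                                     reversed(feats_a), reversed(feats_b)):
            deep = dec(skip(fa, fb, deep))
        return self.head(deep).sigmoid()


class FusionUNet(nn.Module):
    """Plain U-Net used for both E_theta (2 -> 1) and D_phi (1 -> 2);
    sigmoid output keeps images in [0, 1]."""

    def __init__(self, in_ch: int, out_ch: int, widths: tuple[int, ...],
                 dtype=np.float32):
        super().__init__()
        stages, bottleneck = tuple(widths[:-1]), widths[-1]
        self.encoder = Encoder(in_ch, stages,
                               lambda i, o, dt: DoubleConv3x3(i, o, dt), dtype)
        self.bottleneck = DoubleConv3x3(stages[-1], bottleneck, dtype)
        self.ups = []
        self.decoders = []
        deep = bottleneck
        for width in reversed(stages):
            self.ups.append(nn.ConvTranspose2d(deep, width, dtype=dtype))
            self.decoders.append(DoubleConv3x3(2 * width, width, dtype))
            deep = width
        self.head = nn.Conv2d(stages[0], out_ch, 1, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        feats, deep = self.encoder(x)
        deep = self.bottleneck(deep)
        for up, dec, skip in zip(self.ups, self.decoders, reversed(feats)):
            deep = dec(nn.concat([skip, up(deep)], axis=1))
        return self.head(deep).sigmoid()


class FSNet(nn.Module):
    """The full cascade; see the module docstring."""

    def __init__(self, config: FsNetConfig | None = None):
        super().__init__()
        self.config = config or FsNetConfig()
        dtype = self.config.dtype
        if self.config.use_fusion_subnet:
            self.fusion_encoder = FusionUNet(2, 1, self.config.fusion_widths, dtype)
            self.fusion_decoder = FusionUNet(1, 2, self.config.fusion_widths, dtype)
        self.segmentation = SegmentationSubNet(self.config)

    @staticmethod
    def _stack(ct: Tensor, mri: Tensor) -> Tensor:
        if ct.shape != mri.shape:
            raise ValueError(f"CT {ct.shape} and MRI {mri.shape} must be "
                             "co-registered to one shape")
        return nn.concat([ct, mri], axis=1)

    def fusion_forward(self, ct: Tensor, mri: Tensor, mode: str = "train"):
        """Fuse the pair; returns (fused, reconstruction-or-None)."""
        if mode not in ("train", "inference"):
            raise ValueError("mode must be 'train' or 'inference'")
        stacked = self._stack(ct, mri)
        if not self.config.use_fusion_subnet:
            fused = (ct + mri) * 0.5
            return fused, None
        fused = self.fusion_encoder(stacked)
        recon = self.fusion_decoder(fused) if mode == "train" else None
        return fused, recon

    def forward(self, ct: Tensor, mri: Tensor, mode: str = "train"):
        """Full cascade: (probability map, fused image, reconstruction|None)."""
        fused, recon = self.fusion_forward(ct, mri, mode)
        prob = self.segmentation(fused)
        return prob, fused, recon


def layer_inventory(model: nn.Module) -> list[tuple[str, tuple[int, ...]]]:
    """Sorted (parameter name, shape) list — the structural fingerprint used
    by the ablation contracts."""
    return sorted((name, tuple(p.data.shape)) for name, p in model.named_parameters())
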