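"""Architecture configuration for the FasterNet_T0 family.

The backbone is the FasterNet_T0 recipe: a 4x4 stride-4 convolutional stem,
four stages of residual blocks with depths (1, 2, 8, 2) and widths
(40, 80, 160, 320), 2x2 stride-2 patch-merging convolutions between stages,
global average pooling, a 1280-wide pre-classifier 1x1 convolution and a
linear classifier.  Four variants share this skeleton and differ only in the
block internals:

``fasternet_t0``
    PConv(3x3, partial ratio 1/4) -> 1x1 conv (C -> 2C) -> BN -> act ->
    1x1 conv (2C -> C), residual.
``t0_ghost``
    Same, with a stride-1 Ghost bottleneck inserted on the expanded 2C
    channels between activation and the reducing convolution.
``t0_gconv``
    The two pointwise convolutions replaced by 3x3 group convolutions with
    ``groups = C`` (the block width).
``hpfasternet``
    Both modifications together: 3x3 group convolutions for expand/reduce
    plus the Ghost bottleneck on the expanded channels — a residual nested
    inside a residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

VARIANT_NAMES = ("fasternet_t0", "t0_ghost", "t0_gconv", "hpfasternet")


@dataclass(frozen=True)
class GhostSpec:
    """Ghost module hyper-parameters (shared by both modules of a bottleneck).

    ``s`` is the expansion ratio of the module: each of the ``m = n/s``
    intrinsic maps produced by the primary convolution spawns ``s - 1`` ghost
    maps through a cheap per-channel (depthwise) linear operation; the last
    map of each group is the identity, so the intrinsic maps appear verbatim
    in the output.
    """

    s: int = 4
    primary_kernel: int = 1
    dw_kernel: int = 3

    def validate(self, n_out: int) -> None:
        if self.s < 1:
            raise ValueError(f"ghost ratio s must be >= 1, got {self.s}")
        if n_out % self.s:
            raise ValueError(
                f"ghost output width {n_out} is not divisible by ratio s={self.s}"
            )


@dataclass(frozen=True)
class BlockSpec:
    """One residual block of a stage."""

    variant: str
    channels: int
    expansion: int = 2
    partial_ratio_denom: int = 4  # r = 1/4
    ghost: GhostSpec | None = None

    @property
    def cp(self) -> int:
        if self.channels % self.partial_ratio_denom:
            raise ValueError(
                f"block width {self.channels} not divisible by the partial "
                f"ratio denominator {self.partial_ratio_denom}"
            )
        return self.channels // self.partial_ratio_denom

    @property
    def hidden(self) -> int:
        return self.expansion * self.channels

    @property
    def gconv_groups(self) -> int:
        """Group count of the 3x3 expand/reduce convolutions: the block width."""
        return self.channels

    @property
    def uses_gconv(self) -> bool:
        return self.variant in ("t0_gconv", "hpfasternet")

    @property
    def uses_ghost(self) -> bool:
        return self.variant in ("t0_ghost", "hpfasternet")


@dataclass(frozen=True)
class NetworkConfig:
    variant: str = "fasternet_t0"
    stage_depths: tuple[int, ...] = (1, 2, 8, 2)
    stage_channels: tuple[int, ...] = (40, 80, 160, 320)
    stem_kernel: int = 4
    stem_stride: int = 4
    merge_kernel: int = 2
    merge_stride: int = 2
    head_width: int = 1280
    num_classes: int = 19
    input_size: int = 224
    expansion: int = 2
    partial_ratio_denom: int = 4
    ghost: GhostSpec = field(default_factory=GhostSpec)

    def __post_init__(self) -> None:
        if self.variant not in VARIANT_NAMES:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {VARIANT_NAMES}"
            )
        if len(self.stage_depths) != len(self.stage_channels):
            raise ValueError("stage_depths and stage_channels lengths differ")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        stride = self.stem_stride * self.merge_stride ** (len(self.stage_depths) - 1)
        if self.input_size % stride:
            raise ValueError(
                f"input size {self.input_size} not divisible by the cumulative "
                f"stride {stride}"
            )
        for c in self.stage_channels:
            BlockSpec(self.variant, c, self.expansion, self.partial_ratio_denom).cp
            if self.variant in ("t0_ghost", "hpfasternet"):
                self.ghost.validate(self.expansion * c)

    def block_spec(self, stage: int) -> BlockSpec:
        return BlockSpec(
            variant=self.variant,
            channels=self.stage_channels[stage],
            expansion=self.expansion,
            partial_ratio_denom=self.partial_ratio_denom,
            ghost=self.ghost if self.variant in ("t0_ghost", "hpfasternet") else None,
        )


def make_config(variant: str, num_classes: int = 19, input_size: int = 224,
                **overrides) -> NetworkConfig:
    """Convenience constructor for the four Table-style variants."""
    cfg = NetworkConfig(variant=variant, num_classes=num_classes,
                        input_size=input_size)
    return replace(cfg, **overrides) if overrides else cfg


def tiny_config(variant: str = "hpfasternet", num_classes: int = 3,
                input_size: int = 64) -> NetworkConfig:
    """Width-reduced preset used for CPU-scale training experiments."""
    return NetworkConfig(
        variant=variant,
        stage_channels=(8, 16, 32, 64),
        head_width=128,
        num_classes=num_classes,
        input_size=input_size,
    )
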