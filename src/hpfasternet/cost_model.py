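"""Analytic parameter and FLOP accounting for convolution layers and networks.

Per-layer costs follow the standard closed forms for the three convolution
families:

===========  =====================  ==============================
layer        parameters             FLOPs
===========  =====================  ==============================
Conv         K^2 * C_in * C_out     K^2 * C_in * C_out * H * W
DW/GConv     K^2 * (C_in/G)*C_out   K^2 * (C_in/G) * C_out * H * W
PConv        K^2 * Cp^2             K^2 * Cp^2 * H * W
===========  =====================  ==============================

with H, W the *output* spatial extents and one multiply-accumulate counted
as one FLOP.  Network-level totals additionally count, per the accounting
convention calibrated on the FasterNet_T0 baseline:

* batch-normalization affine parameters (2 per channel) and 4 FLOPs per
  normalized element (subtract, divide, scale, shift);
* the classifier's weights and bias (bias adds parameters, no FLOPs);
* (window + 1) FLOPs per output element of the global average pool;
* nothing for activations or convolution biases (the convolutions carry
  no bias, normalization supplies the shift).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .config import NetworkConfig, make_config

KINDS = ("conv", "gconv", "dwconv", "pconv")


@dataclass(frozen=True)
class LayerCostSpec:
    """Symbols of one convolution layer for the closed-form cost formulas."""

    kind: str
    K: int
    C_in: int = 0
    C_out: int = 0
    G: int = 1
    Cp: int = 0
    H: int = 1
    W: int = 1

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        positive = {"K": self.K, "H": self.H, "W": self.W}
        if self.kind == "pconv":
            positive["Cp"] = self.Cp
        else:
            positive.update(C_in=self.C_in, C_out=self.C_out)
        for name, value in positive.items():
            if not isinstance(value, int) or value < 1:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        if self.kind in ("gconv", "dwconv"):
            g = self.C_in if self.kind == "dwconv" else self.G
            if g < 1 or self.C_in % g or self.C_out % g:
                raise ValueError(
                    f"group count G={g} must divide C_in={self.C_in} and "
                    f"C_out={self.C_out}"
                )
        if self.kind == "pconv" and self.C_in and self.Cp > self.C_in:
            raise ValueError(f"Cp={self.Cp} exceeds C_in={self.C_in}")

    @property
    def groups(self) -> int:
        return self.C_in if self.kind == "dwconv" else self.G

    @property
    def partial_ratio(self) -> float:
        """r = Cp / C_in for a partial convolution."""
        if self.kind != "pconv" or not self.C_in:
            raise ValueError("partial_ratio is defined for pconv with C_in set")
        return self.Cp / self.C_in


def layer_params(spec: LayerCostSpec) -> int:
    """Learnable weight count of one convolution (no bias, no normalization)."""
    k2 = spec.K * spec.K
    if spec.kind == "conv":
        return k2 * spec.C_in * spec.C_out
    if spec.kind in ("gconv", "dwconv"):
        return k2 * (spec.C_in // spec.groups) * spec.C_out
    return k2 * spec.Cp * spec.Cp


def layer_flops(spec: LayerCostSpec) -> int:
    """Multiply-accumulate count of one convolution over its output map."""
    return layer_params(spec) * spec.H * spec.W


@dataclass(frozen=True)
class CostReport:
    params: int
    flops: int

    def __post_init__(self) -> None:
        if self.params < 0 or self.flops < 0:
            raise ValueError("costs must be non-negative")

    @staticmethod
    def _millions(x: int) -> float:
        # round half away from zero to 3 decimals on the 1e6 scale
        import math

        scaled = x / 1e6 * 1000.0
        return math.floor(scaled + 0.5) / 1000.0

    @property
    def params_millions(self) -> float:
        return self._millions(self.params)

    @property
    def flops_millions(self) -> float:
        return self._millions(self.flops)


@dataclass(frozen=True)
class LayerCost:
    """One row of a network's cost table."""

    name: str
    kind: str  # conv kinds, or "bn" / "pool" / "linear"
    params: int
    flops: int


def _ghost_module_rows(name: str, c_in: int, c_out: int, S: int,
                       cfg: NetworkConfig) -> Iterator[LayerCost]:
    g = cfg.ghost
    m = c_out // g.s
    ghosts = c_out - m
    primary = LayerCostSpec("conv", K=g.primary_kernel, C_in=c_in, C_out=m, H=S, W=S)
    yield LayerCost(f"{name}.primary", "conv",
                    layer_params(primary), layer_flops(primary))
    yield LayerCost(f"{name}.primary_bn", "bn", 2 * m, 4 * m * S * S)
    if ghosts:
        cheap = LayerCostSpec("gconv", K=g.dw_kernel, C_in=m, C_out=ghosts,
                              G=m, H=S, W=S)
        yield LayerCost(f"{name}.cheap", "gconv",
                        layer_params(cheap), layer_flops(cheap))
        yield LayerCost(f"{name}.cheap_bn", "bn", 2 * ghosts, 4 * ghosts * S * S)


def _block_rows(name: str, cfg: NetworkConfig, stage: int, S: int
                ) -> Iterator[LayerCost]:
    spec = cfg.block_spec(stage)
    C, H = spec.channels, spec.hidden
    pconv = LayerCostSpec("pconv", K=3, C_in=C, Cp=spec.cp, H=S, W=S)
    yield LayerCost(f"{name}.pconv", "pconv",
                    layer_params(pconv), layer_flops(pconv))
    if spec.uses_gconv:
        expand = LayerCostSpec("gconv", K=3, C_in=C, C_out=H,
                               G=spec.gconv_groups, H=S, W=S)
        reduce_ = LayerCostSpec("gconv", K=3, C_in=H, C_out=C,
                                G=spec.gconv_groups, H=S, W=S)
    else:
        expand = LayerCostSpec("conv", K=1, C_in=C, C_out=H, H=S, W=S)
        reduce_ = LayerCostSpec("conv", K=1, C_in=H, C_out=C, H=S, W=S)
    yield LayerCost(f"{name}.expand", expand.kind,
                    layer_params(expand), layer_flops(expand))
    yield LayerCost(f"{name}.bn", "bn", 2 * H, 4 * H * S * S)
    if spec.uses_ghost:
        yield from _ghost_module_rows(f"{name}.ghost1", H, H, S, cfg)
        yield from _ghost_module_rows(f"{name}.ghost2", H, H, S, cfg)
    yield LayerCost(f"{name}.reduce", reduce_.kind,
                    layer_params(reduce_), layer_flops(reduce_))


def layer_table(config: NetworkConfig, input_size: int | None = None
                ) -> list[LayerCost]:
    """Per-layer cost rows of the full network, stem to classifier."""
    size = input_size or config.input_size
    if size % config.stem_stride:
        raise ValueError("input size not divisible by the stem stride")
    rows: list[LayerCost] = []
    S = size // config.stem_stride
    stem = LayerCostSpec("conv", K=config.stem_kernel, C_in=3,
                         C_out=config.stage_channels[0], H=S, W=S)
    rows.append(LayerCost("stem.conv", "conv",
                          layer_params(stem), layer_flops(stem)))
    c0 = config.stage_channels[0]
    rows.append(LayerCost("stem.bn", "bn", 2 * c0, 4 * c0 * S * S))
    for stage, (depth, C) in enumerate(
            zip(config.stage_depths, config.stage_channels)):
        if stage > 0:
            S //= config.merge_stride
            prev = config.stage_channels[stage - 1]
            merge = LayerCostSpec("conv", K=config.merge_kernel, C_in=prev,
                                  C_out=C, H=S, W=S)
            rows.append(LayerCost(f"merge{stage}.conv", "conv",
                                  layer_params(merge), layer_flops(merge)))
            rows.append(LayerCost(f"merge{stage}.bn", "bn", 2 * C, 4 * C * S * S))
        for b in range(depth):
            rows.extend(_block_rows(f"stage{stage + 1}.block{b + 1}",
                                    config, stage, S))
    C_last = config.stage_channels[-1]
    rows.append(LayerCost("head.pool", "pool", 0, (S * S + 1) * C_last))
    head = LayerCostSpec("conv", K=1, C_in=C_last, C_out=config.head_width)
    rows.append(LayerCost("head.conv", "conv",
                          layer_params(head), layer_flops(head)))
    fc_w = config.head_width * config.num_classes
    rows.append(LayerCost("head.fc", "linear", fc_w + config.num_classes, fc_w))
    return rows


def model_cost(config: NetworkConfig | str, input_size: int | None = None,
               num_classes: int | None = None) -> CostReport:
    """Total parameter and FLOP cost of a network variant.

    ``config`` may be a :class:`NetworkConfig` or a variant name.
    """
    if isinstance(config, str):
        config = make_config(config, num_classes=num_classes or 19,
                             input_size=input_size or 224)
    rows = layer_table(config, input_size)
    return CostReport(params=sum(r.params for r in rows),
                      flops=sum(r.flops for r in rows))
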