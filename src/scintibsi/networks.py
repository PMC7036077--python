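"""Butterfly-type dual-view fully convolutional networks.

A butterfly network fuses two U-Net-style encoder–decoder arms — one per
view — into a single model: the anterior and posterior images are encoded
separately, their deepest feature maps are concatenated into a shared
trunk, and two decoder arms (with same-view skip connections at matching
scales) produce per-view class logits. Processing both views through one
trunk couples the predictions, which is the point: a lesion visible in
both projections should be labeled consistently.

Three variants are provided:

- :func:`build_btrflynet` — the plain network (skeleton segmentation,
  13 anterior / 12 posterior output channels; hot-spot extraction, 3 / 3).
- :func:`build_btrflynet_dsv` — adds deep supervision: four side heads at
  the two finest decoder scales of each arm, upsampled to full resolution,
  for a total of six supervised outputs.
- :func:`build_resbtrflynet` — every conv stage replaced by a residual
  block, with a stem conv after the input so the first residual addition
  is well-typed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .labels import N_ANTERIOR_CLASSES, N_HOTSPOT_CLASSES, N_POSTERIOR_CLASSES

__all__ = ["BtrflyConfig", "DualViewLogits", "BtrflyNet", "build_btrflynet",
           "build_btrflynet_dsv", "build_resbtrflynet", "forward"]


@dataclass
class BtrflyConfig:
    """Architecture hyper-parameters.

    ``depth`` is the number of 2x downsamplings per arm; the input shape
    must be divisible by ``2**depth``. ``base_channels`` doubles per level.
    """

    task: str = "skeleton"  # "skeleton" | "hotspot"
    input_shape: tuple[int, int] = (160, 64)
    depth: int = 3
    base_channels: int = 8
    out_channels_anterior: int | None = None
    out_channels_posterior: int | None = None
    use_dsv: bool = False
    use_residual: bool = False
    dsv_taps: int = 4

    def __post_init__(self) -> None:
        if self.task not in ("skeleton", "hotspot"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.out_channels_anterior is None:
            self.out_channels_anterior = (N_ANTERIOR_CLASSES if self.task == "skeleton"
                                          else N_HOTSPOT_CLASSES)
        if self.out_channels_posterior is None:
            self.out_channels_posterior = (N_POSTERIOR_CLASSES if self.task == "skeleton"
                                           else N_HOTSPOT_CLASSES)
        h, w = self.input_shape
        if h % (1 << self.depth) or w % (1 << self.depth):
            raise ValueError(
                f"input shape {self.input_shape} not divisible by 2^depth={1 << self.depth}")

    def to_dict(self) -> dict:
        return {"task": self.task, "input_shape": list(self.input_shape),
                "depth": self.depth, "base_channels": self.base_channels,
                "out_channels_anterior": self.out_channels_anterior,
                "out_channels_posterior": self.out_channels_posterior,
                "use_dsv": self.use_dsv, "use_residual": self.use_residual,
                "dsv_taps": self.dsv_taps}

    @classmethod
    def from_dict(cls, d: dict) -> "BtrflyConfig":
        d = dict(d)
        d["input_shape"] = tuple(d["input_shape"])
        return cls(**d)


@dataclass
class DualViewLogits:
    """Per-view class-logit fields ``(C, H, W)`` plus optional DSV side outputs."""

    anterior: np.ndarray
    posterior: np.ndarray
    side_outputs: list[np.ndarray] = field(default_factory=list)

    @property
    def supervised_outputs(self) -> list[np.ndarray]:
        return [self.anterior, self.posterior] + list(self.side_outputs)


def _stage(cin: int, cout: int, residual: bool, stride: int = 1) -> nn.Module:
    if residual:
        return nn.ResidualBlock(cin, cout, stride=stride)
    return nn.ConvBNRelu(cin, cout, stride=stride)


class _EncoderArm(nn.Module):
    """One view's encoder: stem, then per-level (stage, downsample)."""

    def __init__(self, cfg: BtrflyConfig):
        c = cfg.base_channels
        # plain stem even in the residual variant: it lifts the 1-channel
        # input to base_channels so the first residual addition is well-typed
        self.stem = nn.ConvBNRelu(1, c)
        self.stages = []
        self.downs = []
        for lvl in range(cfg.depth):
            cl = c << lvl
            self.stages.append(_stage(cl, cl, cfg.use_residual))
            self.downs.append(_stage(cl, cl * 2, cfg.use_residual, stride=2))

    def forward(self, x: nn.Tensor) -> tuple[nn.Tensor, list[nn.Tensor]]:
        h = self.stem(x)
        skips: list[nn.Tensor] = []
        for stage, down in zip(self.stages, self.downs):
            h = stage(h)
            skips.append(h)
            h = down(h)
        return h, skips


class _DecoderArm(nn.Module):
    """One view's decoder: per-level (upsample, concat skip, stage), then 1x1 head."""

    def __init__(self, cfg: BtrflyConfig, trunk_channels: int, out_channels: int):
        c = cfg.base_channels
        self.ups = []
        self.stages = []
        cin = trunk_channels
        for lvl in reversed(range(cfg.depth)):
            cl = c << lvl
            self.ups.append(nn.Deconv2x2(cin, cl))
            self.stages.append(_stage(cl * 2, cl, cfg.use_residual))
            cin = cl
        self.head = nn.Conv2d(c, out_channels, k=1, pad=0)

    def forward(self, h: nn.Tensor, skips: list[nn.Tensor]
                ) -> tuple[nn.Tensor, list[nn.Tensor]]:
        feats: list[nn.Tensor] = []
        for up, stage, skip in zip(self.ups, self.stages, reversed(skips)):
            h = up(h)
            h = nn.concat([h, skip], axis=1)
            h = stage(h)
            feats.append(h)
        return self.head(h), feats


class _DsvHead(nn.Module):
    """1x1 projection to class channels + nearest upsampling to full resolution."""

    def __init__(self, cin: int, cout: int, factor: int):
        self.proj = nn.Conv2d(cin, cout, k=1, pad=0)
        self.factor = factor

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        y = self.proj(x)
        return nn.upsample_nearest(y, self.factor) if self.factor > 1 else y


class BtrflyNet(nn.Module):
    """Dual-arm encoder, shared trunk, dual-arm decoder."""

    def __init__(self, cfg: BtrflyConfig):
        if cfg.use_dsv and cfg.depth < 3:
            raise ValueError("deep supervision needs depth >= 3 (two side scales per arm)")
        self.cfg = cfg
        deep = cfg.base_channels << cfg.depth
        self.enc_ant = _EncoderArm(cfg)
        self.enc_post = _EncoderArm(cfg)
        self.trunk = nn.Sequential(_stage(2 * deep, deep, cfg.use_residual),
                                   _stage(deep, deep, cfg.use_residual))
        self.dec_ant = _DecoderArm(cfg, deep, cfg.out_channels_anterior)
        self.dec_post = _DecoderArm(cfg, deep, cfg.out_channels_posterior)
        if cfg.use_dsv:
            # two finest intermediate decoder scales per arm (factors 2 and 4)
            c = cfg.base_channels
            self.dsv_ant = [_DsvHead(c * 2, cfg.out_channels_anterior, 2),
                            _DsvHead(c * 4, cfg.out_channels_anterior, 4)]
            self.dsv_post = [_DsvHead(c * 2, cfg.out_channels_posterior, 2),
                             _DsvHead(c * 4, cfg.out_channels_posterior, 4)]

    def forward(self, ant: nn.Tensor, post: nn.Tensor
                ) -> tuple[nn.Tensor, nn.Tensor, list[nn.Tensor]]:
        ha, skips_a = self.enc_ant(ant)
        hp, skips_p = self.enc_post(post)
        h = self.trunk(nn.concat([ha, hp], axis=1))
        ya, feats_a = self.dec_ant(h, skips_a)
        yp, feats_p = self.dec_post(h, skips_p)
        sides: list[nn.Tensor] = []
        if self.cfg.use_dsv:
            # feats are ordered coarsest->finest; take the two finest
            sides = [self.dsv_ant[0](feats_a[-2]), self.dsv_ant[1](feats_a[-3]),
                     self.dsv_post[0](feats_p[-2]), self.dsv_post[1](feats_p[-3])]
        return ya, yp, sides

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def build_btrflynet(cfg: BtrflyConfig) -> BtrflyNet:
    """The plain butterfly network (no DSV, no residual blocks)."""
    cfg2 = BtrflyConfig(**{**cfg.to_dict(), "use_dsv": False, "use_residual": False,
                           "input_shape": cfg.input_shape})
    return BtrflyNet(cfg2)


def build_btrflynet_dsv(cfg: BtrflyConfig) -> BtrflyNet:
    """Butterfly network with four deep-supervision side heads (six
    supervised outputs in total)."""
    if not cfg.use_dsv:
        cfg = BtrflyConfig(**{**cfg.to_dict(), "use_dsv": True,
                              "input_shape": cfg.input_shape})
    return BtrflyNet(cfg)


def build_resbtrflynet(cfg: BtrflyConfig) -> BtrflyNet:
    """Butterfly network with residual blocks in place of every conv stage."""
    if not cfg.use_residual:
        cfg = BtrflyConfig(**{**cfg.to_dict(), "use_residual": True,
                              "input_shape": cfg.input_shape})
    return BtrflyNet(cfg)


def forward(net: BtrflyNet, anterior: np.ndarray, posterior: np.ndarray
            ) -> DualViewLogits:
    """Run a single pair through the network in eval mode.

    ``anterior``/``posterior`` are ``(H, W)`` rasters matching
    ``cfg.input_shape``; returns ``(C, H, W)`` logits per view.
    """
    cfg = net.cfg
    for name, arr in (("anterior", anterior), ("posterior", posterior)):
        if arr.shape != tuple(cfg.input_shape):
            raise ValueError(f"{name} raster {arr.shape} does not match "
                             f"configured input shape {tuple(cfg.input_shape)}")
    net.eval()
    a = nn.Tensor(np.asarray(anterior, dtype=np.float64)[None, None])
    p = nn.Tensor(np.asarray(posterior, dtype=np.float64)[None, None])
    ya, yp, sides = net.forward(a, p)
    return DualViewLogits(anterior=ya.data[0], posterior=yp.data[0],
                          side_outputs=[s.data[0] for s in sides])
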