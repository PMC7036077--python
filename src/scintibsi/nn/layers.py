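"""Layer modules built on the autodiff core.

Modules own parameter :class:`~scintibsi.nn.tensor.Tensor` objects and any
non-trainable state (batch-norm running statistics, train/eval mode).
"""

from __future__ import annotations

import numpy as np

from . import tensor as _t
from .tensor import Tensor, add, batch_norm, conv2d, deconv2x2, relu

__all__ = ["Module", "Conv2d", "Deconv2x2", "BatchNorm2d", "ConvBNRelu",
           "ResidualBlock", "Sequential"]


class Module:
    """Base class: parameter traversal and train/eval mode switching."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        self._collect_state("", state)
        return state

    def _collect_state(self, prefix: str, state: dict) -> None:
        for k, v in self.__dict__.items():
            key = f"{prefix}{k}"
            if isinstance(v, Tensor):
                state[key] = v.data.copy()
            elif isinstance(v, np.ndarray):
                state[key] = v.copy()
            elif isinstance(v, Module):
                v._collect_state(key + ".", state)
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item._collect_state(f"{key}.{i}.", state)

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self._load_state("", state)

    def _load_state(self, prefix: str, state: dict) -> None:
        for k, v in self.__dict__.items():
            key = f"{prefix}{k}"
            if isinstance(v, Tensor):
                v.data = np.array(state[key], dtype=v.data.dtype)
            elif isinstance(v, np.ndarray):
                v[...] = state[key]
            elif isinstance(v, Module):
                v._load_state(key + ".", state)
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item._load_state(f"{key}.{i}.", state)

    def __call__(self, *args):
        return self.forward(*args)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int | None = None):
        self.stride = stride
        self.pad = (k // 2) if pad is None else pad
        self.weight = Tensor(np.zeros((cout, cin, k, k)), requires_grad=True,
                             name="conv.weight")
        self.bias = Tensor(np.zeros(cout), requires_grad=True, name="conv.bias")

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class Deconv2x2(Module):
    """2x upsampling by a stride-2 transposed convolution."""

    def __init__(self, cin: int, cout: int):
        self.weight = Tensor(np.zeros((cin, cout, 2, 2)), requires_grad=True,
                             name="deconv.weight")
        self.bias = Tensor(np.zeros(cout), requires_grad=True, name="deconv.bias")

    def forward(self, x: Tensor) -> Tensor:
        return deconv2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, c: int):
        self.gamma = Tensor(np.ones(c), requires_grad=True, name="bn.gamma")
        self.beta = Tensor(np.zeros(c), requires_grad=True, name="bn.beta")
        self.running_mean = np.zeros(c, dtype=_t.DTYPE)
        self.running_var = np.ones(c, dtype=_t.DTYPE)
        self.training = True

    def forward(self, x: Tensor) -> Tensor:
        return batch_norm(x, self.gamma, self.beta, self.running_mean,
                          self.running_var, self.training)


class ConvBNRelu(Module):
    """conv -> batch norm -> ReLU, the basic stage of both networks."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1):
        self.conv = Conv2d(cin, cout, k=k, stride=stride)
        self.bn = BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        return relu(self.bn(self.conv(x)))


class ResidualBlock(Module):
    """Two 3x3 conv-BN stages with an identity shortcut.

    A 1x1 (optionally strided) projection aligns the shortcut whenever the
    channel count or resolution changes.
    """

    def __init__(self, cin: int, cout: int, stride: int = 1):
        self.conv1 = Conv2d(cin, cout, k=3, stride=stride)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, k=3, stride=1)
        self.bn2 = BatchNorm2d(cout)
        if cin != cout or stride != 1:
            self.proj = Conv2d(cin, cout, k=1, stride=stride, pad=0)
            self.proj_bn = BatchNorm2d(cout)
        else:
            self.proj = None
            self.proj_bn = None

    def forward(self, x: Tensor) -> Tensor:
        h = relu(self.bn1(self.conv1(x)))
        h = self.bn2(self.conv2(h))
        shortcut = x if self.proj is None else self.proj_bn(self.proj(x))
        return relu(add(h, shortcut))


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x
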