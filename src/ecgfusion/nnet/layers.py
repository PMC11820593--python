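"""Neural-network layers over the autograd Tensor."""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autograd import Tensor

__all__ = [
    "Module",
    "Sequential",
    "Linear",
    "Conv1d",
    "Conv2d",
    "BatchNorm1d",
    "MaxPool1d",
    "MaxPool2d",
    "AdaptiveMaxPool2d",
    "ReLU",
    "Dropout",
]


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self) -> None:
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self) -> Iterator["Module"]:
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
        for child in self._children():
            params.extend(child.parameters())
        return params

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for child in self._children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        """Parameter arrays in a stable order (for checkpointing)."""
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            p.data = np.array(a, dtype=np.float64)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        std = math.sqrt(2.0 / in_features)
        self.weight = Tensor(
            rng.standard_normal((in_features, out_features)) * std, requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        pad: int = 0,
        bias: bool = True,
    ):
        super().__init__()
        self.stride, self.pad = stride, pad
        std = math.sqrt(2.0 / (in_channels * kernel))
        self.weight = Tensor(
            rng.standard_normal((out_channels, in_channels, kernel)) * std,
            requires_grad=True,
        )
        self.bias = (
            Tensor(np.zeros(out_channels), requires_grad=True) if bias else None
        )

    def forward(self, x: Tensor) -> Tensor:
        return x.conv1d(self.weight, self.bias, self.stride, self.pad)


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        pad: int = 0,
        bias: bool = True,
    ):
        super().__init__()
        self.stride, self.pad = stride, pad
        std = math.sqrt(2.0 / (in_channels * kernel * kernel))
        self.weight = Tensor(
            rng.standard_normal((out_channels, in_channels, kernel, kernel)) * std,
            requires_grad=True,
        )
        self.bias = (
            Tensor(np.zeros(out_channels), requires_grad=True) if bias else None
        )

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, self.stride, self.pad)


class BatchNorm1d(Module):
    """Batch normalization over (batch, length) per channel, (B,C,L)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: Tensor) -> Tensor:
        data = x.data
        if self.training:
            mu = data.mean(axis=(0, 2))
            var = data.var(axis=(0, 2))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
        else:
            mu, var = self.running_mean, self.running_var
        sigma = np.sqrt(var + self.eps)
        xhat = (data - mu[None, :, None]) / sigma[None, :, None]
        out_data = self.gamma.data[None, :, None] * xhat + self.beta.data[None, :, None]
        n = data.shape[0] * data.shape[2]
        gamma, training = self.gamma, self.training

        def back_x(g: np.ndarray) -> np.ndarray:
            dxhat = g * gamma.data[None, :, None]
            if not training:
                return dxhat / sigma[None, :, None]
            m_dxhat = dxhat.mean(axis=(0, 2), keepdims=True)
            m_dxhat_xhat = (dxhat * xhat).mean(axis=(0, 2), keepdims=True)
            return (dxhat - m_dxhat - xhat * m_dxhat_xhat) / sigma[None, :, None]

        def back_gamma(g: np.ndarray) -> np.ndarray:
            return (g * xhat).sum(axis=(0, 2))

        def back_beta(g: np.ndarray) -> np.ndarray:
            return g.sum(axis=(0, 2))

        del n
        return Tensor._make(
            out_data, [(x, back_x), (self.gamma, back_gamma), (self.beta, back_beta)]
        )


class MaxPool1d(Module):
    def __init__(self, kernel: int, stride: int, pad: int = 0):
        super().__init__()
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def forward(self, x: Tensor) -> Tensor:
        return x.maxpool1d(self.kernel, self.stride, self.pad)


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int):
        super().__init__()
        self.kernel, self.stride = kernel, stride

    def forward(self, x: Tensor) -> Tensor:
        return x.maxpool2d(self.kernel, self.stride)


class AdaptiveMaxPool2d(Module):
    def __init__(self, out_hw: tuple[int, int]):
        super().__init__()
        self.out_hw = out_hw

    def forward(self, x: Tensor) -> Tensor:
        return x.adaptive_maxpool2d(self.out_hw)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        return x.dropout(self.p, self.rng, self.training)
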