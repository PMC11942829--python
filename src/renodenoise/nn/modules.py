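"""Layer modules with parameter management and checkpointing."""

from __future__ import annotations

from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from . import functional as F
from .autograd import Tensor, _DTYPE

__all__ = [
    "Module", "Parameter", "Conv2d", "ConvTranspose2d", "BatchNorm2d",
    "Linear", "ReLU", "LeakyReLU", "Sigmoid", "Sequential",
]


class Parameter(Tensor):
    """A tensor that is always trainable."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal module base: attribute-walking parameter/state discovery."""

    def __init__(self):
        self.training = True

    # -- traversal -----------------------------------------------------------
    def children(self) -> Iterator["Module"]:
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self) -> List[Parameter]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self) -> "Module":
        self.training = True
        for c in self.children():
            c.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for c in self.children():
            c.eval()
        return self

    # -- state ---------------------------------------------------------------
    def _named_buffers(self, prefix: str = "") -> Iterator[Tuple[str, np.ndarray]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, np.ndarray):
                yield full, value
            elif isinstance(value, Module):
                yield from value._named_buffers(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item._named_buffers(f"{full}.{i}.")

    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({f"buffer:{n}": b.copy() for n, b in self._named_buffers()})
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self._named_buffers())
        for key, value in state.items():
            if key.startswith("buffer:"):
                buf = buffers[key[len("buffer:"):]]
                buf[...] = value
            else:
                params[key].data = np.asarray(value, dtype=_DTYPE)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


def _kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    # Kaiming-uniform with leaky slope sqrt(5): bound = 1/sqrt(fan_in),
    # the common default for convolutional layers
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(_DTYPE)


class Conv2d(Module):
    """Channels-last convolution; weight layout (kh, kw, in_ch, out_ch)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 stride: int = 1, padding: int = 0, dilation: int = 1,
                 bias: bool = True, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel * kernel
        self.weight = Parameter(_kaiming_uniform(
            rng, (kernel, kernel, in_channels, out_channels), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride, self.padding, self.dilation = stride, padding, dilation

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias,
                        stride=self.stride, padding=self.padding,
                        dilation=self.dilation)


class ConvTranspose2d(Module):
    """Channels-last transposed convolution; weight (kh, kw, in_ch, out_ch)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 2,
                 stride: int = 2, padding: int = 0,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel * kernel
        self.weight = Parameter(_kaiming_uniform(
            rng, (kernel, kernel, in_channels, out_channels), fan_in))
        self.bias = Parameter(np.zeros(out_channels))
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2d(x, self.weight, self.bias,
                                  stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=_DTYPE)
        self.running_var = np.ones(channels, dtype=_DTYPE)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm2d(x, self.gamma, self.beta,
                              self.running_mean, self.running_var,
                              training=self.training,
                              momentum=self.momentum, eps=self.eps)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_kaiming_uniform(
            rng, (out_features, in_features), in_features))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x.matmul(Tensor(self.weight.data.T, _parents=(self.weight,),
                               _backward=lambda g: (g.T,))) + self.bias


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
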