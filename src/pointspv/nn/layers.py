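"""Layer modules over the autograd primitives.

Mirrors the familiar Module/Parameter pattern: modules register parameters
and submodules on attribute assignment, expose ``parameters()`` /
``state_dict()`` and a train/eval switch (batchnorm running statistics are
the only mode-dependent piece).
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    """A tensor that is optimized; always requires grad."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=ag.get_default_dtype()), requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> Iterator[Parameter]:
        for p in self._params.values():
            yield p
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for k, p in self._params.items():
            yield prefix + k, p
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix + k + ".")

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for k, b in self._buffers.items():
            yield prefix + k, b
        for k, m in self._modules.items():
            yield from m.named_buffers(prefix + k + ".")

    def train(self, mode: bool = True) -> "Module":
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def freeze(self) -> "Module":
        """Detach all parameters from gradient computation."""
        for p in self.parameters():
            p.requires_grad = False
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: np.array(p.data) for k, p in self.named_parameters()}
        out.update({"buffer:" + k: np.array(b) for k, b in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for k, v in state.items():
            if k.startswith("buffer:"):
                buf = buffers[k[len("buffer:"):]]
                buf[...] = v
            else:
                p = params[k]
                p.data = np.asarray(v, dtype=p.data.dtype).reshape(p.data.shape)

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover
        raise NotImplementedError


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d3x3(Module):
    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(he_init(rng, (out_ch, in_ch, 3, 3), fan_in=9 * in_ch))
        self.bias = Parameter(np.zeros(out_ch))

    def forward(self, x):
        return ag.conv2d_3x3(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(ch))
        self.beta = Parameter(np.zeros(ch))
        self.register_buffer("running_mean", np.zeros(ch, dtype=np.float64))
        self.register_buffer("running_var", np.ones(ch, dtype=np.float64))
        self.momentum = momentum
        self.eps = eps

    def forward(self, x):
        return ag.batchnorm2d(x, self.gamma, self.beta, self.running_mean,
                              self.running_var, training=self.training,
                              momentum=self.momentum, eps=self.eps)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.01):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return ag.leaky_relu(x, self.slope)


class Sigmoid(Module):
    def forward(self, x):
        return ag.sigmoid(x)


class MaxPool2x2(Module):
    def forward(self, x):
        return ag.maxpool2x2(x)


class GlobalAvgPool(Module):
    def forward(self, x):
        return ag.global_avg_pool(x)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(he_init(rng, (out_f, in_f), fan_in=in_f))
        self.bias = Parameter(np.zeros(out_f))

    def forward(self, x):
        return ag.linear(x, self.weight, self.bias)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self._seq = list(mods)
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)

    def __iter__(self):
        return iter(self._seq)

    def __len__(self):
        return len(self._seq)

    def __getitem__(self, i):
        return self._seq[i]

    def forward(self, x):
        for m in self._seq:
            x = m(x)
        return x


class ResidualBlock(Module):
    """conv-BN-act-conv-BN plus identity skip; activation after the sum."""

    def __init__(self, ch: int, rng: np.random.Generator, slope: float = 0.01):
        super().__init__()
        self.conv1 = Conv2d3x3(ch, ch, rng)
        self.bn1 = BatchNorm2d(ch)
        self.conv2 = Conv2d3x3(ch, ch, rng)
        self.bn2 = BatchNorm2d(ch)
        self.slope = slope

    def forward(self, x):
        h = ag.leaky_relu(self.bn1(self.conv1(x)), self.slope)
        h = self.bn2(self.conv2(h))
        return ag.leaky_relu(ag.add(h, x), self.slope)
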