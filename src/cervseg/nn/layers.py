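"""Module/parameter containers built on the autodiff tensor."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor, relu, sigmoid


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class: tracks sub-modules and parameters by attribute name."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            path = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield path, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{path}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{path}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            path = f"{prefix}{name}"
            if isinstance(val, np.ndarray):
                yield path, val
            elif isinstance(val, Module):
                yield from val.named_buffers(f"{path}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{path}.{i}.")

    def modules(self):
        yield self
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # checkpointing ---------------------------------------------------------
    def state_dict(self) -> dict:
        state = {f"param:{k}": v.data.copy() for k, v in self.named_parameters()}
        state.update({f"buffer:{k}": v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        for k, v in self.named_parameters():
            src = state[f"param:{k}"]
            if src.shape != v.data.shape:
                raise ValueError(f"shape mismatch for {k}: {src.shape} vs {v.data.shape}")
            v.data = src.astype(v.data.dtype).copy()
        for k, v in self.named_buffers():
            v[...] = state[f"buffer:{k}"]


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return sigmoid(x)


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, *, stride: int = 1,
                 padding: int | None = None, dilation: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        if padding is None:
            padding = dilation * (kernel - 1) // 2  # 'same' for stride 1
        self.stride, self.padding, self.dilation = stride, padding, dilation
        self.weight = Parameter(_he_normal(rng, (out_ch, in_ch, kernel, kernel),
                                           in_ch * kernel * kernel))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, dilation=self.dilation)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel: int = 3, *, stride: int = 1,
                 dilation: int = 1, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.dilation = dilation
        self.padding = dilation * (kernel - 1) // 2
        self.weight = Parameter(_he_normal(rng, (channels, kernel, kernel),
                                           kernel * kernel))

    def forward(self, x):
        return F.depthwise_conv2d(x, self.weight, stride=self.stride,
                                  padding=self.padding, dilation=self.dilation)


class ConvTranspose2x2(Module):
    def __init__(self, in_ch: int, out_ch: int, *, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_he_normal(rng, (in_ch, out_ch, 2, 2), in_ch * 4))
        self.bias = Parameter(np.zeros(out_ch))

    def forward(self, x):
        return F.conv_transpose2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, *, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x):
        return F.batch_norm2d(x, self.gamma, self.beta, self.running_mean,
                              self.running_var, training=self.training,
                              momentum=self.momentum, eps=self.eps)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, *, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_he_normal(rng, (out_f, in_f), in_f))
        self.bias = Parameter(np.zeros(out_f))

    def forward(self, x):
        return F.linear(x, self.weight, self.bias)
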