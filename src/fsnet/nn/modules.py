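"""Layer abstractions over the autodiff core: Conv2d, ConvTranspose2d,
BatchNorm2d, Sequential, with Kaiming-uniform initialisation drawn from a
seedable module-level generator (:func:`manual_seed`)."""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, conv2d, conv_transpose2d

_rng = np.random.default_rng(0)


def manual_seed(seed: int) -> None:
    """Reset the parameter-initialisation RNG (call before building a model)."""
    global _rng
    _rng = np.random.default_rng(seed)


def kaiming_uniform(shape: tuple, fan_in: int, dtype=np.float32) -> np.ndarray:
    bound = math.sqrt(6.0 / fan_in)
    return _rng.uniform(-bound, bound, size=shape).astype(dtype)


class Parameter(Tensor):
    def __init__(self, data: np.ndarray):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal container: tracks sub-modules and parameters, train/eval mode."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            full = f"{prefix}.{name}" if prefix else name
            if isinstance(val, Parameter):
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(full)
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

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

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # plain-dict (de)serialisation so checkpoints stay numpy-only
    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, val in self._named_buffers():
            state[name] = val.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self._named_buffers())
        for key, arr in state.items():
            if key in params:
                params[key].data = np.asarray(arr, dtype=params[key].data.dtype)
            elif key in buffers:
                buffers[key][...] = arr
            else:
                raise KeyError(f"unexpected state entry {key!r}")

    def _named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            full = f"{prefix}.{name}" if prefix else name
            if isinstance(val, Module):
                yield from val._named_buffers(full)
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item._named_buffers(f"{full}.{i}")
            elif isinstance(val, np.ndarray) and name.startswith("running_"):
                yield full, val


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, padding: int = 0,
                 bias: bool = True, dtype=np.float32):
        super().__init__()
        self.padding = padding
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(kaiming_uniform((out_ch, in_ch, kernel, kernel), fan_in, dtype))
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding)


class ConvTranspose2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int = 2, stride: int = 2,
                 dtype=np.float32):
        super().__init__()
        if kernel != stride:
            raise ValueError("only kernel == stride supported")
        self.stride = stride
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(kaiming_uniform((in_ch, out_ch, kernel, kernel), fan_in, dtype))
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias, stride=self.stride)


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics.

    Training mode normalises by batch statistics and updates the running
    moments; eval mode uses the running moments, making inference
    deterministic and batch-size independent.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(channels, dtype=dtype))
        self.bias = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            self.running_mean += self.momentum * (mu.data.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (unbiased - self.running_var)
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        w = self.weight.reshape(1, -1, 1, 1)
        b = self.bias.reshape(1, -1, 1, 1)
        return xhat * w + b


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


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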