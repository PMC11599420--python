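"""Small neural-network layer zoo over :mod:`constructs.autodiff`.

Provides the modules the translation and segmentation networks are built
from (convolution with reflection padding, instance normalisation, linear
projections) plus an Adam optimiser.  Parameter initialisation is explicit
and seeded so training runs are reproducible.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, avg_pool2d, concat, conv2d, pad2d, upsample_nearest2d

__all__ = [
    "Parameter", "Module", "Sequential", "Conv2d", "Linear", "InstanceNorm2d",
    "ReLU", "LeakyReLU", "Tanh", "Adam", "avg_pool2d", "upsample_nearest2d",
    "concat",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and flat state dicts."""

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{full}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item
            elif isinstance(val, dict):
                for key in sorted(val, key=str):
                    item = val[key]
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{key}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{key}", item

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}")
            p.data = np.asarray(state[k], dtype=np.float32).copy()

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def init_gaussian(self, rng: np.random.Generator, std: float = 0.02):
        """Zero-mean Gaussian weight init; biases and norm scales untouched."""
        for name, p in self.named_parameters():
            if name.endswith(".gamma") or name.endswith(".beta"):
                continue
            if name.endswith(".b"):
                p.data = np.zeros_like(p.data)
            else:
                p.data = rng.normal(0.0, std, size=p.data.shape).astype(np.float32)
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *mods):
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int = 1,
                 pad: int = 0, pad_mode: str = "reflect", bias: bool = True):
        fan_in = in_ch * k * k
        self.w = Parameter(np.random.default_rng(0).normal(0, np.sqrt(1.0 / fan_in),
                                                           (out_ch, in_ch, k, k)))
        self.b = Parameter(np.zeros(out_ch)) if bias else None
        self.stride, self.pad, self.pad_mode = stride, pad, pad_mode

    def forward(self, x):
        if self.pad:
            x = pad2d(x, self.pad, self.pad_mode)
        return conv2d(x, self.w, self.b, stride=self.stride)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, bias: bool = True):
        self.w = Parameter(np.random.default_rng(0).normal(0, np.sqrt(1.0 / in_f),
                                                           (in_f, out_f)))
        self.b = Parameter(np.zeros(out_f)) if bias else None

    def forward(self, x):
        y = x @ self.w
        return y + self.b if self.b is not None else y


class InstanceNorm2d(Module):
    """Per-sample, per-channel spatial normalisation with affine scale/shift."""

    def __init__(self, ch: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones((1, ch, 1, 1)))
        self.beta = Parameter(np.zeros((1, ch, 1, 1)))
        self.eps = eps

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        xn = xc / (var + self.eps).sqrt()
        return xn * self.gamma + self.beta


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x):
        return x.leaky_relu(self.slope)


class Tanh(Module):
    def forward(self, x):
        return x.tanh()


class Adam:
    """Adam with optional linear LR decay over the second half of training."""

    def __init__(self, params, lr: float = 2e-4, betas=(0.5, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.base_lr = self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def set_lr_linear_decay(self, step: int, total: int):
        half = total // 2
        if total > 0 and step > half:
            frac = max(0.0, 1.0 - (step - half) / max(1, total - half))
            self.lr = self.base_lr * frac

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * (g * g)
            p.data = p.data - self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def state_dict(self) -> dict:
        return {"t": self.t, "lr": self.lr,
                "m": [a.copy() for a in self.m], "v": [a.copy() for a in self.v]}

    def load_state_dict(self, s: dict):
        self.t = int(s["t"])
        self.lr = float(s["lr"])
        self.m = [np.asarray(a) for a in s["m"]]
        self.v = [np.asarray(a) for a in s["v"]]
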