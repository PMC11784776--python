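"""Trainable layers and the module system built on the autodiff core."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d, depthwise_conv2d

__all__ = [
    "Parameter", "Module", "Linear", "Conv2d", "DepthwiseConv2d",
    "BatchNorm2d", "LayerNorm", "cross_entropy",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Container with recursive parameter discovery and a train/eval flag."""

    def __init__(self):
        self.training = True

    def modules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item
                        yield from item.modules()

    def parameters(self):
        seen = set()
        for mod in [self, *self.modules()]:
            for v in mod.__dict__.values():
                if isinstance(v, Parameter) and id(v) not in seen:
                    seen.add(id(v))
                    yield v
                elif isinstance(v, (list, tuple)):
                    for item in v:
                        if isinstance(item, Parameter) and id(item) not in seen:
                            seen.add(id(item))
                            yield item

    def named_state(self, prefix: str = ""):
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Parameter):
                yield name, v
            elif isinstance(v, Tensor):
                yield name, v
            elif isinstance(v, np.ndarray):
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_state(f"{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_state(f"{name}.{i}.")
                    elif isinstance(item, (Parameter, Tensor)):
                        yield f"{name}.{i}", item

    def state_dict(self) -> dict:
        out = {}
        for name, v in self.named_state():
            out[name] = v.data.copy() if isinstance(v, Tensor) else v.copy()
        return out

    def load_state_dict(self, state: dict):
        for name, v in self.named_state():
            if name not in state:
                raise KeyError(f"missing state entry: {name}")
            if isinstance(v, Tensor):
                v.data[...] = state[name]
            else:
                v[...] = state[name]

    def train(self):
        self.training = True
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        self.training = False
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


def _he(rng: np.random.Generator, shape, fan_in: int):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.w = Parameter(_he(rng, (in_dim, out_dim), in_dim))
        self.b = Parameter(np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1,
                 padding: int | None = None, bias: bool = True):
        super().__init__()
        if padding is None:
            padding = kernel // 2
        fan_in = in_ch * kernel * kernel
        self.w = Parameter(_he(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.b = Parameter(np.zeros(out_ch)) if bias else None
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None):
        super().__init__()
        if padding is None:
            padding = kernel // 2
        self.w = Parameter(_he(rng, (channels, kernel, kernel), kernel * kernel))
        self.b = Parameter(np.zeros(channels))
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return depthwise_conv2d(x, self.w, self.b, stride=self.stride,
                                padding=self.padding)


class BatchNorm2d(Module):
    """Batch normalisation over (N, H, W) per channel, with running stats.

    Besides the usual EMA update, the layer supports an exact
    statistics-refresh pass (see :func:`refresh_bn_stats`): trainers
    run one forward sweep over the training data after optimisation so
    that eval-mode inference uses true training-set moments even after
    very short training runs.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._acc = None  # (count, sum, sum of squares) during refresh

    def __call__(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            if self._acc is not None:
                cnt, s1, s2 = self._acc
                d = x.data
                n = d.shape[0] * d.shape[2] * d.shape[3]
                self._acc = (cnt + n, s1 + d.sum(axis=axes),
                             s2 + (d * d).sum(axis=axes))
            else:
                self.running_mean = ((1 - self.momentum) * self.running_mean
                                     + self.momentum * mu.data.ravel())
                self.running_var = ((1 - self.momentum) * self.running_var
                                    + self.momentum * var.data.ravel())
            xn = (x - mu) / (var + self.eps).sqrt()
        else:
            mu = self.running_mean[None, :, None, None]
            sd = np.sqrt(self.running_var + self.eps)[None, :, None, None]
            xn = (x - Tensor(mu)) * Tensor(1.0 / sd)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xn * g + b


class LayerNorm(Module):
    """Normalisation over the last axis (token channels)."""

    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        xn = (x - mu) / (var + self.eps).sqrt()
        return xn * self.gamma + self.beta


def refresh_bn_stats(module: Module, forward, batches):
    """Recompute every BatchNorm's running stats exactly from data.

    Runs ``forward(batch)`` for each batch in train mode while the BN
    layers accumulate channelwise first and second moments, then sets
    ``running_mean``/``running_var`` to the pooled moments.
    """
    bns = [m for m in [module, *module.modules()]
           if isinstance(m, BatchNorm2d)]
    was_training = module.training
    module.train()
    for b in bns:
        b._acc = (0, np.zeros_like(b.running_mean),
                  np.zeros_like(b.running_var))
    for batch in batches:
        forward(batch)
    for b in bns:
        cnt, s1, s2 = b._acc
        if cnt > 0:
            mean = s1 / cnt
            b.running_mean = mean
            b.running_var = np.maximum(s2 / cnt - mean**2, 0.0)
        b._acc = None
    if not was_training:
        module.eval()


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy from raw logits (integer labels)."""
    n = logits.shape[0]
    shifted = logits - Tensor(logits.data.max(axis=1, keepdims=True))
    logsumexp = shifted.exp().sum(axis=1, keepdims=True).log()
    logp = shifted - logsumexp
    picked = logp[np.arange(n), labels]
    return -picked.mean()
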