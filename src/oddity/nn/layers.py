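"""Trainable layers built on the autodiff core.

Initialisation follows common deep-learning defaults: Glorot-uniform for
dense and convolutional kernels, zeros for biases (unless a layer overrides
them), orthogonal recurrent matrices for the LSTM.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def orthogonal(rng: np.random.Generator, shape) -> np.ndarray:
    a = rng.standard_normal(shape)
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    return q.astype(np.float32)


class Module:
    """Minimal parameter container."""

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
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def num_params(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters and buffers (for checkpoints)."""
        out: dict[str, np.ndarray] = {}

        def walk(obj, prefix):
            for k, v in obj.__dict__.items():
                name = f"{prefix}{k}"
                if isinstance(v, Tensor):
                    out[name] = v.data
                elif isinstance(v, dict) and set(v) == {"mean", "var"}:
                    out[f"{name}.mean"] = v["mean"]
                    out[f"{name}.var"] = v["var"]
                elif isinstance(v, Module):
                    walk(v, name + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{name}.{i}.")
                        elif isinstance(item, Tensor):
                            out[f"{name}.{i}"] = item.data
        walk(self, "")
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        current = self.state_arrays()
        missing = set(current) - set(arrays)
        if missing:
            raise KeyError(f"checkpoint missing arrays: {sorted(missing)[:5]}")
        for name, target in current.items():
            src = np.asarray(arrays[name])
            if src.shape != target.shape:
                raise ValueError(f"checkpoint array {name!r}: shape {src.shape} != {target.shape}")
            target[...] = src


class Dense(Module):
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int, bias: bool = True):
        self.w = Tensor(glorot_uniform(rng, (n_in, n_out), n_in, n_out), requires_grad=True)
        self.b = Tensor(np.zeros(n_out, dtype=np.float32), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.w
        return y + self.b if self.b is not None else y


class Conv2D(Module):
    """Valid 5x5-style convolution without bias (batch norm follows it)."""

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int, kernel: int):
        fan_in = c_in * kernel * kernel
        fan_out = c_out * kernel * kernel
        self.w = Tensor(glorot_uniform(rng, (c_out, c_in, kernel, kernel), fan_in, fan_out),
                        requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d_valid(x, self.w)


class BatchNorm(Module):
    """Batch normalisation; running statistics use momentum 0.9 so that
    inference-mode statistics are usable within the short training
    schedules this package runs (a 0.99 momentum needs hundreds of updates
    to forget its initialisation)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3):
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running = {"mean": np.zeros(channels, dtype=np.float32),
                        "var": np.ones(channels, dtype=np.float32)}
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, train: bool, fuse_relu: bool = False) -> Tensor:
        return ad.batchnorm(x, self.gamma, self.beta, self.running, train,
                            momentum=self.momentum, eps=self.eps,
                            fuse_relu=fuse_relu)


class Adam:
    """Adam optimiser (lr 1e-3, beta1 0.9, beta2 0.999, eps 1e-8 by default)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if not np.all(np.isfinite(g)):
                raise FloatingPointError("non-finite gradient encountered")
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= lr_t * m / (np.sqrt(v) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
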