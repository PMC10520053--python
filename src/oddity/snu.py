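"""Spiking neural units: leaky integrate-and-fire dynamics as a recurrent layer.

A layer of SNUs evolves per time step as

    s_t = g( W x_t + H y_{t-1} + lambda * s_{t-1} * (1 - y_{t-1}) )
    y_t = h( s_t + b )

with input activation g = identity. The membrane potential s_t (V_m)
integrates weighted input, leaks with factor lambda (default 0.8), and is
reset after an output spike through the (1 - y_{t-1}) gate. The bias b
realises the firing threshold V_th and is initialised to -1.0. Variants:

* ``snn``     h = Heaviside step (binary spikes; trained with a sigmoid
              surrogate derivative),
* ``ssnu``    h = sigmoid ("soft" SNU),
* ``ssnu-r``  sigmoid plus a layer-wise recurrent matrix H.

An LSTM layer with the same step contract is provided as the conventional
deep-learning baseline.

This module exposes both a plain-numpy reference (``snu_step`` /
``unroll_layer``; the test surface and closed-form oracle target) and
autodiff layers used by the trainable saccadic model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Module, Tensor, glorot_uniform, orthogonal
from .nn import autodiff as ad

VARIANTS = ("snn", "ssnu", "ssnu-r", "lstm")
DEFAULT_LEAK = 0.8
DEFAULT_BIAS = -1.0

__all__ = ["SNUParams", "SNUState", "snu_step", "unroll_layer",
           "init_unit_params", "SNULayer", "LSTMLayer", "make_layer",
           "VARIANTS", "DEFAULT_LEAK", "DEFAULT_BIAS"]


def _sigmoid(v):
    return 1.0 / (1.0 + np.exp(-np.clip(v, -60, 60)))


@dataclass
class SNUParams:
    """Numpy parameter set for one SNU layer."""

    W: np.ndarray                       # (fan_in, N)
    b: np.ndarray                       # (N,)
    lam: float = DEFAULT_LEAK
    H: np.ndarray | None = None         # (N, N), recurrent variants only
    variant: str = "snn"                # 'snn' | 'ssnu' | 'ssnu-r'

    def __post_init__(self):
        if self.variant not in ("snn", "ssnu", "ssnu-r"):
            raise ValueError(f"unknown SNU variant {self.variant!r}")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"leak must lie in [0, 1], got {self.lam}")
        if (self.H is not None) != self.variant.endswith("-r"):
            raise ValueError(f"variant {self.variant!r} inconsistent with "
                             f"{'presence' if self.H is not None else 'absence'} of H")

    @property
    def n(self) -> int:
        return self.W.shape[1]


@dataclass
class SNUState:
    """Membrane potentials and previous outputs of one layer."""

    s: np.ndarray
    y: np.ndarray

    @classmethod
    def zeros(cls, n: int, batch: tuple = ()) -> "SNUState":
        shape = batch + (n,)
        return cls(s=np.zeros(shape, dtype=np.float32),
                   y=np.zeros(shape, dtype=np.float32))


def snu_step(x_t: np.ndarray, state: SNUState, params: SNUParams):
    """One Euler step of the SNU dynamics; returns (y_t, new_state)."""
    drive = np.asarray(x_t, dtype=np.float32) @ params.W
    if params.H is not None:
        drive = drive + state.y @ params.H
    s_t = drive + params.lam * state.s * (1.0 - state.y)
    if not np.all(np.isfinite(s_t)):
        raise FloatingPointError("non-finite membrane potential in snu_step")
    v = s_t + params.b
    y_t = (v > 0).astype(np.float32) if params.variant == "snn" else _sigmoid(v).astype(np.float32)
    return y_t, SNUState(s=s_t.astype(np.float32), y=y_t)


def unroll_layer(inputs, params: SNUParams, state: SNUState | None = None):
    """Run ``snu_step`` over a sequence; returns (outputs, states, final state).

    ``states[t]`` holds the membrane potentials after step t.
    """
    inputs = list(inputs)
    if len(inputs) == 0:
        raise ValueError("unroll_layer needs at least one input step")
    x0 = np.asarray(inputs[0])
    if state is None:
        state = SNUState.zeros(params.n, batch=x0.shape[:-1])
    outputs, states = [], []
    for x_t in inputs:
        y_t, state = snu_step(x_t, state, params)
        outputs.append(y_t)
        states.append(state.s)
    return outputs, states, state


def init_unit_params(rng: np.random.Generator, fan_in: int, n: int,
                     variant: str = "snn", lam: float = DEFAULT_LEAK) -> SNUParams:
    """Fresh parameters: Glorot-uniform W (and H), biases at -1.0, leak 0.8."""
    if fan_in <= 0 or n <= 0:
        raise ValueError("fan_in and N must be positive")
    w = glorot_uniform(rng, (fan_in, n), fan_in, n)
    h = glorot_uniform(rng, (n, n), n, n) if variant.endswith("-r") else None
    b = np.full(n, DEFAULT_BIAS, dtype=np.float32)
    return SNUParams(W=w, b=b, lam=lam, H=h, variant=variant)


# ---------------------------------------------------------------------------
# trainable layers (autodiff)
# ---------------------------------------------------------------------------

class SNULayer(Module):
    """Trainable SNU layer with the step contract used by the saccadic model.

    State is a pair of Tensors (s, y); gradients flow through the full
    unrolled sequence (no truncation). The leak is a fixed hyperparameter,
    not a trainable weight.
    """

    def __init__(self, rng: np.random.Generator, fan_in: int, n: int,
                 variant: str = "snn", lam: float = DEFAULT_LEAK):
        if variant not in ("snn", "ssnu", "ssnu-r"):
            raise ValueError(f"unknown SNU variant {variant!r}")
        self.variant = variant
        self.n = n
        self.lam = float(lam)
        self.w = Tensor(glorot_uniform(rng, (fan_in, n), fan_in, n), requires_grad=True)
        self.b = Tensor(np.full(n, DEFAULT_BIAS, dtype=np.float32), requires_grad=True)
        self.h = (Tensor(glorot_uniform(rng, (n, n), n, n), requires_grad=True)
                  if variant.endswith("-r") else None)

    def initial_state(self, batch: int):
        z = Tensor(np.zeros((batch, self.n), dtype=np.float32))
        return (z, z)

    def step(self, x_t: Tensor, state):
        s_prev, y_prev = state
        drive = x_t @ self.w
        if self.h is not None:
            drive = drive + y_prev @ self.h
        s_t = drive + self.lam * (s_prev * (1.0 - y_prev))
        v = s_t + self.b
        y_t = ad.spike(v) if self.variant == "snn" else ad.sigmoid(v)
        return y_t, (s_t, y_t)


class LSTMLayer(Module):
    """Standard LSTM with the same (input, state) -> (output, state) contract.

    Gate order i, f, c, o; forget-gate bias initialised to 1.0; Glorot
    input kernel and orthogonal recurrent kernel.
    """

    def __init__(self, rng: np.random.Generator, fan_in: int, n: int):
        self.n = n
        self.w = Tensor(glorot_uniform(rng, (fan_in, 4 * n), fan_in, 4 * n),
                        requires_grad=True)
        self.u = Tensor(np.concatenate([orthogonal(rng, (n, n)) for _ in range(4)],
                                       axis=1), requires_grad=True)
        bias = np.zeros(4 * n, dtype=np.float32)
        bias[n:2 * n] = 1.0
        self.b = Tensor(bias, requires_grad=True)

    def initial_state(self, batch: int):
        z = Tensor(np.zeros((batch, self.n), dtype=np.float32))
        return (z, z)

    def step(self, x_t: Tensor, state):
        c_prev, h_prev = state
        z = x_t @ self.w + h_prev @ self.u + self.b
        n = self.n
        i = ad.sigmoid(_slice_cols(z, 0, n))
        f = ad.sigmoid(_slice_cols(z, n, 2 * n))
        g = ad.tanh(_slice_cols(z, 2 * n, 3 * n))
        o = ad.sigmoid(_slice_cols(z, 3 * n, 4 * n))
        c_t = f * c_prev + i * g
        h_t = o * ad.tanh(c_t)
        return h_t, (c_t, h_t)


def _slice_cols(t: Tensor, lo: int, hi: int) -> Tensor:
    """Column slice as an autodiff op."""
    def backward(g):
        full = np.zeros_like(t.data)
        full[:, lo:hi] = g
        ad._accum(t, full)
    return ad._make(t.data[:, lo:hi], (t,), backward)


def make_layer(rng: np.random.Generator, fan_in: int, n: int, variant: str):
    """Factory over the shared layer contract."""
    if variant == "lstm":
        return LSTMLayer(rng, fan_in, n)
    if variant in ("snn", "ssnu", "ssnu-r"):
        return SNULayer(rng, fan_in, n, variant=variant)
    raise ValueError(f"unknown unit variant {variant!r}; choose from {VARIANTS}")
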