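"""Saccadic reasoning network.

The six candidate frames are presented one at a time over T = 36 simulated
saccades, built as six consecutive uniform random permutations of the six
frames so every frame is seen exactly six times and exactly once per block
of six. At each step the shared vision CNN embeds the fixated frame; the
embedding is concatenated with a 6-dimensional one-hot eye-position code
(input width D + 6 = 3206 at the default D) and processed by three
recurrent layers (SNN / sSNU / sSNU-R / LSTM) of width N followed by a
single stateless sigmoid readout giving the per-saccade oddity belief
p(oddity | t).

Training minimises a masked binary cross-entropy: the first two saccades
are masked out (the third distinct frame is the earliest moment an oddity
conjecture is possible). Evaluation discards the first S_I = 18
initialisation saccades and averages each frame's beliefs over its three
appearances within the S_E = 18 evaluation saccades; the frame with the
highest integrated belief is the decision (ties to the lowest index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Dense, Module, Tensor
from .nn import autodiff as ad
from .oren import N_FRAMES
from .snu import make_layer
from .vision import VisionConfig, VisionModel

T_STEPS = 36
EPS_BELIEF = 1e-7

__all__ = ["SaccadeConfig", "SaccadeStream", "BeliefTrace", "build_stream",
           "masked_loss", "decide", "SaccadicModel", "T_STEPS"]


@dataclass(frozen=True)
class SaccadeConfig:
    s_init: int = 18        # saccades that warm up the temporal dynamics
    s_eval: int = 18        # saccades whose beliefs are integrated
    mask_first: int = 2     # leading saccades excluded from the loss

    def __post_init__(self):
        if self.s_init + self.s_eval != T_STEPS:
            raise ValueError(f"S_I + S_E must equal {T_STEPS}")


@dataclass
class SaccadeStream:
    """Order of fixations plus the matching one-hot eye-position codes."""

    frame_order: np.ndarray         # (36,) ints in [0, 5]
    position_code: np.ndarray       # (36, 6) one-hot rows

    def __len__(self):
        return len(self.frame_order)


@dataclass
class BeliefTrace:
    """Per-saccade oddity beliefs with the loss mask and frame annotation."""

    beliefs: np.ndarray             # (36,) values in (0, 1)
    frame_order: np.ndarray         # (36,)
    mask: np.ndarray                # (36,) bool; False on masked steps


def build_stream(rng: np.random.Generator, sample=None) -> SaccadeStream:
    """Six independent uniform permutations of the six frames, concatenated."""
    order = np.concatenate([rng.permutation(N_FRAMES) for _ in range(T_STEPS // N_FRAMES)])
    code = np.zeros((T_STEPS, N_FRAMES), dtype=np.float32)
    code[np.arange(T_STEPS), order] = 1.0
    return SaccadeStream(frame_order=order.astype(np.int64), position_code=code)


def stream_orders(rng: np.random.Generator, batch: int) -> np.ndarray:
    """(batch, 36) frame orders, one independent stream per sample."""
    return np.stack([build_stream(rng).frame_order for _ in range(batch)])


def masked_loss(trace: BeliefTrace, oddity_index: int) -> float:
    """Mean binary cross-entropy over unmasked saccades.

    The per-step target is 1 where the fixated frame is the oddity. Beliefs
    are clipped to [eps, 1-eps] before the logarithm.
    """
    if not 0 <= oddity_index < N_FRAMES:
        raise IndexError(f"oddity index {oddity_index} out of range")
    p = np.clip(np.asarray(trace.beliefs, dtype=np.float64), EPS_BELIEF, 1 - EPS_BELIEF)
    target = (trace.frame_order == oddity_index).astype(np.float64)
    mask = np.asarray(trace.mask, dtype=bool)
    bce = -(target * np.log(p) + (1 - target) * np.log(1 - p))
    return float(bce[mask].mean())


def decide(trace: BeliefTrace, config: SaccadeConfig = SaccadeConfig()) -> int:
    """Integrate evaluation-window beliefs per frame and return the argmax.

    Each frame appears exactly S_E/6 times in the evaluation window; its
    beliefs there are averaged. Ties break toward the lowest frame index.
    """
    beliefs = np.asarray(trace.beliefs, dtype=np.float64)[-config.s_eval:]
    order = np.asarray(trace.frame_order)[-config.s_eval:]
    scores = np.zeros(N_FRAMES)
    for k in range(N_FRAMES):
        scores[k] = beliefs[order == k].mean()
    return int(np.argmax(scores))


class SaccadicModel(Module):
    """Vision CNN + three recurrent layers + stateless sigmoid readout."""

    def __init__(self, rng: np.random.Generator, n: int = 128, unit: str = "ssnu",
                 vision_config: VisionConfig = VisionConfig(), n_layers: int = 3):
        self.n = n
        self.unit = unit
        self.vision = VisionModel(rng, vision_config)
        d = self.vision.out_dim
        self.layers = []
        fan_in = d + N_FRAMES
        for _ in range(n_layers):
            self.layers.append(make_layer(rng, fan_in, n, unit))
            fan_in = n
        self.readout = Dense(rng, n, 1)

    # -- forward -----------------------------------------------------------
    def beliefs(self, grids: Tensor | np.ndarray, orders: np.ndarray,
                train: bool = False, return_states: bool = False):
        """(B, 6, S, S) grids + (B, 36) stream orders -> (B, 36) beliefs.

        With ``return_states`` also returns, per layer, the stacked membrane
        state values (B, 36, N) recorded after every step (detached).
        """
        if not isinstance(grids, Tensor):
            grids = Tensor(grids)
        b = grids.data.shape[0]
        if orders.shape != (b, T_STEPS):
            raise ValueError(f"orders must have shape ({b}, {T_STEPS}), got {orders.shape}")
        flat = ad.reshape(grids, (b * N_FRAMES, 1) + grids.data.shape[2:])
        emb = self.vision(flat, train)
        emb = ad.reshape(emb, (b, N_FRAMES, self.vision.out_dim))

        states = [layer.initial_state(b) for layer in self.layers]
        recorded: list[list[np.ndarray]] = [[] for _ in self.layers]
        belief_cols = []
        onehot = np.eye(N_FRAMES, dtype=np.float32)
        for t in range(T_STEPS):
            x_t = ad.take_rows(emb, orders[:, t])
            code = Tensor(onehot[orders[:, t]])
            x_t = ad.concat([x_t, code], axis=1)
            h = x_t
            for li, layer in enumerate(self.layers):
                h, states[li] = layer.step(h, states[li])
                if return_states:
                    recorded[li].append(states[li][0].data)
            belief_cols.append(ad.sigmoid(self.readout(h)))
        beliefs = ad.concat(belief_cols, axis=1)
        if return_states:
            return beliefs, [np.stack(r, axis=1) for r in recorded]
        return beliefs

    def loss(self, grids, orders: np.ndarray, oddity: np.ndarray,
             train: bool = True, mask_first: int = 2) -> Tensor:
        """Masked binary cross-entropy over a batch (graph node)."""
        beliefs = self.beliefs(grids, orders, train=train)
        target = (orders == np.asarray(oddity)[:, None]).astype(np.float32)
        mask = np.ones_like(target)
        mask[:, :mask_first] = 0.0
        p = ad.clip(beliefs, EPS_BELIEF, 1.0 - EPS_BELIEF)
        bce = -(target * ad.log(p) + (1.0 - target) * ad.log(1.0 - p))
        return (bce * mask).sum() * (1.0 / float(mask.sum()))

    # -- inference ---------------------------------------------------------
    def trace(self, grids: np.ndarray, stream: SaccadeStream,
              config: SaccadeConfig = SaccadeConfig()) -> BeliefTrace:
        """Single-sample inference: (6, S, S) grids -> BeliefTrace."""
        beliefs = self.beliefs(grids[None], stream.frame_order[None], train=False)
        mask = np.ones(T_STEPS, dtype=bool)
        mask[:config.mask_first] = False
        return BeliefTrace(beliefs=beliefs.data[0].astype(np.float64),
                           frame_order=stream.frame_order, mask=mask)

    def predict(self, grids_batch: np.ndarray, rng: np.random.Generator,
                config: SaccadeConfig = SaccadeConfig()) -> np.ndarray:
        """Batch decisions, one fresh stream per sample."""
        b = grids_batch.shape[0]
        orders = stream_orders(rng, b)
        beliefs = self.beliefs(grids_batch, orders, train=False).data
        preds = np.empty(b, dtype=np.int64)
        mask = np.ones(T_STEPS, dtype=bool)
        mask[:config.mask_first] = False
        for j in range(b):
            trace = BeliefTrace(beliefs=beliefs[j].astype(np.float64),
                                frame_order=orders[j], mask=mask)
            preds[j] = decide(trace, config)
        return preds
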