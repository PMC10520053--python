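"""Oddity Relation Network (OReN).

Each of the six frame embeddings eta_k is paired by ordered concatenation
with all six embeddings (36 pairs of length 2D). A shared relation MLP
g_theta scores each pair; the six pair outputs sharing the same first item k
are summed and passed through the scoring MLP f_phi:

    q_k = f_phi( sum_{i=1..6} g_theta(eta_k, eta_i) )

and a softmax across the six scores q gives the probability of each frame
being the oddity. g_theta is a four-layer rectified-linear MLP of width N
with dropout 0.3 after each layer; f_phi is two rectified-linear layers of
width N followed by a single linear output neuron (no dropout). Training
minimises the categorical cross-entropy of the softmax probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Dense, Module, Tensor
from .nn import autodiff as ad
from .vision import VisionConfig, VisionModel

N_FRAMES = 6
N_PAIRS = N_FRAMES * N_FRAMES

__all__ = ["ScoreVector", "make_pairs", "oren_forward", "oren_loss", "OReNModel",
           "N_FRAMES", "N_PAIRS"]


@dataclass
class ScoreVector:
    """Per-frame scores q_k and their softmax probabilities."""

    q: np.ndarray
    p: np.ndarray

    @property
    def prediction(self) -> int:
        # ties broken toward the lowest index (np.argmax convention)
        return int(np.argmax(self.p))


def make_pairs(embeddings) -> np.ndarray:
    """Ordered concatenation pairs: (..., 6, D) -> (..., 36, 2D).

    Pair (k, i) sits at flat index 6*k + i and equals [eta_k, eta_i]; k is
    the outer (first-item) index.
    """
    emb = np.asarray(embeddings)
    if emb.shape[-2] != N_FRAMES:
        raise ValueError(f"expected {N_FRAMES} embeddings, got {emb.shape[-2]}")
    d = emb.shape[-1]
    lead = emb.shape[:-2]
    first = np.broadcast_to(emb[..., :, None, :], lead + (N_FRAMES, N_FRAMES, d))
    second = np.broadcast_to(emb[..., None, :, :], lead + (N_FRAMES, N_FRAMES, d))
    return np.concatenate([first, second], axis=-1).reshape(lead + (N_PAIRS, 2 * d))


def oren_forward(embeddings, g_fn, f_fn) -> ScoreVector:
    """Reference forward pass with injectable relation/scoring functions.

    ``g_fn(u, v)`` maps two length-D vectors to a relation vector (or
    scalar); ``f_fn(r)`` maps the summed relation to a scalar score.
    """
    emb = [np.asarray(e, dtype=np.float64).ravel() for e in embeddings]
    if len(emb) != N_FRAMES:
        raise ValueError(f"expected {N_FRAMES} embeddings, got {len(emb)}")
    d = emb[0].size
    if any(e.size != d for e in emb):
        raise ValueError("embeddings must all have the same length")
    q = np.empty(N_FRAMES)
    for k in range(N_FRAMES):
        acc = None
        for i in range(N_FRAMES):
            r = np.asarray(g_fn(emb[k], emb[i]), dtype=np.float64)
            acc = r if acc is None else acc + r
        q[k] = float(np.asarray(f_fn(acc)).reshape(()))
    if not np.all(np.isfinite(q)):
        raise FloatingPointError(f"non-finite OReN scores: {q}")
    z = q - q.max()
    e = np.exp(z)
    return ScoreVector(q=q, p=e / e.sum())


def oren_loss(p, oddity_index) -> float:
    """Categorical cross-entropy -log p[oddity]; batched input is averaged."""
    p = np.asarray(p, dtype=np.float64)
    if p.ndim == 1:
        p, oddity_index = p[None, :], [oddity_index]
    labels = np.asarray(oddity_index)
    if np.any(labels < 0) or np.any(labels >= p.shape[1]):
        raise IndexError(f"oddity index out of range for {p.shape[1]} frames")
    return float(-np.log(p[np.arange(len(p)), labels]).mean())


class OReNModel(Module):
    """Trainable OReN: shared vision CNN + g_theta + f_phi + softmax."""

    def __init__(self, rng: np.random.Generator, n: int = 128,
                 vision_config: VisionConfig = VisionConfig(),
                 dropout_rate: float = 0.3):
        self.n = n
        self.vision = VisionModel(rng, vision_config)
        d = self.vision.out_dim
        self.g_layers = [Dense(rng, 2 * d, n)] + [Dense(rng, n, n) for _ in range(3)]
        self.f_layers = [Dense(rng, n, n), Dense(rng, n, n)]
        self.f_out = Dense(rng, n, 1)
        self.dropout_rate = dropout_rate
        self._dropout_rng = np.random.default_rng(rng.integers(0, 2**31))

    # -- pieces ------------------------------------------------------------
    def g_theta(self, pairs: Tensor, train: bool = False) -> Tensor:
        x = pairs
        for layer in self.g_layers:
            x = ad.relu(layer(x))
            x = ad.dropout(x, self.dropout_rate, self._dropout_rng, train)
        return x

    def f_phi(self, summed: Tensor) -> Tensor:
        x = summed
        for layer in self.f_layers:
            x = ad.relu(layer(x))
        return self.f_out(x)

    # -- forward -----------------------------------------------------------
    def logits_from_embeddings(self, emb: Tensor, train: bool = False) -> Tensor:
        """(B, 6, D) embeddings -> (B, 6) scores q."""
        b, k, d = emb.data.shape
        if k != N_FRAMES:
            raise ValueError(f"expected {N_FRAMES} embeddings per sample, got {k}")
        first = ad.broadcast_to(ad.reshape(emb, (b, k, 1, d)), (b, k, k, d))
        second = ad.broadcast_to(ad.reshape(emb, (b, 1, k, d)), (b, k, k, d))
        pairs = ad.reshape(ad.concat([first, second], axis=-1), (b * N_PAIRS, 2 * d))
        rel = self.g_theta(pairs, train)
        rel = ad.reshape(rel, (b, k, k, self.n))
        summed = ad.reshape(rel.sum(axis=2), (b * k, self.n))
        q = ad.reshape(self.f_phi(summed), (b, k))
        return q

    def logits(self, grids: Tensor, train: bool = False) -> Tensor:
        """(B, 6, S, S) preprocessed grids -> (B, 6) scores."""
        b = grids.data.shape[0]
        flat = ad.reshape(grids, (b * N_FRAMES, 1) + grids.data.shape[2:])
        emb = self.vision(flat, train)
        return self.logits_from_embeddings(
            ad.reshape(emb, (b, N_FRAMES, self.vision.out_dim)), train)

    def score(self, grids: np.ndarray) -> ScoreVector:
        """Inference on one sample: (6, S, S) -> ScoreVector."""
        q = self.logits(Tensor(grids[None]), train=False).data[0]
        z = q - q.max()
        e = np.exp(z.astype(np.float64))
        return ScoreVector(q=q.astype(np.float64), p=e / e.sum())

    def predict(self, grids_batch: np.ndarray) -> np.ndarray:
        """(B, 6, S, S) -> predicted oddity indices (lowest-index ties)."""
        q = self.logits(Tensor(grids_batch), train=False).data
        return q.argmax(axis=1)
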