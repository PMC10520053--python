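"""Introspection of saccadic-network membrane dynamics.

Records the per-saccade membrane-potential vectors s_t (V_m) of a chosen
recurrent layer as a 36 x N activity map, reorders the saccade rows so the
fixated-frame sequence matches the relation network's outer pair order
(all fixations of frame 0, then frame 1, ...), and normalises rows for
heatmap display. On a trained model the rows recorded while fixating the
oddity stand out from the non-oddity rows — the temporal analogue of the
relation network's distinctive pair activations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .saccadic import SaccadeStream, SaccadicModel, T_STEPS

__all__ = ["ActivityMap", "record_membrane_trace", "reorder_saccade_rows",
           "normalize_rows", "oddity_distinctiveness", "save_heatmap",
           "save_csv"]


@dataclass
class ActivityMap:
    """36 x N matrix of layer states with per-row frame annotations."""

    values: np.ndarray          # (36, N)
    frame_index: np.ndarray     # (36,)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.frame_index = np.asarray(self.frame_index)
        if self.values.shape[0] != T_STEPS:
            raise ValueError(f"activity map needs {T_STEPS} rows, got {self.values.shape[0]}")
        if self.frame_index.shape[0] != T_STEPS:
            raise ValueError("missing frame annotations")


def record_membrane_trace(model: SaccadicModel, grids: np.ndarray,
                          stream: SaccadeStream, layer_index: int) -> ActivityMap:
    """Membrane potentials of layer ``layer_index`` (1-based, 1..3) per saccade.

    Row t holds s_t as produced at step t (before the next step's reset
    bookkeeping touches it).
    """
    if not 1 <= layer_index <= len(model.layers):
        raise ValueError(f"layer index {layer_index} out of range 1..{len(model.layers)}")
    _, states = model.beliefs(grids[None], stream.frame_order[None],
                              train=False, return_states=True)
    return ActivityMap(values=states[layer_index - 1][0],
                       frame_index=stream.frame_order.copy())


def reorder_saccade_rows(amap: ActivityMap) -> ActivityMap:
    """Stable sort of rows by fixated frame index (temporal order preserved
    within each frame group), matching the pair enumeration's outer order."""
    if amap.frame_index is None:
        raise ValueError("activity map has no frame annotations")
    order = np.argsort(amap.frame_index, kind="stable")
    return ActivityMap(values=amap.values[order],
                       frame_index=amap.frame_index[order])


def normalize_rows(amap: ActivityMap, method: str = "minmax") -> ActivityMap:
    """Scale each row for display: min-max to [0, 1] by default, with
    z-scoring behind the ``method`` flag. Constant rows map to zeros."""
    return _normalize(amap, method=method)


def _normalize(amap: ActivityMap, method: str = "minmax") -> ActivityMap:
    v = amap.values
    if method == "minmax":
        lo = v.min(axis=1, keepdims=True)
        hi = v.max(axis=1, keepdims=True)
        span = hi - lo
        out = np.where(span > 0, (v - lo) / np.where(span > 0, span, 1.0), 0.0)
    elif method == "zscore":
        mu = v.mean(axis=1, keepdims=True)
        sd = v.std(axis=1, keepdims=True)
        out = np.where(sd > 0, (v - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    else:
        raise ValueError(f"unknown normalisation {method!r}")
    return ActivityMap(values=out, frame_index=amap.frame_index.copy())


def save_csv(amap: ActivityMap, path) -> None:
    """Raw matrix as CSV, one saccade row per line, frame index first."""
    with open(path, "w") as fh:
        for k, row in zip(amap.frame_index, amap.values):
            fh.write(",".join([str(int(k))] + [f"{v:.6f}" for v in row]) + "\n")


def save_heatmap(amap: ActivityMap, path) -> None:
    """Membrane-potential heatmap (saccades x neurons) as PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 6))
    im = ax.imshow(amap.values, aspect="auto", cmap="viridis",
                   interpolation="nearest")
    ax.set_xlabel("neuron")
    ax.set_ylabel("saccade (annotated by fixated frame)")
    ax.set_yticks(range(0, T_STEPS, 6))
    ax.set_yticklabels([f"t={t} (f{amap.frame_index[t]})"
                        for t in range(0, T_STEPS, 6)], fontsize=7)
    fig.colorbar(im, ax=ax, label="V_m (normalised)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def oddity_distinctiveness(amap: ActivityMap, oddity_index: int) -> tuple[float, float]:
    """Contrast statistic behind the "oddity rows look different" claim.

    On the normalised, reordered map, returns (d_odd, d_non): the mean
    absolute row difference between oddity-frame rows and non-oddity rows,
    and the same quantity between rows of two distinct non-oddity frames.
    A trained model should yield d_odd > d_non on correctly solved samples.
    """
    groups = {k: amap.values[amap.frame_index == k] for k in np.unique(amap.frame_index)}
    odd = groups.pop(oddity_index)
    non_keys = sorted(groups)
    d_odd = np.mean([np.abs(odd[:, None, :] - groups[k][None, :, :]).mean()
                     for k in non_keys])
    pairs = [(a, b) for ai, a in enumerate(non_keys) for b in non_keys[ai + 1:]]
    d_non = np.mean([np.abs(groups[a][:, None, :] - groups[b][None, :, :]).mean()
                     for a, b in pairs])
    return float(d_odd), float(d_non)
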