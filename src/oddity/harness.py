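"""Training and evaluation orchestration.

Supports the two setups the architectures are compared in: ``separate``
(one model per concept, accuracies averaged across concepts) and ``joint``
(a single model over the mixed-concept dataset). Also provides parameter
counting for every architecture/unit/width combination and the
epochs-to-threshold statistic against a human-level accuracy reference
(the Munduruku participant average, 66.8%).
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, Tensor
from .nn import autodiff as ad
from .oren import N_FRAMES, OReNModel
from .riddlegen.dataset import DatasetConfig, DatasetSplits, build_dataset
from .saccadic import SaccadeConfig, SaccadicModel, stream_orders
from .vision import VisionConfig, embedding_dim, preprocess

HUMAN_LEVEL_ACCURACY = 0.668   # Munduruku participant average
CHANCE_ACCURACY = 1.0 / N_FRAMES

__all__ = ["TrainConfig", "History", "preprocess_samples", "train_model",
           "train_separate", "evaluate_accuracy", "count_parameters",
           "epochs_to_threshold", "save_checkpoint", "load_checkpoint",
           "HUMAN_LEVEL_ACCURACY", "CHANCE_ACCURACY"]


@dataclass
class TrainConfig:
    arch: str = "saccadic"          # 'oren' | 'saccadic'
    unit: str = "ssnu"              # saccadic only: 'snn' | 'ssnu' | 'ssnu-r' | 'lstm'
    n: int = 128
    epochs: int = 20
    batch_size: int = 32
    lr: float = 1e-3
    seed: int = 0
    mask_first: int = 2
    stop_at_test_accuracy: float | None = None
    stop_after_seconds: float | None = None     # wall-clock cap, checked per epoch
    eval_val: bool = True
    vision_config: VisionConfig = field(default_factory=VisionConfig)

    def __post_init__(self):
        if self.arch not in ("oren", "saccadic"):
            raise ValueError(f"unknown arch {self.arch!r}")
        if self.n < 1:
            raise ValueError("layer width N must be >= 1")


@dataclass
class History:
    """Per-epoch training record."""

    epochs: list = field(default_factory=list)            # 1-based epoch numbers
    train_loss: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)      # None entries if no val split
    test_accuracy: list = field(default_factory=list)
    examples_seen: list = field(default_factory=list)

    def record(self, epoch: int, loss: float, val_acc, test_acc, n_train: int):
        self.epochs.append(epoch)
        self.train_loss.append(loss)
        self.val_accuracy.append(val_acc)
        self.test_accuracy.append(test_acc)
        self.examples_seen.append(epoch * n_train)


def preprocess_samples(samples, side: int = 80) -> tuple[np.ndarray, np.ndarray]:
    """Riddle samples -> ((n, 6, side, side) float32 grids, (n,) labels)."""
    grids = np.stack([[preprocess(f, side) for f in s.frames]
                      for s in samples]).astype(np.float32)
    labels = np.array([s.oddity_index for s in samples], dtype=np.int64)
    return grids, labels


def _build_model(config: TrainConfig, rng: np.random.Generator):
    if config.arch == "oren":
        return OReNModel(rng, n=config.n, vision_config=config.vision_config)
    return SaccadicModel(rng, n=config.n, unit=config.unit,
                         vision_config=config.vision_config)


def evaluate_accuracy(model, samples, rng: np.random.Generator | None = None,
                      batch_size: int = 64,
                      config: SaccadeConfig = SaccadeConfig()) -> float:
    """Fraction of samples whose predicted oddity matches the label.

    ``samples`` may be a list of riddle samples or a pre-processed
    (grids, labels) pair. Saccadic models draw one stream per sample from
    ``rng`` (fresh generator seeded 0 if omitted).
    """
    if isinstance(samples, tuple):
        grids, labels = samples
    else:
        if len(samples) == 0:
            raise ValueError("cannot evaluate on an empty split")
        side = getattr(getattr(model, "vision", None), "config", VisionConfig()).input_side
        grids, labels = preprocess_samples(samples, side)
    if rng is None:
        rng = np.random.default_rng(0)
    correct = 0
    for s in range(0, len(labels), batch_size):
        gb = grids[s:s + batch_size]
        if isinstance(model, SaccadicModel):
            preds = model.predict(gb, rng, config)
        elif isinstance(model, OReNModel):
            preds = model.predict(gb)
        else:  # any object with a .predict over batches of grids
            preds = np.asarray(model.predict(gb))
        correct += int((preds == labels[s:s + batch_size]).sum())
    return correct / len(labels)


def train_model(config: TrainConfig, data: DatasetSplits, progress=None):
    """Train one model on ``data``; returns (model, History).

    Randomness fans out from ``config.seed`` into parameter initialisation,
    batch shuffling, saccade streams and evaluation streams. Saccadic
    streams are re-drawn for every sample at every epoch. Training aborts
    with a diagnostic if the loss becomes non-finite.
    """
    ss = np.random.SeedSequence(config.seed)
    init_rng, shuffle_rng, stream_rng, eval_rng = \
        (np.random.default_rng(s) for s in ss.spawn(4))
    model = _build_model(config, init_rng)
    opt = Adam(model.parameters(), lr=config.lr)

    side = config.vision_config.input_side
    train_grids, train_labels = preprocess_samples(data.train, side)
    val = preprocess_samples(data.val, side) if (config.eval_val and data.val) else None
    test = preprocess_samples(data.test, side)
    n_train = len(train_labels)
    history = History()
    t_start = time.time()

    for epoch in range(1, config.epochs + 1):
        order = shuffle_rng.permutation(n_train)
        losses = []
        for s in range(0, n_train, config.batch_size):
            idx = order[s:s + config.batch_size]
            gb = Tensor(train_grids[idx])
            yb = train_labels[idx]
            opt.zero_grad()
            if config.arch == "oren":
                logits = model.logits(gb, train=True)
                loss = ad.softmax_cross_entropy(logits, yb)
            else:
                orders = stream_orders(stream_rng, len(idx))
                loss = model.loss(gb, orders, yb, train=True,
                                  mask_first=config.mask_first)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_acc = evaluate_accuracy(model, val, rng=eval_rng) if val else None
        test_acc = evaluate_accuracy(model, test, rng=eval_rng)
        history.record(epoch, float(np.mean(losses)), val_acc, test_acc, n_train)
        if progress is not None:
            progress(epoch, history)
        if (config.stop_at_test_accuracy is not None
                and test_acc >= config.stop_at_test_accuracy):
            break
        if (config.stop_after_seconds is not None
                and time.time() - t_start > config.stop_after_seconds):
            break
    return model, history


def train_separate(concepts, config: TrainConfig, size: int = 3840,
                   data_seed: int = 0, registry=None,
                   human_thresholds: dict | None = None, progress=None) -> dict:
    """Separate setup: one model per concept; mean test accuracy across
    concepts.

    ``human_thresholds`` optionally maps concept id -> per-riddle
    human-level accuracy (default: the study average for every concept).
    Returns {"per_concept": {...}, "mean_test_accuracy": float,
    "mean_epochs_to_human_level": float or None}.
    """
    per_concept = {}
    epochs_list = []
    for i, cid in enumerate(concepts):
        data = build_dataset(DatasetConfig(mode="separate", concepts=(cid,),
                                           size=size, seed=data_seed + i),
                             registry=registry)
        model, hist = train_model(config, data, progress=progress)
        thr = (human_thresholds or {}).get(cid, HUMAN_LEVEL_ACCURACY)
        reached = hist.test_accuracy and max(hist.test_accuracy) >= thr
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            epochs = epochs_to_threshold(hist, thr) if reached else None
        if epochs is not None:
            epochs_list.append(epochs)
        per_concept[cid] = {"test_accuracy": hist.test_accuracy[-1],
                            "epochs_to_human_level": epochs,
                            "history": hist}
    return {
        "per_concept": per_concept,
        "mean_test_accuracy": float(np.mean(
            [r["test_accuracy"] for r in per_concept.values()])),
        "mean_epochs_to_human_level": (float(np.mean(epochs_list))
                                       if epochs_list else None),
    }


# ---------------------------------------------------------------------------
# model-size accounting
# ---------------------------------------------------------------------------

def _vision_param_count(cfg: VisionConfig) -> int:
    k2 = cfg.kernel ** 2
    total = k2 * 1 * cfg.channels + 2 * cfg.channels          # conv1 + BN
    total += (cfg.n_conv - 1) * (k2 * cfg.channels ** 2 + 2 * cfg.channels)
    return total


def count_parameters(arch: str, n: int, unit: str = "ssnu",
                     vision_config: VisionConfig = VisionConfig(),
                     n_layers: int = 3) -> int:
    """Exact trainable-parameter total for a fully specified architecture.

    Counts weights, biases and batch-norm scale/shift; excludes batch-norm
    running statistics and the fixed leak hyperparameter. Matches
    ``Module.num_params()`` of the corresponding built model.
    """
    d = embedding_dim(vision_config)
    total = _vision_param_count(vision_config)
    if arch == "oren":
        total += (2 * d) * n + n + 3 * (n * n + n)     # g_theta: 4 ReLU layers
        total += 2 * (n * n + n) + (n + 1)             # f_phi: 2 ReLU layers + linear
        return total
    if arch != "saccadic":
        raise ValueError(f"unknown arch {arch!r}")
    fan = d + N_FRAMES
    for _ in range(n_layers):
        if unit == "lstm":
            total += 4 * (fan * n + n * n + n)
        elif unit in ("snn", "ssnu"):
            total += fan * n + n
        elif unit == "ssnu-r":
            total += fan * n + n + n * n
        else:
            raise ValueError(f"unknown unit {unit!r}")
        fan = n
    total += n + 1                                     # sigmoid readout
    return total


def save_checkpoint(model, path, config: TrainConfig) -> None:
    """Single-file checkpoint: parameter/buffer arrays plus a JSON header."""
    header = {"arch": config.arch, "unit": config.unit, "n": config.n,
              "vision_config": config.vision_config.__dict__}
    np.savez_compressed(path, __header__=np.array(json.dumps(header)),
                        **model.state_arrays())


def load_checkpoint(path):
    """Rebuild the model described by a checkpoint's JSON header."""
    with np.load(path, allow_pickle=False) as store:
        arrays = {k: store[k] for k in store.files}
    raw = arrays.pop("__header__", None)
    if raw is None:
        raise ValueError(f"{path}: not an oddity checkpoint (no header)")
    header = json.loads(str(raw))
    cfg = TrainConfig(arch=header["arch"], unit=header["unit"], n=header["n"],
                      vision_config=VisionConfig(**{
                          k: tuple(v) if isinstance(v, list) else v
                          for k, v in header["vision_config"].items()}))
    model = _build_model(cfg, np.random.default_rng(0))
    model.load_state_arrays(arrays)
    return model, cfg


def epochs_to_threshold(history: History, threshold: float):
    """First 1-based epoch whose test accuracy reaches ``threshold``.

    Returns ``None`` (with a warning) when the threshold is never reached;
    callers averaging across riddles should exclude such runs.
    """
    for epoch, acc in zip(history.epochs, history.test_accuracy):
        if acc >= threshold:
            return epoch
    warnings.warn(f"threshold {threshold} never reached within "
                  f"{len(history.epochs)} epochs", stacklevel=2)
    return None
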