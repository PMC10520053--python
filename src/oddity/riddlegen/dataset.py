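"""Dataset assembly and on-disk storage for riddle collections.

Datasets are split train:validation:test at the fixed 4:1:1 ratio. The
``separate`` mode draws every sample from a single concept (default size
3840 -> 2560/640/640); the ``joint`` mode draws the concept uniformly at
random per sample from the configured set (default size 108,000).

Two interchangeable stores are provided: one PNG per frame plus a JSON-lines
label file per split (inspectable), and a single ``.npz`` archive per split
(fast). Both round-trip pixels and labels losslessly and are described by a
``manifest.json`` recording the config, seed and split counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .concepts import GeneratorSpec, RiddleSample, default_registry, generate_riddle
from .frame import Frame

FORMAT_VERSION = 1
SPLIT_RATIO = (4, 1, 1)
SPLIT_NAMES = ("train", "val", "test")

__all__ = [
    "DatasetConfig", "DatasetSplits", "split_sizes", "build_dataset",
    "write_dataset", "load_dataset",
]


@dataclass
class DatasetConfig:
    mode: str                       # 'separate' | 'joint'
    concepts: tuple
    size: int
    seed: int
    side: int = 100
    antialias: bool = False

    def __post_init__(self):
        if self.mode not in ("separate", "joint"):
            raise ValueError(f"mode must be 'separate' or 'joint', got {self.mode!r}")
        self.concepts = tuple(self.concepts)
        if self.mode == "separate" and len(self.concepts) != 1:
            raise ValueError("separate mode takes exactly one concept")
        if not self.concepts:
            raise ValueError("at least one concept required")


@dataclass
class DatasetSplits:
    train: list
    val: list
    test: list
    config: DatasetConfig | None = None

    def __iter__(self):
        return iter((self.train, self.val, self.test))


def split_sizes(total: int) -> tuple[int, int, int]:
    """Train/validation/test counts at the 4:1:1 ratio."""
    if total % sum(SPLIT_RATIO) != 0:
        raise ValueError(f"dataset size {total} is not divisible by {sum(SPLIT_RATIO)}")
    unit = total // sum(SPLIT_RATIO)
    return tuple(r * unit for r in SPLIT_RATIO)


def sample_concept_ids(config: DatasetConfig, rng: np.random.Generator) -> list:
    """Concept id per sample: fixed in separate mode, uniform in joint mode."""
    if config.mode == "separate":
        return [config.concepts[0]] * config.size
    idx = rng.integers(0, len(config.concepts), size=config.size)
    return [config.concepts[i] for i in idx]


def build_dataset(config: DatasetConfig, registry: dict | None = None,
                  progress=None) -> DatasetSplits:
    """Generate all samples for ``config`` and split them 4:1:1 (disjoint)."""
    n_train, n_val, n_test = split_sizes(config.size)
    reg = registry if registry is not None else default_registry()
    for cid in config.concepts:
        if cid not in reg:
            raise ValueError(f"unknown concept {cid!r}")
    rng = np.random.default_rng(config.seed)
    concept_ids = sample_concept_ids(config, rng)
    samples = []
    for i, cid in enumerate(concept_ids):
        samples.append(generate_riddle(cid, rng, registry=reg, side=config.side,
                                       antialias=config.antialias))
        if progress is not None:
            progress(i + 1, config.size)
    return DatasetSplits(train=samples[:n_train],
                         val=samples[n_train:n_train + n_val],
                         test=samples[n_train + n_val:],
                         config=config)


# ---------------------------------------------------------------------------
# storage
# ---------------------------------------------------------------------------

def _labels_record(i: int, s: RiddleSample) -> dict:
    return {
        "sample_id": i,
        "concept_id": s.concept_id,
        "oddity_index": s.oddity_index,
        "background_shades": [f.background_shade for f in s.frames],
        "ink_shades": [f.ink_shade for f in s.frames],
    }


def write_dataset(splits: DatasetSplits, path, fmt: str = "png") -> dict:
    """Write a dataset directory; returns the manifest dict.

    ``fmt='png'`` stores one grayscale PNG per frame; ``fmt='npz'`` stores a
    single compressed archive per split.
    """
    if fmt not in ("png", "npz"):
        raise ValueError(f"unknown storage format {fmt!r}")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    counts = {}
    for name, samples in zip(SPLIT_NAMES, splits):
        sdir = path / name
        sdir.mkdir(exist_ok=True)
        with open(sdir / "labels.jsonl", "w") as fh:
            for i, s in enumerate(samples):
                fh.write(json.dumps(_labels_record(i, s)) + "\n")
        if fmt == "png":
            for i, s in enumerate(samples):
                for k, f in enumerate(s.frames):
                    Image.fromarray(f.pixels, mode="L").save(
                        sdir / f"sample_{i:06d}_f{k}.png")
        else:
            pix = np.stack([np.stack([f.pixels for f in s.frames]) for s in samples]) \
                if samples else np.zeros((0, 6, 1, 1), dtype=np.uint8)
            np.savez_compressed(sdir / "frames.npz", pixels=pix)
        counts[name] = len(samples)
    cfg = splits.config
    manifest = {
        "format_version": FORMAT_VERSION,
        "storage": fmt,
        "counts": counts,
        "config": None if cfg is None else {
            "mode": cfg.mode, "concepts": list(cfg.concepts), "size": cfg.size,
            "seed": cfg.seed, "side": cfg.side, "antialias": cfg.antialias,
        },
    }
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_dataset(path) -> DatasetSplits:
    """Load a dataset directory written by :func:`write_dataset`.

    Raises on missing/corrupt records rather than skipping them.
    """
    path = Path(path)
    mpath = path / "manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(f"no manifest.json under {path}")
    manifest = json.loads(mpath.read_text())
    if manifest.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"dataset format version {manifest.get('format_version')} "
                         f"not supported (expected {FORMAT_VERSION})")
    fmt = manifest["storage"]
    out = {}
    for name in SPLIT_NAMES:
        sdir = path / name
        labels = []
        lpath = sdir / "labels.jsonl"
        if not lpath.exists():
            raise FileNotFoundError(f"missing label file {lpath}")
        with open(lpath) as fh:
            for line in fh:
                labels.append(json.loads(line))
        if len(labels) != manifest["counts"][name]:
            raise ValueError(f"split {name!r}: manifest says "
                             f"{manifest['counts'][name]} samples, "
                             f"labels.jsonl has {len(labels)}")
        samples = []
        if fmt == "npz":
            pix = np.load(sdir / "frames.npz")["pixels"]
            if pix.shape[0] != len(labels):
                raise ValueError(f"split {name!r}: archive/label count mismatch")
        for i, rec in enumerate(labels):
            frames = []
            for k in range(6):
                if fmt == "png":
                    fpath = sdir / f"sample_{rec['sample_id']:06d}_f{k}.png"
                    if not fpath.exists():
                        raise FileNotFoundError(f"missing frame file {fpath}")
                    arr = np.asarray(Image.open(fpath), dtype=np.uint8)
                else:
                    arr = pix[i, k]
                frames.append(Frame(pixels=arr,
                                    background_shade=rec["background_shades"][k],
                                    ink_shade=rec["ink_shades"][k]))
            samples.append(RiddleSample(frames=frames,
                                        oddity_index=rec["oddity_index"],
                                        concept_id=rec["concept_id"]))
        out[name] = samples
    cfgd = manifest.get("config")
    cfg = None
    if cfgd is not None:
        cfg = DatasetConfig(mode=cfgd["mode"], concepts=tuple(cfgd["concepts"]),
                            size=cfgd["size"], seed=cfgd["seed"],
                            side=cfgd["side"], antialias=cfgd["antialias"])
    return DatasetSplits(train=out["train"], val=out["val"], test=out["test"], config=cfg)
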