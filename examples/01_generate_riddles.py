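"""Generate visual-oddity riddles and inspect their structure.

Builds a handful of riddles from the concept registry, prints the label and
shade bookkeeping for one sample, and writes a small dataset to disk.
"""

import tempfile
from pathlib import Path

import numpy as np

from oddity.riddlegen import (DatasetConfig, build_dataset, default_registry,
                              generate_riddle, write_dataset)

rng = np.random.default_rng(0)

print("registered concepts:")
for cid, spec in sorted(default_registry().items()):
    print(f"  {cid:24s} ({spec.category})")

sample = generate_riddle("vertical_symmetry", rng)
print(f"\none '{sample.concept_id}' riddle:")
print(f"  oddity index: {sample.oddity_index}  (the frame violating the concept)")
for i, f in enumerate(sample.frames):
    marker = " <- oddity" if i == sample.oddity_index else ""
    print(f"  frame {i}: background {f.background_shade}, ink {f.ink_shade}, "
          f"{int((f.pixels == f.ink_shade).sum())} ink pixels{marker}")

with tempfile.TemporaryDirectory() as tmp:
    cfg = DatasetConfig(mode="separate", concepts=("circle",), size=24, seed=7)
    splits = build_dataset(cfg)
    manifest = write_dataset(splits, Path(tmp) / "circle_ds")
    print(f"\nwrote a dataset with split sizes {manifest['counts']} "
          "(train:val:test = 4:1:1)")
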