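"""Membrane-potential activity maps of the saccadic network.

Records the 36 x N layer-3 membrane trace for one riddle, reorders the
saccade rows to the relation network's outer pair order, row-normalises,
and prints the oddity-contrast statistic. On a trained model the rows
recorded while fixating the oddity stand out (d_odd > d_non); untrained
models show no systematic contrast.
"""

import numpy as np

from oddity.harness import preprocess_samples
from oddity.introspect import (normalize_rows, oddity_distinctiveness,
                               record_membrane_trace, reorder_saccade_rows)
from oddity.riddlegen import generate_riddle
from oddity.saccadic import SaccadicModel, build_stream

rng = np.random.default_rng(3)
sample = generate_riddle("equidistant_points", rng)
grids, _ = preprocess_samples([sample])
stream = build_stream(rng)

# soft units keep an untrained network active; a fresh spiking network is
# silent past layer 1 (no unit crosses the -1 threshold before training)
model = SaccadicModel(rng, n=32, unit="ssnu")
amap = record_membrane_trace(model, grids[0], stream, layer_index=3)
print(f"activity map: {amap.values.shape[0]} saccades x {amap.values.shape[1]} neurons")
print("frame per row (temporal order):", amap.frame_index[:12], "...")

amap = normalize_rows(reorder_saccade_rows(amap))
print("after reordering:", amap.frame_index[:12], "...")
d_odd, d_non = oddity_distinctiveness(amap, sample.oddity_index)
print(f"\noddity-row contrast d_odd = {d_odd:.4f}, "
      f"non-oddity contrast d_non = {d_non:.4f}")
print("(an untrained network gives d_odd ~ d_non; training separates them)")
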