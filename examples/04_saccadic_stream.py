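"""The saccadic view of a riddle: streams, beliefs and the decision rule.

Constructs the 36-step saccade stream (six random permutations of the six
frames), runs an untrained saccadic sSNU model over it, and shows how the
per-saccade beliefs from the 18 evaluation saccades are integrated into a
decision. A short training run (see the README) drives the integrated
belief of the oddity toward 1.
"""

import numpy as np

from oddity.harness import count_parameters, preprocess_samples
from oddity.riddlegen import generate_riddle
from oddity.saccadic import SaccadicModel, build_stream, decide

rng = np.random.default_rng(2)
sample = generate_riddle("point_inside", rng)
grids, _ = preprocess_samples([sample])
stream = build_stream(rng)

print("saccade stream (six permutations of frames 0..5):")
for b in range(6):
    print(f"  block {b}: {stream.frame_order[6 * b:6 * b + 6]}")

print(f"\nper-step model input width: 3200 embedding + 6 position = 3206")
for unit, n in (("snn", 128), ("ssnu", 64), ("ssnu-r", 32), ("lstm", 256)):
    c = count_parameters("saccadic", n, unit)
    print(f"  {unit:7s} N={n:<4d} {c:>9,} parameters (~{c / 1e6:.1f} M)")

model = SaccadicModel(rng, n=16, unit="ssnu")
trace = model.trace(grids[0], stream)
print("\nuntrained beliefs p(oddity|t), first 6 saccades:",
      np.round(trace.beliefs[:6], 3))
print(f"decision from the evaluation window: frame {decide(trace)} "
      f"(true oddity: {sample.oddity_index}; untrained = chance)")
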