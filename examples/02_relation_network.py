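"""Score a riddle with the Oddity Relation Network.

Shows the structural pipeline: six frames -> 3200-d embeddings -> 36
ordered pairs of length 6400 -> relation sums -> per-frame scores and a
softmax over the six candidates. The network here is untrained, so the
probabilities hover around chance (1/6 each); training moves the mass onto
the oddity.
"""

import numpy as np

from oddity.harness import count_parameters, preprocess_samples
from oddity.oren import OReNModel, make_pairs
from oddity.riddlegen import generate_riddle
from oddity.vision import embedding_dim

rng = np.random.default_rng(1)
sample = generate_riddle("parallel_lines", rng)
grids, labels = preprocess_samples([sample])

print(f"embedding dimension D = {embedding_dim()}")
pairs = make_pairs(np.zeros((6, embedding_dim())))
print(f"ordered pairs: {pairs.shape[0]} of length {pairs.shape[1]}")
print(f"OReN N=128 trainable parameters: {count_parameters('oren', 128):,} "
      f"(~{count_parameters('oren', 128) / 1e6:.1f} M)")

model = OReNModel(rng, n=16)
sv = model.score(grids[0])
print("\nuntrained per-frame probabilities (about 1/6 = 0.167 each):")
for k, p in enumerate(sv.p):
    print(f"  frame {k}: {p:.3f}")
print(f"prediction {sv.prediction} vs true oddity {sample.oddity_index}")
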