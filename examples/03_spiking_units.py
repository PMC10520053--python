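"""Spiking-neural-unit dynamics: integrate, fire, reset, leak.

Drives a single SNU with a constant input and prints the membrane
potential trace: the state integrates with leak 0.8, crosses the threshold
(bias -1), emits a spike, and resets.
"""

import numpy as np

from oddity.snu import SNUParams, SNUState, snu_step

params = SNUParams(W=np.array([[0.35]], dtype=np.float32),
                   b=np.array([-1.0], dtype=np.float32),
                   lam=0.8, variant="snn")
state = SNUState.zeros(1)
print("constant input 1.0, W=0.35, leak 0.8, threshold bias -1.0")
print(f"{'t':>3} {'V_m':>8} {'spike':>6}")
for t in range(12):
    y, state = snu_step(np.array([1.0], dtype=np.float32), state, params)
    print(f"{t:3d} {state.s[0]:8.4f} {int(y[0]):6d}")
print("\nafter each spike the membrane resets and integration restarts;")
print("the soft (sigmoid) variant replaces the hard threshold for training.")

# closed-form check of the sub-threshold leak
params2 = SNUParams(W=np.array([[0.1]], dtype=np.float32),
                    b=np.array([-100.0], dtype=np.float32), lam=0.8, variant="snn")
state = SNUState.zeros(1)
for t in range(10):
    _, state = snu_step(np.array([1.0], dtype=np.float32), state, params2)
geom = 0.1 * (1 - 0.8 ** 10) / (1 - 0.8)
print(f"\nsub-threshold V_m after 10 steps: {state.s[0]:.6f} "
      f"(geometric closed form {geom:.6f})")
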