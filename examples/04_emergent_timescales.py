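"""Let the per-neuron timescales emerge by training them jointly with weights.

Starts from a homogeneous network whose rates of change alpha are drawn
from N(0.5, 0.1) and trains alpha together with the weights.  After
training, the alpha distribution splits into a fast group (near 1) and a
slow group, and the wiring concentrates input/output connections on the
fast neurons — the modular fast/slow architecture appears on its own.
Runs in a few minutes on one CPU core.
"""

import numpy as np

from modprior.emergence import bimodality_dip, connectivity_summary, group_neurons
from modprior.training import TrainingConfig, train_learnable_alpha

cfg = TrainingConfig(
    m=40, n=48, n_main=None, T=60, batch_size=16, iterations=10000,
    p_t=0.03, learnable_alpha=True, snapshot_iters=(0, 1000, 10000),
    dtype=np.float32,
)
model = train_learnable_alpha(cfg, np.random.default_rng(9))

for epoch, alpha in sorted(model.alpha_snapshots.items()):
    hist, _ = np.histogram(alpha, bins=np.linspace(0, 1, 11))
    print(f"epoch {epoch:5d}: alpha deciles {hist.tolist()}")

alpha = model.spec.alpha
print(f"bimodality dip statistic: {bimodality_dip(alpha):.0f} (positive = two modes)")

grouping = group_neurons(alpha)
conn = connectivity_summary(model.spec, grouping)
print(f"slow neurons (alpha<0.2): {len(grouping.slow)}, "
      f"fast (alpha>0.8): {len(grouping.fast)}")
print(f"input->fast {conn.get(('input', 'fast'), 0):.2f} vs "
      f"input->slow {conn.get(('input', 'slow'), 0):.2f}")
print(f"fast->output {conn.get(('fast', 'output'), 0):.2f} vs "
      f"slow->output {conn.get(('slow', 'output'), 0):.2f}")
print(
    "Training alone differentiates the timescales and wires the input and\n"
    "output preferentially through the fast group: the slow prior-holding\n"
    "sub-module emerges rather than being built in."
)
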