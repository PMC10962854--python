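"""Locate the prior representation with clamp-variance and ridge decoding.

Trains a reduced slow-sub-module network, freezes hidden states under a
grid of fixed generators, and asks (i) which module moves the output when
its stored state is swapped across generator conditions (clamp variance)
and (ii) whether the generator width sigma_g can be linearly decoded from
the sub-module.  Runs in a few minutes on one CPU core.
"""

import numpy as np

from modprior.analysis import (
    clamp_variance,
    collect_frozen_states,
    collect_state_dataset,
    pca_manifold,
    ridge_decode_sigma,
    sample_probes,
)
from modprior.training import TrainingConfig, train

cfg = TrainingConfig(
    m=48, n=84, n_main=63, T=80, batch_size=24, iterations=3000,
    alpha_s=0.1, dtype=np.float32,
)
model = train(cfg, np.random.default_rng(3))
spec = model.spec

library = collect_frozen_states(spec, seed=4, drive_steps=cfg.T)
probes = sample_probes(1000, np.random.default_rng(5))
v_m, v_s = clamp_variance(spec, library, probes, np.random.default_rng(6))
print(f"clamp variance: V_m = {v_m:.4f}, V_s = {v_s:.4f} (ratio {v_s / v_m:.1f})")

states, _, sigma_g = collect_state_dataset(
    spec, 300, np.random.default_rng(7), drive_steps=cfg.T
)
r2 = ridge_decode_sigma(states[:, spec.n_main:], sigma_g, rng=np.random.default_rng(8))
print(f"ridge decoding of sigma_g from sub-module states: R^2 = {r2:.2f}")

_, evr = pca_manifold(states[:, spec.n_main:])
print(f"sub-module PCA explained variance (PC1, PC2): {evr[0]:.2f}, {evr[1]:.2f}")
print(
    "V_s >> V_m: swapping the sub-module's stored state across generator\n"
    "conditions moves the output far more than swapping the main module's —\n"
    "the slow sub-module carries the prior, and its manifold encodes both\n"
    "the generator mean (PC1) and width (decodable sigma_g)."
)
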