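"""Train a small slow-sub-module network and probe its Bayesian behaviour.

Trains a reduced modular RNN (fast main module, slow sub-module) on the
switching task, then establishes a prior with a fixed generator and probes
the trained network with signals across [-1, 1].  A network performing
Bayesian inference outputs values near the MAP shrinkage line rather than
the identity line.  Runs in a couple of minutes on one CPU core.
"""

import numpy as np

from modprior.analysis import probe_fixed_generator
from modprior.training import TrainingConfig, train

cfg = TrainingConfig(
    m=48, n=84, n_main=63, T=80, batch_size=24, iterations=3000,
    alpha_m=1.0, alpha_s=0.1, dtype=np.float32,
)
model = train(cfg, np.random.default_rng(1))
print(f"loss: {model.loss_history[:20].mean():.3f} (start) -> "
      f"{model.loss_history[-20:].mean():.3f} (end)")

out = probe_fixed_generator(
    model.spec, np.random.default_rng(2),
    mu_g=0.5, sigma_g=0.5, sigma_l=1 / np.sqrt(5),
    n_repeats=100, drive_steps=cfg.T,
)
print(f"MSE(y, y_opt) = {out['mse_vs_opt']:.4f}")
print(f"MSE(y, y_ML)  = {out['mse_vs_ml']:.4f}")
print(
    "The output is much closer to the MAP estimate than to the raw probe "
    "signal:\nthe network has internalised the generator's mean and width "
    "as a prior."
)
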