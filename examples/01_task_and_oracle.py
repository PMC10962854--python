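"""Generate a switching-Gaussian trace and compare the closed-form estimators.

Builds a short trace whose latent cause switches with probability 0.03 per
step, then shows that the MAP shrinkage estimate beats the raw observation
at recovering the true value when the generator is known.
"""

import numpy as np

from modprior.oracle import map_estimate, ml_estimate
from modprior.task import GeneratorParams, make_trace

rng = np.random.default_rng(0)
params = GeneratorParams(mu_g=0.3, sigma_g=0.4, sigma_l=1 / np.sqrt(5), p_t=0.03)
trace = make_trace(2000, params, rng)

y_opt = map_estimate(trace.s, trace.mu_g, trace.sigma_g, trace.sigma_l)
y_ml = ml_estimate(trace.s)

mse_opt = np.mean((y_opt - trace.y_true) ** 2)
mse_ml = np.mean((y_ml - trace.y_true) ** 2)

print(f"trace length {len(trace)}, {trace.switch_times.size} generator switches")
print(f"MSE of MAP estimate vs truth: {mse_opt:.4f}")
print(f"MSE of ML estimate  vs truth: {mse_ml:.4f}")
print(
    "The MAP estimate shrinks each noisy observation toward the generator "
    "mean,\nso its error is below the observation-noise floor "
    f"(sigma_l^2 = {params.sigma_l**2:.2f})."
)
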