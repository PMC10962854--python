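"""Closed-form reference estimators for the noisy-cause task.

With a known generator N(mu_g, sigma_g^2) and observation noise SD sigma_l,
the Bayes-optimal (MAP / posterior-mean) point estimate of y_true given one
observation s is the precision-weighted shrinkage

    y_opt = sigma_g^2/(sigma_g^2+sigma_l^2) * s + sigma_l^2/(sigma_g^2+sigma_l^2) * mu_g,

while the maximum-likelihood estimate ignores the prior: y_ML = s.
"""

from __future__ import annotations

import numpy as np

__all__ = ["map_estimate", "ml_estimate", "shrinkage_weight", "adjustability", "bayes_risk"]


def shrinkage_weight(sigma_g, sigma_l):
    """Weight on the observation, sigma_g^2 / (sigma_g^2 + sigma_l^2)."""
    sg2 = np.square(sigma_g)
    sl2 = np.square(sigma_l)
    denom = sg2 + sl2
    if np.any(denom == 0):
        raise ValueError("sigma_g = sigma_l = 0: estimate undefined")
    return sg2 / denom


def map_estimate(s, mu_g, sigma_g, sigma_l):
    """MAP estimate of y_true; lies between s and mu_g (vectorised)."""
    if np.any(np.asarray(sigma_g) < 0):
        raise ValueError("sigma_g must be >= 0")
    if np.any(np.asarray(sigma_l) < 0):
        raise ValueError("sigma_l must be >= 0")
    w = shrinkage_weight(sigma_g, sigma_l)
    return w * s + (1.0 - w) * mu_g


def ml_estimate(s):
    """Maximum-likelihood estimate: the observation itself."""
    return s


def bayes_risk(sigma_g, sigma_l):
    """E[(y_opt - y_true)^2] under the generator: sg^2 sl^2 / (sg^2 + sl^2)."""
    sg2, sl2 = np.square(sigma_g), np.square(sigma_l)
    return sg2 * sl2 / (sg2 + sl2)


def adjustability(y_t, y_opt_a, y_opt_b):
    """Normalised position of the output between two generators' optima.

    a(t) = (y_opt_B - y(t)) / (y_opt_B - y_opt_A): 1 when the output sits at
    generator A's optimum, 0 at generator B's.
    """
    denom = np.asarray(y_opt_b) - np.asarray(y_opt_a)
    if np.any(denom == 0):
        raise ValueError("y_opt_A == y_opt_B: adjustability undefined")
    return (np.asarray(y_opt_b) - np.asarray(y_t)) / denom
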