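"""Probabilistic population code (PPC) input encoding.

A scalar observation ``s`` is represented by independent Poisson spike
counts of ``m`` input neurons with Gaussian tuning curves

    f_i(s) = (1 / sigma_l^2) * exp(-(s - phi_i)^2 / (2 sigma_ppc^2)),

so the position of the most active neurons codes the value of ``s`` while
the overall gain codes its reliability 1/sigma_l^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PPCConfig", "tuning_rates", "encode_step", "encode_series"]


@dataclass(frozen=True)
class PPCConfig:
    """Input-layer geometry: ``m`` neurons with preferred stimuli
    phi_i = -1/2 + i/m (i = 1..m) and common tuning width sigma_ppc^2."""

    m: int = 100
    sigma_ppc_sq: float = 0.5
    phi: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sigma_ppc_sq <= 0:
            raise ValueError("sigma_ppc_sq must be > 0")
        if self.phi is None:
            object.__setattr__(
                self, "phi", -0.5 + np.arange(1, self.m + 1) / self.m
            )
        elif len(self.phi) != self.m:
            raise ValueError("phi length must equal m")


def tuning_rates(s, sigma_l: float, cfg: PPCConfig = PPCConfig()) -> np.ndarray:
    """Expected spike counts f_i(s) for one observation (or an array of them).

    For scalar ``s`` returns shape (m,); for array input the phi axis is
    appended last.
    """
    if sigma_l <= 0:
        raise ValueError("sigma_l must be > 0")
    s = np.asarray(s, dtype=float)
    d = s[..., None] - cfg.phi
    return np.exp(-(d * d) / (2.0 * cfg.sigma_ppc_sq)) / (sigma_l * sigma_l)


def encode_step(
    s: float, sigma_l: float, cfg: PPCConfig, rng: np.random.Generator
) -> np.ndarray:
    """One Poisson draw u_i ~ Poisson(f_i(s)); a fresh draw every call."""
    return rng.poisson(tuning_rates(s, sigma_l, cfg))


def encode_series(
    s: np.ndarray,
    sigma_l,
    cfg: PPCConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Encode a series (or batch) of observations.

    ``s`` of shape (T,) with scalar ``sigma_l`` gives counts of shape (T, m);
    ``s`` of shape (T, B) with ``sigma_l`` of shape (B,) gives (T, B, m),
    matching the layout produced by :func:`modprior.task.make_trace_batch`.
    """
    s = np.asarray(s, dtype=float)
    sl = np.asarray(sigma_l, dtype=float)
    if np.any(sl <= 0):
        raise ValueError("sigma_l must be > 0")
    d = s[..., None] - cfg.phi
    rates = np.exp(-(d * d) / (2.0 * cfg.sigma_ppc_sq)) / (sl[..., None] ** 2 if sl.ndim else sl**2)
    return rng.poisson(rates).astype(np.float64)
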