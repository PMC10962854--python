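"""Switching-Gaussian signal generator.

The latent *cause* (generator) is a Gaussian ``N(mu_g, sigma_g^2)`` from which
the true value ``y_true(t)`` is drawn fresh at every step.  The observed
signal adds measurement noise: ``s(t) ~ N(y_true(t), sigma_l^2)``.  With
probability ``p_t`` per step the generator's ``(mu_g, sigma_g)`` are
re-sampled uniformly from their configured ranges, producing a piecewise
stationary trace whose segments are concatenated into one continuous signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorRanges",
    "GeneratorParams",
    "SignalTrace",
    "sample_generator_params",
    "make_trace",
    "make_alternating_trace",
    "make_trace_batch",
]

#: Default parameter ranges for the switching generator.
DEFAULT_MU_RANGE = (-0.5, 0.5)
DEFAULT_SIGMA_G_RANGE = (0.0, 0.8)
#: Observation-noise SD range.  The lower bound is 1/sqrt(5); a tighter
#: alternate reading of 0.2 (= 1/5) is supported via configuration.
DEFAULT_SIGMA_L_RANGE = (1.0 / np.sqrt(5.0), 1.0)


@dataclass(frozen=True)
class GeneratorRanges:
    """Uniform sampling ranges for the generator parameters."""

    mu_g: tuple[float, float] = DEFAULT_MU_RANGE
    sigma_g: tuple[float, float] = DEFAULT_SIGMA_G_RANGE
    sigma_l: tuple[float, float] = DEFAULT_SIGMA_L_RANGE

    def __post_init__(self) -> None:
        for name in ("mu_g", "sigma_g", "sigma_l"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"invalid range for {name}: min {lo} > max {hi}")
        if self.sigma_g[0] < 0:
            raise ValueError("sigma_g range must be non-negative")
        if self.sigma_l[0] <= 0:
            raise ValueError("sigma_l must be positive")


@dataclass(frozen=True)
class GeneratorParams:
    """One generator state: latent cause N(mu_g, sigma_g^2), noise SD sigma_l,
    and the per-step switching probability p_t."""

    mu_g: float
    sigma_g: float
    sigma_l: float
    p_t: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_g < 0:
            raise ValueError("sigma_g must be >= 0")
        if self.sigma_l <= 0:
            raise ValueError("sigma_l must be > 0")
        if not 0.0 <= self.p_t <= 1.0:
            raise ValueError("p_t must be a probability")


@dataclass
class SignalTrace:
    """Aligned time series of the latent truth and the observed signal.

    ``mu_g``/``sigma_g``/``sigma_l`` are the per-step generator-parameter
    history (piecewise constant, changing only at ``switch_times``).
    """

    y_true: np.ndarray
    s: np.ndarray
    mu_g: np.ndarray
    sigma_g: np.ndarray
    sigma_l: np.ndarray
    switch_times: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        T = len(self.y_true)
        for name in ("s", "mu_g", "sigma_g", "sigma_l"):
            if len(getattr(self, name)) != T:
                raise ValueError(f"{name} length != {T}")
        if not (np.isfinite(self.y_true).all() and np.isfinite(self.s).all()):
            raise ValueError("trace contains non-finite values")

    def __len__(self) -> int:
        return len(self.y_true)

    def to_frame(self) -> pd.DataFrame:
        switched = np.zeros(len(self), dtype=bool)
        switched[self.switch_times] = True
        return pd.DataFrame(
            {
                "t": np.arange(len(self)),
                "y_true": self.y_true,
                "s": self.s,
                "mu_g": self.mu_g,
                "sigma_g": self.sigma_g,
                "sigma_l": self.sigma_l,
                "switched": switched,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SignalTrace":
        df = pd.read_csv(path)
        return cls(
            y_true=df["y_true"].to_numpy(),
            s=df["s"].to_numpy(),
            mu_g=df["mu_g"].to_numpy(),
            sigma_g=df["sigma_g"].to_numpy(),
            sigma_l=df["sigma_l"].to_numpy(),
            switch_times=np.flatnonzero(df["switched"].to_numpy()),
        )


def sample_generator_params(
    rng: np.random.Generator,
    ranges: GeneratorRanges = GeneratorRanges(),
    p_t: float = 0.0,
) -> GeneratorParams:
    """Draw (mu_g, sigma_g, sigma_l) uniformly from their ranges."""
    return GeneratorParams(
        mu_g=float(rng.uniform(*ranges.mu_g)),
        sigma_g=float(rng.uniform(*ranges.sigma_g)),
        sigma_l=float(rng.uniform(*ranges.sigma_l)),
        p_t=p_t,
    )


def make_trace(
    T: int,
    params0: GeneratorParams,
    rng: np.random.Generator,
    ranges: GeneratorRanges = GeneratorRanges(),
    resample_y_true: bool = True,
) -> SignalTrace:
    """Generate a length-``T`` trace from a switching generator.

    At each step, with probability ``params0.p_t`` the generator's
    ``(mu_g, sigma_g)`` are re-sampled from ``ranges`` (``sigma_l`` is held
    fixed for the whole trace).  ``y_true(t)`` is drawn fresh each step from
    the current generator unless ``resample_y_true`` is False, in which case
    it is drawn once per segment and held between switches.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    p_t = params0.p_t
    mu, sg, sl = params0.mu_g, params0.sigma_g, params0.sigma_l

    mu_h = np.empty(T)
    sg_h = np.empty(T)
    y_true = np.empty(T)
    switches = []
    y_seg = mu + sg * rng.standard_normal() if not resample_y_true else None
    for t in range(T):
        if t > 0 and p_t > 0 and rng.random() < p_t:
            mu = rng.uniform(*ranges.mu_g)
            sg = rng.uniform(*ranges.sigma_g)
            switches.append(t)
            if not resample_y_true:
                y_seg = mu + sg * rng.standard_normal()
        mu_h[t] = mu
        sg_h[t] = sg
        y_true[t] = mu + sg * rng.standard_normal() if resample_y_true else y_seg
    s = y_true + sl * rng.standard_normal(T)
    return SignalTrace(
        y_true=y_true,
        s=s,
        mu_g=mu_h,
        sigma_g=sg_h,
        sigma_l=np.full(T, sl),
        switch_times=np.asarray(switches, dtype=int),
    )


def make_alternating_trace(
    gen_a: GeneratorParams,
    gen_b: GeneratorParams,
    mode: str,
    period_or_pt: float,
    T: int,
    rng: np.random.Generator,
) -> SignalTrace:
    """Trace whose generator alternates between two fixed causes A and B.

    ``mode='periodic'`` flips identity every ``period_or_pt`` steps
    (an integer >= 1); ``mode='probabilistic'`` flips with probability
    ``period_or_pt`` per step.  Observation noise uses gen_a's sigma_l.
    """
    if mode not in ("periodic", "probabilistic"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "periodic":
        period = int(period_or_pt)
        if period < 1:
            raise ValueError("period must be >= 1")
        idx = (np.arange(T) // period) % 2  # 0 -> A, 1 -> B
    else:
        flips = rng.random(T - 1) < period_or_pt if T > 1 else np.empty(0, bool)
        idx = np.concatenate([[0], np.cumsum(flips) % 2]).astype(int)
    mu_h = np.where(idx == 0, gen_a.mu_g, gen_b.mu_g)
    sg_h = np.where(idx == 0, gen_a.sigma_g, gen_b.sigma_g)
    y_true = mu_h + sg_h * rng.standard_normal(T)
    sl = gen_a.sigma_l
    s = y_true + sl * rng.standard_normal(T)
    switch_times = np.flatnonzero(np.diff(idx) != 0) + 1
    return SignalTrace(
        y_true=y_true,
        s=s,
        mu_g=mu_h,
        sigma_g=sg_h,
        sigma_l=np.full(T, sl),
        switch_times=switch_times,
    )


def make_trace_batch(
    B: int,
    T: int,
    p_t: float,
    rng: np.random.Generator,
    ranges: GeneratorRanges = GeneratorRanges(),
):
    """Vectorised batch of switching traces, for training throughput.

    Returns arrays ``y_true, s, sigma_l`` of shapes (T, B), (T, B), (B,).
    Each trace draws its own initial (mu_g, sigma_g) and a per-trace sigma_l.
    Statistically identical to stacking ``make_trace`` outputs.
    """
    mu = rng.uniform(*ranges.mu_g, size=B)
    sg = rng.uniform(*ranges.sigma_g, size=B)
    sl = rng.uniform(*ranges.sigma_l, size=B)
    y_true = np.empty((T, B))
    mu_h = np.empty((T, B))
    sg_h = np.empty((T, B))
    for t in range(T):
        if t > 0 and p_t > 0:
            sw = rng.random(B) < p_t
            n = int(sw.sum())
            if n:
                mu[sw] = rng.uniform(*ranges.mu_g, size=n)
                sg[sw] = rng.uniform(*ranges.sigma_g, size=n)
        mu_h[t] = mu
        sg_h[t] = sg
        y_true[t] = mu + sg * rng.standard_normal(B)
    s = y_true + sl[None, :] * rng.standard_normal((T, B))
    return y_true, s, mu_h, sg_h, sl
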