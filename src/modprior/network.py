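"""Leaky recurrent network dynamics.

Every neuron i carries a rate of change alpha_i in [0, 1] (the inverse of
its time scale) and updates as

    x(t+1) = (1 - alpha) * x(t) + alpha * ReLU(W_in u(t) + W x(t)) + alpha * xi,

with elementwise (Hadamard) products and i.i.d. Gaussian noise xi of SD
``xi_sd``.  The output is a linear readout y(t) = W_out x(t).

Two structural variants share this update:

* homogeneous — all neurons receive input and drive the readout;
* modular — only the first ``n_main`` (main-module) neurons connect to the
  input and output layers; the remaining sub-module neurons couple to the
  main module through the recurrent matrix only.  Structural zeros in
  ``w_in`` / ``w_out`` encode this, so the modular network is exactly a
  homogeneous network with a masked input/readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "NetworkSpec",
    "NetworkState",
    "make_spec",
    "step_homogeneous",
    "step_modular",
    "readout",
    "run_trace",
    "save_spec",
    "load_spec",
]


@dataclass
class NetworkSpec:
    """Weights, per-neuron alpha, and (optional) main/sub partition."""

    w_in: np.ndarray  # (N, m); rows >= n_main are structural zeros if modular
    w_rec: np.ndarray  # (N, N), full
    w_out: np.ndarray  # (1, N); cols >= n_main are structural zeros if modular
    alpha: np.ndarray  # (N,), each in [0, 1]
    n_main: int | None = None  # None -> homogeneous
    xi_sd: float = 0.05

    def __post_init__(self) -> None:
        N = self.w_rec.shape[0]
        if self.w_rec.shape != (N, N):
            raise ValueError("w_rec must be square")
        if self.w_in.shape[0] != N or self.w_out.shape != (1, N):
            raise ValueError("inconsistent weight shapes")
        if self.alpha.shape != (N,):
            raise ValueError("alpha must have shape (N,)")
        if np.any(self.alpha < 0) or np.any(self.alpha > 1):
            raise ValueError("alpha entries must lie in [0, 1]")
        if self.n_main is not None and not 0 < self.n_main <= N:
            raise ValueError("n_main out of range")

    @property
    def n(self) -> int:
        return self.w_rec.shape[0]

    @property
    def m(self) -> int:
        return self.w_in.shape[1]

    @property
    def n_sub(self) -> int:
        return 0 if self.n_main is None else self.n - self.n_main

    # Block views for the modular equations.
    @property
    def w_main(self) -> np.ndarray:
        return self.w_rec[: self.n_main, : self.n_main]

    @property
    def w_sub(self) -> np.ndarray:
        return self.w_rec[self.n_main :, self.n_main :]

    @property
    def w_s_to_m(self) -> np.ndarray:
        return self.w_rec[: self.n_main, self.n_main :]

    @property
    def w_m_to_s(self) -> np.ndarray:
        return self.w_rec[self.n_main :, : self.n_main]


@dataclass
class NetworkState:
    """Firing rates; for modular specs ``x_m``/``x_s`` view the partition."""

    x: np.ndarray
    n_main: int | None = None

    @property
    def x_m(self) -> np.ndarray:
        return self.x if self.n_main is None else self.x[..., : self.n_main]

    @property
    def x_s(self) -> np.ndarray:
        if self.n_main is None:
            raise AttributeError("homogeneous state has no sub-module")
        return self.x[..., self.n_main :]


def make_spec(
    m: int,
    n: int,
    rng: np.random.Generator,
    n_main: int | None = None,
    alpha=1.0,
    alpha_m: float | None = None,
    alpha_s: float | None = None,
    xi_sd: float = 0.05,
) -> NetworkSpec:
    """Random spec with 1/sqrt(fan-in) Gaussian weights.

    ``alpha`` may be a scalar or an (N,) vector; for two-timescale networks
    pass ``alpha_m``/``alpha_s`` together with ``n_main`` (the split applies
    whether or not the connectivity is modular — set ``n_main=None`` after
    construction for the non-modular two-timescale control).
    """
    w_in = rng.standard_normal((n, m)) / np.sqrt(m)
    w_rec = rng.standard_normal((n, n)) / np.sqrt(n)
    w_out = rng.standard_normal((1, n)) / np.sqrt(n)
    if alpha_m is not None or alpha_s is not None:
        if n_main is None:
            raise ValueError("alpha_m/alpha_s require n_main")
        a = np.empty(n)
        a[:n_main] = alpha_m if alpha_m is not None else alpha
        a[n_main:] = alpha_s if alpha_s is not None else alpha
    else:
        a = np.broadcast_to(np.asarray(alpha, dtype=float), (n,)).copy()
    spec = NetworkSpec(w_in=w_in, w_rec=w_rec, w_out=w_out, alpha=a,
                       n_main=n_main, xi_sd=xi_sd)
    if n_main is not None:
        apply_structural_mask(spec)
    return spec


def apply_structural_mask(spec: NetworkSpec) -> None:
    """Zero the input rows and readout columns of sub-module neurons."""
    if spec.n_main is not None:
        spec.w_in[spec.n_main :, :] = 0.0
        spec.w_out[:, spec.n_main :] = 0.0


def _noise(spec: NetworkSpec, shape, rng) -> np.ndarray:
    if rng is None or spec.xi_sd == 0:
        return np.zeros(shape)
    return rng.normal(0.0, spec.xi_sd, shape)


def step_homogeneous(
    state: NetworkState, u_t: np.ndarray, spec: NetworkSpec,
    rng: np.random.Generator | None = None,
) -> NetworkState:
    """One update of the full-state dynamics (supports batched states)."""
    x = state.x
    pre = u_t @ spec.w_in.T + x @ spec.w_rec.T
    r = np.maximum(pre, 0.0)
    a = spec.alpha
    x_new = (1.0 - a) * x + a * (r + _noise(spec, x.shape, rng))
    return NetworkState(x=x_new, n_main=state.n_main)


def step_modular(
    state: NetworkState, u_t: np.ndarray, spec: NetworkSpec,
    rng: np.random.Generator | None = None,
) -> NetworkState:
    """One update written in main/sub block form.

    Algebraically identical to :func:`step_homogeneous` on the assembled
    matrices (the input/readout masks carry the structural zeros); kept as
    an explicit implementation of the two-module equations.
    """
    if spec.n_main is None:
        raise ValueError("spec has no module partition")
    nm = spec.n_main
    x_m, x_s = state.x_m, state.x_s
    a_m, a_s = spec.alpha[:nm], spec.alpha[nm:]
    pre_m = u_t @ spec.w_in[:nm].T + x_m @ spec.w_main.T + x_s @ spec.w_s_to_m.T
    pre_s = x_s @ spec.w_sub.T + x_m @ spec.w_m_to_s.T
    xi_m = _noise(spec, x_m.shape, rng)
    xi_s = _noise(spec, x_s.shape, rng)
    new_m = (1.0 - a_m) * x_m + a_m * (np.maximum(pre_m, 0.0) + xi_m)
    new_s = (1.0 - a_s) * x_s + a_s * (np.maximum(pre_s, 0.0) + xi_s)
    return NetworkState(x=np.concatenate([new_m, new_s], axis=-1), n_main=nm)


def readout(state: NetworkState, spec: NetworkSpec) -> float | np.ndarray:
    """Linear readout y = W_out x (main module only, via structural zeros)."""
    y = state.x @ spec.w_out[0]
    return float(y) if np.ndim(y) == 0 else y


def run_trace(
    spec: NetworkSpec,
    encoded_input: np.ndarray,
    rng: np.random.Generator | None = None,
    record_states: bool = False,
    x0: np.ndarray | None = None,
):
    """Run the network over encoded input of shape (T, m) or (T, B, m).

    The output at step t is read *after* the update with u(t), so y(t) is a
    function of observations up to and including s(t).  Returns ``(y, X)``
    where ``X`` (if recorded) stacks the post-update states, shape
    (T, ..., N).
    """
    T = encoded_input.shape[0]
    batch_shape = encoded_input.shape[1:-1]
    x = np.zeros(batch_shape + (spec.n,)) if x0 is None else np.array(x0, dtype=float)
    state = NetworkState(x=x, n_main=spec.n_main)
    y = np.empty((T,) + batch_shape)
    X = np.empty((T,) + batch_shape + (spec.n,)) if record_states else None
    for t in range(T):
        state = step_homogeneous(state, encoded_input[t], spec, rng)
        y[t] = state.x @ spec.w_out[0]
        if record_states:
            X[t] = state.x
    return y, X


def save_spec(spec: NetworkSpec, path) -> None:
    """Checkpoint all weight blocks, alpha and the partition to one archive."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(
        path,
        w_in=spec.w_in,
        w_rec=spec.w_rec,
        w_out=spec.w_out,
        alpha=spec.alpha,
        n_main=np.asarray(-1 if spec.n_main is None else spec.n_main),
        xi_sd=np.asarray(spec.xi_sd),
    )


def load_spec(path) -> NetworkSpec:
    with np.load(path) as z:
        n_main = int(z["n_main"])
        return NetworkSpec(
            w_in=z["w_in"],
            w_rec=z["w_rec"],
            w_out=z["w_out"],
            alpha=z["alpha"],
            n_main=None if n_main < 0 else n_main,
            xi_sd=float(z["xi_sd"]),
        )
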