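"""Backpropagation-through-time training of the leaky RNNs.

Each iteration draws a fresh batch of switching-generator traces, encodes
them with the Poisson population code, runs the network forward, and
minimises the mean squared error between the readout y(t) and the latent
truth y_true(t) (used only in the loss).  Optimisation is Adam with L2
weight decay on the synaptic matrices.  Gradients are computed by an
explicit reverse pass through the leaky dynamics; a finite-difference check
in the test suite pins its correctness.

For timescale-emergence experiments the per-neuron rates of change alpha
are trained jointly with the weights.  alpha is parameterised as
sigmoid(a) of an unconstrained variable so it stays inside (0, 1) with
well-defined gradients at the boundary; weight decay is not applied to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import NetworkSpec, apply_structural_mask
from .ppc import PPCConfig, encode_series
from .task import GeneratorRanges, make_trace_batch

__all__ = ["TrainingConfig", "TrainedModel", "mse_loss", "train", "train_learnable_alpha"]


@dataclass
class TrainingConfig:
    """Hyperparameters; defaults follow the fixed-structure study settings."""

    T: int = 120
    batch_size: int = 50
    iterations: int = 6000
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    p_t: float = 0.03
    m: int = 100
    n: int = 200
    n_main: int | None = 150
    modular: bool = True  # False: keep the alpha_m/alpha_s split but allow
    # all neurons to connect to input and output (two-timescale control)
    alpha_m: float = 1.0
    alpha_s: float = 0.1
    xi_sd: float = 0.05
    sigma_ppc_sq: float = 0.5
    ranges: GeneratorRanges = field(default_factory=GeneratorRanges)
    learnable_alpha: bool = False
    alpha_param: str = "clip"  # 'clip': direct alpha, projected onto [0,1]
    # after each update; 'sigmoid': unconstrained variable through sigmoid
    alpha_init_mean: float = 0.5
    alpha_init_sd: float = 0.1
    snapshot_iters: tuple[int, ...] = ()
    grad_clip: float | None = None
    init: str = "gaussian"  # 'gaussian': N(0, 1/fan_in); 'uniform':
    # U(+-1/sqrt(fan_in)).  See docs/methods.md.
    dtype: type = np.float64

    def __post_init__(self) -> None:
        if min(self.T, self.batch_size, self.iterations, self.m, self.n) < 1:
            raise ValueError("T, batch_size, iterations, m, n must be positive")
        if self.learning_rate < 0 or self.weight_decay < 0:
            raise ValueError("learning_rate and weight_decay must be >= 0")
        if not 0 <= self.p_t <= 1:
            raise ValueError("p_t must be a probability")
        if self.alpha_param not in ("clip", "sigmoid"):
            raise ValueError("alpha_param must be 'clip' or 'sigmoid'")
        if self.init not in ("uniform", "gaussian"):
            raise ValueError("init must be 'uniform' or 'gaussian'")
        if self.n_main is not None and not 0 < self.n_main <= self.n:
            raise ValueError("n_main out of range")

    @property
    def mask_n_main(self) -> int | None:
        """Partition boundary for structural zeros (None if non-modular)."""
        return self.n_main if self.modular else None

    @property
    def ppc(self) -> PPCConfig:
        return PPCConfig(m=self.m, sigma_ppc_sq=self.sigma_ppc_sq)


@dataclass
class TrainedModel:
    spec: NetworkSpec
    loss_history: np.ndarray
    alpha_snapshots: dict[int, np.ndarray]
    config: TrainingConfig


def mse_loss(y: np.ndarray, y_true: np.ndarray) -> float:
    """Mean over time (and batch, if present) of the squared output error."""
    y = np.asarray(y)
    y_true = np.asarray(y_true)
    if y.shape != y_true.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {y_true.shape}")
    return float(np.mean((y - y_true) ** 2))


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def forward_backward(
    params: dict,
    U: np.ndarray,
    y_target: np.ndarray,
    xi: np.ndarray | None,
    n_main: int | None,
    learnable_alpha: bool = False,
    alpha_param: str = "sigmoid",
):
    """Loss and gradients for one batch.

    ``params`` holds ``w_in`` (N,m), ``w_rec`` (N,N), ``w_out`` (1,N) and
    either ``alpha`` (fixed) or ``a_raw`` (learnable, alpha = sigmoid(a_raw)).
    ``U`` is (T,B,m); ``y_target`` is (T,B); ``xi`` is a pre-drawn (T,B,N)
    noise array or None for noiseless dynamics.  The network output at step
    t is read from the state after the update with U[t].
    """
    w_in, w_rec, w_out = params["w_in"], params["w_rec"], params["w_out"]
    if not learnable_alpha:
        alpha = params["alpha"]
    elif alpha_param == "sigmoid":
        alpha = _sigmoid(params["a_raw"])
    else:
        alpha = params["a_raw"]
    T, B, _ = U.shape
    N = w_rec.shape[0]
    dt = w_rec.dtype

    x = np.zeros((B, N), dtype=dt)
    Xs = np.empty((T + 1, B, N), dtype=dt)  # states x(0)..x(T)
    Xs[0] = x
    masks = np.empty((T, B, N), dtype=bool)
    A = np.empty((T, B, N), dtype=dt) if learnable_alpha else None  # r + xi
    y = np.empty((T, B), dtype=dt)
    w_out_row = w_out[0]
    for t in range(T):
        pre = U[t] @ w_in.T + x @ w_rec.T
        mask = pre > 0
        r = np.where(mask, pre, 0.0)
        if xi is not None:
            r = r + xi[t]
        x = (1.0 - alpha) * x + alpha * r
        Xs[t + 1] = x
        masks[t] = mask
        if learnable_alpha:
            A[t] = r
        y[t] = x @ w_out_row

    err = y - y_target
    loss = float(np.mean(err * err))
    if not np.isfinite(loss):
        raise FloatingPointError("training diverged: non-finite loss")

    gscale = 2.0 / (T * B)
    g_w_in = np.zeros_like(w_in)
    g_w_rec = np.zeros_like(w_rec)
    g_w_out = np.zeros_like(w_out)
    g_alpha = np.zeros(N, dtype=dt) if learnable_alpha else None
    gX = np.zeros((B, N), dtype=dt)
    for t in range(T - 1, -1, -1):
        gy = gscale * err[t]  # (B,)
        gX += gy[:, None] * w_out_row
        g_w_out[0] += gy @ Xs[t + 1]
        if learnable_alpha:
            g_alpha += np.sum(gX * (A[t] - Xs[t]), axis=0)
        D = (gX * alpha) * masks[t]  # grad wrt pre-activation
        g_w_in += D.T @ U[t]
        g_w_rec += D.T @ Xs[t]
        gX = gX * (1.0 - alpha) + D @ w_rec

    grads = {"w_in": g_w_in, "w_rec": g_w_rec, "w_out": g_w_out}
    if learnable_alpha:
        grads["a_raw"] = (
            g_alpha * alpha * (1.0 - alpha) if alpha_param == "sigmoid" else g_alpha
        )
    if n_main is not None:  # keep structural zeros exact
        grads["w_in"][n_main:, :] = 0.0
        grads["w_out"][:, n_main:] = 0.0
    return loss, grads


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)


def _init_params(cfg: TrainingConfig, rng: np.random.Generator) -> dict:
    dt = cfg.dtype

    def draw(shape, fan_in):
        b = 1.0 / np.sqrt(fan_in)
        if cfg.init == "uniform":
            return rng.uniform(-b, b, shape).astype(dt)
        return (b * rng.standard_normal(shape)).astype(dt)

    params = {
        "w_in": draw((cfg.n, cfg.m), cfg.m),
        "w_rec": draw((cfg.n, cfg.n), cfg.n),
        "w_out": draw((1, cfg.n), cfg.n),
    }
    if cfg.learnable_alpha:
        a0 = np.clip(rng.normal(cfg.alpha_init_mean, cfg.alpha_init_sd, cfg.n), 1e-3, 1 - 1e-3)
        params["a_raw"] = (
            np.log(a0 / (1.0 - a0)).astype(dt)
            if cfg.alpha_param == "sigmoid"
            else a0.astype(dt)
        )
    else:
        alpha = np.full(cfg.n, cfg.alpha_m, dtype=dt)
        if cfg.n_main is not None:
            alpha[cfg.n_main :] = cfg.alpha_s
        params["alpha"] = alpha
    if cfg.mask_n_main is not None:
        params["w_in"][cfg.mask_n_main :, :] = 0.0
        params["w_out"][:, cfg.mask_n_main :] = 0.0
    return params


def current_alpha(params: dict, cfg: TrainingConfig) -> np.ndarray:
    if not cfg.learnable_alpha:
        return params["alpha"]
    if cfg.alpha_param == "sigmoid":
        return _sigmoid(params["a_raw"])
    return params["a_raw"]


def train(
    cfg: TrainingConfig,
    rng: np.random.Generator,
    params: dict | None = None,
    callback=None,
) -> TrainedModel:
    """Train a network under ``cfg``; all randomness flows through ``rng``.

    Fresh traces are drawn every iteration; y_true enters only through the
    loss.  Weight decay is applied to the synaptic matrices (not to alpha).
    """
    if params is None:
        params = _init_params(cfg, rng)
    opt_keys = [k for k in params if k != "alpha"]
    opt = _Adam({k: params[k] for k in opt_keys}, cfg.learning_rate)
    ppc = cfg.ppc
    losses = np.empty(cfg.iterations)
    snapshots: dict[int, np.ndarray] = {}
    if 0 in cfg.snapshot_iters:
        snapshots[0] = current_alpha(params, cfg).copy()

    for it in range(cfg.iterations):
        y_true, s, _, _, sl = make_trace_batch(
            cfg.batch_size, cfg.T, cfg.p_t, rng, cfg.ranges
        )
        U = encode_series(s, sl, ppc, rng).astype(cfg.dtype)
        xi = (
            rng.normal(0.0, cfg.xi_sd, (cfg.T, cfg.batch_size, cfg.n)).astype(cfg.dtype)
            if cfg.xi_sd > 0
            else None
        )
        loss, grads = forward_backward(
            params, U, y_true.astype(cfg.dtype), xi, cfg.mask_n_main,
            cfg.learnable_alpha, cfg.alpha_param,
        )
        losses[it] = loss
        for k in ("w_in", "w_rec", "w_out"):
            grads[k] += cfg.weight_decay * params[k]
        if cfg.grad_clip is not None:
            norm = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
            if norm > cfg.grad_clip:
                for k in grads:
                    grads[k] *= cfg.grad_clip / norm
        opt.step(params, {k: grads[k] for k in opt_keys})
        if cfg.learnable_alpha and cfg.alpha_param == "clip":
            np.clip(params["a_raw"], 0.0, 1.0, out=params["a_raw"])
        if it + 1 in cfg.snapshot_iters:
            snapshots[it + 1] = current_alpha(params, cfg).copy()
        if callback is not None:
            callback(it, loss, params)

    alpha = current_alpha(params, cfg).astype(np.float64)
    spec = NetworkSpec(
        w_in=params["w_in"].astype(np.float64),
        w_rec=params["w_rec"].astype(np.float64),
        w_out=params["w_out"].astype(np.float64),
        alpha=np.clip(alpha, 0.0, 1.0),
        n_main=cfg.mask_n_main,
        xi_sd=cfg.xi_sd,
    )
    if cfg.mask_n_main is not None:
        apply_structural_mask(spec)
    return TrainedModel(spec=spec, loss_history=losses, alpha_snapshots=snapshots, config=cfg)


def train_learnable_alpha(cfg: TrainingConfig, rng: np.random.Generator) -> TrainedModel:
    """Homogeneous network with jointly trained weights and alpha."""
    if not cfg.learnable_alpha:
        raise ValueError("cfg.learnable_alpha must be True")
    if cfg.n_main is not None:
        raise ValueError("learnable-alpha runs use the homogeneous architecture")
    return train(cfg, rng)
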