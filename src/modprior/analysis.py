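"""Representation and performance analyses of trained networks.

* clamp-variance role attribution: how much the stored state of one neuron
  group (module) moves the output when swapped across generator conditions
  while the other group is clamped to a reference state;
* PCA manifolds of frozen states;
* ridge decoding of the generator SD sigma_g from hidden states;
* pseudoinverse prior readout W_mup and the temporal kernel a_k expressing
  the decoded prior mean as a weighted sum of past observations;
* MSE evaluation against the MAP oracle, the ML estimate, and the truth,
  both on switching traces and in the fixed-generator probe protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import Ridge
from sklearn.metrics import r2_score
from sklearn.model_selection import train_test_split

from . import oracle
from .network import NetworkSpec, run_trace
from .ppc import PPCConfig, encode_series
from .task import DEFAULT_SIGMA_L_RANGE, GeneratorParams, GeneratorRanges, make_alternating_trace

__all__ = [
    "FrozenStateLibrary",
    "collect_frozen_states",
    "collect_state_dataset",
    "clamp_variance",
    "clamp_variance_groups",
    "sample_probes",
    "pca_manifold",
    "ridge_decode_sigma",
    "fit_prior_readout",
    "estimate_prior_kernel",
    "prior_kernel_for_model",
    "evaluate_mse",
    "probe_fixed_generator",
    "adjustability_trajectory",
]

#: Reference generator for clamping: the median of the parameter ranges.
REFERENCE_CELL = (0.0, 0.4)
#: sigma_l used when driving fixed-generator traces for state collection:
#: the observation-noise level of the fixed-generator demonstrations.
DRIVE_SIGMA_L = float(1.0 / np.sqrt(5.0))


@dataclass
class FrozenStateLibrary:
    """Stored hidden states after driving the network with fixed generators.

    ``cells`` is (K, 2) of (mu_g, sigma_g); ``states`` is (K, N).  The
    reference state (generator mu_g=0, sigma_g=0.4) is stored separately.
    """

    cells: np.ndarray
    states: np.ndarray
    reference: np.ndarray

    def __post_init__(self) -> None:
        if len(self.cells) != len(self.states):
            raise ValueError("cells and states must align")


def default_grid(n_mu: int = 10, n_sigma: int = 10) -> np.ndarray:
    mu = np.linspace(-0.5, 0.5, n_mu)
    sg = np.linspace(0.0, 0.8, n_sigma)
    mm, ss = np.meshgrid(mu, sg, indexing="ij")
    return np.column_stack([mm.ravel(), ss.ravel()])


def _cell_rng(seed: int, mu: float, sg: float) -> np.random.Generator:
    bits = np.array([mu, sg], dtype=np.float64).view(np.uint64)
    return np.random.default_rng([int(seed)] + [int(b) for b in bits])


def _drive_state(
    spec: NetworkSpec,
    mu: float,
    sg: float,
    sigma_l: float,
    drive_steps: int,
    rng: np.random.Generator,
    ppc: PPCConfig,
    noise: bool,
) -> np.ndarray:
    y_true = mu + sg * rng.standard_normal(drive_steps)
    s = y_true + sigma_l * rng.standard_normal(drive_steps)
    U = encode_series(s, sigma_l, ppc, rng)
    _, X = run_trace(spec, U, rng if noise else None, record_states=True)
    return X[-1]


def collect_frozen_states(
    spec: NetworkSpec,
    cells: np.ndarray | None = None,
    drive_steps: int = 120,
    seed: int = 0,
    sigma_l: float = DRIVE_SIGMA_L,
    ppc: PPCConfig | None = None,
    noise: bool = False,
) -> FrozenStateLibrary:
    """Drive the network with each fixed generator and store the final state.

    The per-cell random stream is derived from ``seed`` and the cell's
    parameter values, so cells with identical (mu_g, sigma_g) store
    identical states.
    """
    if drive_steps < 1:
        raise ValueError("drive_steps must be >= 1")
    if cells is None:
        cells = default_grid()
    cells = np.atleast_2d(np.asarray(cells, dtype=float))
    ppc = ppc or PPCConfig(m=spec.m)
    states = np.stack(
        [
            _drive_state(spec, mu, sg, sigma_l, drive_steps, _cell_rng(seed, mu, sg), ppc, noise)
            for mu, sg in cells
        ]
    )
    mu0, sg0 = REFERENCE_CELL
    reference = _drive_state(
        spec, mu0, sg0, sigma_l, drive_steps, _cell_rng(seed, mu0, sg0), ppc, noise
    )
    return FrozenStateLibrary(cells=cells, states=states, reference=reference)


def collect_state_dataset(
    spec: NetworkSpec,
    n_samples: int,
    rng: np.random.Generator,
    drive_steps: int = 120,
    ranges: GeneratorRanges = GeneratorRanges(),
    ppc: PPCConfig | None = None,
    noise: bool = False,
    sigma_l: float | str = DRIVE_SIGMA_L,
):
    """States after driving with ``n_samples`` random fixed generators.

    Each sample draws its own (mu_g, sigma_g); the observation noise is the
    fixed-generator demonstration level by default (``sigma_l='sampled'``
    draws it per trace instead).  All samples run as one batch.  Returns
    (states, mu_g, sigma_g).
    """
    ppc = ppc or PPCConfig(m=spec.m)
    mu = rng.uniform(*ranges.mu_g, size=n_samples)
    sg = rng.uniform(*ranges.sigma_g, size=n_samples)
    sl = (
        rng.uniform(*ranges.sigma_l, size=n_samples)
        if isinstance(sigma_l, str)
        else np.full(n_samples, float(sigma_l))
    )
    y_true = mu + sg * rng.standard_normal((drive_steps, n_samples))
    s = y_true + sl * rng.standard_normal((drive_steps, n_samples))
    U = encode_series(s, sl, ppc, rng)
    _, X = run_trace(spec, U, rng if noise else None, record_states=True)
    return X[-1], mu, sg


def sample_probes(
    n: int,
    rng: np.random.Generator,
    s_range: tuple[float, float] = (-1.0, 1.0),
    sigma_l_range: tuple[float, float] = DEFAULT_SIGMA_L_RANGE,
) -> np.ndarray:
    """(n, 2) probe pairs (s, sigma_l) for clamp-variance averaging."""
    return np.column_stack(
        [rng.uniform(*s_range, size=n), rng.uniform(*sigma_l_range, size=n)]
    )


def _one_step_outputs(
    spec: NetworkSpec, composed: np.ndarray, u: np.ndarray
) -> np.ndarray:
    """Deterministic one-step outputs y for a stack of composed states."""
    pre = composed @ spec.w_rec.T + u @ spec.w_in.T
    x_new = (1.0 - spec.alpha) * composed + spec.alpha * np.maximum(pre, 0.0)
    return x_new @ spec.w_out[0]


def clamp_variance_groups(
    spec: NetworkSpec,
    library: FrozenStateLibrary,
    vary_idx: np.ndarray,
    probes: np.ndarray,
    rng: np.random.Generator,
    ppc: PPCConfig | None = None,
) -> float:
    """Output variance attributable to the neuron group ``vary_idx``.

    For each probe (s, sigma_l): compose states that take the library cell's
    values on ``vary_idx`` and the reference state elsewhere, advance the
    dynamics one deterministic step with the encoded probe, and take the
    variance of y over cells.  Returns the probe-averaged variance.
    """
    vary_idx = np.asarray(vary_idx)
    if vary_idx.size == 0:
        raise ValueError("empty neuron group")
    ppc = ppc or PPCConfig(m=spec.m)
    composed = np.tile(library.reference, (len(library.states), 1))
    composed[:, vary_idx] = library.states[:, vary_idx]
    total = 0.0
    for s, sl in probes:
        u = rng.poisson(
            np.exp(-((s - ppc.phi) ** 2) / (2 * ppc.sigma_ppc_sq)) / sl**2
        ).astype(float)
        y = _one_step_outputs(spec, composed, u)
        total += float(np.var(y))
    return total / len(probes)


def clamp_variance(
    spec: NetworkSpec,
    library: FrozenStateLibrary,
    probes: np.ndarray,
    rng: np.random.Generator,
    ppc: PPCConfig | None = None,
) -> tuple[float, float]:
    """(V_m, V_s): main-module and sub-module clamp variances."""
    if spec.n_main is None:
        raise ValueError("clamp_variance requires a modular spec")
    main_idx = np.arange(spec.n_main)
    sub_idx = np.arange(spec.n_main, spec.n)
    # paired comparison: both module variances see identical probe encodings
    probe_seed = int(rng.integers(2**31))
    v_m = clamp_variance_groups(
        spec, library, main_idx, probes, np.random.default_rng(probe_seed), ppc
    )
    v_s = clamp_variance_groups(
        spec, library, sub_idx, probes, np.random.default_rng(probe_seed), ppc
    )
    return v_m, v_s


def pca_manifold(states: np.ndarray, n_components: int = 2):
    """First principal-component coordinates of the state vectors.

    Returns (projections, explained_variance_ratio).
    """
    states = np.asarray(states)
    if states.shape[0] < 3:
        raise ValueError("need at least 3 state vectors for a manifold")
    pca = PCA(n_components=n_components)
    proj = pca.fit_transform(states)
    return proj, pca.explained_variance_ratio_


def ridge_decode_sigma(
    states: np.ndarray,
    sigma_g: np.ndarray,
    regularization: float = 1.0,
    test_size: float = 0.2,
    n_repeats: int = 5,
    rng: np.random.Generator | None = None,
) -> float:
    """Out-of-sample R^2 of a ridge map hidden state -> sigma_g."""
    sigma_g = np.asarray(sigma_g, dtype=float)
    if np.ptp(sigma_g) == 0:
        raise ValueError("sigma_g labels are constant: R^2 undefined")
    rng = rng or np.random.default_rng(0)
    scores = []
    for _ in range(n_repeats):
        seed = int(rng.integers(2**31))
        Xtr, Xte, ytr, yte = train_test_split(
            states, sigma_g, test_size=test_size, random_state=seed
        )
        model = Ridge(alpha=regularization).fit(Xtr, ytr)
        scores.append(r2_score(yte, model.predict(Xte)))
    return float(np.mean(scores))


def fit_prior_readout(X: np.ndarray, m_g: np.ndarray):
    """Least-squares linear map state -> generator mean via pseudoinverse.

    ``X`` is (n_samples, N); ``m_g`` is (n_samples,).  Returns (w, r2) where
    mu_p = X @ w is the decoded prior mean.
    """
    X = np.asarray(X, dtype=float)
    m_g = np.asarray(m_g, dtype=float)
    w = np.linalg.pinv(X) @ m_g
    pred = X @ w
    denom = np.sum((m_g - m_g.mean()) ** 2)
    r2 = 1.0 - np.sum((m_g - pred) ** 2) / denom if denom > 0 else 0.0
    return w, float(r2)


def estimate_prior_kernel(mu_p: np.ndarray, s: np.ndarray, K: int) -> np.ndarray:
    """Kernel a_k with mu_p(t) ~= sum_k a_k s(t-k), lags k = 1..K."""
    mu_p = np.asarray(mu_p, dtype=float)
    s = np.asarray(s, dtype=float)
    T = len(s)
    if len(mu_p) != T:
        raise ValueError("series must align")
    if T <= K:
        raise ValueError("series length must exceed K")
    S = np.column_stack([s[K - k : T - k] for k in range(1, K + 1)])
    target = mu_p[K:]
    return np.linalg.pinv(S) @ target


def prior_readout_for_model(
    spec: NetworkSpec,
    rng: np.random.Generator,
    n_generators: int = 100,
    drive_steps: int = 120,
    burn_in: int = 40,
    ranges: GeneratorRanges = GeneratorRanges(),
    ppc: PPCConfig | None = None,
):
    """Build (X, M_g) from fixed-generator runs and fit W_mup."""
    ppc = ppc or PPCConfig(m=spec.m)
    mu = rng.uniform(*ranges.mu_g, size=n_generators)
    sg = rng.uniform(*ranges.sigma_g, size=n_generators)
    sl = rng.uniform(*ranges.sigma_l, size=n_generators)
    y_true = mu + sg * rng.standard_normal((drive_steps, n_generators))
    s = y_true + sl * rng.standard_normal((drive_steps, n_generators))
    U = encode_series(s, sl, ppc, rng)
    _, X = run_trace(spec, U, None, record_states=True)
    Xd = X[burn_in:].reshape(-1, spec.n)
    Md = np.broadcast_to(mu, (drive_steps - burn_in, n_generators)).ravel()
    return fit_prior_readout(Xd, Md)


def prior_kernel_for_model(
    spec: NetworkSpec,
    w_mup: np.ndarray,
    rng: np.random.Generator,
    T: int = 3000,
    p_t: float = 0.03,
    K: int = 40,
    ranges: GeneratorRanges = GeneratorRanges(),
    ppc: PPCConfig | None = None,
) -> np.ndarray:
    """Decode mu_p along one long switching trace and fit the lag kernel."""
    from .task import make_trace_batch

    ppc = ppc or PPCConfig(m=spec.m)
    _, s, _, _, sl = make_trace_batch(1, T, p_t, rng, ranges)
    U = encode_series(s, sl, ppc, rng)
    _, X = run_trace(spec, U, None, record_states=True)
    mu_p = X[:, 0, :] @ w_mup
    return estimate_prior_kernel(mu_p, s[:, 0], K)


def evaluate_mse(
    spec: NetworkSpec,
    rng: np.random.Generator,
    n_traces: int = 100,
    T: int = 120,
    p_t: float = 0.03,
    ranges: GeneratorRanges = GeneratorRanges(),
    ppc: PPCConfig | None = None,
    burn_in: int = 20,
    noise: bool = True,
):
    """MSE of the output vs the MAP oracle, the truth, and the ML estimate
    on switching traces, with standard errors over traces."""
    from .task import make_trace_batch

    ppc = ppc or PPCConfig(m=spec.m)
    y_true, s, mu_h, sg_h, sl = make_trace_batch(n_traces, T, p_t, rng, ranges)
    U = encode_series(s, sl, ppc, rng)
    y, _ = run_trace(spec, U, rng if noise else None)
    y_opt = oracle.map_estimate(s, mu_h, sg_h, sl[None, :])
    out = {}
    for name, ref in (("opt", y_opt), ("true", y_true), ("ml", s)):
        per_trace = np.mean((y - ref)[burn_in:] ** 2, axis=0)
        out[f"mse_vs_{name}"] = float(per_trace.mean())
        out[f"se_vs_{name}"] = float(per_trace.std(ddof=1) / np.sqrt(n_traces))
    return out


def probe_fixed_generator(
    spec: NetworkSpec,
    rng: np.random.Generator,
    mu_g: float = 0.5,
    sigma_g: float = 0.5,
    sigma_l: float = 1.0 / np.sqrt(5.0),
    n_repeats: int = 200,
    probes: np.ndarray | None = None,
    drive_steps: int = 120,
    ppc: PPCConfig | None = None,
    drive_noise: bool = True,
):
    """Fixed-generator probe protocol.

    A prior-establishing trace from the fixed generator drives the network
    for ``drive_steps``; then each probe value s* is applied for a single
    deterministic step and the readout compared with y_opt(s*) and
    y_ML = s*.  Probes default to a uniform grid over [-1, 1], the range the
    output-vs-signal relation is examined over.
    """
    ppc = ppc or PPCConfig(m=spec.m)
    if probes is None:
        probes = np.linspace(-1.0, 1.0, 41)
    probes = np.asarray(probes, dtype=float)

    y_true = mu_g + sigma_g * rng.standard_normal((drive_steps, n_repeats))
    s = y_true + sigma_l * rng.standard_normal((drive_steps, n_repeats))
    U = encode_series(s, np.full(n_repeats, sigma_l), ppc, rng)
    _, X = run_trace(spec, U, rng if drive_noise else None, record_states=True)
    x_end = X[-1]  # (n_repeats, N)

    P = len(probes)
    u_probe = encode_series(
        np.repeat(probes, n_repeats), sigma_l, ppc, rng
    )  # (P*n_repeats, m)
    composed = np.tile(x_end, (P, 1))
    y = _one_step_outputs(spec, composed, u_probe).reshape(P, n_repeats)

    y_opt = oracle.map_estimate(probes, mu_g, sigma_g, sigma_l)[:, None]
    y_ml = probes[:, None]
    return {
        "probes": probes,
        "y": y,
        "mse_vs_opt": float(np.mean((y - y_opt) ** 2)),
        "mse_vs_ml": float(np.mean((y - y_ml) ** 2)),
    }


def adjustability_trajectory(
    spec: NetworkSpec,
    gen_a: GeneratorParams,
    gen_b: GeneratorParams,
    mode: str,
    period_or_pt: float,
    T: int,
    rng: np.random.Generator,
    ppc: PPCConfig | None = None,
    noise: bool = True,
):
    """a(t) along an alternating-generator trace.

    ``identity`` is 0 where generator A is active (a fully adjusted output
    would give a(t) = 1 there) and 1 for B.
    """
    ppc = ppc or PPCConfig(m=spec.m)
    trace = make_alternating_trace(gen_a, gen_b, mode, period_or_pt, T, rng)
    U = encode_series(trace.s, trace.sigma_l[0], ppc, rng)
    y, _ = run_trace(spec, U, rng if noise else None)
    sl = trace.sigma_l
    y_opt_a = oracle.map_estimate(trace.s, gen_a.mu_g, gen_a.sigma_g, sl)
    y_opt_b = oracle.map_estimate(trace.s, gen_b.mu_g, gen_b.sigma_g, sl)
    a_t = oracle.adjustability(y, y_opt_a, y_opt_b)
    identity = (trace.mu_g != gen_a.mu_g) | (trace.sigma_g != gen_a.sigma_g)
    return {"a_t": a_t, "identity": identity.astype(int), "y": y, "trace": trace}
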