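"""Leaky-RNN dynamics: trivial limits, block equivalence, round trips."""

import numpy as np
import pytest

from modprior.network import (
    NetworkSpec,
    NetworkState,
    load_spec,
    make_spec,
    readout,
    run_trace,
    save_spec,
    step_homogeneous,
    step_modular,
)


@pytest.fixture
def rng():
    return np.random.default_rng(5)


def test_alpha_zero_freezes_state(rng):
    spec = make_spec(m=4, n=6, rng=rng, alpha=0.0, xi_sd=0.0)
    x0 = rng.normal(size=6)
    state = step_homogeneous(NetworkState(x=x0.copy()), rng.random(4), spec, rng)
    np.testing.assert_array_equal(state.x, x0)


def test_alpha_one_zero_weights_resets_to_zero(rng):
    spec = make_spec(m=4, n=6, rng=rng, alpha=1.0, xi_sd=0.0)
    spec.w_in[:] = 0.0
    spec.w_rec[:] = 0.0
    state = step_homogeneous(NetworkState(x=rng.normal(size=6)), rng.random(4), spec, rng)
    np.testing.assert_array_equal(state.x, 0.0)


def test_relu_clamps_negative_preactivation(rng):
    # scalar neuron driven to a negative pre-activation stays at zero
    spec = NetworkSpec(
        w_in=np.array([[-3.0]]), w_rec=np.zeros((1, 1)),
        w_out=np.ones((1, 1)), alpha=np.ones(1), xi_sd=0.0,
    )
    state = step_homogeneous(NetworkState(x=np.zeros(1)), np.array([1.0]), spec)
    assert state.x[0] == 0.0


def test_geometric_decay_with_zero_weights(rng):
    alpha = 0.3
    spec = make_spec(m=2, n=4, rng=rng, alpha=alpha, xi_sd=0.0)
    spec.w_in[:] = 0.0
    spec.w_rec[:] = 0.0
    x0 = np.abs(rng.normal(size=4))
    state = NetworkState(x=x0.copy())
    for t in range(1, 6):
        state = step_homogeneous(state, np.zeros(2), spec)
        np.testing.assert_allclose(state.x, (1 - alpha) ** t * x0, rtol=1e-12)


@pytest.mark.parametrize("trial", range(20))
def test_modular_step_matches_assembled_homogeneous(trial):
    """Eqs in block form agree with the merged-matrix update along T=50."""
    rng = np.random.default_rng(100 + trial)
    spec = make_spec(m=5, n=9, n_main=6, rng=rng, alpha_m=1.0, alpha_s=0.2, xi_sd=0.0)
    T = 50
    U = rng.random((T, 5))
    state_h = NetworkState(x=np.zeros(9), n_main=6)
    state_m = NetworkState(x=np.zeros(9), n_main=6)
    for t in range(T):
        state_h = step_homogeneous(state_h, U[t], spec)
        state_m = step_modular(state_m, U[t], spec)
    assert np.max(np.abs(state_h.x - state_m.x)) < 1e-6 * max(1, np.max(np.abs(state_h.x)))


def test_modular_step_with_noise_matches_under_same_seed(rng):
    spec = make_spec(m=3, n=7, n_main=4, rng=rng, alpha_m=0.9, alpha_s=0.1, xi_sd=0.05)
    u = rng.random(3)
    x = rng.normal(size=7)
    a = step_homogeneous(NetworkState(x=x.copy(), n_main=4), u, spec, np.random.default_rng(1))
    b = step_modular(NetworkState(x=x.copy(), n_main=4), u, spec, np.random.default_rng(1))
    np.testing.assert_allclose(a.x, b.x, rtol=1e-12)


def test_alpha_one_is_memoryless_map(rng):
    spec = make_spec(m=3, n=5, rng=rng, alpha=1.0, xi_sd=0.0)
    u = rng.random(3)
    x = rng.normal(size=5)
    state = step_homogeneous(NetworkState(x=x.copy()), u, spec)
    expect = np.maximum(spec.w_in @ u + spec.w_rec @ x, 0.0)
    np.testing.assert_allclose(state.x, expect, rtol=1e-12)


def test_sub_module_ignores_input_when_frozen(rng):
    spec = make_spec(m=3, n=6, n_main=4, rng=rng, alpha_m=1.0, alpha_s=0.0, xi_sd=0.0)
    state = NetworkState(x=rng.normal(size=6), n_main=4)
    xs0 = state.x_s.copy()
    for _ in range(5):
        state = step_modular(state, rng.random(3), spec, rng)
    np.testing.assert_array_equal(state.x_s, xs0)


def test_readout_matches_dot_product_oracle(rng):
    spec = make_spec(m=3, n=8, n_main=5, rng=rng)
    state = NetworkState(x=rng.normal(size=8), n_main=5)
    assert readout(state, spec) == pytest.approx(float(np.dot(spec.w_out[0], state.x)))
    e_k = np.zeros((1, 8))
    e_k[0, 2] = 1.0
    spec.w_out = e_k
    assert readout(state, spec) == pytest.approx(state.x[2])


def test_run_trace_single_step_hand_computation(rng):
    spec = make_spec(m=2, n=3, rng=rng, alpha=0.5, xi_sd=0.0)
    U = rng.random((1, 2))
    y, _ = run_trace(spec, U)
    x1 = 0.5 * np.maximum(spec.w_in @ U[0], 0.0)
    assert y[0] == pytest.approx(float(spec.w_out[0] @ x1))


def test_run_trace_deterministic_and_recording_neutral(rng):
    spec = make_spec(m=4, n=10, n_main=7, rng=rng, alpha_m=1.0, alpha_s=0.1)
    U = rng.random((30, 4))
    y1, _ = run_trace(spec, U, np.random.default_rng(9))
    y2, X = run_trace(spec, U, np.random.default_rng(9), record_states=True)
    np.testing.assert_array_equal(y1, y2)
    assert X.shape == (30, 10)


def test_checkpoint_round_trip(rng, tmp_path):
    spec = make_spec(m=6, n=12, n_main=8, rng=rng, alpha_m=1.0, alpha_s=0.05)
    save_spec(spec, tmp_path / "ckpt.npz")
    back = load_spec(tmp_path / "ckpt.npz")
    np.testing.assert_array_equal(back.w_rec, spec.w_rec)
    np.testing.assert_array_equal(back.alpha, spec.alpha)
    assert back.n_main == 8 and back.xi_sd == spec.xi_sd


def test_invalid_alpha_rejected(rng):
    with pytest.raises(ValueError):
        make_spec(m=2, n=3, rng=rng, alpha=1.5)
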