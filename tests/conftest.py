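"""Shared fixtures: trained networks reused across analysis tests.

Training is the expensive step, so trained models are session-scoped and
scaled down from the headline configuration.  Three tiers are used:

* full architecture (N=200, m=100, T=120) with shortened training, for the
  quantitative near-optimality and decoding targets;
* a reduced architecture for cross-condition comparisons, at two training
  lengths — the alpha_s orderings need ~3000 iterations to stabilise,
  while the behaviour under per-step generator alternation only settles
  near full convergence (10000 iterations);
* small learnable-timescale networks trained the full 10000 iterations
  (the timescale split develops slowly, so the architecture is shrunk
  rather than the training shortened).
"""

from __future__ import annotations

import numpy as np
import pytest

from modprior.training import TrainingConfig, train

FULL_ARCH = dict(m=100, n=200, n_main=150, T=120, batch_size=50,
                 iterations=2000, dtype=np.float32)
SMALL_ARCH = dict(m=48, n=84, n_main=63, T=80, batch_size=24,
                  iterations=3000, dtype=np.float32)

FULL_SEED = 42
SMALL_SEED = 12345


def train_model(arch: dict, seed: int, **overrides):
    cfg = TrainingConfig(**{**arch, **overrides})
    return train(cfg, np.random.default_rng(seed))


@pytest.fixture(scope="session")
def slow_model():
    """Full-architecture modular network with a slow sub-module (alpha_s=0.1)."""
    return train_model(FULL_ARCH, FULL_SEED, alpha_s=0.1)


@pytest.fixture(scope="session")
def uniform_model():
    """Full-architecture modular connectivity, uniform timescale (alpha_s=1)."""
    return train_model(FULL_ARCH, FULL_SEED, alpha_s=1.0)


@pytest.fixture(scope="session")
def small_models():
    """Matched-seed reduced models across alpha_s and structure variants."""
    out = {}
    for a_s in (0.1, 1.0, 0.01, 0.2):
        out[("modular", a_s)] = train_model(SMALL_ARCH, SMALL_SEED, alpha_s=a_s)
    # two-timescale but non-modular control: same alpha split, no
    # structural zeros on input/readout
    out[("nonmodular", 0.1)] = train_model(SMALL_ARCH, SMALL_SEED, alpha_s=0.1,
                                           modular=False)
    return out


@pytest.fixture(scope="session")
def converged_small_pair():
    """Reduced-architecture alpha_s={0.1, 1} pair trained to convergence."""
    return {
        a_s: train_model(SMALL_ARCH, SMALL_SEED, alpha_s=a_s, iterations=10000)
        for a_s in (0.1, 1.0)
    }


@pytest.fixture(scope="session")
def learnable_models():
    """Learnable-alpha homogeneous networks trained at three switching rates."""
    out = {}
    for i, p_t in enumerate((0.03, 0.1, 0.3)):
        cfg = TrainingConfig(
            m=40, n=48, n_main=None, T=60, batch_size=16, iterations=10000,
            p_t=p_t, learnable_alpha=True, dtype=np.float32,
            snapshot_iters=(0, 1000, 10000),
        )
        out[p_t] = train(cfg, np.random.default_rng(900 + i))
    return out


def pytest_collection_modifyitems(config, items):
    # run cheap unit tests before the trained-model integration tests
    items.sort(key=lambda it: "acceptance" in it.nodeid)
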