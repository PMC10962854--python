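"""Analyses of learnable-timescale runs.

After joint training of weights and per-neuron rates of change alpha, the
alpha distribution typically splits into a fast group (alpha near 1) and a
slow group; these functions quantify that split, attribute prior
representation to the slow vs fast groups via the clamp-variance procedure,
and summarise the emergent block connectivity between the input layer, the
slow / intermediate / fast neuron groups, and the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import FrozenStateLibrary, clamp_variance_groups
from .network import NetworkSpec
from .ppc import PPCConfig

__all__ = [
    "NeuronGrouping",
    "group_neurons",
    "alpha_histogram",
    "bimodality_dip",
    "group_roles",
    "connectivity_summary",
]

SLOW_THRESHOLD = 0.2
FAST_THRESHOLD = 0.8


@dataclass
class NeuronGrouping:
    slow: np.ndarray  # alpha < 0.2
    fast: np.ndarray  # alpha > 0.8
    mid: np.ndarray  # the rest

    @property
    def n(self) -> int:
        return len(self.slow) + len(self.fast) + len(self.mid)


def group_neurons(
    alpha: np.ndarray,
    slow_threshold: float = SLOW_THRESHOLD,
    fast_threshold: float = FAST_THRESHOLD,
) -> NeuronGrouping:
    alpha = np.asarray(alpha)
    slow = np.flatnonzero(alpha < slow_threshold)
    fast = np.flatnonzero(alpha > fast_threshold)
    mid = np.flatnonzero((alpha >= slow_threshold) & (alpha <= fast_threshold))
    return NeuronGrouping(slow=slow, fast=fast, mid=mid)


def alpha_histogram(
    snapshots: dict[int, np.ndarray], bins: int = 20
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Binned alpha counts per logged epoch over [0, 1]."""
    edges = np.linspace(0.0, 1.0, bins + 1)
    return {
        epoch: (np.histogram(a, bins=edges)[0], edges)
        for epoch, a in snapshots.items()
    }


def bimodality_dip(alpha: np.ndarray, bins: int = 20) -> float:
    """Occupancy contrast between the outer modes and the mid bins.

    Returns (min of the two outer-third maxima) minus the mid-third minimum,
    in units of counts; positive values indicate a dip between two modes.
    """
    counts, _ = np.histogram(np.asarray(alpha), bins=np.linspace(0, 1, bins + 1))
    third = bins // 3
    lo, mid, hi = counts[:third], counts[third : bins - third], counts[bins - third :]
    return float(min(lo.max(), hi.max()) - mid.min())


def group_roles(
    spec: NetworkSpec,
    grouping: NeuronGrouping,
    library: FrozenStateLibrary,
    probes: np.ndarray,
    rng: np.random.Generator,
    ppc: PPCConfig | None = None,
) -> tuple[float, float]:
    """(V_slow, V_fast): clamp variances with the slow and fast neuron sets
    playing the varied role while the rest is clamped to the reference."""
    if len(grouping.slow) == 0 or len(grouping.fast) == 0:
        raise ValueError(
            f"need non-empty slow and fast groups "
            f"(slow={len(grouping.slow)}, fast={len(grouping.fast)})"
        )
    probe_seed = int(rng.integers(2**31))
    v_slow = clamp_variance_groups(
        spec, library, grouping.slow, probes, np.random.default_rng(probe_seed), ppc
    )
    v_fast = clamp_variance_groups(
        spec, library, grouping.fast, probes, np.random.default_rng(probe_seed), ppc
    )
    return v_slow, v_fast


def connectivity_summary(spec: NetworkSpec, grouping: NeuronGrouping) -> dict:
    """Mean absolute connection strength per block, max-normalised to 1.

    Blocks cover input->group, group->group, and group->output for every
    non-empty group among slow / mid / fast.  w_rec[i, j] is the j -> i
    connection.
    """
    groups = {
        name: idx
        for name, idx in (("slow", grouping.slow), ("mid", grouping.mid), ("fast", grouping.fast))
        if len(idx) > 0
    }
    raw: dict[tuple[str, str], float] = {}
    for name, idx in groups.items():
        raw[("input", name)] = float(np.mean(np.abs(spec.w_in[idx, :])))
        raw[(name, "output")] = float(np.mean(np.abs(spec.w_out[0, idx])))
        for name2, idx2 in groups.items():
            raw[(name, name2)] = float(np.mean(np.abs(spec.w_rec[np.ix_(idx2, idx)])))
    peak = max(raw.values())
    if peak > 0:
        raw = {k: v / peak for k, v in raw.items()}
    return raw
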