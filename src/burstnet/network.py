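"""Connectivity construction and current-based synaptic transmission.

Wiring is homogeneous fixed in-degree: every postsynaptic neuron receives
exactly K = round(p * N_pre) presynaptic partners sampled uniformly without
replacement (optionally excluding the autapse).  Synaptic currents are
exponential: a presynaptic spike produces an instantaneous jump of w_ij in the
postsynaptic filter, which then decays with tau = 5 ms (excitatory) or 10 ms
(inhibitory).  Weights are stored as nonnegative magnitudes; the sign is a
property of the group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SynapseGroup", "build_connectivity", "propagate_spikes",
           "TAU_EXC_MS", "TAU_INH_MS"]

TAU_EXC_MS = 5.0
TAU_INH_MS = 10.0


class ConfigurationError(ValueError):
    pass


def build_connectivity(
    N_pre: int,
    N_post: int,
    p: float,
    exclude_autapses: bool = False,
    seed: int | np.random.Generator = 0,
    in_degree: int | None = None,
) -> np.ndarray:
    """Fixed in-degree random adjacency.

    Returns an (N_post, K) integer array: row i lists the presynaptic indices
    of post neuron i.  K = round(p * N_pre) unless ``in_degree`` overrides it
    (used by scaled-down presets that preserve the full-scale in-degree).
    ``exclude_autapses`` removes index i from row i's candidates (recurrent
    inhibitory wiring within one population).
    """
    if in_degree is None:
        if not 0 < p <= 1:
            raise ConfigurationError("connection probability must be in (0, 1]")
        K = int(round(p * N_pre))
    else:
        K = int(in_degree)
    if K < 1:
        raise ConfigurationError("in-degree must be at least 1")
    max_k = N_pre - 1 if exclude_autapses else N_pre
    if K > max_k:
        raise ConfigurationError(
            f"in-degree {K} infeasible for N_pre={N_pre}"
            f"{' with autapses excluded' if exclude_autapses else ''}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    adj = np.empty((N_post, K), dtype=np.int64)
    candidates = np.arange(N_pre)
    for i in range(N_post):
        if exclude_autapses and i < N_pre:
            pool = np.delete(candidates, i)
        else:
            pool = candidates
        adj[i] = rng.choice(pool, size=K, replace=False)
    return adj


@dataclass
class SynapseGroup:
    """One pre->post pathway with exponential current-based synapses."""

    name: str
    adjacency: np.ndarray          # (N_post, K) presynaptic indices
    weights: np.ndarray            # (N_post, K) magnitudes, pA, >= 0
    sign: int                      # +1 excitatory, -1 inhibitory
    target: str = "single"         # soma | dendrite | single
    tau_syn: float | None = None   # ms; defaults by sign
    filtered: np.ndarray = field(default=None)  # per-post filter state (pA)

    def __post_init__(self) -> None:
        if self.sign not in (+1, -1):
            raise ConfigurationError("sign must be +1 or -1")
        if np.any(self.weights < 0):
            raise ConfigurationError("weights are magnitudes and must be >= 0")
        if self.tau_syn is None:
            self.tau_syn = TAU_EXC_MS if self.sign > 0 else TAU_INH_MS
        if self.filtered is None:
            self.filtered = np.zeros(self.adjacency.shape[0])

    @property
    def n_post(self) -> int:
        return self.adjacency.shape[0]

    @property
    def in_degree(self) -> int:
        return self.adjacency.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Edge list as a (post, pre, weight_pA) table."""
        n_post, k = self.adjacency.shape
        return pd.DataFrame(
            {
                "post": np.repeat(np.arange(n_post), k),
                "pre": self.adjacency.ravel(),
                "weight_pA": self.weights.ravel(),
            }
        )

    def to_dense(self, n_pre: int) -> np.ndarray:
        """Dense signed weight matrix (N_post, N_pre)."""
        dense = np.zeros((self.n_post, n_pre))
        rows = np.repeat(np.arange(self.n_post), self.in_degree)
        np.add.at(dense, (rows, self.adjacency.ravel()), self.sign * self.weights.ravel())
        return dense


def propagate_spikes(group: SynapseGroup, pre_spikes: np.ndarray, dt: float) -> np.ndarray:
    """Advance the group's filter one step and return the signed current.

    The filter first decays by exp(-dt/tau), then each presynaptic spike adds
    its weight instantaneously to every connected postsynaptic filter, so a
    spike delivered at this step contributes exactly w at the returned sample.
    """
    if not np.all(np.isfinite(group.filtered)):
        raise RuntimeError("non-finite synaptic filter state")
    group.filtered *= np.exp(-dt / group.tau_syn)
    if pre_spikes.any():
        spiking = np.flatnonzero(pre_spikes)
        mask = np.isin(group.adjacency, spiking)
        group.filtered += np.where(mask, group.weights, 0.0).sum(axis=1)
    return group.sign * group.filtered
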