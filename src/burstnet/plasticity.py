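"""Homeostatic inhibitory plasticity rules.

Four variants, all built on exponentially decaying activity traces with a
common time constant tau_STDP (20 ms):

* ``vogels_spike`` — symmetric spike-pair rule: coincident pre/post spikes
  potentiate, every presynaptic spike depresses by eta*alpha.  The depression
  factor alpha = 2 * rho_0 * tau_STDP pins the postsynaptic firing rate at the
  target rho_0.
* ``burst_algorithmic`` — same ledger, but the postsynaptic trace is driven by
  *burst* events (detected online by the 16 ms ISI criterion, counted once per
  burst), so the fixed point is a target burst rate.
* ``burst_voltage`` — the local-dendrite variant: postsynaptic events are
  dendritic calcium spikes, detected as upward crossings of the dendritic
  potential through -20 mV (a near-step sigmoid); alpha is an empirical knob.
* ``rate_only`` — drops the presynaptic factor: every update_interval (50 ms)
  each weight moves by eta * (x_post - alpha) with alpha = rho_0 * tau_STDP.

Weights are magnitudes in pA, floored at 0; potentiation of an inhibitory
synapse means stronger inhibition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PlasticityConfig",
    "TraceState",
    "OnlineBurstDetector",
    "decay_traces",
    "vogels_update",
    "burst_update_algorithmic",
    "rate_only_update",
    "detect_calcium_events",
]

TAU_STDP_MS = 20.0
CA_THRESHOLD_MV = -20.0   # sharp-sigmoid threshold for dendritic calcium events
CA_MERGE_MS = 10.0        # crossings closer than this merge into one plateau event
BURST_ISI_MS = 16.0


@dataclass(frozen=True)
class PlasticityConfig:
    """Rule variant plus its scalar knobs.

    ``alpha`` is derived from ``rho_0`` (Hz) when not given explicitly:
    2*rho_0*tau_STDP for the pair-based rules, rho_0*tau_STDP for rate_only.
    The burst_voltage variant has no closed-form relation — its alpha is
    calibrated empirically and must be supplied.
    """

    rule: str = "vogels_spike"     # vogels_spike | burst_algorithmic | burst_voltage | rate_only
    eta: float = 0.1               # learning rate (multiplier on pA updates)
    tau_stdp: float = TAU_STDP_MS  # ms
    rho_0: float | None = None     # target rate, Hz
    alpha: float | None = None     # depression factor (unitless)
    update_interval: float = 50.0  # ms, rate_only only
    w_min: float = 0.0             # weight floor, pA

    def __post_init__(self) -> None:
        if self.rule not in ("vogels_spike", "burst_algorithmic", "burst_voltage", "rate_only"):
            raise ValueError(f"unknown plasticity rule {self.rule!r}")
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.alpha is None:
            if self.rho_0 is None:
                raise ValueError("need rho_0 or an explicit alpha")
            if self.rule == "burst_voltage":
                raise ValueError("burst_voltage takes an empirical alpha, not rho_0")
            factor = 1.0 if self.rule == "rate_only" else 2.0
            object.__setattr__(
                self, "alpha", factor * self.rho_0 * self.tau_stdp / 1000.0
            )


@dataclass
class TraceState:
    """Per-neuron pre/post activity traces (unitless, decay with tau_STDP)."""

    x_pre: np.ndarray
    x_post: np.ndarray

    @classmethod
    def zeros(cls, n_pre: int, n_post: int) -> "TraceState":
        return cls(np.zeros(n_pre), np.zeros(n_post))


def decay_traces(traces: TraceState, dt: float, tau_stdp: float = TAU_STDP_MS) -> TraceState:
    """Multiply every trace by exp(-dt/tau_STDP); mutates and returns."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    decay = np.exp(-dt / tau_stdp)
    traces.x_pre *= decay
    traces.x_post *= decay
    return traces


def _clamp(w, w_min):
    return np.maximum(w, w_min)


def vogels_update(w, traces: TraceState, event: str, config: PlasticityConfig,
                  pre_idx=None, post_idx=None):
    """Apply one spike event of the symmetric pair rule to weights ``w``.

    ``w`` is the (N_post, K)-or-scalar weight magnitude array of the synapses
    touched by the event; the caller has already incremented the event's own
    trace (x -> x + 1).  ``event`` is "pre" (spike of pre neuron ``pre_idx``;
    depresses by eta*alpha, potentiates by eta*x_post) or "post" (spike of post
    neuron ``post_idx``; potentiates by eta*x_pre).
    """
    eta, alpha = config.eta, config.alpha
    if event == "pre":
        x_post = traces.x_post if post_idx is None else traces.x_post[post_idx]
        return _clamp(w + eta * (x_post - alpha), config.w_min)
    if event == "post":
        x_pre = traces.x_pre if pre_idx is None else traces.x_pre[pre_idx]
        return _clamp(w + eta * x_pre, config.w_min)
    raise ValueError("event must be 'pre' or 'post'")


def burst_update_algorithmic(w, traces: TraceState, event: str, config: PlasticityConfig,
                             pre_idx=None, post_idx=None):
    """Burst-timing rule: identical ledger to the pair rule, but the
    postsynaptic trace counts burst events rather than spikes.  ``event`` is
    "pre" or "burst"."""
    if event == "burst":
        event = "post"
    return vogels_update(w, traces, event, config, pre_idx=pre_idx, post_idx=post_idx)


def rate_only_update(w, x_post, config: PlasticityConfig):
    """Spike-timing-independent tick: w += eta * (x_post - alpha), floored.

    Called once per update_interval of simulated time; x_post is the burst (or
    calcium-event) trace of the postsynaptic neuron, broadcast over its
    incoming weights.
    """
    return _clamp(np.asarray(w, dtype=float) + config.eta * (np.asarray(x_post) - config.alpha),
                  config.w_min)


class OnlineBurstDetector:
    """Causal per-neuron burst detection with the 16 ms ISI criterion.

    A spike emits a burst event iff its ISI to the previous spike is below the
    threshold and the previous spike was not already part of the same burst
    (first-ISI convention: a 3-spike burst emits exactly one event, at its
    second spike — the earliest causally possible report).
    """

    def __init__(self, n: int, isi_threshold: float = BURST_ISI_MS):
        self.isi_threshold = isi_threshold
        self.last_spike = np.full(n, -np.inf)
        self.in_burst = np.zeros(n, dtype=bool)

    def update(self, spike_flags: np.ndarray, t: float) -> np.ndarray:
        """Feed this step's spike flags at time ``t`` (ms); returns burst-event flags."""
        events = np.zeros_like(spike_flags, dtype=bool)
        idx = np.flatnonzero(spike_flags)
        short = (t - self.last_spike[idx]) < self.isi_threshold
        events[idx[short & ~self.in_burst[idx]]] = True
        self.in_burst[idx] = short
        self.last_spike[idx] = t
        return events


def detect_calcium_events(
    V_d: np.ndarray,
    dt: float,
    threshold: float = CA_THRESHOLD_MV,
    merge_ms: float = CA_MERGE_MS,
) -> np.ndarray:
    """Event times (ms) of dendritic calcium spikes in a sampled V_d trace.

    One event per upward crossing of the threshold; crossings within
    ``merge_ms`` of the previous event are merged (a plateau is one event).
    The first sample already above threshold counts as a crossing.
    """
    V_d = np.asarray(V_d, dtype=float)
    above = V_d >= threshold
    crossings = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    times = []
    last = -np.inf
    for k in crossings:
        t = k * dt
        if t - last >= merge_ms:
            times.append(t)
            last = t
    return np.asarray(times)
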