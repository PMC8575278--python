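"""Single-timestep dynamics of the three neuron classes.

Pyramidal cells (PCs) are two-compartment generalised leaky integrate-and-fire
neurons: a somatic compartment with spike-triggered adaptation and a dendritic
compartment with a sigmoidal voltage nonlinearity that regeneratively produces
calcium-spike plateaus.  Somatic spikes back-propagate into the dendrite as a
delayed rectangular current pulse (BAP); the coincidence of a BAP with dendritic
depolarisation triggers a plateau and a somatic burst (BAC firing).

PV interneurons are plain leaky integrate-and-fire units; SOM interneurons add a
spike-triggered adaptation current, reflecting the firing-rate adaptation of
Martinotti cells.

All quantities use mV / ms / pA / pF / nS, so current divided by capacitance is
mV/ms, and pF/nS is ms.  Integration is forward Euler; the contract timestep is
0.1 ms.  These functions are the vectorised reference implementations; the
engine runs a numba kernel with identical semantics (cross-checked in tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PCParams",
    "PCState",
    "InterneuronParams",
    "InterneuronState",
    "PV_PARAMS",
    "SOM_PARAMS",
    "dendritic_nonlinearity",
    "step_pc",
    "step_interneuron",
]


class InvalidStateError(RuntimeError):
    """Raised when a membrane state variable becomes non-finite."""


@dataclass(frozen=True)
class PCParams:
    """Two-compartment PC constants.

    Defaults are the published parameter set for the soma/dendrite model.
    ``somatic_adaptation_enabled=False`` together with ``a_w_d=-28`` is the
    variant used for the noise-free recurrent network, where somatic adaptation
    is removed to permit short ISIs and the dendritic adaptation is strengthened
    to keep bursts short.
    """

    tau_s: float = 16.0        # somatic membrane time constant (ms)
    C_s: float = 370.0         # somatic capacitance (pF)
    g_s: float = 1300.0        # dendrite->soma coupling current scale (pA)
    b_w_s: float = -200.0      # somatic adaptation increment per spike (pA)
    tau_w_s: float = 100.0     # somatic adaptation time constant (ms)
    E_L: float = -70.0         # resting / reset potential (mV)
    tau_d: float = 7.0         # dendritic membrane time constant (ms)
    C_d: float = 170.0         # dendritic capacitance (pF)
    g_d: float = 1200.0        # dendritic regenerative current scale (pA)
    c_d: float = 2600.0        # BAP pulse amplitude into the dendrite (pA)
    tau_w_d: float = 30.0      # dendritic adaptation time constant (ms)
    a_w_d: float = -13.0       # dendritic subthreshold adaptation strength (nS)
    E_d: float = -38.0         # half-activation of the dendritic nonlinearity (mV)
    D_m: float = 6.0           # slope of the dendritic nonlinearity (mV)
    V_T: float = -50.0         # somatic spike threshold (mV)
    t_refrac: float = 3.0      # absolute refractory period (ms)
    bap_delay: float = 0.5     # BAP onset delay after the somatic spike (ms)
    bap_duration: float = 2.0  # BAP pulse duration (ms)
    somatic_adaptation_enabled: bool = True

    def __post_init__(self) -> None:
        for name in ("tau_s", "C_s", "tau_w_s", "tau_d", "C_d", "tau_w_d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.D_m <= 0:
            raise ValueError("D_m must be strictly positive")
        if self.V_T <= self.E_L:
            raise ValueError("V_T must exceed E_L")

    def no_adaptation_variant(self) -> "PCParams":
        """The recurrent-network variant: no somatic adaptation, a_w_d = -28 nS."""
        return replace(self, somatic_adaptation_enabled=False, a_w_d=-28.0)


@dataclass
class PCState:
    """Per-neuron PC state vectors.

    ``bap_remaining`` counts down the active BAP pulse (ms) per pending window;
    windows are stored as (time-to-onset, count) pairs in ``bap_queue`` — the
    reference implementation keeps an explicit list per neuron so overlapping
    pulses from the no-adaptation variant superpose linearly.
    """

    V_s: np.ndarray
    V_d: np.ndarray
    w_s: np.ndarray
    w_d: np.ndarray
    refrac_remaining: np.ndarray
    bap_queue: list = field(default_factory=list)  # per neuron: list of [onset_in, offset_in] (ms from now)

    @classmethod
    def zeros(cls, n: int, params: PCParams) -> "PCState":
        return cls(
            V_s=np.full(n, params.E_L),
            V_d=np.full(n, params.E_L),
            w_s=np.zeros(n),
            w_d=np.zeros(n),
            refrac_remaining=np.zeros(n),
            bap_queue=[[] for _ in range(n)],
        )

    @property
    def n(self) -> int:
        return self.V_s.shape[0]


@dataclass(frozen=True)
class InterneuronParams:
    """Leaky integrate-and-fire interneuron constants; adaptation for SOM only."""

    tau_m: float
    C_m: float
    E_L: float = -70.0
    V_T: float = -50.0
    t_refrac: float = 3.0
    b_w: float = 0.0       # adaptation increment per spike (pA); 0 disables
    tau_w: float = 100.0   # adaptation time constant (ms)

    def __post_init__(self) -> None:
        if self.tau_m <= 0 or self.C_m <= 0 or self.tau_w <= 0:
            raise ValueError("time constants and capacitance must be positive")


PV_PARAMS = InterneuronParams(tau_m=10.0, C_m=100.0)
SOM_PARAMS = InterneuronParams(tau_m=20.0, C_m=100.0, b_w=-150.0, tau_w=100.0)


@dataclass
class InterneuronState:
    V: np.ndarray
    w: np.ndarray
    refrac_remaining: np.ndarray

    @classmethod
    def zeros(cls, n: int, params: InterneuronParams) -> "InterneuronState":
        return cls(
            V=np.full(n, params.E_L),
            w=np.zeros(n),
            refrac_remaining=np.zeros(n),
        )


def dendritic_nonlinearity(V_d, E_d: float, D_m: float):
    """Sigmoidal activation f(V) = 1 / (1 + exp(-(V - E_d)/D_m)) in (0, 1).

    Models the regenerative calcium-channel activation of the apical dendrite:
    near-zero below threshold, saturating above, with slope set by ``D_m``.
    """
    if D_m <= 0:
        raise ValueError("D_m must be strictly positive")
    V_d = np.asarray(V_d, dtype=float)
    if not np.all(np.isfinite(V_d)):
        raise InvalidStateError("non-finite dendritic potential")
    # expit-style stable evaluation
    x = (V_d - E_d) / D_m
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def _check_finite(state: PCState | InterneuronState) -> None:
    arrays = (
        (state.V_s, state.V_d, state.w_s, state.w_d)
        if isinstance(state, PCState)
        else (state.V, state.w)
    )
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise InvalidStateError("non-finite membrane state")


def step_pc(state: PCState, params: PCParams, I_s, I_d, dt: float):
    """One forward-Euler step of the PC population; mutates ``state``.

    ``I_s`` and ``I_d`` are the *total* somatic and dendritic input currents
    (external + background + synaptic), excluding the internally generated
    dendro-somatic coupling, BAP and adaptation currents, which this function
    adds itself.

    Returns the boolean spike flags for this step.  A spike resets V_s to E_L,
    clamps the soma for ``t_refrac`` (the dendrite keeps integrating), schedules
    a BAP window of amplitude ``c_d`` on [t+bap_delay, t+bap_delay+bap_duration),
    and — if enabled — increments the somatic adaptation current by ``b_w_s``.
    V_d is never reset.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    _check_finite(state)
    p = params
    I_s = np.broadcast_to(np.asarray(I_s, dtype=float), state.V_s.shape)
    I_d = np.broadcast_to(np.asarray(I_d, dtype=float), state.V_s.shape)

    f = dendritic_nonlinearity(state.V_d, p.E_d, p.D_m)

    # active BAP windows: onset passed, offset not yet
    bap_on = np.zeros(state.n)
    half = 0.5 * dt  # epsilon against float drift of the decremented clocks
    for i, queue in enumerate(state.bap_queue):
        for onset, offset in queue:
            if onset < half and offset > half:
                bap_on[i] += 1.0

    # half-step threshold guards against float drift of the decremented clock
    refractory = state.refrac_remaining > half

    dV_s = -(state.V_s - p.E_L) / p.tau_s + (p.g_s * f + I_s + state.w_s) / p.C_s
    dV_d = (
        -(state.V_d - p.E_L) / p.tau_d
        + (p.g_d * f + p.c_d * bap_on + I_d + state.w_d) / p.C_d
    )
    dw_s = -state.w_s / p.tau_w_s
    dw_d = (-state.w_d + p.a_w_d * (state.V_d - p.E_L)) / p.tau_w_d

    state.V_s = np.where(refractory, p.E_L, state.V_s + dt * dV_s)
    state.V_d = state.V_d + dt * dV_d
    state.w_s = state.w_s + dt * dw_s
    state.w_d = state.w_d + dt * dw_d

    spikes = (state.V_s >= p.V_T) & ~refractory
    state.V_s[spikes] = p.E_L
    state.refrac_remaining = np.maximum(state.refrac_remaining - dt, 0.0)
    state.refrac_remaining[spikes] = p.t_refrac
    if p.somatic_adaptation_enabled:
        state.w_s[spikes] += p.b_w_s

    # advance BAP clocks, enqueue new windows
    for i, queue in enumerate(state.bap_queue):
        state.bap_queue[i] = [
            [onset - dt, offset - dt] for onset, offset in queue if offset - dt > half
        ]
        if spikes[i]:
            # stored pre-decremented so a window becomes active on the step
            # whose start time is >= spike time + bap_delay
            state.bap_queue[i].append(
                [p.bap_delay - dt, p.bap_delay + p.bap_duration - dt]
            )
    return spikes


def step_interneuron(state: InterneuronState, params: InterneuronParams, I, dt: float):
    """One forward-Euler step of an interneuron population; mutates ``state``.

    SOM spikes increment the adaptation current ``w`` by ``b_w`` (a negative,
    hyperpolarising quantity that is added to the input current); PV has
    ``b_w = 0`` and so no adaptation.  Returns spike flags.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    _check_finite(state)
    p = params
    I = np.broadcast_to(np.asarray(I, dtype=float), state.V.shape)

    refractory = state.refrac_remaining > 0.5 * dt
    dV = -(state.V - p.E_L) / p.tau_m + (I + state.w) / p.C_m
    state.V = np.where(refractory, p.E_L, state.V + dt * dV)
    state.w = state.w + dt * (-state.w / p.tau_w)

    spikes = (state.V >= p.V_T) & ~refractory
    state.V[spikes] = p.E_L
    state.refrac_remaining = np.maximum(state.refrac_remaining - dt, 0.0)
    state.refrac_remaining[spikes] = p.t_refrac
    if p.b_w != 0.0:
        state.w[spikes] += p.b_w
    return spikes
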