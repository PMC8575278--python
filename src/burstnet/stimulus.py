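"""External input generation: constant drives, Ornstein-Uhlenbeck background
noise, and anti-phase square-pulse protocols.

The OU background current relaxes to its mean mu with correlation time tau_OU
(default 2 ms) and has stationary standard deviation sigma; the Euler-Maruyama
update uses the sqrt(2*dt/tau) scaling so sigma is the stationary s.d. at any
timestep.  Each neuron and compartment gets an independent stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OUParams", "OUProcess", "PulseProtocol", "ou_step", "pulse_value",
           "total_input"]


@dataclass(frozen=True)
class OUParams:
    mu: float = 0.0        # mean current (pA)
    sigma: float = 0.0     # stationary standard deviation (pA)
    tau_ou: float = 2.0    # correlation time (ms)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_ou <= 0:
            raise ValueError("tau_ou must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


def ou_step(I_bg, params: OUParams, dt: float, rng: np.random.Generator):
    """One Euler-Maruyama update: I += dt*(mu-I)/tau + sigma*sqrt(2*dt/tau)*N(0,1)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    I_bg = np.asarray(I_bg, dtype=float)
    drift = dt * (params.mu - I_bg) / params.tau_ou
    if params.sigma == 0.0:
        return I_bg + drift
    noise = params.sigma * np.sqrt(2.0 * dt / params.tau_ou) * rng.standard_normal(I_bg.shape)
    return I_bg + drift + noise


class OUProcess:
    """Stateful per-neuron OU stream, started at the stationary mean."""

    def __init__(self, n: int, params: OUParams):
        self.params = params
        self.rng = np.random.default_rng(params.seed)
        self.I = np.full(n, params.mu)

    def step(self, dt: float) -> np.ndarray:
        self.I = ou_step(self.I, self.params, dt, self.rng)
        return self.I


@dataclass(frozen=True)
class PulseProtocol:
    """Anti-phase square wave for the two compartments.

    The somatic channel sits at ``high`` during the first half-period after
    ``onset`` and at ``low`` during the second; the dendritic channel is the
    opposite ("alternating and opposite").  ``period`` is the full cycle (ms),
    so each phase lasts period/2.
    """

    high: float              # pA
    low: float               # pA
    period: float = 200.0    # ms (100 ms per phase)
    phase: str = "soma_leading"   # soma_leading | dendrite_leading
    onset: float = 0.0       # ms

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.phase not in ("soma_leading", "dendrite_leading"):
            raise ValueError("phase must be soma_leading or dendrite_leading")


def pulse_value(t, proto: PulseProtocol):
    """Square-wave level at time ``t`` (ms) for this protocol's channel.

    Before ``onset`` the level is ``low``.  Vectorised over ``t``.
    """
    t = np.asarray(t, dtype=float)
    in_first_half = np.mod(t - proto.onset, proto.period) < proto.period / 2.0
    if proto.phase == "dendrite_leading":
        in_first_half = ~in_first_half
    out = np.where((t >= proto.onset) & in_first_half, proto.high, proto.low)
    return float(out) if out.ndim == 0 else out


def total_input(ext, bg, syn):
    """Total current per compartment: external + background + synaptic (pA)."""
    out = np.asarray(ext, dtype=float) + np.asarray(bg) + np.asarray(syn)
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite input current")
    return float(out) if out.ndim == 0 else out
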