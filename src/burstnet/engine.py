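"""Scenario configuration, presets and the time-stepped simulation loop.

``run_scenario`` binds neurons, synapses, plasticity and stimuli into a single
Euler loop (contract timestep 0.1 ms) executed chunk-by-chunk by the numba
kernel, so the Python layer can monitor weight convergence between chunks and
switch recording on for the measurement window.  Update order within a step:
filter/trace decay, spike delivery (one-step delay), input assembly, neuron
stepping, event detection, plasticity (pre events before post events), then
recording — deterministic for a given seed.

Presets mirror the four published network configurations at a configurable
scale factor:

* ``fig1`` — feedforward burst control: externally driven PCs and SOMs, plastic
  SOM->dendrite synapses under the burst rule.
* ``fig2`` — dual control: adds externally driven PVs with the spike-pair rule
  on PV->soma.
* ``fig3`` — fully recurrent, noise-free microcircuit (somatic adaptation off,
  stronger dendritic adaptation); all inhibitory pathways plastic, dendritic
  rule driven by local calcium events.
* ``fig4`` — recurrent multiplexing circuit with weaker excitatory weights and
  anti-phase pulse inputs.
* ``s1`` / ``s2`` — feedforward variants with the voltage-based and the
  rate-only dendritic rule.

Scaled-down presets shrink population sizes but preserve each pathway's
full-scale in-degree (current-based weights are absolute, so the in-degree —
not the connection probability — sets the input statistics).  Fully connected
presets stay fully connected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import _kernels
from .model_core import PCParams, PV_PARAMS, SOM_PARAMS
from .network import build_connectivity, TAU_EXC_MS, TAU_INH_MS
from .plasticity import (
    PlasticityConfig, TAU_STDP_MS, BURST_ISI_MS, CA_THRESHOLD_MV, CA_MERGE_MS,
)
from .stimulus import PulseProtocol, pulse_value

__all__ = [
    "InputSpec", "PathwaySpec", "ScenarioConfig", "RunResult",
    "run_scenario", "convergence_monitor", "preset", "PRESET_NAMES",
]

_RULE_CODE = {"vogels_spike": 1, "burst_algorithmic": 2, "burst_voltage": 3,
              "rate_only": 4}
# which postsynaptic trace each rule consumes when the post side is a PC
_PC_POST_TRACE = {"vogels_spike": 0, "burst_algorithmic": 1, "burst_voltage": 2,
                  "rate_only": 1}


@dataclass(frozen=True)
class InputSpec:
    """External drive to one population/compartment: constant or pulse, plus
    OU background noise of standard deviation ``sigma`` (pA)."""

    ext: float = 0.0
    sigma: float = 0.0
    pulse: PulseProtocol | None = None

    def trace(self, t_ms: np.ndarray) -> np.ndarray:
        base = np.full(t_ms.shape, float(self.ext))
        if self.pulse is not None:
            base = base + pulse_value(t_ms, self.pulse)
        return base


@dataclass(frozen=True)
class PathwaySpec:
    """One synaptic pathway.  ``pre`` in {pc, som, pv}; ``post`` in
    {pc_soma, pc_dend, som, pv}.  ``p`` is the connection probability;
    ``in_degree`` overrides K = round(p*N_pre) for scale-preserving presets."""

    pre: str
    post: str
    w_init: float
    p: float = 1.0
    in_degree: int | None = None
    plasticity: PlasticityConfig | None = None
    exclude_autapses: bool = False
    # explicit wiring/weights (e.g. to continue from a learned state); both
    # must be (N_post, K) arrays and override the random construction
    adjacency: object = None
    weights: object = None


@dataclass
class ScenarioConfig:
    n_pc: int
    n_som: int = 0
    n_pv: int = 0
    pc_params: PCParams = field(default_factory=PCParams)
    inputs: dict = field(default_factory=dict)   # keys: pc_soma, pc_dend, som, pv
    pathways: list = field(default_factory=list)
    dt: float = 0.1                  # ms
    duration_s: float = 100.0        # learning-phase cap (s)
    measure_s: float = 50.0          # recorded measurement window (s)
    seed: int = 0
    convergence_tol: float = 0.05    # relative mean-weight change per window
    convergence_window_s: float = 20.0
    stop_on_convergence: bool = True
    chunk_s: float = 10.0
    record_max_rate_hz: float = 120.0   # per-neuron capacity bound for spike buffers
    n_current_sample: int = 25       # PCs with recorded net input currents
    current_every_ms: float = 1.0
    weight_sample_ms: float = 500.0
    init_jitter: bool = True         # draw V in [E_L, V_T] per neuron at t=0
    name: str = "custom"

    def validate(self) -> None:
        if self.n_pc <= 0:
            raise ValueError("need at least one PC")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        sizes = {"pc": self.n_pc, "som": self.n_som, "pv": self.n_pv}
        for pw in self.pathways:
            if sizes.get(pw.pre, 0) <= 0:
                raise ValueError(f"pathway {pw.pre}->{pw.post}: empty presynaptic population")
        taus = {pw.plasticity.tau_stdp for pw in self.pathways if pw.plasticity}
        if len(taus) > 1:
            raise ValueError("all plastic pathways must share tau_STDP")


@dataclass
class RunResult:
    spikes: pd.DataFrame             # population, neuron_id, time_s (measurement window)
    ca_events: pd.DataFrame          # neuron_id, time_s (PC dendritic calcium events)
    burst_events: pd.DataFrame       # neuron_id, time_s (online detector, diagnostics)
    weight_traj: pd.DataFrame        # time_s, pathway, mean_w_pA
    currents: dict                   # {"time_s", "soma", "dend"} sampled net inputs
    converged: bool
    learn_end_s: float
    duration_s: float
    manifest: dict
    final_weights: dict              # pathway name -> (N_post, K) array
    adjacency: dict = None           # pathway name -> (N_post, K) pre indices


def convergence_monitor(times_s, mean_w, window_s: float, tol: float):
    """Plateau detection on a population-mean weight trajectory.

    Converged when the relative change of the window-averaged mean weight
    between the two most recent non-overlapping windows is below ``tol``.
    Returns (converged, stats dict).
    """
    times_s = np.asarray(times_s, dtype=float)
    mean_w = np.asarray(mean_w, dtype=float)
    if times_s.size == 0 or times_s[-1] - times_s[0] < 2 * window_s:
        return False, {"reason": "trajectory shorter than two windows"}
    t1 = times_s[-1]
    cur = mean_w[(times_s > t1 - window_s)]
    prev = mean_w[(times_s > t1 - 2 * window_s) & (times_s <= t1 - window_s)]
    if cur.size == 0 or prev.size == 0:
        return False, {"reason": "empty window"}
    m_cur, m_prev = cur.mean(), prev.mean()
    denom = max(abs(m_prev), 1e-12)
    rel = abs(m_cur - m_prev) / denom
    return bool(rel < tol), {"rel_change": float(rel), "plateau_mean_pA": float(m_cur)}


def _pathway_arrays(config: ScenarioConfig, rng: np.random.Generator):
    """Build the flat synapse-group arrays the kernel consumes."""
    sizes = {"pc": config.n_pc, "som": config.n_som, "pv": config.n_pv}
    # interneuron population is SOM (offset 0) then PV (offset n_som)
    in_offset = {"som": 0, "pv": config.n_som}

    meta = {k: [] for k in
            ("pre_is_pc", "post_comp", "sign", "dec", "plast", "post_trace",
             "eta", "alpha", "rate_interval_steps", "K", "pre_lo", "post_lo")}
    names, adjacencies, weights = [], [], []
    syn_post_parts, syn_pre_parts = [], []
    pre_ptr_parts, pre_sid_parts = [], []
    syn_off = [0]
    pre_ptr_off = [0]
    filt_off = []
    filt_sizes = 0

    for pw in config.pathways:
        n_pre = sizes[pw.pre]
        n_post = sizes["pc"] if pw.post.startswith("pc") else sizes[pw.post]
        if pw.adjacency is not None:
            adj = np.asarray(pw.adjacency, dtype=np.int64)
        else:
            adj = build_connectivity(
                n_pre, n_post, pw.p, exclude_autapses=pw.exclude_autapses,
                seed=rng, in_degree=pw.in_degree,
            )
        k = adj.shape[1]
        if pw.weights is not None:
            w = np.array(pw.weights, dtype=float)
            if w.shape != adj.shape:
                raise ValueError("explicit weights must match adjacency shape")
        else:
            w = np.full((n_post, k), float(pw.w_init))
        sign = +1 if pw.pre == "pc" else -1
        tau = TAU_EXC_MS if sign > 0 else TAU_INH_MS

        names.append(f"{pw.pre}->{pw.post}")
        adjacencies.append(adj)
        weights.append(w)
        meta["pre_is_pc"].append(1 if pw.pre == "pc" else 0)
        meta["post_comp"].append({"pc_soma": 0, "pc_dend": 1}.get(pw.post, 2))
        meta["sign"].append(float(sign))
        meta["dec"].append(np.exp(-config.dt / tau))
        pl = pw.plasticity
        meta["plast"].append(0 if pl is None else _RULE_CODE[pl.rule])
        if pl is None:
            meta["post_trace"].append(0)
            meta["eta"].append(0.0)
            meta["alpha"].append(0.0)
            meta["rate_interval_steps"].append(1)
        else:
            if pw.post.startswith("pc"):
                meta["post_trace"].append(_PC_POST_TRACE[pl.rule])
            else:
                meta["post_trace"].append(3)
            meta["eta"].append(pl.eta)
            meta["alpha"].append(pl.alpha)
            meta["rate_interval_steps"].append(
                max(int(round(pl.update_interval / config.dt)), 1))
        meta["K"].append(k)
        meta["pre_lo"].append(0 if pw.pre == "pc" else in_offset[pw.pre])
        meta["post_lo"].append(0 if pw.post.startswith("pc") else in_offset[pw.post])

        # synapse ids contiguous by post; local pre indices
        syn_pre_parts.append(adj.ravel().astype(np.int64))
        syn_post_parts.append(np.repeat(np.arange(n_post, dtype=np.int64), k))
        base = syn_off[-1]
        order = np.argsort(adj.ravel(), kind="stable")
        ptr = np.zeros(n_pre + 1, dtype=np.int64)
        np.cumsum(np.bincount(adj.ravel(), minlength=n_pre), out=ptr[1:])
        pre_sid_parts.append(order.astype(np.int64) + base)
        pre_ptr_parts.append(ptr + base)  # global indices into concatenated pre_sid
        syn_off.append(base + n_post * k)
        pre_ptr_off.append(pre_ptr_off[-1] + n_pre + 1)
        filt_off.append(filt_sizes)
        filt_sizes += n_post

    G = len(config.pathways)
    arrays = dict(
        names=names,
        adjacencies=adjacencies,
        pre_is_pc=np.array(meta["pre_is_pc"], dtype=np.int8),
        post_comp=np.array(meta["post_comp"], dtype=np.int8),
        sign=np.array(meta["sign"], dtype=np.float64),
        dec=np.array(meta["dec"], dtype=np.float64),
        plast=np.array(meta["plast"], dtype=np.int8),
        post_trace=np.array(meta["post_trace"], dtype=np.int8),
        eta=np.array(meta["eta"], dtype=np.float64),
        alpha=np.array(meta["alpha"], dtype=np.float64),
        rate_interval_steps=np.array(meta["rate_interval_steps"], dtype=np.int64),
        K=np.array(meta["K"], dtype=np.int64),
        pre_lo=np.array(meta["pre_lo"], dtype=np.int64),
        post_lo=np.array(meta["post_lo"], dtype=np.int64),
        syn_off=np.array(syn_off, dtype=np.int64),
        syn_post=(np.concatenate(syn_post_parts) if G else np.empty(0, dtype=np.int64)),
        syn_pre=(np.concatenate(syn_pre_parts) if G else np.empty(0, dtype=np.int64)),
        syn_w=(np.concatenate([w.ravel() for w in weights]).astype(np.float64)
               if G else np.empty(0)),
        pre_ptr=(np.concatenate(pre_ptr_parts) if G else np.empty(0, dtype=np.int64)),
        pre_ptr_off=np.array(pre_ptr_off, dtype=np.int64),
        pre_sid=(np.concatenate(pre_sid_parts) if G else np.empty(0, dtype=np.int64)),
        filt=np.zeros(filt_sizes),
        filt_off=np.array(filt_off, dtype=np.int64),
    )
    return arrays


def _pack_pc_params(p: PCParams) -> np.ndarray:
    return np.array([
        p.tau_s, p.C_s, p.g_s, p.b_w_s, p.tau_w_s, p.E_L, p.tau_d, p.C_d,
        p.g_d, p.c_d, p.tau_w_d, p.a_w_d, p.E_d, p.D_m, p.V_T,
        1.0 if p.somatic_adaptation_enabled else 0.0,
    ])


def run_scenario(config: ScenarioConfig) -> RunResult:
    """Run learning (until convergence or the duration cap), then a recorded
    measurement window; returns spike tables, weight trajectories and sampled
    net input currents."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    dt = config.dt
    p = config.pc_params
    n_pc, n_som, n_pv = config.n_pc, config.n_som, config.n_pv
    n_in = n_som + n_pv

    ga = _pathway_arrays(config, rng)

    # initial conditions: membrane potentials jittered in [E_L, V_T] to avoid
    # artificial first-step synchrony (adaptation variables start at 0)
    if config.init_jitter:
        Vs = rng.uniform(p.E_L, p.V_T, n_pc)
        Vd = rng.uniform(p.E_L, p.V_T, n_pc)
    else:
        Vs = np.full(n_pc, p.E_L)
        Vd = np.full(n_pc, p.E_L)
    ws_a = np.zeros(n_pc)
    wd_a = np.zeros(n_pc)
    refrac_pc = np.zeros(n_pc, dtype=np.int64)
    bap_on_steps = int(round(p.bap_delay / dt))
    bap_dur_steps = int(round(p.bap_duration / dt))
    L = bap_on_steps + bap_dur_steps + 2
    ring_on = np.zeros((L, n_pc), dtype=np.int64)
    ring_off = np.zeros((L, n_pc), dtype=np.int64)
    bap_count = np.zeros(n_pc, dtype=np.int64)

    som_p, pv_p = SOM_PARAMS, PV_PARAMS
    tau_m_in = np.concatenate([np.full(n_som, som_p.tau_m), np.full(n_pv, pv_p.tau_m)])
    C_m_in = np.concatenate([np.full(n_som, som_p.C_m), np.full(n_pv, pv_p.C_m)])
    b_w_in = np.concatenate([np.full(n_som, som_p.b_w), np.full(n_pv, pv_p.b_w)])
    tau_w_in = np.concatenate([np.full(n_som, som_p.tau_w), np.full(n_pv, pv_p.tau_w)])
    if n_in:
        V_in = (rng.uniform(som_p.E_L, som_p.V_T, n_in) if config.init_jitter
                else np.full(n_in, som_p.E_L))
    else:
        V_in = np.empty(0)
    w_in = np.zeros(n_in)
    refrac_in = np.zeros(n_in, dtype=np.int64)

    tr_spk_pc = np.zeros(n_pc)
    tr_spk_in = np.zeros(n_in)
    tr_burst_pc = np.zeros(n_pc)
    tr_ca_pc = np.zeros(n_pc)
    last_spike_pc = np.full(n_pc, -1e18)
    in_burst_pc = np.zeros(n_pc, dtype=np.bool_)
    prev_above_pc = np.zeros(n_pc, dtype=np.bool_)
    last_ca_pc = np.full(n_pc, -1e18)

    inputs = {k: config.inputs.get(k, InputSpec()) for k in ("pc_soma", "pc_dend", "som", "pv")}
    sigma_in = np.concatenate([
        np.full(n_som, inputs["som"].sigma), np.full(n_pv, inputs["pv"].sigma)
    ])
    ext_in = np.concatenate([
        np.full(n_som, inputs["som"].ext), np.full(n_pv, inputs["pv"].ext)
    ])
    bg_s = np.zeros(n_pc)
    bg_d = np.zeros(n_pc)
    bg_in = np.zeros(n_in)

    # recording buffers (measurement window only)
    cap_pc = int(config.record_max_rate_hz * n_pc * config.measure_s) + 1000
    cap_in = int(config.record_max_rate_hz * max(n_in, 1) * config.measure_s) + 1000
    # calcium events are capped at one per merge window (100 Hz)
    cap_ev = int(min(100.0, config.record_max_rate_hz) * n_pc * config.measure_s) + 1000
    pc_si = np.empty(cap_pc, dtype=np.int64); pc_st = np.empty(cap_pc)
    in_si = np.empty(cap_in, dtype=np.int64); in_st = np.empty(cap_in)
    ca_ri = np.empty(cap_ev, dtype=np.int64); ca_rt = np.empty(cap_ev)
    bu_ri = np.empty(cap_ev, dtype=np.int64); bu_rt = np.empty(cap_ev)
    rec_counts = np.zeros(4, dtype=np.int64)

    cur_every = max(int(round(config.current_every_ms / dt)), 1)
    n_cur_sample = min(config.n_current_sample, n_pc)
    n_cur_t = int(config.measure_s * 1000.0 / config.current_every_ms) + 4
    cur_s_rec = np.zeros((n_cur_t, n_cur_sample))
    cur_d_rec = np.zeros((n_cur_t, n_cur_sample))

    wmean_every = max(int(round(config.weight_sample_ms / dt)), 1)
    total_cap_s = config.duration_s + config.measure_s
    n_w_t = int(total_cap_s * 1000.0 / config.weight_sample_ms) + 8
    G = len(config.pathways)
    wmean_out = np.zeros((n_w_t, G))

    tau_stdp = TAU_STDP_MS
    for pw in config.pathways:
        if pw.plasticity is not None:
            tau_stdp = pw.plasticity.tau_stdp
            break

    ppc = _pack_pc_params(p)
    refrac_steps_pc = int(round(p.t_refrac / dt))
    refrac_steps_in = int(round(som_p.t_refrac / dt))

    # noise-column layout: somatic PC block, dendritic PC block, interneurons
    sig_s, sig_d = inputs["pc_soma"].sigma, inputs["pc_dend"].sigma
    noise_off_d = n_pc if sig_s > 0 else 0
    noise_off_in = noise_off_d + (n_pc if sig_d > 0 else 0)
    n_noise = noise_off_in + (n_in if np.any(sigma_in > 0) else 0)

    chunk_steps = int(round(config.chunk_s * 1000.0 / dt))
    if n_noise:
        # keep the pre-drawn deviate buffer around ~40 MB
        chunk_steps = min(chunk_steps, max(int(5_000_000 / n_noise), 1000))
    step0 = 0
    cur_pos = 0
    wmean_pos = 0
    converged = False
    learn_end_s = None

    def _call(n_steps, record, chunk_seed):
        nonlocal step0, cur_pos, wmean_pos
        t0_ms = step0 * dt
        t_grid = t0_ms + np.arange(n_steps) * dt
        ext_s = inputs["pc_soma"].trace(t_grid)
        ext_d = inputs["pc_dend"].trace(t_grid)
        if n_noise:
            # SFC64: fastest numpy bit generator; whitening only, no
            # statistical structure needed beyond i.i.d. normals
            gen = np.random.Generator(np.random.SFC64(chunk_seed))
            noise = gen.standard_normal((n_steps, n_noise))
        else:
            noise = np.zeros((1, 1))
        status, cur_pos, wmean_pos = _kernels.simulate_chunk(
            n_steps, dt, t0_ms, step0,
            ppc, refrac_steps_pc, bap_on_steps, bap_dur_steps,
            Vs, Vd, ws_a, wd_a, refrac_pc, ring_on, ring_off, bap_count,
            tau_m_in, C_m_in, b_w_in, tau_w_in, refrac_steps_in,
            som_p.E_L, som_p.V_T, V_in, w_in, refrac_in,
            tau_stdp, tr_spk_pc, tr_spk_in, tr_burst_pc, tr_ca_pc,
            BURST_ISI_MS, last_spike_pc, in_burst_pc,
            CA_THRESHOLD_MV, CA_MERGE_MS, prev_above_pc, last_ca_pc,
            ext_s, ext_d, ext_in,
            sig_s, sig_d, sigma_in, 2.0,
            bg_s, bg_d, bg_in, noise, noise_off_d, noise_off_in,
            ga["pre_is_pc"], ga["post_comp"], ga["sign"], ga["dec"],
            ga["plast"], ga["post_trace"], ga["eta"], ga["alpha"],
            ga["rate_interval_steps"], ga["K"], ga["syn_off"],
            ga["syn_post"], ga["syn_pre"], ga["syn_w"],
            ga["pre_ptr"], ga["pre_ptr_off"], ga["pre_sid"],
            ga["filt"], ga["filt_off"], ga["pre_lo"], ga["post_lo"],
            record, rec_counts,
            pc_si, pc_st, in_si, in_st, ca_ri, ca_rt, bu_ri, bu_rt,
            cur_every, cur_pos, cur_s_rec, cur_d_rec,
            wmean_every, wmean_pos, wmean_out,
        )
        step0 += n_steps
        if status == _kernels.STATUS_DIVERGED:
            raise RuntimeError(
                f"simulation diverged at t={step0 * dt / 1000.0:.2f} s "
                f"(max |V_s|={np.nanmax(np.abs(Vs)):.1f} mV); "
                "state dump: " + json.dumps({
                    "t_s": step0 * dt / 1000.0,
                    "mean_w": {n: float(np.mean(w)) for n, w in
                               zip(ga["names"], _split_weights(ga))},
                })
            )
        if status == _kernels.STATUS_OVERFLOW:
            raise RuntimeError("spike-record buffer overflow; raise record_max_rate_hz")

    # --- learning phase ---
    learn_steps_cap = int(round(config.duration_s * 1000.0 / dt))
    seed_seq = np.random.SeedSequence(config.seed)
    chunk_seeds = iter(seed_seq.generate_state(10_000) % (2**31 - 1))
    while step0 < learn_steps_cap:
        n = min(chunk_steps, learn_steps_cap - step0)
        _call(n, 0, int(next(chunk_seeds)))
        if config.stop_on_convergence and G > 0 and any(ga["plast"] > 0):
            t_w = np.arange(wmean_pos) * config.weight_sample_ms / 1000.0
            oks = []
            for g in range(G):
                if ga["plast"][g] == 0:
                    continue
                ok, _ = convergence_monitor(
                    t_w, wmean_out[:wmean_pos, g],
                    config.convergence_window_s, config.convergence_tol)
                oks.append(ok)
            if oks and all(oks):
                converged = True
                break
    learn_end_s = step0 * dt / 1000.0

    # --- measurement phase ---
    measure_steps = int(round(config.measure_s * 1000.0 / dt))
    done = 0
    while done < measure_steps:
        n = min(chunk_steps, measure_steps - done)
        _call(n, 1, int(next(chunk_seeds)))
        done += n

    # assemble outputs
    n1, n2, n3, n4 = rec_counts
    pop = np.empty(n1 + n2, dtype=object)
    pop[:n1] = "pc"
    in_pop = np.where(in_si[:n2] < n_som, "som", "pv")
    pop[n1:] = in_pop
    nid = np.concatenate([pc_si[:n1], np.where(in_si[:n2] < n_som, in_si[:n2],
                                               in_si[:n2] - n_som)])
    t_all = np.concatenate([pc_st[:n1], in_st[:n2]]) / 1000.0
    spikes = pd.DataFrame({"population": pop, "neuron_id": nid, "time_s": t_all})
    spikes = spikes.sort_values(["population", "neuron_id", "time_s"],
                                kind="stable").reset_index(drop=True)

    ca_events = pd.DataFrame({"neuron_id": ca_ri[:n3], "time_s": ca_rt[:n3] / 1000.0})
    burst_events = pd.DataFrame({"neuron_id": bu_ri[:n4], "time_s": bu_rt[:n4] / 1000.0})

    t_w = np.arange(wmean_pos) * config.weight_sample_ms / 1000.0
    traj_frames = [
        pd.DataFrame({"time_s": t_w, "pathway": ga["names"][g],
                      "mean_w_pA": wmean_out[:wmean_pos, g]})
        for g in range(G)
    ]
    weight_traj = (pd.concat(traj_frames, ignore_index=True) if traj_frames
                   else pd.DataFrame(columns=["time_s", "pathway", "mean_w_pA"]))

    cur_t = learn_end_s + np.arange(cur_pos) * config.current_every_ms / 1000.0
    currents = {"time_s": cur_t, "soma": cur_s_rec[:cur_pos],
                "dend": cur_d_rec[:cur_pos]}

    manifest = {
        "name": config.name,
        "seed": config.seed,
        "dt_ms": dt,
        "n_pc": n_pc, "n_som": n_som, "n_pv": n_pv,
        "pathways": [
            {"name": ga["names"][g], "K": int(ga["K"][g]),
             "plastic": bool(ga["plast"][g] > 0),
             "mean_w_final_pA": float(np.mean(w))}
            for g, w in enumerate(_split_weights(ga))
        ],
        "inputs": {k: {"ext": v.ext, "sigma": v.sigma,
                       "pulse": None if v.pulse is None else asdict(v.pulse)}
                   for k, v in inputs.items()},
        "learn_end_s": learn_end_s,
        "converged": converged,
        "duration_s": learn_end_s + config.measure_s,
    }

    final_weights = {ga["names"][g]: w for g, w in enumerate(_split_weights(ga))}
    return RunResult(
        spikes=spikes, ca_events=ca_events, burst_events=burst_events,
        weight_traj=weight_traj, currents=currents, converged=converged,
        learn_end_s=learn_end_s, duration_s=learn_end_s + config.measure_s,
        manifest=manifest, final_weights=final_weights,
        adjacency={ga["names"][g]: ga["adjacencies"][g] for g in range(G)},
    )


def _split_weights(ga) -> list[np.ndarray]:
    out = []
    for g in range(len(ga["names"])):
        lo, hi = ga["syn_off"][g], ga["syn_off"][g + 1]
        k = ga["K"][g]
        out.append(ga["syn_w"][lo:hi].reshape(-1, k))
    return out


# ---------------------------------------------------------------------------
# presets

PRESET_NAMES = ("fig1", "fig2", "fig3", "fig4", "s1", "s2")

# full-scale in-degrees of the sparse recurrent circuits (p=0.02)
_K_FROM_PC = 160
_K_FROM_IN = 40


def preset(
    name: str,
    scale: float = 1.0,
    seed: int = 0,
    duration_s: float | None = None,
    measure_s: float | None = None,
    **overrides,
) -> ScenarioConfig:
    """Build a published network configuration at the given scale factor.

    ``overrides`` replace individual ``ScenarioConfig`` fields; input levels
    can be changed afterwards by editing ``config.inputs``.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")

    def _n(full):
        return max(int(round(full * scale)), 1)

    # Fully connected presets keep p=1 when scaled, so each PC receives
    # scale-times fewer inhibitory synapses.  Both the initial weight and the
    # learning rate are scaled by 1/scale so that the total initial inhibition
    # and the total weight drift per postsynaptic neuron (K*eta) match the
    # full-size circuit; the plastic equilibrium weight scales the same way.
    w_inh_init = 10.0 / scale
    eta_scale = 1.0 / scale

    if name in ("fig1", "s1", "s2"):
        rule = {"fig1": PlasticityConfig(rule="burst_algorithmic", eta=0.1 * eta_scale, rho_0=1.0),
                "s1": PlasticityConfig(rule="burst_voltage", eta=0.1 * eta_scale, alpha=0.05),
                "s2": PlasticityConfig(rule="rate_only", eta=0.1 * eta_scale, rho_0=1.0)}[name]
        cfg = ScenarioConfig(
            n_pc=_n(1600), n_som=_n(400),
            inputs={
                "pc_soma": InputSpec(ext=500.0, sigma=100.0),
                "pc_dend": InputSpec(ext=650.0, sigma=100.0),
                "som": InputSpec(ext=90.0, sigma=400.0),
            },
            pathways=[PathwaySpec(pre="som", post="pc_dend", w_init=w_inh_init,
                                  p=1.0, plasticity=rule)],
            duration_s=400.0, measure_s=50.0, seed=seed, name=name,
        )
    elif name == "fig2":
        cfg = ScenarioConfig(
            n_pc=_n(1600), n_som=_n(400), n_pv=_n(400),
            inputs={
                "pc_soma": InputSpec(ext=1100.0, sigma=100.0),
                "pc_dend": InputSpec(ext=650.0, sigma=100.0),
                "som": InputSpec(ext=90.0, sigma=400.0),
                "pv": InputSpec(ext=-45.0, sigma=400.0),
            },
            pathways=[
                PathwaySpec(pre="som", post="pc_dend", w_init=w_inh_init, p=1.0,
                            plasticity=PlasticityConfig(rule="burst_algorithmic",
                                                        eta=0.1 * eta_scale, rho_0=1.0)),
                PathwaySpec(pre="pv", post="pc_soma", w_init=w_inh_init, p=1.0,
                            plasticity=PlasticityConfig(rule="vogels_spike",
                                                        eta=0.01 * eta_scale, rho_0=10.0)),
            ],
            duration_s=400.0, measure_s=50.0, seed=seed, name=name,
        )
    elif name == "fig3":
        cfg = ScenarioConfig(
            n_pc=_n(8000), n_som=_n(2000), n_pv=_n(2000),
            pc_params=PCParams().no_adaptation_variant(),
            inputs={
                "pc_soma": InputSpec(ext=1500.0),
                "pc_dend": InputSpec(ext=500.0),
                "som": InputSpec(ext=0.0),
                "pv": InputSpec(ext=200.0),
            },
            pathways=[
                PathwaySpec(pre="pc", post="pc_soma", w_init=25.0,
                            p=0.02, in_degree=_K_FROM_PC),
                PathwaySpec(pre="pc", post="som", w_init=25.0,
                            p=0.02, in_degree=_K_FROM_PC),
                PathwaySpec(pre="pc", post="pv", w_init=25.0,
                            p=0.02, in_degree=_K_FROM_PC),
                PathwaySpec(pre="som", post="pc_dend", w_init=0.1,
                            p=0.02, in_degree=_K_FROM_IN,
                            plasticity=PlasticityConfig(rule="burst_voltage",
                                                        eta=1.0, alpha=0.03)),
                PathwaySpec(pre="pv", post="pc_soma", w_init=0.1,
                            p=0.02, in_degree=_K_FROM_IN,
                            plasticity=PlasticityConfig(rule="vogels_spike",
                                                        eta=0.1, rho_0=10.0)),
                PathwaySpec(pre="pv", post="pv", w_init=0.1,
                            p=0.02, in_degree=_K_FROM_IN, exclude_autapses=True,
                            plasticity=PlasticityConfig(rule="vogels_spike",
                                                        eta=0.05, rho_0=10.0)),
            ],
            duration_s=400.0, measure_s=100.0, seed=seed, name=name,
        )
    else:  # fig4
        # 200 ms per phase: long enough that the ~10-15 ms plateau/burst
        # registration lag costs little decoding correlation (the pulse
        # amplitudes are model constants; the duration is a free default)
        pulse_s = PulseProtocol(high=800.0, low=500.0, period=400.0,
                                phase="soma_leading")
        pulse_d = PulseProtocol(high=105.0, low=-480.0, period=400.0,
                                phase="dendrite_leading")
        cfg = ScenarioConfig(
            n_pc=_n(8000), n_som=_n(2000), n_pv=_n(2000),
            inputs={
                # constant background raised by 900 pA with pulses superimposed;
                # both interneuron classes get the 200 pA noise-free drive (with
                # the weak 4 pA PC->SOM weights the SOMs are silent without it
                # and the dendritic control loop disappears)
                "pc_soma": InputSpec(ext=900.0, pulse=pulse_s),
                "pc_dend": InputSpec(ext=900.0, pulse=pulse_d),
                "som": InputSpec(ext=200.0),
                "pv": InputSpec(ext=200.0),
            },
            pathways=[
                PathwaySpec(pre="pc", post="pc_soma", w_init=13.0,
                            p=0.02, in_degree=_K_FROM_PC),
                PathwaySpec(pre="pc", post="som", w_init=4.0,
                            p=0.02, in_degree=_K_FROM_PC),
                PathwaySpec(pre="pc", post="pv", w_init=15.0,
                            p=0.02, in_degree=_K_FROM_PC),
                PathwaySpec(pre="som", post="pc_dend", w_init=0.1,
                            p=0.02, in_degree=_K_FROM_IN,
                            plasticity=PlasticityConfig(rule="burst_algorithmic",
                                                        eta=1.0, rho_0=1.0)),
                PathwaySpec(pre="pv", post="pc_soma", w_init=0.1,
                            p=0.02, in_degree=_K_FROM_IN,
                            plasticity=PlasticityConfig(rule="vogels_spike",
                                                        eta=0.1, rho_0=10.0)),
                PathwaySpec(pre="pv", post="pv", w_init=0.1,
                            p=0.02, in_degree=_K_FROM_IN, exclude_autapses=True,
                            plasticity=PlasticityConfig(rule="vogels_spike",
                                                        eta=0.05, rho_0=10.0)),
            ],
            duration_s=400.0, measure_s=60.0, seed=seed, name=name,
        )

    if duration_s is not None:
        cfg.duration_s = duration_s
    if measure_s is not None:
        cfg.measure_s = measure_s
    for key, val in overrides.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown ScenarioConfig field {key!r}")
        setattr(cfg, key, val)
    # keep in-degrees feasible at very small scales
    sizes = {"pc": cfg.n_pc, "som": cfg.n_som, "pv": cfg.n_pv}
    for pw in cfg.pathways:
        if pw.in_degree is not None:
            cap = sizes[pw.pre] - (1 if pw.exclude_autapses else 0)
            if pw.in_degree > cap:
                object.__setattr__(pw, "in_degree", cap)
    return cfg
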