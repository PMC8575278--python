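# Methods

## Model

`burstnet` simulates current-based spiking microcircuits built from three cell
classes.

**Pyramidal cells (PCs)** are two-compartment generalised leaky
integrate-and-fire neurons. The somatic potential `V_s` integrates a leak
toward `E_L = -70 mV` (time constant `τ_s = 16 ms`), the external/synaptic
current, a spike-triggered adaptation current `w_s` (increment
`b_w^s = -200 pA` per spike, decay `τ_w^s = 100 ms`), and a coupling current
`g_s·f(V_d)` from the dendrite. Crossing `V_T = -50 mV` emits a spike, resets
`V_s` to `E_L`, and clamps the soma for the 3 ms absolute refractory period
(the dendrite keeps integrating). The dendritic potential `V_d` has its own
leak (`τ_d = 7 ms`), a regenerative current `g_d·f(V_d)` with

    f(V) = 1 / (1 + exp(-(V - E_d)/D_m)),     E_d = -38 mV, D_m = 6 mV,

a subthreshold adaptation current `w_d` (`dw_d/dt = (-w_d + a_w^d (V_d -
E_L))/τ_w^d`, `a_w^d = -13 nS`, `τ_w^d = 30 ms`), and a back-propagating
action potential (BAP): every somatic spike injects a rectangular current
pulse of amplitude `c_d = 2600 pA` into the dendrite, 2 ms long, delayed by
0.5 ms. The coincidence of a BAP with sufficient dendritic depolarisation
ignites the sigmoidal nonlinearity — a calcium-spike plateau — which in turn
drives a somatic burst (BAC firing). `V_d` is never reset; plateaus are
terminated by the dendritic adaptation.

A variant used for the noise-free recurrent circuit disables the somatic
adaptation (to permit short inter-spike intervals) and strengthens the
dendritic adaptation to `a_w^d = -28 nS` to keep bursts short.

**Interneurons** are single-compartment integrate-and-fire units: PV cells
(`τ = 10 ms`, `C = 100 pF`, no adaptation) and SOM cells (`τ = 20 ms`, spike-
triggered adaptation `b_w = -150 pA`, `τ_w = 100 ms`, giving the
characteristic rate adaptation of Martinotti cells). The spike threshold,
reset and 3 ms refractory period are shared with the PC soma; the source
model does not state interneuron thresholds separately, so the somatic values
are reused.

**Synapses** are current-based and exponential: a presynaptic spike adds the
weight `w_ij` (pA) instantaneously to a per-target filter that decays with
`τ = 5 ms` (excitatory) or `10 ms` (inhibitory). Spikes produced at step `t`
enter the filters at the end of step `t` and first contribute — undecayed —
to the currents of step `t+1`; there are no further conduction delays.
Wiring is homogeneous fixed in-degree: every postsynaptic cell draws exactly
`K = round(p·N_pre)` partners without replacement (autapses excluded for
PV→PV). Weights are magnitudes with the sign carried by the pathway.

**Inputs** per compartment are `I = I_ext + I_bg + I_syn`, with `I_bg` an
Ornstein–Uhlenbeck process (`τ_OU = 2 ms`, mean 0) discretised as
`I += dt (μ - I)/τ + σ √(2 dt/τ) ξ`, so `σ` is the stationary standard
deviation at any `dt`. Each neuron and compartment has an independent stream.
Square-pulse protocols drive the two compartments in anti-phase; the pulse
amplitudes are model constants while the period (400 ms full cycle, 200 ms
per phase) is a configuration default, since only the amplitudes are printed
in the source description; the phase length is chosen long relative to the
~10-15 ms latency with which a dendritic plateau registers as a burst, which
mainly benefits the event-rate channel of the decoder.

## Inhibitory plasticity

All rules share exponentially decaying per-neuron traces
(`τ_STDP = 20 ms`; on an event `x → x + 1`, the increment applied before the
weight update that consumes the same event). Weights are floored at 0 pA.

* **Spike-pair rule** (PV→soma, PV→PV): on a presynaptic spike
  `w += η (x_post − α)`; on a postsynaptic spike `w += η x_pre` with
  `α = 2 ρ₀ τ_STDP`. Under independent pre/post activity the weight drift
  vanishes exactly when the postsynaptic rate equals `ρ₀`.
* **Burst rule, algorithmic** (SOM→dendrite): identical ledger, but the
  postsynaptic trace is driven by *burst events*. A causal online detector
  emits one event per burst at the first spike whose ISI to the previous
  spike is below 16 ms (first-ISI convention: a three-spike burst counts
  once); `α = 2 ρ₀ τ_STDP` with `ρ₀` a target *burst* rate.
* **Burst rule, voltage-based**: the postsynaptic events are dendritic
  calcium spikes — upward crossings of `V_d` through −20 mV (a near-step
  sigmoid with `D_m = 0.01 mV`), merged within 10 ms so one plateau is one
  event. Here `α` has no closed-form relation to the burst rate and is
  calibrated empirically (below).
* **Rate-only rule**: every 50 ms, `w += η (x_post − α)` with
  `α = ρ₀ τ_STDP` and no presynaptic factor.

When a presynaptic spike and a postsynaptic event fall into the same 0.1 ms
step, presynaptic updates are processed first; orderings differ by `η α` per
exact coincidence, which is negligible at the simulated rates.

## Integration and determinism

Forward Euler at `dt = 0.1 ms` is the contract integrator (finer steps are
used only as test oracles; halving `dt` changes single-neuron spike counts by
under 2 %, and a 100× finer integration by under 1 %). The engine executes
the loop in a numba kernel with a fixed within-step order (input assembly,
neuron update, event detection, plasticity pre-then-post, spike delivery), so
runs are bit-reproducible for a given seed; a test verifies the kernel
against the vectorised reference implementations step for step on a
noise-free circuit. Initial membrane potentials are jittered uniformly in
`[E_L, V_T]` (adaptation variables start at 0) to avoid artificial first-step
synchrony; OU deviates are pre-drawn per chunk from a PCG64 stream derived
from the run seed.

Divergence (non-finite state, or potentials outside a generous physical
envelope) aborts a run with a diagnostic dump. Membrane potentials are
bounded above by the threshold/reset mechanism but not below, so only the
lower bound is informative.

## Desk-scale experiment conditions

The published circuits use up to 8000 PCs; the packaged experiment suite
(`burstnet.experiments`) runs them at 1/8–1/4 scale with the following
scale-preserving choices, which are the package's reference conditions:

* **Sparse recurrent circuits** (connection probability 0.02): population
  sizes shrink but each pathway keeps its full-scale in-degree (160 from PCs,
  40 from each interneuron class). Current-based weights are absolute, so
  the in-degree — not the probability — sets the mean input.
* **Fully connected circuits**: connectivity stays all-to-all, and both the
  initial inhibitory weight (10 pA at full scale) and the learning rate are
  multiplied by 1/scale, preserving the total initial inhibition and the
  total weight drift per postsynaptic neuron (`K·η`). The plastic
  equilibrium weight scales the same way.
* **Learning rates** of the recurrent circuit are raised (×3 on the two
  spike-pair pathways, ×2 on the dendritic rule) so that every experiment
  converges within a few hundred simulated seconds — following the original
  practice of maximising learning rates to shorten simulated time. The
  homeostatic fixed point is set by `α`, not by `η`.
* **Durations**: learning runs 300–650 s of simulated time per condition with
  measurement windows of 20–100 s, sizes chosen so the full suite completes
  on a single CPU in well under half an hour.

The voltage-based rule's depression factor was calibrated with
`experiments.calibrate_voltage_alpha` — sweep `α`, run to convergence,
interpolate the monotone `α → burst rate` relation — on the scaled recurrent
circuit: `α = 0.053` for a 1 Hz and `α = 0.096` for a 1.5 Hz burst target
(the full-scale circuit needs smaller values, 0.03/0.045, because the
relation is circuit-specific; this is why it is defined empirically).

## Analysis definitions

A **burst** is a maximal run of spikes whose consecutive ISIs are all below
16 ms; the run ends at the first ISI ≥ 16 ms, and the burst time is its first
spike. **Events** are singlet spikes plus burst-first spikes. For the
no-somatic-adaptation circuit, a candidate burst must additionally be
confirmed by a dendritic calcium event within [first spike − 5 ms, last
spike + 5 ms], because short ISIs can occur there without a dendritic
plateau. Interval CVs use the population (uncorrected) standard deviation;
population averages pool per-neuron CVs over neurons with at least two
intervals. Population rates divide bin counts by `N × bin`; optional
smoothing uses a unit-area rectangular window (10 ms for decoding, none for
the irregularity analysis). The multiplexed decoder compares the somatic
input with the event rate and the dendritic input with the burst fraction
(burst rate / event rate, undefined bins masked) by Pearson correlation on
the smoothed traces, and displays them after an affine least-squares
rescaling (which cannot change |r|).

## What the synthetic fixtures do and do not show

`fixtures_io.generate_labeled_trains` produces renewal event trains with
ground-truth labels: gaps of at least 16 ms between event groups so labels
are unambiguous by construction, bursts injected per event with a configurable
size distribution at 8 ms intra-burst ISI, and the exponential gap mean
adjusted so the nominal event rate is exact. These fixtures validate the
segmentation and rate estimators independently of the simulator; they do not
reproduce rate fluctuations, cross-neuron correlations or the calcium
verification pathway of real simulated data — those are exercised by the
engine-level tests.

## Known limitations

* Finite-size biases: at 1/8–1/4 scale each inhibitory synapse carries a
  larger share of the total inhibition, and the pre/post correlations that
  the pair-rule fixed-point argument neglects shift the converged rates a few
  per cent above their targets (e.g. ~10.9 Hz for a 10 Hz target at 1/4
  scale). The bias shrinks roughly with 1/K toward the published full-scale
  behaviour.
* The burst-fraction channel of the multiplexed decoder responds to a square
  dendritic pulse with an adaptation transient (overshoot, then decay driven
  by the dendritic subthreshold adaptation and delayed SOM feedback) rather
  than a square plateau, and carries per-bin burst shot noise at the 10 ms
  smoothing. This caps its Pearson correlation with the input at roughly
  0.7–0.75 in the desk-scale circuit, invariant to network scale (1/8 vs
  1/4), learning time and pulse period; the event-rate channel is not
  affected. Decoding quality should therefore be read as "restored and
  strongly informative", not as near-perfect reconstruction.
* The convergence monitor compares successive window means of the
  population-mean weight; very slow approaches (relative change below
  tolerance while still drifting) can be declared converged early, so the
  experiment suite uses fixed learning durations sized from the observed
  weight trajectories instead of early stopping.
* Conductance-based synapses, synaptic delays, short-term plasticity,
  SOM↔PV connections and stimulus tuning are out of scope; excitatory
  synapses are static throughout.
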