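# burstnet

Cortical layer-5 pyramidal cells fire occasional **bursts** — short volleys of
spikes driven by dendritic calcium plateaus — and in vivo they do so rarely
but consistently. Because the plateau mechanism is threshold-like, that
sparse-bursting regime is fragile: a little more dendritic drive converts
every spike into a burst, a little less abolishes bursts entirely. `burstnet`
is a spiking-network simulator for studying how **homeostatic inhibitory
plasticity** solves this tuning problem. It implements:

* two-compartment pyramidal-cell models (soma + apical dendrite) with a
  sigmoidal dendritic nonlinearity, back-propagating action potentials and
  BAC firing;
* PV-like (fast, non-adapting) and SOM-like (adapting, dendrite-targeting)
  interneurons with current-based exponential synapses and fixed in-degree
  random wiring;
* four inhibitory plasticity rules: the symmetric spike-pair homeostatic rule
  with depression factor `α = 2ρ₀τ_STDP`, its burst-timing analogue (the
  postsynaptic trace counts bursts instead of spikes), a local voltage-based
  variant driven by dendritic calcium events, and a spike-timing-independent
  simplification;
* the burst/event analysis suite — 16 ms ISI segmentation with optional
  calcium verification, inter-event/inter-burst interval CVs, population
  rates, net-current statistics — and the multiplexed decoder that reads the
  somatic input from the population **event rate** and the dendritic input
  from the **burst fraction**.

The plasticity rules drive the circuit into a *doubly asynchronous irregular*
state in which both events and bursts occur irregularly at controlled rates,
and that state is what makes the multiplexed event/burst code work without
fine-tuning.

For whom: computational neuroscientists who want a compact, fast (numba),
deterministic test bed for burst-rate homeostasis and multiplexed coding, at
desk scale rather than cluster scale.

## Worked example

Feedforward burst homeostasis: a population of noise-driven PCs receives
strong dendritic drive (650 pA); plastic SOM→dendrite synapses, governed by
the burst-timing rule with a 1 Hz target, pull the population burst rate from
its initially saturated level down to the target.

```python
import burstnet
from burstnet import experiments

m = experiments.burst_homeostasis(seed=0)
print(f"firing {m['firing_hz']:.2f} Hz  burst {m['burst_hz']:.3f} Hz")
print(f"mean SOM->dend weight "
      f"{m['result'].final_weights['som->pc_dend'].mean():.1f} pA")
```

prints

```
firing 9.21 Hz  burst 1.101 Hz
mean SOM->dend weight 60.4 pA
```

The burst rate sits at the 1 Hz target (not at the ~3 Hz it would reach with
the 40 pA initial weights) because the inhibitory weights grew until bursts
became as rare as the rule demands; the firing rate is left free in this
configuration. The same machinery is available from the shell:

```bash
burstnet run --preset fig1 --scale 0.25 --seed 0 --duration 300 --out runs/demo
burstnet analyze --spikes runs/demo/spikes.csv
```

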