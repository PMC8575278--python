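"""Synthetic spike-train fixtures, spike-table IO and scenario-file handling.

``generate_labeled_trains`` builds spike trains with known ground-truth
event/burst structure — a renewal event process whose inter-event gaps are
kept at or above the 16 ms burst threshold, with each event independently
expanded into a short high-frequency burst — so the analysis segmentation can
be tested without running the simulator.

Spike tables are CSV with columns (population, neuron_id, time_s); times on
disk are seconds, written with enough digits to round-trip the 0.1 ms grid.
Scenario files are YAML: either ``preset: fig1`` plus overrides, or a fully
explicit configuration.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .analysis import BurstLabels, classify_spikes
from .engine import (InputSpec, PathwaySpec, ScenarioConfig, preset,
                     PRESET_NAMES)
from .model_core import PCParams
from .plasticity import PlasticityConfig
from .stimulus import PulseProtocol

__all__ = ["FixtureSpec", "generate_labeled_trains", "write_spike_table",
           "read_spike_table", "load_scenario"]

_GAP_S = 0.016  # minimum separation keeping ground-truth labels unambiguous


@dataclass(frozen=True)
class FixtureSpec:
    event_rate: float = 10.0        # Hz
    burst_prob: float = 0.1         # probability an event is a burst
    spikes_per_burst: tuple = ((2, 0.5), (3, 0.35), (4, 0.15))  # (size, prob)
    intra_burst_isi: float = 8.0    # ms, must be < 16
    duration: float = 10.0          # s
    n_neurons: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.burst_prob <= 1:
            raise ValueError("burst_prob must be in [0, 1]")
        if self.intra_burst_isi >= 16.0 or self.intra_burst_isi <= 0:
            raise ValueError("intra-burst ISI must be in (0, 16) ms")
        sizes, probs = zip(*self.spikes_per_burst)
        if any(s < 2 for s in sizes) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("burst sizes must be >= 2 spikes with probabilities summing to 1")

    @property
    def mean_burst_span_s(self) -> float:
        return self.burst_prob * sum(
            p * (s - 1) for s, p in self.spikes_per_burst
        ) * self.intra_burst_isi / 1000.0


def generate_labeled_trains(spec: FixtureSpec) -> list[tuple[np.ndarray, BurstLabels]]:
    """Spike trains with ground-truth segmentation, one per neuron.

    The gap from the last spike of one event group to the next event is
    16 ms + Exp(lam), with the exponential mean chosen so the expected event
    rate equals ``spec.event_rate`` exactly (the mean cycle length is
    mean burst span + 16 ms + 1/lam = 1/rate).  Returns a list of
    (spike_times, BurstLabels) pairs; labels come from the same segmentation
    contract as ``classify_spikes`` and are guaranteed unambiguous by
    construction.
    """
    mean_cycle = 1.0 / spec.event_rate
    exp_mean = mean_cycle - _GAP_S - spec.mean_burst_span_s
    if exp_mean <= 0:
        raise ValueError(
            f"event rate {spec.event_rate} Hz infeasible with >= 16 ms gaps")
    rng = np.random.default_rng(spec.seed)
    sizes = np.array([s for s, _ in spec.spikes_per_burst])
    probs = np.array([p for _, p in spec.spikes_per_burst])
    isi_s = spec.intra_burst_isi / 1000.0

    out = []
    for _ in range(spec.n_neurons):
        spikes = []
        t = rng.exponential(exp_mean)
        while t < spec.duration:
            if rng.random() < spec.burst_prob:
                n = rng.choice(sizes, p=probs)
                group = t + isi_s * np.arange(n)
            else:
                group = np.array([t])
            if group[-1] >= spec.duration:
                break
            spikes.append(group)
            t = group[-1] + _GAP_S + rng.exponential(exp_mean)
        times = np.concatenate(spikes) if spikes else np.empty(0)
        out.append((times, classify_spikes(times)))
    return out


def write_spike_table(path, record: pd.DataFrame) -> None:
    """Write a (population, neuron_id, time_s) table; rows sorted by time."""
    cols = ["population", "neuron_id", "time_s"]
    missing = [c for c in cols if c not in record.columns]
    if missing:
        raise ValueError(f"spike table missing columns: {missing}")
    df = record[cols].sort_values("time_s", kind="stable")
    df.to_csv(path, index=False, float_format="%.9g")


def read_spike_table(path) -> pd.DataFrame:
    """Read a spike table, asserting sortedness by time."""
    try:
        df = pd.read_csv(
            path,
            dtype={"population": str, "neuron_id": np.int64, "time_s": float},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed spike table {path}: {exc}") from exc
    missing = [c for c in ("population", "neuron_id", "time_s") if c not in df.columns]
    if missing:
        raise ValueError(f"spike table {path} missing columns: {missing}")
    if not df["time_s"].is_monotonic_increasing:
        raise ValueError(f"spike table {path} is not sorted by time")
    return df


# ---------------------------------------------------------------------------
# scenario files

_INPUT_KEYS = ("pc_soma", "pc_dend", "som", "pv")


def _input_from_dict(d: dict) -> InputSpec:
    pulse = d.get("pulse")
    return InputSpec(
        ext=float(d.get("ext", 0.0)),
        sigma=float(d.get("sigma", 0.0)),
        pulse=None if pulse is None else PulseProtocol(**pulse),
    )


def _pathway_from_dict(d: dict) -> PathwaySpec:
    pl = d.get("plasticity")
    return PathwaySpec(
        pre=d["pre"], post=d["post"], w_init=float(d["w_init"]),
        p=float(d.get("p", 1.0)),
        in_degree=d.get("in_degree"),
        exclude_autapses=bool(d.get("exclude_autapses", False)),
        plasticity=None if pl is None else PlasticityConfig(**pl),
    )


def load_scenario(path_or_stream) -> ScenarioConfig:
    """Load a YAML scenario file into a fully resolved ``ScenarioConfig``.

    Either ``preset: <name>`` (with optional ``scale``, ``seed`` and scalar
    field overrides) or an explicit configuration with ``n_pc``, ``inputs``
    and ``pathways``.  Unknown keys are rejected; all validation violations
    are reported together.
    """
    if isinstance(path_or_stream, (str, bytes)) or hasattr(path_or_stream, "read"):
        if hasattr(path_or_stream, "read"):
            raw = yaml.safe_load(path_or_stream)
        else:
            with open(path_or_stream) as fh:
                raw = yaml.safe_load(fh)
    elif isinstance(path_or_stream, io.IOBase):
        raw = yaml.safe_load(path_or_stream)
    else:
        raise TypeError("expected a path or stream")
    if not isinstance(raw, dict):
        raise ValueError("scenario file must be a mapping")

    errors = []
    if "preset" in raw:
        name = raw.pop("preset")
        if name not in PRESET_NAMES:
            raise ValueError(f"unknown preset {name!r}")
        scale = float(raw.pop("scale", 1.0))
        seed = int(raw.pop("seed", 0))
        inputs_over = raw.pop("inputs", None)
        cfg = preset(name, scale=scale, seed=seed)
        for key, val in raw.items():
            if not hasattr(cfg, key):
                errors.append(f"unknown key {key!r}")
                continue
            setattr(cfg, key, val)
        if inputs_over:
            for k, v in inputs_over.items():
                if k not in _INPUT_KEYS:
                    errors.append(f"unknown input target {k!r}")
                    continue
                cfg.inputs[k] = _input_from_dict(v)
    else:
        known = {f for f in ScenarioConfig.__dataclass_fields__}
        bad = set(raw) - known
        errors.extend(f"unknown key {k!r}" for k in sorted(bad))
        kwargs = {k: v for k, v in raw.items() if k in known
                  and k not in ("inputs", "pathways", "pc_params")}
        inputs = {}
        for k, v in (raw.get("inputs") or {}).items():
            if k not in _INPUT_KEYS:
                errors.append(f"unknown input target {k!r}")
            else:
                inputs[k] = _input_from_dict(v)
        pathways = [_pathway_from_dict(d) for d in (raw.get("pathways") or [])]
        pc_kwargs = raw.get("pc_params") or {}
        try:
            pc_params = PCParams(**pc_kwargs)
        except (TypeError, ValueError) as exc:
            errors.append(str(exc))
            pc_params = PCParams()
        if errors:
            raise ValueError("invalid scenario: " + "; ".join(errors))
        cfg = ScenarioConfig(inputs=inputs, pathways=pathways,
                             pc_params=pc_params, **kwargs)
    if errors:
        raise ValueError("invalid scenario: " + "; ".join(errors))
    try:
        cfg.validate()
    except ValueError as exc:
        raise ValueError(f"invalid scenario: {exc}") from exc
    return cfg
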