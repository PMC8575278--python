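"""Spike-train analysis: burst/event segmentation, interval statistics,
population rates, net-current statistics and the multiplexed decoder.

Bursts are maximal runs of spikes whose consecutive ISIs are all below 16 ms;
the run ends at the first ISI at or above the threshold.  Events are isolated
(singlet) spikes plus the first spike of each burst — the unit of the
event-rate code.  The burst fraction (burst rate / event rate) carries the
dendritic channel of the multiplexed code; the event rate carries the somatic
channel.  Optionally a candidate burst must be confirmed by a coincident
dendritic calcium event (used when somatic adaptation is disabled, where short
ISIs can occur without a dendritic plateau).

Spike times in this module are in seconds (the on-disk unit); ISI thresholds
and bin sizes are given in ms, as in the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BurstLabels",
    "DecodeResult",
    "classify_spikes",
    "classify_record",
    "interval_cv",
    "mean_cv",
    "population_rates",
    "burst_fraction",
    "net_current_stats",
    "decode_multiplexed",
]

SINGLET, BURST_FIRST, BURST_MEMBER = 0, 1, 2
CA_MARGIN_S = 0.005  # calcium-confirmation margin around the burst span


@dataclass
class BurstLabels:
    """Segmentation of one spike train."""

    spike_times: np.ndarray   # s, sorted
    labels: np.ndarray        # per spike: SINGLET | BURST_FIRST | BURST_MEMBER
    event_times: np.ndarray   # s: singlets + first spikes of bursts
    burst_times: np.ndarray   # s: first spike of each burst
    burst_sizes: np.ndarray   # spikes per burst

    @property
    def n_events(self) -> int:
        return self.event_times.size

    @property
    def n_bursts(self) -> int:
        return self.burst_times.size

    @property
    def isi(self) -> np.ndarray:
        return np.diff(self.spike_times)

    @property
    def iei(self) -> np.ndarray:
        return np.diff(self.event_times)

    @property
    def ibi(self) -> np.ndarray:
        return np.diff(self.burst_times)


def classify_spikes(
    spike_times,
    isi_threshold_ms: float = 16.0,
    calcium_events=None,
) -> BurstLabels:
    """Segment one sorted spike train (s) into singlet events and bursts.

    With ``calcium_events`` (times in s), a candidate burst lacking a calcium
    event within [first spike - 5 ms, last spike + 5 ms] is demoted: all its
    spikes become singlet events.
    """
    t = np.asarray(spike_times, dtype=float)
    if t.ndim != 1:
        raise ValueError("spike_times must be one-dimensional")
    if t.size and (np.any(np.diff(t) < 0) or t[0] < 0):
        raise ValueError("spike times must be sorted and nonnegative")
    thr = isi_threshold_ms / 1000.0
    labels = np.full(t.size, SINGLET, dtype=np.int8)
    if t.size:
        short = np.diff(t) < thr               # ISI i-1 -> i below threshold
        in_run = np.concatenate(([False], short))       # spike continues a run
        starts_run = np.concatenate((short, [False])) & ~in_run
        labels[starts_run] = BURST_FIRST
        labels[in_run] = BURST_MEMBER

    if calcium_events is not None and t.size:
        ca = np.asarray(calcium_events, dtype=float)
        first_idx = np.flatnonzero(labels == BURST_FIRST)
        for i0 in first_idx:
            i1 = i0
            while i1 + 1 < t.size and labels[i1 + 1] == BURST_MEMBER:
                i1 += 1
            lo, hi = t[i0] - CA_MARGIN_S, t[i1] + CA_MARGIN_S
            if ca.size == 0 or not np.any((ca >= lo) & (ca <= hi)):
                labels[i0 : i1 + 1] = SINGLET

    first_idx = np.flatnonzero(labels == BURST_FIRST)
    sizes = np.empty(first_idx.size, dtype=np.int64)
    for k, i0 in enumerate(first_idx):
        i1 = i0
        while i1 + 1 < t.size and labels[i1 + 1] == BURST_MEMBER:
            i1 += 1
        sizes[k] = i1 - i0 + 1
    return BurstLabels(
        spike_times=t,
        labels=labels,
        event_times=t[labels != BURST_MEMBER],
        burst_times=t[labels == BURST_FIRST],
        burst_sizes=sizes,
    )


def classify_record(
    spikes: pd.DataFrame,
    isi_threshold_ms: float = 16.0,
    calcium_events: dict | None = None,
    n_neurons: int | None = None,
) -> dict[int, BurstLabels]:
    """Segment every neuron of a (neuron_id, time_s) spike table.

    ``calcium_events`` maps neuron_id -> calcium event times (s).  Neurons
    without spikes get empty labels when ``n_neurons`` is given.
    """
    out: dict[int, BurstLabels] = {}
    for nid, grp in spikes.groupby("neuron_id"):
        ca = None if calcium_events is None else calcium_events.get(int(nid), np.empty(0))
        out[int(nid)] = classify_spikes(
            np.sort(grp["time_s"].to_numpy()), isi_threshold_ms, calcium_events=ca
        )
    if n_neurons is not None:
        for nid in range(n_neurons):
            out.setdefault(nid, classify_spikes(np.empty(0), isi_threshold_ms))
    return out


def interval_cv(intervals) -> float:
    """Coefficient of variation: population (uncorrected) s.d. over mean.

    NaN for fewer than 2 intervals or zero mean (such neurons are excluded
    from population averages).
    """
    x = np.asarray(intervals, dtype=float)
    if x.size < 2:
        return np.nan
    m = x.mean()
    if m == 0:
        return np.nan
    return float(x.std() / m)


def mean_cv(labels: dict[int, BurstLabels], kind: str = "iei") -> float:
    """Mean per-neuron CV over neurons with at least 2 intervals.

    ``kind``: "isi", "iei" or "ibi".
    """
    cvs = [interval_cv(getattr(lab, kind)) for lab in labels.values()]
    cvs = [c for c in cvs if np.isfinite(c)]
    return float(np.mean(cvs)) if cvs else np.nan


def population_rates(
    times,
    n_neurons: int,
    duration_s: float,
    bin_ms: float = 1.0,
    smooth_ms: float | None = None,
    t0_s: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Population rate trace (Hz per neuron): counts per bin / (N * bin).

    ``times`` are event (or spike, or burst) times in s, pooled over the
    population.  Optional smoothing convolves with a unit-area rectangular
    window of ``smooth_ms``.  Returns (bin_centers_s, rate_hz).
    """
    if bin_ms <= 0 or n_neurons <= 0:
        raise ValueError("bin and population size must be positive")
    bin_s = bin_ms / 1000.0
    n_bins = max(int(round(duration_s / bin_s)), 1)
    edges = t0_s + np.arange(n_bins + 1) * bin_s
    counts, _ = np.histogram(np.asarray(times, dtype=float), bins=edges)
    rate = counts / (n_neurons * bin_s)
    if smooth_ms is not None:
        width = max(int(round(smooth_ms / bin_ms)), 1)
        kernel = np.full(width, 1.0 / width)
        rate = np.convolve(rate, kernel, mode="same")
    centers = edges[:-1] + bin_s / 2.0
    return centers, rate


def burst_fraction(event_rate: np.ndarray, burst_rate: np.ndarray) -> np.ndarray:
    """Burst rate / event rate per bin; bins without events are masked (NaN)."""
    event_rate = np.asarray(event_rate, dtype=float)
    burst_rate = np.asarray(burst_rate, dtype=float)
    out = np.full_like(event_rate, np.nan)
    ok = event_rate > 0
    out[ok] = burst_rate[ok] / event_rate[ok]
    return out


def net_current_stats(currents: np.ndarray) -> tuple[float, float]:
    """Time-and-population mean and s.d. of recorded net input currents.

    ``currents`` is (time, neurons) or 1-D; the s.d. pools over both axes.
    """
    c = np.asarray(currents, dtype=float)
    return float(c.mean()), float(c.std())


@dataclass
class DecodeResult:
    """Multiplexed-decoding summary for one analysis window."""

    event_rate: np.ndarray          # Hz
    burst_fraction: np.ndarray      # in [0, 1] (NaN where undefined)
    soma_decoded: np.ndarray        # event rate affinely rescaled onto I_s (pA)
    dend_decoded: np.ndarray        # BF affinely rescaled onto I_d (pA)
    r_soma: float                   # Pearson r (I_s, event rate)
    r_dend: float                   # Pearson r (I_d, burst fraction)


def _affine_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares a, b minimising ||a*x + b - y||^2."""
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(coef[0]), float(coef[1])


def decode_multiplexed(
    event_rate: np.ndarray,
    bf: np.ndarray,
    soma_input: np.ndarray,
    dend_input: np.ndarray,
) -> DecodeResult:
    """Decode the two input channels from the event rate and burst fraction.

    The event rate is affinely rescaled onto the somatic input and the burst
    fraction onto the dendritic input (least squares); Pearson r per channel is
    computed between the true input and the unscaled trace (rescaling cannot
    change |r|).  Bins where the burst fraction is undefined are dropped from
    the dendritic channel.  A constant trace has undefined correlation,
    reported as NaN.
    """
    event_rate = np.asarray(event_rate, dtype=float)
    bf = np.asarray(bf, dtype=float)
    soma_input = np.asarray(soma_input, dtype=float)
    dend_input = np.asarray(dend_input, dtype=float)

    def _pearson(a, b):
        if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
            return np.nan
        return float(stats.pearsonr(a, b)[0])

    r_soma = _pearson(soma_input, event_rate)
    ok = np.isfinite(bf)
    r_dend = _pearson(dend_input[ok], bf[ok])

    a_s, b_s = _affine_fit(event_rate, soma_input)
    soma_dec = a_s * event_rate + b_s
    dend_dec = np.full_like(bf, np.nan)
    if ok.any():
        a_d, b_d = _affine_fit(bf[ok], dend_input[ok])
        dend_dec[ok] = a_d * bf[ok] + b_d
    return DecodeResult(
        event_rate=event_rate,
        burst_fraction=bf,
        soma_decoded=soma_dec,
        dend_decoded=dend_dec,
        r_soma=r_soma,
        r_dend=r_dend,
    )
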