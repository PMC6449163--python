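"""Spike detection and per-spike / per-train feature extraction.

Spikes are counted at a -20 mV detection level (upward crossing followed by
a local maximum).  Per-spike waveform features follow the dV/dt-criterion
convention: threshold is the membrane potential where the first derivative
first exceeds 20 mV/ms; amplitude is peak minus rest; the fast
afterhyperpolarization (fAHP) is located as the second zero-crossing of
dV/dt after threshold, accepted only within 1.5 ms of the spike peak.
The derivative estimator is a central difference over one sample step.

Spike-frequency accommodation (SFA) is the ratio of the sixth interspike
interval to the first (requires at least seven spikes).  The reciprocal
(first-to-sixth) convention also appears in the literature and is exposed
via ``train_features(..., reciprocal=True)``; the default is documented,
not silently chosen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SweepSet, Trace

__all__ = [
    "APFeatures",
    "TrainFeatures",
    "FICurve",
    "detect_spikes",
    "ap_waveform_features",
    "train_features",
    "fi_curve",
    "select_trains",
    "count_spikes_in_step",
]


@dataclass(frozen=True)
class APFeatures:
    """Single-spike waveform metrics (all voltages mV, times ms)."""

    peak_time: float
    threshold: float
    max_dvdt: float  # mV/ms
    amplitude: float  # peak minus rest
    fahp: float | None  # threshold minus trough; positive = trough below threshold
    fahp_time: float | None


@dataclass(frozen=True)
class TrainFeatures:
    spike_times: tuple
    isis: tuple
    sfa: float | None
    count: int


@dataclass(frozen=True)
class FICurve:
    amplitudes: tuple  # pA
    counts: tuple  # spikes within the step window


class FeatureExtractionError(ValueError):
    """A per-spike feature could not be measured."""


def _dvdt(v: np.ndarray, dt: float) -> np.ndarray:
    """Central-difference first derivative, mV/ms (one-sided at the ends)."""
    return np.gradient(v, dt)


def detect_spikes(
    trace: Trace, level: float = -20.0, min_isi: float = 2.0
) -> list[float]:
    """Times (ms) of local maxima following upward crossings of ``level``.

    Peaks closer together than ``min_isi`` are merged (the earlier, and if
    equal-voltage the first, peak is kept), which prevents double counting
    on noisy repolarizations.
    """
    trace.require_unit("mV")
    v = trace.samples
    above = v >= level
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    times: list[float] = []
    for c in crossings:
        # supra-level excursion runs until v falls back below level
        end = c
        while end < v.size and v[end] >= level:
            end += 1
        peak_idx = c + int(np.argmax(v[c:end]))
        t = trace.t0 + peak_idx * trace.dt
        if times and t - times[-1] < min_isi:
            continue
        times.append(t)
    return times


def ap_waveform_features(
    trace: Trace,
    peak_time: float,
    rmp: float,
    dvdt_criterion: float = 20.0,
    fahp_window: float = 1.5,
    level: float = -20.0,
    search_back: float = 3.0,
) -> APFeatures:
    """Waveform features for one detected spike.

    Threshold search scans forward from ``search_back`` ms before the
    detection-level crossing for the first sample where the central
    difference dV/dt meets ``dvdt_criterion``.  The fAHP trough is the
    second zero-crossing of dV/dt after threshold (first: rise-to-fall at
    the peak; second: fall-to-rise at the trough) and is reported absent
    when it does not occur within ``fahp_window`` ms of the peak.
    """
    trace.require_unit("mV")
    v, dt = trace.samples, trace.dt
    peak_idx = trace.index_at(peak_time)
    d = _dvdt(v, dt)

    # last upward crossing of the detection level at or before the peak
    above = v >= level
    ups = np.flatnonzero(~above[:-1] & above[1:]) + 1
    ups = ups[ups <= peak_idx]
    cross_idx = int(ups[-1]) if ups.size else peak_idx
    start = max(0, cross_idx - int(round(search_back / dt)))
    thr_rel = np.flatnonzero(d[start : peak_idx + 1] >= dvdt_criterion)
    if thr_rel.size == 0:
        raise FeatureExtractionError(
            f"dV/dt never reached {dvdt_criterion} mV/ms before the spike "
            f"at {peak_time} ms"
        )
    thr_idx = start + int(thr_rel[0])
    threshold = float(v[thr_idx])
    max_dvdt = float(np.max(d[thr_idx : peak_idx + 1]))
    amplitude = float(v[peak_idx] - rmp)

    # zero crossings of dV/dt after threshold: #1 (+ -> -) at the peak,
    # #2 (- -> +) at the fAHP trough
    fahp = fahp_time = None
    seg = d[thr_idx:]
    down = np.flatnonzero((seg[:-1] > 0) & (seg[1:] <= 0))
    if down.size:
        first = int(down[0])
        up = np.flatnonzero((seg[first + 1 : -1] < 0) & (seg[first + 2 :] >= 0))
        if up.size:
            trough_idx = thr_idx + first + 1 + int(up[0]) + 1
            t_trough = trace.t0 + trough_idx * trace.dt
            if t_trough - (trace.t0 + peak_idx * dt) <= fahp_window + 1e-9:
                fahp = float(threshold - v[trough_idx])
                fahp_time = float(t_trough)
    return APFeatures(
        peak_time=trace.t0 + peak_idx * dt,
        threshold=threshold,
        max_dvdt=max_dvdt,
        amplitude=amplitude,
        fahp=fahp,
        fahp_time=fahp_time,
    )


def train_features(spike_times, reciprocal: bool = False) -> TrainFeatures:
    """Interspike intervals and accommodation ratio for one spike train.

    SFA = ISI6 / ISI1 by default (``reciprocal=True`` gives ISI1 / ISI6);
    absent when the train has fewer than 7 spikes.
    """
    times = np.asarray(list(spike_times), dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("spike_times must be strictly increasing")
    isis = np.diff(times)
    sfa = None
    if times.size >= 7:
        sfa = float(isis[5] / isis[0])
        if reciprocal:
            sfa = 1.0 / sfa
    return TrainFeatures(
        spike_times=tuple(times),
        isis=tuple(isis),
        sfa=sfa,
        count=int(times.size),
    )


def count_spikes_in_step(sweep, level: float = -20.0, min_isi: float = 2.0) -> int:
    """Number of detected spikes whose peak lies within the step epoch."""
    if sweep.epoch is None:
        raise ValueError("sweep has no step epoch")
    times = detect_spikes(sweep.voltage, level=level, min_isi=min_isi)
    on, off = sweep.epoch.onset, sweep.epoch.offset
    return sum(on <= t <= off for t in times)


def fi_curve(
    sweeps: SweepSet,
    amplitudes=tuple(range(100, 501, 50)),
    level: float = -20.0,
) -> FICurve:
    """Spike count within the step window per requested current amplitude."""
    by_amp = {}
    for sw in sweeps:
        if sw.epoch is not None:
            by_amp.setdefault(sw.epoch.amplitude, sw)
    missing = [a for a in amplitudes if a not in by_amp]
    if missing:
        raise ValueError(f"no sweeps at requested amplitudes {missing} pA")
    counts = [count_spikes_in_step(by_amp[a], level=level) for a in amplitudes]
    return FICurve(amplitudes=tuple(amplitudes), counts=tuple(counts))


def select_trains(
    sweeps: SweepSet, count_range=(8, 11), level: float = -20.0
) -> set[int]:
    """Indices of sweeps whose in-step spike count lies in ``count_range``.

    The 8-11 default picks trains from the middle of the response curve,
    where spike-shape features are comparable across cells.
    """
    lo, hi = count_range
    selected = set()
    for k, sw in enumerate(sweeps):
        if sw.epoch is None:
            continue
        if lo <= count_spikes_in_step(sw, level=level) <= hi:
            selected.add(k)
    return selected
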