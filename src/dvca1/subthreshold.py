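"""Resting potential, input resistance, and rebound slope from step families.

Input resistance is the ordinary-least-squares slope of steady-state voltage
change against injected current over the near-rest range (-70 to +10 pA by
default); a slope in mV/pA is numerically GOhm and is reported in MOhm.
Steady state is taken as the mean over the last 100 ms of the 800-ms step,
minus the mean over the last 100 ms of baseline — late-step averaging keeps
sag transients out of the estimate.  Sweeps that fired action potentials
are excluded and reported.

The rebound slope quantifies sag/rebound machinery (I_h-like currents): the
post-step rebound amplitude (peak of V minus baseline within a 400-ms
post-step window) is regressed on the membrane potential at the end of the
step (mean over the last 10 ms); a memoryless membrane gives slope 0, and
more rebound current gives a more negative slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import SweepSet, Trace
from .suprathreshold import detect_spikes

__all__ = [
    "SubthresholdFeatures",
    "resting_membrane_potential",
    "input_resistance",
    "rebound_slope",
    "extract_subthreshold",
]

STEADY_WINDOW_MS = 100.0  # late-step / late-baseline averaging window
END_OF_STEP_WINDOW_MS = 10.0  # rebound-slope abscissa window


@dataclass(frozen=True)
class SubthresholdFeatures:
    rmp: float  # mV
    input_resistance: float  # MOhm
    r_squared: float  # of the Rin fit
    rebound_slope: float  # mV/mV
    sweeps_used: tuple
    sweeps_excluded: tuple


def resting_membrane_potential(trace: Trace, baseline=(0.0, 100.0)) -> float:
    """Mean voltage (mV) over the baseline window (ms), before any step."""
    trace.require_unit("mV")
    start, stop = baseline
    if stop <= start:
        raise ValueError(f"empty baseline window {baseline}")
    return float(np.mean(trace.slice_time(start, stop)))


def _steady_state_delta(sweep) -> float:
    """Late-step mean minus late-baseline mean, mV."""
    ep = sweep.epoch
    v = sweep.voltage
    base = np.mean(v.slice_time(max(0.0, ep.onset - STEADY_WINDOW_MS), ep.onset))
    step = np.mean(v.slice_time(ep.offset - STEADY_WINDOW_MS, ep.offset))
    return float(step - base)


def _spiking_sweeps(sweeps: SweepSet, level: float) -> set[int]:
    return {
        k
        for k, sw in enumerate(sweeps)
        if detect_spikes(sw.voltage, level=level)
    }


def input_resistance(
    sweeps: SweepSet,
    current_range=(-70.0, 10.0),
    spike_level: float = -20.0,
):
    """OLS slope of steady-state dV (mV) vs step amplitude (pA), in MOhm.

    Returns ``(rin_mohm, diagnostics)`` where diagnostics carries the fit
    r^2 and the used/excluded sweep index sets.  Spike-containing sweeps
    are excluded before fitting; fewer than two usable sweeps is an error
    that lists the exclusions.
    """
    lo, hi = current_range
    excluded = _spiking_sweeps(sweeps, spike_level)
    used, dv, amps = [], [], []
    for k, sw in enumerate(sweeps):
        if sw.epoch is None or not (lo <= sw.epoch.amplitude <= hi):
            continue
        if k in excluded:
            continue
        used.append(k)
        amps.append(sw.epoch.amplitude)
        dv.append(_steady_state_delta(sw))
    if len(used) < 2:
        raise ValueError(
            f"need >=2 spike-free sweeps in [{lo}, {hi}] pA, have {len(used)} "
            f"(excluded for spikes: {sorted(excluded)})"
        )
    fit = stats.linregress(amps, dv)
    rin_mohm = fit.slope * 1000.0  # mV/pA == GOhm -> MOhm
    diagnostics = {
        "r_squared": float(fit.rvalue**2),
        "intercept_mv": float(fit.intercept),
        "sweeps_used": tuple(used),
        "sweeps_excluded": tuple(sorted(excluded)),
    }
    return float(rin_mohm), diagnostics


def rebound_slope(
    sweeps: SweepSet,
    post_window: float = 400.0,
    spike_level: float = -20.0,
) -> float:
    """OLS slope of rebound amplitude vs end-of-step potential, mV/mV.

    Uses hyperpolarizing, spike-free sweeps only.  Rebound amplitude is the
    maximum of (V - baseline mean) in the ``post_window`` ms after step
    offset; the abscissa is the mean V over the last 10 ms of the step.
    """
    excluded = _spiking_sweeps(sweeps, spike_level)
    x, y = [], []
    for k, sw in enumerate(sweeps):
        ep = sw.epoch
        if ep is None or ep.amplitude >= 0 or k in excluded:
            continue
        v = sw.voltage
        baseline = np.mean(
            v.slice_time(max(0.0, ep.onset - STEADY_WINDOW_MS), ep.onset)
        )
        end_v = np.mean(v.slice_time(ep.offset - END_OF_STEP_WINDOW_MS, ep.offset))
        stop = min(ep.offset + post_window, v.t0 + v.duration)
        rebound = np.max(v.slice_time(ep.offset, stop) - baseline)
        x.append(end_v)
        y.append(float(rebound))
    if len(x) < 2:
        raise ValueError(
            f"need >=2 hyperpolarizing spike-free sweeps, have {len(x)}"
        )
    return float(stats.linregress(x, y).slope)


def extract_subthreshold(
    sweeps: SweepSet,
    current_range=(-70.0, 10.0),
    post_window: float = 400.0,
) -> SubthresholdFeatures:
    """All subthreshold features of a step family in one call."""
    first = sweeps[0]
    onset = first.epoch.onset if first.epoch else first.voltage.duration
    rmp = resting_membrane_potential(
        first.voltage, baseline=(max(0.0, onset - STEADY_WINDOW_MS), onset)
    )
    rin, diag = input_resistance(sweeps, current_range=current_range)
    slope = rebound_slope(sweeps, post_window=post_window)
    return SubthresholdFeatures(
        rmp=rmp,
        input_resistance=rin,
        r_squared=diag["r_squared"],
        rebound_slope=slope,
        sweeps_used=diag["sweeps_used"],
        sweeps_excluded=diag["sweeps_excluded"],
    )
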