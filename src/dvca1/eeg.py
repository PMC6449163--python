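"""Sliding-window power and threshold-based seizure-candidate flagging.

Power is the within-window variance (mean squared deviation from the window
mean, uV^2), which makes detection invariant to electrode DC drift.  The
defaults follow the chronic video-EEG screening convention: a 3-s window
advanced in 15-ms steps (exactly 12 samples at 800 Hz), flagging windows
whose power is strictly above 100 uV^2.  Flagged windows are merged into
maximal candidate intervals for human inspection — electrographic
candidates only; behavioural correlation is outside algorithmic scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EEGRecord, Trace

__all__ = [
    "PowerSeries",
    "CandidateInterval",
    "sliding_window_power",
    "flag_candidates",
    "detect_record",
]


@dataclass(frozen=True)
class PowerSeries:
    window_starts: np.ndarray  # s
    power: np.ndarray  # uV^2
    window: float  # s
    step: float  # s


@dataclass(frozen=True)
class CandidateInterval:
    start: float  # s
    end: float  # s
    peak_power: float  # uV^2


def sliding_window_power(
    channel: Trace, fs: float, window: float = 3.0, step: float = 0.015
) -> PowerSeries:
    """Within-window variance over left-aligned sliding windows.

    Windows start at 0, step, 2*step, ... ; the last partial window is
    dropped.  A record shorter than one window is an error.
    """
    channel.require_unit("uV")
    x = channel.samples
    w = int(round(window * fs))
    s = max(1, int(round(step * fs)))
    if x.size < w:
        raise ValueError(
            f"record of {x.size} samples shorter than the {w}-sample window"
        )
    starts = np.arange(0, x.size - w + 1, s)
    # variance via cumulative sums: E[x^2] - E[x]^2 per window
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x.astype(float) ** 2)])
    sums = c1[starts + w] - c1[starts]
    sqs = c2[starts + w] - c2[starts]
    mean = sums / w
    power = np.maximum(sqs / w - mean**2, 0.0)
    return PowerSeries(
        window_starts=starts / fs, power=power, window=window, step=step
    )


def flag_candidates(
    power: PowerSeries, threshold: float = 100.0
) -> list[CandidateInterval]:
    """Maximal runs of windows with power strictly above ``threshold``.

    Each interval spans the union of its member windows (first window start
    to last window start + window length).
    """
    hot = power.power > threshold
    if not np.any(hot):
        return []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], hot.view(np.int8), [0]])))
    out = []
    for i0, i1 in zip(edges[::2], edges[1::2]):
        out.append(
            CandidateInterval(
                start=float(power.window_starts[i0]),
                end=float(power.window_starts[i1 - 1] + power.window),
                peak_power=float(np.max(power.power[i0:i1])),
            )
        )
    return out


def detect_record(
    rec: EEGRecord,
    window: float = 3.0,
    step: float = 0.015,
    threshold: float = 100.0,
) -> dict:
    """Per-channel candidate intervals for a whole EEG record."""
    return {
        name: flag_candidates(
            sliding_window_power(tr, rec.fs, window=window, step=step),
            threshold=threshold,
        )
        for name, tr in rec.channels.items()
    }
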