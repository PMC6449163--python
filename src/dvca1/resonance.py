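"""Chirp (ZAP) stimulus, impedance amplitude profile, and resonance peak.

The stimulus is a linear chirp — instantaneous frequency rising linearly
from f_start to f_end over the sweep — the standard ZAP convention:

    I(t) = A sin(theta(t)),  theta(t) = 2 pi (f_start t + (f_end - f_start) t^2 / (2 T))

The impedance amplitude profile is computed from single full-length FFTs of
the mean-subtracted voltage and the current.  The default mode is the
complex-ratio magnitude |V(f)/I(f)|, evaluated only at frequencies where the
stimulus has power (|I(f)| above 1% of its in-band maximum).  A literal
real-part ratio Re(V)/Re(I) is retained behind ``mode="real_ratio"`` —
Re(I) has zeros that make it numerically unstable, which is why it is not
the default; the two agree at the resonance peak for clean recordings.

The peak resonance frequency is the argmax, on a dense grid, of a
polynomial (order 6 by default) fitted to the profile over the evaluation
band.  The band starts at 0.5 Hz to exclude the DC bin and leakage near
0 Hz.  A profile whose fitted maximum sits at the band's low edge is
monotone-decreasing (low-pass) and is flagged non-resonant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Trace

__all__ = [
    "ChirpSpec",
    "ImpedanceProfile",
    "make_chirp",
    "impedance_profile",
    "peak_resonance_frequency",
]

STIMULUS_POWER_FLOOR = 0.01  # fraction of in-band |I(f)| maximum


@dataclass(frozen=True)
class ChirpSpec:
    """amplitude pA; f_start/f_end Hz; duration s."""

    amplitude: float = 50.0
    f_start: float = 0.0
    f_end: float = 15.0
    duration: float = 15.0

    def __post_init__(self):
        if not self.amplitude > 0:
            raise ValueError("amplitude must be positive")
        if not (0 <= self.f_start < self.f_end):
            raise ValueError("need 0 <= f_start < f_end")
        if not self.duration > 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class ImpedanceProfile:
    freqs: np.ndarray  # Hz, strictly increasing
    z: np.ndarray  # MOhm
    mode: str = "magnitude"
    fit_coeffs: np.ndarray | None = None
    peak_freq: float | None = None
    resonant: bool | None = None


def make_chirp(spec: ChirpSpec, dt: float) -> Trace:
    """Linear chirp current trace; dt in ms, amplitude in pA.

    dt must resolve f_end (dt <= 1/(2 f_end)); I(0) = 0 and |I| <= A with
    the maximum attained.
    """
    nyquist_dt_ms = 1000.0 / (2.0 * spec.f_end)
    if dt > nyquist_dt_ms:
        raise ValueError(
            f"dt={dt} ms cannot resolve f_end={spec.f_end} Hz "
            f"(need dt <= {nyquist_dt_ms:.4g} ms)"
        )
    n = int(round(spec.duration * 1000.0 / dt))
    t_s = np.arange(n) * (dt / 1000.0)
    theta = 2.0 * np.pi * (
        spec.f_start * t_s
        + (spec.f_end - spec.f_start) * t_s**2 / (2.0 * spec.duration)
    )
    return Trace(spec.amplitude * np.sin(theta), dt=dt, unit="pA")


def impedance_profile(
    voltage: Trace,
    current: Trace,
    band=(0.5, 15.0),
    mode: str = "magnitude",
) -> ImpedanceProfile:
    """Impedance amplitude profile in MOhm over the frequency band.

    FFT of the mean-subtracted voltage over the FFT of the current; mV/pA
    is GOhm, scaled to MOhm.  Frequencies where the stimulus magnitude
    falls below 1% of its in-band maximum are dropped.
    """
    voltage.require_unit("mV")
    current.require_unit("pA")
    if voltage.n != current.n or voltage.dt != current.dt:
        raise ValueError("voltage and current must share length and dt")
    if mode not in ("magnitude", "real_ratio"):
        raise ValueError(f"unknown mode {mode!r}")
    n = voltage.n
    dt_s = voltage.dt / 1000.0
    freqs = np.fft.rfftfreq(n, dt_s)
    vf = np.fft.rfft(voltage.samples - np.mean(voltage.samples))
    cf = np.fft.rfft(current.samples - np.mean(current.samples))
    lo, hi = band
    in_band = (freqs >= lo) & (freqs <= hi)
    if not np.any(in_band):
        raise ValueError(f"no FFT bins in band [{lo}, {hi}] Hz")
    floor = STIMULUS_POWER_FLOOR * np.max(np.abs(cf[in_band]))
    keep = in_band & (np.abs(cf) > floor)
    if not np.any(keep):
        raise ValueError("stimulus has no power in band")
    if mode == "magnitude":
        z_gohm = np.abs(vf[keep] / cf[keep])
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            z_gohm = np.abs(np.real(vf[keep]) / np.real(cf[keep]))
        finite = np.isfinite(z_gohm)
        keep_idx = np.flatnonzero(keep)[finite]
        z_gohm = z_gohm[finite]
        return ImpedanceProfile(freqs=freqs[keep_idx], z=z_gohm * 1000.0, mode=mode)
    return ImpedanceProfile(freqs=freqs[keep], z=z_gohm * 1000.0, mode=mode)


def peak_resonance_frequency(
    profile: ImpedanceProfile,
    poly_order: int = 6,
    band_low: float = 0.5,
    grid_points: int = 3001,
):
    """Peak of a polynomial fit to the impedance profile.

    Returns ``(ImpedanceProfile with fit and peak filled in, peak_freq Hz,
    resonant flag)``.  The fitted curve is evaluated on a dense grid over
    [band_low, max freq]; the argmax is the peak (ties broken toward lower
    frequency), and the profile is flagged non-resonant when the argmax
    falls on the low band edge.
    """
    mask = profile.freqs >= band_low
    f, z = profile.freqs[mask], profile.z[mask]
    if f.size < poly_order + 1:
        raise ValueError(
            f"need at least {poly_order + 1} profile points above "
            f"{band_low} Hz, have {f.size}"
        )
    coeffs = np.polynomial.polynomial.polyfit(f, z, poly_order)
    grid = np.linspace(band_low, f[-1], grid_points)
    fit = np.polynomial.polynomial.polyval(grid, coeffs)
    peak_idx = int(np.argmax(fit))  # argmax takes the first (lowest-f) tie
    peak = float(grid[peak_idx])
    resonant = peak_idx > 0
    out = ImpedanceProfile(
        freqs=profile.freqs,
        z=profile.z,
        mode=profile.mode,
        fit_coeffs=coeffs,
        peak_freq=peak,
        resonant=resonant,
    )
    return out, peak, resonant
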