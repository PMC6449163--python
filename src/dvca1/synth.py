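"""Synthetic ground-truth generators for every pipeline stage.

The model neuron is a generalized (resonant) integrate-and-fire cell: a
passive membrane augmented with one slow feedback conductance, the simplest
model whose impedance has a closed form and can show a subthreshold
resonance peak.  Subthreshold dynamics:

    C dV/dt    = -g_L (V - E_L) - g_1 w + I(t)
    tau_1 dw/dt = (V - E_L) - w

with C in pF, conductances in nS, tau_1 in ms, so pF/nS = ms and the
impedance magnitude is

    |Z(f)| = | 1 / (g_L + i 2 pi f C + g_1 / (1 + i 2 pi f tau_1)) |

in GOhm when evaluated in (nS, pF, ms) units; reported in MOhm.  The slow
variable w mimics a resonating current such as I_h: it opposes voltage
deviations with a lag, producing sag, rebound, and a band-pass impedance
when g_1 is large enough.

Integration uses the exact zero-order-hold discretisation of the 2x2 linear
subsystem (matrix exponential per step), so subthreshold output is exact for
piecewise-constant stimuli and unconditionally stable for stiff parameter
draws.  Optional threshold/reset spiking pastes a stereotyped spike waveform
at each threshold crossing and logs the ground-truth spike time.

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.signal import butter, sosfiltfilt

from .core import EEGRecord, GrayImage, Morphology, SWCNode, Trace

__all__ = [
    "ResonantNeuronParams",
    "SpikeParams",
    "SeizureEpochSpec",
    "simulate_neuron",
    "closed_form_impedance",
    "closed_form_peak_frequency",
    "synth_ap_template",
    "synth_eeg",
    "synth_morphology",
    "synth_layer_image",
    "synth_anatomical_ratios",
    "DORSAL_LIKE",
    "VENTRAL_LIKE",
]


@dataclass(frozen=True)
class SpikeParams:
    """Threshold/reset spiking bolted onto the linear subthreshold core.

    b is an adaptation increment added to the slow variable w at each spike
    (mV-equivalent, since w has voltage units); refractory holds V at reset.
    """

    v_threshold: float = -50.0  # mV
    v_reset: float = -65.0  # mV
    b: float = 0.0  # mV-equivalent increment to w per spike
    refractory: float = 2.0  # ms
    spike_peak: float = 30.0  # mV, pasted waveform apex


@dataclass(frozen=True)
class ResonantNeuronParams:
    C: float = 200.0  # pF
    g_L: float = 15.0  # nS
    g_1: float = 25.0  # nS
    tau_1: float = 50.0  # ms
    E_L: float = -65.0  # mV
    spike: SpikeParams | None = None

    def __post_init__(self):
        if not (self.C > 0 and self.g_L > 0):
            raise ValueError("C and g_L must be positive")
        if self.g_1 < 0 or self.tau_1 < 0:
            raise ValueError("g_1 and tau_1 must be non-negative")

    @property
    def dc_resistance_mohm(self) -> float:
        """Steady-state input resistance 1/(g_L + g_1), in MOhm."""
        return 1000.0 / (self.g_L + self.g_1)


#: demo presets; illustrative only, no quantitative claim about real cells.
#: dorsal-like: stronger resonant conductance, peak near 4 Hz, lower Rin;
#: ventral-like: weaker resonant conductance, peak near 3 Hz, higher Rin.
DORSAL_LIKE = ResonantNeuronParams(C=350.0, g_L=8.0, g_1=20.0, tau_1=130.0, E_L=-68.0)
VENTRAL_LIKE = ResonantNeuronParams(C=300.0, g_L=10.0, g_1=10.0, tau_1=150.0, E_L=-64.0)


def closed_form_impedance(p: ResonantNeuronParams, f) -> np.ndarray:
    """|Z(f)| of the resonant neuron in MOhm, for f in Hz (scalar or array)."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    omega_ms = 2.0 * np.pi * f / 1000.0  # rad per ms
    admittance_ns = (
        p.g_L + 1j * omega_ms * p.C + p.g_1 / (1.0 + 1j * omega_ms * p.tau_1)
    )
    z_gohm = np.abs(1.0 / admittance_ns)
    return z_gohm * 1000.0


def closed_form_peak_frequency(
    p: ResonantNeuronParams, f_low: float = 0.5, f_high: float = 15.0, n: int = 20001
) -> float:
    """Dense-grid argmax of |Z(f)| on [f_low, f_high]; the resonance oracle."""
    grid = np.linspace(f_low, f_high, n)
    return float(grid[np.argmax(closed_form_impedance(p, grid))])


def _discretize(p: ResonantNeuronParams, dt: float):
    """Exact ZOH discretisation of the (V, w) system for one step of dt ms."""
    if p.tau_1 > 0 and p.g_1 > 0:
        A = np.array(
            [
                [-p.g_L / p.C, -p.g_1 / p.C],
                [1.0 / p.tau_1, -1.0 / p.tau_1],
            ]
        )
        B = np.array([[1.0 / p.C], [0.0]])
        nstate = 2
    else:
        A = np.array([[-p.g_L / p.C]])
        B = np.array([[1.0 / p.C]])
        nstate = 1
    Ad = expm(A * dt)
    Bd = np.linalg.solve(A, (Ad - np.eye(nstate)) @ B)
    return Ad, Bd, nstate


def simulate_neuron(
    p: ResonantNeuronParams,
    stim: Trace,
    seed: int = 0,
    noise_sd: float = 0.0,
    v0: float | None = None,
):
    """Integrate the model neuron against a pA stimulus trace.

    Returns ``(voltage Trace in mV, spike_times ms list)``.  The spike log is
    empty when ``p.spike`` is None.  Gaussian voltage noise of ``noise_sd``
    mV is added per sample after integration (seeded, reproducible).

    dt must resolve the dynamics: dt <= tau_1/10 and dt <= membrane time
    constant / 10, else the integration is rejected as unstable.
    """
    stim.require_unit("pA")
    dt = stim.dt
    tau_m = p.C / p.g_L
    if dt > tau_m / 10.0 or (p.tau_1 > 0 and p.g_1 > 0 and dt > p.tau_1 / 10.0):
        raise ValueError(
            f"dt={dt} ms too coarse for tau_m={tau_m:.3g} ms, tau_1={p.tau_1} ms"
        )
    Ad, Bd, nstate = _discretize(p, dt)
    I = stim.samples
    n = I.size
    v = np.empty(n)
    x = np.zeros(nstate)  # deviations from E_L: [V - E_L, w]
    if v0 is not None:
        x[0] = v0 - p.E_L
    v[0] = p.E_L + x[0]
    spikes: list[float] = []

    sp = p.spike
    if sp is None:
        # pure linear system: iterate the exact one-step map
        a11 = Ad
        for k in range(1, n):
            x = a11 @ x + Bd[:, 0] * I[k - 1]
            v[k] = p.E_L + x[0]
    else:
        rise_n = max(1, int(round(0.4 / dt)))  # 0.4 ms rise to apex
        fall_n = max(1, int(round(0.6 / dt)))  # 0.6 ms fall to reset
        refr_n = int(round(sp.refractory / dt))
        k = 1
        while k < n:
            x = Ad @ x + Bd[:, 0] * I[k - 1]
            v[k] = p.E_L + x[0]
            if v[k] >= sp.v_threshold:
                # paste stereotyped spike: linear rise then fall
                apex = min(k + rise_n, n - 1)
                up = np.linspace(v[k], sp.spike_peak, apex - k + 1)
                v[k : apex + 1] = up
                spikes.append(stim.t0 + apex * dt)
                end_fall = min(apex + fall_n, n - 1)
                if end_fall > apex:
                    v[apex + 1 : end_fall + 1] = np.linspace(
                        sp.spike_peak, sp.v_reset, end_fall - apex + 1
                    )[1:]
                # refractory clamp at reset; w keeps relaxing with V clamped
                k_res = end_fall
                x[0] = sp.v_reset - p.E_L
                if nstate == 2:
                    x[1] += sp.b
                end_ref = min(k_res + refr_n, n - 1)
                for j in range(k_res + 1, end_ref + 1):
                    if nstate == 2:
                        x[1] += dt / p.tau_1 * (x[0] - x[1])
                    v[j] = sp.v_reset
                k = end_ref + 1
            else:
                k += 1

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=n)
    return Trace(v, dt=dt, t0=stim.t0, unit="mV"), spikes


# ---------------------------------------------------------------------------
# Action-potential template
# ---------------------------------------------------------------------------


def synth_ap_template(
    threshold: float,
    peak: float,
    trough: float,
    rmp: float,
    rise_slope: float,
    dt: float = 0.02,
    foot_slope: float = 5.0,
    fall_time: float = 1.0,
    pre_ms: float = 20.0,
    post_ms: float = 20.0,
) -> Trace:
    """Piecewise waveform whose spike landmarks equal the arguments.

    Baseline at ``rmp``; a slow depolarising foot at ``foot_slope`` mV/ms
    (kept below the 20 mV/ms threshold criterion) from rmp to ``threshold``;
    a linear rise at ``rise_slope`` mV/ms from threshold to ``peak``; a fall
    over ``fall_time`` ms from peak to ``trough``; exponential recovery back
    toward rmp.  Setting fall_time > 1.5 ms puts the fAHP trough outside the
    detection window by construction.
    """
    if peak <= threshold:
        raise ValueError("peak must exceed threshold")
    if trough >= threshold:
        raise ValueError("trough must lie below threshold")
    if rmp >= threshold:
        raise ValueError("rmp must lie below threshold")
    if rise_slope <= 0 or foot_slope <= 0:
        raise ValueError("slopes must be positive")

    seg_base = np.full(int(round(pre_ms / dt)), rmp)
    n_foot = max(2, int(round((threshold - rmp) / foot_slope / dt)))
    seg_foot = np.linspace(rmp, threshold, n_foot + 1)[1:]
    n_rise = max(2, int(round((peak - threshold) / rise_slope / dt)))
    seg_rise = np.linspace(threshold, peak, n_rise + 1)[1:]
    n_fall = max(2, int(round(fall_time / dt)))
    # half-cosine fall: dV/dt is zero at the peak and at the trough, so the
    # derivative's sign changes there are clean
    phase = np.linspace(0.0, np.pi, n_fall + 1)[1:]
    seg_fall = trough + (peak - trough) * 0.5 * (1.0 + np.cos(phase))
    # after the fAHP trough the potential climbs back toward the inter-spike
    # level (halfway from trough to threshold), making the trough a genuine
    # local minimum where dV/dt crosses zero from below
    n_post = int(round(post_ms / dt))
    t_rec = np.arange(1, n_post + 1) * dt
    recovery_level = trough + 0.5 * (threshold - trough)
    seg_rec = recovery_level + (trough - recovery_level) * np.exp(-t_rec / 3.0)
    v = np.concatenate([seg_base, seg_foot, seg_rise, seg_fall, seg_rec])
    return Trace(v, dt=dt, unit="mV")


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SeizureEpochSpec:
    """A high-power epoch embedded in background EEG."""

    start: float  # s
    duration: float  # s
    rms: float  # uV
    carrier: float = 8.0  # Hz

    def __post_init__(self):
        if not self.duration > 0:
            raise ValueError("epoch duration must be positive")
        if not self.rms > 0:
            raise ValueError("epoch rms must be positive")

    @property
    def end(self) -> float:
        return self.start + self.duration


def synth_eeg(
    duration: float,
    background_rms: float,
    epochs=(),
    fs: float = 800.0,
    seed: int = 0,
    channel: str = "ch1",
):
    """Low-pass-filtered Gaussian background plus sinusoidal seizure epochs.

    Returns ``(EEGRecord, ground-truth (start_s, end_s) interval list)``.
    Epochs are amplitude-modulated sinusoids with a 5% raised-cosine ramp at
    each end; overlapping epochs are rejected.
    """
    epochs = sorted(epochs, key=lambda e: e.start)
    for a, b in zip(epochs, epochs[1:]):
        if b.start < a.end:
            raise ValueError(f"overlapping epochs at {b.start} s")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    x = rng.normal(0.0, 1.0, size=n)
    sos = butter(4, 100.0, btype="low", fs=fs, output="sos")
    x = sosfiltfilt(sos, x)
    x *= background_rms / np.sqrt(np.mean(x**2))
    t = np.arange(n) / fs
    truth = []
    for ep in epochs:
        if ep.end > duration:
            raise ValueError("epoch extends past the record")
        i0, i1 = int(round(ep.start * fs)), int(round(ep.end * fs))
        seg_t = t[i0:i1]
        env = np.ones(i1 - i0)
        ramp = max(1, int(round(0.05 * (i1 - i0))))
        env[:ramp] = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[-ramp:] = env[:ramp][::-1]
        x[i0:i1] += ep.rms * np.sqrt(2.0) * env * np.sin(
            2 * np.pi * ep.carrier * seg_t
        )
        truth.append((ep.start, ep.end))
    rec = EEGRecord(
        channels={channel: Trace(x, dt=1000.0 / fs, unit="uV")}, fs=fs
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Morphology
# ---------------------------------------------------------------------------


def synth_morphology(
    depth: int, mean_segment: float = 40.0, seed: int = 0
) -> Morphology:
    """Random binary dendritic tree rooted at a soma node at the origin.

    Each branch level adds two daughters per tip with exponentially
    distributed lengths around ``mean_segment`` um and directions biased
    away from the soma.  depth 0 yields a soma-only morphology.
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    rng = np.random.default_rng(seed)
    nodes = [SWCNode(1, 1, 0.0, 0.0, 0.0, 5.0, -1)]
    next_id = 2
    # (node_id, position, outward direction, radius)
    tips = [(1, np.zeros(3), None, 2.0)]
    for level in range(depth):
        new_tips = []
        for parent_id, pos, direction, radius in tips:
            for _ in range(2):
                if direction is None:
                    d = rng.normal(size=3)
                else:
                    d = direction + 0.6 * rng.normal(size=3)
                d /= np.linalg.norm(d)
                length = rng.exponential(mean_segment)
                new_pos = pos + length * d
                child_r = max(0.3, radius * 0.8)
                nodes.append(
                    SWCNode(
                        next_id, 3,
                        float(new_pos[0]), float(new_pos[1]), float(new_pos[2]),
                        child_r, parent_id,
                    )
                )
                new_tips.append((next_id, new_pos, d, child_r))
                next_id += 1
        tips = new_tips
    return Morphology(nodes)


# ---------------------------------------------------------------------------
# Layered image
# ---------------------------------------------------------------------------


def synth_layer_image(shape, band_edges, band_values) -> GrayImage:
    """Axis-aligned banded image: bands along the column (x) axis.

    ``band_edges`` are normalized x positions (len = len(values) + 1,
    starting at 0 and ending at 1); ``band_values`` are gray levels.
    """
    edges = np.asarray(band_edges, dtype=float)
    values = list(band_values)
    if len(edges) != len(values) + 1:
        raise ValueError("need len(band_edges) == len(band_values) + 1")
    if edges[0] != 0.0 or edges[-1] != 1.0 or np.any(np.diff(edges) <= 0):
        raise ValueError("band_edges must increase from 0 to 1")
    for val in values:
        if not (0 <= val <= 65535):
            raise ValueError(f"band value {val} outside [0, 65535]")
    h, w = shape
    img = np.empty((h, w), dtype=np.uint16)
    xs = (np.arange(w) + 0.5) / w
    idx = np.clip(np.searchsorted(edges, xs, side="right") - 1, 0, len(values) - 1)
    for j in range(w):
        img[:, j] = values[idx[j]]
    return GrayImage(pixels=img)


# ---------------------------------------------------------------------------
# Anatomical ratios
# ---------------------------------------------------------------------------


def synth_anatomical_ratios(position: float, seed: int = 0):
    """Draw shape ratios consistent with the printed position regression.

    ca1 and ca3 are drawn uniformly from the feasible box, and dg is solved
    so the regression returns ``position`` exactly; raises if no non-negative
    solution exists (position below the regression's intercept).
    """
    from .position import INTERCEPT, COEF_CA1, COEF_CA3, COEF_DG, AnatomicalRatios

    budget = position - INTERCEPT
    if budget < 0:
        raise ValueError(
            f"position {position} mm infeasible: requires negative ratios"
        )
    rng = np.random.default_rng(seed)
    ca1 = rng.uniform(0.0, budget / COEF_CA1)
    ca3 = rng.uniform(0.0, (budget - COEF_CA1 * ca1) / COEF_CA3)
    dg = (budget - COEF_CA1 * ca1 - COEF_CA3 * ca3) / COEF_DG
    return AnatomicalRatios(ca1=ca1, ca3=ca3, dg=dg)
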