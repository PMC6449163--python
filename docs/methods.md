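# Methods

## Scope and units

The package implements the per-cell / per-record analysis stages of a
dorsoventral CA1 excitability workflow; group-level hypothesis testing
(t tests, ANOVAs, post hocs) is deliberately left to standard statistics
tooling, with only the Holm–Šidák step-down adjustment provided because it
wraps the repeated multiple-t-test pattern of such studies.

Canonical units: mV (membrane potential), pA (injected current), ms (time),
μV (EEG, stored as ASCII `uV`), μm (distance), MΩ (impedance), Hz. A slope
of mV/pA is numerically GΩ; R_in in MΩ is 1000 × that slope. Time series
are `(t0, dt, samples)` triplets — never explicit time columns — so
resampling inconsistencies cannot be represented. The liquid junction
potential is never subtracted from voltages; if known it can be recorded in
sweep metadata as documentation.

## Subthreshold features

**Input resistance.** Steady-state ΔV is the mean over the last 100 ms of
the 800-ms step minus the mean over the last 100 ms of baseline; late-step
averaging keeps sag transients out of the estimate (the averaging windows
are a package convention; results are insensitive to them once the membrane
has settled). The OLS fit uses sweeps within −70…10 pA after excluding any
sweep that fired a spike (detected at the −20 mV level); exclusions are
reported alongside the fit r².

**Rebound slope.** For hyperpolarizing, spike-free sweeps: rebound
amplitude = max(V − baseline) in a 400-ms window after step offset (window
configurable); abscissa = mean V over the last 10 ms of the step; the OLS
slope is the rebound slope. A memoryless membrane gives exactly 0; a
resonant conductance (I_h-like) gives a negative slope.

**Resting membrane potential** is a baseline-window mean. How the original
workflow computed RMP is not specified anywhere we could anchor to; the
mean-over-baseline choice is ours and is the only point in this module with
that status.

## Resonance

The chirp is linear in instantaneous frequency (the standard ZAP
convention): θ(t) = 2π(f₀t + (f₁−f₀)t²/2T), amplitude ±50 pA, 0→15 Hz over
15 s by default. The impedance profile is computed from single full-length
FFTs of the mean-subtracted voltage and the current — no taper, no segment
averaging — and evaluated only where the stimulus magnitude exceeds 1% of
its in-band maximum.

Two modes exist. The default is the complex-ratio magnitude |V̂/Î|. The
literal ratio of real parts Re(V̂)/Re(Î) is retained behind
`mode="real_ratio"`: Re(Î) has zeros across the band, which make that
estimator unstable bin-to-bin; its local median around the peak agrees with
the magnitude mode within a few percent on clean simulations (tested). The
magnitude default is therefore a deliberate reading of "ratio of the real
portion" as shorthand for the standard impedance amplitude.

The peak resonance frequency is the dense-grid argmax of an order-6
polynomial fitted to the profile on [0.5, 15] Hz. Order 6 tracks a
single-peaked profile without ringing; 0.5 Hz excludes the DC bin and
leakage near 0 Hz; ties break toward lower frequency; an argmax on the low
band edge means a monotone (low-pass) profile and sets `resonant=False`.

## Suprathreshold features

Spikes are upward crossings of −20 mV followed by the local maximum of the
supra-level excursion; peaks closer than 2 ms are merged (configurable) to
avoid double counts on noisy repolarizations. The derivative estimator
everywhere is the central difference over one sample step, in mV/ms.

Per spike: threshold = V at the first sample (scanning forward from 3 ms
before the −20 mV crossing) where dV/dt ≥ 20 mV/ms; max dV/dt over
threshold→peak; amplitude = V(peak) − RMP; the fAHP trough is the second
zero crossing of dV/dt after threshold (first +→− at the peak, second −→+
at the trough), accepted only within 1.5 ms of the peak, with
fahp = threshold − V(trough) (positive = trough below threshold). The
1.5-ms window is anchored at the spike peak.

Per train: ISIs and SFA = ISI₆/ISI₁, defined only for ≥7 spikes. The
literature also uses the reciprocal (first-to-sixth) convention;
`train_features(..., reciprocal=True)` provides it, and the default is
documented rather than silently chosen. FI curves count spikes inside the
step window per amplitude (100–500 pA); spike-shape analysis selects trains
of 8–11 spikes (inclusive).

## EEG seizure candidates

Power is the within-window variance (mean squared deviation from the window
mean), which makes flagging invariant to DC electrode drift and matches the
μV² unit of the screening rule. Windows are left-aligned, 3 s long, advanced
in 15-ms steps (exactly 12 samples at 800 Hz); the last partial window is
dropped. Flagging is strictly above 100 μV²; contiguous hot windows merge
into one candidate interval spanning the union of member windows. Because
the window is long relative to the step, flagged intervals extend up to one
window length beyond a true high-power epoch — candidates are meant for
human review, and behavioural confirmation is out of scope.

## Position model

The regression `position = −7.23 + 0.43·CA1 + 0.50·CA3 + 0.34·DG` (mm,
dorsal positive) is evaluated, never re-fitted: its calibration data belong
to the prior study that built it, and its stated ±0.59-mm (90% confidence)
precision is carried as metadata only. Zone edges are reconstructed from
the published zone midpoints (dorsal 2 mm, ventral −2.5 mm) and the 1.5-mm
bin width: dorsal [1.25, 2.75], dorsal-intermediate [−0.25, 1.25),
ventral-intermediate [−1.75, −0.25), ventral [−3.25, −1.75), everything
else "outside". The edges are a reconstruction — the source prints
midpoints, not edges — and bins are closed at their dorsal edge for
deterministic boundaries.

## Morphometry

Sholl counting uses the chord (endpoint-straddle) convention consistent
with tracing-software counts: a parent–child chord crosses the shell of
radius r when its endpoint distances straddle r (`min < r ≤ max`). A
segment tangent to a sphere without endpoint straddle is not counted — a
known limitation of the convention. Spheres are 3-D by default;
`flatten_z=True` gives projected 2-D circles. Dendrite means SWC type
∈ {3, 4}; axons and soma are excluded everywhere, and a segment with a soma
parent contributes length from the soma centroid. Surface area is the
lateral frustum per segment, π(r₁+r₂)·√(L²+(r₁−r₂)²); the soma surface is
not included.

## Immunostain profiles

The radial profile samples bilinearly at stations cell-centred in arc
length (about one per pixel, an equal integer count per bin so binning is
exact and path reversal reverses bins exactly), averaging across `width`
perpendicular 1-px offsets. The canonical path direction is alveus →
fissure (SO first, SLM last). No background subtraction or flat-field
correction is applied by default; a constant dark-frame level can be
subtracted. Path width is an explicit required choice, not a default guess.

## Synthetic data: what it emulates and what it does not

The model neuron is a generalized (resonant) integrate-and-fire cell:
C·dV/dt = −g_L(V−E_L) − g₁w + I, τ₁·dw/dt = (V−E_L) − w, with closed-form
impedance |1/(g_L + i2πfC + g₁/(1+i2πfτ₁))| and DC resistance 1/(g_L+g₁).
Integration is the exact zero-order-hold discretisation of the 2×2 linear
system (matrix exponential per step) — exact for piecewise-constant
stimuli and unconditionally stable for stiff parameter draws. Optional
threshold/reset spiking pastes a stereotyped waveform (0.4-ms rise, 0.6-ms
fall, then a refractory clamp) and logs ground-truth spike times; an
adaptation increment on w produces accommodating trains.

Synthetic EEG is low-pass-filtered (100 Hz, 4th-order Butterworth,
zero-phase) Gaussian noise calibrated to a target RMS, plus sinusoidal
epochs with 5% raised-cosine ramps. Morphologies are random binary trees
with exponential segment lengths and outward-biased directions. Layered
images are axis-aligned bands. Anatomical ratios are drawn uniformly from
the feasible box and closed under the position regression, so the
position→ratios→position round trip is exact.

These generators provide *known ground truth*, not biological realism: real
recordings have electrode artifacts, drifting baselines, channel noise with
structure, spikes whose shape varies through a train, EEG with spectral
seizure signatures rather than pure tones, and reconstructions with
tortuous neurites. Passing tests therefore demonstrate that the estimators
recover what they are defined to measure, not that they are robust to every
failure mode of experimental data. The "dorsal-like"/"ventral-like" presets
(resonance near 4 vs 3 Hz, lower vs higher R_in) are illustrative demos and
carry no quantitative claim about real neurons.

## Problem sizes and numerical choices

Default working scales: chirp simulations at dt = 0.5 ms (30 000 samples);
step families at dt = 0.2–0.5 ms; 20-cell ensembles for parameter-recovery
checks; 50 seeded runs for spike-count and morphometry oracle equivalence;
40–60-s EEG records for detector checks. Polynomial fits use the numpy
polynomial basis; OLS fits use `scipy.stats.linregress`. Degenerate inputs
(empty windows, <2 usable sweeps, soma-only trees, zero-length paths,
stimuli without band power) raise errors rather than returning defaults.

## Known limitations

- No ABF/NWB/EDF binary readers (the CSV sweep-table is the interchange
  format); no multi-electrode support.
- No sag-ratio metric, no spike-shape clustering or burst metrics, no
  phase/impedance-locus analysis.
- EEG flagging has no artifact rejection or spectral features; per-channel
  only.
- Sholl tangent crossings are missed by the chord convention (above).
- The real-part impedance ratio is unstable where Re(Î) ≈ 0; use the
  default magnitude mode unless reproducing the literal historical
  computation.
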