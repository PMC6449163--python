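"""Spike detection, AP waveform features, trains, and FI curves."""

import math

import numpy as np
import pytest

from dvca1 import core, synth
from dvca1.suprathreshold import (
    ap_waveform_features,
    count_spikes_in_step,
    detect_spikes,
    fi_curve,
    select_trains,
    train_features,
)
from dvca1.suprathreshold import FeatureExtractionError

from conftest import make_step_family


def place_templates(times_ms, dt=0.02, total_ms=400.0, **kwargs):
    """Voltage trace with synthetic AP templates pasted at given times."""
    tpl = synth.synth_ap_template(
        threshold=-50.0, peak=30.0, trough=-58.0, rmp=-65.0, rise_slope=150.0,
        dt=dt, pre_ms=0.0, post_ms=10.0, **kwargs
    )
    v = np.full(int(total_ms / dt), -65.0)
    peak_times = []
    for t in times_ms:
        i0 = int(t / dt)
        seg = tpl.samples
        v[i0 : i0 + seg.size] = seg
        peak_times.append((i0 + int(np.argmax(seg))) * dt)
    return core.Trace(v, dt=dt, unit="mV"), peak_times


class TestDetectSpikes:
    def test_subthreshold_trace_empty(self):
        v = core.Trace(np.full(1000, -40.0), dt=0.1, unit="mV")
        assert detect_spikes(v) == []

    def test_three_templates_at_known_times(self):
        v, truth = place_templates([100.0, 200.0, 300.0])
        found = detect_spikes(v)
        assert len(found) == 3
        for f, t in zip(found, truth):
            assert f == pytest.approx(t, abs=0.1)

    def test_lif_counts_match_simulator_log(self, lif_params):
        dt = 0.2
        cmd = np.zeros(int(1000 / dt))
        cmd[int(100 / dt) : int(900 / dt)] = 300.0
        stim = core.Trace(cmd, dt=dt, unit="pA")
        v, log = synth.simulate_neuron(lif_params, stim)
        assert len(detect_spikes(v)) == len(log)

    def test_dc_offset_invariance(self):
        v, _ = place_templates([100.0, 200.0])
        shifted = core.Trace(v.samples + 5.0, dt=v.dt, unit="mV")  # still < -20
        assert detect_spikes(shifted) == detect_spikes(v)

    def test_fifty_seeded_simulations_exact(self, lif_params):
        """Detected counts equal simulator ground truth on 50 seeded runs."""
        dt = 0.2
        rng = np.random.default_rng(7)
        for _ in range(50):
            amp = rng.uniform(320, 700)
            cmd = np.zeros(int(600 / dt))
            cmd[int(50 / dt) : int(550 / dt)] = amp
            stim = core.Trace(cmd, dt=dt, unit="pA")
            v, log = synth.simulate_neuron(lif_params, stim)
            found = detect_spikes(v)
            assert len(found) == len(log)
            np.testing.assert_allclose(found, log, atol=dt / 2)


def brute_force_ap_features(trace, peak_time, rmp, criterion=20.0,
                            fahp_window=1.5, level=-20.0, search_back=3.0):
    """Exhaustive scan of the sampled central-difference derivative."""
    v, dt = trace.samples, trace.dt
    d = np.gradient(v, dt)
    peak_idx = int(round((peak_time - trace.t0) / dt))
    cross = peak_idx
    for i in range(peak_idx, 0, -1):
        if v[i] >= level and v[i - 1] < level:
            cross = i
            break
    start = max(0, cross - int(round(search_back / dt)))
    thr_idx = None
    for i in range(start, peak_idx + 1):
        if d[i] >= criterion:
            thr_idx = i
            break
    assert thr_idx is not None
    crossings = []
    for i in range(thr_idx, v.size - 1):
        if d[i] > 0 and d[i + 1] <= 0:
            crossings.append(("down", i + 1))
        elif d[i] < 0 and d[i + 1] >= 0:
            crossings.append(("up", i + 1))
        if len(crossings) == 2:
            break
    fahp = None
    if len(crossings) == 2 and crossings[0][0] == "down":
        trough = crossings[1][1]
        if (trough - peak_idx) * dt <= fahp_window + 1e-9:
            fahp = v[thr_idx] - v[trough]
    return {
        "threshold": v[thr_idx],
        "max_dvdt": d[thr_idx : peak_idx + 1].max(),
        "amplitude": v[peak_idx] - rmp,
        "fahp": fahp,
    }


class TestAPWaveformFeatures:
    def test_template_landmarks_recovered(self):
        v, peaks = place_templates([100.0])
        feats = ap_waveform_features(v, peaks[0], rmp=-65.0)
        assert feats.threshold == pytest.approx(-50.0, abs=0.5)
        assert feats.amplitude == pytest.approx(95.0, abs=0.5)
        assert feats.fahp == pytest.approx(8.0, abs=0.5)
        assert feats.fahp_time is not None
        assert feats.fahp_time - feats.peak_time <= 1.5 + 1e-9

    @pytest.mark.parametrize("rise_slope", [60.0, 100.0, 150.0, 300.0])
    def test_max_dvdt_equals_programmed_rise(self, rise_slope):
        dt = 0.02
        tpl = synth.synth_ap_template(
            threshold=-50.0, peak=30.0, trough=-58.0, rmp=-65.0,
            rise_slope=rise_slope, dt=dt,
        )
        peaks = detect_spikes(tpl)
        feats = ap_waveform_features(tpl, peaks[0], rmp=-65.0)
        # discretization of the piecewise-linear rise costs at most a couple %
        assert feats.max_dvdt == pytest.approx(rise_slope, rel=0.05)

    def test_late_trough_reports_absent_fahp(self):
        v, peaks = place_templates([100.0], fall_time=2.5)
        feats = ap_waveform_features(v, peaks[0], rmp=-65.0)
        assert feats.fahp is None
        assert feats.fahp_time is None

    def test_matches_brute_force_oracle_on_templates(self):
        for thr, peak, trough, rise in [
            (-50.0, 30.0, -58.0, 150.0),
            (-45.0, 25.0, -52.0, 100.0),
            (-55.0, 35.0, -60.0, 250.0),
        ]:
            tpl = synth.synth_ap_template(
                threshold=thr, peak=peak, trough=trough, rmp=-65.0,
                rise_slope=rise,
            )
            pt = detect_spikes(tpl)[0]
            got = ap_waveform_features(tpl, pt, rmp=-65.0)
            want = brute_force_ap_features(tpl, pt, rmp=-65.0)
            assert got.threshold == pytest.approx(want["threshold"], abs=1e-9)
            assert got.max_dvdt == pytest.approx(want["max_dvdt"], abs=1e-9)
            assert got.amplitude == pytest.approx(want["amplitude"], abs=1e-9)
            assert got.fahp == pytest.approx(want["fahp"], abs=1e-9)

    def test_never_reaching_criterion_is_an_error(self):
        dt = 0.1
        t = np.arange(0, 50, dt)
        v = core.Trace(-60 + 45 * np.sin(2 * np.pi * t / 50), dt=dt, unit="mV")
        peaks = detect_spikes(v)  # slow sine crosses -20 but dV/dt < 20
        with pytest.raises(FeatureExtractionError):
            ap_waveform_features(v, peaks[0], rmp=-60.0)


class TestTrainFeatures:
    def test_regular_train_sfa_is_one(self):
        times = np.arange(10) * 50.0
        assert train_features(times).sfa == pytest.approx(1.0)

    def test_accommodating_train(self):
        isis = [50, 60, 70, 80, 90, 100]
        times = np.concatenate([[0.0], np.cumsum(isis)])
        tf = train_features(times)
        assert tf.sfa == pytest.approx(2.0)
        assert train_features(times, reciprocal=True).sfa == pytest.approx(0.5)

    def test_short_train_sfa_absent(self):
        tf = train_features(np.arange(5) * 50.0)
        assert tf.sfa is None
        assert tf.count == 5
        assert len(tf.isis) == 4

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            train_features([10.0, 5.0, 20.0])


class TestFICurve:
    def test_passive_family_all_zero(self, passive_params):
        fam = make_step_family(passive_params, list(range(100, 501, 100)))
        fi = fi_curve(fam, amplitudes=range(100, 501, 100))
        assert all(c == 0 for c in fi.counts)

    def test_lif_counts_match_closed_form(self, lif_params):
        fam = make_step_family(
            lif_params, list(range(100, 501, 50)), dt=0.2, onset=100.0,
            duration=800.0, tail=100.0,
        )
        fi = fi_curve(fam, amplitudes=range(100, 501, 50))
        # closed-form LIF: dV_inf = R*I; latency tau*ln(dV/(dV - gap));
        # per-spike dead time = rise + fall + refractory of the paste
        R, tau, gap, dead = 0.05, 20.0, 15.0, 3.0
        for amp, count in zip(fi.amplitudes, fi.counts):
            dv = R * amp
            if dv <= gap:
                assert count == 0
                continue
            t_isi = tau * math.log(dv / (dv - gap))
            expected = int((800.0 - t_isi) // (t_isi + dead)) + 1
            assert abs(count - expected) <= 1

    def test_counts_non_decreasing_in_amplitude(self, lif_params):
        fam = make_step_family(lif_params, list(range(100, 501, 100)))
        fi = fi_curve(fam, amplitudes=range(100, 501, 100))
        assert list(fi.counts) == sorted(fi.counts)

    def test_missing_amplitude_listed(self, lif_params):
        fam = make_step_family(lif_params, [100, 200])
        with pytest.raises(ValueError, match="300"):
            fi_curve(fam, amplitudes=[100, 200, 300])


class TestSelectTrains:
    @pytest.mark.parametrize(
        "counts,expected",
        [([3, 9, 12], {1}), ([8, 11], {0, 1}), ([0, 0, 0], set())],
    )
    def test_inclusive_count_range(self, counts, expected, lif_params):
        # build sweeps whose in-step counts are exactly `counts` by pasting
        # template spikes inside the step window
        dt = 0.1
        n = int(1000 / dt)
        sweeps = []
        tpl = synth.synth_ap_template(
            threshold=-50.0, peak=30.0, trough=-58.0, rmp=-65.0,
            rise_slope=150.0, dt=dt, pre_ms=0.0, post_ms=5.0,
        )
        for c in counts:
            v = np.full(n, -65.0)
            for k in range(c):
                i0 = int((150 + 60 * k) / dt)
                v[i0 : i0 + tpl.n] = tpl.samples
            cmd = np.zeros(n)
            cmd[int(100 / dt) : int(900 / dt)] = 200.0
            sweeps.append(
                core.Sweep(
                    core.Trace(v, dt=dt, unit="mV"),
                    core.Trace(cmd, dt=dt, unit="pA"),
                    core.StepEpoch(100.0, 800.0, 200.0),
                )
            )
        fam = core.SweepSet(sweeps)
        assert select_trains(fam, count_range=(8, 11)) == expected
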