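"""Shared fixtures: synthetic sweep families built from the model neuron."""

import numpy as np
import pytest

from dvca1 import core
from dvca1 import synth


def make_step_family(
    params,
    amplitudes,
    dt=0.2,
    onset=200.0,
    duration=800.0,
    tail=400.0,
    seed=0,
    noise_sd=0.0,
):
    """Simulate one sweep per amplitude and wrap as a SweepSet."""
    n = int(round((onset + duration + tail) / dt))
    sweeps = []
    for k, amp in enumerate(amplitudes):
        cmd = np.zeros(n)
        cmd[int(round(onset / dt)) : int(round((onset + duration) / dt))] = amp
        ct = core.Trace(cmd, dt=dt, unit="pA")
        v, _ = synth.simulate_neuron(
            params, ct, seed=seed * 1000 + k, noise_sd=noise_sd
        )
        sweeps.append(core.Sweep(v, ct, core.StepEpoch(onset, duration, amp)))
    return core.SweepSet(sweeps)


def make_resistor_family(r_mohm=50.0, amplitudes=(-70, -50, -30, -10, 10), dt=0.2):
    """Ideal-resistor sweeps: instantaneous dV = R * I, no dynamics."""
    onset, duration, tail = 200.0, 800.0, 200.0
    n = int(round((onset + duration + tail) / dt))
    slope_mv_per_pa = r_mohm / 1000.0
    sweeps = []
    for amp in amplitudes:
        cmd = np.zeros(n)
        i0, i1 = int(round(onset / dt)), int(round((onset + duration) / dt))
        cmd[i0:i1] = amp
        v = -65.0 + slope_mv_per_pa * cmd
        sweeps.append(
            core.Sweep(
                core.Trace(v, dt=dt, unit="mV"),
                core.Trace(cmd, dt=dt, unit="pA"),
                core.StepEpoch(onset, duration, amp),
            )
        )
    return core.SweepSet(sweeps)


@pytest.fixture
def resistor_family():
    return make_resistor_family()


@pytest.fixture
def passive_params():
    # g_1 = 0: a plain RC membrane, no resonant current
    return synth.ResonantNeuronParams(C=200.0, g_L=20.0, g_1=0.0, tau_1=0.0,
                                      E_L=-65.0)


@pytest.fixture
def resonant_params():
    return synth.ResonantNeuronParams(C=200.0, g_L=15.0, g_1=25.0, tau_1=50.0,
                                      E_L=-65.0)


@pytest.fixture
def lif_params():
    # R = 1/g_L = 50 MOhm, tau_m = C/g_L = 20 ms, threshold gap 15 mV
    return synth.ResonantNeuronParams(
        C=400.0, g_L=20.0, g_1=0.0, tau_1=0.0, E_L=-65.0,
        spike=synth.SpikeParams(v_threshold=-50.0, v_reset=-65.0, refractory=2.0),
    )
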