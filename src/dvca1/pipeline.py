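"""Per-cell report assembly, Holm-Sidak adjustment, and configuration.

``run_cell_report`` composes the subthreshold, resonance, and suprathreshold
stages over one recorded cell into a deterministic JSON-serialisable report:
identical inputs and configuration give byte-identical JSON (provenance is
confined to its own block).  Sweeps are classified as step or chirp by the
shape of their command waveform; a protocol that is absent yields an
explicitly null report section, never a silent default.

``holm_sidak_adjust`` is the step-down Sidak multiple-comparison adjustment
used with families of t tests: sort the m p-values ascending, adjust the
k-th (1-based) as 1 - (1 - p_k)^(m - k + 1), enforce monotonicity with a
running maximum, clip at 1, and return in the original order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__
from .core import Sweep, SweepSet
from .resonance import impedance_profile, peak_resonance_frequency
from .subthreshold import extract_subthreshold
from .suprathreshold import (
    count_spikes_in_step,
    ap_waveform_features,
    detect_spikes,
    select_trains,
    train_features,
)

__all__ = [
    "DEFAULT_CONFIG",
    "CellReport",
    "holm_sidak_adjust",
    "classify_sweep",
    "run_cell_report",
]

#: every default equals the printed analysis value where one exists
DEFAULT_CONFIG = {
    "subthreshold.current_range": (-70.0, 10.0),  # pA, Rin fit range
    "subthreshold.post_window": 400.0,  # ms, rebound search
    "resonance.band": (0.5, 15.0),  # Hz
    "resonance.mode": "magnitude",
    "resonance.poly_order": 6,
    "suprathreshold.level": -20.0,  # mV detection level
    "suprathreshold.dvdt_criterion": 20.0,  # mV/ms
    "suprathreshold.fahp_window": 1.5,  # ms
    "suprathreshold.train_range": (8, 11),  # spikes
    "eeg.window": 3.0,  # s
    "eeg.step": 0.015,  # s
    "eeg.threshold": 100.0,  # uV^2
    "morpho.sholl_increment": 20.6,  # um
    "ihc.n_bins": 20,
}


def make_config(overrides: dict | None = None) -> dict:
    """DEFAULT_CONFIG with overrides; unknown keys are rejected up front."""
    cfg = dict(DEFAULT_CONFIG)
    for key, value in (overrides or {}).items():
        if key not in cfg:
            raise KeyError(f"unknown configuration parameter {key!r}")
        cfg[key] = value
    return cfg


def holm_sidak_adjust(pvals) -> np.ndarray:
    """Step-down Holm-Sidak adjusted p-values, in the input order."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def classify_sweep(sweep: Sweep) -> str:
    """'step' for a piecewise-constant command, 'chirp' otherwise."""
    cmd = sweep.command.samples
    baseline = cmd[0]
    dev = cmd - baseline
    # a step command has at most one contiguous non-baseline block and
    # at most a couple of distinct levels; a chirp oscillates in sign
    sign_changes = int(np.sum(np.diff(np.sign(dev[np.abs(dev) > 1e-9])) != 0))
    return "chirp" if sign_changes > 4 else "step"


@dataclass
class CellReport:
    cell_id: str
    subthreshold: dict | None
    resonance: dict | None
    suprathreshold: dict | None
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        """Canonical JSON: sorted keys, fixed separators — byte-stable."""
        return json.dumps(asdict(self), sort_keys=True, separators=(",", ":"))


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return [float(v) for v in x]
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    return x


def run_cell_report(
    sweeps: SweepSet, config: dict | None = None, cell_id: str = "cell"
) -> CellReport:
    """Compose all per-cell stages into one deterministic report.

    Step sweeps feed the subthreshold and suprathreshold stages; the chirp
    sweep (if any) feeds the resonance stage.  Missing protocols give null
    sections.
    """
    cfg = make_config(config)
    kinds = [classify_sweep(sw) for sw in sweeps]
    step_sweeps = [sw for sw, k in zip(sweeps, kinds) if k == "step"]
    chirp_sweeps = [sw for sw, k in zip(sweeps, kinds) if k == "chirp"]

    sub = None
    supra = None
    if step_sweeps:
        steps = SweepSet(step_sweeps, metadata=sweeps.metadata)
        try:
            feats = extract_subthreshold(
                steps,
                current_range=cfg["subthreshold.current_range"],
                post_window=cfg["subthreshold.post_window"],
            )
            sub = _jsonable(asdict(feats))
        except ValueError:
            sub = None
        level = cfg["suprathreshold.level"]
        counts = [
            count_spikes_in_step(sw, level=level) if sw.epoch else 0
            for sw in steps
        ]
        selected = sorted(
            select_trains(steps, count_range=cfg["suprathreshold.train_range"],
                          level=level)
        )
        trains = {}
        for k in selected:
            times = detect_spikes(steps[k].voltage, level=level)
            trains[str(k)] = _jsonable(asdict(train_features(times)))
        supra = {
            "counts_per_sweep": counts,
            "amplitudes_pa": [
                sw.epoch.amplitude if sw.epoch else None for sw in steps
            ],
            "selected_trains": selected,
            "train_features": trains,
        }

    res = None
    if chirp_sweeps:
        sw = chirp_sweeps[0]
        profile = impedance_profile(
            sw.voltage, sw.command,
            band=tuple(cfg["resonance.band"]), mode=cfg["resonance.mode"],
        )
        _, peak, resonant = peak_resonance_frequency(
            profile, poly_order=cfg["resonance.poly_order"],
            band_low=cfg["resonance.band"][0],
        )
        res = {
            "peak_freq_hz": float(peak),
            "resonant": bool(resonant),
            "n_profile_points": int(profile.freqs.size),
            "z_at_peak_mohm": float(
                profile.z[int(np.argmin(np.abs(profile.freqs - peak)))]
            ),
        }

    digest = hashlib.sha256()
    for sw in sweeps:
        digest.update(np.ascontiguousarray(sw.voltage.samples).tobytes())
        digest.update(np.ascontiguousarray(sw.command.samples).tobytes())
    provenance = {
        "software_version": __version__,
        "input_sha256": digest.hexdigest(),
        "parameters": _jsonable(cfg),
    }
    return CellReport(
        cell_id=cell_id,
        subthreshold=sub,
        resonance=res,
        suprathreshold=supra,
        provenance=provenance,
    )
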