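"""Domain types, unit conventions, and file readers/writers.

Canonical units throughout the package: membrane potential in mV, injected
current in pA, time in ms, EEG voltage in uV, distance in um, impedance in
MOhm, frequency in Hz.  A slope of mV per pA is numerically GOhm, so input
resistance in MOhm is 1000 x the mV/pA slope; that conversion is stated here
once and reused everywhere.

Time series are stored as (t0, dt, samples) rather than an explicit time
column, which makes resampling inconsistencies unrepresentable.  The liquid
junction potential is never applied to any voltage; if known it may be
recorded in ``SweepSet.metadata`` as documentation only.

Greek unit glyphs are accepted on input and normalised to ASCII ("uV", "um").
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Trace",
    "StepEpoch",
    "Sweep",
    "SweepSet",
    "EEGRecord",
    "Morphology",
    "GrayImage",
    "FormatError",
    "UnitError",
    "read_sweep_table",
    "write_sweep_table",
    "read_swc",
    "write_swc",
    "read_eeg_record",
    "write_eeg_record",
    "read_gray_image",
]

#: units a Trace may carry
UNITS = ("mV", "pA", "uV")

_UNIT_ALIASES = {"μV": "uV", "µV": "uV", "uv": "uV", "mv": "mV", "pa": "pA"}


class FormatError(ValueError):
    """A file does not conform to its documented format."""


class UnitError(ValueError):
    """An operation received a Trace with the wrong unit tag."""


def _normalize_unit(unit: str) -> str:
    unit = _UNIT_ALIASES.get(unit, unit)
    if unit not in UNITS:
        raise UnitError(f"unknown unit {unit!r}; expected one of {UNITS}")
    return unit


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled scalar time series.

    Parameters
    ----------
    samples : array-like
        Sample values in the declared unit.
    dt : float
        Sampling interval, ms.
    t0 : float
        Time of the first sample, ms.
    unit : str
        One of ``"mV"``, ``"pA"``, ``"uV"`` (Greek glyphs accepted).
    """

    samples: np.ndarray
    dt: float
    t0: float = 0.0
    unit: str = "mV"

    def __post_init__(self):
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(arr)):
            raise ValueError("samples must be finite")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "unit", _normalize_unit(self.unit))

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Span covered by the samples, ms (n * dt)."""
        return self.n * self.dt

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms, reconstructed from (t0, dt, n)."""
        return self.t0 + self.dt * np.arange(self.n)

    def require_unit(self, unit: str) -> "Trace":
        unit = _normalize_unit(unit)
        if self.unit != unit:
            raise UnitError(f"expected a {unit} trace, got {self.unit}")
        return self

    def index_at(self, t_ms: float) -> int:
        """Nearest sample index for time ``t_ms`` (clipped to range)."""
        i = int(round((t_ms - self.t0) / self.dt))
        return min(max(i, 0), self.n - 1)

    def slice_time(self, start_ms: float, stop_ms: float) -> np.ndarray:
        """Samples with t0 + i*dt in [start_ms, stop_ms)."""
        i0 = int(np.ceil((start_ms - self.t0) / self.dt - 1e-9))
        i1 = int(np.ceil((stop_ms - self.t0) / self.dt - 1e-9))
        i0, i1 = max(i0, 0), min(max(i1, 0), self.n)
        if i1 <= i0:
            raise ValueError(f"empty window [{start_ms}, {stop_ms}) ms")
        return self.samples[i0:i1]


@dataclass(frozen=True)
class StepEpoch:
    """A rectangular current step: onset and duration in ms, amplitude in pA."""

    onset: float
    duration: float
    amplitude: float

    def __post_init__(self):
        if not self.duration > 0:
            raise ValueError("step duration must be positive")
        if self.onset < 0:
            raise ValueError("step onset must be non-negative")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class Sweep:
    """One recorded sweep: voltage response, command current, step metadata."""

    voltage: Trace
    command: Trace
    epoch: StepEpoch | None = None

    def __post_init__(self):
        self.voltage.require_unit("mV")
        self.command.require_unit("pA")
        if self.voltage.n != self.command.n or self.voltage.dt != self.command.dt:
            raise ValueError("voltage and command must share dt and length")
        if self.epoch is not None and self.epoch.offset > self.voltage.duration + 1e-9:
            raise ValueError("step epoch extends past the end of the trace")


class SweepSet:
    """An ordered family of sweeps sharing sampling rate and length.

    ``metadata`` is a free-form key/value store (e.g. cell id, holding
    potential, the uncorrected liquid-junction potential).
    """

    def __init__(self, sweeps, metadata: dict | None = None):
        sweeps = list(sweeps)
        if not sweeps:
            raise ValueError("SweepSet requires at least one sweep")
        dt0, n0 = sweeps[0].voltage.dt, sweeps[0].voltage.n
        for k, sw in enumerate(sweeps):
            if sw.voltage.dt != dt0:
                raise ValueError(f"sweep {k} has dt {sw.voltage.dt}, expected {dt0}")
            if sw.voltage.n != n0:
                raise ValueError(f"sweep {k} has {sw.voltage.n} samples, expected {n0}")
        self.sweeps = sweeps
        self.metadata = dict(metadata or {})

    def __len__(self) -> int:
        return len(self.sweeps)

    def __getitem__(self, i) -> Sweep:
        return self.sweeps[i]

    def __iter__(self):
        return iter(self.sweeps)

    @property
    def dt(self) -> float:
        return self.sweeps[0].voltage.dt

    @property
    def fs_hz(self) -> float:
        return 1000.0 / self.dt


@dataclass
class EEGRecord:
    """Named EEG channels in uV, all the same length, sampled at ``fs`` Hz."""

    channels: dict  # name -> Trace (uV)
    fs: float

    def __post_init__(self):
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not self.channels:
            raise ValueError("EEGRecord requires at least one channel")
        lengths = {tr.n for tr in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError("all channels must have equal length")
        for name, tr in self.channels.items():
            tr.require_unit("uV")

    @property
    def n(self) -> int:
        return next(iter(self.channels.values())).n

    @property
    def duration_s(self) -> float:
        return self.n / self.fs


@dataclass(frozen=True)
class SWCNode:
    id: int
    type: int
    x: float
    y: float
    z: float
    radius: float
    parent: int


class Morphology:
    """An SWC-derived neuronal tree.

    Node type codes follow the SWC convention: 1 soma, 2 axon, 3 basal
    dendrite, 4 apical dendrite.  "Dendrite" throughout the package means
    type in {3, 4}.
    """

    DENDRITE_TYPES = frozenset({3, 4})

    def __init__(self, nodes):
        nodes = list(nodes)
        if not nodes:
            raise ValueError("Morphology requires at least one node")
        ids = [n.id for n in nodes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate node ids")
        seen = set()
        roots = []
        for n in nodes:
            if n.radius < 0:
                raise ValueError(f"node {n.id} has negative radius")
            if n.parent == -1:
                roots.append(n.id)
            elif n.parent not in seen:
                raise ValueError(
                    f"node {n.id} references parent {n.parent} "
                    "which does not precede it"
                )
            seen.add(n.id)
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        self.nodes = nodes
        self._by_id = {n.id: n for n in nodes}
        self.root_id = roots[0]

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, node_id: int) -> SWCNode:
        return self._by_id[node_id]

    @property
    def soma(self) -> SWCNode:
        return self._by_id[self.root_id]

    def xyz(self, node_id: int) -> np.ndarray:
        n = self._by_id[node_id]
        return np.array([n.x, n.y, n.z])

    def segments(self, types=None):
        """Yield (parent_node, child_node) chords, filtered by child type."""
        for n in self.nodes:
            if n.parent == -1:
                continue
            if types is not None and n.type not in types:
                continue
            yield self._by_id[n.parent], n

    def dendrite_segments(self):
        return self.segments(types=self.DENDRITE_TYPES)


@dataclass(frozen=True)
class GrayImage:
    """A 16-bit grayscale image: non-negative integers, 0 = black.

    A lighter signal indicates more protein in the immunostain convention.
    """

    pixels: np.ndarray
    pixel_size_um: float | None = None

    def __post_init__(self):
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError("pixels must be a 2-D grid")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("pixels must be integer-valued")
        if arr.min() < 0 or arr.max() > 65535:
            raise ValueError("pixel values must lie in [0, 65535]")
        object.__setattr__(self, "pixels", arr.astype(np.uint16))

    @property
    def shape(self):
        return self.pixels.shape


# ---------------------------------------------------------------------------
# Sweep-table CSV
#
# One CSV per SweepSet.  Header comment lines carry the shared protocol:
#   # fs_hz=<float>
#   # step_onset_ms=<float>
#   # step_duration_ms=<float>
# Body columns: sweep, amplitude_pa, sample_index, voltage_mv, command_pa.
# ---------------------------------------------------------------------------

_SWEEP_COLUMNS = ["sweep", "amplitude_pa", "sample_index", "voltage_mv", "command_pa"]


def write_sweep_table(path, sweeps: SweepSet) -> None:
    """Write a SweepSet as the documented sweep-table CSV."""
    rows = []
    for k, sw in enumerate(sweeps):
        amp = sw.epoch.amplitude if sw.epoch is not None else 0.0
        idx = np.arange(sw.voltage.n)
        rows.append(
            pd.DataFrame(
                {
                    "sweep": k,
                    "amplitude_pa": amp,
                    "sample_index": idx,
                    "voltage_mv": sw.voltage.samples,
                    "command_pa": sw.command.samples,
                }
            )
        )
    body = pd.concat(rows, ignore_index=True)
    ep = sweeps[0].epoch
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={sweeps.fs_hz!r}\n")
        if ep is not None:
            fh.write(f"# step_onset_ms={ep.onset!r}\n")
            fh.write(f"# step_duration_ms={ep.duration!r}\n")
        body.to_csv(fh, index=False, float_format="%.17g")


def _parse_header_fields(path):
    fields = {}
    n_comment = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_comment += 1
            text = line[1:].strip()
            if "=" in text:
                key, _, val = text.partition("=")
                fields[key.strip()] = val.strip()
    return fields, n_comment


def read_sweep_table(path) -> SweepSet:
    """Read a sweep-table CSV into a SweepSet.

    Raises :class:`FormatError` naming the offending field for missing
    columns, mixed sampling rates, or malformed headers.
    """
    if os.path.getsize(path) == 0:
        raise FormatError(f"{path}: empty file")
    header, n_comment = _parse_header_fields(path)
    if "fs_hz" not in header:
        raise FormatError(f"{path}: missing '# fs_hz=' header")
    try:
        fs = float(header["fs_hz"])
    except ValueError:
        raise FormatError(f"{path}: fs_hz is not numeric: {header['fs_hz']!r}")
    if fs <= 0:
        raise FormatError(f"{path}: fs_hz must be positive")
    try:
        body = pd.read_csv(path, skiprows=n_comment)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: unreadable CSV body: {exc}") from exc
    missing = [c for c in _SWEEP_COLUMNS if c not in body.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for col in _SWEEP_COLUMNS:
        if not np.issubdtype(body[col].dtype, np.number):
            raise FormatError(f"{path}: column {col!r} contains non-numeric data")
    if body[_SWEEP_COLUMNS].isna().any().any():
        raise FormatError(f"{path}: missing values in body")

    dt = 1000.0 / fs
    epoch = None
    if "step_onset_ms" in header and "step_duration_ms" in header:
        onset = float(header["step_onset_ms"])
        duration = float(header["step_duration_ms"])
    else:
        onset = duration = None

    sweeps = []
    for k, grp in body.groupby("sweep", sort=True):
        grp = grp.sort_values("sample_index")
        idx = grp["sample_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise FormatError(
                f"{path}: sweep {k}: sample_index must be 0..n-1 without gaps"
            )
        amps = grp["amplitude_pa"].unique()
        if len(amps) != 1:
            raise FormatError(f"{path}: sweep {k}: mixed amplitude_pa values")
        ep = None
        if onset is not None:
            ep = StepEpoch(onset=onset, duration=duration, amplitude=float(amps[0]))
        sweeps.append(
            Sweep(
                voltage=Trace(grp["voltage_mv"].to_numpy(), dt=dt, unit="mV"),
                command=Trace(grp["command_pa"].to_numpy(), dt=dt, unit="pA"),
                epoch=ep,
            )
        )
    try:
        return SweepSet(sweeps, metadata=dict(header))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------


def read_swc(path) -> Morphology:
    """Read a standard whitespace-delimited 7-column SWC file.

    '#' comment lines are skipped.  Parse errors carry the 1-based line
    number of the offending row.
    """
    nodes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.split()
            if len(parts) < 7:
                raise FormatError(
                    f"{path}:{lineno}: expected 7 columns, got {len(parts)}"
                )
            try:
                nid = int(parts[0])
                ntype = int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field: {exc}")
            nodes.append(SWCNode(nid, ntype, x, y, z, r, parent))
    if not nodes:
        raise FormatError(f"{path}: no SWC records")
    try:
        return Morphology(nodes)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_swc(path, m: Morphology) -> None:
    with open(path, "w") as fh:
        for n in m.nodes:
            fh.write(
                f"{n.id} {n.type} {n.x:.17g} {n.y:.17g} {n.z:.17g} "
                f"{n.radius:.17g} {n.parent}\n"
            )


# ---------------------------------------------------------------------------
# EEG CSV
# ---------------------------------------------------------------------------


def read_eeg_record(path, fs: float) -> EEGRecord:
    """Read an EEG CSV (header row = channel names, body in uV)."""
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise FormatError(f"{path}: empty file")
        names = [c.strip() for c in header_line.rstrip("\n").split(",")]
        data = [[] for _ in names]
        for rowno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split(",")
            if len(cells) != len(names):
                raise FormatError(
                    f"{path}: row {rowno}: expected {len(names)} cells, "
                    f"got {len(cells)}"
                )
            for j, cell in enumerate(cells):
                if cell.strip() == "":
                    raise FormatError(f"{path}: row {rowno}: missing cell")
                try:
                    data[j].append(float(cell))
                except ValueError:
                    raise FormatError(
                        f"{path}: row {rowno}: non-numeric cell {cell!r}"
                    )
    if not data[0]:
        raise FormatError(f"{path}: no samples")
    dt = 1000.0 / fs
    channels = {
        name: Trace(np.asarray(col), dt=dt, unit="uV")
        for name, col in zip(names, data)
    }
    return EEGRecord(channels=channels, fs=fs)


def write_eeg_record(path, rec: EEGRecord) -> None:
    names = list(rec.channels)
    arr = np.column_stack([rec.channels[n].samples for n in names])
    pd.DataFrame(arr, columns=names).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------


def read_gray_image(path, pixel_size_um: float | None = None) -> GrayImage:
    """Read a 16-bit grayscale TIFF or PNG."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected single-channel grayscale image")
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"{path}: expected integer pixel data")
    return GrayImage(pixels=arr.astype(np.uint16), pixel_size_um=pixel_size_um)
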