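"""Readers, writers, domain-type invariants, and unit discipline."""

import numpy as np
import pytest

from dvca1 import core
from dvca1.core import (
    FormatError,
    Morphology,
    StepEpoch,
    Sweep,
    SweepSet,
    SWCNode,
    Trace,
    UnitError,
)

from conftest import make_resistor_family


class TestTrace:
    def test_invariants(self):
        with pytest.raises(ValueError):
            Trace([], dt=0.1)
        with pytest.raises(ValueError):
            Trace([1.0], dt=0.0)
        with pytest.raises(UnitError):
            Trace([1.0], dt=0.1, unit="volts")

    def test_greek_unit_glyph_normalised(self):
        assert Trace([1.0], dt=0.1, unit="μV").unit == "uV"

    def test_unit_discipline_fails_before_computing(self):
        from dvca1.subthreshold import resting_membrane_potential

        current = Trace(np.zeros(100), dt=1.0, unit="pA")
        with pytest.raises(UnitError):
            resting_membrane_potential(current, baseline=(0, 50))

    def test_times_reconstructed_from_t0_dt(self):
        tr = Trace(np.zeros(5), dt=0.5, t0=10.0)
        assert np.allclose(tr.times, [10.0, 10.5, 11.0, 11.5, 12.0])


class TestSweepTable:
    def test_round_trip_identity(self, tmp_path):
        fam = make_resistor_family()
        path = tmp_path / "sweeps.csv"
        core.write_sweep_table(path, fam)
        back = core.read_sweep_table(path)
        assert len(back) == len(fam)
        for a, b in zip(fam, back):
            np.testing.assert_allclose(
                a.voltage.samples, b.voltage.samples, rtol=1e-9
            )
            np.testing.assert_allclose(
                a.command.samples, b.command.samples, rtol=1e-9
            )
            assert b.epoch.amplitude == a.epoch.amplitude
        assert back.dt == pytest.approx(fam.dt)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(FormatError, match="empty"):
            core.read_sweep_table(path)

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "# fs_hz=1000\nsweep,amplitude_pa,sample_index,voltage_mv\n"
            "0,10,0,-65\n"
        )
        with pytest.raises(FormatError, match="command_pa"):
            core.read_sweep_table(path)

    def test_missing_fs_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "sweep,amplitude_pa,sample_index,voltage_mv,command_pa\n0,0,0,-65,0\n"
        )
        with pytest.raises(FormatError, match="fs_hz"):
            core.read_sweep_table(path)

    def test_mixed_sampling_rate_rejected(self):
        # two sweeps with different dt cannot form a SweepSet
        a = make_resistor_family(dt=0.2)[0]
        b = make_resistor_family(dt=0.4)[0]
        with pytest.raises(ValueError, match="dt"):
            SweepSet([a, b])

    def test_non_numeric_cell_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "# fs_hz=1000\n"
            "sweep,amplitude_pa,sample_index,voltage_mv,command_pa\n"
            "0,10,0,oops,0\n"
        )
        with pytest.raises(FormatError, match="voltage_mv"):
            core.read_sweep_table(path)


class TestSWC:
    def test_single_soma(self, tmp_path):
        path = tmp_path / "soma.swc"
        path.write_text("# comment\n1 1 0 0 0 5 -1\n")
        m = core.read_swc(path)
        assert len(m) == 1
        assert m.soma.type == 1
        assert m.root_id == 1

    def test_collinear_dendrite_path_length(self, tmp_path):
        lines = ["1 1 0 0 0 5 -1"]
        for k in range(1, 6):
            lines.append(f"{k + 1} 3 {20 * k} 0 0 1 {k}")
        path = tmp_path / "line.swc"
        path.write_text("\n".join(lines) + "\n")
        m = core.read_swc(path)
        assert len(m) == 6
        from dvca1.morphometry import total_dendritic_length

        assert total_dendritic_length(m) == pytest.approx(100.0)

    def test_dangling_parent_rejected(self, tmp_path):
        path = tmp_path / "bad.swc"
        path.write_text("1 1 0 0 0 5 -1\n2 3 10 0 0 1 99\n")
        with pytest.raises(FormatError, match="parent 99"):
            core.read_swc(path)

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "bad.swc"
        path.write_text("1 1 0 0 0 5 -1\n1 3 10 0 0 1 1\n")
        with pytest.raises(FormatError, match="duplicate"):
            core.read_swc(path)

    def test_short_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.swc"
        path.write_text("1 1 0 0 0 5 -1\n2 3 10 0\n")
        with pytest.raises(FormatError, match=":2"):
            core.read_swc(path)

    def test_write_read_round_trip(self, tmp_path):
        from dvca1.synth import synth_morphology

        m = synth_morphology(depth=3, seed=7)
        path = tmp_path / "tree.swc"
        core.write_swc(path, m)
        back = core.read_swc(path)
        assert len(back) == len(m)
        for a, b in zip(m.nodes, back.nodes):
            assert (a.id, a.type, a.parent) == (b.id, b.type, b.parent)
            np.testing.assert_allclose(
                [a.x, a.y, a.z, a.radius], [b.x, b.y, b.z, b.radius], rtol=1e-9
            )

    def test_two_roots_rejected(self):
        nodes = [
            SWCNode(1, 1, 0, 0, 0, 5, -1),
            SWCNode(2, 1, 10, 0, 0, 5, -1),
        ]
        with pytest.raises(ValueError, match="one root"):
            Morphology(nodes)


class TestEEGCSV:
    def test_duration_from_fs(self, tmp_path):
        path = tmp_path / "eeg.csv"
        path.write_text("ch1\n" + "\n".join(["0.0"] * 2400) + "\n")
        rec = core.read_eeg_record(path, fs=800.0)
        assert rec.duration_s == pytest.approx(3.0)

    def test_channel_names_preserved_in_order(self, tmp_path):
        path = tmp_path / "eeg.csv"
        path.write_text("frontal,parietal,ref\n1,2,3\n4,5,6\n")
        rec = core.read_eeg_record(path, fs=800.0)
        assert list(rec.channels) == ["frontal", "parietal", "ref"]
        assert rec.channels["parietal"].samples.tolist() == [2.0, 5.0]

    def test_ragged_row_reports_index(self, tmp_path):
        path = tmp_path / "eeg.csv"
        path.write_text("a,b\n1,2\n3\n")
        with pytest.raises(FormatError, match="row 3"):
            core.read_eeg_record(path, fs=800.0)

    def test_round_trip(self, tmp_path):
        from dvca1.synth import synth_eeg

        rec, _ = synth_eeg(duration=2.0, background_rms=3.0, seed=4)
        path = tmp_path / "eeg.csv"
        core.write_eeg_record(path, rec)
        back = core.read_eeg_record(path, fs=rec.fs)
        np.testing.assert_allclose(
            back.channels["ch1"].samples,
            rec.channels["ch1"].samples,
            rtol=1e-9,
            atol=1e-12,
        )


class TestStepEpoch:
    def test_epoch_must_fit_trace(self):
        v = Trace(np.zeros(100), dt=1.0, unit="mV")
        c = Trace(np.zeros(100), dt=1.0, unit="pA")
        with pytest.raises(ValueError, match="past the end"):
            Sweep(v, c, StepEpoch(onset=50.0, duration=200.0, amplitude=10.0))

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            StepEpoch(onset=0.0, duration=-1.0, amplitude=10.0)


class TestGrayImage:
    def test_value_range_enforced(self):
        with pytest.raises(ValueError):
            core.GrayImage(np.array([[-1, 0]], dtype=np.int32))
        with pytest.raises(ValueError):
            core.GrayImage(np.array([[70000]], dtype=np.int64))

    def test_tiff_round_trip(self, tmp_path):
        import tifffile

        arr = np.arange(12, dtype=np.uint16).reshape(3, 4) * 1000
        path = tmp_path / "img.tif"
        tifffile.imwrite(path, arr)
        img = core.read_gray_image(path)
        np.testing.assert_array_equal(img.pixels, arr)
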