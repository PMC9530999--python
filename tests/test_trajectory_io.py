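"""Structure/trajectory reading, unit conversion, and frame selection."""

import numpy as np
import pytest

import hjdimer as h
from hjdimer.errors import ConfigurationError, FormatError, FrameConsistencyError


def pdb_line(serial, name, resname, chain, resid, x, y, z, element):
    return (
        f"ATOM  {serial:5d} {name:<4s}{resname:>4s} {chain}{resid:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


@pytest.fixture
def tiny_pdb(tmp_path):
    lines = [
        pdb_line(1, "N1", "CY5", "A", 1, 14.0, 0.0, 0.0, "N"),
        pdb_line(2, "N2", "CY5", "A", 1, 0.0, 2.5, 0.0, "N"),
        "END",
    ]
    path = tmp_path / "tiny.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


def test_read_structure_converts_angstrom_to_nm(tiny_pdb):
    topology, coords = h.read_structure(tiny_pdb)
    assert topology.n_atoms == 2
    assert coords[0] == pytest.approx([1.4, 0.0, 0.0])
    assert coords[1] == pytest.approx([0.0, 0.25, 0.0])
    assert list(topology.atom_names) == ["N1", "N2"]
    assert list(topology.chain_ids) == ["A", "A"]


def test_read_structure_empty_file_is_format_error(tmp_path):
    path = tmp_path / "empty.pdb"
    path.write_text("")
    with pytest.raises(FormatError):
        h.read_structure(path)


def test_read_structure_preserves_residue_numbering(tmp_path):
    """Residue numbers come from the file verbatim: 1-based, no renumbering."""
    topo, _, _ = h.generate_mock_junction("IsoI", "transverse", n_frames=1)
    path = tmp_path / "mock.pdb"
    h.write_structure(topo, np.zeros((topo.n_atoms, 3)), path)
    reread, _ = h.read_structure(path)
    strands = reread.strands()
    assert set(strands) == {"A", "B", "C", "D"}
    for chain in "ABCD":
        assert strands[chain][:26] == list(range(1, 27))


def test_mock_junction_topology_has_four_26_residue_strands():
    topo, _, _ = h.generate_mock_junction("IsoI", "transverse", n_frames=1)
    strands = topo.strands()
    for chain in "ABCD":
        base_ids = [r for r in strands[chain] if r <= 26]
        assert base_ids == list(range(1, 27))


def test_multi_model_pdb_roundtrip(tmp_path):
    spec = h.SyntheticSpec(mode="H_dimer", n_frames=10, dt_ps=10.0, seed=5)
    traj, _ = h.generate_dimer_trajectory(spec)
    path = tmp_path / "traj.pdb"
    h.write_trajectory(traj, path, format="pdb")
    reread = h.read_trajectory(traj.topology, path, format="pdb", dt_ps=10.0)
    assert reread.n_frames == 10
    assert reread.times[0] == 0.0 and reread.times[-1] == 90.0
    # PDB keeps 3 decimals in Angstrom, i.e. 1e-4 nm round-trip precision
    assert np.abs(reread.coords - traj.coords).max() < 1e-3


def test_multi_model_pdb_requires_dt(tmp_path):
    spec = h.SyntheticSpec(mode="H_dimer", n_frames=3, seed=5)
    traj, _ = h.generate_dimer_trajectory(spec)
    path = tmp_path / "traj.pdb"
    h.write_trajectory(traj, path, format="pdb")
    with pytest.raises(ConfigurationError):
        h.read_trajectory(traj.topology, path, format="pdb")


def test_frames_format_roundtrip_is_bit_identical(tmp_path):
    spec = h.SyntheticSpec(mode="H_dimer", n_frames=25, seed=7)
    traj, _ = h.generate_dimer_trajectory(spec)
    path = tmp_path / "traj.frames"
    h.write_trajectory(traj, path, format="frames")
    reread = h.read_trajectory(traj.topology, path, format="frames")
    assert np.array_equal(reread.coords, traj.coords)
    assert reread.dt == traj.dt
    # writing the reread trajectory reproduces the file byte for byte
    path2 = tmp_path / "traj2.frames"
    h.write_trajectory(reread, path2, format="frames")
    assert path.read_bytes() == path2.read_bytes()


def test_pdb_frame_atom_count_mismatch_names_frame(tmp_path):
    blocks = []
    for i in range(4):
        blocks.append(f"MODEL     {i+1}")
        blocks.append(pdb_line(1, "N1", "CY5", "A", 1, 1.0, 0.0, 0.0, "N"))
        if i != 2:  # frame index 2 misses its second atom
            blocks.append(pdb_line(2, "N2", "CY5", "A", 1, 0.0, 1.0, 0.0, "N"))
        blocks.append("ENDMDL")
    path = tmp_path / "bad.pdb"
    path.write_text("\n".join(blocks) + "\n")
    topology, _ = h.read_structure(path)  # first model has 2 atoms
    with pytest.raises(FrameConsistencyError, match="frame 2"):
        h.read_trajectory(topology, path, format="pdb", dt_ps=10.0)


def test_frames_format_incomplete_frame_names_frame(tmp_path):
    path = tmp_path / "bad.frames"
    path.write_text("2 10\n0 0 0\n1 0 0\n0 0 0\n")  # frame 1 has 1/2 atoms
    spec = h.SyntheticSpec(mode="H_dimer", n_frames=2, seed=1)
    traj, _ = h.generate_dimer_trajectory(spec)
    two_atom = h.Topology(
        atom_names=traj.topology.atom_names[:2],
        elements=traj.topology.elements[:2],
        res_names=traj.topology.res_names[:2],
        res_ids=traj.topology.res_ids[:2],
        chain_ids=traj.topology.chain_ids[:2],
    )
    with pytest.raises(FrameConsistencyError, match="frame 1"):
        h.read_trajectory(two_atom, path, format="frames")


class TestSelectFrames:
    def _traj(self, n_frames, dt):
        topo = h.Topology(
            atom_names=np.array(["X"]),
            elements=np.array(["C"]),
            res_names=np.array(["DN"]),
            res_ids=np.array([1]),
            chain_ids=np.array(["A"]),
        )
        return h.Trajectory(
            topology=topo,
            times=np.arange(n_frames) * float(dt),
            coords=np.zeros((n_frames, 1, 3)),
        )

    def test_basic_stride(self):
        traj = self._traj(1000, 10.0)
        sub = h.select_frames(traj, burn_in=0.0, stride=100.0)
        assert sub.n_frames == 100
        assert sub.times[0] == 0.0 and sub.times[-1] == 9900.0

    def test_production_protocol_counts(self):
        """1 us written every 10 ps, minus 100 ns burn-in: 9001 orientation
        frames at 100 ps and 1801 contact frames at 500 ps."""
        traj = self._traj(100001, 10.0)
        assert h.select_frames(traj, burn_in=1e5, stride=100.0).n_frames == 9001
        assert h.select_frames(traj, burn_in=1e5, stride=500.0).n_frames == 1801

    def test_idempotent(self):
        traj = self._traj(500, 10.0)
        once = h.select_frames(traj, burn_in=1000.0, stride=50.0)
        twice = h.select_frames(once, burn_in=1000.0, stride=50.0)
        assert np.array_equal(once.times, twice.times)
        assert np.array_equal(once.coords, twice.coords)

    def test_burn_in_beyond_end_gives_empty_and_downstream_refuses(self):
        traj = self._traj(100, 10.0)
        sub = h.select_frames(traj, burn_in=5000.0, stride=10.0)
        assert sub.n_frames == 0
        spec = h.SyntheticSpec(mode="H_dimer", n_frames=10, seed=0)
        dtraj, _ = h.generate_dimer_trajectory(spec)
        from hjdimer.synthetic_data import dimer_dye_definitions

        dm, dn = dimer_dye_definitions(spec)
        with pytest.raises(h.AnalysisError):
            h.observe_dimer(dtraj, dm, dn, burn_in=1e9)

    def test_stride_not_multiple_of_dt_rejected(self):
        traj = self._traj(100, 10.0)
        with pytest.raises(ConfigurationError):
            h.select_frames(traj, stride=15.0)
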