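"""Residue-group construction and contact-map computation."""

import numpy as np
import pytest

import hjdimer as h
from hjdimer.contacts import ResidueGroup, build_groups, contact_map, in_contact
from hjdimer.errors import AnalysisError, TopologyError
from hjdimer.synthetic_data import mock_junction_dyes


@pytest.fixture(scope="module")
def mock_system():
    topo, traj, _ = h.generate_mock_junction("IsoI", "transverse", n_frames=5)
    dyes = mock_junction_dyes("IsoI", "transverse")
    return topo, traj, dyes


def point_group(label, idx, masses):
    return ResidueGroup(
        label=label, kind="base",
        atom_indices=np.asarray(idx), masses=np.asarray(masses, float),
    )


class TestBuildGroups:
    def test_26_groups_on_mock_junction(self, mock_system):
        topo, _, dyes = mock_system
        groups = build_groups(topo, dyes)
        assert len(groups) == 26
        labels = [g.label for g in groups]
        assert "13A" in labels and "16D" in labels
        assert "Cy5_A" in labels and "Cy5_C" in labels
        assert sum(g.kind == "dye" for g in groups) == 2

    def test_narrow_window_counts(self, mock_system):
        topo, _, dyes = mock_system
        groups = build_groups(topo, dyes, center_window=(12, 13))
        assert len(groups) == 4 * 2 + 2

    def test_dye_inside_window_is_excluded_from_base_groups(self):
        # a dye residue sitting inside the 11-16 window must be its own
        # group, not double-counted as the base "13A"
        names, elements, res_names, res_ids, chains = [], [], [], [], []
        for chain in "ABCD":
            for rid in range(11, 17):
                if chain == "A" and rid == 13:
                    for nm, el in (("N1", "N"), ("N2", "N")):
                        names.append(nm); elements.append(el)
                        res_names.append("CY5"); res_ids.append(rid)
                        chains.append(chain)
                else:
                    names.append("C1"); elements.append("C")
                    res_names.append("DN"); res_ids.append(rid)
                    chains.append(chain)
        topo = h.Topology(
            atom_names=np.array(names), elements=np.array(elements),
            res_names=np.array(res_names), res_ids=np.array(res_ids),
            chain_ids=np.array(chains),
        )
        dye = h.DyeDefinition(label="Cy5_A", chain="A", res_id=13)
        groups = build_groups(topo, [dye])
        labels = [g.label for g in groups]
        assert "13A" not in labels
        assert "Cy5_A" in labels
        assert len(groups) == 4 * 6 - 1 + 1

    def test_missing_window_residue_names_strand_and_number(self, mock_system):
        topo, _, dyes = mock_system
        with pytest.raises(TopologyError, match="strand A.*residue 30"):
            build_groups(topo, dyes, center_window=(30, 31))


class TestInContact:
    def test_com_distance_threshold(self):
        frame = np.array([[0.0, 0, 0], [1.0, 0, 0], [1.3, 0, 0]])
        g0 = point_group("a", [0], [12.0])
        g1 = point_group("b", [1], [12.0])
        g2 = point_group("c", [2], [12.0])
        assert in_contact(frame, g0, g1, cutoff=1.2)
        assert not in_contact(frame, g0, g2, cutoff=1.2)

    def test_boundary_is_closed(self):
        frame = np.array([[0.0, 0, 0], [1.2, 0, 0]])
        g0 = point_group("a", [0], [12.0])
        g1 = point_group("b", [1], [12.0])
        assert in_contact(frame, g0, g1, cutoff=1.2)

    def test_dye_end_reaches_while_com_is_far(self):
        # dye along x: ends at 0 and 2.8, COM atom geometry puts whole-dye
        # COM at 1.4; base at x = 3.9: COM-COM = 2.5 but end-to-base = 1.1
        frame = np.array([[0.0, 0, 0], [2.8, 0, 0], [1.4, 0, 0], [3.9, 0, 0]])
        dye = ResidueGroup(
            label="dye", kind="dye",
            atom_indices=np.array([0, 1, 2]),
            masses=np.array([14.0, 14.0, 12.0]),
            end_r_indices=np.array([0]),
            end_s_indices=np.array([1]),
        )
        base = point_group("base", [3], [12.0])
        # brute-force min over representative points
        pts = dye.representative_points(frame)
        dists = np.linalg.norm(pts - frame[3], axis=1)
        assert dists.min() == pytest.approx(1.1)
        assert in_contact(frame, dye, base, cutoff=1.2)
        assert not in_contact(frame, dye, base, cutoff=1.0)


class TestContactMap:
    def test_static_frames_give_exact_binary_entries(self, mock_system):
        topo, traj, dyes = mock_system
        groups = build_groups(topo, dyes)
        cmap = contact_map(traj, groups, stride=None)
        frame = traj.coords[0]
        for i in range(len(groups)):
            for j in range(len(groups)):
                expected = 1.0 if (i == j or in_contact(frame, groups[i], groups[j])) else 0.0
                assert cmap.matrix[i, j] == expected

    def test_symmetry_diagonal_bounds(self, mock_system):
        topo, traj, dyes = mock_system
        cmap = contact_map(traj, build_groups(topo, dyes), stride=None)
        assert np.array_equal(cmap.matrix, cmap.matrix.T)
        assert np.all(np.diag(cmap.matrix) == 1.0)
        assert cmap.matrix.min() >= 0.0 and cmap.matrix.max() <= 1.0

    def test_monotone_in_cutoff(self):
        topo, traj, _ = h.generate_mock_junction(
            "IsoI", "transverse", n_frames=20, seed=4, jitter_sd_nm=0.05
        )
        groups = build_groups(topo, mock_junction_dyes("IsoI", "transverse"))
        lo = contact_map(traj, groups, cutoff=0.9, stride=None)
        hi = contact_map(traj, groups, cutoff=1.2, stride=None)
        assert np.all(hi.matrix >= lo.matrix)

    def test_constructed_contact_fraction_recovered(self):
        """Two single-atom groups inside the cutoff in exactly 40% of frames."""
        topo = h.Topology(
            atom_names=np.array(["X", "Y"]),
            elements=np.array(["C", "C"]),
            res_names=np.array(["DN", "DN"]),
            res_ids=np.array([1, 2]),
            chain_ids=np.array(["A", "A"]),
        )
        n = 50
        coords = np.zeros((n, 2, 3))
        coords[:, 1, 0] = 2.0   # apart by default
        coords[:20, 1, 0] = 1.0  # first 40% of frames: in contact
        traj = h.Trajectory(topology=topo, times=np.arange(n) * 10.0, coords=coords)
        groups = [
            point_group("g1", [0], [12.0]),
            point_group("g2", [1], [12.0]),
        ]
        cmap = contact_map(traj, groups, cutoff=1.2, stride=None)
        assert cmap.entry("g1", "g2") == pytest.approx(0.4)

    def test_pooling_is_frame_count_weighted(self, mock_system):
        topo, _, dyes = mock_system
        _, t1, _ = h.generate_mock_junction("IsoI", "transverse", n_frames=10)
        _, t2, _ = h.generate_mock_junction("IsoII", "transverse", n_frames=30)
        groups = build_groups(topo, dyes)
        pooled = contact_map([t1, t2], groups, stride=None)
        # IsoI frames have the dye pair in contact, IsoII frames do not
        assert pooled.entry("Cy5_A", "Cy5_C") == pytest.approx(10 / 40)
        assert pooled.n_frames_used == 40

    def test_empty_frame_set_rejected(self, mock_system):
        topo, traj, dyes = mock_system
        groups = build_groups(topo, dyes)
        with pytest.raises(AnalysisError):
            contact_map(traj, groups, stride=None, burn_in=1e9)
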