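"""Structural observables: RMSD traces, H-bonds, SASA, dihedrals, RMSD maps."""

from math import degrees

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import pathmetad as pm
from pathmetad.analysis import VDW_RADII, dihedral_angle
from pathmetad.core import AtomSelection, Structure, Trajectory
from pathmetad.errors import RadiusTableError, SelectionError, TopologyError


class TestElementRmsdTrace:
    def test_copies_give_zero(self, two_state):
        ref = two_state.state_a
        traj = Trajectory([ref] * 4)
        element = pm.ElementDefinition("all", [(1, ref.n_atoms)])
        trace = pm.element_rmsd_trace(traj, ref, element)
        # the singular-value RMSD identity cancels to ~1e-6 on identical frames
        assert np.allclose(trace, 0.0, atol=1e-6)

    def test_interpolation_strictly_decreases(self, two_state):
        traj = pm.make_interpolated_trajectory(two_state.state_a, two_state.state_b, 8)
        element = pm.ElementDefinition("half", [(1, 15)])
        trace = pm.element_rmsd_trace(traj, two_state.state_b, element)
        assert np.all(np.diff(trace) < 0)

    def test_full_element_equals_global_rmsd(self, two_state):
        traj = pm.make_interpolated_trajectory(two_state.state_a, two_state.state_b, 5)
        element = pm.ElementDefinition("all", [(1, 30)])
        trace = pm.element_rmsd_trace(traj, two_state.state_b, element, mode="calpha")
        for i in range(5):
            rmsd, _ = pm.displacement_metrics(traj.frame(i), two_state.state_b,
                                              pm.select_calpha(two_state.state_b), fit=True)
            assert trace[i] == pytest.approx(rmsd, abs=1e-9)

    def test_empty_element_raises(self, two_state):
        element = pm.ElementDefinition("nowhere", [(900, 950)])
        with pytest.raises(SelectionError):
            pm.element_rmsd_trace(Trajectory([two_state.state_a]), two_state.state_a, element)


def water_dimer(o_o=2.8):
    """Two waters, linear O-H...O hydrogen bond along x."""
    coords = np.array([
        [0.0, 0.0, 0.0],      # O donor
        [0.96, 0.0, 0.0],     # H pointing at acceptor
        [-0.32, 0.91, 0.0],   # second H
        [o_o, 0.0, 0.0],      # O acceptor
        [o_o + 0.32, 0.91, 0.0],
        [o_o + 0.32, -0.91, 0.0],
    ])
    return Structure(
        coords,
        atom_names=np.array(["O", "H1", "H2", "O", "H1", "H2"], dtype=object),
        residue_ids=np.array([1, 1, 1, 2, 2, 2]),
        residue_names=np.array(["HOH"] * 6, dtype=object),
        elements=np.array(["O", "H", "H", "O", "H", "H"], dtype=object),
    )


class TestHbondCount:
    def test_ideal_dimer_counts_one(self):
        s = water_dimer(2.8)
        donors = AtomSelection(np.array([0]), "d")
        acceptors = AtomSelection(np.array([3]), "a")
        assert pm.hbond_count(s, donors, acceptors) == 1

    def test_stretched_dimer_counts_zero(self):
        s = water_dimer(3.6)
        donors = AtomSelection(np.array([0]), "d")
        acceptors = AtomSelection(np.array([3]), "a")
        assert pm.hbond_count(s, donors, acceptors) == 0

    def test_rigid_transform_invariance(self):
        s = water_dimer(2.8)
        R = Rotation.random(random_state=1).as_matrix()
        moved = s.with_coords(s.coords @ R.T + np.array([3.0, -1.0, 7.0]))
        donors = AtomSelection(np.array([0]), "d")
        acceptors = AtomSelection(np.array([3]), "a")
        assert pm.hbond_count(moved, donors, acceptors) == pm.hbond_count(s, donors, acceptors)

    def test_donor_without_hydrogen_raises(self):
        s = water_dimer(2.8)
        donors = AtomSelection(np.array([3]), "d")  # acceptor-side O has Hs...
        bare = Structure(s.coords[[0, 3]],
                         elements=np.array(["O", "O"], dtype=object))
        with pytest.raises(TopologyError):
            pm.hbond_count(bare, AtomSelection(np.array([0])), AtomSelection(np.array([1])))

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(8)
        n_d = 4
        donors_xyz = rng.uniform(0, 8, size=(n_d, 3))
        h_xyz = donors_xyz + rng.normal(size=(n_d, 3)) * 0.05 + np.array([0.95, 0, 0])
        acceptors_xyz = rng.uniform(0, 8, size=(5, 3))
        coords = np.vstack([donors_xyz, h_xyz, acceptors_xyz])
        elements = np.array(["O"] * n_d + ["H"] * n_d + ["O"] * 5, dtype=object)
        s = Structure(coords, elements=elements)
        donors = AtomSelection(np.arange(n_d), "d")
        acceptors = AtomSelection(np.arange(2 * n_d, 2 * n_d + 5), "a")
        got = pm.hbond_count(s, donors, acceptors)
        expected = 0
        for d in range(n_d):
            for a in range(2 * n_d, 2 * n_d + 5):
                r = coords[a] - coords[d]
                if np.linalg.norm(r) > 3.5:
                    continue
                hv = coords[n_d + d] - coords[d]
                cosang = hv @ r / (np.linalg.norm(hv) * np.linalg.norm(r))
                if degrees(np.arccos(np.clip(cosang, -1, 1))) <= 30.0:
                    expected += 1
        assert got == expected


class TestSasa:
    def test_isolated_atom_analytic_sphere(self):
        s = Structure(np.zeros((1, 3)), elements=np.array(["C"], dtype=object))
        area = pm.sasa_shrake_rupley(s)
        exact = 4 * np.pi * (VDW_RADII["C"] + 1.4) ** 2
        assert area == pytest.approx(exact, rel=0.01)

    def test_coincident_atoms_one_sphere(self):
        s = Structure(np.zeros((2, 3)), elements=np.array(["C", "C"], dtype=object))
        area = pm.sasa_shrake_rupley(s)
        exact = 4 * np.pi * (VDW_RADII["C"] + 1.4) ** 2
        assert area == pytest.approx(exact, rel=0.01)

    def test_separation_sweep_monotone_to_additive(self):
        exact = 4 * np.pi * (VDW_RADII["C"] + 1.4) ** 2
        areas = []
        for d in np.linspace(0.0, 7.0, 15):
            s = Structure(np.array([[0.0, 0, 0], [d, 0, 0]]),
                          elements=np.array(["C", "C"], dtype=object))
            areas.append(pm.sasa_shrake_rupley(s))
        assert np.all(np.diff(areas) >= -1e-9)
        assert areas[-1] == pytest.approx(2 * exact, rel=0.01)

    def test_buried_selection_below_isolated_sum(self, two_state):
        s = two_state.state_a
        total = pm.sasa_shrake_rupley(s)
        isolated = sum(
            pm.sasa_shrake_rupley(Structure(s.coords[i:i + 1],
                                            elements=s.elements[i:i + 1]))
            for i in range(s.n_atoms)
        )
        assert total <= isolated + 1e-6

    def test_unknown_element_raises(self):
        s = Structure(np.zeros((1, 3)), elements=np.array(["Xx"], dtype=object))
        with pytest.raises(RadiusTableError):
            pm.sasa_shrake_rupley(s)


def place_dihedral(p0, p1, p2, length, angle_deg, dihedral_deg):
    """NeRF atom placement: next atom at given bond length/angle/dihedral."""
    bc = p2 - p1
    bc = bc / np.linalg.norm(bc)
    n = np.cross(p1 - p0, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    theta = np.deg2rad(angle_deg)
    phi = np.deg2rad(dihedral_deg)
    local = length * np.array([-np.cos(theta), np.sin(theta) * np.cos(phi),
                               np.sin(theta) * np.sin(phi)])
    return p2 + local[0] * bc + local[1] * m + local[2] * n


class TestDihedrals:
    @pytest.mark.parametrize("target", [-57.0, -47.0, 180.0, 63.0, -120.0])
    def test_construction_inverse(self, target):
        p0 = np.array([0.0, 0.0, 0.0])
        p1 = np.array([1.5, 0.0, 0.0])
        p2 = np.array([2.0, 1.4, 0.0])
        p3 = place_dihedral(p0, p1, p2, 1.5, 115.0, target)
        got = dihedral_angle(p0, p1, p2, p3)
        assert got == pytest.approx(target, abs=1e-6)

    def test_matches_independent_atan2_formula(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            p = rng.normal(size=(4, 3)) * 2
            # independent evaluation via the standard two-plane construction
            b0, b1, b2 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
            n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
            x = n1 @ n2
            y = np.cross(n1, n2) @ (b1 / np.linalg.norm(b1))
            ref = degrees(np.arctan2(y, x))
            assert dihedral_angle(*p) == pytest.approx(ref, abs=1e-9)

    def _tripeptide(self, phi=-57.0, psi=-47.0):
        # residue 2 has full phi/psi context; build backbone by NeRF
        coords = [np.array([0.0, 0, 0]), np.array([1.33, 0, 0]),
                  np.array([1.8, 1.36, 0])]
        names = ["C", "N", "CA"]
        res = [1, 2, 2]
        coords.append(place_dihedral(coords[0], coords[1], coords[2], 1.52, 111.0, phi))
        names.append("C")
        res.append(2)
        coords.append(place_dihedral(coords[1], coords[2], coords[3], 1.33, 116.0, psi))
        names.append("N")
        res.append(3)
        return Structure(np.array(coords),
                         atom_names=np.array(names, dtype=object),
                         residue_ids=np.array(res),
                         elements=np.array(["C", "N", "C", "C", "N"], dtype=object))

    def test_backbone_phi_psi_recovered(self):
        s = self._tripeptide(phi=-57.0, psi=-47.0)
        d = pm.backbone_dihedrals(s, 2)
        assert d.phi == pytest.approx(-57.0, abs=1e-6)
        assert d.psi == pytest.approx(-47.0, abs=1e-6)

    def test_planar_zigzag(self):
        s = self._tripeptide(phi=180.0, psi=180.0)
        d = pm.backbone_dihedrals(s, 2)
        assert abs(d.phi) == pytest.approx(180.0, abs=1e-6)
        assert abs(d.psi) == pytest.approx(180.0, abs=1e-6)

    def test_terminal_residue_flagged_not_raised(self):
        s = self._tripeptide()
        # residue 3 has only N: no CA/C -> topology error; craft terminal case
        coords = s.coords[1:4]
        term = Structure(coords,
                         atom_names=np.array(["N", "CA", "C"], dtype=object),
                         residue_ids=np.array([2, 2, 2]),
                         elements=np.array(["N", "C", "C"], dtype=object))
        d = pm.backbone_dihedrals(term, 2)
        assert not d.phi_defined and not d.psi_defined
        with pytest.raises(TopologyError):
            pm.backbone_dihedrals(s, 1)  # residue 1 lacks N/CA


class TestPairwiseRmsdMap:
    def test_self_map_zero_diagonal_symmetric(self, two_state):
        traj = pm.make_interpolated_trajectory(two_state.state_a, two_state.state_b, 5)
        sel = pm.select_all(two_state.state_a)
        M, rows = pm.pairwise_rmsd_map(traj, traj, sel)
        assert np.allclose(np.diag(M), 0.0, atol=1e-6)
        assert np.allclose(M, M.T, atol=1e-6)
        assert np.array_equal(rows, np.arange(5))

    def test_entries_match_displacement_metrics(self, two_state):
        a = pm.make_interpolated_trajectory(two_state.state_a, two_state.state_b, 3)
        b = pm.make_interpolated_trajectory(two_state.state_b, two_state.state_a, 4,
                                            noise_sigma=0.2, seed=9)
        sel = pm.select_all(two_state.state_a)
        M, _ = pm.pairwise_rmsd_map(a, b, sel)
        for i in range(3):
            for j in range(4):
                rmsd, _ = pm.displacement_metrics(a.frame(i), b.frame(j), sel, fit=True)
                assert M[i, j] == pytest.approx(rmsd, abs=1e-9)

    def test_single_frame_sets(self, two_state):
        a = Trajectory([two_state.state_a])
        b = Trajectory([two_state.state_b])
        M, rows = pm.pairwise_rmsd_map(a, b, pm.select_all(two_state.state_a))
        assert M.shape == (1, 1) and rows.tolist() == [0]
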