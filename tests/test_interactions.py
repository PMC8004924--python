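"""Geometric contact detection, collapse rules and occupancies."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lrabind.interactions import (
    InteractionCriteria,
    detect_hbonds,
    detect_hydrophobic,
    interaction_occupancy,
)
from lrabind.topology import Trajectory

from conftest import build_topology


def _hbond_topology(with_hydrogen=True):
    """Ligand donor O (+ optional H) against an environment acceptor O."""
    atoms = [
        dict(name="OD", element="O", res_name="LIG", res_id=1, chain="L",
             charge=-0.4, rmin_half=1.66, epsilon=0.21,
             flags=("ligand", "donor")),
    ]
    if with_hydrogen:
        atoms.append(
            dict(name="HD", element="H", res_name="LIG", res_id=1, chain="L",
                 charge=0.4, rmin_half=0.3, epsilon=0.01, flags=("ligand",))
        )
    atoms.append(
        dict(name="OA", element="O", res_name="SER", res_id=101,
             charge=-0.4, rmin_half=1.66, epsilon=0.21, flags=("acceptor",))
    )
    return build_topology(atoms)


class TestHydrogenBonds:
    def test_beyond_distance_cutoff_no_event(self):
        top = _hbond_topology(with_hydrogen=False)
        frame = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        assert detect_hbonds(frame, top, InteractionCriteria(heavy_atom_only=True)) == []

    def test_ideal_linear_geometry_detected(self):
        top = _hbond_topology()
        frame = np.array([[0.0, 0, 0], [0.96, 0, 0], [2.8, 0, 0]])
        events = detect_hbonds(frame, top)
        assert len(events) == 1
        ev = events[0]
        assert ev.distance == pytest.approx(2.8)
        assert ev.angle == pytest.approx(180.0)
        assert ev.residue == "A/SER101"

    def test_perpendicular_geometry_rejected_by_angle(self):
        top = _hbond_topology()
        # D-A still 2.8 Å but the D-H···A angle is 90°
        d = np.sqrt(2.8**2 - 0.96**2)
        frame = np.array([[0.0, 0, 0], [0.96, 0, 0], [0.96, d, 0]])
        assert detect_hbonds(frame, top) == []
        # the same geometry passes when the angle test is disabled
        events = detect_hbonds(
            frame, top, InteractionCriteria(heavy_atom_only=True)
        )
        assert len(events) == 1

    def test_without_hydrogens_angle_test_is_skipped(self):
        top = _hbond_topology(with_hydrogen=False)
        frame = np.array([[0.0, 0, 0], [3.5, 0, 0]])
        events = detect_hbonds(frame, top)
        assert len(events) == 1 and events[0].angle is None

    def test_no_flags_warns_and_returns_empty(self):
        atoms = [
            dict(name="C1", flags=("ligand",)),
            dict(name="C2", res_id=2),
        ]
        top = build_topology(atoms)
        frame = np.zeros((2, 3))
        frame[1, 0] = 3.0
        with pytest.warns(UserWarning, match="no donor/acceptor"):
            assert detect_hbonds(frame, top) == []


def _hydrophobic_topology(n_ligand_carbons=1):
    atoms = [
        dict(name=f"C{i + 1}", res_name="LIG", res_id=1, chain="L",
             flags=("ligand", "hydrophobic"))
        for i in range(n_ligand_carbons)
    ]
    atoms.append(dict(name="CB", res_name="LEU", res_id=101,
                      flags=("hydrophobic",)))
    return build_topology(atoms)


class TestHydrophobic:
    def test_contact_within_cutoff(self):
        top = _hydrophobic_topology()
        frame = np.array([[0.0, 0, 0], [3.8, 0, 0]])
        events = detect_hydrophobic(frame, top)
        assert len(events) == 1
        assert events[0].distance == pytest.approx(3.8)

    def test_no_contact_beyond_cutoff(self):
        top = _hydrophobic_topology()
        frame = np.array([[0.0, 0, 0], [4.5, 0, 0]])
        assert detect_hydrophobic(frame, top) == []

    def test_collapse_to_closest_pair_per_residue(self):
        top = _hydrophobic_topology(n_ligand_carbons=2)
        frame = np.array([[0.0, 0, 0], [0.4, 0, 0], [3.9, 0, 0]])
        # distances 3.9 and 3.5 to the same residue -> one event at 3.5
        events = detect_hydrophobic(frame, top)
        assert len(events) == 1
        assert events[0].distance == pytest.approx(3.5)
        assert events[0].ligand_atom == 1


class TestInvariance:
    def _random_mixed_system(self, seed):
        rng = np.random.default_rng(seed)
        atoms = [
            dict(name="OD", element="O", res_name="LIG", res_id=1, chain="L",
                 flags=("ligand", "donor", "acceptor")),
            dict(name="C1", res_name="LIG", res_id=1, chain="L",
                 flags=("ligand", "hydrophobic")),
        ]
        for i in range(6):
            flags = [("acceptor",), ("donor",), ("hydrophobic",)][i % 3]
            atoms.append(
                dict(name=f"X{i}", element="O" if i % 3 < 2 else "C",
                     res_name="SER", res_id=100 + i, flags=flags)
            )
        top = build_topology(atoms)
        coords = rng.uniform(-4, 4, (top.n_atoms, 3))
        return top, coords

    @pytest.mark.parametrize("seed", range(4))
    def test_detection_invariant_under_rigid_motion(self, seed):
        top, coords = self._random_mixed_system(40 + seed)
        criteria = InteractionCriteria(heavy_atom_only=True)
        base = detect_hbonds(coords, top, criteria) + detect_hydrophobic(
            coords, top, criteria
        )
        rot = Rotation.from_euler("zxz", [33.0, 71.0, -15.0], degrees=True)
        moved = coords @ rot.as_matrix().T + np.array([-3.0, 9.0, 2.0])
        after = detect_hbonds(moved, top, criteria) + detect_hydrophobic(
            moved, top, criteria
        )
        assert len(base) == len(after)
        for b, a in zip(base, after):
            assert (b.kind, b.ligand_atom, b.environment_atom) == (
                a.kind, a.ligand_atom, a.environment_atom
            )
            assert a.distance == pytest.approx(b.distance, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_loosening_criteria_is_monotone(self, seed):
        top, coords = self._random_mixed_system(60 + seed)
        tight = InteractionCriteria(
            hbond_da_max=3.2, hydrophobic_max=3.4, heavy_atom_only=True
        )
        loose = InteractionCriteria(
            hbond_da_max=4.1, hydrophobic_max=4.0, heavy_atom_only=True
        )
        def keys(events):
            return {(e.kind, e.residue) for e in events}
        tight_set = keys(
            detect_hbonds(coords, top, tight)
            + detect_hydrophobic(coords, top, tight)
        )
        loose_set = keys(
            detect_hbonds(coords, top, loose)
            + detect_hydrophobic(coords, top, loose)
        )
        assert tight_set <= loose_set


class TestOccupancy:
    def _trajectory(self, n_present, n_total, d_present=3.5, d_absent=8.0):
        top = _hydrophobic_topology()
        frames = np.zeros((n_total, 2, 3))
        frames[:, 1, 0] = d_absent
        frames[:n_present, 1, 0] = d_present
        return top, Trajectory(coords=frames)

    def test_always_present_contact(self):
        top, traj = self._trajectory(10, 10)
        reports = interaction_occupancy(traj, top,
                                        InteractionCriteria(heavy_atom_only=True))
        assert len(reports) == 1
        assert reports[0].occupancy == 1.0

    def test_constructed_96_percent_occupancy(self):
        top, traj = self._trajectory(96, 100)
        reports = interaction_occupancy(traj, top,
                                        InteractionCriteria(heavy_atom_only=True))
        assert reports[0].occupancy == pytest.approx(0.96)
        # mean distance averages only the frames where the contact exists
        assert reports[0].mean_distance == pytest.approx(3.5)

    def test_counts_match_per_frame_brute_force(self, bundle):
        out, _ = bundle
        from lrabind.io import read_parameters, read_structure

        skeleton, traj = read_structure(out / "bound_P_q_run1.pdb")
        top = read_parameters(out / "params_bound_P.tsv", skeleton)
        criteria = InteractionCriteria(heavy_atom_only=True)
        reports = interaction_occupancy(traj, top, criteria)
        counts = {}
        for f in range(traj.n_frames):
            frame = traj.frame(f)
            events = detect_hbonds(frame, top, criteria) + detect_hydrophobic(
                frame, top, criteria
            )
            seen = {(e.kind, e.ligand_atom, e.residue) for e in events}
            for key in seen:
                counts[key] = counts.get(key, 0) + 1
        assert {
            (r.kind, r.ligand_atom, r.residue): r.n_present for r in reports
        } == counts

    def test_concatenation_matches_frame_weighted_mean(self):
        top, traj_a = self._trajectory(8, 10)
        _, traj_b = self._trajectory(2, 30)
        criteria = InteractionCriteria(heavy_atom_only=True)
        occ_a = interaction_occupancy(traj_a, top, criteria)[0]
        occ_b = interaction_occupancy(traj_b, top, criteria)[0]
        merged = Trajectory(
            coords=np.concatenate([traj_a.coords, traj_b.coords])
        )
        occ = interaction_occupancy(merged, top, criteria)[0]
        expected = (occ_a.occupancy * 10 + occ_b.occupancy * 30) / 40
        assert occ.occupancy == pytest.approx(expected)

    def test_reports_sorted_by_descending_occupancy(self, bundle):
        out, _ = bundle
        from lrabind.io import read_parameters, read_structure

        skeleton, traj = read_structure(out / "bound_P_q_run1.pdb")
        top = read_parameters(out / "params_bound_P.tsv", skeleton)
        reports = interaction_occupancy(
            traj, top, InteractionCriteria(heavy_atom_only=True)
        )
        occ = [r.occupancy for r in reports]
        assert occ == sorted(occ, reverse=True)
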