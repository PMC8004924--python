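"""Superposition, RMSD/RMSF conventions and cross-run aggregation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lrabind.metrics import (
    FitError,
    aggregate_metric,
    apply_fit,
    kabsch_fit,
    rmsd_series,
    rmsf,
    MetricSeries,
)
from lrabind.stats import round_half_up
from lrabind.topology import Trajectory


def grid_search_min_rmsd(mobile, reference):
    """Oracle: hierarchical rotation-grid search over proper rotations."""
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def best_on(angles):
        rots = Rotation.from_euler("zyz", angles, degrees=True).as_matrix()
        moved = np.einsum("mij,nj->mni", rots, mob)
        rmsds = np.sqrt(((moved - ref) ** 2).sum(axis=2).mean(axis=1))
        k = int(np.argmin(rmsds))
        return angles[k], float(rmsds[k])

    spacing = 8.0
    grid = np.stack(
        np.meshgrid(
            np.arange(0, 360, spacing),
            np.arange(0, 180 + spacing, spacing),
            np.arange(0, 360, spacing),
            indexing="ij",
        ),
        axis=-1,
    ).reshape(-1, 3)
    center, best = best_on(grid)
    for spacing_new in (2.0, 0.5, 0.1):
        offsets = np.arange(-spacing, spacing + spacing_new / 2, spacing_new)
        local = np.stack(
            np.meshgrid(offsets, offsets, offsets, indexing="ij"), axis=-1
        ).reshape(-1, 3) + center
        center, best = best_on(local)
        spacing = spacing_new
    return best


class TestKabsch:
    def test_identity_fit_is_zero(self):
        pts = np.random.default_rng(1).normal(size=(5, 3))
        _, _, rmsd = kabsch_fit(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_recovers_rigid_motion_exactly(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(6, 3))
        rot = Rotation.from_euler("zyx", [40.0, 25.0, -70.0], degrees=True)
        mobile = ref @ rot.as_matrix().T + np.array([1.0, -2.0, 3.0])
        matrix, trans, rmsd = kabsch_fit(mobile, ref)
        assert rmsd < 1e-9
        np.testing.assert_allclose(apply_fit(mobile, matrix, trans), ref,
                                   atol=1e-9)
        assert np.linalg.det(matrix) == pytest.approx(1.0)

    def test_reflection_is_not_used(self):
        # a mirrored chiral point set cannot be fit to zero by a proper
        # rotation; the result must stay a rotation (det +1)
        ref = np.array([[0, 0, 0], [1.5, 0, 0], [0, 1.2, 0], [0, 0, 2.0]],
                       dtype=float)
        mirrored = ref * np.array([1, 1, -1])
        matrix, _, rmsd = kabsch_fit(mirrored, ref)
        assert np.linalg.det(matrix) == pytest.approx(1.0)
        assert rmsd > 0.1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_rotation_grid_oracle(self, seed):
        rng = np.random.default_rng(300 + seed)
        n = int(rng.integers(4, 7))
        mobile = rng.normal(size=(n, 3))
        reference = rng.normal(size=(n, 3))
        _, _, rmsd = kabsch_fit(mobile, reference)
        oracle = grid_search_min_rmsd(mobile, reference)
        assert rmsd == pytest.approx(oracle, abs=1e-3)
        assert rmsd <= oracle + 1e-9  # closed form can only be better

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        with pytest.raises(FitError, match="collinear"):
            kabsch_fit(line, line)
        with pytest.raises(FitError, match="3 points"):
            kabsch_fit(line[:2], line[:2])


def _rigid_fixture():
    """Backbone tetrahedron (atoms 0-3) plus 2 ligand atoms (4-5)."""
    backbone = np.array(
        [[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]], dtype=float
    )
    ligand = np.array([[1.0, 1.0, 1.0], [2.0, 1.0, 1.0]])
    return np.concatenate([backbone, ligand])


class TestRMSDSeries:
    def test_static_trajectory_is_zero(self):
        frame = _rigid_fixture()
        traj = Trajectory(coords=np.stack([frame] * 4))
        series = rmsd_series(traj, frame, np.arange(4), np.arange(4, 6))
        np.testing.assert_allclose(series.values, 0.0, atol=1e-12)

    def test_comoving_measure_set_stays_zero(self):
        frame = _rigid_fixture()
        frames = [frame]
        rng = np.random.default_rng(4)
        for _ in range(3):
            rot = Rotation.random(rng=rng).as_matrix()
            frames.append(frame @ rot.T + rng.normal(size=3))
        traj = Trajectory(coords=np.stack(frames))
        series = rmsd_series(traj, frame, np.arange(4), np.arange(4, 6))
        np.testing.assert_allclose(series.values, 0.0, atol=1e-9)

    def test_constructed_ligand_displacement(self):
        frame = _rigid_fixture()
        shifted = frame.copy()
        shifted[4:, 0] += 2.0  # ligand moves 2 Å, backbone fixed
        traj = Trajectory(coords=np.stack([frame, frame, shifted]))
        series = rmsd_series(traj, frame, np.arange(4), np.arange(4, 6))
        assert series.values[2] == pytest.approx(2.0, abs=1e-9)
        assert series.values[1] == pytest.approx(0.0, abs=1e-12)

    def test_uniform_rigid_motion_of_a_frame_is_invisible(self):
        frame = _rigid_fixture()
        rot = Rotation.from_euler("xyz", [10.0, 20.0, 30.0], degrees=True)
        moved = frame @ rot.as_matrix().T + np.array([4.0, 4.0, 4.0])
        traj = Trajectory(coords=np.stack([frame, moved]))
        series = rmsd_series(traj, frame, np.arange(4), np.arange(4, 6))
        assert series.values[1] == pytest.approx(0.0, abs=1e-9)


class TestRMSF:
    def test_static_trajectory_gives_zero(self):
        frame = _rigid_fixture()
        traj = Trajectory(coords=np.stack([frame] * 3))
        series = rmsf(traj, np.arange(4), np.arange(4, 6))
        np.testing.assert_allclose(series.values, 0.0, atol=1e-12)

    def test_single_frame_rejected(self):
        frame = _rigid_fixture()
        with pytest.raises(ValueError, match="2 frames"):
            rmsf(Trajectory(coords=frame[None]), np.arange(4), np.arange(4, 6))

    def test_two_frame_oscillation_closed_form(self):
        frame = _rigid_fixture()
        up, down = frame.copy(), frame.copy()
        d = 0.7
        up[5, 2] += d
        down[5, 2] -= d
        traj = Trajectory(coords=np.stack([up, down]))
        series = rmsf(traj, np.arange(4), np.arange(4, 6))
        assert series.values[0] == pytest.approx(0.0, abs=1e-12)
        assert series.values[1] == pytest.approx(d, abs=1e-12)

    def test_gaussian_jitter_monte_carlo(self):
        # isotropic jitter sigma per axis gives RMSF = sigma*sqrt(3)
        rng = np.random.default_rng(8)
        frame = _rigid_fixture()
        sigma = 0.25
        frames = np.stack([frame] * 1000)
        frames[:, 4:, :] += rng.normal(0, sigma, (1000, 2, 3))
        series = rmsf(Trajectory(coords=frames), np.arange(4), np.arange(4, 6))
        np.testing.assert_allclose(
            series.values, sigma * np.sqrt(3), rtol=0.05
        )

    def test_frame_permutation_invariance(self):
        rng = np.random.default_rng(9)
        frame = _rigid_fixture()
        frames = np.stack([frame] * 50)
        frames[:, 4:, :] += rng.normal(0, 0.3, (50, 2, 3))
        traj = Trajectory(coords=frames)
        series = rmsf(traj, np.arange(4), np.arange(4, 6))
        perm = rng.permutation(50)
        series_p = rmsf(Trajectory(coords=frames[perm]), np.arange(4),
                        np.arange(4, 6))
        np.testing.assert_allclose(series.values, series_p.values, atol=1e-12)


class TestAggregation:
    @staticmethod
    def _as_series(means, kind="rmsd_ligand"):
        return [
            MetricSeries(kind=kind, values=np.array([m]),
                         fit_selection=np.arange(1),
                         measure_selection=np.arange(1),
                         run_id=f"run{i + 1}")
            for i, m in enumerate(means)
        ]

    def test_published_ligand_rmsd_average(self):
        # four independent runs of a small rigid polyphenol stabilize
        # around 0.40 Å
        agg = aggregate_metric(self._as_series([0.47, 0.35, 0.36, 0.43]))
        assert agg.mean == pytest.approx(0.4025, abs=1e-12)
        assert round_half_up(agg.mean, 2) == 0.40

    def test_published_backbone_rmsd_average(self):
        agg = aggregate_metric(
            self._as_series([0.69, 0.75, 0.68, 0.72], kind="rmsd_backbone")
        )
        assert round_half_up(agg.mean, 2) == 0.71

    def test_single_run_flagged_with_zero_sd(self):
        agg = aggregate_metric(self._as_series([0.5]))
        assert agg.single_run and agg.sd == 0.0

    def test_sample_sd_uses_n_minus_one(self):
        agg = aggregate_metric(self._as_series([1.0, 2.0, 3.0]))
        assert agg.sd == pytest.approx(1.0)
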