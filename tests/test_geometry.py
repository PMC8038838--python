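"""Distance machinery, superposition and equilibration detection."""

import numpy as np
import pytest

from memtraj.core import Frame, Trajectory
from memtraj.geometry import (
    detect_equilibration,
    kabsch_superpose,
    min_image_distance,
    min_residue_group_distance,
    pairwise_min_image_distances,
    rmsd_timeseries,
)


def brute_force_min_image(a, b, box, reach=2):
    """Oracle: explicit minimum over (2*reach+1)^3 periodic images."""
    best = np.inf
    delta = np.asarray(b, float) - np.asarray(a, float)
    for i in range(-reach, reach + 1):
        for j in range(-reach, reach + 1):
            for k in range(-reach, reach + 1):
                shift = i * box[0] + j * box[1] + k * box[2]
                best = min(best, np.linalg.norm(delta + shift))
    return best


def random_triclinic(rng):
    """Random reduced triclinic box with modest skew."""
    diag = rng.uniform(3.0, 6.0, 3)
    box = np.diag(diag)
    box[1, 0] = rng.uniform(-0.3, 0.3) * diag[0]
    box[2, 0] = rng.uniform(-0.3, 0.3) * diag[0]
    box[2, 1] = rng.uniform(-0.3, 0.3) * diag[1]
    return box


class TestMinImage:
    def test_wraparound(self):
        box = np.diag([4.0, 4.0, 4.0])
        d = min_image_distance([0.1, 0, 0], [3.9, 0, 0], box)
        assert d == pytest.approx(0.2, abs=1e-12)

    def test_identity(self):
        box = np.diag([4.0, 4.0, 4.0])
        assert min_image_distance([1, 2, 3], [1, 2, 3], box) == 0.0

    def test_matches_brute_force_on_random_triclinic(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            box = random_triclinic(rng)
            a = rng.uniform(0, 1, 3) @ box
            b = rng.uniform(0, 1, 3) @ box
            expect = brute_force_min_image(a, b, box)
            assert min_image_distance(a, b, box) == pytest.approx(expect, abs=1e-9)

    def test_lattice_translation_invariance(self):
        rng = np.random.default_rng(7)
        box = random_triclinic(rng)
        a, b = rng.uniform(0, 3, 3), rng.uniform(0, 3, 3)
        d0 = min_image_distance(a, b, box)
        for shift in (box[0], box[1] + box[2], 2 * box[0] - box[1]):
            assert min_image_distance(a + shift, b, box) == pytest.approx(d0, abs=1e-9)
            assert min_image_distance(a, b + shift, box) == pytest.approx(d0, abs=1e-9)

    def test_singular_box_raises(self):
        with pytest.raises(ValueError):
            min_image_distance([0, 0, 0], [1, 1, 1], np.zeros((3, 3)))


class TestResidueGroupDistance:
    def test_reduces_to_pair_distance(self):
        rng = np.random.default_rng(0)
        box = np.diag([5.0, 5.0, 5.0])
        coords = rng.uniform(0, 5, (2, 3))
        frame = Frame(coordinates=coords, box=box)
        d = min_residue_group_distance(frame, np.array([0]), np.array([1]))
        assert d == pytest.approx(
            min_image_distance(coords[0], coords[1], box), abs=1e-5
        )

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            box = random_triclinic(rng)
            coords = rng.uniform(0, 3, (60, 3))
            frame = Frame(coordinates=coords, box=box)
            res = np.arange(10)
            grp = np.arange(10, 60)
            naive = min(
                brute_force_min_image(coords[i], coords[j], box)
                for i in res
                for j in grp
            )
            fast = min_residue_group_distance(frame, res, grp)
            assert fast == pytest.approx(naive, abs=1e-5)

    def test_grid_equals_naive_bulk(self):
        # the accelerated distance_array path against per-pair scalars
        rng = np.random.default_rng(11)
        box = random_triclinic(rng)
        a = rng.uniform(0, 3, (20, 3))
        b = rng.uniform(0, 3, (30, 3))
        dmat = pairwise_min_image_distances(a, b, box)
        for i in range(0, 20, 5):
            for j in range(0, 30, 7):
                assert dmat[i, j] == pytest.approx(
                    min_image_distance(a[i], b[j], box), abs=1e-5
                )

    def test_empty_set_raises(self):
        frame = Frame(coordinates=np.zeros((2, 3)), box=np.eye(3))
        with pytest.raises(ValueError):
            min_residue_group_distance(frame, np.array([]), np.array([0]))


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(1).normal(size=(10, 3))
        res = kabsch_superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_rigid_motion_gives_zero(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(15, 3))
        rot = random_rotation(rng)
        moved = pts @ rot.T + np.array([1.0, -2.0, 0.5])
        res = kabsch_superpose(moved, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(12, 3)), rng.normal(size=(12, 3))
        assert kabsch_superpose(a, b).rmsd == pytest.approx(
            kabsch_superpose(b, a).rmsd, abs=1e-9
        )

    def test_against_independent_implementations(self):
        # scipy's align_vectors and MDAnalysis' rotation_matrix both solve
        # the same problem by different code paths
        from scipy.spatial.transform import Rotation
        from MDAnalysis.analysis.align import rotation_matrix as mda_rotmat

        rng = np.random.default_rng(4)
        for _ in range(5):
            a = rng.normal(size=(10, 3))
            b = rng.normal(size=(10, 3))
            ours = kabsch_superpose(a, b)
            ac = a - a.mean(axis=0)
            bc = b - b.mean(axis=0)
            rot_scipy, rssd = Rotation.align_vectors(bc, ac)
            rmsd_scipy = np.sqrt(rssd**2 / len(a))
            assert ours.rmsd == pytest.approx(rmsd_scipy, abs=1e-8)
            _, rmsd_mda = mda_rotmat(ac, bc)
            assert ours.rmsd == pytest.approx(rmsd_mda, abs=1e-6)

    def test_collinear_raises(self):
        pts = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(ValueError):
            kabsch_superpose(pts, pts + 1.0)

    def test_reflection_excluded(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(10, 3))
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        res = kabsch_superpose(mirrored, pts)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
        assert res.rmsd > 0.1


class TestRmsdTimeseries:
    def _make_traj(self, coords_list, dt=10.0):
        import warnings as w

        from memtraj.core import MolecularSystem

        n = coords_list[0].shape[0]
        system = MolecularSystem(
            names=["CA"] * n,
            elements=["C"] * n,
            residue_indices=np.arange(n),
            residue_names=["GLY"] * n,
            residue_seqs=np.arange(1, n + 1),
        )
        frames = [
            Frame(coordinates=c, box=np.diag([99.0] * 3), time=k * dt)
            for k, c in enumerate(coords_list)
        ]
        with w.catch_warnings():
            w.simplefilter("ignore")
            return Trajectory(system, frames)

    def test_rigid_motions_give_zero_with_fit(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(20, 3)) + 10.0
        frames = [base]
        for _ in range(5):
            rot = random_rotation(rng)
            frames.append(base @ rot.T + rng.normal(size=3))
        traj = self._make_traj(frames)
        series = rmsd_timeseries(traj, traj.frames[0], fit=True)
        assert np.allclose(series[:, 1], 0.0, atol=1e-9)

    def test_repeated_reference_constant_zero(self):
        base = np.random.default_rng(7).normal(size=(10, 3)) + 5.0
        traj = self._make_traj([base] * 4)
        series = rmsd_timeseries(traj, traj.frames[0], fit=False)
        assert np.allclose(series[:, 1], 0.0)

    def test_gaussian_noise_expectation(self):
        # per-atom isotropic Gaussian displacement sigma, no fitting:
        # RMSD per frame concentrates at sigma*sqrt(3) for many atoms
        rng = np.random.default_rng(8)
        sigma = 0.05
        base = rng.normal(size=(500, 3)) + 10.0
        frames = [base] + [
            base + rng.normal(scale=sigma, size=base.shape) for _ in range(200)
        ]
        traj = self._make_traj(frames)
        series = rmsd_timeseries(traj, traj.frames[0], fit=False)
        mean_rmsd = series[1:, 1].mean()
        assert mean_rmsd == pytest.approx(sigma * np.sqrt(3), rel=0.02)


class TestDetectEquilibration:
    def test_constant_series_returns_first_time(self):
        t = np.arange(0, 100000.0, 100.0)
        series = np.column_stack([t, np.full_like(t, 0.3)])
        assert detect_equilibration(series, window=10000.0) == t[0]

    def test_ramp_then_flat_detects_breakpoint(self):
        t = np.arange(0, 100000.0, 100.0)
        v = np.where(t < 50000.0, t * 1e-5, 0.5)
        series = np.column_stack([t, v])
        found = detect_equilibration(series, window=10000.0, slope_tol=0.005)
        assert abs(found - 50000.0) <= 10000.0

    def test_unbounded_ramp_warns_and_returns_end(self):
        t = np.arange(0, 100000.0, 100.0)
        series = np.column_stack([t, t * 1e-4])
        with pytest.warns(UserWarning):
            assert detect_equilibration(series, window=10000.0) == t[-1]

    def test_window_longer_than_series_raises(self):
        t = np.arange(0, 1000.0, 100.0)
        series = np.column_stack([t, t])
        with pytest.raises(ValueError):
            detect_equilibration(series, window=10000.0)
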