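"""Pore-radius profiling and membrane-span detection."""

import warnings

import numpy as np
import pytest

from memtraj.channel import (
    channel_profile,
    detect_span,
    profile_over_time,
    vdw_radii,
)
from memtraj.core import Frame, MolecularSystem, Trajectory
from memtraj.synthetic import make_cylinder


def cylinder_inputs(pore_radius=0.45, vdw=0.15, **kwargs):
    system, frame = make_cylinder(pore_radius=pore_radius, **kwargs)
    atoms = np.arange(system.n_atoms)
    return system, frame, atoms, np.full(len(atoms), vdw)


def grid_search_radius(frame, atoms, radii, z, r_max=1.0, grid=0.01, extent=0.3):
    """Oracle: exhaustive in-plane grid search for the maximal free sphere."""
    pts = frame.coordinates[atoms]
    center = pts[:, :2].mean(axis=0)
    best = -np.inf
    for cx in np.arange(center[0] - extent, center[0] + extent, grid):
        for cy in np.arange(center[1] - extent, center[1] + extent, grid):
            d = np.sqrt(
                (pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2 + (pts[:, 2] - z) ** 2
            )
            r = (d - radii).min()
            if r > best:
                best = r
    return min(max(best, 0.0), r_max)


class TestProfile:
    def test_cylinder_radius_recovery(self):
        system, frame, atoms, radii = cylinder_inputs()
        z = frame.coordinates[:, 2]
        prof = channel_profile(
            frame, atoms, radii, z_range=(z.min(), z.max()), dz=0.1, seed=5
        )
        interior = prof.radius[2:-2]
        assert np.all(np.abs(interior - 0.30) < 0.02)

    def test_cap_where_no_atoms(self):
        system, frame, atoms, radii = cylinder_inputs()
        z = frame.coordinates[:, 2]
        prof = channel_profile(
            frame,
            atoms,
            radii,
            z_range=(z.min() - 3.0, z.min() - 1.6),
            dz=0.2,
            seed=5,
        )
        assert np.all(prof.radius == 1.0)

    def test_conical_frustum_linear_in_z(self):
        # rings with linearly growing radius: the profile must grow
        # linearly too (geometric radius minus the vdW radius)
        zs = np.arange(0.0, 2.05, 0.1)
        coords = []
        for z in zs:
            r = 0.4 + 0.2 * z
            ang = np.linspace(0, 2 * np.pi, 40, endpoint=False)
            coords.append(
                np.column_stack(
                    [r * np.cos(ang) + 3, r * np.sin(ang) + 3, np.full(40, z + 2.0)]
                )
            )
        coords = np.vstack(coords)
        frame = Frame(coordinates=coords, box=np.diag([6.0, 6.0, 8.0]))
        atoms = np.arange(len(coords))
        radii = np.full(len(coords), 0.15)
        prof = channel_profile(
            frame, atoms, radii, z_range=(2.2, 3.8), dz=0.2, seed=1
        )
        expected = 0.4 + 0.2 * (prof.z - 2.0) - 0.15
        # cone walls tilt the maximal sphere slightly; allow a loose band
        assert np.all(np.abs(prof.radius - expected) < 0.05)
        slope = np.polyfit(prof.z, prof.radius, 1)[0]
        assert slope == pytest.approx(0.2, abs=0.05)

    def test_matches_exhaustive_grid_search(self):
        system, frame, atoms, radii = cylinder_inputs(
            z_extent=(-0.2, 0.2), n_per_ring=24
        )
        assert len(atoms) <= 200
        z = frame.coordinates[:, 2]
        prof = channel_profile(
            frame, atoms, radii, z_range=(z.min(), z.max()), dz=0.2, seed=2
        )
        for zb, r in zip(prof.z, prof.radius):
            oracle = grid_search_radius(frame, atoms, radii, zb)
            assert abs(r - oracle) < 0.02

    def test_monotone_occlusion(self):
        system, frame, atoms, radii = cylinder_inputs()
        z = frame.coordinates[:, 2]
        kwargs = dict(z_range=(z.min(), z.max()), dz=0.2, seed=3)
        before = channel_profile(frame, atoms, radii, **kwargs)
        center = frame.coordinates.mean(axis=0)
        extra = np.vstack([frame.coordinates, center + [0.2, 0.0, 0.0]])
        frame2 = Frame(coordinates=extra, box=frame.box)
        after = channel_profile(
            frame2,
            np.arange(len(extra)),
            np.append(radii, 0.15),
            **kwargs,
        )
        assert np.all(after.radius <= before.radius + 5e-3)

    def test_rotation_equivariance(self):
        from scipy.spatial.transform import Rotation

        system, frame, atoms, radii = cylinder_inputs()
        z = frame.coordinates[:, 2]
        prof = channel_profile(
            frame, atoms, radii, z_range=(z.min(), z.max()), dz=0.2, seed=4
        )
        rot = Rotation.from_euler("xyz", [20, -35, 50], degrees=True).as_matrix()
        coords_rot = frame.coordinates @ rot.T
        frame_rot = Frame(coordinates=coords_rot, box=np.diag([20.0] * 3))
        axis_rot = rot @ np.array([0.0, 0.0, 1.0])
        zr = coords_rot @ axis_rot
        prof_rot = channel_profile(
            frame_rot,
            atoms,
            radii,
            axis=axis_rot,
            z_range=(zr.min(), zr.max()),
            dz=0.2,
            seed=4,
        )
        assert np.all(np.abs(prof.radius - prof_rot.radius) < 0.02)

    def test_deterministic_for_fixed_seed(self):
        system, frame, atoms, radii = cylinder_inputs()
        z = frame.coordinates[:, 2]
        kwargs = dict(z_range=(z.min(), z.max()), dz=0.1, seed=11)
        p1 = channel_profile(frame, atoms, radii, **kwargs)
        p2 = channel_profile(frame, atoms, radii, **kwargs)
        assert np.array_equal(p1.radius, p2.radius)
        assert np.array_equal(p1.center, p2.center)

    def test_fully_occluded_warns_and_returns_zeros(self):
        # a dense atom block with no pore: no free sphere fits anywhere
        spacing = 0.15
        xs = np.arange(0.0, 2.4 + spacing / 2, spacing)
        zs = np.arange(0.0, 0.6 + spacing / 2, spacing)
        grid = np.array([(x, y, z) for x in xs for y in xs for z in zs])
        frame = Frame(coordinates=grid + 1.0, box=np.diag([5.0, 5.0, 4.0]))
        atoms = np.arange(len(grid))
        radii = np.full(len(grid), 0.15)
        with pytest.warns(UserWarning):
            prof = channel_profile(
                frame, atoms, radii, z_range=(1.15, 1.45), dz=0.15, seed=0
            )
        assert np.all(prof.radius == 0.0)


class TestProfileOverTime:
    def _static_traj(self, n_frames, dt=10.0):
        system, frame, atoms, radii = cylinder_inputs(z_extent=(-0.2, 0.2),
                                                      n_per_ring=12)
        frames = [
            Frame(coordinates=frame.coordinates, box=frame.box, time=k * dt)
            for k in range(n_frames)
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return Trajectory(system, frames), atoms, radii

    def test_stride_counts_include_first_frame(self):
        traj, atoms, radii = self._static_traj(11)
        z = traj.frames[0].coordinates[:, 2]
        profs = profile_over_time(
            traj, atoms, radii, stride=20.0, z_range=(z.min(), z.max()),
            dz=0.2, seed=0,
        )
        assert len(profs) == 6  # t = 0, 20, ..., 100
        assert profs[0].time == 0.0

    def test_stride_equal_dt_gives_every_frame(self):
        traj, atoms, radii = self._static_traj(5)
        z = traj.frames[0].coordinates[:, 2]
        profs = profile_over_time(
            traj, atoms, radii, stride=10.0, z_range=(z.min(), z.max()),
            dz=0.2, seed=0,
        )
        assert len(profs) == 5

    def test_static_trajectory_identical_profiles(self):
        traj, atoms, radii = self._static_traj(3)
        z = traj.frames[0].coordinates[:, 2]
        profs = profile_over_time(
            traj, atoms, radii, stride=10.0, z_range=(z.min(), z.max()),
            dz=0.2, seed=9,
        )
        for p in profs[1:]:
            assert np.array_equal(p.radius, profs[0].radius)

    def test_non_multiple_stride_rejected(self):
        traj, atoms, radii = self._static_traj(5)
        with pytest.raises(ValueError):
            profile_over_time(traj, atoms, radii, stride=15.0)


class TestSpanDetection:
    def _profile(self, **kwargs):
        system, frame, atoms, radii = cylinder_inputs(**kwargs)
        z = frame.coordinates[:, 2]
        return channel_profile(
            frame, atoms, radii, z_range=(z.min(), z.max()), dz=0.1, seed=6
        )

    def test_open_cylinder_spans(self):
        prof = self._profile()
        span = detect_span(prof, (prof.z[2], prof.z[-3]), r_open=0.1)
        assert span.spans_membrane

    def test_blocked_cylinder_does_not_span(self):
        system, frame, atoms, radii = cylinder_inputs(blocked_z=0.0)
        # the blocking atom sits on the axis at construction z=0, which
        # is shifted into the box like the rest
        z = frame.coordinates[:-1, 2]
        radii = np.full(system.n_atoms, 0.15)
        # enlarge the blocker so the slab is fully occluded
        radii[-1] = 0.5
        prof = channel_profile(
            frame,
            np.arange(system.n_atoms),
            radii,
            z_range=(z.min(), z.max()),
            dz=0.1,
            seed=6,
        )
        span = detect_span(prof, (prof.z[2], prof.z[-3]), r_open=0.1)
        assert not span.spans_membrane

    def test_threshold_sweep_is_exact_at_minimum(self):
        prof = self._profile()
        membrane = (prof.z[2], prof.z[-3])
        inside = (prof.z >= membrane[0]) & (prof.z <= membrane[1])
        r_min = prof.radius[inside].min()
        assert detect_span(prof, membrane, r_open=r_min).spans_membrane
        assert not detect_span(prof, membrane, r_open=r_min + 1e-6).spans_membrane

    def test_bundle_pore_spans_membrane(self, pore_bundle):
        traj, truth = pore_bundle
        prot = np.asarray(truth["protein_atoms"])
        radii = vdw_radii(traj.system, prot)
        zs = traj.frames[0].coordinates[prot, 2]
        prof = channel_profile(
            traj.frames[0],
            prot,
            radii,
            z_range=(zs.min() + 0.3, zs.max() - 0.3),
            dz=0.2,
            seed=0,
        )
        span = detect_span(prof, truth["membrane_z"], r_open=0.1)
        assert span.spans_membrane
        # the pore is the geometric radius minus the (largest) vdW radius
        geo = truth["geometric_pore_radius"]
        assert span.min_radius == pytest.approx(geo - 0.17, abs=0.05)
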