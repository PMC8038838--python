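"""Pore-radius profile along the membrane normal and channel-span detection.

At each position z along the pore axis the channel radius is the radius
of the largest sphere, centred in that z plane, that overlaps no
protein atom: r(z) = max over in-plane centres of
min_i(|centre − atom_i| − vdW_i), capped at ``r_max`` (default 1 nm).
The in-plane maximisation is a seeded multi-start Nelder–Mead search
continued from the neighbouring slab's centre, walking outward from the
middle of the protein — a deterministic simplification of the
simulated-annealing sphere walk of classic pore-profiling tools.
Membrane span is then a contiguous stretch of z bins with radius at or
above an opening threshold covering both leaflet boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .core import Frame, MolecularSystem, Trajectory

__all__ = [
    "VDW_RADII_NM",
    "vdw_radii",
    "read_hole_radius_file",
    "ChannelProfile",
    "ChannelSpan",
    "channel_profile",
    "profile_over_time",
    "detect_span",
]

#: Bondi-style van der Waals radii in nm; fallback 0.17 nm.
VDW_RADII_NM = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
    "P": 0.180,
    "F": 0.147,
    "CL": 0.175,
    "K": 0.275,
    "NA": 0.227,
    "MG": 0.173,
}
_DEFAULT_VDW = 0.17


def vdw_radii(system: MolecularSystem, atom_indices: np.ndarray) -> np.ndarray:
    """Per-atom van der Waals radii (nm) from the bundled element table."""
    return np.array(
        [
            VDW_RADII_NM.get(str(system.elements[i]).upper(), _DEFAULT_VDW)
            for i in atom_indices
        ]
    )


def read_hole_radius_file(path) -> dict[str, float]:
    """Read a HOLE-format vdW radius file (``VDWR atom res radius``, Å → nm).

    Records are keyed ``"RES:ATOM"``; ``*`` wildcards are kept verbatim.
    """
    table: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) >= 4 and parts[0].upper() == "VDWR":
                atom, res, radius = parts[1], parts[2], float(parts[3])
                table[f"{res.upper()}:{atom.upper()}"] = radius / 10.0
    return table


@dataclass
class ChannelProfile:
    """Radius r(z) along the pore axis for one frame.

    ``z`` is a uniform strictly-increasing grid (nm, in the axis frame),
    ``radius`` the capped pore radius per bin, ``center`` the optimised
    in-plane (x, y) sphere centre per bin.
    """

    z: np.ndarray
    radius: np.ndarray
    center: np.ndarray
    time: float = 0.0
    r_max: float = 1.0


@dataclass
class ChannelSpan:
    spans_membrane: bool
    interval: tuple[float, float] | None
    min_radius: float


def _axis_frame(axis: np.ndarray) -> np.ndarray:
    """Orthonormal basis with the given axis as its third row."""
    w = np.asarray(axis, dtype=np.float64)
    w = w / np.linalg.norm(w)
    if np.allclose(w, [0.0, 0.0, 1.0]):
        return np.eye(3)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(w @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(helper, w)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return np.vstack([u, v, w])


def _slab_radius(
    center0: np.ndarray,
    z: float,
    xy: np.ndarray,
    zs: np.ndarray,
    radii: np.ndarray,
    r_max: float,
    rng: np.random.Generator,
    n_starts: int,
    max_displacement: float = 0.5,
    jitter: float = 0.08,
) -> tuple[float, np.ndarray]:
    """Maximise the free-sphere radius in one z plane by local search.

    The centre may move at most ``max_displacement`` from the previous
    slab's centre — the channel is followed continuously rather than
    letting the sphere jump out of the pore through a gap elsewhere.
    """
    near = np.abs(zs - z) < r_max + radii.max() + 0.05
    if not np.any(near):
        return r_max, center0
    pxy = xy[near]
    pdz2 = (zs[near] - z) ** 2
    pr = radii[near]

    def neg_radius(c):
        d = np.sqrt(((pxy - c) ** 2).sum(axis=1) + pdz2) - pr
        r = min(d.min(), r_max)
        excess = np.hypot(c[0] - center0[0], c[1] - center0[1]) - max_displacement
        if excess > 0:
            r -= 10.0 * excess
        return -r

    best_r = -np.inf
    best_c = center0
    starts = [center0] + [
        center0 + rng.normal(scale=jitter, size=2) for _ in range(n_starts - 1)
    ]
    for s in starts:
        res = minimize(
            neg_radius,
            s,
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-5, "maxiter": 300},
        )
        if -res.fun > best_r:
            best_r = -res.fun
            best_c = res.x
    return float(np.clip(best_r, 0.0, r_max)), np.asarray(best_c)


def channel_profile(
    frame: Frame,
    atom_indices: np.ndarray,
    radii: np.ndarray,
    axis: np.ndarray = (0.0, 0.0, 1.0),
    z_range: tuple[float, float] | None = None,
    dz: float = 0.1,
    r_max: float = 1.0,
    seed: int = 0,
    n_starts: int = 4,
    seed_point: np.ndarray | None = None,
    max_displacement: float = 0.5,
) -> ChannelProfile:
    """Pore-radius profile of one frame along ``axis``.

    The search starts at the slab nearest the protein centroid (or at
    ``seed_point``, given in the axis frame) and walks outward in both
    directions, each slab's optimisation starting from its neighbour's
    optimised centre — following the channel as it meanders.  Fully
    occluded slabs report radius 0 (with a warning if the whole profile
    is occluded); slabs with no nearby atoms report the cap ``r_max``.
    """
    atom_indices = np.asarray(atom_indices)
    if len(atom_indices) == 0:
        raise ValueError("protein atom set must be non-empty")
    radii = np.asarray(radii, dtype=np.float64)
    basis = _axis_frame(np.asarray(axis, dtype=np.float64))
    pts = frame.coordinates[atom_indices] @ basis.T
    xy, zs = pts[:, :2], pts[:, 2]
    if z_range is None:
        z_range = (float(zs.min()), float(zs.max()))
    zlo, zhi = z_range
    nbins = max(1, int(round((zhi - zlo) / dz)))
    zgrid = zlo + (np.arange(nbins) + 0.5) * (zhi - zlo) / nbins

    rng = np.random.default_rng(seed)
    centroid = (
        np.asarray(seed_point, dtype=np.float64)[:2]
        if seed_point is not None
        else xy.mean(axis=0)
    )
    mid = int(np.argmin(np.abs(zgrid - zs.mean())))
    order = [mid]
    for off in range(1, nbins):
        if mid + off < nbins:
            order.append(mid + off)
        if mid - off >= 0:
            order.append(mid - off)

    radius = np.empty(nbins)
    center = np.empty((nbins, 2))
    prev_up = prev_down = centroid
    for k in order:
        start = prev_up if k >= mid else prev_down
        r, c = _slab_radius(
            start, zgrid[k], xy, zs, radii, r_max, rng, n_starts,
            max_displacement=max_displacement,
        )
        radius[k] = r
        center[k] = c
        if k >= mid:
            prev_up = c
        if k <= mid:
            prev_down = c

    if np.all(radius <= 0):
        warnings.warn("channel profile fully occluded (radius 0 everywhere)")
    return ChannelProfile(
        z=zgrid, radius=radius, center=center, time=frame.time, r_max=r_max
    )


def profile_over_time(
    traj: Trajectory,
    atom_indices: np.ndarray,
    radii: np.ndarray,
    stride: float = 200.0,
    start_time: float = 0.0,
    **kwargs,
) -> list[ChannelProfile]:
    """One profile per strided frame (stride in ps, multiple of dt).

    The first frame of the analysed window (t = start_time) is included.
    """
    if traj.dt > 0:
        ratio = stride / traj.dt
        if abs(ratio - round(ratio)) > 1e-6:
            raise ValueError("stride must be a multiple of the frame interval")
    idx = traj.analyzed_indices(start_time)
    t0 = traj.times[idx[0]]
    profiles = []
    for fi in idx:
        offset = traj.times[fi] - t0
        if traj.dt == 0 or abs(offset % stride) < 1e-6 or abs(
            offset % stride - stride
        ) < 1e-6:
            profiles.append(
                channel_profile(traj.frames[fi], atom_indices, radii, **kwargs)
            )
    return profiles


def detect_span(
    profile: ChannelProfile,
    membrane_z: tuple[float, float],
    r_open: float = 0.1,
) -> ChannelSpan:
    """Does an open channel cross the whole membrane slab?

    True iff one contiguous run of z bins with radius >= ``r_open``
    covers both membrane boundaries.  Reports the run's z interval and
    its minimum radius inside the membrane.
    """
    zlo, zhi = membrane_z
    open_mask = profile.radius >= r_open
    n = len(open_mask)
    half_bin = (profile.z[1] - profile.z[0]) / 2 if n > 1 else 0.0
    i = 0
    while i < n:
        if open_mask[i]:
            j = i
            while j < n and open_mask[j]:
                j += 1
            z_start = profile.z[i]
            z_end = profile.z[j - 1]
            if z_start - half_bin <= zlo and z_end + half_bin >= zhi:
                inside = (profile.z >= zlo) & (profile.z <= zhi)
                return ChannelSpan(
                    spans_membrane=True,
                    interval=(float(z_start), float(z_end)),
                    min_radius=float(profile.radius[inside].min())
                    if np.any(inside)
                    else float(profile.radius[i:j].min()),
                )
            i = j
        else:
            i += 1
    inside = (profile.z >= zlo) & (profile.z <= zhi)
    return ChannelSpan(
        spans_membrane=False,
        interval=None,
        min_radius=float(profile.radius[inside].min()) if np.any(inside) else 0.0,
    )
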