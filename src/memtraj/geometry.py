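"""Periodic-boundary distances, superposition and RMSD.

The scalar minimum-image primitive is implemented here for triclinic
boxes in the reduced convention (row lattice vectors, zero upper
triangle).  Bulk residue-to-group distance matrices go through
MDAnalysis' grid-accelerated ``distance_array``, which handles the same
box convention; the two routes are cross-checked against each other and
against brute-force image enumeration in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import Frame, Trajectory

__all__ = [
    "min_image_distance",
    "pairwise_min_image_distances",
    "min_residue_group_distance",
    "SuperpositionResult",
    "kabsch_superpose",
    "rmsd_timeseries",
    "detect_equilibration",
]

_NEIGHBOR_SHIFTS = np.array(
    [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)],
    dtype=np.float64,
)


def _check_box(box: np.ndarray) -> np.ndarray:
    box = np.asarray(box, dtype=np.float64)
    if box.shape == (3,):
        box = np.diag(box)
    if abs(np.linalg.det(box)) < 1e-12:
        raise ValueError("singular box matrix")
    return box


def min_image_distance(a, b, box) -> float:
    """Minimum-image distance between two points in a triclinic box (nm).

    The displacement is reduced to the central cell in fractional
    coordinates and then minimised over the 27 neighbouring images,
    which is exact for reduced triclinic boxes.
    """
    box = _check_box(box)
    delta = np.asarray(b, np.float64) - np.asarray(a, np.float64)
    frac = np.linalg.solve(box.T, delta)
    frac -= np.round(frac)
    images = (frac[None, :] + _NEIGHBOR_SHIFTS) @ box
    return float(np.sqrt(np.min(np.einsum("ij,ij->i", images, images))))


def _mda_box(box: np.ndarray) -> np.ndarray:
    from MDAnalysis.lib import mdamath

    return np.asarray(mdamath.triclinic_box(*box), dtype=np.float32)


def pairwise_min_image_distances(
    coords_a: np.ndarray, coords_b: np.ndarray, box: np.ndarray | None
) -> np.ndarray:
    """(n_a, n_b) matrix of minimum-image distances.

    Delegates to MDAnalysis' distance_array (cell-list accelerated for
    large inputs); with ``box=None`` plain Euclidean distances.
    """
    from MDAnalysis.lib import distances

    a = np.ascontiguousarray(coords_a, dtype=np.float32)
    b = np.ascontiguousarray(coords_b, dtype=np.float32)
    mda_box = None if box is None else _mda_box(_check_box(box))
    return distances.distance_array(a, b, box=mda_box)


def min_residue_group_distance(
    frame: Frame,
    residue_atoms: np.ndarray,
    group_atoms: np.ndarray,
    use_pbc: bool = True,
) -> float:
    """Minimum distance between any residue atom and any group atom (nm)."""
    residue_atoms = np.asarray(residue_atoms)
    group_atoms = np.asarray(group_atoms)
    if len(residue_atoms) == 0 or len(group_atoms) == 0:
        raise ValueError("residue and group atom sets must be non-empty")
    dmat = pairwise_min_image_distances(
        frame.coordinates[residue_atoms],
        frame.coordinates[group_atoms],
        frame.box if use_pbc else None,
    )
    return float(dmat.min())


# ---------------------------------------------------------------------------
# superposition / RMSD
# ---------------------------------------------------------------------------

@dataclass
class SuperpositionResult:
    """Optimal rigid-body fit of a mobile point set onto a reference.

    ``rotation`` (proper, det=+1) and ``translation`` map mobile
    coordinates as ``x' = rotation @ (x - mobile_centroid) + translation``
    where ``translation`` is the (weighted) reference centroid.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray, mobile_centroid: np.ndarray) -> np.ndarray:
        return (coords - mobile_centroid) @ self.rotation.T + self.translation


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares rigid superposition (Kabsch, reflections excluded).

    Returns the proper rotation and translation minimising the
    (weighted) RMSD between the point sets, and that RMSD in nm.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("at least 3 points are required")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=np.float64)
        w = w / w.sum()
    com_m = w @ mobile
    com_r = w @ reference
    x = mobile - com_m
    y = reference - com_r
    h = (x * w[:, None]).T @ y
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-12:  # rank < 2: collinear or degenerate point set
        raise ValueError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = x @ rot.T - y
    rmsd = float(np.sqrt(np.sum(w * np.einsum("ij,ij->i", diff, diff))))
    return SuperpositionResult(rotation=rot, translation=com_r, rmsd=rmsd)


def rmsd_timeseries(
    traj: Trajectory,
    reference: Frame,
    selection: np.ndarray | None = None,
    fit: bool = True,
) -> np.ndarray:
    """Per-frame RMSD against a reference frame.

    Returns an (n_frames, 2) array of (time ps, rmsd nm).  With
    ``fit=True`` every frame is Kabsch-superposed onto the reference
    over the selection before the deviation is measured; with
    ``fit=False`` only the raw coordinate deviation is taken.
    """
    if selection is None:
        selection = np.arange(traj.system.n_atoms)
    selection = np.asarray(selection)
    if len(selection) == 0:
        raise ValueError("selection must be non-empty")
    ref = reference.coordinates[selection]
    out = np.empty((len(traj), 2))
    for k, frame in enumerate(traj):
        mob = frame.coordinates[selection]
        if fit:
            rmsd = kabsch_superpose(mob, ref).rmsd
        else:
            diff = mob - ref
            rmsd = float(np.sqrt(np.mean(np.einsum("ij,ij->i", diff, diff))))
        out[k] = (frame.time, rmsd)
    return out


def detect_equilibration(
    series: np.ndarray, window: float = 10000.0, slope_tol: float = 0.005
) -> float:
    """Earliest time after which a running-window RMSD slope stays flat.

    ``series`` is (n, 2) of (time ps, value nm); ``window`` in ps;
    ``slope_tol`` in nm/ns.  Scans windows [t, t+window] and returns the
    first start time from which every subsequent full window has
    |linear slope| below the tolerance.  If the series never flattens,
    the final time is returned with a warning.
    """
    series = np.asarray(series, dtype=np.float64)
    times, values = series[:, 0], series[:, 1]
    span = times[-1] - times[0]
    if span < 2 * window:
        raise ValueError("series must span at least twice the window")
    slopes = []
    starts = []
    for i in range(len(times)):
        j = np.searchsorted(times, times[i] + window, side="right")
        if j - i < 2 or times[j - 1] - times[i] < window * 0.999:
            break
        t = times[i:j] - times[i]
        v = values[i:j]
        slope = np.polyfit(t, v, 1)[0] * 1000.0  # nm/ps → nm/ns
        slopes.append(abs(slope))
        starts.append(times[i])
    slopes_arr = np.array(slopes)
    flat = slopes_arr < slope_tol
    # last index from which all remaining windows are flat
    ok_from = None
    for i in range(len(flat) - 1, -1, -1):
        if not flat[i]:
            break
        ok_from = i
    if ok_from is None:
        warnings.warn("series never equilibrates within tolerance")
        return float(times[-1])
    return float(starts[ok_from])
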