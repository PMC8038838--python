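"""Residue–group contact statistics: proximity, binding events, residence times.

For every protein residue and every particle group (water, lipid tails,
ions, ligand) the per-frame minimum distance between any residue atom
and any group atom defines a contact time series at a cutoff (default
0.4 nm, strict ``<``).  From it follow the three statistics reported
per residue:

* **proximity** P — the fraction of analysed frames in contact, the
  probability of finding any group particle within the cutoff;
* **binding events** Nb — a frame in contact immediately preceded by a
  frame out of contact starts an event, so a series that *begins* in
  contact does not count its initial stretch;
* **residence time** t̄ — each event lasts until the distance first
  exceeds the cutoff again; its duration counts the triggering frame,
  i.e. (number of consecutive in-contact frames) × dt.  The mean over
  events gives t̄.  An event still in contact at the final frame is
  censored (true duration unknown) and excluded from t̄ by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Frame, GroupRole, Trajectory
from .geometry import pairwise_min_image_distances

__all__ = [
    "ContactSeries",
    "BindingEvents",
    "ContactStats",
    "contact_series",
    "proximity",
    "binding_events",
    "mean_residence_time",
    "residue_group_distance_matrix",
    "contact_stats_all",
]

DEFAULT_CUTOFF_NM = 0.4


@dataclass
class ContactSeries:
    """Per-frame minimum residue–group distance and contact state."""

    residue_index: int
    group: GroupRole
    times: np.ndarray  # ps
    distances: np.ndarray  # nm
    cutoff: float
    dt: float  # ps

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.distances = np.asarray(self.distances, dtype=np.float64)
        if len(self.times) != len(self.distances):
            raise ValueError("times and distances must be the same length")

    @property
    def in_contact(self) -> np.ndarray:
        return self.distances < self.cutoff

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class BindingEvents:
    n_events: int
    durations: np.ndarray  # ps, one per event, in order; includes censored last
    censored_last: bool


@dataclass
class ContactStats:
    """Aggregated per residue×group statistics (possibly over replicas)."""

    residue_index: int
    group: GroupRole
    proximity: float
    n_events: float  # mean per run by default
    mean_residence_ps: float  # NaN when no (uncensored) events
    event_durations: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_censored: int = 0


def contact_series(
    traj: Trajectory,
    residue_index: int,
    group: GroupRole | str,
    cutoff: float = DEFAULT_CUTOFF_NM,
    start_time: float = 0.0,
    heavy_only: bool = False,
) -> ContactSeries:
    """Minimum-distance series from one residue to a particle group."""
    group = GroupRole(group)
    system = traj.system
    res_atoms = system.residue_atoms(residue_index)
    if heavy_only:
        res_atoms = res_atoms[system.elements[res_atoms] != "H"]
    grp_atoms = system.group_atoms(group, heavy_only=heavy_only)
    if len(grp_atoms) == 0:
        raise ValueError(f"group {group.value!r} contains no atoms")
    idx = traj.analyzed_indices(start_time)
    dists = np.empty(len(idx))
    for k, fi in enumerate(idx):
        fr = traj.frames[fi]
        dists[k] = pairwise_min_image_distances(
            fr.coordinates[res_atoms], fr.coordinates[grp_atoms], fr.box
        ).min()
    return ContactSeries(
        residue_index=residue_index,
        group=group,
        times=traj.times[idx],
        distances=dists,
        cutoff=cutoff,
        dt=traj.dt,
    )


def proximity(series: ContactSeries) -> float:
    """Fraction of analysed frames in contact: 1 = always, 0 = never."""
    if len(series) == 0:
        raise ValueError("empty contact series")
    return float(series.in_contact.mean())


def _events_from_mask(contact: np.ndarray, dt: float) -> BindingEvents:
    contact = np.asarray(contact, dtype=bool)
    n = len(contact)
    durations: list[float] = []
    censored = False
    i = 0
    # skip an initial bound stretch: an event needs a preceding unbound frame
    while i < n and contact[i]:
        i += 1
    while i < n:
        if contact[i]:
            j = i
            while j < n and contact[j]:
                j += 1
            durations.append((j - i) * dt)
            if j == n:
                censored = True
            i = j
        else:
            i += 1
    return BindingEvents(
        n_events=len(durations),
        durations=np.asarray(durations, dtype=np.float64),
        censored_last=censored,
    )


def binding_events(series: ContactSeries) -> BindingEvents:
    """Count binding events and their durations.

    An event is triggered by an out-of-contact frame followed by an
    in-contact frame; it lasts while the distance stays below the
    cutoff, the triggering frame counting as the first dt of residence.
    A trajectory that opens in contact contributes that stretch to the
    proximity but not to the event statistics, and an event still bound
    at the last frame is flagged censored.
    """
    if len(series) < 2:
        raise ValueError("binding events need at least two frames")
    return _events_from_mask(series.in_contact, series.dt)


def mean_residence_time(
    durations: np.ndarray,
    censored_last: bool = False,
    include_censored: bool = False,
) -> float:
    """Arithmetic mean event duration in ps; NaN when no usable events.

    A censored final event (still bound at the end) is dropped unless
    ``include_censored`` — its recorded duration is a lower bound only.
    """
    durations = np.asarray(durations, dtype=np.float64)
    if censored_last and not include_censored and len(durations):
        durations = durations[:-1]
    if len(durations) == 0:
        return float("nan")
    return float(durations.mean())


# ---------------------------------------------------------------------------
# bulk computation
# ---------------------------------------------------------------------------

def residue_group_distance_matrix(
    traj: Trajectory,
    residues: np.ndarray,
    group: GroupRole | str,
    start_time: float = 0.0,
    heavy_only: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """(times, D) with D of shape (n_frames, n_residues): per-frame
    minimum distance from each residue to the group.

    One distance matrix per frame between all selected protein atoms
    and all group atoms, reduced per residue — much faster than calling
    :func:`contact_series` residue by residue.
    """
    group = GroupRole(group)
    system = traj.system
    residues = np.asarray(residues)
    atom_idx = []
    starts = []
    for ri in residues:
        span = system.residue_atoms(int(ri))
        if heavy_only:
            span = span[system.elements[span] != "H"]
        starts.append(len(atom_idx))
        atom_idx.extend(span.tolist())
    atom_idx = np.asarray(atom_idx)
    starts = np.asarray(starts)
    grp_atoms = system.group_atoms(group, heavy_only=heavy_only)
    if len(grp_atoms) == 0:
        raise ValueError(f"group {group.value!r} contains no atoms")
    idx = traj.analyzed_indices(start_time)
    out = np.empty((len(idx), len(residues)))
    for k, fi in enumerate(idx):
        fr = traj.frames[fi]
        dmat = pairwise_min_image_distances(
            fr.coordinates[atom_idx], fr.coordinates[grp_atoms], fr.box
        )
        per_atom = dmat.min(axis=1)
        out[k] = np.minimum.reduceat(per_atom, starts)
    return traj.times[idx], out


def contact_stats_all(
    trajs: list[Trajectory],
    groups: tuple[GroupRole | str, ...] = (
        GroupRole.WATER,
        GroupRole.LIPID_TAIL,
        GroupRole.ION,
        GroupRole.LIGAND,
    ),
    cutoff: float = DEFAULT_CUTOFF_NM,
    start_time: float = 0.0,
    heavy_only: bool = False,
    nb_mode: str = "mean",
    include_censored: bool = False,
) -> pd.DataFrame:
    """Contact statistics for every protein residue × group over replicas.

    Proximity is the equal-weight mean of per-run proximities; the event
    count is the mean per run (``nb_mode="mean"``) or the total over
    runs (``"sum"``); residence times are pooled over all events of all
    runs before averaging.  Returns a tidy DataFrame with one row per
    residue×group.
    """
    if not trajs:
        raise ValueError("at least one trajectory is required")
    system = trajs[0].system
    for t in trajs[1:]:
        if t.system.n_atoms != system.n_atoms:
            raise ValueError("trajectories come from inconsistent systems")
    if nb_mode not in ("mean", "sum"):
        raise ValueError("nb_mode must be 'mean' or 'sum'")
    residues = system.protein_residues
    rows = []
    for group in groups:
        group = GroupRole(group)
        per_run_P = []
        per_run_events: list[list[BindingEvents]] = []
        for traj in trajs:
            _, dmat = residue_group_distance_matrix(
                traj, residues, group, start_time=start_time, heavy_only=heavy_only
            )
            contact = dmat < cutoff
            per_run_P.append(contact.mean(axis=0))
            per_run_events.append(
                [_events_from_mask(contact[:, r], traj.dt) for r in range(len(residues))]
            )
        P = np.mean(per_run_P, axis=0)
        for r, ri in enumerate(residues):
            events = [run_ev[r] for run_ev in per_run_events]
            counts = [ev.n_events for ev in events]
            pooled = []
            n_censored = 0
            for ev in events:
                durs = ev.durations
                if ev.censored_last:
                    n_censored += 1
                    if not include_censored and len(durs):
                        durs = durs[:-1]
                pooled.append(durs)
            pooled_arr = np.concatenate(pooled) if pooled else np.empty(0)
            nb = float(np.mean(counts)) if nb_mode == "mean" else float(np.sum(counts))
            rows.append(
                ContactStats(
                    residue_index=int(ri),
                    group=group,
                    proximity=float(P[r]),
                    n_events=nb,
                    mean_residence_ps=(
                        float(pooled_arr.mean()) if len(pooled_arr) else float("nan")
                    ),
                    event_durations=pooled_arr,
                    n_censored=n_censored,
                )
            )
    return pd.DataFrame(
        {
            "residue_index": [s.residue_index for s in rows],
            "residue_seq": [
                int(system.residue_seqs[s.residue_index]) for s in rows
            ],
            "residue_name": [
                str(system.residue_names[s.residue_index]) for s in rows
            ],
            "group": [s.group.value for s in rows],
            "proximity": [s.proximity for s in rows],
            "n_events": [s.n_events for s in rows],
            "mean_residence_ps": [s.mean_residence_ps for s in rows],
            "n_censored": [s.n_censored for s in rows],
        }
    )
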