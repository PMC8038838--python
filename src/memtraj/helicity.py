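"""Per-residue helicity from the i→i+4 backbone hydrogen-bond distance.

The helicity metric is the distance between the backbone carbonyl
oxygen of residue n and the backbone amide nitrogen of residue n+4,
averaged over the analysed frames.  In an ideal α-helix this O(n)···
N(n+4) distance sits near 0.29–0.31 nm; below 0.35 nm the hydrogen bond
is considered formed and the residue is classified helical.  The
heavy-atom O···N proxy is used (rather than O···H) so the metric is
defined on heavy-atom-only models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Frame, GroupRole, Trajectory
from .geometry import min_image_distance

__all__ = [
    "HelicityProfile",
    "HelixSegment",
    "helicity_profile",
    "aggregate_profiles",
    "classify_helical",
    "call_segments",
    "segments_to_bed",
]

HBOND_THRESHOLD_NM = 0.35


@dataclass
class HelicityProfile:
    """Mean O(n)···N(n+4) distance per residue.

    ``residue_indices`` are the 0-based indices n for which residue n+4
    exists; residues whose backbone O or N could not be resolved carry
    NaN.  ``per_run`` keeps the individual replica profiles when the
    profile was aggregated over runs.
    """

    residue_indices: np.ndarray
    residue_seqs: np.ndarray
    mean_distance: np.ndarray
    per_run: list[np.ndarray] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue_index": self.residue_indices,
                "residue_seq": self.residue_seqs,
                "mean_distance_nm": self.mean_distance,
            }
        )


@dataclass
class HelixSegment:
    start: int  # first residue index (inclusive)
    end: int  # past-the-end residue index (0-based half-open)
    label: str = "helix"

    @property
    def length(self) -> int:
        return self.end - self.start


def helicity_profile(
    traj: Trajectory,
    residues: np.ndarray | None = None,
    start_time: float = 0.0,
) -> HelicityProfile:
    """Mean O(n)···N(n+4) distance over frames with time >= start_time.

    ``residues`` restricts the profile to a residue-index subset
    (default: all protein residues, or all residues when no group roles
    are assigned).  A residue missing its backbone O, or whose n+4
    partner is missing N, gets NaN rather than raising.
    """
    system = traj.system
    if residues is None:
        residues = system.protein_residues
        if len(residues) == 0:
            residues = np.arange(system.n_residues)
    residues = np.asarray(residues)
    valid_n = residues[np.isin(residues + 4, residues)]
    # the i→i+4 partner must belong to the same chain: separate helices
    # of a bundle must not produce spurious cross-chain pairs
    same_chain = np.array(
        [system.chain_ids[n] == system.chain_ids[n + 4] for n in valid_n], dtype=bool
    )
    valid_n = valid_n[same_chain]
    frame_idx = traj.analyzed_indices(start_time)

    pairs = []  # (n, O-atom, N-atom) with None marking unresolvable
    for n in valid_n:
        o = system.find_atom(int(n), "O")
        if o is None:
            o = system.find_atom(int(n), "O1")
        nn = system.find_atom(int(n) + 4, "N")
        pairs.append((int(n), o, nn))

    mean_d = np.full(len(pairs), np.nan)
    for p, (n, o, nn) in enumerate(pairs):
        if o is None or nn is None:
            continue
        acc = 0.0
        for k in frame_idx:
            fr = traj.frames[k]
            acc += min_image_distance(fr.coordinates[o], fr.coordinates[nn], fr.box)
        mean_d[p] = acc / len(frame_idx)

    return HelicityProfile(
        residue_indices=valid_n,
        residue_seqs=system.residue_seqs[valid_n],
        mean_distance=mean_d,
    )


def aggregate_profiles(profiles: list[HelicityProfile]) -> HelicityProfile:
    """Average replica profiles: the mean of per-run mean distances.

    With equal frame counts per run this equals the pooled mean over all
    frames.  Residue sets must match across runs.
    """
    if not profiles:
        raise ValueError("no profiles to aggregate")
    first = profiles[0]
    for p in profiles[1:]:
        if not np.array_equal(p.residue_indices, first.residue_indices):
            raise ValueError("profiles cover different residue sets")
    stacked = np.stack([p.mean_distance for p in profiles])
    return HelicityProfile(
        residue_indices=first.residue_indices.copy(),
        residue_seqs=first.residue_seqs.copy(),
        mean_distance=stacked.mean(axis=0),
        per_run=[p.mean_distance for p in profiles],
    )


def classify_helical(
    profile: HelicityProfile, threshold: float = HBOND_THRESHOLD_NM
) -> np.ndarray:
    """Boolean per profile entry: helical iff mean distance < threshold.

    NaN entries (unresolvable backbone atoms) classify as non-helical.
    """
    with np.errstate(invalid="ignore"):
        return np.asarray(profile.mean_distance < threshold)


def call_segments(
    helical: np.ndarray, min_length: int = 5, max_gap: int = 2
) -> list[HelixSegment]:
    """Merge helical residues into segments, bridging short interruptions.

    Helical regions in real profiles are "primarily" below the
    hydrogen-bond threshold, with occasional frames-averaged outliers;
    runs of helical residues separated by at most ``max_gap``
    non-helical residues are merged, and merged runs shorter than
    ``min_length`` residues are discarded.
    """
    helical = np.asarray(helical, dtype=bool)
    segments: list[HelixSegment] = []
    runs = []
    i = 0
    n = len(helical)
    while i < n:
        if helical[i]:
            j = i
            while j < n and helical[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] <= max_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    for start, end in merged:
        if end - start >= min_length:
            segments.append(HelixSegment(start=start, end=end))
    return segments


def label_segments(
    segments: list[HelixSegment],
    residue_z: np.ndarray,
    membrane_z: tuple[float, float],
) -> list[HelixSegment]:
    """Label segments TM when their z extent crosses both leaflet planes."""
    zlo, zhi = membrane_z
    out = []
    for seg in segments:
        z = residue_z[seg.start : seg.end]
        label = "TM" if z.min() <= zlo and z.max() >= zhi else "loop-helix"
        out.append(HelixSegment(seg.start, seg.end, label))
    return out


def segments_to_bed(
    segments: list[HelixSegment], chrom: str = "protein"
) -> pd.DataFrame:
    """Segment list as BED-like 0-based half-open intervals over residues."""
    return pd.DataFrame(
        {
            "chrom": [chrom] * len(segments),
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "label": [s.label for s in segments],
        }
    )
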