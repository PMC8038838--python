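"""End-to-end per-model analysis: load → trim → RMSD → helicity → contacts → channel.

The pipeline reproduces a standard multi-replica membrane-protein
analysis: several runs of one model are loaded, the equilibration
segment is trimmed (default 50 ns, justified by the RMSD plateau),
and per-residue helicity, per-residue×group contact statistics and the
pore-radius profile are computed and averaged over runs with equal
weight.  All outputs are plain TSV with a config-hash header comment,
so a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import channel as channel_mod
from . import contacts as contacts_mod
from . import helicity as helicity_mod
from .core import Frame, GroupRole, MolecularSystem, Trajectory
from .geometry import kabsch_superpose, rmsd_timeseries
from .io import SelectionSpec, assign_groups, load_structure, load_trajectory

__all__ = ["RunConfig", "AnalysisReport", "run_pipeline", "pairwise_model_rmsd"]

ALL_STAGES = ("rmsd", "helicity", "contacts", "channel")
BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass
class ChannelConfig:
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    dz: float = 0.2  # nm slab thickness
    r_max: float = 1.0  # nm radius cap
    stride_ps: float = 200.0  # profile every 200 ps
    r_open: float = 0.1  # nm opening threshold for span detection
    membrane_z: tuple[float, float] | None = None  # inferred from tails if None
    n_starts: int = 4


@dataclass
class RunConfig:
    """Configuration of one model's multi-run analysis."""

    runs: list[dict]  # each: {structure, trajectory, format?, dt?}
    out_dir: str = "memtraj_out"
    selection: str | None = None  # YAML selection spec; None = built-in default
    contact_cutoff: float = 0.4  # nm
    helicity_threshold: float = 0.35  # nm
    equilibration_trim_ps: float = 50000.0
    groups: tuple[str, ...] = ("water", "lipid_tail", "ion", "ligand")
    heavy_only: bool = False
    nb_mode: str = "mean"
    channel: ChannelConfig = field(default_factory=ChannelConfig)
    proximity_bands: tuple[tuple[float, float], ...] = ((0.01, 0.3), (0.4, 1.0))
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValueError("at least one run is required")
        if self.contact_cutoff <= 0 or self.helicity_threshold <= 0:
            raise ValueError("cutoffs must be positive")
        for stage in self.stages:
            if stage not in ALL_STAGES:
                raise ValueError(f"unknown stage {stage!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        chan = data.pop("channel", {})
        if "membrane_z" in chan and chan["membrane_z"] is not None:
            chan["membrane_z"] = tuple(chan["membrane_z"])
        if "axis" in chan:
            chan["axis"] = tuple(chan["axis"])
        data["channel"] = ChannelConfig(**chan)
        if "groups" in data:
            data["groups"] = tuple(data["groups"])
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        base = Path(path).parent
        for run in data["runs"]:
            for key in ("structure", "trajectory"):
                if key in run and not Path(run[key]).is_absolute():
                    run[key] = str(base / run[key])
        return cls(**data)

    def config_hash(self) -> str:
        # hash only the scientific parameters: stage gating and output
        # location must not perturb the tables the other stages write
        payload = json.dumps(
            {
                k: v
                for k, v in self.__dict__.items()
                if k not in ("channel", "stages", "out_dir")
            }
            | {"channel": self.channel.__dict__},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    helicity: pd.DataFrame | None = None
    segments: pd.DataFrame | None = None
    contacts: dict[str, pd.DataFrame] = field(default_factory=dict)
    rmsd: dict[int, np.ndarray] = field(default_factory=dict)
    channel_summary: pd.DataFrame | None = None
    channel_profiles: pd.DataFrame | None = None
    manifest: dict[str, str] = field(default_factory=dict)


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_runs(config: RunConfig) -> list[Trajectory]:
    spec = (
        SelectionSpec.from_yaml(config.selection)
        if config.selection
        else None
    )
    trajs = []
    for run in config.runs:
        system = load_structure(run["structure"])
        traj = load_trajectory(
            run["trajectory"],
            system,
            format=run.get("format"),
            dt=run.get("dt"),
        )
        system = assign_groups(system, spec, frame=traj.frames[0])
        traj.system = system
        trajs.append(traj)
    return trajs


def _infer_membrane_z(traj: Trajectory, start_time: float) -> tuple[float, float]:
    """Membrane slab from the 5–95% z quantiles of the lipid-tail atoms."""
    tails = traj.system.group_atoms(GroupRole.LIPID_TAIL)
    if len(tails) == 0:
        raise ValueError(
            "cannot infer the membrane slab: no lipid-tail atoms; "
            "set channel.membrane_z explicitly"
        )
    fr = traj.frames[traj.analyzed_indices(start_time)[0]]
    z = fr.coordinates[tails, 2]
    return (float(np.quantile(z, 0.05)), float(np.quantile(z, 0.95)))


def run_pipeline(config: RunConfig) -> AnalysisReport:
    """Execute the enabled stages and write all tables into ``out_dir``.

    Identical config and seed yield byte-identical TSV outputs.  A
    failing stage removes the files it already wrote and aborts with an
    error naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    report = AnalysisReport()
    trim = config.equilibration_trim_ps
    trajs = _load_runs(config)

    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = out / name
        _write_tsv(df, path, cfg_hash)
        written.append(path)

    def run_stage(name, fn):
        if name not in config.stages:
            return
        stage_written_before = len(written)
        try:
            fn()
        except Exception as exc:
            for p in written[stage_written_before:]:
                p.unlink(missing_ok=True)
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    def stage_rmsd():
        for i, traj in enumerate(trajs, start=1):
            sel = traj.system.group_atoms(GroupRole.PROTEIN)
            if len(sel) == 0:
                sel = np.arange(traj.system.n_atoms)
            series = rmsd_timeseries(traj, traj.frames[0], selection=sel, fit=True)
            report.rmsd[i] = series
            emit(
                pd.DataFrame({"time_ps": series[:, 0], "rmsd_nm": series[:, 1]}),
                f"rmsd_run{i}.tsv",
            )

    def stage_helicity():
        profiles = [
            helicity_mod.helicity_profile(t, start_time=trim) for t in trajs
        ]
        profile = helicity_mod.aggregate_profiles(profiles)
        helical = helicity_mod.classify_helical(profile, config.helicity_threshold)
        system = trajs[0].system
        df = profile.to_frame()
        df["chain"] = [str(system.chain_ids[i]) for i in profile.residue_indices]
        df["helical"] = helical
        report.helicity = df
        # segments are called chain by chain so helices of a bundle are
        # never merged across chain breaks
        seg_frames = []
        for chain in dict.fromkeys(df["chain"]):
            mask = (df["chain"] == chain).to_numpy()
            segments = helicity_mod.call_segments(helical[mask])
            idx_map = profile.residue_indices[mask]
            for seg in segments:
                seg.start = int(idx_map[seg.start])
                seg.end = int(idx_map[seg.end - 1]) + 1
            seg_frames.append(helicity_mod.segments_to_bed(segments, chrom=chain))
        report.segments = pd.concat(seg_frames, ignore_index=True)
        emit(df, "helicity.tsv")
        emit(report.segments, "segments.tsv")

    def stage_contacts():
        df = contacts_mod.contact_stats_all(
            trajs,
            groups=tuple(GroupRole(g) for g in config.groups),
            cutoff=config.contact_cutoff,
            start_time=trim,
            heavy_only=config.heavy_only,
            nb_mode=config.nb_mode,
        )
        for group in config.groups:
            sub = df[df["group"] == group].reset_index(drop=True)
            report.contacts[group] = sub
            emit(sub, f"contacts_{group}.tsv")

    def stage_channel():
        cc = config.channel
        membrane_z = cc.membrane_z or _infer_membrane_z(trajs[0], trim)
        rows = []
        profile_rows = []
        for i, traj in enumerate(trajs, start=1):
            system = traj.system
            prot = system.group_atoms(GroupRole.PROTEIN)
            radii = channel_mod.vdw_radii(system, prot)
            fr0 = traj.frames[traj.analyzed_indices(trim)[0]]
            zs = fr0.coordinates[prot, 2]
            profiles = channel_mod.profile_over_time(
                traj,
                prot,
                radii,
                stride=cc.stride_ps,
                start_time=trim,
                axis=np.asarray(cc.axis),
                z_range=(float(zs.min()) + 0.2, float(zs.max()) - 0.2),
                dz=cc.dz,
                r_max=cc.r_max,
                seed=config.seed,
                n_starts=cc.n_starts,
            )
            for prof in profiles:
                span = channel_mod.detect_span(prof, membrane_z, cc.r_open)
                rows.append(
                    {
                        "run": i,
                        "time_ps": prof.time,
                        "min_radius_nm": span.min_radius,
                        "spans_membrane": span.spans_membrane,
                    }
                )
                for z, r, (cx, cy) in zip(prof.z, prof.radius, prof.center):
                    profile_rows.append(
                        {
                            "run": i,
                            "time_ps": prof.time,
                            "z_nm": z,
                            "radius_nm": r,
                            "cx_nm": cx,
                            "cy_nm": cy,
                        }
                    )
        report.channel_summary = pd.DataFrame(rows)
        report.channel_profiles = pd.DataFrame(profile_rows)
        emit(report.channel_summary, "channel_summary.tsv")
        emit(report.channel_profiles, "channel_profiles.tsv")

    run_stage("rmsd", stage_rmsd)
    run_stage("helicity", stage_helicity)
    run_stage("contacts", stage_contacts)
    run_stage("channel", stage_channel)

    report.manifest = {p.name: _sha256(p) for p in written}
    with open(out / "manifest.json", "w") as fh:
        json.dump(
            {"config_hash": cfg_hash, "files": report.manifest},
            fh,
            indent=2,
            sort_keys=True,
        )
    return report


def pairwise_model_rmsd(
    models: list[tuple[MolecularSystem, Frame]],
    backbone: tuple[str, ...] = BACKBONE_NAMES,
) -> np.ndarray:
    """Backbone RMSD matrix between structural models of one protein.

    Homology models built from different templates cover slightly
    different residue ranges; the comparison uses the backbone atoms of
    the residues present in *all* models, matched by author residue
    number, Kabsch-superposing each pair.  Returns a symmetric matrix
    in nm with a zero diagonal.
    """
    if len(models) < 2:
        raise ValueError("at least two models are required")
    shared: set[int] | None = None
    for system, _ in models:
        residues = system.protein_residues
        if len(residues) == 0:
            residues = np.arange(system.n_residues)
        seqs = {int(system.residue_seqs[r]) for r in residues}
        shared = seqs if shared is None else shared & seqs
    if not shared:
        raise ValueError("models share no residues")
    shared_sorted = sorted(shared)

    coords = []
    for system, frame in models:
        seq_to_res = {}
        residues = system.protein_residues
        if len(residues) == 0:
            residues = np.arange(system.n_residues)
        for r in residues:
            seq_to_res.setdefault(int(system.residue_seqs[r]), int(r))
        pts = []
        for seq in shared_sorted:
            ri = seq_to_res[seq]
            for name in backbone:
                ai = system.find_atom(ri, name)
                if ai is None:
                    raise ValueError(
                        f"residue {seq} lacks backbone atom {name!r} in one model"
                    )
                pts.append(frame.coordinates[ai])
        coords.append(np.asarray(pts))

    n = len(models)
    matrix = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rmsd = kabsch_superpose(coords[i], coords[j]).rmsd
            matrix[i, j] = matrix[j, i] = rmsd
    return matrix
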