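"""Synthetic systems and trajectories with known ground truth.

Every statistic in the package is testable against these generators
without external data:

* :func:`make_ideal_helix` — a poly-alanine backbone with standard bond
  geometry laid on an ideal helical path (default rise 0.15 nm/residue,
  twist 100°/residue), whose O(n)···N(n+4) distances are below the
  0.35 nm hydrogen-bond threshold by construction;
* :func:`make_markov_contact_trajectory` — a one-residue "protein" and
  a single group particle whose distance hops between a bound and an
  unbound value following a two-state Markov chain with per-frame entry
  probability a and exit probability b, so that proximity, event counts
  and residence times have closed forms: E[P] = a/(a+b),
  E[t̄] = dt/b, E[Nb] ≈ N·a·b/(a+b);
* :func:`make_pore_bundle` — a ring of ideal transmembrane helices
  around an axial pore inside a membrane slab, with water/ions/ligand
  random-walking outside the slab, tail particles inside it, and an
  optional harmonic loitering bias drawing ligand particles to chosen
  loop residues.

No forces or energetics are simulated; the generators emulate the
*statistical* structure the analyses consume (compartments, contact
kinetics, sampling interval), not the physics that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .core import Frame, GroupRole, MolecularSystem, Trajectory

__all__ = [
    "HelixSpec",
    "MarkovContactSpec",
    "PoreBundleSpec",
    "make_ideal_helix",
    "make_extended_chain",
    "make_markov_contact_trajectory",
    "make_markov_runs",
    "markov_expectations",
    "make_pore_bundle",
    "make_cylinder",
]


# ---------------------------------------------------------------------------
# backbone geometry
# ---------------------------------------------------------------------------

# standard peptide internal coordinates (Angstrom / degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.229
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_PHI_ALPHA, _PSI_ALPHA, _OMEGA = -57.0, -47.0, 180.0


def _place_atom(a, b, c, bond, angle, torsion):
    """NeRF placement of atom d: bond c–d, angle b–c–d, torsion a–b–c–d."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang, tor = np.radians(angle), np.radians(torsion)
    d = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _build_backbone(n_residues: int, phi: float, psi: float) -> np.ndarray:
    """(n_residues, 4, 3) N/CA/C/O coordinates in nm for given (phi, psi)."""
    n_ext = n_residues + 1  # one extra residue so the last O is placeable
    xyz = np.zeros((n_ext, 3, 3))  # N, CA, C in Angstrom
    xyz[0, 0] = (0.0, 0.0, 0.0)
    xyz[0, 1] = (_B_N_CA, 0.0, 0.0)
    ang = np.radians(_A_N_CA_C)
    xyz[0, 2] = xyz[0, 1] + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_ext):
        xyz[i, 0] = _place_atom(
            xyz[i - 1, 0], xyz[i - 1, 1], xyz[i - 1, 2], _B_C_N, _A_CA_C_N, psi
        )
        xyz[i, 1] = _place_atom(
            xyz[i - 1, 1], xyz[i - 1, 2], xyz[i, 0], _B_N_CA, _A_C_N_CA, _OMEGA
        )
        xyz[i, 2] = _place_atom(
            xyz[i - 1, 2], xyz[i, 0], xyz[i, 1], _B_CA_C, _A_N_CA_C, phi
        )
    out = np.zeros((n_residues, 4, 3))
    out[:, :3] = xyz[:n_residues, :]
    for i in range(n_residues):
        u1 = out[i, 2] - out[i, 1]
        u2 = out[i, 2] - xyz[i + 1, 0]
        u1 /= np.linalg.norm(u1)
        u2 /= np.linalg.norm(u2)
        bis = u1 + u2
        out[i, 3] = out[i, 2] + _B_C_O * bis / np.linalg.norm(bis)
    return out / 10.0  # Angstrom → nm


def _fit_circle(xy: np.ndarray) -> np.ndarray:
    """Algebraic (Kasa) circle fit; exact for points on a true circle."""
    a = np.column_stack([2 * xy[:, 0], 2 * xy[:, 1], np.ones(len(xy))])
    b = (xy**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    return sol[:2]


@lru_cache(maxsize=1)
def _helical_template() -> dict:
    """Cylindrical template of the alpha-helical backbone.

    Builds a long ideal (phi, psi) = (-57, -47) helix with standard bond
    geometry, identifies its axis from second differences of the CA
    trace (which lie in the plane perpendicular to the axis), and
    records each backbone atom type's radius, phase offset and axial
    offset relative to its residue's CA, together with the natural rise
    and twist.  Helices at arbitrary rise/twist are then generated by
    re-parameterising this template along a new helical path.
    """
    n = 40
    bb = _build_backbone(n, _PHI_ALPHA, _PSI_ALPHA)
    ca = bb[:, 1]
    d2 = ca[:-2] - 2 * ca[1:-1] + ca[2:]
    axis = np.cross(d2[10], d2[13])
    axis /= np.linalg.norm(axis)
    if (ca[-1] - ca[0]) @ axis < 0:
        axis = -axis
    # orthonormal in-plane basis
    e1 = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 0.5:
        e1 = np.cross(axis, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    sel = np.arange(5, n - 5)  # away from chain ends (periodic anyway)
    proj_ca = np.column_stack([ca[sel] @ e1, ca[sel] @ e2])
    center = _fit_circle(proj_ca)

    def cylindrical(points):
        xy = np.column_stack([points @ e1, points @ e2]) - center
        radius = np.hypot(xy[:, 0], xy[:, 1])
        phase = np.arctan2(xy[:, 1], xy[:, 0])
        z = points @ axis
        return radius, phase, z

    r_ca, ph_ca, z_ca = cylindrical(ca[sel])
    dph = np.angle(np.exp(1j * np.diff(ph_ca)))
    twist = float(np.mean(dph))
    rise = float(np.mean(np.diff(z_ca)))
    template = {}
    for t, name in enumerate(("N", "CA", "C", "O")):
        r, ph, z = cylindrical(bb[sel, t])
        rel_ph = np.angle(np.exp(1j * (ph - ph_ca)))
        template[name] = (
            float(np.mean(r)),
            float(np.mean(rel_ph)),
            float(np.mean(z - z_ca)),
        )
    return {
        "atoms": template,
        "natural_rise": rise,
        "natural_twist_deg": float(np.degrees(twist)),
        "twist_sign": float(np.sign(twist)),
        "max_radius": max(v[0] for v in template.values()),
    }


# ---------------------------------------------------------------------------
# ideal helix / extended chain
# ---------------------------------------------------------------------------

@dataclass
class HelixSpec:
    """Geometry of a generated poly-alanine helix."""

    n_residues: int = 20
    rise: float = 0.15  # nm per residue
    twist: float = 100.0  # degrees per residue
    resname: str = "ALA"

    def __post_init__(self) -> None:
        if self.n_residues < 5:
            raise ValueError("need at least 5 residues for a defined helicity")


_BACKBONE_NAMES = ("N", "CA", "C", "O")
_BACKBONE_ELEMENTS = ("N", "C", "C", "O")


def _helix_coordinates(spec: HelixSpec, phase0: float = 0.0) -> np.ndarray:
    """(n_residues*4, 3) backbone coordinates on the helical path (axis z)."""
    tpl = _helical_template()
    sign = tpl["twist_sign"]
    twist = np.radians(abs(spec.twist)) * sign
    coords = np.empty((spec.n_residues * 4, 3))
    for n in range(spec.n_residues):
        theta = phase0 + n * twist
        z = n * spec.rise
        for t, name in enumerate(_BACKBONE_NAMES):
            r, dph, dz = tpl["atoms"][name]
            coords[n * 4 + t] = (
                r * np.cos(theta + dph),
                r * np.sin(theta + dph),
                z + dz,
            )
    return coords


def _poly_ala_system(
    n_residues: int, resname: str = "ALA", chain: str = "A", seq_start: int = 1
) -> dict:
    n_atoms = n_residues * 4
    return dict(
        names=list(_BACKBONE_NAMES) * n_residues,
        elements=list(_BACKBONE_ELEMENTS) * n_residues,
        residue_indices=np.repeat(np.arange(n_residues), 4),
        residue_names=[resname] * n_residues,
        residue_seqs=np.arange(seq_start, seq_start + n_residues),
        chain_ids=[chain] * n_residues,
        roles=[GroupRole.PROTEIN.value] * n_atoms,
    )


def make_ideal_helix(spec: HelixSpec | None = None) -> tuple[MolecularSystem, Frame]:
    """Static poly-alanine helix centred in a comfortable orthorhombic box."""
    spec = spec or HelixSpec()
    coords = _helix_coordinates(spec)
    extent = coords.max(axis=0) - coords.min(axis=0)
    box = np.diag(extent + 4.0)
    coords = coords - coords.min(axis=0) + 2.0
    parts = _poly_ala_system(spec.n_residues, spec.resname)
    system = MolecularSystem(**parts)
    return system, Frame(coordinates=coords, box=box, time=0.0)


def make_extended_chain(n_residues: int = 20) -> tuple[MolecularSystem, Frame]:
    """Fully extended (phi = psi = 180°) chain: no i→i+4 hydrogen bonds."""
    bb = _build_backbone(n_residues, 180.0, 180.0)
    coords = bb.reshape(-1, 3)
    extent = coords.max(axis=0) - coords.min(axis=0)
    box = np.diag(extent + 4.0)
    coords = coords - coords.min(axis=0) + 2.0
    system = MolecularSystem(**_poly_ala_system(n_residues))
    return system, Frame(coordinates=coords, box=box, time=0.0)


# ---------------------------------------------------------------------------
# two-state Markov contact process
# ---------------------------------------------------------------------------

@dataclass
class MarkovContactSpec:
    """Two-state (bound/unbound) contact process parameters.

    ``a`` is the per-frame probability of entering contact from the
    unbound state, ``b`` the per-frame probability of leaving it.  The
    stationary contact probability is a/(a+b) and the mean dwell time
    in contact dt/b.
    """

    a: float = 0.02
    b: float = 0.2
    n_frames: int = 5000
    dt: float = 10.0  # ps
    n_runs: int = 5
    seed: int = 1
    bound_distance: float = 0.3  # nm, < cutoff
    unbound_distance: float = 0.8  # nm, > cutoff
    group: GroupRole = GroupRole.WATER

    def __post_init__(self) -> None:
        if not (0 <= self.a <= 1 and 0 <= self.b <= 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not self.bound_distance < self.unbound_distance:
            raise ValueError("bound distance must be below unbound distance")


def markov_expectations(spec: MarkovContactSpec) -> dict[str, float]:
    """Closed-form expectations for the generated contact process."""
    a, b = spec.a, spec.b
    return {
        "proximity": a / (a + b) if a + b > 0 else 0.0,
        "mean_residence_ps": spec.dt / b if b > 0 else float("inf"),
        "events_per_run": spec.n_frames * a * b / (a + b) if a + b > 0 else 0.0,
    }


def make_markov_contact_trajectory(
    spec: MarkovContactSpec | None = None, seed: int | None = None
) -> Trajectory:
    """One run of the two-state contact process as a real trajectory.

    The system holds a single one-atom protein residue at the box
    centre and a single group particle that sits at the bound or
    unbound distance along x according to the chain state.  The initial
    state is drawn from the stationary distribution.
    """
    spec = spec or MarkovContactSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    box_len = 2 * spec.unbound_distance + 2.5
    center = np.full(3, box_len / 2)
    a, b = spec.a, spec.b
    p_stat = a / (a + b) if a + b > 0 else 0.0
    bound = bool(rng.random() < p_stat)
    states = np.empty(spec.n_frames, dtype=bool)
    u = rng.random(spec.n_frames)
    for k in range(spec.n_frames):
        states[k] = bound
        bound = (u[k] >= b) if bound else (u[k] < a)

    system = MolecularSystem(
        names=["CA", "OW"],
        elements=["C", "O"],
        residue_indices=[0, 1],
        residue_names=["GLY", "SOL"],
        residue_seqs=[1, 2],
        chain_ids=["A", "W"],
        roles=[GroupRole.PROTEIN.value, spec.group.value],
    )
    frames = []
    for k in range(spec.n_frames):
        d = spec.bound_distance if states[k] else spec.unbound_distance
        coords = np.vstack([center, center + (d, 0.0, 0.0)])
        frames.append(
            Frame(coordinates=coords, box=np.diag([box_len] * 3), time=k * spec.dt)
        )
    return Trajectory(system, frames)


def make_markov_runs(spec: MarkovContactSpec | None = None) -> list[Trajectory]:
    """Independent replicas with seeds spec.seed, spec.seed+1, ..."""
    spec = spec or MarkovContactSpec()
    return [
        make_markov_contact_trajectory(spec, seed=spec.seed + i)
        for i in range(spec.n_runs)
    ]


# ---------------------------------------------------------------------------
# pore bundle
# ---------------------------------------------------------------------------

@dataclass
class PoreBundleSpec:
    """A transmembrane helix bundle with an axial pore plus mobile particles.

    Ten helices (the presumed TM count of an amino-acid transporter
    fold) stand on a circle around the z axis, leaving a free axial
    pore of radius ``pore_radius`` (distance from the axis to the
    nearest atom *centre*).  A membrane slab |z| <= ``slab_half`` holds
    the tail particles in an annulus around the bundle; water, ions and
    ligand particles random-walk outside the slab.  Ligands can be
    biased to loiter near designated residues through a harmonic pull.
    """

    n_helices: int = 10
    pore_radius: float = 0.5  # nm, axis to nearest atom centre
    slab_half: float = 1.5  # nm, membrane half-thickness
    helix_margin: float = 1.2  # nm each helix extends beyond the slab
    n_water: int = 1000
    n_tail_particles: int = 600
    n_ions: int = 40
    n_ligand: int = 20
    sigma_step: float = 0.1  # nm per frame random-walk step
    dt: float = 10.0  # ps
    seed: int = 0
    ligand_bias: float = 0.25  # harmonic pull strength per frame, 0 disables
    n_bias_residues: int = 2

    def __post_init__(self) -> None:
        if self.pore_radius <= 0 or self.slab_half <= 0:
            raise ValueError("pore_radius and slab_half must be positive")


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    width = hi - lo
    y = np.mod(x - lo, 2 * width)
    y = np.where(y > width, 2 * width - y, y)
    return lo + y


def _reflect_radial(xy: np.ndarray, lo: float, hi: float) -> np.ndarray:
    r = np.hypot(xy[:, 0], xy[:, 1])
    r_safe = np.where(r < 1e-9, 1e-9, r)
    r_new = _reflect(r, lo, hi)
    return xy * (r_new / r_safe)[:, None]


def make_pore_bundle(
    spec: PoreBundleSpec | None = None, n_frames: int = 50
) -> tuple[Trajectory, dict]:
    """Generate the bundle trajectory and a ground-truth dictionary.

    The ground truth echoes the spec plus quantities measured from the
    construction itself: the geometric pore radius (minimum cylindrical
    atom distance from the axis), the membrane z interval, the residue
    indices inside/outside the slab, and the bias-target residues.
    """
    spec = spec or PoreBundleSpec()
    rng = np.random.default_rng(spec.seed)
    tpl = _helical_template()
    helix_spec = HelixSpec(
        n_residues=int(np.ceil(2 * (spec.slab_half + spec.helix_margin) / 0.15))
    )
    axis_circle = spec.pore_radius + tpl["max_radius"]

    names, elements, res_idx, res_names, res_seqs, chains, roles = (
        [], [], [], [], [], [], []
    )
    coords_parts = []
    resi = 0
    # helices
    helix_len = (helix_spec.n_residues - 1) * helix_spec.rise
    for h in range(spec.n_helices):
        ang = 2 * np.pi * h / spec.n_helices
        local = _helix_coordinates(helix_spec, phase0=rng.uniform(0, 2 * np.pi))
        local[:, 2] -= helix_len / 2  # centre on z = 0
        local[:, 0] += axis_circle * np.cos(ang)
        local[:, 1] += axis_circle * np.sin(ang)
        coords_parts.append(local)
        chain = chr(ord("A") + h)
        for n in range(helix_spec.n_residues):
            names.extend(_BACKBONE_NAMES)
            elements.extend(_BACKBONE_ELEMENTS)
            res_idx.extend([resi] * 4)
            res_names.append("ALA")
            res_seqs.append(n + 1)
            chains.append(chain)
            roles.extend([GroupRole.PROTEIN.value] * 4)
            resi += 1

    protein_coords = np.vstack(coords_parts)
    half_z = spec.slab_half + spec.helix_margin + 1.5
    lateral = axis_circle + 2.0
    box = np.diag([2 * lateral, 2 * lateral, 2 * half_z])

    def add_particles(n, resname, atname, element, role):
        nonlocal resi
        for _ in range(n):
            names.append(atname)
            elements.append(element)
            res_idx.append(resi)
            res_names.append(resname)
            res_seqs.append(resi + 1)
            chains.append("X")
            roles.append(role)
            resi += 1

    # initial positions per compartment (coordinates centred on the axis,
    # shifted into the box at the end)
    n_w = spec.n_water
    water0 = np.empty((n_w, 3))
    water_side = rng.random(n_w) < 0.5
    water0[:, 0] = rng.uniform(-lateral, lateral, n_w)
    water0[:, 1] = rng.uniform(-lateral, lateral, n_w)
    top = rng.uniform(spec.slab_half + 0.1, half_z - 0.1, n_w)
    water0[:, 2] = np.where(water_side, top, -top)
    add_particles(n_w, "SOL", "OW", "O", GroupRole.WATER.value)

    ann_lo = axis_circle + tpl["max_radius"] + 0.05
    ann_hi = min(ann_lo + 0.9, lateral - 0.2)
    n_t = spec.n_tail_particles
    tail_r = np.sqrt(rng.uniform(ann_lo**2, ann_hi**2, n_t))
    tail_ang = rng.uniform(0, 2 * np.pi, n_t)
    tail0 = np.column_stack(
        [
            tail_r * np.cos(tail_ang),
            tail_r * np.sin(tail_ang),
            rng.uniform(-spec.slab_half, spec.slab_half, n_t),
        ]
    )
    tail_atnames = [f"C2{2 + k % 8}" for k in range(n_t)]
    for k in range(n_t):
        names.append(tail_atnames[k])
        elements.append("C")
        res_idx.append(resi)
        res_names.append("POPE")
        res_seqs.append(resi + 1)
        chains.append("X")
        roles.append(GroupRole.LIPID_TAIL.value)
        resi += 1

    n_i = spec.n_ions
    ion0 = np.empty((n_i, 3))
    ion_side = rng.random(n_i) < 0.5
    ion0[:, 0] = rng.uniform(-lateral, lateral, n_i)
    ion0[:, 1] = rng.uniform(-lateral, lateral, n_i)
    topi = rng.uniform(spec.slab_half + 0.1, half_z - 0.1, n_i)
    ion0[:, 2] = np.where(ion_side, topi, -topi)
    add_particles(n_i, "K", "K", "K", GroupRole.ION.value)

    # bias targets: top-end loop residues of well-separated helices; the
    # loitering point sits just outside the residue, radially away from
    # the bundle, so the ligand cloud hugs that residue and not the pore
    bias_targets = []
    helix_stride = max(1, spec.n_helices // max(spec.n_bias_residues, 1))
    for h in range(spec.n_bias_residues):
        ri = (h * helix_stride) * helix_spec.n_residues + helix_spec.n_residues - 2
        bias_targets.append(ri)
    target_pos = []
    for ri in bias_targets:
        centroid = protein_coords[np.arange(ri * 4, ri * 4 + 4)].mean(axis=0)
        outward = centroid.copy()
        lateral_norm = np.hypot(centroid[0], centroid[1])
        if lateral_norm > 1e-9:
            outward[:2] += centroid[:2] / lateral_norm * 0.25
        target_pos.append(outward)
    target_pos = np.array(target_pos)
    n_l = spec.n_ligand
    lig0 = np.empty((n_l, 3))
    lig0[:, 0] = rng.uniform(-lateral, lateral, n_l)
    lig0[:, 1] = rng.uniform(-lateral, lateral, n_l)
    lig0[:, 2] = rng.uniform(spec.slab_half + 0.1, half_z - 0.1, n_l)
    lig_target = rng.integers(0, len(bias_targets), n_l) if bias_targets else None
    add_particles(n_l, "ALA", "CA", "C", GroupRole.LIGAND.value)

    system = MolecularSystem(
        names=names,
        elements=elements,
        residue_indices=res_idx,
        residue_names=res_names,
        residue_seqs=res_seqs,
        chain_ids=chains,
        roles=roles,
    )

    shift = np.array([lateral, lateral, half_z])
    water, tails, ions, ligs = water0, tail0, ion0, lig0
    frames = []
    for k in range(n_frames):
        coords = np.vstack([protein_coords, water, tails, ions, ligs]) + shift
        frames.append(Frame(coordinates=coords, box=box, time=k * spec.dt))
        # advance the walkers
        water = water + rng.normal(scale=spec.sigma_step, size=water.shape)
        water[:, :2] = _reflect(water[:, :2], -lateral, lateral)
        wtop = water[:, 2] >= 0
        water[wtop, 2] = _reflect(water[wtop, 2], spec.slab_half + 0.05, half_z - 0.05)
        water[~wtop, 2] = _reflect(
            water[~wtop, 2], -(half_z - 0.05), -(spec.slab_half + 0.05)
        )
        tails = tails + rng.normal(scale=spec.sigma_step, size=tails.shape)
        tails[:, :2] = _reflect_radial(tails[:, :2], ann_lo, ann_hi)
        tails[:, 2] = _reflect(tails[:, 2], -spec.slab_half, spec.slab_half)
        ions = ions + rng.normal(scale=spec.sigma_step, size=ions.shape)
        ions[:, :2] = _reflect(ions[:, :2], -lateral, lateral)
        itop = ions[:, 2] >= 0
        ions[itop, 2] = _reflect(ions[itop, 2], spec.slab_half + 0.05, half_z - 0.05)
        ions[~itop, 2] = _reflect(
            ions[~itop, 2], -(half_z - 0.05), -(spec.slab_half + 0.05)
        )
        step = rng.normal(scale=spec.sigma_step, size=ligs.shape)
        if spec.ligand_bias > 0 and lig_target is not None:
            step += spec.ligand_bias * (target_pos[lig_target] - ligs)
        ligs = ligs + step
        ligs[:, :2] = _reflect(ligs[:, :2], -lateral, lateral)
        ligs[:, 2] = _reflect(ligs[:, 2], spec.slab_half + 0.05, half_z - 0.05)

    traj = Trajectory(system, frames)

    # ground truth measured from the construction
    prot_atoms = np.arange(len(protein_coords))
    cyl_r = np.hypot(protein_coords[:, 0], protein_coords[:, 1])
    res_z = np.array(
        [
            protein_coords[np.arange(r * 4, r * 4 + 4), 2].mean()
            for r in range(spec.n_helices * helix_spec.n_residues)
        ]
    )
    truth = {
        "geometric_pore_radius": float(cyl_r.min()),
        "membrane_z": (
            float(half_z - spec.slab_half),
            float(half_z + spec.slab_half),
        ),
        "axis_shift": shift.tolist(),
        "slab_residues": np.flatnonzero(np.abs(res_z) < spec.slab_half - 0.3).tolist(),
        "outside_residues": np.flatnonzero(
            np.abs(res_z) > spec.slab_half + 0.3
        ).tolist(),
        "bias_residues": bias_targets,
        "bias_target_points": (target_pos + shift).tolist(),
        "n_residues_per_helix": helix_spec.n_residues,
        "protein_atoms": prot_atoms.tolist(),
    }
    return traj, truth


def make_cylinder(
    pore_radius: float = 0.45,
    z_extent: tuple[float, float] = (-1.5, 1.5),
    dz: float = 0.1,
    n_per_ring: int = 36,
    blocked_z: float | None = None,
) -> tuple[MolecularSystem, Frame]:
    """Rings of pseudo-atoms lining a cylindrical pore of known radius.

    Atom centres sit exactly ``pore_radius`` from the z axis, so the
    accessible channel radius equals pore_radius − vdW(atom).  With
    ``blocked_z`` an extra atom is dropped on the axis at that height to
    occlude the channel there.  Atoms are carbons (vdW 0.17 nm) under
    the bundled radius table; tests that want vdW = 0.15 nm pass their
    own radii to the profiler.
    """
    zlo, zhi = z_extent
    zs = np.arange(zlo, zhi + dz / 2, dz)
    coords = []
    for z in zs:
        ang = np.linspace(0, 2 * np.pi, n_per_ring, endpoint=False)
        ring = np.column_stack(
            [pore_radius * np.cos(ang), pore_radius * np.sin(ang), np.full(n_per_ring, z)]
        )
        coords.append(ring)
    coords = np.vstack(coords)
    if blocked_z is not None:
        coords = np.vstack([coords, [0.0, 0.0, blocked_z]])
    n = len(coords)
    lateral = pore_radius + 3.0
    box = np.diag([2 * lateral, 2 * lateral, (zhi - zlo) + 6.0])
    coords = coords + np.array([lateral, lateral, -zlo + 3.0])
    system = MolecularSystem(
        names=["C"] * n,
        elements=["C"] * n,
        residue_indices=np.arange(n),
        residue_names=["CYL"] * n,
        residue_seqs=np.arange(1, n + 1),
        roles=[GroupRole.PROTEIN.value] * n,
    )
    return system, Frame(coordinates=coords, box=box, time=0.0)
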