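# Methods

This note records what each statistic computes, the conventions and
defaults behind it, what the synthetic generators do and do not
emulate, and the numerical choices a maintainer would want to know.

## Units and data model

Coordinates are in nanometres and times in picoseconds throughout —
the native GRO/XTC convention, and the units of every threshold
(0.4 nm contact cutoff, 0.35 nm hydrogen-bond distance, 10 ps frame
interval).  PDB and DCD input (Ångström) is converted on read.  Boxes
are 3×3 row-lattice-vector matrices in the reduced triclinic
convention; orthorhombic boxes are the common case and the synthetic
default.  A trajectory must be uniformly sampled; the frame interval dt
is validated against the stored timestamps (multi-model PDB has no
physical times, so dt is supplied by the caller there).

File parsing is delegated to MDAnalysis, except for multi-frame GRO
(concatenated GRO blocks), which MDAnalysis reads as a single frame and
which therefore has a small dedicated reader/writer here.  Writers are
plain-text only (PDB, GRO, multi-frame variants, plus XTC through
MDAnalysis) — enough to round-trip every synthetic fixture through the
same readers real data uses.

## Particle groups

Every atom gets exactly one role: protein, water, lipid_tail,
lipid_other, ion, ligand, other.  Lipid tails are the *aliphatic
acyl-chain carbons only* (CHARMM names C22…C2*n*, C32…C3*n*; the ester
carbonyls C21/C31 and all head-group atoms are lipid_other), so
"contact with the tails" means contact with the hydrophobic core.
A free amino-acid ligand is chemically identical to a protein residue,
so names cannot separate them: a chain of two or more peptide-bonded
amino-acid residues (C–N distance < 0.2 nm when coordinates are
available, same chain otherwise) is protein, an isolated amino-acid
residue is ligand.  Formats without chain records get per-molecule
chain ids assigned from this connectivity, which the helicity pairing
relies on.  Distance definitions default to all atoms, with a
heavy-atoms-only switch.

## Helicity

The per-residue metric is the mean minimum-image distance between the
backbone O of residue n and the backbone N of residue n+4, over the
analysed frames.  The heavy-atom O···N pair (rather than O···H) is the
standard proxy for the i→i+4 hydrogen bond and keeps the metric defined
on heavy-atom-only models; in an ideal α-helix it evaluates to
0.285 nm, in a fully extended chain 1.23 nm.  Classification is strict:
helical iff mean distance < 0.35 nm.  Segments are maximal runs of
helical residues, bridging interruptions of at most `max_gap` residues
(default 2) and discarding runs shorter than `min_length` (default 5);
helical profiles of real proteins are "primarily", not uniformly, below
threshold, and these two knobs operationalise that.  Segment calling is
per chain.  Replica aggregation is the mean of per-run mean distances,
which equals the pooled mean when frame counts are equal.

## Contact statistics

For residue r and group g, the per-frame statistic is the minimum
minimum-image distance over all (residue atom, group atom) pairs —
any-molecule semantics: the statistic does not care *which* water is
close, only whether one is.  Per-molecule tracking is deliberately not
the default.  Contact is strict `<` at the cutoff (default 0.4 nm;
boundary ties are measure-zero on real data).

* Proximity P = in-contact frames / analysed frames.
* A binding event needs an out-of-contact frame followed by an
  in-contact frame; the triggering frame counts as the first dt of the
  event, so the duration is (consecutive in-contact frames) × dt.
  A series that *starts* in contact contributes that stretch to P but
  not to the event statistics (no preceding unbound frame exists).
* An event still bound at the last frame is censored: its duration is
  a lower bound, and it is excluded from t̄ by default (flag to
  include).  Nothing forces this choice; excluding censored events
  biases t̄ slightly low, including them biases it low differently —
  with event counts ≫ 1 per run the difference is negligible.
* Over replicas: P is the equal-weight mean of per-run P; the event
  count is reported as the mean per run (configurable to the total);
  residence times are pooled over all events of all runs.

Under a two-state Markov contact process with per-frame entry
probability a and exit probability b, the estimators converge to
P = a/(a+b), t̄ = dt/b (geometric dwell times), and
N_b ≈ N·a·b/(a+b) events per N-frame run; the test suite verifies
recovery within three standard errors at a = 0.02, b = 0.2, dt = 10 ps,
5 × 5000 frames.

## Pore profile

At each z bin along the chosen axis (the membrane normal by default)
the channel radius is max over in-plane centres of
min_i(|c − x_i| − vdW_i), capped at r_max = 1 nm.  The maximisation is
a multi-start Nelder–Mead search (fixed seed, deterministic) that
starts at the neighbouring slab's optimised centre and walks outward
from the slab nearest the protein centroid — following the channel as
it meanders, in the spirit of the classic simulated-annealing sphere
walk, but simpler and dependency-free.  The centre may move at most
0.5 nm per slab (configurable): without that continuity bound the
sphere can escape through any thin gap and report bulk solvent.
Van der Waals radii come from a bundled Bondi-style element table
(C 0.170, N 0.155, O 0.152, H 0.120 nm, …); HOLE-format radius files
can be imported.  Slab thickness defaults to 0.1–0.2 nm; profiles are
taken every 200 ps by default, including the first analysed frame.
A membrane-spanning channel is a contiguous run of bins with radius ≥
r_open (default 0.1 nm, the low edge of typical transient openings)
covering both leaflet boundaries; the boundaries are supplied or
inferred from the 5–95% z quantiles of the lipid-tail atoms.

Accuracy is validated against exhaustive in-plane grid search (0.01 nm
grid) on ≤200-atom fixtures, against analytic cylinder and frustum
constructions (recovered within 0.02 nm), and with monotone-occlusion
and rotation-equivariance property tests.

## RMSD and equilibration

Superposition is Kabsch via SVD with the reflection excluded; RMSD
time series fit each frame onto the reference by default (the unfitted
variant is exposed, and equals σ√3 in expectation for isotropic
per-atom Gaussian noise of width σ — a test anchor).  Pairwise model
RMSD uses backbone atoms N, CA, C, O of the residues present in all
models, matched by author residue number; alternative homology models
of one sequence share numbering, making this the natural mapping.
Equilibration detection reports the earliest time from which every
10 ns window has |linear slope| < 0.005 nm/ns; because a window
overlapping the end of a ramp can already be flat on average, the
detected time can precede the true breakpoint by up to one window.
The pipeline does not rely on detection: it trims a fixed 50 ns by
default, with detection available as a diagnostic.

## Synthetic generators

*Ideal helix.*  A 40-residue poly-alanine backbone is built once from
standard internal coordinates (bond lengths N–CA 1.458, CA–C 1.525,
C–N 1.329 Å; torsions φ = −57°, ψ = −47°, ω = 180°; carbonyl O placed
on the CA–C/N(+1) bisector).  Its helical axis is identified from
second differences of the CA trace, and each backbone atom type's
cylindrical radius, phase offset and axial offset relative to CA are
recorded.  Arbitrary (rise, twist) helices are generated by laying this
template on a new helical path; defaults 0.15 nm and 100° per residue
(the template's natural values are 0.156 nm and 99.4°).  Note that the
re-parameterised geometry is only exactly peptide-like at the natural
rise/twist; a "helix" forced to 180°/residue keeps O pointing along the
path and its O···N(+4) distance (0.32 nm) is *not* a valid non-helical
control — the extended-chain generator (φ = ψ = 180°, d ≈ 1.23 nm) is.

*Markov contact process.*  One single-atom protein residue and one
group particle whose separation switches between 0.3 nm (bound) and
0.8 nm (unbound) by the two-state chain; the initial state is drawn
from the stationary distribution, replicas use consecutive seeds.

*Pore bundle.*  Ten template helices (the presumed TM-helix count of
an APC-fold transporter) stand on a circle leaving an axial pore of
0.5 nm geometric radius; a membrane slab of half-thickness 1.5 nm holds
600 tail particles in an annulus around the bundle; 1000 water
particles, 40 ions and 20 ligand particles random-walk (σ = 0.1 nm per
10 ps frame) outside the slab with reflecting compartment walls, and
ligands feel a harmonic pull (0.25 per frame) toward loitering points
just outside two designated loop residues.  Particle densities are
chosen so the construction exhibits the pattern it is meant to test:
slab-embedded residues are tail-dominated, extramembrane residues
water-dominated, and the designated residues carry the ligand-proximity
peaks.  The generator returns a ground-truth dictionary (geometric pore
radius, membrane interval, residue compartments, bias targets) measured
from its own construction.

What the generators deliberately do **not** emulate: forces and
energetics, lipid chemistry beyond labelled tail particles, water
hydrogens (a water is one particle), protein flexibility in the bundle
(helices are static), and realistic diffusion (steps are i.i.d.
Gaussian).  Passing tests therefore demonstrate that the *estimators*
are correct on processes with known truth, not that any particular
protein behaves a particular way.

## Pipeline

Stages run in order load → trim → RMSD → helicity → contacts →
channel; every table is TSV with a config-hash header, floats printed
at 6 significant digits, so identical config + seed reproduce outputs
byte for byte (the hash covers only scientific parameters, not stage
selection or output paths, so disabling one stage leaves the others'
files identical).  A failing stage deletes its partial outputs and
aborts with the stage name.  Replicas are weighted equally regardless
of frame count.  Test problem sizes (tens of frames, hundreds of
particles) are scaled-down versions of the production conditions
(100 ns runs sampled every 10 ps, 5 replicas, last 50 ns analysed);
the statistics are size-intensive, so the scale-down changes sampling
error only.

## Known limitations

* The pore profiler is a spherical-probe method: it reports the
  largest inscribed sphere per slab, not ellipsoidal or capsule
  cross-sections, and it follows one channel (the continuity bound
  prevents jumping to a parallel pathway).
* Event statistics are defined on the group minimum distance; two
  molecules swapping inside the cutoff count as one continuous event.
* `detect_equilibration` assumes monotone-ish approach to a plateau;
  oscillating series can satisfy the slope test early.
* The multi-frame GRO reader assumes fixed-width records as written by
  this package or GROMACS tools.
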