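"""Per-residue helicity of an ideal α-helix vs. an extended chain.

Builds two poly-alanine fixtures with standard backbone geometry and
computes the mean O(n)···N(n+4) distance per residue — the i→i+4
hydrogen-bond proxy.  Distances below 0.35 nm mean the hydrogen bond is
formed and the residue is α-helical.
"""

import warnings

import numpy as np

from memtraj import Trajectory, classify_helical, helicity_profile
from memtraj.synthetic import HelixSpec, make_extended_chain, make_ideal_helix

warnings.simplefilter("ignore")

for label, (system, frame) in (
    ("ideal alpha-helix", make_ideal_helix(HelixSpec(n_residues=20))),
    ("extended chain", make_extended_chain(20)),
):
    profile = helicity_profile(Trajectory(system, [frame]))
    helical = classify_helical(profile, threshold=0.35)
    print(f"{label}:")
    print(f"  mean O(n)...N(n+4) distance : {profile.mean_distance.mean():.3f} nm")
    print(f"  residues classified helical : {helical.sum()} / {len(helical)}")

print(
    "\nAn ideal helix sits near 0.29 nm (every residue hydrogen-bonded);"
    "\na fully extended chain sits near 1.2 nm (no i->i+4 bonds at all)."
)
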