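import warnings

import numpy as np
import pytest

from memtraj.core import Trajectory
from memtraj.synthetic import (
    HelixSpec,
    MarkovContactSpec,
    PoreBundleSpec,
    make_extended_chain,
    make_ideal_helix,
    make_markov_runs,
    make_pore_bundle,
)


@pytest.fixture(scope="session")
def ideal_helix_traj():
    system, frame = make_ideal_helix(HelixSpec(n_residues=20))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return Trajectory(system, [frame])


@pytest.fixture(scope="session")
def extended_traj():
    system, frame = make_extended_chain(20)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return Trajectory(system, [frame])


@pytest.fixture(scope="session")
def markov_runs_std():
    """The standard recovery conditions: a=0.02, b=0.2, dt=10 ps,
    5 runs x 5000 frames, seeds 1..5."""
    return make_markov_runs(MarkovContactSpec(seed=1))


@pytest.fixture(scope="session")
def pore_bundle():
    traj, truth = make_pore_bundle(PoreBundleSpec(seed=0), n_frames=30)
    return traj, truth


def toy_distance_series(distances, dt=10.0, cutoff=0.4):
    """ContactSeries wrapper around a hand-written distance list."""
    from memtraj.contacts import ContactSeries
    from memtraj.core import GroupRole

    distances = np.asarray(distances, dtype=float)
    return ContactSeries(
        residue_index=0,
        group=GroupRole.WATER,
        times=np.arange(len(distances)) * dt,
        distances=distances,
        cutoff=cutoff,
        dt=dt,
    )
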