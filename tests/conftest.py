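import numpy as np
import pytest

from unfoldmap import metrics, synth
from unfoldmap.io import Structure


def ca_structure(coords, res_names=None, ss=None):
    """Cα-only Structure from an (n, 3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    names = res_names if res_names is not None else ["ALA"] * n
    return Structure(
        atom_name=np.array(["CA"] * n),
        element=np.array(["C"] * n),
        res_id=np.arange(1, n + 1),
        res_name=np.array(names),
        chain_id=np.array(["A"] * n),
        coord=coords,
        hetero=np.zeros(n, dtype=bool),
        ss=ss,
    )


@pytest.fixture(scope="session")
def toy_native():
    return synth.make_toy_polymer(20, seed=1)


@pytest.fixture(scope="session")
def toy_native_40():
    return synth.make_toy_polymer(40, seed=3)


@pytest.fixture(scope="session")
def expanding_trajectory(toy_native):
    """Zero-noise monotone-expansion trajectory: 4 states, 60 frames."""
    spec = synth.SyntheticTrajectorySpec(
        n_residues=20,
        n_frames=60,
        states=[(0.25, 1.0, 0.0), (0.25, 1.4, 0.0), (0.25, 1.9, 0.0), (0.25, 2.5, 0.0)],
        seed=1,
    )
    traj, labels = synth.simulate_unfolding_trajectory(toy_native, spec)
    return traj, labels


@pytest.fixture(scope="session")
def expanding_property_matrix(expanding_trajectory):
    traj, _ = expanding_trajectory
    return metrics.property_matrix(traj)
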