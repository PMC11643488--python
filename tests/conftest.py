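import numpy as np
import pytest

from gelkinetics.trajectory import Configuration


@pytest.fixture
def single_atom_box():
    """One atom of radius 2 A centered in a 10 A periodic box."""
    return Configuration(positions=[[5.0, 5.0, 5.0]], box_edge=10.0, vdw_radii=[2.0])


def random_hbond_config(seed: int, n_pairs: int = 60, n_acceptors: int = 80,
                        box: float = 20.0):
    """Random donor+hydrogen pairs and scattered acceptors (~200 atoms).

    Each hydrogen sits 0.95-1.05 A from its own donor, so nearest-donor
    pairing is unambiguous with overwhelming probability.
    """
    rng = np.random.default_rng(seed)
    donors = rng.random((n_pairs, 3)) * box
    direc = rng.normal(size=(n_pairs, 3))
    direc /= np.linalg.norm(direc, axis=1, keepdims=True)
    hydrogens = donors + direc * rng.uniform(0.95, 1.05, size=(n_pairs, 1))
    acceptors = rng.random((n_acceptors, 3)) * box
    pos = np.vstack([donors, hydrogens, acceptors])
    roles = np.array(["donor"] * n_pairs + ["hydrogen"] * n_pairs
                     + ["acceptor"] * n_acceptors, dtype=object)
    elements = np.array(["O"] * n_pairs + ["H"] * n_pairs + ["O"] * n_acceptors,
                        dtype=object)
    return Configuration(positions=pos, box_edge=box, elements=elements,
                         hbond_roles=roles)
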