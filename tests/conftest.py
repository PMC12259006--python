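import numpy as np
import pytest

from allostate.structio import Atom, Topology, Trajectory
from allostate import synthdata


@pytest.fixture(scope="session")
def ideal_helix():
    """20-residue ideal alpha-helix backbone (phi=-57, psi=-47)."""
    return synthdata.generate_ideal_helix(20)


@pytest.fixture(scope="session")
def toy_small():
    """Small toy allosteric ensemble with default (wild-type) coupling."""
    params = synthdata.ToyAllostericParams(n_frames=600, seed=11)
    return synthdata.generate_toy_allosteric(params)


@pytest.fixture()
def single_atom_traj():
    top = Topology([Atom(1, "C1", "C", 1, "LIG", "A")])
    return Trajectory(top, np.zeros((1, 1, 3)))


def make_chain(resnames, atom_names_per_res, chain="A", start_resid=1, coords=None):
    """Build a simple topology/trajectory for selection and metric tests."""
    atoms = []
    serial = 1
    for i, (rn, names) in enumerate(zip(resnames, atom_names_per_res)):
        for name in names:
            element = "H" if name.startswith("H") else name[0]
            atoms.append(Atom(serial, name, element, start_resid + i, rn, chain))
            serial += 1
    top = Topology(atoms)
    n = top.n_atoms
    if coords is None:
        rng = np.random.default_rng(0)
        coords = rng.normal(0, 5, size=(1, n, 3))
    return Trajectory(top, coords)
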