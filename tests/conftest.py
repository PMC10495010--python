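import numpy as np
import pytest

from epsim.electrostatics import (GridSpec, SolventParams, dh_potential_grid)
from epsim.structure_io import ChargedAtom, ChargedStructure
from epsim.surface import extract_isosurface


@pytest.fixture
def ion():
    """A single +1 e ion at the origin."""
    return ChargedStructure("ion", [ChargedAtom("NA", np.zeros(3), 1.0, 1.6)])


@pytest.fixture
def dipole():
    return ChargedStructure("dipole", [
        ChargedAtom("P", np.array([0.0, 0.0, 2.0]), 1.0, 1.6),
        ChargedAtom("N", np.array([0.0, 0.0, -2.0]), -1.0, 1.6),
    ])


@pytest.fixture
def ion_dh_grid(ion):
    return dh_potential_grid(ion)


@pytest.fixture
def sphere_surface(ion_dh_grid):
    """The +1 kT/e isosurface of the single ion: a near-perfect sphere."""
    return extract_isosurface(ion_dh_grid, 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_structure(rng, n_atoms=5, box=4.0):
    atoms = [ChargedAtom(f"A{i}", rng.uniform(-box, box, 3),
                         float(rng.uniform(-1, 1)), float(rng.uniform(1.0, 2.0)))
             for i in range(n_atoms)]
    return ChargedStructure("random", atoms)
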