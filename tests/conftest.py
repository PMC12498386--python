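import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gagconf.structure import Structure
from gagconf.synthetic import EnsembleRecipe, build_chain, generate_ensemble


def random_structure(rng: np.random.Generator, n_atoms: int = 12) -> Structure:
    """A random non-degenerate atom cloud with varied masses."""
    return Structure(
        atom_names=[f"A{i}" for i in range(n_atoms)],
        elements=["C"] * n_atoms,
        masses=rng.uniform(1.0, 32.0, n_atoms),
        residue_indices=np.ones(n_atoms, dtype=int),
        residue_types=["X"] * n_atoms,
        positions=rng.normal(scale=4.0, size=(n_atoms, 3)),
    )


def random_rigid_motion(rng: np.random.Generator):
    """A uniformly random rotation and a translation of a few Å."""
    rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    trans = rng.normal(scale=10.0, size=3)
    return rot, trans


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def dp12_chain():
    """A dodecamer template chain with the default linkage minima."""
    return build_chain(12)


@pytest.fixture(scope="session")
def small_ensemble():
    """A 30-frame dp6 ensemble with mild noise, shared across tests."""
    return generate_ensemble(
        EnsembleRecipe(n_frames=30, seed=11, n_residues=6)
    )
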