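import numpy as np
import pytest

from alphaq.chem_io import Atom, Molecule
from alphaq.espgrid import ChargeModel, build_common_box


@pytest.fixture
def dumbbell():
    """Asymmetric two-atom molecule (C-O) along x: no rotational symmetry
    about z, so 90-degree rotations are distinguishable."""
    return Molecule("dumbbell", [
        Atom("C", [-0.8, 0.0, 0.0], 0.1),
        Atom("O", [0.8, 0.0, 0.0], -0.1),
    ])


@pytest.fixture
def tripod():
    """Four-atom chiral-ish cluster used where a featureless shape would
    make alignments degenerate."""
    return Molecule("tripod", [
        Atom("C", [0.0, 0.0, 0.0], 0.12),
        Atom("O", [1.3, 0.0, 0.0], -0.2),
        Atom("N", [0.0, 1.1, 0.0], 0.05),
        Atom("H", [0.0, 0.0, 0.9], 0.03),
    ])


@pytest.fixture
def promolecule_model():
    return ChargeModel(mode="promolecule", sigma=0.4)


@pytest.fixture
def charge_model():
    return ChargeModel(mode="partial_charge", sigma=0.4)


@pytest.fixture
def coarse_box(dumbbell, tripod):
    """Shared coarse alignment box (0.4 Å) holding the small fixtures."""
    return build_common_box([dumbbell, tripod], spacing=0.4, margin=2.7)


def random_cluster(seed: int, n_atoms: int = 5, mol_id: str | None = None):
    """Seeded neutral random cluster for property tests."""
    rng = np.random.default_rng(seed)
    elements = rng.choice(["C", "N", "O", "H"], size=n_atoms)
    pos = rng.normal(scale=1.0, size=(n_atoms, 3))
    pos -= pos.mean(axis=0)
    q = rng.uniform(-0.3, 0.3, size=n_atoms)
    q -= q.mean()
    atoms = [Atom(e, p, c) for e, p, c in zip(elements, pos, q)]
    return Molecule(mol_id or f"cluster{seed}", atoms)
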