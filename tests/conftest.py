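import numpy as np
import pytest

from hintmd.params import HydropathicAtom
from hintmd.sasa import AtomSASA
from hintmd.structure import Frame, MolecularSystem, build_exclusions


def build_toy_system(
    positions,
    polarity_classes=None,
    constants=None,
    bonds=(),
    radius=1.6,
):
    """Hand-assemble a minimal parameterized system for unit tests.

    All atoms are heavy (retained); classes default to hydrophobic with
    positive unit constants.
    """
    positions = np.asarray(positions, dtype=np.float64)
    n = positions.shape[0]
    if polarity_classes is None:
        polarity_classes = ["hydrophobic"] * n
    if constants is None:
        constants = [1.0 if c == "hydrophobic" else -1.0 for c in polarity_classes]
    atoms = [
        HydropathicAtom(
            atom_id=i,
            atom_name=f"X{i}",
            element="C",
            residue_name="UNK",
            residue_number=i + 1,
            chain_id="A",
            hydrophobic_constant=constants[i],
            polarity_class=polarity_classes[i],
            radius=radius,
        )
        for i in range(n)
    ]
    bonds12, excl13 = build_exclusions(bonds)
    system = MolecularSystem(
        atoms=atoms,
        bonds=bonds12,
        exclusions_12=bonds12,
        exclusions_13=excl13,
        source="toy",
    )
    return system, Frame(coordinates=positions)


def uniform_sasa(system, value=10.0):
    return AtomSASA(values=np.full(system.n_atoms, value, dtype=np.float64))


def random_toy_system(rng, n_atoms=20, box=12.0, n_bonds=6):
    """Seeded random system with mixed polarity classes, random SASA."""
    positions = rng.uniform(0, box, size=(n_atoms, 3))
    # enforce minimum separation so no pair is pathologically close
    for _ in range(200):
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(positions))
        np.fill_diagonal(d, np.inf)
        close = np.argwhere(d < 1.5)
        if not len(close):
            break
        positions[close[0][0]] += rng.uniform(-1, 1, 3)
    classes = rng.choice(
        ["hydrophobic", "acid", "base", "polar_neutral"], size=n_atoms
    ).tolist()
    constants = [
        (1 if c == "hydrophobic" else -1) * rng.uniform(0.2, 1.5) for c in classes
    ]
    possible = [(i, j) for i in range(n_atoms) for j in range(i + 1, n_atoms)]
    chosen = rng.choice(len(possible), size=n_bonds, replace=False)
    bonds = [possible[k] for k in chosen]
    system, frame = build_toy_system(positions, classes, constants, bonds)
    sasa = AtomSASA(values=rng.uniform(0.0, 40.0, size=n_atoms))
    return system, frame, sasa


@pytest.fixture
def toy_factory():
    return build_toy_system


@pytest.fixture
def hinge_spec():
    from hintmd.fixtures import FixtureSpec

    return FixtureSpec(
        name="hinge", n_residues=6, displacement_amplitude=3.0,
        n_frames=10, seed=7,
    )
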