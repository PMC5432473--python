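"""Shared molecular fixtures, built programmatically (no data files)."""

import numpy as np
import pytest

from bioconfbench.chem import AROMATIC, Atom, Bond, Conformer, MoleculeGraph


def mk(atoms, bonds):
    """Terse graph constructor: atoms as (el, charge, nH), bonds as (i, j, order)."""
    return MoleculeGraph([Atom(*a) for a in atoms],
                         [Bond(*b) for b in bonds])


@pytest.fixture
def benzene():
    return mk([("C", 0, 1)] * 6, [(i, (i + 1) % 6, AROMATIC) for i in range(6)])


@pytest.fixture
def para_xylene():
    atoms = [("C", 0, 0), ("C", 0, 1), ("C", 0, 1), ("C", 0, 0),
             ("C", 0, 1), ("C", 0, 1), ("C", 0, 3), ("C", 0, 3)]
    bonds = [(i, (i + 1) % 6, AROMATIC) for i in range(6)] + [(0, 6, 1), (3, 7, 1)]
    return mk(atoms, bonds)


@pytest.fixture
def butane():
    return mk([("C", 0, 3), ("C", 0, 2), ("C", 0, 2), ("C", 0, 3)],
              [(0, 1, 1), (1, 2, 1), (2, 3, 1)])


@pytest.fixture
def n_methylacetamide():
    # CH3-C(=O)-N(H)-CH3
    return mk([("C", 0, 3), ("C", 0, 0), ("O", 0, 0), ("N", 0, 1), ("C", 0, 3)],
              [(0, 1, 1), (1, 2, 2), (1, 3, 1), (3, 4, 1)])


@pytest.fixture
def ethanol():
    return mk([("C", 0, 3), ("C", 0, 2), ("O", 0, 1)], [(0, 1, 1), (1, 2, 1)])


@pytest.fixture
def pyridine():
    atoms = [("N", 0, 0)] + [("C", 0, 1)] * 5
    return mk(atoms, [(i, (i + 1) % 6, AROMATIC) for i in range(6)])


@pytest.fixture
def cyclohexane():
    return mk([("C", 0, 2)] * 6, [(i, (i + 1) % 6, 1) for i in range(6)])


@pytest.fixture
def acetate():
    # CH3-COO(-)
    return mk([("C", 0, 3), ("C", 0, 0), ("O", 0, 0), ("O", -1, 0)],
              [(0, 1, 1), (1, 2, 2), (1, 3, 1)])


@pytest.fixture
def acetic_acid():
    return mk([("C", 0, 3), ("C", 0, 0), ("O", 0, 0), ("O", 0, 1)],
              [(0, 1, 1), (1, 2, 2), (1, 3, 1)])


@pytest.fixture
def glycine_zwitterion():
    # (+)H3N-CH2-COO(-)
    return mk([("N", 1, 3), ("C", 0, 2), ("C", 0, 0), ("O", 0, 0), ("O", -1, 0)],
              [(0, 1, 1), (1, 2, 1), (2, 3, 2), (2, 4, 1)])


@pytest.fixture
def tetramethylammonium():
    return mk([("N", 1, 0)] + [("C", 0, 3)] * 4,
              [(0, k, 1) for k in range(1, 5)])


def random_conformer(mol, rng, scale=1.5):
    """A random (not chemically sensible) coordinate set for metric tests."""
    return Conformer(rng.normal(scale=scale, size=(mol.n_atoms, 3)))
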