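"""Core chemical data types: molecular graphs, conformers, pools.

The package operates on a light element/charge-labeled heavy-atom graph
(:class:`MoleculeGraph`) with implicit hydrogens, and on plain-numpy
:class:`Conformer` coordinate sets aligned to the graph's atom order.
SDF V2000 round-tripping goes through RDKit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Optional, Sequence

import networkx as nx
import numpy as np

AROMATIC = "ar"

#: Elements the curation whitelist accepts ("biogenic" set).
BIOGENIC_ELEMENTS = frozenset({"C", "H", "N", "O", "S", "P", "F", "Cl", "Br", "I"})

ATOMIC_WEIGHTS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "P": 30.974, "S": 32.06, "Cl": 35.45, "Br": 79.904, "I": 126.904,
    "Se": 78.971,  # non-biogenic; present so fixtures can exercise the whitelist
}

#: Bondi (1964) van der Waals radii in Å, config-overridable in the filters.
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
    "Se": 1.90,
}


@dataclass(frozen=True)
class Atom:
    element: str
    charge: int = 0
    n_h: int = 0  # implicit hydrogens


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: object = 1  # 1 | 2 | 3 | "ar"
    in_ring: bool = False

    def other(self, k: int) -> int:
        return self.j if k == self.i else self.i


class MoleculeGraph:
    """Element- and charge-labeled heavy-atom graph with implicit hydrogens.

    Indices into ``atoms`` are the canonical atom order that every
    :class:`Conformer` of the molecule follows.
    """

    def __init__(self, atoms: Sequence[Atom], bonds: Sequence[Bond]):
        self.atoms = list(atoms)
        n = len(self.atoms)
        for b in bonds:
            if not (0 <= b.i < n and 0 <= b.j < n) or b.i == b.j:
                raise ValueError(f"bond ({b.i},{b.j}) has invalid indices for {n} atoms")
        self.bonds = [self._flag_ring(b, bonds) for b in bonds]
        self._adj: list[list[tuple[int, Bond]]] = [[] for _ in range(n)]
        for b in self.bonds:
            self._adj[b.i].append((b.j, b))
            self._adj[b.j].append((b.i, b))
        if n > 1 and not nx.is_connected(self.to_networkx()):
            raise ValueError("molecule graph must be connected")

    @staticmethod
    def _flag_ring(bond: Bond, bonds: Sequence[Bond]) -> Bond:
        # an edge lies in a ring iff its endpoints stay connected without it
        g = nx.Graph()
        for b in bonds:
            g.add_edge(b.i, b.j)
        g.remove_edge(bond.i, bond.j)
        in_ring = bond.j in g and bond.i in g and nx.has_path(g, bond.i, bond.j)
        return replace(bond, in_ring=in_ring)

    # -- introspection -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> list[int]:
        return [j for j, _ in self._adj[i]]

    def incident_bonds(self, i: int) -> list[Bond]:
        return [b for _, b in self._adj[i]]

    def bond_between(self, i: int, j: int) -> Optional[Bond]:
        for k, b in self._adj[i]:
            if k == j:
                return b
        return None

    def degree(self, i: int) -> int:
        return len(self._adj[i])

    def is_aromatic_atom(self, i: int) -> bool:
        return any(b.order == AROMATIC for _, b in self._adj[i])

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, a in enumerate(self.atoms):
            g.add_node(i, element=a.element, charge=a.charge, n_h=a.n_h)
        for b in self.bonds:
            g.add_edge(b.i, b.j, order=b.order, in_ring=b.in_ring)
        return g

    def graph_distances(self) -> np.ndarray:
        """All-pairs shortest path length in bonds (int matrix)."""
        n = self.n_atoms
        d = np.full((n, n), n + 1, dtype=int)
        for i, lengths in nx.all_pairs_shortest_path_length(self.to_networkx()):
            for j, l in lengths.items():
                d[i, j] = l
        return d

    def total_charge(self) -> int:
        return sum(a.charge for a in self.atoms)

    def with_atoms(self, atoms: Sequence[Atom]) -> "MoleculeGraph":
        return MoleculeGraph(atoms, self.bonds)

    def __repr__(self) -> str:  # pragma: no cover
        return f"MoleculeGraph({self.n_atoms} atoms, {len(self.bonds)} bonds)"


@dataclass
class Conformer:
    """3D heavy-atom coordinates (Å) aligned to a molecule's atom order."""

    coords: np.ndarray
    energy: Optional[float] = None
    engine: Optional[str] = None
    solvent: Optional[str] = None
    charge_state: str = "charged"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coordinates must be (N, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.energy is not None and not np.isfinite(self.energy):
            raise ValueError("energy must be finite when present")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def copy(self, **kw) -> "Conformer":
        c = Conformer(self.coords.copy(), self.energy, self.engine,
                      self.solvent, self.charge_state)
        for k, v in kw.items():
            setattr(c, k, v)
        return c


class ConformerPool:
    """Energy-sorted conformer collection for one molecule and condition."""

    def __init__(self, mol: MoleculeGraph, conformers: Iterable[Conformer],
                 params=None, charge_state: str = "charged",
                 exhaustive: bool = False):
        self.mol = mol
        self.params = params
        self.charge_state = charge_state
        #: True when the generating engine enumerated its full search space,
        #: so member energies are exact functions of geometry (no two
        #: congruent members can differ in energy)
        self.exhaustive = exhaustive
        members = list(conformers)
        for c in members:
            if c.n_atoms != mol.n_atoms:
                raise ValueError("conformer size does not match molecule")
        # stable sort: unknown energies sink to the end in input order
        self.conformers = sorted(
            members, key=lambda c: np.inf if c.energy is None else c.energy)

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self) -> Iterator[Conformer]:
        return iter(self.conformers)

    def __getitem__(self, k) -> Conformer:
        return self.conformers[k]

    @property
    def min_energy(self) -> float:
        if not self.conformers or self.conformers[0].energy is None:
            raise ValueError("pool has no energies")
        return self.conformers[0].energy

    def energies(self) -> np.ndarray:
        return np.array([c.energy for c in self.conformers], dtype=float)

    def coords_array(self) -> np.ndarray:
        """(M, N, 3) stack of all member coordinates."""
        return np.stack([c.coords for c in self.conformers])

    def replaced(self, conformers: Iterable[Conformer]) -> "ConformerPool":
        return ConformerPool(self.mol, conformers, self.params,
                             self.charge_state, self.exhaustive)


# ---------------------------------------------------------------------------
# RDKit conversion and SDF V2000 I/O
# ---------------------------------------------------------------------------

_RDKIT_ORDERS = {1: "SINGLE", 2: "DOUBLE", 3: "TRIPLE", AROMATIC: "AROMATIC"}


def to_rdkit(mol: MoleculeGraph, conformer: Optional[Conformer] = None):
    """Convert to an RDKit Mol (explicit heavy atoms, implicit H counts)."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    rw = Chem.RWMol()
    for a in mol.atoms:
        ra = Chem.Atom(a.element)
        ra.SetFormalCharge(a.charge)
        ra.SetNumExplicitHs(a.n_h)
        ra.SetNoImplicit(True)
        rw.AddAtom(ra)
    for b in mol.bonds:
        rw.AddBond(b.i, b.j, getattr(Chem.BondType, _RDKIT_ORDERS[b.order]))
    if any(b.order == AROMATIC for b in mol.bonds):
        for b in mol.bonds:
            if b.order == AROMATIC:
                rw.GetAtomWithIdx(b.i).SetIsAromatic(True)
                rw.GetAtomWithIdx(b.j).SetIsAromatic(True)
                rw.GetBondBetweenAtoms(b.i, b.j).SetIsAromatic(True)
    m = rw.GetMol()
    Chem.SanitizeMol(m)
    if conformer is not None:
        conf = Chem.Conformer(mol.n_atoms)
        for i, xyz in enumerate(conformer.coords):
            conf.SetAtomPosition(i, Point3D(*map(float, xyz)))
        m.AddConformer(conf, assignId=True)
    return m


def from_rdkit(rdmol) -> tuple[MoleculeGraph, Optional[Conformer]]:
    """Convert an RDKit Mol (no explicit H atoms) back to package types."""
    from rdkit import Chem

    atoms = []
    for a in rdmol.GetAtoms():
        if a.GetSymbol() == "H":
            raise ValueError("explicit hydrogen atoms are not supported; use implicit H")
        atoms.append(Atom(a.GetSymbol(), a.GetFormalCharge(), a.GetTotalNumHs()))
    bonds = []
    for b in rdmol.GetBonds():
        if b.GetIsAromatic():
            order: object = AROMATIC
        else:
            order = int(b.GetBondTypeAsDouble())
        bonds.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    mg = MoleculeGraph(atoms, bonds)
    conf = None
    if rdmol.GetNumConformers():
        coords = rdmol.GetConformer().GetPositions()
        props = rdmol.GetPropsAsDict()
        conf = Conformer(
            np.asarray(coords, float),
            energy=props.get("ENERGY_KCAL"),
            engine=props.get("ENGINE"),
            solvent=props.get("SOLVENT"),
            charge_state=props.get("CHARGE_STATE", "charged"),
        )
    return mg, conf


def write_sdf(path, mol: MoleculeGraph, conformers: Sequence[Conformer],
              name: str = "ligand") -> None:
    """Write conformers as an SDF V2000 multi-record file with SD tags."""
    from rdkit import Chem

    with Chem.SDWriter(str(path)) as w:
        w.SetForceV3000(False)
        for k, conf in enumerate(conformers):
            m = to_rdkit(mol, conf)
            m.SetProp("_Name", f"{name}_{k}")
            if conf.energy is not None:
                m.SetDoubleProp("ENERGY_KCAL", float(conf.energy))
            if conf.engine:
                m.SetProp("ENGINE", conf.engine)
            if conf.solvent:
                m.SetProp("SOLVENT", conf.solvent)
            m.SetProp("CHARGE_STATE", conf.charge_state)
            w.write(m)


def read_sdf(path) -> list[tuple[MoleculeGraph, Optional[Conformer]]]:
    from rdkit import Chem

    out = []
    for m in Chem.SDMolSupplier(str(path), removeHs=True):
        if m is None:
            raise ValueError(f"unparseable SDF record in {path}")
        out.append(from_rdkit(m))
    return out
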