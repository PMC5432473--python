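"""Constitutional and physico-chemical descriptors for filtering and stratification.

All descriptors operate on the package's :class:`~bioconfbench.chem.MoleculeGraph`
(heavy atoms with implicit hydrogens). The topological polar surface area uses
the published atomic-contribution table (N/O with the S/P extension, toggleable);
the solvent-accessible surface area is a Shrake–Rupley quadrature on the
conformer; LogP is a coarse atomic-contribution estimate used only for binning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chem import (AROMATIC, ATOMIC_WEIGHTS, BONDI_RADII, Conformer,
                   MoleculeGraph)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Rotatable bonds
# ---------------------------------------------------------------------------

def _is_amide_cn(mol: MoleculeGraph, i: int, j: int) -> bool:
    """True for the C–N single bond of an amide (C carries a double-bonded O)."""
    for c, n in ((i, j), (j, i)):
        if mol.atoms[c].element == "C" and mol.atoms[n].element == "N":
            for b in mol.incident_bonds(c):
                k = b.other(c)
                if b.order == 2 and mol.atoms[k].element == "O":
                    return True
    return False


def rotatable_bonds(mol: MoleculeGraph) -> list[tuple[int, int]]:
    """Acyclic single bonds between two non-terminal heavy atoms, amides excluded."""
    out = []
    for b in mol.bonds:
        if b.order != 1 or b.in_ring:
            continue
        if mol.degree(b.i) < 2 or mol.degree(b.j) < 2:
            continue
        if _is_amide_cn(mol, b.i, b.j):
            continue
        out.append((b.i, b.j))
    return out


def count_rotatable_bonds(mol: MoleculeGraph) -> int:
    return len(rotatable_bonds(mol))


# ---------------------------------------------------------------------------
# Constitution
# ---------------------------------------------------------------------------

def molecular_weight(mol: MoleculeGraph) -> float:
    """Sum of standard atomic weights, implicit hydrogens included."""
    mw = 0.0
    for a in mol.atoms:
        try:
            mw += ATOMIC_WEIGHTS[a.element]
        except KeyError:
            raise KeyError(f"no atomic weight for element {a.element!r}") from None
        mw += a.n_h * ATOMIC_WEIGHTS["H"]
    return mw


def heavy_atom_count(mol: MoleculeGraph) -> int:
    return sum(1 for a in mol.atoms if a.element != "H")


# ---------------------------------------------------------------------------
# Topological polar surface area (atomic contributions)
# ---------------------------------------------------------------------------

# (element, charge, n_H, aromatic, sorted heavy-bond orders) -> Å²
_TPSA_CONTRIB = {
    ("N", 0, 0, False, (1, 1, 1)): 3.24,
    ("N", 0, 0, False, (1, 2)): 12.36,
    ("N", 0, 0, False, (3,)): 23.79,
    ("N", 0, 1, False, (1, 1)): 12.03,
    ("N", 0, 1, False, (2,)): 23.85,
    ("N", 0, 2, False, (1,)): 26.02,
    ("N", 1, 0, False, (1, 1, 1, 1)): 0.00,
    ("N", 1, 0, False, (1, 1, 2)): 3.01,
    ("N", 1, 1, False, (1, 1, 1)): 4.44,
    ("N", 1, 1, False, (1, 2)): 13.97,
    ("N", 1, 2, False, (1, 1)): 16.61,
    ("N", 1, 2, False, (2,)): 25.59,
    ("N", 1, 3, False, (1,)): 27.64,
    ("N", 0, 0, True, ("ar", "ar")): 12.89,
    ("N", 0, 1, True, ("ar", "ar")): 15.79,
    ("N", 0, 0, True, (1, "ar", "ar")): 4.93,
    ("O", 0, 0, False, (1, 1)): 9.23,
    ("O", 0, 1, False, (1,)): 20.23,
    ("O", 0, 0, False, (2,)): 17.07,
    ("O", -1, 0, False, (1,)): 23.06,
    ("O", 0, 0, True, ("ar", "ar")): 13.14,
}

_TPSA_CONTRIB_SP = {
    ("S", 0, 0, False, (1, 1)): 25.30,
    ("S", 0, 0, False, (2,)): 32.09,
    ("S", 0, 1, False, (1,)): 38.80,
    ("S", 0, 0, True, ("ar", "ar")): 28.24,
    ("S", 0, 0, False, (1, 1, 2)): 19.21,
    ("S", 0, 0, False, (1, 1, 2, 2)): 8.38,
    ("P", 0, 0, False, (1, 1, 1)): 13.59,
    ("P", 0, 0, False, (1, 2)): 34.14,
    ("P", 0, 0, False, (1, 1, 1, 2)): 9.81,
    ("P", 0, 1, False, (1, 1, 2)): 23.47,
}


def _order_key(orders: Sequence[object]) -> tuple:
    return tuple(sorted(orders, key=str))


def tpsa(mol: MoleculeGraph, include_sp: bool = True) -> float:
    """Topological PSA: sum of per-atom polar contributions over N/O (+S/P)."""
    table = dict(_TPSA_CONTRIB)
    if include_sp:
        table.update(_TPSA_CONTRIB_SP)
    total = 0.0
    for i, a in enumerate(mol.atoms):
        if a.element not in ("N", "O", "S", "P"):
            continue
        orders = _order_key(b.order for b in mol.incident_bonds(i))
        key = (a.element, a.charge, a.n_h, mol.is_aromatic_atom(i), orders)
        contrib = table.get(key)
        if contrib is None:
            log.warning("no PSA contribution for atom %d environment %s; using 0", i, key)
            continue
        total += contrib
    return total


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake–Rupley)
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = math.pi * (1 + 5 ** 0.5) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def sasa(mol: MoleculeGraph, conf: Conformer, radii: Optional[dict] = None,
         probe: float = 1.4, n_points: int = 960) -> float:
    """Numerical solvent-accessible surface area in Å².

    Shrake–Rupley quadrature: each atom is covered with ``n_points``
    quasi-uniform sphere points at radius r_vdw + probe; points inside any
    neighboring atom's expanded sphere are buried.
    """
    if n_points < 32:
        raise ValueError("n_points must be at least 32 for a usable quadrature")
    radii = radii or BONDI_RADII
    try:
        r = np.array([radii[a.element] for a in mol.atoms]) + probe
    except KeyError as e:
        raise KeyError(f"no vdW radius for element {e.args[0]!r}") from None
    xyz = conf.coords
    sphere = _fibonacci_sphere(n_points)
    total = 0.0
    for i in range(mol.n_atoms):
        pts = xyz[i] + r[i] * sphere
        buried = np.zeros(n_points, dtype=bool)
        for j in range(mol.n_atoms):
            if j == i:
                continue
            if np.linalg.norm(xyz[i] - xyz[j]) >= r[i] + r[j]:
                continue
            buried |= np.linalg.norm(pts - xyz[j], axis=1) < r[j]
        total += 4.0 * math.pi * r[i] ** 2 * (n_points - buried.sum()) / n_points
    return total


# ---------------------------------------------------------------------------
# LogP (coarse atomic contributions; binning only)
# ---------------------------------------------------------------------------

_LOGP_CONTRIB = {
    ("C", False): 0.20, ("C", True): 0.30,
    ("N", False): -1.03, ("N", True): -0.60,
    ("O", False): -0.41, ("O", True): -0.30,
    ("S", False): 0.39, ("S", True): 0.45,
    ("P", False): -0.45,
    ("F", False): 0.21, ("Cl", False): 0.65,
    ("Br", False): 0.89, ("I", False): 1.22,
}
_LOGP_CHARGE_PENALTY = -1.30  # per unit of |formal charge|


def logp(mol: MoleculeGraph) -> float:
    total = 0.0
    for i, a in enumerate(mol.atoms):
        total += _LOGP_CONTRIB.get((a.element, mol.is_aromatic_atom(i)), 0.0)
        total += _LOGP_CHARGE_PENALTY * abs(a.charge)
    return total


# ---------------------------------------------------------------------------
# Charge descriptors
# ---------------------------------------------------------------------------

def charged_group_count(mol: MoleculeGraph) -> int:
    """Charge centers counted per functional group.

    Charged atoms at graph distance ≤ 2 (e.g. the two oxygens of a doubly
    deprotonated phosphate) collapse into one center; a delocalized group is
    represented with one charged atom anyway.
    """
    charged = [i for i, a in enumerate(mol.atoms) if a.charge != 0]
    if not charged:
        return 0
    d = mol.graph_distances()
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(charged)
    for ii in charged:
        for jj in charged:
            if ii < jj and d[ii, jj] <= 2:
                g.add_edge(ii, jj)
    return nx.number_connected_components(g)


def total_formal_charge(mol: MoleculeGraph) -> int:
    return mol.total_charge()


# ---------------------------------------------------------------------------
# Descriptor bundle and stratification
# ---------------------------------------------------------------------------

@dataclass
class DescriptorSet:
    rotb: int
    mw: float
    ha: int
    psa: float
    logp: float
    charged_groups: int
    total_charge: int
    sasa: Optional[float] = None
    psa_sasa: Optional[float] = None


def compute_descriptors(mol: MoleculeGraph, conf: Optional[Conformer] = None,
                        sasa_points: int = 960) -> DescriptorSet:
    d = DescriptorSet(
        rotb=count_rotatable_bonds(mol),
        mw=molecular_weight(mol),
        ha=heavy_atom_count(mol),
        psa=tpsa(mol),
        logp=logp(mol),
        charged_groups=charged_group_count(mol),
        total_charge=total_formal_charge(mol),
    )
    if conf is not None:
        d.sasa = sasa(mol, conf, n_points=sasa_points)
        d.psa_sasa = d.psa / d.sasa if d.sasa > 0 else None
    return d


@dataclass
class StrataConfig:
    """Bin definitions for the stratified fraction reports.

    Convention: lower edge inclusive at the first bin, upper edges inclusive
    at the printed boundary — [150, 250], (250, 350], (350, 450], (450, 650].
    """

    rotb_bins: list = field(default_factory=lambda: [
        (0, 3, "low"), (4, 6, "fair"), (7, 10, "high"), (11, 15, "extreme")])
    mw_bins: list = field(default_factory=lambda: [
        (150, 250, "150-250"), (250, 350, "250-350"),
        (350, 450, "350-450"), (450, 650, "450-650")])
    ha_bins: list = field(default_factory=lambda: [
        (10, 14, "10-14"), (15, 20, "15-20"), (21, 25, "21-25"),
        (26, 30, "26-30"), (31, 10**9, ">30")])
    logp_bins: list = field(default_factory=lambda: [
        (-1e9, 0, "<0"), (0, 1, "0-0.99"), (1, 2, "1-1.99"), (2, 3, "2-2.99"),
        (3, 4, "3-3.99"), (4, 5, "4-4.99"), (5, 1e9, ">=5")])
    psa_bins: list = field(default_factory=lambda: [
        (0, 70, "0-70"), (70, 140, "70-140"), (140, 210, "140-210"),
        (210, 1e9, ">210")])
    psa_sasa_cuts: tuple = (0.1, 0.4)
    rmsd_thresholds: tuple = (0.5, 1.0)


def _bin_label_int(value: int, bins) -> str:
    for lo, hi, label in bins:
        if lo <= value <= hi:
            return label
    return "out-of-range"


def _bin_label_float(value: float, bins) -> str:
    # first bin closed, then half-open (lo, hi]
    for k, (lo, hi, label) in enumerate(bins):
        if (lo <= value <= hi) if k == 0 else (lo < value <= hi):
            return label
    return "out-of-range"


def assign_strata(desc: DescriptorSet, cfg: Optional[StrataConfig] = None) -> dict:
    """One bin label per stratification axis."""
    cfg = cfg or StrataConfig()
    labels = {
        "rotb": _bin_label_int(desc.rotb, cfg.rotb_bins),
        "mw": _bin_label_float(desc.mw, cfg.mw_bins),
        "ha": _bin_label_int(desc.ha, cfg.ha_bins),
        "logp": _bin_label_float(desc.logp, cfg.logp_bins),
        "psa": _bin_label_float(desc.psa, cfg.psa_bins),
    }
    if desc.psa_sasa is not None:
        lo, hi = cfg.psa_sasa_cuts
        if desc.psa_sasa < lo:
            labels["psa_sasa"] = f"<{lo}"
        elif desc.psa_sasa > hi:
            labels["psa_sasa"] = f">{hi}"
        else:
            labels["psa_sasa"] = f"{lo}-{hi}"
    return labels
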