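"""Ligand curation: complex parsing and the selection/inclusion filters.

Filters implemented (all config-driven, defaults as used throughout):
element whitelist (biogenic set), water close contacts (vdW sum scaled by
f=0.891 for carbon / 0.8 otherwise), crystal-packing contacts against
symmetry mates within 5.0 Å, alternate-location selection by occupancy,
covalent-attachment detection, the occurrence analysis (mean + deviation,
ceiling threshold), and the drug-likeness window.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import gemmi
import numpy as np

from .chem import BIOGENIC_ELEMENTS, BONDI_RADII, Conformer, MoleculeGraph

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Parameter blocks
# ---------------------------------------------------------------------------

@dataclass
class WaterContactParams:
    f_carbon: float = 0.891
    f_other: float = 0.8
    radii: dict = field(default_factory=lambda: dict(BONDI_RADII))

    def __post_init__(self) -> None:
        if not (0 < self.f_carbon <= 1 and 0 < self.f_other <= 1):
            raise ValueError("contact factors must be in (0, 1]")


@dataclass
class PackingParams:
    cutoff: float = 5.0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("packing cutoff must be positive")


@dataclass
class DruglikenessWindow:
    rotb_max: int = 15
    mw_range: tuple = (150.0, 650.0)
    ha_range: tuple = (10, 150)
    charge_range: tuple = (-3, 3)


COVALENT_CUTOFF = 1.8  # Å; ligand heavy atom this close to protein => covalent


# ---------------------------------------------------------------------------
# Complex model
# ---------------------------------------------------------------------------

@dataclass
class LigandAtom:
    name: str
    element: str
    altloc: str
    occupancy: float
    xyz: np.ndarray


@dataclass
class ComplexModel:
    ligand_atoms: list  # file-ordered LigandAtom records (all altlocs)
    waters: np.ndarray  # (W, 3) water oxygen coordinates
    cell: tuple  # (a, b, c, alpha, beta, gamma)
    operators: list  # [(R 3x3 fractional, t fractional)]
    protein_coords: np.ndarray  # (P, 3) heavy atoms, may be empty
    ph: Optional[float] = None


_SMTRY_RE = re.compile(
    r"^REMARK 290\s+SMTRY([123])\s+(\d+)\s+([-\d.]+)\s+([-\d.]+)\s+([-\d.]+)\s+([-\d.]+)")
_PH_RE = re.compile(r"^REMARK 200\s+PH\s*:\s*([\d.]+)")


def _parse_remark290(text: str, cell: gemmi.UnitCell) -> list:
    """REMARK 290 SMTRY operators (Cartesian in the file) as fractional pairs."""
    rows: dict[int, dict[int, tuple]] = {}
    for line in text.splitlines():
        m = _SMTRY_RE.match(line)
        if m:
            axis, opnum = int(m.group(1)), int(m.group(2))
            rows.setdefault(opnum, {})[axis] = tuple(float(m.group(k)) for k in (3, 4, 5, 6))
    ops = []
    frac = np.array(cell.frac.mat.tolist())
    orth = np.array(cell.orth.mat.tolist())
    for opnum in sorted(rows):
        if set(rows[opnum]) != {1, 2, 3}:
            raise ValueError(f"incomplete SMTRY operator {opnum}")
        R_cart = np.array([rows[opnum][k][:3] for k in (1, 2, 3)])
        t_cart = np.array([rows[opnum][k][3] for k in (1, 2, 3)])
        ops.append((frac @ R_cart @ orth, frac @ t_cart))
    return ops


def parse_pdb_complex(text: str) -> list[ComplexModel]:
    """Parse a (possibly multi-MODEL) PDB complex into one model per MODEL."""
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as e:
        raise ValueError(f"unparseable PDB text: {e}") from None
    st.setup_entities()
    cell = st.cell
    ops = _parse_remark290(text, cell)
    if not ops:
        log.warning("no REMARK 290 operators found; assuming identity only")
        ops = [(np.eye(3), np.zeros(3))]
    ph = None
    for line in text.splitlines():
        m = _PH_RE.match(line)
        if m:
            ph = float(m.group(1))
    out = []
    for model in st:
        lig, wat, prot = [], [], []
        for chain in model:
            for res in chain:
                if res.name == "HOH":
                    for at in res:
                        if at.element.name != "H":
                            wat.append([at.pos.x, at.pos.y, at.pos.z])
                elif res.het_flag == "H":
                    for at in res:
                        lig.append(LigandAtom(
                            at.name, at.element.name, at.altloc or "",
                            at.occ, np.array([at.pos.x, at.pos.y, at.pos.z])))
                else:
                    for at in res:
                        if at.element.name != "H":
                            prot.append([at.pos.x, at.pos.y, at.pos.z])
        if not lig:
            raise ValueError("PDB model contains no HETATM ligand records")
        out.append(ComplexModel(
            ligand_atoms=lig,
            waters=np.array(wat).reshape(-1, 3),
            cell=(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma),
            operators=ops,
            protein_coords=np.array(prot).reshape(-1, 3),
            ph=ph,
        ))
    return out


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def select_altloc(ligand_atoms: Sequence[LigandAtom]) -> Conformer:
    """Keep the alternate location with the highest occupancy (first on ties)."""
    groups: dict[str, list[LigandAtom]] = {}
    order: list[str] = []
    shared = [a for a in ligand_atoms if not a.altloc]
    for a in ligand_atoms:
        if a.altloc:
            if a.altloc not in groups:
                groups[a.altloc] = []
                order.append(a.altloc)
            groups[a.altloc].append(a)
    if not groups:
        return Conformer(np.array([a.xyz for a in ligand_atoms]))
    sizes = {len(v) for v in groups.values()}
    if len(sizes) != 1:
        raise ValueError("altloc groups have inconsistent atom counts")
    best = max(order, key=lambda k: (groups[k][0].occupancy, -order.index(k)))
    chosen = shared + groups[best]
    return Conformer(np.array([a.xyz for a in chosen]))


def element_whitelist_check(mol: MoleculeGraph,
                            whitelist: frozenset = BIOGENIC_ELEMENTS) -> bool:
    return all(a.element in whitelist for a in mol.atoms)


def water_contact_filter(mol: MoleculeGraph, conf: Conformer, waters: np.ndarray,
                         params: Optional[WaterContactParams] = None
                         ) -> tuple[bool, list]:
    """Discard when any water oxygen sits inside the scaled vdW contact sum.

    Returns (keep, offending (water index, atom index, distance, cutoff)).
    """
    params = params or WaterContactParams()
    offenders = []
    if len(waters) == 0:
        return True, offenders
    try:
        r_o = params.radii["O"]
        radii = np.array([params.radii[a.element] for a in mol.atoms])
    except KeyError as e:
        raise KeyError(f"no vdW radius configured for element {e.args[0]!r}") from None
    factors = np.array([params.f_carbon if a.element == "C" else params.f_other
                        for a in mol.atoms])
    cutoffs = factors * (r_o + radii)
    d = np.linalg.norm(waters[:, None, :] - conf.coords[None, :, :], axis=2)
    for w, i in zip(*np.where(d < cutoffs[None, :])):
        offenders.append((int(w), int(i), float(d[w, i]), float(cutoffs[i])))
    return len(offenders) == 0, offenders


def expand_symmetry_mates(cm: ComplexModel,
                          source_coords: Optional[np.ndarray] = None,
                          include_lattice: bool = True) -> np.ndarray:
    """Cartesian heavy-atom coordinates of all symmetry/lattice neighbors.

    Every deposited operator, combined with lattice translations in
    {-1,0,1}^3, is applied to the model's heavy atoms (ligand + protein, or
    ``source_coords``); the identity image is dropped.
    """
    a, b, c, al, be, ga = cm.cell
    cell = gemmi.UnitCell(a, b, c, al, be, ga)
    if cell.volume <= 0:
        raise ValueError("singular unit cell")
    frac = np.array(cell.frac.mat.tolist())
    orth = np.array(cell.orth.mat.tolist())
    if source_coords is None:
        lig = np.array([at.xyz for at in cm.ligand_atoms]).reshape(-1, 3)
        source_coords = np.vstack([lig, cm.protein_coords]) \
            if len(cm.protein_coords) else lig
    fx = source_coords @ frac.T
    mates = []
    if include_lattice:
        shifts = [np.array([i, j, k]) for i in (-1, 0, 1) for j in (-1, 0, 1)
                  for k in (-1, 0, 1)]
    else:
        shifts = [np.zeros(3)]
    for R, t in cm.operators:
        identity_rot = np.allclose(R, np.eye(3), atol=1e-9)
        for n in shifts:
            tt = t + n
            if identity_rot and np.allclose(tt, 0.0, atol=1e-9):
                continue
            mates.append((fx @ R.T + tt) @ orth.T)
    if not mates:
        return np.empty((0, 3))
    return np.vstack(mates)


def packing_contact_filter(conf: Conformer, mates: np.ndarray,
                           params: Optional[PackingParams] = None) -> bool:
    """Keep unless any symmetry-mate atom lies within the packing cutoff."""
    params = params or PackingParams()
    if len(mates) == 0:
        return True
    d = np.linalg.norm(mates[:, None, :] - conf.coords[None, :, :], axis=2)
    return bool(d.min() >= params.cutoff)


def covalent_attachment_check(conf: Conformer, protein_coords: np.ndarray,
                              cutoff: float = COVALENT_CUTOFF) -> bool:
    """True (discard-worthy) if the ligand is within covalent range of protein."""
    if len(protein_coords) == 0:
        return False
    d = np.linalg.norm(protein_coords[:, None, :] - conf.coords[None, :, :], axis=2)
    return bool(d.min() < cutoff)


# ---------------------------------------------------------------------------
# Occurrence analysis
# ---------------------------------------------------------------------------

@dataclass
class OccurrenceStats:
    mean: float
    deviation: float
    raw_threshold: float
    threshold: int

    @classmethod
    def from_values(cls, mean: float, deviation: float) -> "OccurrenceStats":
        """Threshold from precomputed statistics: ceiling(mean + deviation)."""
        raw = mean + deviation
        return cls(mean, deviation, raw, math.ceil(raw))


def occurrence_analysis(counts: dict, deviation="sample"
                        ) -> tuple[OccurrenceStats, list]:
    """Occurrence filter: ligands appearing more than ceil(μ + s) times go.

    ``deviation`` selects the spread statistic: "sample" or "population"
    standard deviation of the counts, or a literal numeric value added to the
    mean as-is (the published protocol adds a printed deviation figure).
    """
    if not counts:
        raise ValueError("occurrence counts must be nonempty")
    values = np.array(list(counts.values()), dtype=float)
    mu = float(values.mean())
    if deviation == "sample":
        s = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    elif deviation == "population":
        s = float(values.std(ddof=0))
    else:
        s = float(deviation)
    stats = OccurrenceStats.from_values(mu, s)
    kept = [k for k, v in counts.items() if v <= stats.threshold]
    return stats, kept


# ---------------------------------------------------------------------------
# Drug-likeness window
# ---------------------------------------------------------------------------

def druglikeness_filter(descriptor_set, window: Optional[DruglikenessWindow] = None
                        ) -> tuple[bool, list]:
    """Window check on #RotB, MW, heavy atoms and total charge."""
    window = window or DruglikenessWindow()
    failed = []
    if descriptor_set.rotb > window.rotb_max:
        failed.append("RotB")
    if not window.mw_range[0] <= descriptor_set.mw <= window.mw_range[1]:
        failed.append("MW")
    if not window.ha_range[0] <= descriptor_set.ha <= window.ha_range[1]:
        failed.append("HA")
    if not window.charge_range[0] <= descriptor_set.total_charge <= window.charge_range[1]:
        failed.append("charge")
    return len(failed) == 0, failed


def curate_complex(mol: MoleculeGraph, cm: ComplexModel,
                   water_params: Optional[WaterContactParams] = None,
                   packing_params: Optional[PackingParams] = None) -> dict:
    """Run the per-complex filters; returns per-filter verdicts and the pose."""
    conf = select_altloc(cm.ligand_atoms)
    if conf.n_atoms != mol.n_atoms:
        raise ValueError("parsed ligand atom count does not match the graph")
    keep_water, offenders = water_contact_filter(mol, conf, cm.waters, water_params)
    mates = expand_symmetry_mates(cm)
    return {
        "conformer": conf,
        "element_ok": element_whitelist_check(mol),
        "water_ok": keep_water,
        "water_offenders": offenders,
        "packing_ok": packing_contact_filter(conf, mates, packing_params),
        "not_covalent": not covalent_attachment_check(conf, cm.protein_coords),
    }
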