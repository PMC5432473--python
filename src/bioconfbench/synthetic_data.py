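"""Synthetic ligands, crystal poses, complex files and NMR-like ensembles.

Everything the pipeline consumes can be generated here with known ground
truth and no external downloads. Molecules are assembled from a small
fragment alphabet — rigid aromatic rings, amide links, sp3 methylenes,
and terminal caps (CH3/OH/COOH-like, plus charged carboxylate/ammonium) —
joined by acyclic single bonds, so the rotatable-bond count of the product
is controlled exactly by construction. Controllability is deliberately
favored over chemical realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem import Atom, Bond, Conformer, MoleculeGraph, AROMATIC, BONDI_RADII
from .geometry import (dihedral, min_nonbonded_distance, place_atom,
                       set_torsions, torsion_reference)
from . import descriptors as desc

CLASH_FLOOR = 2.0  # Å; nonbonded heavy-atom pairs >3 bonds apart must clear this

# approximate fragment masses used only for pre-build composition tuning
_FRAG_MASS = {"CH2": 14.03, "phenylene": 76.10, "amide": 43.03, "branch": 28.06}
_CAP_MASS = 15.03  # CH3


# ---------------------------------------------------------------------------
# Incremental 3D builder
# ---------------------------------------------------------------------------

class _Builder:
    """Grows a molecule atom-by-atom with internal-coordinate placement."""

    def __init__(self) -> None:
        self.atoms: list[Atom] = []
        self.bonds: list[Bond] = []
        self.coords: list[np.ndarray] = []
        self.parent: list[Optional[int]] = []

    def add(self, element: str, *, charge: int = 0, n_h: int = 0,
            parent: Optional[int] = None, order: object = 1,
            length: float = 1.53, angle: float = 112.0,
            dihedral: float = 180.0) -> int:
        idx = len(self.atoms)
        self.atoms.append(Atom(element, charge, n_h))
        self.parent.append(parent)
        if parent is None:
            self.coords.append(np.zeros(3))
        else:
            self.bonds.append(Bond(parent, idx, order))
            gp = self.parent[parent]
            if gp is None:
                self.coords.append(self.coords[parent] + np.array([length, 0.0, 0.0]))
            else:
                ggp = self.parent[gp]
                if ggp is None:
                    ref = self.coords[gp] + np.array([0.0, 0.0, 1.0])
                else:
                    ref = self.coords[ggp]
                self.coords.append(place_atom(ref, self.coords[gp],
                                              self.coords[parent],
                                              length, angle, dihedral))
        return idx

    def close_ring(self, i: int, j: int, order: object = AROMATIC) -> None:
        self.bonds.append(Bond(i, j, order))

    def build(self) -> tuple[MoleculeGraph, Conformer]:
        mol = MoleculeGraph(self.atoms, self.bonds)
        return mol, Conformer(np.array(self.coords))


# ---------------------------------------------------------------------------
# Fragment alphabet
# ---------------------------------------------------------------------------

def _attach_fragment(b: _Builder, name: str, tail: Optional[int]) -> int:
    """Append one interior fragment; returns its exit (attachment) atom."""
    if name == "CH2":
        return b.add("C", n_h=2, parent=tail)
    if name == "phenylene":
        r1 = b.add("C", n_h=0 if tail is not None else 1, parent=tail,
                   length=1.48, dihedral=180.0)
        r2 = b.add("C", n_h=1, parent=r1, order=AROMATIC, length=1.39,
                   angle=120.0, dihedral=0.0)
        r3 = b.add("C", n_h=1, parent=r2, order=AROMATIC, length=1.39,
                   angle=120.0, dihedral=180.0)
        r4 = b.add("C", n_h=0, parent=r3, order=AROMATIC, length=1.39,
                   angle=120.0, dihedral=0.0)
        r5 = b.add("C", n_h=1, parent=r4, order=AROMATIC, length=1.39,
                   angle=120.0, dihedral=0.0)
        r6 = b.add("C", n_h=1, parent=r5, order=AROMATIC, length=1.39,
                   angle=120.0, dihedral=0.0)
        b.close_ring(r6, r1)
        return r4
    if name == "amide":
        c = b.add("C", n_h=0, parent=tail, length=1.52)
        b.add("O", n_h=0, parent=c, order=2, length=1.23, angle=121.0,
              dihedral=0.0)
        n = b.add("N", n_h=1, parent=c, length=1.34, angle=116.0,
                  dihedral=180.0)
        return n
    if name == "branch":
        c = b.add("C", n_h=1, parent=tail)
        b.add("C", n_h=3, parent=c, length=1.53, angle=109.0, dihedral=60.0)
        return c
    raise ValueError(f"unknown fragment {name!r}")


def _attach_cap(b: _Builder, name: str, tail: int) -> int:
    if name == "CH3":
        return b.add("C", n_h=3, parent=tail)
    if name == "OH":
        return b.add("O", n_h=1, parent=tail, length=1.43, angle=109.0)
    raise ValueError(f"unknown cap {name!r}")


def _build_chain(fragments: Sequence[str],
                 caps: tuple[str, str] = ("CH3", "CH3")) -> tuple[MoleculeGraph, Conformer]:
    """Assemble cap–F1–…–Fm–cap in an extended (all-anti) geometry."""
    b = _Builder()
    head = b.add("C", n_h=3) if caps[0] == "CH3" else b.add("O", n_h=1)
    tail = head
    for name in fragments:
        tail = _attach_fragment(b, name, tail)
    _attach_cap(b, caps[1], tail)
    return b.build()


def _acene(n_rings: int = 3) -> tuple[MoleculeGraph, Conformer]:
    """Linearly fused aromatic rings (n=3: anthracene); fully rigid."""
    R = 1.39
    centers = [np.array([k * R * math.sqrt(3.0), 0.0]) for k in range(n_rings)]
    pts: list[np.ndarray] = []
    for c in centers:
        for k in range(6):
            ang = math.radians(30 + 60 * k)
            p = c + R * np.array([math.cos(ang), math.sin(ang)])
            if not any(np.linalg.norm(p - q) < 0.1 for q in pts):
                pts.append(p)
    coords = np.column_stack([np.array(pts), np.zeros(len(pts))])
    bonds = []
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            if abs(np.linalg.norm(coords[i] - coords[j]) - R) < 0.05:
                bonds.append(Bond(i, j, AROMATIC))
    deg = np.zeros(len(pts), dtype=int)
    for b in bonds:
        deg[b.i] += 1
        deg[b.j] += 1
    atoms = [Atom("C", 0, 1 if deg[i] == 2 else 0) for i in range(len(pts))]
    mol = MoleculeGraph(atoms, bonds)
    return mol, Conformer(coords)


# ---------------------------------------------------------------------------
# Pose generation
# ---------------------------------------------------------------------------

def extended_pose(mol: MoleculeGraph, conf: Conformer) -> Conformer:
    """All-anti (180°) torsions on every rotatable bond; clash-free for chains."""
    rb = desc.rotatable_bonds(mol)
    if not rb:
        return conf.copy()
    coords = set_torsions(mol, conf.coords, rb, np.full(len(rb), 180.0))
    return Conformer(coords)


POSE_JITTER_DEG = 20.0  # crystal poses sit off the ideal rotamer grid


def _sample_pose(mol: MoleculeGraph, conf: Conformer,
                 rng: np.random.Generator, max_tries: int = 30) -> Conformer:
    """Seeded torsion draw: rotamer wells ± wrapped-normal jitter, clash-free.

    Bound ligands rarely adopt ideal gauche/anti angles, so each torsion is
    displaced off its well; clashed draws are rejected, falling back to the
    all-anti chain.
    """
    rb = desc.rotatable_bonds(mol)
    if not rb:
        return conf.copy()
    for _ in range(max_tries):
        wells = rng.choice([60.0, 180.0, 300.0], size=len(rb))
        angles = np.mod(wells + rng.normal(0.0, POSE_JITTER_DEG, size=len(rb)), 360.0)
        coords = set_torsions(mol, conf.coords, rb, angles)
        if min_nonbonded_distance(mol, coords) >= CLASH_FLOOR:
            return Conformer(coords)
    return extended_pose(mol, conf)


# ---------------------------------------------------------------------------
# Public generators
# ---------------------------------------------------------------------------

def make_linear_ligand(n_rotb: int, seed: int,
                       fragments: Optional[Sequence[str]] = None
                       ) -> tuple[MoleculeGraph, Conformer]:
    """A ligand whose rotatable-bond count equals ``n_rotb`` by construction.

    ``n_rotb = 0`` yields a rigid fused-ring acene; otherwise a chain of
    ``n_rotb + 1`` interior fragments between two methyl caps, so the
    inter-fragment joints contribute exactly ``n_rotb`` rotatable bonds.
    The returned conformer is a clash-free seeded "crystal pose".
    """
    if not 0 <= n_rotb <= 15:
        raise ValueError(f"n_rotb must be in [0, 15], got {n_rotb}")
    rng = np.random.default_rng(seed)
    if n_rotb == 0 and fragments is None:
        mol, conf = _acene(3)
        return mol, conf
    if fragments is None:
        fragments = _draw_fragments(rng, n_rotb + 1)
    mol, conf = _build_chain(list(fragments))
    return mol, _sample_pose(mol, conf, rng)


def _draw_fragments(rng: np.random.Generator, m: int,
                    n_branch: int = 0) -> list[str]:
    """Seeded interior-fragment draw; amide never adjacent to amide."""
    names = ["CH2", "phenylene", "amide"]
    probs = [0.60, 0.25, 0.15]
    out: list[str] = []
    for _ in range(m - n_branch):
        name = rng.choice(names, p=probs)
        if name == "amide" and out and out[-1] == "amide":
            name = "CH2"
        out.append(str(name))
    # branch points interleaved deterministically, never first/adjacent-critical
    for k in range(n_branch):
        out.insert(min(1 + 2 * k, len(out)), "branch")
    return out


def make_charged_variant(mol: MoleculeGraph, n_centers: int, seed: int,
                         conformer: Optional[Conformer] = None
                         ) -> tuple[MoleculeGraph, Optional[Conformer]]:
    """Install formal-charge centers at substitutable terminal methyls.

    Centers alternate carboxylate (−1; terminal CH3 → C(=O)O⁻, two oxygens
    appended) and ammonium (+1; terminal CH3 carbon → N⁺H3), so the total
    charge is 0 for even ``n_centers`` and −1 for odd. Each carboxylate adds
    one rotatable bond (its cap joint gains heavy neighbors).
    """
    if n_centers == 0:
        return mol, conformer
    caps = [i for i, a in enumerate(mol.atoms)
            if a.element == "C" and a.n_h == 3 and mol.degree(i) == 1]
    if len(caps) < n_centers:
        raise ValueError(
            f"molecule has {len(caps)} substitutable terminals, need {n_centers}")
    rng = np.random.default_rng(seed)
    chosen = [caps[k] for k in rng.permutation(len(caps))[:n_centers]]

    atoms = list(mol.atoms)
    bonds = list(mol.bonds)
    coords = None if conformer is None else [xyz for xyz in conformer.coords]
    for rank, i in enumerate(chosen):
        if rank % 2 == 0:  # carboxylate
            atoms[i] = Atom("C", 0, 0)
            o1 = len(atoms)
            atoms.append(Atom("O", 0, 0))
            bonds.append(Bond(i, o1, 2))
            o2 = len(atoms)
            atoms.append(Atom("O", -1, 0))
            bonds.append(Bond(i, o2, 1))
            if coords is not None:
                p = mol.neighbors(i)[0]
                gps = [k for k in mol.neighbors(p) if k != i]
                gp = gps[0] if gps else None
                ref = coords[gp] if gp is not None else coords[p] + np.array([0.0, 0.0, 1.0])
                coords.append(place_atom(ref, coords[p], coords[i], 1.25, 117.0, 0.0))
                coords.append(place_atom(ref, coords[p], coords[i], 1.25, 117.0, 180.0))
        else:  # ammonium
            atoms[i] = Atom("N", 1, 3)
    out = MoleculeGraph(atoms, bonds)
    out_conf = None if coords is None else Conformer(np.array(coords))
    return out, out_conf


def make_nmr_ensemble(mol: MoleculeGraph, crystal: Conformer, n_models: int,
                      jitter_deg: float, seed: int) -> list[Conformer]:
    """Models obtained by wrapped-normal torsion noise around the crystal pose."""
    if n_models < 2:
        raise ValueError("an ensemble needs at least 2 models")
    if jitter_deg < 0:
        raise ValueError("jitter_deg must be nonnegative")
    rng = np.random.default_rng(seed)
    rb = desc.rotatable_bonds(mol)
    if not rb:
        return [crystal.copy() for _ in range(n_models)]
    base = np.array([
        dihedral(*(crystal.coords[k] for k in torsion_reference(mol, i, j)))
        for i, j in rb])
    models = []
    for _ in range(n_models):
        noise = rng.normal(0.0, jitter_deg, size=len(rb))
        angles = np.mod(base + noise, 360.0)
        models.append(Conformer(set_torsions(mol, crystal.coords, rb, angles)))
    return models


# ---------------------------------------------------------------------------
# PDB fixture writer
# ---------------------------------------------------------------------------

def _direction_fan(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = math.pi * (1 + 5 ** 0.5) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta), np.cos(phi)])


_IDENTITY_SMTRY = (
    "REMARK 290   SMTRY1   1  1.000000  0.000000  0.000000        0.00000\n"
    "REMARK 290   SMTRY2   1  0.000000  1.000000  0.000000        0.00000\n"
    "REMARK 290   SMTRY3   1  0.000000  0.000000  1.000000        0.00000\n"
)


def _atom_names(mol: MoleculeGraph) -> list[str]:
    counts: dict[str, int] = {}
    names = []
    for a in mol.atoms:
        counts[a.element] = counts.get(a.element, 0) + 1
        names.append(f"{a.element}{counts[a.element]}")
    return names


def _hetatm(serial: int, name: str, altloc: str, res: str, chain: str,
            resseq: int, xyz, occ: float, element: str) -> str:
    return (f"HETATM{serial:5d} {name:<4s}{altloc:1s}{res:<3s} {chain:1s}"
            f"{resseq:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{occ:6.2f}{0.0:6.2f}          {element:>2s}\n")


def _solve_mate_cell(coords: np.ndarray, offset: float) -> float:
    """Cell length a such that the +a x-translated copy approaches to ``offset``."""
    from scipy.optimize import brentq

    def f(D: float) -> float:
        shifted = coords + np.array([D, 0.0, 0.0])
        d = np.linalg.norm(shifted[:, None, :] - coords[None, :, :], axis=2)
        return float(d.min()) - offset

    span = float(coords[:, 0].max() - coords[:, 0].min())
    return float(brentq(f, 1e-6, span + offset + 10.0, xtol=1e-6))


def make_complex_file(mol: MoleculeGraph, conf: Conformer, *,
                      waters: Sequence[tuple[int, float]] = (),
                      altlocs: Optional[Sequence[tuple[str, float]]] = None,
                      mate_offset: Optional[float] = None,
                      models: Optional[Sequence[Conformer]] = None,
                      ph: Optional[float] = None,
                      seed: int = 0,
                      include_remark290: bool = True,
                      res_name: str = "LIG") -> str:
    """Emit a synthetic PDB complex for the curation filters.

    ``waters`` places HOH oxygens at exact distances from named ligand atoms;
    ``altlocs`` duplicates every ligand atom per (altloc id, occupancy);
    ``mate_offset`` shrinks the P1 cell along x so the lattice-translated
    symmetry mate's nearest heavy-atom approach equals the offset;
    ``models`` wraps multiple conformers in MODEL/ENDMDL blocks.
    """
    for _, dist in waters:
        if dist <= 0:
            raise ValueError("water distances must be positive")
    if altlocs is not None and abs(sum(o for _, o in altlocs) - 1.0) > 1e-6:
        raise ValueError("altloc occupancies must sum to 1")
    rng = np.random.default_rng(seed)
    names = _atom_names(mol)
    coords = conf.coords
    cell_a = 200.0
    if mate_offset is not None:
        if mate_offset <= 0:
            raise ValueError("mate offset must be positive")
        cell_a = _solve_mate_cell(coords - coords.min(axis=0), mate_offset)

    lines = []
    if ph is not None:
        lines.append(f"REMARK 200  PH                             : {ph:.2f}\n")
    lines.append(f"CRYST1{cell_a:9.3f}{200.0:9.3f}{200.0:9.3f}"
                 f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n")
    if include_remark290:
        lines.append(_IDENTITY_SMTRY)

    # place the ligand well inside the cell so fractionalization stays clean
    origin = coords - coords.min(axis=0) + 5.0
    water_xyz = []
    centroid = origin.mean(axis=0)
    # deterministic direction fan; the named atom must be the water's nearest
    fan = np.vstack([_direction_fan(256), rng.normal(size=(64, 3))])
    fan /= np.linalg.norm(fan, axis=1, keepdims=True)
    for atom_idx, dist in waters:
        best_u, best_clear = None, -np.inf
        for u in fan:
            cand = origin[atom_idx] + dist * u
            others = np.linalg.norm(origin - cand, axis=1)
            others[atom_idx] = np.inf
            if others.min() > best_clear:
                best_clear, best_u = float(others.min()), u
        if best_clear <= dist:
            raise ValueError(f"could not place water at {dist} Å from atom {atom_idx}")
        water_xyz.append(origin[atom_idx] + dist * best_u)

    def ligand_block(xyz: np.ndarray, serial0: int) -> tuple[list[str], int]:
        out = []
        serial = serial0
        groups = altlocs if altlocs else [("", 1.0)]
        for gi, (alt, occ) in enumerate(groups):
            block = xyz if gi == 0 else xyz + rng.normal(0.0, 0.15, size=xyz.shape)
            for i in range(mol.n_atoms):
                out.append(_hetatm(serial, names[i], alt, res_name, "A", 1,
                                   block[i], occ, mol.atoms[i].element))
                serial += 1
        return out, serial

    if models is not None:
        for k, mconf in enumerate(models, start=1):
            mxyz = mconf.coords - mconf.coords.min(axis=0) + 5.0
            lines.append(f"MODEL {k:8d}\n")
            blk, serial = ligand_block(mxyz, 1)
            lines += blk
            lines.append("ENDMDL\n")
    else:
        blk, serial = ligand_block(origin, 1)
        lines += blk
        for w, xyz in enumerate(water_xyz):
            lines.append(_hetatm(serial, "O", "", "HOH", "W", 100 + w, xyz, 1.0, "O"))
            serial += 1
    lines.append("END\n")
    return "".join(lines)


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDatasetConfig:
    """Study conditions for a synthetic ligand set.

    Defaults emulate the curated crystal-structure set: #RotB spanning 0–15
    with a mean near 5.5, mostly 0–1 charge centers (a few up to 5), and an
    occurrence distribution with mean near 1.8.
    """

    n_ligands: int = 100
    rotb_weights: Sequence[float] = field(default_factory=lambda: [
        0.05, 0.07, 0.09, 0.10, 0.11, 0.10, 0.10, 0.09,
        0.07, 0.06, 0.05, 0.04, 0.03, 0.02, 0.01, 0.01])
    charge_weights: Sequence[float] = field(default_factory=lambda: [
        0.45, 0.32, 0.12, 0.06, 0.03, 0.02])
    occurrence_weights: Sequence[float] = field(default_factory=lambda: [
        0.55, 0.20, 0.10, 0.06, 0.04, 0.02, 0.02, 0.01])
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ligands < 0:
            raise ValueError("n_ligands must be nonnegative")
        for w in (self.rotb_weights, self.charge_weights, self.occurrence_weights):
            if any(x < 0 for x in w):
                raise ValueError("distribution weights must be nonnegative")


@dataclass
class SyntheticLigand:
    ligand_id: str
    mol: MoleculeGraph
    crystal: Conformer
    rotb: int
    charge_centers: int
    occurrence: int


def _feasible(rotb: int, centers: int) -> bool:
    n_carbox = math.ceil(centers / 2)
    if n_carbox > rotb:
        return False
    m = rotb + 1 - n_carbox
    n_branch = max(0, centers - 2)
    if m < max(1, n_branch + 1):
        return False
    n_ammon = centers - n_carbox
    max_mw = m * _FRAG_MASS["phenylene"] + 2 * _CAP_MASS + 29.0 * n_carbox + 3.0 * n_ammon
    return max_mw >= 150.0


def _tune_composition(frags: list[str], n_carbox: int, n_ammon: int) -> list[str]:
    """Swap CH2 ↔ phenylene until the estimated MW falls inside [150, 650]."""
    def est(fr):
        return (sum(_FRAG_MASS[f] for f in fr) + 2 * _CAP_MASS
                + 29.0 * n_carbox + 3.0 * n_ammon)

    frags = list(frags)
    while est(frags) < 150.0:
        if "CH2" in frags:
            frags[frags.index("CH2")] = "phenylene"
        elif "amide" in frags:
            frags[frags.index("amide")] = "phenylene"
        else:
            break
    while est(frags) > 650.0 and "phenylene" in frags:
        frags[frags.index("phenylene")] = "CH2"
    return frags


def make_dataset(config: SyntheticDatasetConfig
                 ) -> tuple[list[SyntheticLigand], pd.DataFrame]:
    """Draw a full ligand set plus its occurrence manifest; seed-deterministic.

    Charge-center draws are clamped down when a (#RotB, centers) pair is not
    constructible (rigid acenes carry no substitutable caps; carboxylates
    consume rotatable-bond budget), so the #RotB histogram always matches the
    draws exactly while the charge histogram may be shifted at low #RotB.
    """
    rng = np.random.default_rng(config.seed)
    rotb_p = np.asarray(config.rotb_weights, float)
    rotb_p = rotb_p / rotb_p.sum()
    ch_p = np.asarray(config.charge_weights, float)
    ch_p = ch_p / ch_p.sum()
    occ_p = np.asarray(config.occurrence_weights, float)
    occ_p = occ_p / occ_p.sum()

    ligands: list[SyntheticLigand] = []
    rows = []
    for k in range(config.n_ligands):
        r = int(rng.choice(len(rotb_p), p=rotb_p))
        c = int(rng.choice(len(ch_p), p=ch_p))
        occ = int(rng.choice(len(occ_p), p=occ_p)) + 1
        while c > 0 and not _feasible(r, c):
            c -= 1
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if r == 0:
            mol, crystal = make_linear_ligand(0, sub_seed)
            c = 0
        else:
            n_carbox = math.ceil(c / 2)
            n_ammon = c - n_carbox
            m = r + 1 - n_carbox
            n_branch = max(0, c - 2)
            frag_rng = np.random.default_rng(sub_seed)
            frags = _draw_fragments(frag_rng, m, n_branch=n_branch)
            frags = _tune_composition(frags, n_carbox, n_ammon)
            mol, base_conf = _build_chain(frags)
            if c > 0:
                mol, base_conf = make_charged_variant(mol, c, sub_seed, base_conf)
            crystal = _sample_pose(mol, base_conf, np.random.default_rng(sub_seed + 1))
        lig = SyntheticLigand(f"L{k:04d}", mol, crystal, r, c, occ)
        ligands.append(lig)
        rows.append({"ligand_id": lig.ligand_id, "rotb": r,
                     "charge_centers": c, "occurrence": occ})
    manifest = pd.DataFrame(rows, columns=["ligand_id", "rotb",
                                           "charge_centers", "occurrence"])
    return ligands, manifest
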