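"""Debiased two-step conformational search over a pluggable engine.

The protocol: (1) search from the crystal pose with a wide 50.0 kcal/mol
acceptance window, pick the conformer *most dissimilar* to the crystal
(removing the positive bias of starting at the answer); (2) search again
from that conformer, keep the production energy window (5.0 kcal/mol by
default, 10.0 as a variant), deduplicate. Best-RMSD queries then ask whether
any pool member reproduces the crystal pose.

The bundled engine is a deterministic toy: it enumerates a gauche+/anti/
gauche- torsion grid (or a seeded random torsion sample when the grid
exceeds the step budget), scoring each conformer with a minimal energy
model — repulsive Lennard-Jones clash term, Coulomb term screened by a
scalar solvent dielectric, and a threefold torsion potential. It is not a
force field; it exists to make solvent and charge effects testable.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .chem import BONDI_RADII, Atom, Conformer, ConformerPool, MoleculeGraph
from .descriptors import rotatable_bonds
from .geometry import apply_torsions_batch
from .symrmsd import (AutomorphismSet, find_automorphisms, map_heavy_atoms,
                      symmetry_rmsd_many)

log = logging.getLogger(__name__)

#: Relative dielectric constants for the toy engine's Coulomb screening.
SOLVENT_DIELECTRIC = {"water": 78.4, "octanol": 10.3, "chloroform": 4.81, "gas": 1.0}

COULOMB_K = 332.06  # kcal·Å/(mol·e²)
CLASH_SCALE = 0.59  # sigma_ij = scale*(r_i+r_j): 1 kcal/mol at the 2.0 Å C-C floor
CLASH_EPS = 1.0     # kcal/mol at r = sigma
TORSION_V3 = 0.25   # kcal/mol barrier; small so electrostatics leads


@dataclass
class SearchParams:
    """Operating parameters of the two-step search."""

    step1_window: float = 50.0   # kcal/mol, step-1 acceptance
    window: float = 5.0          # kcal/mol, production acceptance
    max_steps: int = 5000        # torsion-vector budget per search
    max_saved: int = 1000        # conformer cap per pool
    solvent: str = "water"
    engine: str = "toy"
    seed: int = 0
    dedup_tol: float = 0.25      # Å symmetry-RMSD

    def __post_init__(self) -> None:
        if self.step1_window <= 0 or self.window <= 0:
            raise ValueError("energy windows must be positive")
        if self.max_steps < 1 or self.max_saved < 1:
            raise ValueError("search caps must be >= 1")
        if self.solvent not in SOLVENT_DIELECTRIC:
            raise ValueError(f"unknown solvent {self.solvent!r}")


class ProtocolError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Toy engine
# ---------------------------------------------------------------------------

def _nonbonded_pairs(mol: MoleculeGraph) -> tuple[np.ndarray, np.ndarray]:
    d = mol.graph_distances()
    ii, jj = np.where(np.triu(d >= 3, k=1))
    return ii, jj


def toy_energy(mol: MoleculeGraph, coords: np.ndarray,
               torsion_angles_deg: Optional[np.ndarray],
               dielectric: float) -> np.ndarray:
    """Vectorized toy energies for a (M, N, 3) coordinate stack."""
    ii, jj = _nonbonded_pairs(mol)
    radii = np.array([BONDI_RADII[a.element] for a in mol.atoms])
    charges = np.array([a.charge for a in mol.atoms], dtype=float)
    e = np.zeros(coords.shape[0])
    if len(ii):
        d = np.linalg.norm(coords[:, ii] - coords[:, jj], axis=2)
        sigma = CLASH_SCALE * (radii[ii] + radii[jj])
        e += CLASH_EPS * np.sum((sigma / d) ** 12, axis=1)
        qq = charges[ii] * charges[jj]
        live = qq != 0.0
        if live.any():
            e += np.sum(COULOMB_K * qq[live] / (dielectric * d[:, live]), axis=1)
    if torsion_angles_deg is not None and torsion_angles_deg.size:
        phi = np.deg2rad(torsion_angles_deg)
        e += np.sum(0.5 * TORSION_V3 * (1.0 + np.cos(3.0 * phi)), axis=1)
    return e


def toy_engine_generate(mol: MoleculeGraph, start: Conformer,
                        params: SearchParams,
                        charge_state: str = "charged") -> ConformerPool:
    """Deterministic torsion-grid engine honoring the step and save caps.

    Exhaustive 3-per-bond grid when 3^k fits the step budget; otherwise a
    seeded uniform sample of ``max_steps`` continuous torsion vectors
    (logged). The ``max_saved`` lowest-energy conformers are kept.
    """
    rb = rotatable_bonds(mol)
    eps = SOLVENT_DIELECTRIC[params.solvent]
    k = len(rb)
    if k == 0:
        e = toy_energy(mol, start.coords[None], None, eps)
        conf = start.copy(energy=float(e[0]), engine=params.engine,
                          solvent=params.solvent, charge_state=charge_state)
        return ConformerPool(mol, [conf], params, charge_state, exhaustive=True)
    exhaustive = 3 ** k <= params.max_steps
    if exhaustive:
        angles = np.array(list(itertools.product([60.0, 180.0, 300.0], repeat=k)))
    else:
        log.info("torsion grid 3^%d exceeds %d steps; seeded random sampling",
                 k, params.max_steps)
        rng = np.random.default_rng(params.seed)
        angles = rng.uniform(0.0, 360.0, size=(params.max_steps, k))
    coords = apply_torsions_batch(mol, start.coords, rb, angles)
    energies = toy_energy(mol, coords, angles, eps)
    order = np.argsort(energies, kind="stable")[:params.max_saved]
    members = [Conformer(coords[m], float(energies[m]), params.engine,
                         params.solvent, charge_state) for m in order]
    return ConformerPool(mol, members, params, charge_state,
                         exhaustive=exhaustive)


ENGINES: dict[str, Callable] = {"toy": toy_engine_generate}


# ---------------------------------------------------------------------------
# Protocol operations
# ---------------------------------------------------------------------------

def energy_window_filter(pool: ConformerPool, window: float) -> ConformerPool:
    """Keep conformers within ``window`` kcal/mol of the pool's global minimum."""
    if not len(pool):
        raise ProtocolError("cannot window-filter an empty pool")
    emin = pool.min_energy
    kept = [c for c in pool if c.energy - emin <= window + 1e-9]
    return pool.replaced(kept)


def debias_select(pool: ConformerPool, crystal: Conformer,
                  autos: Optional[AutomorphismSet] = None) -> Conformer:
    """The pool member most dissimilar (max symmetry-RMSD) to the crystal.

    Ties break toward lower energy, then pool order — the pool is already
    energy-sorted, so the first maximal member wins.
    """
    if not len(pool):
        raise ProtocolError("debias selection on an empty pool")
    vals = symmetry_rmsd_many(crystal.coords, pool.coords_array(), pool.mol,
                              autos=autos)
    best = float(vals.max())
    idx = int(np.nonzero(vals >= best - 1e-9)[0][0])
    return pool[idx]


def _shape_spectra(coords: np.ndarray) -> np.ndarray:
    """Singular values of each centered coordinate matrix, (M, 3).

    By Mirsky's inequality the best-fit RMSD between two conformers is at
    least ||sigma_a - sigma_b||_2 / sqrt(N) under any rotation *and* any
    atom permutation — a cheap, rigorous pruning bound for deduplication.
    """
    c = coords - coords.mean(axis=-2, keepdims=True)
    return np.linalg.svd(c, compute_uv=False)


DEDUP_ENERGY_NEIGHBORHOOD = 0.5  # kcal/mol


def _distance_profiles(coords: np.ndarray) -> np.ndarray:
    """Sorted pairwise-distance vector per conformer, (M, N(N-1)/2).

    For matched atoms, Σ_{i<j}(Δd_ij)² ≤ 2N²·RMSD², and sorting minimizes
    the sum over unknown matchings (rearrangement), so
    RMSD_sym ≥ ||Δ sorted profile||₂ / (N√2) — a permutation- and
    rotation-invariant lower bound sharper than the shape spectrum for
    conformer pools.
    """
    n = coords.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    return np.sort(np.linalg.norm(coords[:, iu] - coords[:, ju], axis=2), axis=1)


def dedup(pool: ConformerPool, tol: float,
          autos: Optional[AutomorphismSet] = None,
          energy_neighborhood: Optional[float] = None) -> ConformerPool:
    """Greedy energy-ordered deduplication at a symmetry-RMSD tolerance.

    With ``energy_neighborhood`` set (the standard double criterion for
    engine-generated pools, where energy is a function of geometry), a
    candidate is compared only against retained conformers within that many
    kcal/mol — congruent geometries have identical energies, so exact
    duplicates are always caught. By default every retained conformer is a
    comparison candidate. The shape-spectrum lower bound
    (see :func:`_shape_spectra`) prunes most pairs exactly either way.
    """
    if not len(pool):
        return pool
    if autos is None:
        autos = find_automorphisms(pool.mol)
    members = list(pool)
    coords = pool.coords_array()
    n = coords.shape[1]
    spectra = _shape_spectra(coords)
    profiles = _distance_profiles(coords)
    profile_cut = tol * n * np.sqrt(2.0)
    energies = np.array([np.nan if c.energy is None else c.energy
                         for c in members])
    kept_idx: list[int] = []
    for m in range(len(members)):
        dup = False
        if kept_idx:
            kept = np.asarray(kept_idx)
            if energy_neighborhood is None:
                near = np.ones(len(kept), dtype=bool)
            else:
                near = np.abs(energies[kept] - energies[m]) <= energy_neighborhood
                near |= np.isnan(energies[kept]) | np.isnan(energies[m])
            if tol <= 0:
                dup = any(np.allclose(coords[m], coords[k], atol=1e-12)
                          for k in kept[near])
            else:
                near &= (np.linalg.norm(spectra[kept] - spectra[m], axis=1)
                         / np.sqrt(n)) < tol
                near &= np.linalg.norm(profiles[kept] - profiles[m],
                                       axis=1) < profile_cut
                cand = kept[near]
                if len(cand):
                    vals = symmetry_rmsd_many(coords[m], coords[cand], pool.mol,
                                              autos=autos)
                    dup = bool(vals.min() < tol)
        if not dup:
            kept_idx.append(m)
    return pool.replaced([members[k] for k in kept_idx])


def two_step_search(mol: MoleculeGraph, crystal: Conformer,
                    engine: Callable | str, params: SearchParams,
                    charge_state: str = "charged",
                    autos: Optional[AutomorphismSet] = None) -> ConformerPool:
    """The full debiased protocol: wide search, debias, production search."""
    fn = ENGINES[engine] if isinstance(engine, str) else engine
    if autos is None:
        autos = find_automorphisms(mol)
    try:
        pool1 = fn(mol, crystal, params, charge_state=charge_state)
        pool1 = energy_window_filter(pool1, params.step1_window)
        debiased = debias_select(pool1, crystal, autos=autos)
    except ProtocolError:
        raise
    except Exception as e:
        raise ProtocolError(f"step 1 (debias search) failed: {e}") from e
    try:
        pool2 = fn(mol, debiased, params, charge_state=charge_state)
        pool2 = energy_window_filter(pool2, params.window)
        # exhaustive pools: sub-tolerance neighbors have exactly equal
        # energies (congruences and partial mirror moves), so a degenerate
        # neighborhood suffices; sampled pools get a finite one
        neighborhood = 1e-6 if pool2.exhaustive else DEDUP_ENERGY_NEIGHBORHOOD
        pool2 = dedup(pool2, params.dedup_tol, autos=autos,
                      energy_neighborhood=neighborhood)
    except ProtocolError:
        raise
    except Exception as e:
        raise ProtocolError(f"step 2 (production search) failed: {e}") from e
    return pool2


# ---------------------------------------------------------------------------
# Neutralization and combined pools
# ---------------------------------------------------------------------------

def neutralize(mol: MoleculeGraph) -> tuple[MoleculeGraph, list]:
    """Clear formal charges by proton bookkeeping; heavy-atom graph unchanged.

    Anionic O/S gain a hydrogen; protonated nitrogens lose one; quaternary
    nitrogens (nothing to remove) stay charged and are flagged.
    """
    atoms = []
    changes = []
    for i, a in enumerate(mol.atoms):
        if a.charge == -1 and a.element in ("O", "S"):
            atoms.append(Atom(a.element, 0, a.n_h + 1))
            changes.append((i, "protonated"))
        elif a.charge == 1 and a.element == "N" and a.n_h > 0:
            atoms.append(Atom(a.element, 0, a.n_h - 1))
            changes.append((i, "deprotonated"))
        elif a.charge != 0:
            atoms.append(a)
            changes.append((i, "non-neutralizable"))
        else:
            atoms.append(a)
    return mol.with_atoms(atoms), changes


def combine_pools(charged: ConformerPool, neutral: ConformerPool,
                  mapping: Optional[np.ndarray] = None) -> ConformerPool:
    """Union of charged- and neutral-input pools in the charged atom order.

    Per-member charge-state tags are preserved; energies are never ranked
    against each other across charge states — the union exists for best-RMSD
    queries only.
    """
    if mapping is None:
        mapping = map_heavy_atoms(charged.mol, neutral.mol)
    members = [c.copy(charge_state="charged") for c in charged]
    for c in neutral:
        members.append(Conformer(c.coords[mapping], c.energy, c.engine,
                                 c.solvent, "neutralized"))
    return ConformerPool(charged.mol, members, charged.params, "combined")


def best_rmsd(pool: ConformerPool, crystal: Conformer,
              autos: Optional[AutomorphismSet] = None) -> float:
    """Minimum symmetry-RMSD between any pool member and the crystal pose."""
    if not len(pool):
        raise ProtocolError("best_rmsd on an empty pool")
    vals = symmetry_rmsd_many(crystal.coords, pool.coords_array(), pool.mol,
                              autos=autos)
    return float(vals.min())


def global_min_rmsd(pool: ConformerPool, crystal: Conformer,
                    autos: Optional[AutomorphismSet] = None) -> float:
    """Symmetry-RMSD of the pool's lowest-energy conformer to the crystal."""
    if not len(pool):
        raise ProtocolError("global_min_rmsd on an empty pool")
    vals = symmetry_rmsd_many(crystal.coords, pool[0].coords[None], pool.mol,
                              autos=autos)
    return float(vals[0])
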