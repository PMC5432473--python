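"""3D geometry utilities: internal-coordinate placement and torsion driving.

Torsion driving is the workhorse of both the synthetic-pose generator and the
toy conformational-search engine, so the batched path (many torsion vectors
applied to one base geometry at once) is fully vectorized.
"""

from __future__ import annotations

import numpy as np

from .chem import MoleculeGraph


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom D from chain A-B-C.

    Returns coordinates such that |CD| = ``bond``, angle(B,C,D) = ``angle_deg``
    and dihedral(A,B,C,D) = ``dihedral_deg``.
    """
    theta = np.deg2rad(angle_deg)
    phi = np.deg2rad(dihedral_deg)
    d_local = bond * np.array([
        -np.cos(theta),
        np.sin(theta) * np.cos(phi),
        np.sin(theta) * np.sin(phi),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:  # collinear reference frame; pick any perpendicular
        ref = np.array([1.0, 0.0, 0.0]) if abs(bc[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        n = np.cross(ref, bc)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees for a single atom quadruple."""
    return float(dihedral_batch(np.asarray(p0)[None], np.asarray(p1)[None],
                                np.asarray(p2)[None], np.asarray(p3)[None])[0])


def dihedral_batch(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedrals in degrees; inputs are (..., 3) stacks."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    return np.degrees(np.arctan2(y, x))


def moving_side(mol: MoleculeGraph, i: int, j: int) -> np.ndarray:
    """Atom indices on the j-side of acyclic bond (i, j), excluding i's side."""
    seen = {i, j}
    stack = [j]
    out = [j]
    while stack:
        k = stack.pop()
        for nb in mol.neighbors(k):
            if nb not in seen:
                seen.add(nb)
                out.append(nb)
                stack.append(nb)
    if i in out:
        raise ValueError(f"bond ({i},{j}) lies in a ring; torsion undefined")
    return np.array(sorted(out), dtype=int)


def torsion_reference(mol: MoleculeGraph, i: int, j: int) -> tuple[int, int, int, int]:
    """Canonical (a, i, j, b) quadruple defining the torsion of bond (i, j).

    Reference neighbors are the lowest-index heavy neighbors on each side.
    """
    a = min(k for k in mol.neighbors(i) if k != j)
    b = min(k for k in mol.neighbors(j) if k != i)
    return a, i, j, b


def _rodrigues(axis: np.ndarray, angle_rad: np.ndarray) -> np.ndarray:
    """Batched rotation matrices about unit axes; shapes (M,3), (M,) -> (M,3,3)."""
    c = np.cos(angle_rad)
    s = np.sin(angle_rad)
    ux, uy, uz = axis[:, 0], axis[:, 1], axis[:, 2]
    K = np.zeros(axis.shape[:1] + (3, 3))
    K[:, 0, 1], K[:, 0, 2] = -uz, uy
    K[:, 1, 0], K[:, 1, 2] = uz, -ux
    K[:, 2, 0], K[:, 2, 1] = -uy, ux
    eye = np.eye(3)[None]
    outer = axis[:, :, None] * axis[:, None, :]
    return c[:, None, None] * eye + s[:, None, None] * K + (1 - c)[:, None, None] * outer


def set_torsions(mol: MoleculeGraph, coords: np.ndarray,
                 bonds: list[tuple[int, int]], angles_deg: np.ndarray) -> np.ndarray:
    """Set each listed torsion to an absolute angle; single conformer."""
    out = apply_torsions_batch(mol, coords, bonds,
                               np.asarray(angles_deg, float)[None, :])
    return out[0]


def apply_torsions_batch(mol: MoleculeGraph, base: np.ndarray,
                         bonds: list[tuple[int, int]],
                         angles_deg: np.ndarray) -> np.ndarray:
    """Apply (M, k) absolute torsion targets to one base geometry.

    Each bond is driven once; because a rotation about bond b is rigid on
    everything beyond b, previously set torsions are preserved and the final
    geometry realizes all k targets simultaneously.
    """
    angles_deg = np.asarray(angles_deg, dtype=float)
    M = angles_deg.shape[0]
    coords = np.broadcast_to(base, (M,) + base.shape).copy()
    refs = [torsion_reference(mol, i, j) for i, j in bonds]
    movers = [moving_side(mol, i, j) for i, j in bonds]
    for (i, j), (a, _, _, b), mov, target in zip(
            bonds, refs, movers, angles_deg.T):
        cur = dihedral_batch(coords[:, a], coords[:, i], coords[:, j], coords[:, b])
        delta = np.deg2rad(target - cur)
        axis = coords[:, j] - coords[:, i]
        axis /= np.linalg.norm(axis, axis=1, keepdims=True)
        R = _rodrigues(axis, delta)
        pivot = coords[:, i][:, None, :]
        rel = coords[:, mov, :] - pivot
        coords[:, mov, :] = np.einsum("mab,mnb->mna", R, rel) + pivot
    return coords


def min_nonbonded_distance(mol: MoleculeGraph, coords: np.ndarray,
                           min_separation: int = 4) -> float:
    """Smallest heavy-atom distance among pairs ≥ ``min_separation`` bonds apart."""
    d = mol.graph_distances()
    ii, jj = np.where(np.triu(d >= min_separation))
    if len(ii) == 0:
        return np.inf
    dist = np.linalg.norm(coords[ii] - coords[jj], axis=1)
    return float(dist.min())
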