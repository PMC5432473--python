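"""Two-step search protocol: engine, windows, dedup, neutralization, pools."""

import numpy as np
import pytest

from bioconfbench import conformer_protocol as cp
from bioconfbench import descriptors as d
from bioconfbench import synthetic_data as sd
from bioconfbench.chem import Conformer, ConformerPool
from bioconfbench.symrmsd import map_heavy_atoms, symmetry_rmsd


@pytest.fixture(scope="module")
def flexible():
    mol, conf = sd.make_linear_ligand(3, seed=4)
    return mol, conf


@pytest.fixture(scope="module")
def zwitterion():
    mol0, conf0 = sd.make_linear_ligand(6, seed=1, fragments=["CH2"] * 7)
    mol, conf = sd.make_charged_variant(mol0, 2, seed=0, conformer=conf0)
    return mol, sd.extended_pose(mol, conf)


def _pool(mol, energies, coords=None):
    rng = np.random.default_rng(0)
    members = [Conformer(rng.normal(size=(mol.n_atoms, 3)) if coords is None
                         else coords[k], e) for k, e in enumerate(energies)]
    return ConformerPool(mol, members)


# ---------------------------------------------------------------------------
# Toy engine
# ---------------------------------------------------------------------------

def test_rigid_molecule_yields_single_conformer():
    mol, conf = sd.make_linear_ligand(0, seed=2)
    pool = cp.toy_engine_generate(mol, conf, cp.SearchParams())
    assert len(pool) == 1
    assert np.allclose(pool[0].coords, conf.coords)


def test_two_rotb_grid_at_most_nine(flexible):
    mol, conf = sd.make_linear_ligand(2, seed=9)
    pool = cp.toy_engine_generate(mol, conf, cp.SearchParams())
    assert len(pool) <= 9


def test_engine_deterministic_and_capped():
    mol, conf = sd.make_linear_ligand(8, seed=3)  # 3^8 > 5000 -> sampling
    params = cp.SearchParams(seed=5, max_saved=50)
    a = cp.toy_engine_generate(mol, conf, params)
    b = cp.toy_engine_generate(mol, conf, params)
    assert len(a) == 50
    assert all(np.array_equal(x.coords, y.coords) for x, y in zip(a, b))


def test_salt_bridge_ranks_better_at_low_dielectric(zwitterion):
    """The closed (bridged) torsion vector wins at eps=4.81, not at 78.4."""
    mol, crystal = zwitterion
    import itertools
    from bioconfbench.geometry import apply_torsions_batch
    rb = d.rotatable_bonds(mol)
    angles = np.array(list(itertools.product([60.0, 180.0, 300.0], repeat=len(rb))))
    coords = apply_torsions_batch(mol, crystal.coords, rb, angles)
    charged_idx = [i for i, a in enumerate(mol.atoms) if a.charge != 0]
    sep = np.linalg.norm(coords[:, charged_idx[0]] - coords[:, charged_idx[1]], axis=1)
    e_water = cp.toy_energy(mol, coords, angles, 78.4)
    e_chloro = cp.toy_energy(mol, coords, angles, 4.81)
    closed = sep < 5.0
    gap_water = e_water[closed].min() - e_water[~closed].min()
    gap_chloro = e_chloro[closed].min() - e_chloro[~closed].min()
    assert gap_chloro < gap_water < 0  # closed wins in both, far more at low eps


# ---------------------------------------------------------------------------
# Window filter
# ---------------------------------------------------------------------------

def test_energy_window_examples(flexible):
    mol, _ = flexible
    pool = _pool(mol, [0.0, 3.0, 6.0])
    assert len(cp.energy_window_filter(pool, 5.0)) == 2
    assert len(cp.energy_window_filter(pool, 50.0)) == 3
    zero = cp.energy_window_filter(pool, 1e-12)
    assert len(zero) == 1 and zero[0].energy == 0.0


def test_window_monotonicity_property(flexible):
    mol, crystal = flexible
    pool = cp.toy_engine_generate(mol, crystal, cp.SearchParams())
    small = cp.energy_window_filter(pool, 2.0)
    large = cp.energy_window_filter(pool, 8.0)
    ids_small = {id(c) for c in small}
    assert ids_small <= {id(c) for c in large}
    assert cp.best_rmsd(small, crystal) >= cp.best_rmsd(large, crystal) - 1e-12


# ---------------------------------------------------------------------------
# Debias selection
# ---------------------------------------------------------------------------

def test_debias_picks_most_dissimilar(flexible):
    mol, crystal = flexible
    pool = cp.toy_engine_generate(mol, crystal, cp.SearchParams())
    chosen = cp.debias_select(pool, crystal)
    worst = max(symmetry_rmsd(crystal, c, mol) for c in pool)
    assert symmetry_rmsd(crystal, chosen, mol) == pytest.approx(worst, abs=1e-9)


def test_debias_single_member_and_ties(flexible):
    mol, crystal = flexible
    single = _pool(mol, [1.0], coords=[crystal.coords])
    assert cp.debias_select(single, crystal) is single[0]
    same = _pool(mol, [2.0, 1.0, 3.0], coords=[crystal.coords] * 3)
    assert cp.debias_select(same, crystal).energy == 1.0  # lowest energy wins tie
    with pytest.raises(cp.ProtocolError):
        cp.debias_select(ConformerPool(mol, []), crystal)


# ---------------------------------------------------------------------------
# Dedup
# ---------------------------------------------------------------------------

def test_dedup_removes_exact_duplicate(flexible):
    mol, crystal = flexible
    pool = _pool(mol, [0.0, 1.0], coords=[crystal.coords, crystal.coords])
    out = cp.dedup(pool, 0.25)
    assert len(out) == 1 and out[0].energy == 0.0


def test_dedup_tol_zero_keeps_distinct(flexible):
    mol, crystal = flexible
    rng = np.random.default_rng(1)
    pool = _pool(mol, [0.0, 1.0, 2.0])
    out = cp.dedup(pool, 0.0)
    assert len(out) == 3
    dup = ConformerPool(mol, [pool[0], pool[0].copy(energy=5.0)])
    assert len(cp.dedup(dup, 0.0)) == 1


def test_dedup_idempotent(flexible):
    mol, crystal = flexible
    pool = cp.toy_engine_generate(mol, crystal, cp.SearchParams())
    once = cp.dedup(pool, 0.25)
    twice = cp.dedup(once, 0.25)
    assert len(once) == len(twice)
    assert all(np.array_equal(a.coords, b.coords) for a, b in zip(once, twice))


# ---------------------------------------------------------------------------
# Two-step search
# ---------------------------------------------------------------------------

def test_rigid_two_step_recovers_crystal():
    mol, crystal = sd.make_linear_ligand(0, seed=2)
    pool = cp.two_step_search(mol, crystal, "toy", cp.SearchParams())
    assert len(pool) == 1
    assert cp.best_rmsd(pool, crystal) == pytest.approx(0.0, abs=1e-9)


def test_two_step_deterministic(flexible):
    mol, crystal = flexible
    params = cp.SearchParams(seed=11)
    a = cp.two_step_search(mol, crystal, "toy", params)
    b = cp.two_step_search(mol, crystal, "toy", params)
    assert len(a) == len(b)
    assert all(np.array_equal(x.coords, y.coords) for x, y in zip(a, b))


def test_engine_failure_carries_stage_label(flexible):
    mol, crystal = flexible

    def broken(mol, start, params, charge_state="charged"):
        raise RuntimeError("boom")

    with pytest.raises(cp.ProtocolError, match="step 1"):
        cp.two_step_search(mol, crystal, broken, cp.SearchParams())


# ---------------------------------------------------------------------------
# Neutralization
# ---------------------------------------------------------------------------

def test_neutralize_acetate(acetate):
    out, changes = cp.neutralize(acetate)
    assert out.total_charge() == 0
    assert out.atoms[3].n_h == 1  # gained the acid proton
    assert ("protonated" in dict((i, c) for i, c in changes).values())


def test_neutralize_zwitterion(glycine_zwitterion):
    out, changes = cp.neutralize(glycine_zwitterion)
    assert out.total_charge() == 0
    assert out.atoms[0].n_h == 2  # ammonium lost a proton
    assert len(changes) == 2


def test_quaternary_nitrogen_flagged(tetramethylammonium):
    out, changes = cp.neutralize(tetramethylammonium)
    assert out.total_charge() == 1
    assert changes == [(0, "non-neutralizable")]


def test_neutralize_preserves_heavy_atom_graph(zwitterion):
    mol, _ = zwitterion
    out, _ = cp.neutralize(mol)
    m = map_heavy_atoms(mol, out)
    assert np.array_equal(m, np.arange(mol.n_atoms))


# ---------------------------------------------------------------------------
# Combined pools and best-RMSD queries
# ---------------------------------------------------------------------------

def test_combined_best_is_min_of_sources(zwitterion):
    mol, crystal = zwitterion
    params = cp.SearchParams(seed=2)
    charged = cp.two_step_search(mol, crystal, "toy", params)
    mol_n, _ = cp.neutralize(mol)
    neutral = cp.two_step_search(mol_n, Conformer(crystal.coords), "toy",
                                 params, charge_state="neutralized")
    combined = cp.combine_pools(charged, neutral)
    bc = cp.best_rmsd(charged, crystal)
    bn = cp.best_rmsd(neutral, Conformer(crystal.coords))
    assert cp.best_rmsd(combined, crystal) == pytest.approx(min(bc, bn), abs=1e-9)


def test_empty_neutral_pool_is_identity(flexible):
    mol, crystal = flexible
    charged = cp.toy_engine_generate(mol, crystal, cp.SearchParams())
    empty = ConformerPool(mol, [], charge_state="neutralized")
    combined = cp.combine_pools(charged, empty)
    assert len(combined) == len(charged)
    assert cp.best_rmsd(combined, crystal) == pytest.approx(
        cp.best_rmsd(charged, crystal), abs=1e-12)


def test_best_and_global_min_queries(flexible):
    mol, crystal = flexible
    pool = _pool(mol, [0.0, 1.0], coords=[crystal.coords, crystal.coords + 3.0])
    assert cp.best_rmsd(pool, crystal) == pytest.approx(0.0, abs=1e-9)
    assert cp.global_min_rmsd(pool, crystal) >= cp.best_rmsd(pool, crystal)
    with pytest.raises(cp.ProtocolError):
        cp.best_rmsd(ConformerPool(mol, []), crystal)


def test_pool_invariants(flexible):
    mol, crystal = flexible
    pool = cp.toy_engine_generate(mol, crystal, cp.SearchParams(max_saved=5))
    e = pool.energies()
    assert len(pool) <= 5
    assert np.all(np.diff(e) >= 0)
    assert np.all(e >= pool.min_energy)
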