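"""Curation filters: parsing, altlocs, contacts, symmetry mates, occurrence."""

import numpy as np
import pytest

from bioconfbench import curation as cur
from bioconfbench import synthetic_data as sd
from bioconfbench.chem import Conformer
from bioconfbench.descriptors import DescriptorSet
from conftest import mk


@pytest.fixture
def simple_complex():
    mol, conf = sd.make_linear_ligand(2, seed=3)
    return mol, conf


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def test_parse_counts_ligand_and_waters(simple_complex):
    mol, conf = simple_complex
    text = sd.make_complex_file(mol, conf, waters=[(0, 3.0), (1, 3.5), (2, 4.0)])
    cm = cur.parse_pdb_complex(text)[0]
    assert len(cm.ligand_atoms) == mol.n_atoms
    assert cm.waters.shape == (3, 3)


def test_missing_remark290_defaults_to_identity(simple_complex, caplog):
    mol, conf = simple_complex
    text = sd.make_complex_file(mol, conf, include_remark290=False)
    with caplog.at_level("WARNING"):
        cm = cur.parse_pdb_complex(text)[0]
    assert len(cm.operators) == 1
    R, t = cm.operators[0]
    assert np.allclose(R, np.eye(3)) and np.allclose(t, 0)
    assert any("identity" in r.message for r in caplog.records)


def test_model_blocks_yield_one_complex_each(simple_complex):
    mol, conf = simple_complex
    other = Conformer(conf.coords + 0.5)
    text = sd.make_complex_file(mol, conf, models=[conf, other])
    models = cur.parse_pdb_complex(text)
    assert len(models) == 2


def test_ph_read_from_header(simple_complex):
    mol, conf = simple_complex
    cm = cur.parse_pdb_complex(sd.make_complex_file(mol, conf, ph=6.5))[0]
    assert cm.ph == pytest.approx(6.5)
    cm = cur.parse_pdb_complex(sd.make_complex_file(mol, conf))[0]
    assert cm.ph is None


def test_unparseable_text_raises():
    with pytest.raises(ValueError):
        cur.parse_pdb_complex("ATOM  garbage\nEND\n")


# ---------------------------------------------------------------------------
# Altloc selection
# ---------------------------------------------------------------------------

def _alt_atom(alt, occ, x):
    return cur.LigandAtom("C1", "C", alt, occ, np.array([x, 0.0, 0.0]))


def test_highest_occupancy_wins():
    conf = cur.select_altloc([_alt_atom("A", 0.6, 0.0), _alt_atom("B", 0.4, 5.0)])
    assert conf.coords[0, 0] == 0.0


def test_tie_breaks_to_first_in_file():
    conf = cur.select_altloc([_alt_atom("A", 0.5, 0.0), _alt_atom("B", 0.5, 5.0)])
    assert conf.coords[0, 0] == 0.0
    conf = cur.select_altloc([_alt_atom("B", 0.5, 5.0), _alt_atom("A", 0.5, 0.0)])
    assert conf.coords[0, 0] == 5.0  # B listed first


def test_single_conformation_unchanged():
    atoms = [_alt_atom("", 1.0, 0.0), _alt_atom("", 1.0, 1.0)]
    assert cur.select_altloc(atoms).n_atoms == 2


def test_inconsistent_altloc_counts_raise():
    atoms = [_alt_atom("A", 0.5, 0.0), _alt_atom("A", 0.5, 1.0),
             _alt_atom("B", 0.5, 0.0)]
    with pytest.raises(ValueError):
        cur.select_altloc(atoms)


# ---------------------------------------------------------------------------
# Element whitelist
# ---------------------------------------------------------------------------

def test_selenium_rejected():
    mol = mk([("C", 0, 3), ("Se", 0, 1)], [(0, 1, 1)])
    assert not cur.element_whitelist_check(mol)


def test_biogenic_accepted(simple_complex):
    assert cur.element_whitelist_check(simple_complex[0])


def test_empty_whitelist_rejects_everything(simple_complex):
    assert not cur.element_whitelist_check(simple_complex[0], frozenset())


# ---------------------------------------------------------------------------
# Water contact filter
# ---------------------------------------------------------------------------

def test_water_contact_cutoff_formula():
    """Bondi C/O: cutoff 0.891 x (1.70+1.52) = 2.869 Å around carbon."""
    mol = mk([("C", 0, 4)], [])
    conf = Conformer(np.zeros((1, 3)))
    inside = np.array([[2.80, 0.0, 0.0]])
    outside = np.array([[2.90, 0.0, 0.0]])
    keep, offenders = cur.water_contact_filter(mol, conf, inside)
    assert not keep
    assert offenders[0][3] == pytest.approx(0.891 * 3.22, abs=1e-9)
    keep, _ = cur.water_contact_filter(mol, conf, outside)
    assert keep
    keep, _ = cur.water_contact_filter(mol, conf, np.empty((0, 3)))
    assert keep


def test_water_filter_noncarbon_factor():
    mol = mk([("N", 0, 3)], [])
    conf = Conformer(np.zeros((1, 3)))
    cutoff = 0.8 * (1.52 + 1.55)
    keep, _ = cur.water_contact_filter(mol, conf, np.array([[cutoff - 0.01, 0, 0]]))
    assert not keep
    keep, _ = cur.water_contact_filter(mol, conf, np.array([[cutoff + 0.01, 0, 0]]))
    assert keep


def test_water_filter_monotone_in_factor():
    """If discarded at factor f, discarded at any larger factor."""
    mol = mk([("C", 0, 4)], [])
    conf = Conformer(np.zeros((1, 3)))
    water = np.array([[2.6, 0.0, 0.0]])
    discarded_at = []
    for f in (0.75, 0.80, 0.85, 0.891, 0.95):
        params = cur.WaterContactParams(f_carbon=f, f_other=f)
        keep, _ = cur.water_contact_filter(mol, conf, water, params)
        discarded_at.append(not keep)
    assert discarded_at == sorted(discarded_at)


def test_missing_radius_is_a_config_error():
    mol = mk([("Se", 0, 0)], [])
    conf = Conformer(np.zeros((1, 3)))
    params = cur.WaterContactParams(radii={"O": 1.52})
    with pytest.raises(KeyError, match="Se"):
        cur.water_contact_filter(mol, conf, np.array([[3.0, 0, 0]]), params)


# ---------------------------------------------------------------------------
# Symmetry mates and packing
# ---------------------------------------------------------------------------

def _cm(coords, cell, ops):
    atoms = [cur.LigandAtom(f"C{i}", "C", "", 1.0, c) for i, c in enumerate(coords)]
    return cur.ComplexModel(atoms, np.empty((0, 3)), cell, ops, np.empty((0, 3)))


def test_identity_only_no_lattice_is_empty():
    cm = _cm(np.zeros((2, 3)), (10, 10, 10, 90, 90, 90),
             [(np.eye(3), np.zeros(3))])
    mates = cur.expand_symmetry_mates(cm, include_lattice=False)
    assert mates.shape == (0, 3)


def test_p1_translation_closed_form():
    coords = np.array([[1.0, 1.0, 1.0], [2.0, 1.0, 1.0]])
    cm = _cm(coords, (10, 10, 10, 90, 90, 90), [(np.eye(3), np.zeros(3))])
    mates = cur.expand_symmetry_mates(cm)
    assert len(mates) == 26 * 2
    shifted = coords + np.array([10.0, 0.0, 0.0])
    assert any(np.allclose(mates[k:k + 2], shifted, atol=1e-9)
               for k in range(0, len(mates), 2))


def test_symmetry_expansion_is_isometric():
    """Operator images preserve all intra-molecular distances."""
    rng = np.random.default_rng(0)
    coords = rng.uniform(2, 8, size=(5, 3))
    d0 = np.linalg.norm(coords[:, None] - coords[None], axis=2)
    # twofold rotation about z plus a half-cell translation (P21-like)
    R = np.diag([-1.0, -1.0, 1.0])
    ops = [(np.eye(3), np.zeros(3)), (R, np.array([0.0, 0.0, 0.5]))]
    cm = _cm(coords, (17.0, 23.0, 31.0, 90, 90, 90), ops)
    mates = cur.expand_symmetry_mates(cm)
    assert len(mates) % 5 == 0
    for k in range(0, len(mates), 5):
        dm = np.linalg.norm(mates[k:k + 5, None] - mates[None, k:k + 5], axis=2)
        assert np.allclose(dm, d0, atol=1e-6)


def test_packing_filter_cutoff():
    conf = Conformer(np.zeros((1, 3)))
    assert not cur.packing_contact_filter(conf, np.array([[4.9, 0, 0]]))
    assert cur.packing_contact_filter(conf, np.array([[5.1, 0, 0]]))
    assert cur.packing_contact_filter(conf, np.empty((0, 3)))


def test_singular_cell_raises():
    cm = _cm(np.zeros((1, 3)), (0.0, 10, 10, 90, 90, 90),
             [(np.eye(3), np.zeros(3))])
    with pytest.raises(ValueError):
        cur.expand_symmetry_mates(cm)


# ---------------------------------------------------------------------------
# Occurrence analysis
# ---------------------------------------------------------------------------

def test_printed_statistics_worked_example():
    stats = cur.OccurrenceStats.from_values(1.80, 1.33)
    assert stats.raw_threshold == pytest.approx(3.13, abs=1e-12)
    assert stats.threshold == 4


def test_all_single_occurrences_keep_everything():
    counts = {f"L{i}": 1 for i in range(5)}
    stats, kept = cur.occurrence_analysis(counts)
    assert sorted(kept) == sorted(counts)


def test_deviation_statistic_against_direct_arithmetic():
    """Brute-force mean/SD oracle on {2, 2, 8} for both SD conventions."""
    counts = {"A": 2, "B": 2, "C": 8}
    vals = np.array([2.0, 2.0, 8.0])
    # population SD: ceil(4 + 2.828) = 7 -> the heavy hitter (8 > 7) goes
    stats, kept = cur.occurrence_analysis(counts, deviation="population")
    assert stats.mean == pytest.approx(vals.mean())
    assert stats.deviation == pytest.approx(vals.std(ddof=0))
    assert stats.threshold == int(np.ceil(vals.mean() + vals.std(ddof=0))) == 7
    assert kept == ["A", "B"]
    # sample SD: ceil(4 + 3.464) = 8 -> the count of 8 sits on the boundary
    stats, kept = cur.occurrence_analysis(counts, deviation="sample")
    assert stats.threshold == 8
    assert kept == ["A", "B", "C"]


def test_single_distinct_count_never_excludes():
    for v in (1, 3, 7):
        counts = {f"L{i}": v for i in range(4)}
        for mode in ("sample", "population", 1.33):
            _, kept = cur.occurrence_analysis(counts, deviation=mode)
            assert len(kept) == 4


def test_empty_counts_raise():
    with pytest.raises(ValueError):
        cur.occurrence_analysis({})


# ---------------------------------------------------------------------------
# Drug-likeness window and filter independence
# ---------------------------------------------------------------------------

def _ds(**kw):
    base = dict(rotb=5, mw=313.0, ha=22, psa=80.0, logp=1.5,
                charged_groups=0, total_charge=0)
    base.update(kw)
    return DescriptorSet(**base)


def test_druglikeness_examples():
    keep, failed = cur.druglikeness_filter(_ds(mw=700.0))
    assert not keep and failed == ["MW"]
    keep, failed = cur.druglikeness_filter(_ds(rotb=16))
    assert not keep and "RotB" in failed
    keep, failed = cur.druglikeness_filter(_ds())
    assert keep and failed == []
    keep, failed = cur.druglikeness_filter(_ds(total_charge=-4))
    assert not keep and "charge" in failed


def test_filter_predicates_are_order_independent():
    """The kept set is the AND of independent predicates; order cannot matter."""
    mol, conf = sd.make_linear_ligand(2, seed=3)
    text = sd.make_complex_file(mol, conf, waters=[(0, 2.5)])
    cm = cur.parse_pdb_complex(text)[0]
    verdict = cur.curate_complex(mol, cm)
    flags = [verdict[k] for k in
             ("element_ok", "water_ok", "packing_ok", "not_covalent")]
    rng = np.random.default_rng(0)
    for _ in range(5):
        order = rng.permutation(len(flags))
        assert all(np.array(flags)[order]) == all(flags)
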