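"""Report layer: tables, stratified fractions, regression, NMR stats, pipeline."""

import numpy as np
import pandas as pd
import pytest

from bioconfbench import evaluation_report as er
from bioconfbench import synthetic_data as sd
from bioconfbench.chem import Conformer, ConformerPool
from bioconfbench.descriptors import DescriptorSet, StrataConfig, compute_descriptors


def _record(ligand_id, rotb, best, mol=None, crystal=None):
    rec = er.LigandRecord(ligand_id, mol, crystal,
                          DescriptorSet(rotb=rotb, mw=300.0, ha=20, psa=80.0,
                                        logp=1.0, charged_groups=0, total_charge=0))
    cond = er.Condition()
    rec.best[cond] = best
    return rec


COND = er.Condition()


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def test_best_rmsd_table_delegates_and_reports_missing(caplog):
    recs = [_record("a", 2, 0.4), _record("b", 5, 0.9), _record("c", 8, 1.5)]
    t = er.best_rmsd_table(recs, COND)
    assert list(t["best_rmsd"]) == [0.4, 0.9, 1.5]
    recs.append(er.LigandRecord("d", None, None, None))
    with caplog.at_level("WARNING"):
        t = er.best_rmsd_table(recs, COND)
    assert t["best_rmsd"].isna().sum() == 1
    with pytest.raises(er.ReportError):
        er.best_rmsd_table([er.LigandRecord("e", None, None, None)], COND)


def test_empty_record_list_warns(caplog):
    with caplog.at_level("WARNING"):
        t = er.best_rmsd_table([], COND)
    assert t.empty


# ---------------------------------------------------------------------------
# Stratified fractions
# ---------------------------------------------------------------------------

def test_fraction_arithmetic_single_bin():
    recs = [_record(k, 2, v) for k, v in
            zip("abc", (0.4, 0.8, 1.5))]
    t = er.best_rmsd_table(recs, COND)
    rep = er.stratified_fractions(t, recs, StrataConfig(), "rotb")
    row = rep.table.set_index("bin").loc["low"]
    assert row["n"] == 3
    assert row["frac_below_0.5"] == pytest.approx(100 / 3)
    assert row["frac_below_1"] == pytest.approx(200 / 3)


def test_all_below_half_gives_hundred():
    recs = [_record(k, 1, 0.2) for k in "abcd"]
    t = er.best_rmsd_table(recs, COND)
    rep = er.stratified_fractions(t, recs, StrataConfig(), "rotb")
    row = rep.table.set_index("bin").loc["low"]
    assert row["frac_below_0.5"] == 100.0 and row["frac_below_1"] == 100.0


def test_fractions_match_brute_force_recount():
    rng = np.random.default_rng(3)
    recs = [_record(f"L{k}", int(rng.integers(0, 16)), float(rng.uniform(0, 2)))
            for k in range(60)]
    t = er.best_rmsd_table(recs, COND)
    cfg = StrataConfig()
    rep = er.stratified_fractions(t, recs, cfg, "rotb")
    for lo, hi, label in cfg.rotb_bins:
        members = [r for r in recs if lo <= r.descriptors.rotb <= hi]
        row = rep.table.set_index("bin").loc[label]
        assert row["n"] == len(members)
        if members:
            expect = 100.0 * np.mean([r.best[COND] < 0.5 for r in members])
            assert row["frac_below_0.5"] == pytest.approx(expect)


def test_fraction_monotone_in_threshold():
    rng = np.random.default_rng(4)
    recs = [_record(f"L{k}", int(rng.integers(0, 16)), float(rng.uniform(0, 2)))
            for k in range(40)]
    t = er.best_rmsd_table(recs, COND)
    rep = er.stratified_fractions(t, recs, StrataConfig(), "rotb")
    sub = rep.table.dropna()
    assert (sub["frac_below_0.5"] <= sub["frac_below_1"] + 1e-12).all()


# ---------------------------------------------------------------------------
# Scalar summaries and regression
# ---------------------------------------------------------------------------

def test_average_best_rmsd():
    recs = [_record("a", 1, 0.5), _record("b", 2, 1.5)]
    assert er.average_best_rmsd(er.best_rmsd_table(recs, COND)) == 1.0
    assert er.average_best_rmsd(er.best_rmsd_table(recs[:1], COND)) == 0.5
    with pytest.raises(er.ReportError):
        er.average_best_rmsd(pd.DataFrame({"best_rmsd": []}))


def test_regression_exact_line_and_constant():
    recs = [_record(f"L{k}", k, 0.13 * k) for k in range(8)]
    fit = er.rotb_regression(er.best_rmsd_table(recs, COND), recs)
    assert fit.slope == pytest.approx(0.13, abs=1e-12)
    assert fit.r2 == pytest.approx(1.0, abs=1e-12)
    recs = [_record(f"L{k}", k, 0.7) for k in range(8)]
    fit = er.rotb_regression(er.best_rmsd_table(recs, COND), recs)
    assert fit.slope == pytest.approx(0.0, abs=1e-12)
    assert fit.r2 == pytest.approx(0.0, abs=1e-12)


def test_regression_matches_textbook_ols():
    rng = np.random.default_rng(5)
    x = rng.integers(0, 16, size=50)
    y = 0.1 * x + rng.normal(0, 0.2, size=50)
    recs = [_record(f"L{k}", int(xi), float(yi)) for k, (xi, yi) in
            enumerate(zip(x, y))]
    fit = er.rotb_regression(er.best_rmsd_table(recs, COND), recs)
    xm, ym = x.mean(), y.mean()
    slope = np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2)
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    se = np.sqrt(np.sum(resid ** 2) / (len(x) - 2) / np.sum((x - xm) ** 2))
    r2 = np.corrcoef(x, y)[0, 1] ** 2
    assert fit.slope == pytest.approx(slope, abs=1e-10)
    assert fit.intercept == pytest.approx(intercept, abs=1e-10)
    assert fit.slope_se == pytest.approx(se, abs=1e-10)
    assert fit.r2 == pytest.approx(r2, abs=1e-10)
    with pytest.raises(er.ReportError):
        er.rotb_regression(er.best_rmsd_table(recs[:2], COND), recs[:2])


# ---------------------------------------------------------------------------
# Global-minimum proximity and solvent scatter
# ---------------------------------------------------------------------------

def test_global_min_fraction_recount():
    recs = []
    vals = [0.2, 0.9, 1.4, 2.0]
    for k, v in enumerate(vals):
        r = _record(f"L{k}", 3, v)
        r.global_min[COND] = v
        recs.append(r)
    assert er.global_min_fraction(recs, COND, 1.0) == pytest.approx(50.0)
    assert er.global_min_fraction(recs, COND, 0.1) == 0.0
    assert er.global_min_fraction(recs, COND, 5.0) == 100.0


def test_solvent_scatter_counts():
    a = pd.DataFrame({"ligand_id": list("abc"), "best_rmsd": [0.5, 0.7, 0.9]})
    ties = er.solvent_scatter(a, a.copy())
    assert ties["ties"] == 3 and ties["better_in_a"] == 0
    b = a.copy()
    b["best_rmsd"] += 0.1
    out = er.solvent_scatter(a, b)
    assert out["better_in_a"] == 3 and out["better_in_b"] == 0
    mixed = a.copy()
    mixed["best_rmsd"] = [0.4, 0.7, 1.2]
    out = er.solvent_scatter(a, mixed)
    assert (out["better_in_a"], out["better_in_b"], out["ties"]) == (1, 1, 1)
    with pytest.raises(er.ReportError):
        er.solvent_scatter(a, b.assign(ligand_id=list("abd")))


# ---------------------------------------------------------------------------
# NMR statistics
# ---------------------------------------------------------------------------

def test_inter_model_mean_equals_pair_enumeration():
    from bioconfbench.symrmsd import symmetry_rmsd
    mol, conf = sd.make_linear_ligand(3, seed=8)
    models = sd.make_nmr_ensemble(mol, conf, 5, 15.0, seed=4)
    direct = []
    for i in range(5):
        for j in range(i + 1, 5):
            direct.append(symmetry_rmsd(models[i], models[j], mol))
    assert er.nmr_inter_model_mean(models, mol) == pytest.approx(
        np.mean(direct), abs=1e-9)
    with pytest.raises(er.ReportError):
        er.nmr_inter_model_mean(models[:1], mol)


def test_ensemble_correlation_edge_cases():
    stats = [er.EnsembleStats(f"e{k}", 0.1 * k, 10, k) for k in range(5)]
    out = er.ensemble_correlations(stats)
    assert out["r_rotb"] == pytest.approx(1.0)
    assert not out["r_n_models_defined"]  # constant model count
    flat = [er.EnsembleStats(f"e{k}", 0.5, 10 + k, k) for k in range(5)]
    out = er.ensemble_correlations(flat)
    assert not out["r_rotb_defined"]
    with pytest.raises(er.ReportError):
        er.ensemble_correlations(stats[:2])


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("pipe")
    cfg = er.PipelineConfig(n_ligands=10, seed=2, out_dir=str(out))
    return er.run_pipeline(cfg), out, cfg


def test_pipeline_outputs_complete(small_bundle):
    bundle, out, _ = small_bundle
    for name in ("ligand_table.csv", "strata_rotb.csv",
                 "strata_charge_solvent.csv", "regression.csv",
                 "nmr_stats.csv", "run_log.json", "curation_report.csv"):
        assert (out / name).exists()
    assert len(bundle["records"]) >= 1


def test_pipeline_reports_are_recomputable(small_bundle):
    """Every report number re-derives from the persisted per-ligand table."""
    bundle, _, _ = small_bundle
    lt = bundle["ligand_table"]
    cond = er.Condition("toy", "water", "charged", 5.0)
    col = f"best_{cond}"
    t2 = bundle["strata_charge_solvent"]
    row = t2[(t2.solvent == "water") & (t2.charge_state == "charged")].iloc[0]
    assert row["frac_below_1"] == pytest.approx(
        100.0 * (lt[col] < 1.0).mean())


def test_pipeline_combined_dominates_sources(small_bundle):
    bundle, _, _ = small_bundle
    t2 = bundle["strata_charge_solvent"].set_index("charge_state")
    for th in ("frac_below_0.5", "frac_below_1"):
        assert t2.loc["combined", th] >= max(t2.loc["charged", th],
                                             t2.loc["neutralized", th]) - 1e-9


def test_pipeline_byte_identical_under_seed(small_bundle, tmp_path):
    _, out, cfg = small_bundle
    cfg2 = er.PipelineConfig(n_ligands=10, seed=2, out_dir=str(tmp_path))
    er.run_pipeline(cfg2)
    for name in ("ligand_table.csv", "strata_rotb.csv", "nmr_stats.csv"):
        assert (out / name).read_bytes() == (tmp_path / name).read_bytes()


def test_pipeline_zero_survivors_is_explicit_error():
    cfg = er.PipelineConfig(n_ligands=3, seed=2, frac_close_water=1.0)
    with pytest.raises(er.ReportError):
        er.run_pipeline(cfg)
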