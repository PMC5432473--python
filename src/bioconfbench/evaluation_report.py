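"""Per-ligand best-RMSD tables, stratified fraction reports, regression and
NMR-ensemble statistics, plus the end-to-end pipeline orchestrator.

Report conventions: percentages use strict ``<`` thresholds (0.5 / 1.0 Å),
Pearson correlations throughout (r² is squared Pearson), percentages printed
to one decimal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .chem import Conformer, ConformerPool, MoleculeGraph
from .curation import (DruglikenessWindow, curate_complex,
                       druglikeness_filter, occurrence_analysis,
                       parse_pdb_complex)
from .conformer_protocol import (SearchParams, best_rmsd, combine_pools,
                                 global_min_rmsd, neutralize, two_step_search)
from .descriptors import (DescriptorSet, StrataConfig, assign_strata,
                          compute_descriptors)
from .symrmsd import find_automorphisms, symmetry_rmsd, symmetry_rmsd_many
from . import synthetic_data as synth

log = logging.getLogger(__name__)


class ReportError(RuntimeError):
    pass


@dataclass(frozen=True)
class Condition:
    """One search condition: engine × solvent × charge state × energy window."""
    engine: str = "toy"
    solvent: str = "water"
    charge_state: str = "charged"
    window: float = 5.0

    def __str__(self) -> str:
        return f"{self.engine}|{self.solvent}|{self.charge_state}|{self.window:g}"


@dataclass
class LigandRecord:
    ligand_id: str
    mol: MoleculeGraph
    crystal: Conformer
    descriptors: Optional[DescriptorSet] = None
    pools: dict = field(default_factory=dict)       # Condition -> ConformerPool
    best: dict = field(default_factory=dict)        # Condition -> Å
    global_min: dict = field(default_factory=dict)  # Condition -> Å


@dataclass
class StrataReport:
    axis: str
    condition: str
    table: pd.DataFrame  # columns: bin, n, frac_below_<t> ... (percent)


@dataclass
class RegressionResult:
    slope: float
    slope_se: float
    intercept: float
    r2: float


@dataclass
class EnsembleStats:
    entry_id: str
    mean_rmsd: float
    n_models: int
    rotb: int


# ---------------------------------------------------------------------------
# Tables and stratifications
# ---------------------------------------------------------------------------

def best_rmsd_table(records: Sequence[LigandRecord], condition: Condition
                    ) -> pd.DataFrame:
    """One row per ligand: its best (minimum) RMSD under the condition.

    Ligands without a pool for the condition appear with NaN and a warning
    rather than being dropped.
    """
    if not records:
        log.warning("best_rmsd_table called with no ligand records")
        return pd.DataFrame(columns=["ligand_id", "best_rmsd"])
    rows = []
    n_missing = 0
    for r in records:
        val = r.best.get(condition)
        if val is None:
            n_missing += 1
        rows.append({"ligand_id": r.ligand_id,
                     "best_rmsd": np.nan if val is None else val})
    if n_missing == len(records):
        raise ReportError(f"condition {condition} absent for every ligand")
    if n_missing:
        log.warning("%d ligands missing pools for %s", n_missing, condition)
    return pd.DataFrame(rows)


def stratified_fractions(table: pd.DataFrame, records: Sequence[LigandRecord],
                         cfg: StrataConfig, axis: str,
                         condition: str = "") -> StrataReport:
    """Per-bin percentage of ligands whose best RMSD is below each threshold."""
    labels = {}
    order: list[str] = []
    bins = {"rotb": cfg.rotb_bins, "mw": cfg.mw_bins, "ha": cfg.ha_bins,
            "logp": cfg.logp_bins, "psa": cfg.psa_bins}
    if axis not in bins and axis != "psa_sasa":
        raise ReportError(f"unknown stratification axis {axis!r}")
    for r in records:
        if r.descriptors is None:
            continue
        labels[r.ligand_id] = assign_strata(r.descriptors, cfg).get(axis, "n/a")
    if axis == "psa_sasa":
        lo, hi = cfg.psa_sasa_cuts
        order = [f"<{lo}", f"{lo}-{hi}", f">{hi}"]
    else:
        order = [b[2] for b in bins[axis]]
    df = table.dropna(subset=["best_rmsd"]).copy()
    df["bin"] = df["ligand_id"].map(labels)
    rows = []
    for label in order:
        sub = df[df["bin"] == label]
        row = {"bin": label, "n": len(sub)}
        for t in cfg.rmsd_thresholds:
            frac = 100.0 * (sub["best_rmsd"] < t).mean() if len(sub) else np.nan
            row[f"frac_below_{t:g}"] = frac
        rows.append(row)
    return StrataReport(axis, condition, pd.DataFrame(rows))


def average_best_rmsd(table: pd.DataFrame) -> float:
    """Arithmetic mean of per-ligand best RMSDs."""
    vals = table["best_rmsd"].dropna()
    if not len(vals):
        raise ReportError("cannot average an empty best-RMSD table")
    return float(vals.mean())


def rotb_regression(table: pd.DataFrame, records: Sequence[LigandRecord]
                    ) -> RegressionResult:
    """OLS of best RMSD on rotatable-bond count (raw per-ligand data)."""
    rotb = {r.ligand_id: r.descriptors.rotb for r in records
            if r.descriptors is not None}
    df = table.dropna(subset=["best_rmsd"]).copy()
    df["rotb"] = df["ligand_id"].map(rotb)
    df = df.dropna(subset=["rotb"])
    if df["rotb"].nunique() < 3:
        raise ReportError("regression needs at least 3 distinct #RotB values")
    fit = sps.linregress(df["rotb"], df["best_rmsd"])
    r2 = float(fit.rvalue ** 2)
    if np.isnan(r2):  # zero response variance: no trend to explain
        r2 = 0.0
    return RegressionResult(float(fit.slope), float(fit.stderr),
                            float(fit.intercept), r2)


def global_min_fraction(records: Sequence[LigandRecord], condition: Condition,
                        threshold: float = 1.0) -> float:
    """% of ligands whose lowest-energy conformer lies within the threshold."""
    vals = [r.global_min[condition] for r in records if condition in r.global_min]
    if not vals:
        return 0.0
    return 100.0 * float(np.mean(np.asarray(vals) <= threshold))


def solvent_scatter(table_a: pd.DataFrame, table_b: pd.DataFrame,
                    tol: float = 1e-6) -> dict:
    """Paired per-ligand comparison of two conditions (diagonal-plot counts)."""
    a = table_a.set_index("ligand_id")["best_rmsd"]
    b = table_b.set_index("ligand_id")["best_rmsd"]
    if set(a.index) != set(b.index):
        raise ReportError("solvent scatter requires identical ligand ids")
    b = b.reindex(a.index)
    diff = a - b
    return {
        "better_in_a": int((diff < -tol).sum()),
        "better_in_b": int((diff > tol).sum()),
        "ties": int((diff.abs() <= tol).sum()),
        "pairs": pd.DataFrame({"ligand_id": a.index, "a": a.values, "b": b.values}),
    }


# ---------------------------------------------------------------------------
# NMR ensemble statistics
# ---------------------------------------------------------------------------

def nmr_inter_model_mean(models: Sequence[Conformer], mol: MoleculeGraph,
                         superpose: bool = True) -> float:
    """Mean symmetry-RMSD over all unordered model pairs.

    "Each model vs. all other models" averages identically over ordered or
    unordered pairs; unordered pairs are computed once.
    """
    if len(models) < 2:
        raise ReportError("inter-model statistics need at least 2 models")
    autos = find_automorphisms(mol)
    stack = np.stack([m.coords for m in models])
    vals = []
    for i in range(len(models) - 1):
        vals.append(symmetry_rmsd_many(stack[i], stack[i + 1:], mol,
                                       superpose=superpose, autos=autos))
    return float(np.mean(np.concatenate(vals)))


def ensemble_correlations(stats: Sequence[EnsembleStats]) -> dict:
    """Pearson r of mean inter-model RMSD vs #RotB and vs model count."""
    if len(stats) < 3:
        raise ReportError("correlations need at least 3 ensembles")
    mean_rmsd = np.array([s.mean_rmsd for s in stats])
    rotb = np.array([s.rotb for s in stats], dtype=float)
    nmod = np.array([s.n_models for s in stats], dtype=float)
    out = {}
    for name, x in (("rotb", rotb), ("n_models", nmod)):
        if np.std(x) == 0 or np.std(mean_rmsd) == 0:
            out[f"r_{name}"] = float("nan")
            out[f"r_{name}_defined"] = False
        else:
            out[f"r_{name}"] = float(sps.pearsonr(x, mean_rmsd).statistic)
            out[f"r_{name}_defined"] = True
    return out


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Study conditions of a full synthetic benchmark run."""

    n_ligands: int = 100
    seed: int = 0
    solvents: tuple = ("water",)
    include_neutralized: bool = True
    search: SearchParams = field(default_factory=SearchParams)
    strata: StrataConfig = field(default_factory=StrataConfig)
    window: DruglikenessWindow = field(default_factory=DruglikenessWindow)
    occurrence_deviation: object = "sample"
    # curation stress fractions: ligands written with a deliberately close
    # water / packing mate so the filters have work to do
    frac_close_water: float = 0.05
    frac_close_mate: float = 0.05
    frac_altloc: float = 0.10
    sasa_points: int = 194
    out_dir: Optional[str] = None


def run_pipeline(config: PipelineConfig) -> dict:
    """simulate → curate → describe → search → evaluate; returns the bundle.

    Deterministic under ``config.seed``; writes CSV/JSON reports when
    ``config.out_dir`` is set. Raises with a stage label on failure.
    """
    rng = np.random.default_rng(config.seed)
    bundle: dict = {"log": {"seed": config.seed,
                            "conventions": [
                                "thresholds strict '<' 0.5/1.0 Å",
                                "bins lower-inclusive, upper edge inclusive",
                                "superposed symmetry-corrected RMSD",
                                "topological PSA"]}}

    # --- simulate ---------------------------------------------------------
    ds_cfg = synth.SyntheticDatasetConfig(n_ligands=config.n_ligands,
                                          seed=config.seed)
    ligands, manifest = synth.make_dataset(ds_cfg)
    bundle["manifest"] = manifest

    # --- curate -----------------------------------------------------------
    kept: list = []
    cur_rows = []
    for lig in ligands:
        u = rng.random(3)
        # anchor waters at the most solvent-exposed carbon that admits a
        # clean placement; folded poses may reject an anchor entirely
        spread = np.linalg.norm(
            lig.crystal.coords - lig.crystal.coords.mean(axis=0), axis=1)
        carbons = sorted(
            (i for i, a in enumerate(lig.mol.atoms) if a.element == "C"),
            key=lambda i: -spread[i])
        wdist = 2.5 if u[0] < config.frac_close_water else 4.0
        mate = 4.5 if u[1] < config.frac_close_mate else None
        altlocs = [("A", 0.6), ("B", 0.4)] if u[2] < config.frac_altloc else None
        fix_seed = int(rng.integers(2**31 - 1))
        try:
            text = None
            for anchor in carbons:
                try:
                    text = synth.make_complex_file(
                        lig.mol, lig.crystal, waters=[(anchor, wdist)],
                        altlocs=altlocs, mate_offset=mate, seed=fix_seed)
                    break
                except ValueError:
                    continue
            if text is None:  # no clean water site on this pose
                text = synth.make_complex_file(
                    lig.mol, lig.crystal, altlocs=altlocs,
                    mate_offset=mate, seed=fix_seed)
            cm = parse_pdb_complex(text)[0]
            verdict = curate_complex(lig.mol, cm)
        except Exception as e:  # pragma: no cover - stage label contract
            raise ReportError(f"curation stage failed for {lig.ligand_id}: {e}") from e
        desc_set = compute_descriptors(lig.mol, lig.crystal,
                                       sasa_points=config.sasa_points)
        dl_ok, dl_failed = druglikeness_filter(desc_set, config.window)
        row = {"ligand_id": lig.ligand_id, "element_ok": verdict["element_ok"],
               "water_ok": verdict["water_ok"], "packing_ok": verdict["packing_ok"],
               "not_covalent": verdict["not_covalent"], "druglike_ok": dl_ok,
               "druglike_failed": ";".join(dl_failed)}
        cur_rows.append(row)
        if all(row[k] for k in ("element_ok", "water_ok", "packing_ok",
                                "not_covalent", "druglike_ok")):
            kept.append((lig, desc_set))
    occ_counts = {lig.ligand_id: lig.occurrence for lig, _ in kept}
    if occ_counts:
        occ_stats, occ_kept = occurrence_analysis(occ_counts,
                                                  config.occurrence_deviation)
        occ_keep = set(occ_kept)
        kept = [(lig, d) for lig, d in kept if lig.ligand_id in occ_keep]
        bundle["occurrence"] = occ_stats
    bundle["curation"] = pd.DataFrame(cur_rows)
    if not kept:
        raise ReportError("curation stage: zero ligands survive the filters")

    # --- describe + search -------------------------------------------------
    records: list[LigandRecord] = []
    for lig, desc_set in kept:
        rec = LigandRecord(lig.ligand_id, lig.mol, lig.crystal, desc_set)
        autos = find_automorphisms(lig.mol)
        for solvent in config.solvents:
            params = SearchParams(
                step1_window=config.search.step1_window,
                window=config.search.window,
                max_steps=config.search.max_steps,
                max_saved=config.search.max_saved,
                solvent=solvent, engine=config.search.engine,
                seed=config.seed, dedup_tol=config.search.dedup_tol)
            cond_c = Condition(params.engine, solvent, "charged", params.window)
            try:
                pool_c = two_step_search(lig.mol, lig.crystal, params.engine,
                                         params, autos=autos)
            except Exception as e:
                raise ReportError(
                    f"search stage failed for {lig.ligand_id}/{solvent}: {e}") from e
            rec.pools[cond_c] = pool_c
            rec.best[cond_c] = best_rmsd(pool_c, lig.crystal, autos=autos)
            rec.global_min[cond_c] = global_min_rmsd(pool_c, lig.crystal, autos=autos)
            if config.include_neutralized and lig.charge_centers > 0:
                mol_n, _ = neutralize(lig.mol)
                pool_n = two_step_search(mol_n, Conformer(lig.crystal.coords),
                                         params.engine, params,
                                         charge_state="neutralized")
                cond_n = Condition(params.engine, solvent, "neutralized",
                                   params.window)
                rec.pools[cond_n] = pool_n
                rec.best[cond_n] = best_rmsd(
                    pool_n, Conformer(lig.crystal.coords))
                combined = combine_pools(pool_c, pool_n)
                cond_u = Condition(params.engine, solvent, "combined",
                                   params.window)
                rec.pools[cond_u] = combined
                rec.best[cond_u] = best_rmsd(combined, lig.crystal, autos=autos)
            elif config.include_neutralized:
                # neutral form of a neutral ligand is itself
                for cs in ("neutralized", "combined"):
                    cond_x = Condition(params.engine, solvent, cs, params.window)
                    rec.pools[cond_x] = pool_c
                    rec.best[cond_x] = rec.best[cond_c]
        records.append(rec)
    bundle["records"] = records

    # --- evaluate -----------------------------------------------------------
    charge_states = (("charged", "neutralized", "combined")
                     if config.include_neutralized else ("charged",))
    lt_rows = []
    for rec in records:
        row = {"ligand_id": rec.ligand_id, "rotb": rec.descriptors.rotb,
               "mw": rec.descriptors.mw, "ha": rec.descriptors.ha,
               "psa": rec.descriptors.psa, "logp": rec.descriptors.logp,
               "charged_groups": rec.descriptors.charged_groups}
        for cond in rec.best:
            row[f"best_{cond}"] = rec.best[cond]
        for cond in rec.global_min:
            row[f"gmin_{cond}"] = rec.global_min[cond]
        lt_rows.append(row)
    bundle["ligand_table"] = pd.DataFrame(lt_rows)

    base_cond = Condition("toy", config.solvents[0], "charged",
                          config.search.window)
    table = best_rmsd_table(records, base_cond)
    bundle["strata_rotb"] = stratified_fractions(
        table, records, config.strata, "rotb", str(base_cond))
    t2_rows = []
    for solvent in config.solvents:
        for cs in charge_states:
            cond = Condition("toy", solvent, cs, config.search.window)
            t = best_rmsd_table(records, cond)["best_rmsd"].dropna()
            t2_rows.append({
                "solvent": solvent, "charge_state": cs, "n": len(t),
                **{f"frac_below_{th:g}": 100.0 * (t < th).mean()
                   for th in config.strata.rmsd_thresholds}})
    bundle["strata_charge_solvent"] = pd.DataFrame(t2_rows)
    bundle["regression"] = rotb_regression(table, records)
    bundle["global_min_fraction"] = global_min_fraction(records, base_cond)

    # --- NMR-like ensembles -------------------------------------------------
    nmr_rows = []
    stats_list = []
    nmr_rng = np.random.default_rng(config.seed + 1)
    for rec in records:
        n_models = int(nmr_rng.integers(5, 21))
        jitter = 4.0 * rec.descriptors.rotb
        models = synth.make_nmr_ensemble(rec.mol, rec.crystal, n_models,
                                         jitter, int(nmr_rng.integers(2**31 - 1)))
        mean = nmr_inter_model_mean(models, rec.mol)
        stats_list.append(EnsembleStats(rec.ligand_id, mean, n_models,
                                        rec.descriptors.rotb))
        nmr_rows.append({"ligand_id": rec.ligand_id, "mean_inter_model_rmsd": mean,
                         "n_models": n_models, "rotb": rec.descriptors.rotb})
    bundle["nmr_stats"] = pd.DataFrame(nmr_rows)
    if len(stats_list) >= 3:
        bundle["nmr_correlations"] = ensemble_correlations(stats_list)

    if config.out_dir:
        _write_bundle(bundle, config)
    return bundle


def _write_bundle(bundle: dict, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.6f"
    bundle["ligand_table"].to_csv(out / "ligand_table.csv", index=False,
                                  float_format=fmt)
    bundle["curation"].to_csv(out / "curation_report.csv", index=False)
    bundle["strata_rotb"].table.to_csv(out / "strata_rotb.csv", index=False,
                                       float_format="%.1f")
    bundle["strata_charge_solvent"].to_csv(out / "strata_charge_solvent.csv",
                                           index=False, float_format="%.1f")
    reg = bundle["regression"]
    pd.DataFrame([asdict(reg)]).to_csv(out / "regression.csv", index=False,
                                       float_format=fmt)
    bundle["nmr_stats"].to_csv(out / "nmr_stats.csv", index=False,
                               float_format=fmt)
    logd = dict(bundle["log"])
    logd["global_min_fraction"] = bundle["global_min_fraction"]
    if "nmr_correlations" in bundle:
        logd["nmr_correlations"] = bundle["nmr_correlations"]
    if "occurrence" in bundle:
        logd["occurrence"] = asdict(bundle["occurrence"])
    (out / "run_log.json").write_text(json.dumps(logd, indent=2, sort_keys=True))
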