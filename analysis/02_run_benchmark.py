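#!/usr/bin/env python
"""Run the full benchmark: simulate → curate → describe → search → report.

The headline outputs are the flexibility-stratified success fractions
(share of ligands with a pool conformer below 0.5 / 1.0 Å of the crystal
pose), the charge-state comparison (charged vs neutralized vs combined
pools), the #RotB regression, and the global-minimum proximity fraction.
"""

import time
from pathlib import Path

from bioconfbench import evaluation_report as er

OUT = Path(__file__).resolve().parents[1] / "results" / "benchmark"

t0 = time.time()
cfg = er.PipelineConfig(n_ligands=100, seed=17, out_dir=str(OUT))
bundle = er.run_pipeline(cfg)
print(f"pipeline finished in {time.time()-t0:.0f}s; "
      f"{len(bundle['records'])} of {cfg.n_ligands} ligands survived curation")

print("\nfraction (%) of ligands near the crystal pose, by flexibility:")
print(bundle["strata_rotb"].table.to_string(index=False,
                                            float_format=lambda v: f"{v:.1f}"))
print("\ncharge-state comparison (water):")
print(bundle["strata_charge_solvent"].to_string(index=False,
                                                float_format=lambda v: f"{v:.1f}"))
fit = bundle["regression"]
print(f"\nbest RMSD vs #RotB: slope {fit.slope:.3f} ± {fit.slope_se:.3f} Å/bond, "
      f"r² = {fit.r2:.3f}")
print(f"global minimum within 1.0 Å of crystal pose: "
      f"{bundle['global_min_fraction']:.1f}% of ligands")
print(f"reports written to {OUT}")
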