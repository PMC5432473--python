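# bioconfbench

Can a conformational search produce the **bioactive conformation** — the
geometry a drug-like ligand adopts in a protein binding site? This package
implements, end to end on synthetic fixtures, the benchmark pipeline used to
answer that question for crystal-structure ligands: curation of
protein–ligand complexes by explicit geometric and chemical filters, a
debiased two-step conformational search with energy-window acceptance,
symmetry-corrected RMSD as the similarity metric, charged/neutralized
combined conformer pools, and descriptor-stratified success statistics.

It is aimed at computational chemists who want a tested, reproducible
harness for the protocol itself — the filters, the metric, the search
bookkeeping and the reports — independent of any commercial search engine.

## The metric and the protocol

**Symmetry-corrected RMSD.** Topologically equivalent atoms make naive
index-matched RMSD overestimate conformational differences: a
para-substituted benzene flipped 180° about its linker bond is the same
conformation with permuted labels. The corrected metric minimizes over the
molecule's graph automorphisms Aut(G) — permutations preserving elements,
formal charges and bonds:

```
RMSD_sym(A, B) = min_{π ∈ Aut(G)}  min_{R,t} sqrt( (1/N) Σ_i ‖A_i − R·B_π(i) − t‖² )
```

with the inner minimum the Kabsch least-squares superposition.
Automorphisms are enumerated exactly by a backtracking matcher pruned with
color refinement; aromatic bonds form one label class so Kekulé alternation
never breaks a symmetry.

**Debiased two-step search.** Starting a search at the crystal pose biases
the pool toward the answer. Step 1 searches from the crystal pose with a
wide 50.0 kcal/mol acceptance window and selects the pool member *most
dissimilar* to the crystal; step 2 searches from that conformer, keeps
conformers within the production energy window (5.0 kcal/mol; 10.0 as a
variant) of the global minimum, caps the pool at 1000, and deduplicates.
A ligand "succeeds" when some pool member lies below 0.5 / 1.0 Å of the
crystal pose.

**Curation filters** (defaults as used throughout): biogenic-element
whitelist (C,H,N,O,S,P,F,Cl,Br,I); water close contacts — discard when a
water oxygen is nearer to a ligand heavy atom than f·(r_O + r_X) with
f = 0.891 for carbon, 0.8 otherwise (Bondi radii); crystal-packing contacts
— discard when any symmetry mate (deposited operators × lattice
translations) comes within 5.0 Å; highest-occupancy altloc selection;
occurrence analysis — exclude ligands appearing more than
⌈μ + s⌉ times; drug-likeness window (#RotB ≤ 15, MW 150–650, 10–150 heavy
atoms, |total charge| ≤ 3).

The search engine behind the protocol is pluggable; the bundled engine is a
deterministic torsion-grid toy (gauche±/anti per rotatable bond, or seeded
random torsion vectors beyond the 5000-step budget) scored by a clash +
screened-Coulomb + torsion energy. It exists to make the protocol's
bookkeeping and the solvent/charge phenomenology testable, not to model any
force field — see `docs/methods.md`.

## Worked example

```python
import bioconfbench as bb
from bioconfbench.chem import Conformer

# a zwitterionic flexible chain with an extended "crystal" pose
mol0, conf0 = bb.make_linear_ligand(6, seed=1, fragments=["CH2"] * 7)
mol, conf = bb.make_charged_variant(mol0, 2, seed=0, conformer=conf0)
crystal = bb.extended_pose(mol, conf)

params = bb.SearchParams(seed=17)            # water, EW 5.0 kcal/mol
charged = bb.two_step_search(mol, crystal, "toy", params)
neutral_mol, _ = bb.neutralize(mol)
neutral = bb.two_step_search(neutral_mol, Conformer(crystal.coords), "toy",
                             params, charge_state="neutralized")
print(f"charged input:     {bb.best_rmsd(charged, crystal):.2f} A")
print(f"neutralized input: {bb.best_rmsd(neutral, Conformer(crystal.coords)):.2f} A")
combined = bb.combine_pools(charged, neutral)
print(f"combined pool:     {bb.best_rmsd(combined, crystal):.2f} A")
```

prints

```
charged input:     1.02 A
neutralized input: 0.00 A
combined pool:     0.00 A
```

— the salt bridge between the ammonium and carboxylate ends ranks compact
conformers ahead of extended ones, so the charged-input pool (capped at its
1000 lowest-energy members) loses the crystal-like geometries; neutralizing
the input removes the bias and the combined pool keeps the better answer.

The numbered scripts under `analysis/` run the full studies: dataset
simulation, the 100-ligand benchmark with stratified reports, the
energy-window widening study, the charge-neutralization case above, the
NMR-like fluctuation analysis, and the water/octanol comparison. Each
writes its tables under `results/`.

## Command line

```
bioconfbench run --n-ligands 100 --seed 17 --out results/benchmark
bioconfbench search ligand.sdf crystal.sdf --ew 5.0 --solvent water
symrmsd A.sdf B.sdf [--no-superpose] [--cap N]
```

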