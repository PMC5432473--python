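# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `bioconfbench`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Scope and design stance

The package reimplements a benchmarking *protocol* — curation filters,
symmetry-corrected RMSD, a debiased two-step search with energy-window
acceptance, charged/neutral combined pools, stratified statistics — as a
tested library plus analysis drivers. Commercial search engines and force
fields (MCMM/Low-Mode sampling, GB/SA solvation, MD minimization) are
deliberately out of scope: the search engine is a *contract*
(`generate(mol, start, params) → pool`), and the bundled implementation is
a deterministic toy whose sole purpose is to exercise the protocol and make
solvent/charge phenomenology testable. Conclusions drawn from this package
concern the protocol's bookkeeping and statistics, not any force field's
accuracy.

## Molecular representation

Heavy-atom graphs with implicit hydrogens: atoms carry (element, formal
charge, implicit-H count), bonds carry order (1/2/3/aromatic) and a ring
flag. Conformers are (N×3) Å coordinate arrays aligned to the graph's atom
order, optionally tagged with an energy (kcal/mol), engine, solvent and
charge state. SDF V2000 I/O goes through RDKit; PDB fixtures are written
with a fixed-column writer and parsed with gemmi.

## Symmetry-corrected RMSD

Automorphisms are enumerated by a backtracking matcher over refined node
colors (iterative neighborhood-label refinement seeded with
element+charge). Aromatic bonds are a single label class — a
Kekulé-literal treatment would wrongly break the 180° para-ring-flip
symmetry. Hydrogens are excluded from both the automorphism graph and the
RMSD. The default cap of 100 000 permutations is far above anything
drug-like graphs produce; truncation sets a flag and the result is reported
as a bound. Superposition uses the Kabsch SVD solution with the
proper-rotation (det +1) correction; batched evaluation computes RMSDs
from singular values without forming rotations.

Superposition defaults ON everywhere, including inter-model comparisons of
multi-model ensembles: free conformers have arbitrary frames, so the
superposed metric is the only generally meaningful reading. A
`superpose=False` mode computes in-frame RMSD for co-aligned deposited
models.

Batched evaluation over a conformer stack and an automorphism set permutes
the single reference rather than the stack (RMSD(X, πY) = RMSD(π⁻¹X, Y)),
builds all 3×3 cross-covariances in one matrix product, scores every
(conformer, permutation) pair with closed-form eigenvalues of HᵀH
(trigonometric method, ~1e-6 accurate), and re-derives each row's
near-minimal candidates exactly through SVD rotations and residuals — the
σ-sum shortcut loses precision near zero RMSD, where it matters most.
Molecules with hundreds of automorphisms (e.g. polyphenylene chains)
therefore cost one GEMM, not hundreds of array copies.

Deduplication of pools compares candidates at a symmetry-RMSD tolerance of
0.25 Å (engine-internal deduplication settings of published protocols are
unstated; 0.25 Å merges numerically-identical grid neighbors without
collapsing distinct rotamers). Three rigorous, permutation-invariant
screens prune the quadratic comparison exactly: the Mirsky singular-value
bound (RMSD ≥ ‖σ(X) − σ(Y)‖₂/√N), a sorted pairwise-distance-profile
bound (RMSD ≥ ‖Δ sorted d‖₂/(N√2), by the rearrangement inequality), and
an energy neighborhood — congruent geometries score identical energies, so
on exhaustive grids (where all sub-tolerance neighbors observed are
exactly energy-degenerate mirror-move pairs) a 1e-6 kcal/mol neighborhood
suffices, while sampled pools use 0.5 kcal/mol.

## Curation filters

* vdW radii: Bondi (1964), config-overridable.
* Water contacts: discard when d(O_water, X) < f·(r_O + r_X), f = 0.891
  for carbon, 0.8 otherwise.
* Packing: symmetry mates from the deposited operators (REMARK 290,
  converted to fractional form) combined with lattice translations in
  {−1,0,1}³; discard on any mate atom within 5.0 Å. The one-cell
  translation range is sufficient for nearest-mate contacts at 5 Å in
  realistic cells; a documented limitation for pathologically thin cells.
* Altlocs: highest occupancy wins; exact ties resolve to the first
  orientation in file order.
* Covalent attachment: any ligand heavy atom within 1.8 Å of a protein
  heavy atom (a standard covalent-range cutoff; the source protocol states
  the rule but not the criterion).
* Occurrence analysis: threshold ⌈μ + s⌉, ligands strictly above it are
  excluded. The deviation statistic is configurable — sample SD,
  population SD, or a literal value added as-is — because published usage
  labels a variance as if it were an SD; no convention is guessed as
  "correct". `OccurrenceStats.from_values(1.80, 1.33)` reproduces the
  printed worked example (raw 3.13, integer 4). "Rounding to the next
  higher integer" is the ceiling, applied as-is to exact integers.
* Drug-likeness window: #RotB ≤ 15, MW ∈ [150, 650], #HA ∈ [10, 150],
  total charge ∈ [−3, +3]. Crystallization pH is parsed from the header
  when present and recorded; no protonation is performed (protonation
  states are inputs).

## Descriptors

* #RotB: acyclic single bonds between two heavy atoms that each have at
  least one further heavy neighbor, excluding amide C–N bonds (the
  convention of the tool the source protocol cross-checked against);
  conjugated esters are not excluded.
* Topological PSA: the published atomic-contribution table over N/O
  environments with the S/P extension (toggleable to N/O-only). Verified
  in tests against RDKit's implementation of the same table. Unrecognized
  polar environments contribute 0 with a warning.
* SASA: Shrake–Rupley quadrature with Fibonacci-sphere points (default
  960 per atom, probe 1.4 Å, Bondi radii); the isolated-sphere case is
  exact by construction, and quadrature error shrinks with the point
  count. 2D (topological) PSA is used for stratification; 3D molecular
  surface areas are out of scope.
* LogP: a coarse per-atom contribution scheme (aromatic/aliphatic carbon
  positive, heteroatoms negative, charge-penalized); used solely for
  binning, pluggable by design.
* Stratification bins: #RotB {0–3, 4–6, 7–10, 11–15}; MW
  [150,250], (250,350], (350,450], (450,650] — bin edges as printed
  overlap at the boundaries, so the declared convention is
  lower-inclusive first bin, then upper-edge-inclusive; #HA
  {10–14, 15–20, 21–25, 26–30, >30}; LogP unit-width bins from <0 to ≥5
  (only the "4.0–4.99" boundary is externally fixed); PSA width-70 bins;
  PSA/SASA cut points {0.1, 0.4}. RMSD thresholds 0.5/1.0 Å with strict
  `<` (boundary cases are measure-zero; convention logged in reports).

## The toy search engine

For k rotatable bonds the engine enumerates the 3^k gauche+/anti/gauche−
torsion grid when it fits the 5000-step budget, otherwise scores a seeded
uniform sample of 5000 continuous torsion vectors (logged). Conformers are
built by batched torsion driving of the start geometry and scored with

```
E = Σ_clash ε (σ_ij / d_ij)^12  +  Σ_pairs 332.06 q_i q_j / (ε_s d_ij)  +  Σ_tors (V3/2)(1 + cos 3φ)
```

over atom pairs ≥ 3 bonds apart. Parameter choices, fixed a priori:

* σ_ij = 0.59·(r_i + r_j): the clash energy reaches 1 kcal/mol at the
  2.0 Å steric floor the pose generator enforces for a C–C pair — the
  term is a hard-clash penalty, not an attractive LJ well.
* Partial charges are the formal charges; solvent enters only as the
  scalar relative dielectric ε_s (water 78.4, octanol 10.3, chloroform
  4.81, gas 1.0).
* V3 = 0.25 kcal/mol: small, so the electrostatic term is the leading
  energy scale — the minimal model in which solvent and charge effects
  are observable at all.

The energy window is applied as post-filtering of the saved pool, and the
1000-conformer cap keeps the lowest energies after the window (how the
original engine interleaved cap and window is unstated; both choices are
flagged in the code). With this model the salt-bridge trap emerges through
the *save cap*, not the window: at ε = 78.4 a ±1 salt bridge is worth only
~1.5 kcal/mol — far inside a 5 kcal/mol window — but it dominates the
ranking of an otherwise flat torsion landscape, so the 1000 saved
conformers of a zwitterion are the most compact ones and the extended
crystal-like geometries are never accepted into the pool. That reproduces,
mechanistically, how a search that ranks by energy under-samples extended
conformations of charged flexible ligands.

Step 2 of the two-step protocol restarts the engine from the most
crystal-dissimilar step-1 conformer (ties: lower energy, then pool order).
For the exhaustive grid the restart cannot change the enumerated set — the
debias step matters for engines with genuine start-dependence and is kept
for protocol faithfulness.

Neutralization is proton bookkeeping on the graph: anionic O/S gain an
implicit H, protonated N loses one, quaternary N is flagged
non-neutralizable; the heavy-atom graph is unchanged, so the neutral pool
maps atom-by-atom onto the charged molecule. Combined pools are set unions
for best-RMSD queries only — energies are never ranked across charge
states, whose scales are incomparable.

## Synthetic data generator

The generator favors controllability over realism. Ligands are chains of
rigid fragments — sp3 methylene, para-phenylene, amide, a methyl-bearing
branch point — between two caps, so the rotatable-bond count is exact by
construction: m interior fragments yield m−1 rotatable joints (amide C–N
joints are never created adjacent), and each carboxylate cap adds one.
#RotB = 0 ligands are a rigid three-ring acene. Geometry is built by
internal-coordinate (NeRF) placement with standard bond lengths/angles.

* Crystal poses: each rotatable torsion drawn from {60°, 180°, 300°} plus
  wrapped-normal jitter of 20° (bound ligands are strained off ideal
  rotamers), rejected until all heavy-atom pairs > 3 bonds apart clear a
  2.0 Å floor; fall-back is the all-anti chain.
* Charge centers alternate carboxylate (−1) and ammonium (+1), so total
  charge is 0 (even counts) or −1 (odd). Dataset draws clamp the center
  count when a (#RotB, centers) pair is not constructible (acenes carry
  no caps; carboxylates consume rotatable-bond budget), which shifts the
  charge histogram slightly at low #RotB; the manifest records realized
  values.
* Dataset defaults emulate the curated crystal-ligand population: #RotB
  weights spanning 0–15 with mean ≈ 5.5, charge-center weights with ~77%
  of ligands at 0–1 centers, occurrence weights with mean ≈ 1.9, MW
  composition tuned into [150, 650] by CH2↔phenylene swaps.
* NMR-like ensembles: wrapped-normal torsion noise of a chosen scale
  around the crystal pose; studies set the scale proportional to #RotB.
* Complex fixtures: fixed-column PDB with CRYST1, the identity REMARK 290
  operator always present, HOH oxygens placed at exact distances from a
  named ligand atom along the clearest direction of a deterministic
  direction fan, optional altloc duplicates (second location jittered
  0.15 Å), and a packing mate encoded as a shrunken P1 cell whose lattice
  translation brings the mate to the requested nearest approach (cell
  length solved by bisection).

What the generator does **not** emulate: real protein environments,
force-field-quality geometries, ring puckering and amide cis/trans
isomerism, correlated MW/HA joint distributions, experimental coordinate
error. Passing tests therefore demonstrate the correctness of the
protocol's machinery and the qualitative phenomenology (flexibility
degrades success; charge traps; window/cap interactions) — not predictive
accuracy on real PDB ligands.

## Statistics and reports

Ordinary least squares (scipy) for best-RMSD vs #RotB, reporting slope,
slope SE and r² (squared Pearson, on raw per-ligand data, not bin means;
r² of a zero-variance response is reported as 0). Pearson correlations
throughout. Inter-model means average over unordered model pairs (ordered
averaging is identical). Percentages print to one decimal. Every report
number is recomputable from the persisted per-ligand table; pipeline runs
are byte-deterministic under a fixed seed, and the run log records the
seed and all defaulted conventions.

Problem sizes used by the shipped studies: 100-ligand benchmark (the
pipeline's default population), 20-ligand energy-window and protocol
property studies, 50-ensemble NMR study, 200-point slope-recovery study —
sizes at which the statistics above are stable yet a full run stays in the
minutes range on a single CPU.

## Known limitations

* The toy engine has no minimization step; conformers sit exactly on the
  driven torsion geometry.
* Coulomb screening by a scalar dielectric has no distance dependence or
  desolvation; gas phase (ε=1) exaggerates charge effects, qualitatively
  mirroring the degradation searches show without solvation.
* Symmetry expansion is limited to deposited operators ± one lattice cell.
* The PDB reader handles the fixture dialect (HETATM ligands, HOH waters,
  CRYST1, REMARK 290, MODEL blocks), not the full wwPDB remediation
  surface; mmCIF is out of scope.
* LogP is a binning device, not a solvation model.
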