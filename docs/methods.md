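# Methods

## Problem setting

A dual-target inhibitor series is characterised by two half-maximal
inhibitory concentrations per compound: IC50 against MAO-A and against
MAO-B.  Potency is expressed as pIC50 = −log₁₀ IC50 with IC50 in molar;
selectivity as the ratio SI = IC50(A)/IC50(B), so large SI means
B-selective.  A compound is classed *selective* when SI ≥ 50.  The
threshold is not a physical constant: published selective/non-selective
partitions of MAO-B series leave a gap between a non-selective maximum
near 49 and a selective minimum near 57, and 50 sits strictly inside that
gap.  It is configurable everywhere it is used.

Other dataset-level conventions:

- IC50 units are declared once per input file (nM default), never per row.
- Duplicate canonical SMILES keep the first occurrence with a warning.
- Molecular weight uses average (not monoisotopic) atomic masses;
  Lipinski counts use HBA = N+O, HBD = NH+OH.
- Bemis–Murcko frameworks retain exocyclic atoms double-bonded to the
  ring/linker skeleton (the common "framework" variant, as implemented by
  RDKit's Murcko scaffold).  Unique-framework counts depend on this
  convention and should only be compared under it.

## Synthetic data: what it emulates and what it does not

`maosel.synthetic.generate_dataset` is the test bed for every stage.  It
emulates the *shape* of a curated MAO-B inhibitor dataset:

- n = 126 compounds, 34 selective (27%), assembled from a fixed library
  of ten fused bicyclic cores (dihydroquinolinone, indanone, tetralone,
  quinazolinone, coumarin, chromone, benzothiophene families) with two
  substitution points each;
- one planted signal fragment (default: a 4-iodobenzyl ether arm; iodine
  appears nowhere else, so carriage is unambiguous) with class-dependent
  prevalence 0.65 / 0.15 and an additive pIC50 effect of 1.2 log units;
- pIC50 = class baseline (6.9 selective / 5.4 non-selective) + effects +
  N(0, 0.45), which spans roughly 4–9.5 and yields a global span near the
  4.76 log units reported for real series;
- log₁₀ SI drawn per class from truncated normals — N(3.0, 0.8) on
  [log 57, log 40000] for selective, N(0.5, 0.9) on [log 0.048,
  log 49.032] for non-selective — so the SI-50 classifier recovers the
  intended labels with zero error by construction, and the extreme values
  match the printed SI ranges of real series.

Signal flags are drawn once per compound (their marginal is exactly the
configured prevalence); structures are then de-duplicated by redrawing
scaffold and benign substituents, because a duplicate-checked dataset is
assumed downstream and exact duplicates flood the SALI ranking with
infinite-scored pairs.  When n approaches the size of the combinatorial
library, duplicates are retained (logged at debug level).

What the generator does **not** emulate: synthetic accessibility,
activity landscapes with multi-fragment epistasis, assay noise structure
(censored "<"/">" values), tautomers/protomers, or 3D conformer realism —
the QSAR harness uses *abstract* occupancy matrices (below).  Passing
tests therefore demonstrate correctness of the statistical machinery on
data with known ground truth, not predictive validity on real chemistry.

`generate_aligned_grid_set` produces binary occupancy matrices X
(per-cell carrier frequency uniform in [0.2, 0.8]) with y = Xβ + ε, β
nonzero on a chosen number of cells.  Active coefficients are drawn as
sign · U(0.5, 1.5) · effect_sd rather than N(0, effect_sd): a zero-mean
draw can plant a coefficient arbitrarily close to zero whose sign no
estimator could recover, which would make sign-recovery checks ill-posed.
The default study condition for the QSAR battery is n = 126 rows over 60
cells (5×4×3 grid) with 10 active cells and noise_sd = 0.35: with an
89/37 split this puts the fitted model in the same statistical regime as
published atom-based 3D QSAR models of this size (training r² ≈ 0.9–0.97,
external Q² ≈ 0.65–0.85, Pearson R ≈ 0.8–0.93).  A grid much wider than
the training set (p ≫ n) instead produces memorisation, which is not the
regime those models report.

## Fingerprint selectivity profile

Fingerprints are Morgan/ECFP4 (bond radius 2 = diameter 4), folded to
1024 bits.  Folded bit indices are hash artefacts: they are treated as
opaque labels, never compared across implementations, and interpreted
only through the atom environment extracted from a carrier molecule
(`substructure_for_bit`, smallest-radius environment first).

Per bit, with s = carrier frequency among selective and t among
non-selective compounds, the bit-as-score ROC AUC has the closed form

    AUC = s(1 − t) + ½(st + (1 − s)(1 − t)),

the Mann–Whitney estimator with ties credited 0.5.  Because "AUC of a
bit against selectivity" admits a second reading, the package also
reports the SI-as-score AUC with bit carriage as the label (rank-based,
midranks for ties).  Both are reported side by side; neither is collapsed
into the other.  There is no canonical significance cutoff for a bit
AUC; the profile reports all prevalence-filtered bits (default: carried
by ≥ 10% of the set) and leaves |AUC − 0.5| thresholding to the caller.
Zones (A–E style regions of a scaffold) are user-declared SMARTS
patterns matched against the representative substructures; first match
wins, multiple matches log a warning.

## Cliff landscape

SALI_ij = |A_i − A_j| / (1 − sim_ij).  The absolute value makes the score
symmetric and non-negative; pairs with sim = 1 and differing activity are
flagged *infinite* and ranked first rather than capped, so downstream
consumers must handle them explicitly.  Activity cliffs use pIC50;
selectivity cliffs use log₁₀ SI, since SI spans six orders of magnitude
and a ratio scale would let a single extreme pair dominate.  The default
similarity is ECFP4 Tanimoto behind a pluggable interface — 3D
pharmacophore descriptors used by some published landscapes are
proprietary, so absolute SALI magnitudes are not comparable across
descriptor choices and no cliff cutoff is hard-coded (top-k ranking is
the default presentation).  An all-zero fingerprint has no defined
Tanimoto similarity; it is assigned 0 to every other compound with a
warning.  Clustering is average-linkage on distance 1 − sim.

## Pharmacophore matching

Features: acceptor (N/O with a lone pair, not positively charged), donor
(N–H/O–H), hydrophobic (carbons with only C/H neighbours), negative /
positive ionic (formally charged groups), aromatic ring at the ring
centroid.  The SMARTS rules are deliberately simple, shipped as data and
editable; no pKa engine is involved (the ligand-prep configuration
records the intended pH 7.2 ± 0.2 window and conformer limits as
metadata for external preparation tools).

A hypothesis is an ordered set of feature types with a symmetric,
triangle-inequality-checked inter-feature distance matrix and a single
scalar tolerance (default 2.0 Å) applied per pairwise distance.  Vendor
implementations use per-feature matching spheres and an unpublished
fitness; the scalar-tolerance model and the *survival-lite* score

    w₁·(fraction of actives matched) + w₂·(mean fit of matched actives)
      − w₃·(fraction of inactives matched),   fit = max(0, 1 − RMSD/tol)

are transparent surrogates, labelled as such.  Matching enumerates
type-compatible injective assignments, prunes by distance compatibility,
and scores survivors by least-squares rigid superposition (Kabsch with
the determinant correction, so mirror-image matches are rejected).
Hypotheses built from distances alone obtain reference coordinates by
classical multidimensional scaling of the distance matrix.

## Atom-based grid QSAR

Heavy atoms are typed with first-match priority D, N, P, W, H, X
(donor, negative, positive, electron-withdrawing/acceptor, hydrophobic
carbon, miscellaneous), so multi-rule atoms classify deterministically;
carboxylic-acid oxygens are typed N on the grounds that they are ionized
at physiological pH.  A cubic grid (spacing 1.0 Å) covers the aligned
set plus the largest van der Waals radius; the bit for (cube, class) is
set iff the **cube center** lies inside the vdW sphere (Bondi radii,
table shipped in code) of at least one atom of that class.  Center-in-
sphere is chosen over sphere–cube volume overlap because it is exactly
testable by lattice enumeration (a 1.7 Å carbon on a grid node covers
exactly 19 cubes); it is a documented divergence risk from vendor
implementations.  Dataset-constant columns may be dropped; predictions
are unchanged and the drop is recorded in the model.

Regression is NIPALS PLS1 on column-centred X with at most 4 factors
(adding factors beyond that is not rewarded by the external battery in
this regime).  Per factor count k: r², SD = √(SS_res/(n−k−1)),
F = (r²/k)/((1−r²)/(n−k−1)) with its p-value from F(k, n−k−1).  The
"stability" column mirrors a vendor statistic whose formula is
unpublished; the surrogate reported here — mean Pearson correlation
between full-model predictions and predictions of models refit on ten
random 80% subsets — is labelled a surrogate in every output.
Coefficient fields per atom class export as Gaussian cube files
(coordinates in bohr, data values at full float64 precision so re-reads
are bit-exact); positive and negative masks export separately as
favorable/unfavorable regions.

## Validation battery

With SSE = Σ(y_test − ŷ)²:

    Q²F1 = 1 − SSE / Σ(y_test − ȳ_train)²
    Q²F2 = 1 − SSE / Σ(y_test − ȳ_test)²
    Q²F3 = 1 − (SSE/n_test) / (Σ(y_train − ȳ_train)²/n_train)

plus Lin's CCC with population (1/n) variances, RMSE/MAE for both sets,
Pearson R and its square.  "Q² (test)" in summary outputs maps to Q²F1,
consistent with batteries where both F1 and F2 variants print the same
value when the split means coincide.  Metrics with a zero-variance
denominator are reported as undefined with a reason, never silently as 0.

The 70/30 split takes ⌈0.70·n⌉ training compounds (126 → 89/37; plain
round-half-up of 88.2 would give 88/38, which is not the canonical
split).  The split is random and seed-reproducible, with an
activity-range overlap report; stratification is available but off by
default, matching the "random division" convention.

Y-randomization refits the model on permuted activities and passes iff
the real training r² exceeds the empirical (1 − α) quantile of the null
(default α = 0.05, 100 permutations) — by construction the false-pass
rate on signal-free data is ≈ α, which the test suite checks
binomially.  Leave-n-out q² = 1 − PRESS/TSS reduces to exhaustive LOO at
n_out = 1.

## Numerical conventions and degenerate inputs

- AUC ties: 0.5 credit (midranks).  Classes must both be non-empty.
- SALI with equal activities is 0 even at sim = 1.
- PLS stops early (with a warning) when the residual X norm is exhausted;
  requesting more factors than rank supports truncates.
- Constant y, empty molecule lists, atoms outside an explicit grid,
  k > n clusters, non-metric distance matrices and invalid SMARTS all
  raise with named context rather than propagating NaNs.
- Cliff and hypothesis rankings break ties deterministically by id order,
  so reruns are byte-identical.

## Known limitations

- The pipeline's default QSAR battery runs on the abstract grid set; the
  molecular route (conformer embedding, O3A alignment onto the most
  selective compound, occupancy encoding) is implemented and unit-tested
  but depends on conformer/alignment quality that single-conformer ETKDG
  embedding does not guarantee.
- Docking, binding-energy estimation and protein-structure handling are
  out of scope by design.
- Bit-level results depend on the folding width (1024 default); cross-
  width comparisons are meaningless at the index level.
- The survival-lite score and the stability surrogate are this package's
  own definitions; they rank hypotheses/models sensibly but are not
  numerically comparable to vendor scores of similar names.
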