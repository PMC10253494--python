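# maosel

Ligand-based analysis of potency and **selectivity** for dual-target
inhibitor series — written for the monoamine oxidase (MAO) case, where a
compound's value hinges on inhibiting the MAO-B isozyme far more strongly
than MAO-A.  Given a table of structures with IC50 values against both
targets, the package derives the standard quantities

- pIC50 = −log₁₀ IC50 (molar) and the selectivity index
  **SI = IC50(MAO-A) / IC50(MAO-B)**, with a configurable SI threshold
  (default 50) splitting the set into selective / non-selective classes;
- per-bit **ECFP4** (Morgan, radius 2, 1024 bits) selectivity profiles:
  class-conditional carrier frequencies and two ROC-AUC readings per bit
  (bit-as-score vs class, and SI-as-score vs bit carriage), a 10%
  prevalence filter, representative atom-environment substructures and
  user-declared molecular zones;
- the **SALI** structure–activity landscape,
  SALI_ij = |A_i − A_j| / (1 − sim_ij), for activity (pIC50) and
  selectivity (log₁₀ SI) cliffs, with a similarity network (GraphML) and
  average-linkage clustering;
- **pharmacophore** feature perception (A/D/H/N/P/R), k-point hypothesis
  enumeration and rigid (Kabsch) matching with a transparent
  survival-lite hypothesis score;
- **atom-based 3D QSAR**: aligned conformers encoded as binary occupancy
  of 1 Å grid cubes by van der Waals spheres of six atom classes, fit by
  NIPALS PLS (≤ 4 factors), with coefficient field maps (Gaussian cube);
- the full **validation battery**: per-factor r², SD, F, p and a
  stability surrogate; external Q²F1/Q²F2/Q²F3, Lin's CCC, RMSE/MAE,
  Pearson R; leave-n-out q²; and Y-randomization at the 95% level.

Because curated dual-target datasets are rarely redistributable, the
package ships a first-class synthetic generator
(`maosel.synthetic`) that assembles drug-like molecules from quinolinone/
indanone-like scaffolds, plants substructures whose prevalence differs
between classes and whose presence shifts pIC50 additively, and returns
the full ground truth — so every stage is testable end to end.

## Worked example

```bash
python analysis/01_simulate_dataset.py
python analysis/02_profile_selectivity.py
python analysis/05_grid_qsar_validation.py
```

generates the reference-shaped dataset (126 compounds, 34 selective) and
prints, among others:

```
100 bits pass the 10% prevalence filter; top discriminators:
 bit  freq_sel  freq_nonsel  auc_bit substructure_smiles
 107  0.617647     0.217391 0.700128            cc(c)COc
 661  0.617647     0.217391 0.700128                   I
...
per-factor training statistics:
 n_factors       r2       sd    f_value      p_value  stability_surrogate
         1 0.734783 0.753238 241.033717 8.370318e-27             0.954837
         4 0.956158 0.311672 457.990141 3.749342e-56             0.969089
external: Q2F1=0.661 Q2F2=0.649 Q2F3=0.609 CCC=0.811 R=0.881 Y-randomization=pass
```

Reading this: the top-AUC fingerprint bits are exactly the atom
environments of the planted halo-benzyl-ether fragment (carried by ~62%
of selective but only ~22% of non-selective compounds — AUC 0.70), i.e.
the profiling stage recovers the planted structure–selectivity signal.
The PLS model's training r² grows with factor count while the external
battery on the held-out 37 compounds stays strong (Q² > 0.6,
Pearson R > 0.8), and permuting the activities destroys the fit
(Y-randomization passes), so the model is predictive rather than memorised.

The same stages are available as a CLI (`maosel simulate | prepare |
profile | cliffs | pharmacophore | qsar | validate | report`, each taking
`--config config.yaml` plus overrides) and as library calls
(`maosel.pipeline.run_pipeline`).

## Layout

- `src/maosel/` — the library (dataset, synthetic, fingerprints, cliffs,
  pharmacophore, qsar, validation, pipeline, cli)
- `analysis/` — numbered narrative drivers writing under `results/run/`
- `tests/` — pytest suite incl. the statistical property battery
- `docs/methods.md` — models, parameter choices and known limitations
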