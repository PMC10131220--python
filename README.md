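# gpcractivity

Structure–activity maps and transition pathways for G protein-coupled
receptor (GPCR) conformational ensembles.

GPCRs switch between inactive, intermediate and active conformations, and
the route a receptor takes between those states is what a drug ultimately
perturbs. Crystal structures give only the endpoints; molecular-dynamics
ensembles give millions of frames with no activity annotation. This
package connects the two: it learns a mapping from conserved receptor
geometry to activation state and activity level from annotated
structures, applies it frame-by-frame to trajectories, and extracts the
most probable inactive→active pathway from the resulting population
landscape. It is aimed at structural bioinformaticians and simulation
groups working on class-A GPCR activation.

## Method

1. **Conserved features.** For a configurable set of *n* polar-network
   residues (default 11, spanning TM1/2/3/6/7 in Ballesteros–Weinstein
   numbering) all *n(n−1)/2* pairwise Cα distances are measured, plus one
   backbone O–C–N angle (vertex at the carbonyl carbon) for each NPxxY
   residue (7.49, 7.50, 7.53). The default schema is 55 distances + 3
   angles = 58 features. The classic activation coordinate — the H3–H6
   Cα distance 3.50–6.34, ≈8.4 Å inactive and ≈14.1 Å active in β₂AR —
   is deliberately excluded from the schema and reserved for validation.
2. **Shallow models.** A gradient-boosted tree ensemble (or random
   forest / single decision tree) is trained as a 3-class activation
   classifier and a 0–100 % activity regressor, with stratified k-fold
   cross-validation reporting accuracy, MAE and pooled R².
3. **Landscapes.** Trajectory frames are scored with the fitted model
   and binned over two structural coordinates (angle × H3–H6 distance)
   into a probability-density histogram whose occupied cells carry the
   mean predicted activity; activity is averaged in small fixed cells
   (3×10⁻³ rad·Å by default).
4. **Pathways.** Density peaks (metastable states) are found on the
   smoothed landscape, each peak gets a basin activity, and consecutive
   peaks — ordered by ascending activity — are joined by the
   minimax-barrier ("widest") grid path on −log(density + ε): the route
   over the lowest density saddle.

A synthetic-data module provides the ground truth for all of this: a
latent activation coordinate λ ∈ [0, 1] drives linear feature loadings,
toy 3D receptor templates (H3–H6 pinned to 8.4/14.1 Å), and overdamped
Langevin dynamics on a 3-well potential with known well ordering.

## Worked example

```python
from gpcractivity import (
    GeneratorConfig, StructureActivityModel, make_feature_dataset,
    recover_well_ordering,
)

dataset, truth = make_feature_dataset(GeneratorConfig(seed=1))
results = StructureActivityModel(dataset, "xgboost", seed=1).fit(cv=5)
print(results.summary(top_k=5))
```

```text
Structure-activity model
================================================
model family   : xgboost
features       : 58
training rows  : 555
states seen    : inactive, intermediate, active
seed           : 1

5-fold CV, xgboost
  state accuracy :  98.38 % (SD 0.75)
  activity MAE   :   4.33 %  (SD 0.47)
  pooled R^2     :  0.974

top 5 features (regressor importance):
  d_1.50_2.50        0.4434
  d_2.45_3.32        0.1307
  d_3.39_8.47        0.1188
  d_2.45_8.47        0.0720
  d_7.45_7.53        0.0573
```

The model classifies the three activation states of the synthetic
training set with 98.4 % cross-validated accuracy and predicts activity
with 4.3-point mean absolute error; importances name the Cα pairs the
regressor relies on. The full pipeline — train, simulate a 50,000-step
Langevin trajectory over three wells at activities 10/50/90 %, build the
landscape, extract the pathway — recovers the well ordering:

```python
out = recover_well_ordering(seed=0)
print(out.recovered)                        # True
print([round(a, 1) for a in out.peak_activities])   # [10.0, 49.6, 91.3]
```

The same stages are available from the shell (`gpcract featurize`,
`train`, `score`, `landscape`, `pathway`, `synth ...`) for work with real
PDB structures, BW-map TSVs and XTC/DCD trajectories.

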