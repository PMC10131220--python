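# Methods

This note records the models, the numerical choices and the open design
decisions behind `gpcractivity`, and what the synthetic ground truth does
and does not establish about real receptor data.

## Feature schema

The schema measures conserved geometry only. Distances are Cα–Cα
Euclidean distances in Å between every unordered pair of polar-network
positions; angles are the backbone O–C–N angle of a residue, with the
carbonyl carbon as vertex, computed as arccos of the normalised dot
product of C→O and C→N, in (0, π].

*Polar network default.* The 11-position default —
1.50, 2.40, 2.45, 2.50, 3.32, 3.39, 6.48, 7.45, 7.49, 7.53, 8.47 —
collects the conserved polar positions across TM1/2/3/6/7 plus the
TM7→H8 elbow that are implicated in the activation hydrogen-bond
rearrangement of class-A receptors (including D3.32, W6.48 and N7.45
from the β-adrenoceptor binding-pocket literature, and the 2.40/8.47
positions whose backbone angles serve as landscape axes). The list is a
config input, not a constant: other receptor classes can substitute
their own set, and the pair count follows as n(n−1)/2.

*Angle convention.* All three atoms are taken from one residue. An
alternative reading spans the peptide bond (O_i–C_i–N_{i+1}); the
intra-residue form was chosen because it is self-contained (no
neighbour-residue dependency after TM truncation) and deterministic.
Switching conventions would shift every angle by a roughly constant
offset and would not change any downstream machinery.

*Canonical order.* Distance pairs are sorted by (helix, position) of
the smaller then larger BW label; angles follow the NPxxY sequence
order. Feature order is hashed into a schema fingerprint stored with
every trained model and checked at prediction time.

*Missing atoms.* Training featurization fails loudly, listing every
unresolvable BW position; trajectory scoring can instead skip frames
(logged with reasons), since truncated MD frames occasionally lose
atoms.

The H3–H6 distance (3.50–6.34 Cα) is never a model input. Because it is
the best-characterised activation coordinate, leaving it out of training
keeps it available as an independent check: predicted activity should
organise along it without ever having seen it.

## Models

Three shallow tree families are supported through one interface:
gradient-boosted trees (xgboost; 300 estimators, depth 6, learning rate
0.1), random forest (300 trees) and a single unlimited-depth decision
tree. These defaults are ordinary shallow-model settings, exposed as
constructor overrides; nothing in the pipeline depends on them beyond
accuracy. Tree models fit the regime — hundreds of rows, 58 features —
and provide per-feature attribution. Importance is read from the
regressor (total gain for boosted trees, impurity decrease otherwise),
normalised to sum to one, ties broken by canonical feature order.

Cross-validation is stratified by state with shuffling driven by the run
seed; accuracy and MAE are per-fold, R² is computed once on pooled
out-of-fold predictions. Regressor output is clamped to [0, 100]
post-hoc because activity is a percentage. Classifier labels are encoded
in activation order (inactive < intermediate < active) over the classes
present in the training fold.

## Landscapes

Densities are probability densities (count / (N · cell area)), so
Σ density · area = 1 is an exact invariant and the map is independent of
bin-width choices. Mean activity is attached per occupied cell and never
imputed for empty cells — 0 % is a meaningful activity, absence of data
is not. A landscape retains its source samples, so re-binning at the
activity-averaging cell area (default 3×10⁻³ rad·Å, cell shape
0.03 rad × 0.1 Å via the aspect parameter) conserves counts exactly.
Grid files written to disk drop the samples; a reloaded landscape
supports peak finding and pathways but not exact re-binning.

## Transition pathways

"Minimum-density path" is formalised as the minimax-barrier path: among
all 8-connected grid paths between two peaks, minimise the maximum of
−log(density + ε) along the path. This is the saddle-crossing reading —
the route over the lowest pass — rather than lowest-integral routes,
which would reward paths hugging empty regions. ε defaults to half a
count spread over one cell, 1/(2N·cell area), keeping empty-cell
barriers finite but worst-ranked.

The search computes the exact bottleneck by a union-find sweep (activate
cells in increasing barrier order until the endpoints connect), then
extracts a concrete path by BFS restricted to admissible cells, with
ties broken by fewest cells and then lexicographically smallest cell
sequence. The tests cross-check the bottleneck value against two
independent routes: exhaustive simple-path enumeration on tiny grids and
a heap-based widest-path search on 100 random 6×6 grids.

Peaks are strict local maxima of the Gaussian-smoothed density over an
8-neighbourhood, thresholded at a fraction of the global maximum, with
near-duplicates (Chebyshev distance < min separation) merged into the
denser peak. Basin activity is the count-weighted mean activity in a
Chebyshev neighbourhood (default radius 2 cells) — a deterministic local
average rather than watershed segmentation, which would add a
segmentation algorithm's own parameters without changing the ordering in
the well-separated regime. Peaks are chained in ascending basin
activity; equal activities fall back to descending density. The output
asserts its own monotonicity.

Only 2D landscapes are gridded. Higher-dimensional generalisation is
exposed as batch processing of feature pairs; a true n-D grid search
grows exponentially with dimension and is out of scope.

## Synthetic ground truth

The generators define the conditions under which the pipeline is
validated.

* **Feature datasets.** A latent coordinate λ ∈ [0, 1] is drawn from a
  3-well Gaussian mixture (centers 0.1/0.5/0.9, widths 0.08, equal
  weights); feature i = baseline_i + λ·span_i + N(0, σ_f²) with
  deterministic loadings (distances within a 3–17 Å envelope with
  alternating motion sign; angles within (0.5, 2.8) rad so the (0, π]
  clip never activates); activity = clamp(100λ + N(0, σ_a²)); state from
  thresholds at λ = 1/3, 2/3. Defaults: 555 samples, σ_f = 0.2 (Å or
  rad), σ_a = 5 percentage points — a training-set size matching the
  curated-structure regime and noise a scientist would call moderate
  annotation error.
* **Toy structures.** 14 mapped residues (the 11 polar positions, the
  NPxxY triplet and the H3–H6 pair; 16 roles with 2 overlaps) with four
  backbone atoms each, interpolated linearly between an inactive and an
  active template. The H3–H6 Cα pair is pinned to 8.4 Å (λ=0) and
  14.1 Å (λ=1), the crystallographic endpoint values for β₂AR; selected
  backbone angles move monotonically (e.g. 8.47: 1.8→2.2 rad). Jitter is
  optional isotropic Gaussian noise per atom.
* **Langevin trajectories.** Overdamped Euler–Maruyama on
  U(λ, y) = Σ_k −d_k exp(−(λ−c_k)²/2w_k²) + (κ/2)y², with T = 0.6,
  dt = 2×10⁻³, κ = 4, depths 2.0, and λ clipped to [0, 1]. At these
  settings a 50,000-step run crosses all three wells many times
  (occupancies within a few percent of uniform across seeds), which is
  the property the pathway test needs; divergence (|z| overflow) raises
  a stability error. Fast mode maps sampled λ directly into feature
  space; integration mode goes through toy 3D frames.

What this does **not** show: the generators are linear in one latent
coordinate with isotropic noise, so passing tests demonstrate that the
machinery recovers a known monotone structure–activity relationship and
a known well ordering — not that 58 conserved features suffice for any
particular real receptor, nor that real MD ensembles are well described
by a 1D reaction coordinate. Real-data performance must be established
on real annotated structures.

## Problem sizes and numerical choices

The end-to-end recovery loop trains on 1,500 synthetic samples with the
default boosted-tree settings, simulates 50,000 Langevin steps (stride
10 → 5,000 frames), grids at 3×10⁻³ rad·Å, smooths with σ = 2 cells,
thresholds peaks at 20 % of the maximum with 8-cell separation, and uses
basin radius 3; these sizes give stable recovery across seeds while
keeping a 20-seed replicate affordable on one CPU. Superposition uses
least-squares rigid alignment (Kabsch via quaternion) on shared Cα
anchors, requiring ≥3; altlocs resolve to highest occupancy with ties to
'A'; trajectory coordinates are converted to Å on read (nm-based formats
×10). Angle computations clip the cosine into [−1, 1] before arccos;
zero-length O–C or N–C vectors are degenerate-geometry errors rather
than NaNs.

## Known limitations

* BW maps must be supplied per structure; there is no automatic
  BW-number assignment from sequence, and no mmCIF reader.
* TM truncation ranges are user configuration; no automatic helix
  detection.
* The empirical-landscape pathway depends on histogram occupancy; very
  sparse trajectories produce noisy peaks, and the peak-merging
  parameters matter more as wells overlap.
* Activity is modelled as a single scalar percentage; multi-pathway
  receptors with branched activation would need a richer label.
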