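# Methods

This note records the models, algorithms, parameter choices and known
limitations of `morphostage`, in the order the pipeline applies them.

## Inputs and coordinate conventions

Inputs are per-subject binary label volumes (NIfTI or MetaImage) of a
single organ, or pre-extracted triangle meshes (PLY/OBJ/STL), plus a
label table (subject id, binary label, stage label 0/1/2 with missing
allowed). All geometry is in physical millimetres, right-handed, with
0-based voxel indexing; the physical position of voxel (i, j, k) is
`origin + (i, j, k) * spacing`. A valid organ surface is closed,
orientable and genus 0 (Euler characteristic 2).

## Surface extraction and standardization

Marching cubes runs at iso-level 0.5 on the zero-padded occupancy grid.
The binary grid is first smoothed with a Gaussian of σ = 1 voxel: the
staircase isosurface of a raw binary grid overestimates surface area by
roughly 10%, while the smoothed field recovers a digital ball's area and
volume to within 5% at radius 10 voxels. Disconnected foreground keeps
the largest component (with a warning); normals are oriented outward.

Meshes are standardized to exactly 1000 vertices by quadric-error-metric
edge collapse (area-weighted plane quadrics, optimal collapse placement
with midpoint/endpoint fallback). Collapses that would break the
manifold (link condition) or flip a surviving face normal are skipped.
The collapse queue breaks cost ties by vertex index, so decimation is
deterministic. The result must stay within 2% of the input bounding-box
diagonal in symmetric vertex-to-surface Hausdorff distance (computed
with exact point-to-triangle distances); upsampling is not supported.

## Rigid normalization

Every subject's organ is rigidly registered (rotation + translation,
det = +1, **no scaling** — organ size is diagnostic signal) to a
reference subject: the first training-subject id in lexicographic order,
recorded in the model metadata. The solver is point-to-point ICP seeded
by centroid alignment plus all four proper-rotation principal-axes
orientations (the identity attitude is always a candidate); the
candidate with the lowest final RMS nearest-neighbour distance wins.
Registration is computed per organ ("organ-to-organ"); a configuration
flag can instead reuse the liver transform for both organs. A residual
above 2% of the reference bounding-box diagonal marks the registration
as non-converged — the signature of an input that rigid motion cannot
align, e.g. a mirrored organ (reflections are unrepresentable by
construction).

## Correspondence (TPS-RPM)

Vertex correspondence to the reference is established by robust point
matching: alternating softassign correspondence updates with regularized
thin-plate-spline refits under deterministic annealing. Implementation
choices:

- Point sets are centred and scaled to unit RMS radius internally;
  temperatures are therefore dimensionless. The returned warp acts in
  physical coordinates.
- Affinity `exp(-d² / 2T)`, Sinkhorn row/column normalization (10
  passes; no outlier row/column since the standardized vertex counts are
  equal — configurable).
- TPS kernel φ(r) = −r (3-D biharmonic), side conditions enforced
  exactly by null-space elimination; kernel terms at 150 control points
  chosen by deterministic farthest-point sampling. Bending
  regularization λ = 0.01·N·T anneals with the temperature.
- The affine block of each refit is anchored at the identity with weight
  0.1·N·T. Without this anchor the fit collapses toward the target
  barycentre at high temperature (where softassign targets are nearly
  uniform) and the match never recovers.
- Default schedule: T from 0.1 down to the squared mean
  nearest-neighbour spacing, decay 0.93, two alternations per
  temperature. The pipeline uses a shorter schedule (T₀ = 0.05, decay
  0.88, 100 control points, 5 Sinkhorn passes) because its inputs are
  already rigidly registered, so displacements are a small fraction of
  the organ scale.
- Each alternation is exact coordinate descent on the free energy
  Σ m d² + 2T Σ m log m + λ‖bend‖² + λ_A‖A−I‖²; the test suite asserts
  per-iteration non-increase at fixed temperature.
- Hard correspondence: greedy conflict-free row argmax of the final
  softassign matrix (rows claimed in order of confidence, ties toward
  the smaller subject index), followed by a final warp refit to the hard
  targets so the reported residual describes the returned
  correspondence. Matching is fully deterministic.

On cohorts from the synthetic generator, matched correspondences land
within ~1 mm (a fraction of the mean vertex spacing) of the generator's
ground-truth anatomical correspondence, and a permuted self-match with
1% noise recovers ≥ 95% of vertex identities exactly.

## Statistical shape model

Shapes are flattened to vectors (single organ 3V = 3000; joint
liver‖spleen 6V = 6000, liver block first). The model is the
eigendecomposition of the sample covariance with **1/N normalization**
(the point-distribution-model convention; the choice affects eigenvalue
scale only), computed through the thin SVD of the centred data so the
D×D covariance is never formed. At most N−1 modes exist; modes below
1e-10 of the leading eigenvalue are discarded as numerical noise. Each
eigenshape's largest-magnitude entry is made positive, which fixes the
arbitrary eigenvector sign and makes repeated fits bit-identical (the
downstream regression needs a stable sign). No Procrustes scale
normalization is applied anywhere. Mixed normal/abnormal training sets
are used for the PCA; class-separate models are out of scope.

## Mode selection

Two rankings are intersected per model:

- AVCR: smallest mode prefix with accumulated variance contribution
  ≥ 0.90 (the threshold is configurable and recorded; there is no
  canonical value).
- Correlation: top 4 modes by the uncentered absolute cosine between the
  mode's coefficient vector and the binary labels. This is deliberately
  *not* Pearson correlation — no mean-centering — though a centred
  variant is available behind a flag. Ties break toward the smaller
  mode index; a top-k larger than the mode count is clipped with a
  warning.

The selected set is the intersection ordered by correlation, truncated
to one mode per model (three features in total for the proposed
approach). An empty intersection falls back to the strongest-correlation
mode inside the AVCR set, with a warning.

Because PCA coefficients are zero-mean, the uncentered cosine against
0/1 labels has a structural ceiling below 1 that depends on class
proportions (≈ 0.786 for 25 normal / 10 staged-abnormal; ≈ 0.69 once
mixed-severity unlabelled cirrhotic subjects join the abnormal class).
Selection only needs the ranking, so this ceiling is harmless, but
absolute correlation values should be read against it.

## Classification and staging

Features (the selected mode coefficients) are standardized to zero mean
and unit variance on each training fold; the scaling is stored for
test-time reuse. Classification is 1-nearest-neighbour with ties toward
the smallest subject index. Staging is ε-SVR with a Gaussian kernel,
trained only on stage-labelled subjects. Defaults C = 10, ε = 0.1,
γ = 1/(n_features · feature variance); none of these has a canonical
published value, and the defaults sit in the flat middle of the
behaviour range on synthetic cohorts. The dual is solved by libsvm
(scikit-learn) to tolerance 1e-8; the package stores the full dual
solution and checks Σ(αᵢ − αᵢ*) = 0, box feasibility and the KKT/tube
conditions after every fit. An independent SLSQP solve of the same dual
is the conformance oracle in the tests (objective agreement to 1e-5).
Hard stages are the nearest label in {0, 1, 2}.

## Synthetic cohorts

The generator provides ground truth for every downstream test. Organs
are star-shaped radial surfaces evaluated on a fixed spherical template
mesh (an icosphere decimated once to the standardized vertex count, then
re-projected to unit directions):

- Liver: union of two overlapping ellipsoidal lobes (right ≈ 4× the
  left by volume, matching hepatic asymmetry) plus a stage-independent
  caudate-like component that keeps the shape chiral at every stage.
  Stage scales lobe *volume* by (1 ± effect·stage) — left up, right
  down.
- Spleen: main body plus an offset polar bump (bean-like, asymmetric);
  volume scales by (1 + effect·stage).
- Per-subject variation: smooth radial modulation by real spherical
  harmonics of order 1–4 with per-coefficient SD 0.04/l², plus isotropic
  vertex jitter (2% of organ size), a random rigid misalignment
  (rotation ≤ 20°, translation ≤ 10% of size) shared by both organs,
  and a random vertex relabelling so that index order carries no
  correspondence information.
- Cohort structure: 25 normal, 8 early-stage, 2 middle/late-stage, plus
  9 cirrhotic subjects whose stage label is withheld (their latent
  severity is drawn from the labelled abnormal mix). Classification
  uses all 44 subjects; staging uses the 35 labelled ones.

All randomness flows from one seeded generator; identical specs produce
bit-identical cohorts. What the generator does *not* emulate: real
segmentation error, CT intensity/texture (the texture baseline is out of
scope by design), anatomically detailed lobe boundaries, vessel
indentations, or inter-organ contact constraints. Passing tests
demonstrate that the pipeline recovers a stage-linked morphological
signal under controlled nuisance variation — not clinical performance.

## Evaluation protocol

Strict leave-one-out: for each fold the held-out subject is excluded
from reference choice, registration targets, model fitting, mode
selection and classifier/regressor training, and enters only through
projection. The reference is the first training subject by id (a fixed
deterministic stand-in for an arbitrary choice). Mode selection is
re-run inside every fold. Normalization results are cached by
(subject, reference, organ) — they depend on nothing else, so the cache
cannot leak fold information; the test suite checks this by replacing
the held-out subject's data with a decoy and hashing the fold artifacts.
Folds whose training set collapses to a single class are skipped with a
warning.

Three approaches run under identical conditions: liver-only + AVCR
selection, liver-only + combined selection, and the three-model combined
selection (one mode per model). Reports carry per-class accuracies,
per-subject predictions, per-stage SVR score statistics, the selected
modes per fold, and a configuration hash.

## Problem sizes and determinism

Default experiments use the 44-subject cohort at 1000 vertices per
organ; a full three-approach leave-one-out evaluation performs 172
registration+matching operations (two references × 43 subjects × two
organs) and finishes in about three minutes on one CPU. Unit and
property tests use 162–642-vertex meshes and smaller cohorts. Every
stochastic component (cohort generation, test fixtures) is seeded;
matching, decimation and model fitting are deterministic by
construction.

## Known limitations

- TPS-RPM is pairwise against one reference; groupwise correspondence
  is out of scope, so reference choice can bias correspondences (the
  leave-one-out protocol varies the reference only when the default is
  held out).
- The greedy hard-assignment step guarantees a bijection but not global
  optimality of the final discrete assignment.
- The uncentered label correlation is bounded away from 1 for zero-mean
  coefficients (see above); it is used as the method defines it.
- Stage labels are treated as equally spaced scalar targets by the SVR;
  no ordinal-regression loss, probability calibration, or non-Gaussian
  kernels.
- The generator's deformation model is low-order and radial; it cannot
  produce self-intersecting, multi-component or highly concave organs,
  and conclusions about robustness to such anatomy cannot be drawn from
  these tests.
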