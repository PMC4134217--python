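# Methods

This document records the generative model, the algorithms, the numerical
choices and the known limitations of `gsvc`. Symbols: a dataset holds `S`
subjects; each subject has `n` grid points, `T` trials and `q` parcels.

## 1. Synthetic data model

Each subject's region of interest is a rectangular grid of `100 × 20` points
(2000 points; the first coordinate is the row, the axis along which the bands
stack). The grid is split into three horizontal bands; only the **middle
band** (height 30 rows) responds to the stimulus. The true, noiseless pattern
of subject `s` under condition `y ∈ {1, 2}` is piecewise constant:

```
x(p; s, y) = a(y) + η(b, y, s)   if point p lies in the middle band
           = 0    + η(b, y, s)   in the outer bands b
```

with activation levels `a(1) = 1`, `a(2) = 2` and a band-level perturbation
`η ~ N(0, σ_η²)` drawn **once per (band, condition, subject) per dataset** and
held fixed across that dataset's trials — it models stable between-subject
activation differences, not trial noise. A trial's map adds pixel noise
`N(0, σ_pix²)` smoothed with a Gaussian of FWHM 2.35 px (reflective
boundaries); the true pattern itself is *not* smoothed, so band edges are
sharp and the `q = 3` parcellation problem is well posed in the noiseless
limit.

Geometric variability between subjects is controlled by the **overlap
fraction** `f` of the middle bands: subject 1's band always starts at row 20,
subject 2's at row `20 + round((1 − f) · 30)`, so `f = 1` means identical
geometry and `f = 0` means disjoint responsive regions.

| Parameter | Default | Meaning |
| --- | --- | --- |
| `overlap_fraction` | 1.0 | shared fraction of the two subjects' middle bands |
| `sigma_eta` | 0.0 | std of the per-band activation perturbation (grid `{0, 0.1, 0.2, 0.3}`) |
| `sigma_pix` | 0.5 | std of the pre-smoothing pixel noise |
| `fwhm_pix` | 2.35 | smoothing kernel FWHM in pixels (`σ = FWHM / 2.355`) |
| `n_trials_per_condition` | 10 | trials per condition per subject |
| `n_subjects` | 2 | subjects per dataset |

**Generator limitations.** Bands are axis-aligned rectangles on a flat grid:
there is no cortical folding, no within-band activation texture, no
hemodynamic or temporal structure, and the two conditions differ only by a
uniform offset of the middle band. Geometric variability is a pure
translation — no rotation, scaling, or shape change. Conclusions drawn from it
concern the *mechanism* of the classifiers (what information each
representation can transfer across subjects), not realistic effect sizes.

## 2. Spatially constrained Ward parcellation

Parcellation uses agglomerative clustering with Ward's variance criterion
(`sklearn.AgglomerativeClustering`), constrained by the 4-neighbor grid
adjacency so that only spatially contiguous clusters can merge — every parcel
is spatially connected. The feature vector of a point concatenates two
blocks, each z-scored per column and then scaled by
`weight / sqrt(n_columns)`:

* spatial block — the point coordinates;
* functional block — the point's activation across all trials.

Dividing each block by the square root of its column count makes the blocks'
contributions independent of how many trials (or coordinate dimensions) there
are; in particular, a **group parcellation** computed on one subject's data
equals the one computed on that subject duplicated, and group parcellation is
just the same procedure on the horizontally stacked trials of all training
subjects (which requires a shared grid).

Parcel labels are relabeled to order of first appearance, making results
independent of library-internal label conventions. Ward merge ties are broken
by scikit-learn's deterministic internal order; exact assignments may
therefore differ across library versions, but all reported quantities are
label-permutation invariant.

## 3. Attributed region-adjacency graphs

Given a parcellation, each trial becomes a graph `G = (A, L, U, y)`:

* `A` — binary symmetric parcel adjacency: `a_ij = 1` iff some point of
  parcel `i` is a 4-neighbor of some point of parcel `j`;
* `L` — node geometry: parcel centroids (mean point coordinates);
* `U` — node activation: parcel mean of the trial's map;
* `y` — the trial's condition label.

`A` and `L` are shared by all trials of a subject; only `U` varies.

## 4. The graph kernel

For graphs `G`, `H` the kernel sums over all **ordered node pairs** of each
graph:

```
K(G, H) = Σ_{i,j ∈ G} Σ_{k,l ∈ H}  k_s(a_ij, a_kl) · k_g · k_a
k_s = a_ij · a_kl                                    (edge indicator)
k_g = exp(−‖(L_i − L_j) − (L_k − L_l)‖² / 2σ_g²)     (centroid displacement)
k_a = exp(−((U_i − U_k)² + (U_j − U_l)²) / 2σ_a²)    (activation levels)
```

`k_s` restricts the sum to pairs of directed edges, so `K` is an
R-convolution kernel over walks of length one; `k_g` compares edge
*displacement vectors*, making the kernel invariant to joint translation of a
graph's coordinates; `k_a` compares endpoint activations. As
`σ_g, σ_a → ∞`, `K(G, H) → 4 · m_G · m_H` (ordered-edge-pair count, `m` =
undirected edge count) — a closed form used as a test oracle.

**Ablation variants** drop one factor each: `sg` (no activation), `sa` (no
geometry), `ga` (no structure; the sum runs over all ordered pairs with
`i ≠ j`, `k ≠ l`).

**Bandwidth heuristic.** `σ_g` is the median Euclidean distance between
centroids pooled over all nodes of the training graphs, `σ_a` the median
absolute difference of the pooled node activations (subsampled above 10⁶
pairs, seeded). Degenerate medians are floored at `10⁻⁶ ×` the attribute
range with a warning. Bandwidths are estimated **per cross-validation fold on
the training graphs only**, so nothing leaks from the held-out subject.

**Numerical choices.**

* The `s`-variants are evaluated by restricting a precomputed `q_G × q_H`
  node-similarity matrix to the directed edge lists (`O(m_G m_H)` after an
  `O(q_G q_H)` setup), which matches a brute-force quadruple loop to
  ~10⁻¹⁶ relative error.
* The `ga` variant uses the explicit ordered-pair sum whenever
  `q(q − 1) ≤ 4000` for both graphs — exact to machine precision. Only for
  larger graphs does it switch to the inclusion–exclusion form
  `total − (i = j) − (k = l) + both`, which is faster but can lose ~8 digits
  to cancellation.
* The kernel is **unnormalized by default**: kernel magnitude scales with
  edge counts, which is unproblematic when training and test graphs have
  similar node counts and is the plain form of the sum above. Cosine
  normalization (`normalize=True`) is available and advisable when node
  counts differ strongly between training and test.
* Every square Gram matrix is checked for symmetry and numerical positive
  semi-definiteness (smallest eigenvalue ≥ −10⁻⁸ × spectral norm); violation
  raises rather than silently feeding an indefinite matrix to the SVM.

## 5. Classification and evaluation

The classifier is a soft-margin SVM on the precomputed Gram matrix
(`sklearn.SVC(kernel="precomputed")`, `C = 1` by default; one-vs-one for more
than two classes). Evaluation is **leave-one-subject-out** (LOSO): all trials
of one subject form the test set, and parcellation-dependent and
bandwidth-dependent quantities are computed from training subjects only.
Individual parcellation itself is unsupervised and per subject, so it is
computed once, not per fold.

Two graph-classifier modes exist: individual parcellations per subject
(default; `q` may be an integer or a per-subject mapping, so node counts may
differ across subjects), and a per-fold **group parcellation** learnt on the
training subjects and applied to all (requires a shared grid).

**Benchmarks.** Vector methods classify flattened point-value vectors; parcel
methods classify per-parcel mean activations under a per-fold group
parcellation. Families: linear/RBF/polynomial SVM, k-nearest neighbors, and
l1/l2-regularized logistic regression. For each family the **best mean LOSO
accuracy over its hyper-parameter grid** is reported — an optimistic bound
that biases comparisons *against* the graph classifier.

## 6. Permutation tests

Comparing cross-validated accuracies with a t test is unsound (fold scores
are dependent and non-normal), so two permutation tests are provided.

* **Paired sign-permutation test** (`test1_paired_sign`): statistic is the
  mean per-unit accuracy difference of two methods; the null flips each
  difference's sign. When `2ⁿ ≤ n_perm` all sign patterns are enumerated and
  the p-value is exact (`count / 2ⁿ`, identity included); otherwise random
  signs with the add-one correction `(1 + count) / (n_perm + 1)`. Two-sided;
  ties handled with a `10⁻¹²` tolerance.
* **Randomized ANOVA on curves** (`test2_randomized_anova`): input is an
  array `(methods, grid values, folds)` of accuracies; the statistic is the
  ANOVA F for the method main effect with the grid as a blocking factor
  (within-cell error with fold replicates, interaction error with one fold);
  the null permutes method assignment independently within each
  (grid value, fold) cell. Implemented vectorized over all permutations.

Both calibrate to the nominal level under a simulated null (checked in the
test suite over 500 replicates).

## 7. Experiment designs

`gsvc.experiments` registers five designs, each returning tidy tables and
writing CSVs plus a JSON manifest (design, full config, seed, version):

* `variability_grid` — graph classifier vs vector methods over the
  (overlap × σ_η) grid, with per-cell sign-test p-values;
* `q_sweep` — accuracy vs `q` for the graph classifier, its group variant and
  parcel benchmarks, compared by the randomized ANOVA;
* `variable_q` — per-subject `q` drawn at random from a list;
* `ablation` — the four kernel variants on a shared dataset suite;
* `bandwidth_stability` — fold-wise bandwidth estimates and their
  coefficient of variation.

All randomness is derived from the config seed through
`SeedSequence`-spawned sub-seeds, so a rerun from the manifest reproduces
byte-identical CSVs.

**Design decision — subjects in `variable_q`.** With two subjects, LOSO
training sets contain a single subject and hence a single node count, and the
unnormalized kernel's magnitude mismatch between training and test graphs
cannot be calibrated away; mixing node counts *within* the training set is
the premise of the design. `variable_q` therefore defaults to four subjects
per dataset (other designs keep two); with two subjects, use
`normalize=True` instead.

## 8. Limitations

* The generator's simplifications (Section 1) mean absolute accuracies here
  do not predict real-data performance; the suite demonstrates mechanisms and
  correctness, not effect sizes.
* The kernel costs `O(m_G m_H)` per pair and the Gram `O(N²)` in the number
  of trials; it is intended for dozens of parcels and hundreds of trials, not
  voxel-scale graphs.
* The unnormalized kernel is sensitive to strong node-count imbalance between
  training and test (see Section 7).
* Parcel-level mean activation discards within-parcel pattern structure; with
  very small `q` this can hide fine-grained condition differences.
* The best-over-grid benchmark reporting is an optimistic bound for the
  benchmarks, not a properly nested model selection; it is intentional
  (hardening the comparison) but not a recipe for estimating benchmark
  generalization.
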