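# Methods

## Data model and preprocessing

An `ExpressionStudy` holds a probes × samples matrix of linear-scale
intensities, a same-shaped boolean present/absent flag matrix, and one
annotation row per sample: chemical, class label, acquisition batch, the
vehicle-control group the sample is matched to, and a control flag.
Validation enforces unique ids, matching shapes, non-negative linear
intensities, that every treated sample's control group contains at least
one control sample, and that control samples carry the control class label.

Preprocessing mirrors one-color array conventions:

- **Intensity floor** (default 5.0): scanned values below the detection
  limit are replaced by it. Idempotent and monotone.
- **Sample QC** (default threshold 0.80): a sample is dropped when its mean
  Pearson correlation with all other samples is *strictly* below the
  threshold. The correlation is computed on log2 of floored intensities —
  a deliberate choice, since Pearson on linear microarray intensities is
  dominated by a handful of bright probes; the threshold comparison is
  strict so a sample exactly at the threshold is retained.
- **Flag filter** (default 0.50): a probe is kept iff its fraction of
  present flags over all arrays is at least the threshold. A missing flags
  file means all-present, so external or synthetic data without flags pass
  through unchanged.
- **log2 transform** is applied after normalization (the normalizations
  are ratios of linear intensities); double transforms and non-positive
  inputs are errors.

## Normalization

Stage one divides every chip (sample column) by that chip's median over
all probes, so every chip has median 1 afterwards. Stage two divides every
gene (probe row) either by its median across all samples (*median* mode)
or by the median over the matched vehicle-control samples of the sample's
control group (*control* mode). Medians are 50th percentiles with linear
interpolation for even counts — deterministic and bit-stable across runs.
Stage ordering is enforced through the stage record the study carries;
running a per-gene step before the per-chip step is an error, as is a zero
chip or gene median (unreachable after flooring).

Control mode normalizes control samples by their own group's control
median — the interpretation we chose for a point the procedure leaves
open — so a control sample identical to its group median profile maps to
all-ones. Because a batch-wide multiplicative chip offset multiplies
treated and matched control samples alike, control normalization cancels
it exactly; this is verified to machine precision in the tests.

## The gradient selector

Defined for at least 3 classes, each with at least 2 samples (the power
term needs a within-class variance). On log2 data, for each gene:

1. per-class medians;
2. sort ascending;
3. successive differences of the sorted medians (= log2 fold changes
   between neighbor classes; on log2 data differences and fold changes
   coincide);
4. power of a two-sided two-sample t-test for each neighbor pair, at the
   standardized effect `|median difference| / pooled SD` of the two
   classes, α = 0.05;
5. `R = stdev(differences, ddof=1) × geometric mean(powers)`.

An across-class pre-filter (Kruskal-Wallis by default; one-way ANOVA and
Welch ANOVA are available) removes genes with p ≥ α before scoring.
Ranking is by R descending, ties broken by pre-filter p-value ascending,
then probe id — fully deterministic.

Numerical and definitional choices:

- There are n−1 neighbor pairs, hence n−1 differences and n−1 powers; the
  geometric mean runs over those n−1 powers.
- The power definition (two-sided pooled t-test at the observed
  standardized median difference) is the simplest standard pairwise power
  and is swappable through `PowerSpec`.
- Each power is floored at ε = 1e-6 before the geometric mean so a single
  zero power cannot annihilate the product.
- Power is evaluated with the noncentral-t closed form
  `P = F̄_nct(t_crit) + F_nct(−t_crit)`; scipy's noncentral t returns NaN
  in far tails at moderate noncentrality, where we substitute the Gaussian
  limit (the affected term is < 1e-12 there). A zero pooled SD with a
  positive difference yields power 1; a zero difference yields power α.
- Degenerate inputs: a constant gene has all differences 0, so R = 0; so
  does a gene whose sorted class medians form an *equal-gap* staircase —
  a strictly monotone but uniform marker is discarded by the formula.
  This is a property of the score as defined, implemented as printed and
  exercised in the tests; callers who want uniform staircases retained
  must use a different selector.

## SVM-RFE

One-vs-rest linear SVMs (liblinear, fixed random state); feature criterion
`c_i = Σ_k w_{k,i}²` summed over class weight vectors — the natural
multi-class extension of the single-weight-vector criterion. Each round
keeps `floor(active/2)` features (at least one is always eliminated) until
one survives, giving the active-set schedule 400 → 200 → 100 → 50 → 25 →
12 → 6 → 3 → 1. Features are ranked by survival round, ties within a
round by criterion value, then index.

## Classic rankers, discretization, PCA

Chi-square, information gain and gain ratio operate on supervised
discretized expression: Fayyad–Irani recursive entropy minimization with
the MDL stopping rule, falling back to 10 equal-frequency bins when MDL
accepts no cut (so weakly informative continuous features still get a
score; a constant feature collapses to one bin and scores 0). ReliefF uses
k = 10 nearest hits/misses with every instance as a reference point,
Manhattan distance on range-normalized features, and miss contributions
weighted by class priors renormalized over the complement of the reference
class. PCA components carry a deterministic sign (largest-magnitude
loading positive) and are capped at 200; when the benchmark harness
requests more components than the training fold supports, the count is
clamped to the data limit with a logged warning (direct construction
still raises).

## Benchmark harness

Classifier backends are scikit-learn estimators behind a name contract:
`j48` → entropy-criterion decision tree, `random_forest`, `naive_bayes` →
Gaussian NB, `simple_logistic` → multinomial logistic regression with its
built-in L2 regularization, `smo` → linear-kernel SVM with pairwise
multi-class voting, `libsvm` → RBF-kernel SVM. Hyperparameters default to
the backend defaults and are recorded with results. The classifiers are
standard components, deliberately not re-implemented; the harness and the
selectors are the package's contribution.

Cross-validation is stratified k-fold (default 10 folds) repeated
(default 10 iterations) with iteration seeds at fixed offsets from the
master seed. When the smallest class has fewer samples than the requested
fold count, the fold count degrades to that class size (logged); a fold
count of n runs leave-one-out. Feature selection runs *inside* each
training fold by default (`in_fold`), so reported accuracies are
leakage-free; `selection_scope="global"` selects once on all samples
before CV — the optimistic protocol some published benchmarks used, kept
for replication with a logged warning. A poisoning test (sentinel values
in test folds) verifies in-fold selection never reads test data.

Cross-batch evaluation fits selector and classifier on one study and
predicts another after intersecting probe universes; training accuracy is
resubstitution accuracy, and the overfitting rate is
`100·(train − pred)/(train + pred)` — antisymmetric, zero iff the
accuracies agree, negative when prediction beats training.

Marker-panel clustering is agglomerative (Euclidean, average linkage) on
rows and columns separately, with inputs pre-sorted by id so leaf orders
are deterministic.

## Synthetic studies

The generator emulates the screening design the pipeline targets: a
control class plus 13 chemical classes (names configurable), 105 chemicals
distributed round-robin over the treated classes, 3 replicates per
chemical per batch, one vehicle-control group (with its own replicates)
per 3 chemicals, and two acquisition batches. Linear intensities are

```
baseline × 2^(class effect) × batch factor × chip factor × 2^noise
```

floored at 5. Noise is log-normal on the linear scale (normal on log2),
σ = 0.2 by default; per-probe baselines are log2-normal with mean 8 and
SD 2; chips carry a small log2-normal scale (σ = 0.1) plus a shared
multiplicative batch offset (1.5 by default) that per-chip or control
normalization can remove. Planted staircase markers draw their per-class
log2 offsets as a random permutation of cumulative gaps — Dirichlet-random
(irregular, the gradient selector's intended catch) or uniform (equal-gap,
scoring R = 0 by construction) — with a total range of 3 log2 units by
default. Marker *blocks* assign −a/+a offsets to named class groups,
emulating co-regulated transcript clusters. Ground truth (marker ids,
effect table, baselines) is returned, and generation is bit-deterministic
per seed.

What the generator does **not** emulate: probe-sequence and dye effects,
spatial artifacts, correlated noise between probes, heavy-tailed outliers,
and chemical-specific (rather than class-wide) responses. Passing tests
therefore demonstrate correctness of the algorithms and the harness under
the stated error model, not field performance on real arrays.

## Problem sizes used in tests and the acceptance script

Recovery and harness checks run at deliberately modest scale — 2,000
probes for marker recovery (50 planted markers, 5 seeds), a balanced
14-class study of 84 samples and 600 probes for the CV sanity checks, and
~150–600 probes elsewhere — sizes at which every property under test is
already well expressed. The cross-batch experiment on real data (531
arrays, 41k probes) is reachable through the same CLI given the
corresponding TSV inputs, but no download is required or assumed anywhere.

## Known limitations

- The gradient score discards equal-gap monotone markers (see above).
- Welch's ANOVA is computed by the standard closed form; for very small
  groups (n = 2) its df approximation is crude, as usual.
- ReliefF is O(n²) in samples; at screening-study scale this is fine, but
  for thousands of samples a sampled variant (m < n reference instances)
  would be preferable.
- `global` selection scope reproduces optimistic published protocols and
  should not be used for honest error estimation.
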