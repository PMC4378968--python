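# Methods

## Problem setting

Two-class expression data: a real-valued matrix of `g` genes × `K`
samples (genes as rows) with binary sample labels. Both classes must hold
at least two samples before any scoring. The regime of interest is
`g ≫ K` (thousands of genes, tens of samples), which drives both halves
of the design: univariate gene selection before classification, and
explicit rule-count control inside the classifier.

## Pre-processing

`dataio` offers four percentile pre-filters — max absolute value,
variance, profile range (max − min), and Shannon entropy of a fixed-width
10-bin histogram of the gene profile — each disabled by default and
conventionally set to the 0.10 percentile when enabled. A gene is removed
when its statistic falls strictly below the configured percentile of that
statistic over all genes, so with all statistics equal nothing is
removed; removing *every* gene is an error that names the remedy.
Quantile normalization maps every sample onto the across-sample mean of
order statistics; ties within a column receive the mean of the normalized
values at their tied ranks, which keeps the map deterministic and
symmetric under sample reordering. Default order is filter → normalize;
both orders are supported since neither is canonical.

Missing cells are rejected at load time unless per-gene median imputation
is requested; imputation is I/O plumbing, not part of the method.

## Filter statistics

All five criteria score a single gene and are direction-free
(label-swap-invariant, nonnegative):

* `ttest` — |t| with the Welch denominator √(σ₁²/n₁ + σ₂²/n₂),
  sample standard deviations with the n−1 denominator.
* `entropy` — symmetric Kullback–Leibler divergence of the two Gaussian
  class-conditional models:
  ½[(σ₁²/σ₂² + σ₂²/σ₁² − 2) + (1/σ₁² + 1/σ₂²)(μ₁ − μ₂)²].
* `roc` — |AUC − ½|, the area between the empirical ROC curve and the
  diagonal. AUC comes from the Mann–Whitney rank formula with midrank
  ties, which equals brute-force pair counting exactly (tested to n = 12
  over 200 random draws). The |·− ½| form makes the score direction-free
  like the other four; raw AUC is available via `auc_mann_whitney`.
* `wilcoxon` — |z| of the rank sum W of the smaller class (class 0 on
  equal sizes; the choice only flips the sign of z), with
  μ_W = n_s(n_s + n_l + 1)/2 and the standard tie-corrected variance
  n_s·n_l/12·[(N + 1) − Σ(t³ − t)/(N(N − 1))].
* `snr` — |μ₁ − μ₂|/(σ₁ + σ₂).

Numerical guards: class variances are floored at 1e−8 of the pooled
variance before the three moment-based scores, so near-constant genes
score deterministically; a constant gene with a nonzero mean gap returns
a +inf sentinel that ranks first and is handled specially downstream.
Ties in ranking break by ascending gene index.

## Modified AHP fusion

For one criterion with scores `c`, the pairwise judgement matrix is
`x_ij = f(|c_i − c_j|)` on the continuous [1, 10] scale (see README for
the formula); `c_max` is computed per criterion as max − min of the
finite scores, so the scale is affine-equivariant: rescaling a
criterion's statistics leaves its matrix unchanged. +inf sentinels are
excluded from `c_max` and pinned to element 10 against any finite score
(1 against another sentinel).

The priority vector follows the column-normalized row-averaging
procedure: S_j = Σ_i x_ij, ε_i = (1/n)Σ_j x_ij/S_j, λ_i = (row_i·ε)/ε_i,
λ_max = max λ_i, CI = (λ_max − n)/(n − 1), CR = CI/RI(n) with Saaty's
tabulated random index up to n = 15 and the asymptote 1.98(n − 2)/n
beyond. This procedure (rather than the principal eigenvector by power
iteration) is the method's defined arithmetic; a spectral cross-check in
the tests confirms the two agree closely and produce identical rankings
on random matrices. CR > 0.1 raises a warning only — the continuous
scale keeps CR small in practice, and consistency is diagnostic, not a
gate.

Dominance monotonicity holds by construction: a higher score can only
enlarge row elements and shrink the corresponding column elements, so
ε is monotone in the score (property-tested on random draws, n ≤ 50);
consequently the equal-weight fusion of the five eigenvectors preserves
unanimous orderings.

**Scaling.** A dense n×n matrix per criterion is impractical at
microarray scale, but every element is a closed-form function of
(c_i, c_j, c_max), so column sums and ε stream over blocks without
materializing X (`dense_limit` 2000 by default, block size 512). The
streaming path is the dense arithmetic reordered and agrees with it to
1e−12 (tested to n = 200).

Criterion weights default to equal fifths, matching the convention of
not privileging any statistic; they are configurable and validated to be
nonnegative and sum to one.

## Fuzzy standard additive model

Rules have factorable sinc if-part sets and a then-part summarized by
centroid c_j and volume V_j, plus a rule weight w_j; the output is the
convex combination in the README. Design choices:

* Output dimension is fixed to 1 with classes coded 0/1; the decision
  rule is F(x) ≥ 0.5 → class 1, the boundary going to the positive
  class. This coding and threshold are a documented convention of this
  package.
* Sinc side lobes can make firings (and the denominator) negative; raw
  values are kept because clamping would zero the gradients the tuning
  stage needs. |denominator| < 1e−12 falls back to the mean of the
  centroids.
* `sinc(u)` uses the series 1 − u²/6 below |u| < 1e−8; its derivative
  uses −u/3 + u³/30 below 1e−6.

**Initialization.** Fuzzy c-means (Bezdek alternating updates, fuzzifier
2.0, convergence when the largest center shift < 1e−6 or 300 iterations,
seeded random membership start) clusters the joint (p+1)-dimensional
(input, output) observations. Each cluster becomes a rule: input part of
the center → sinc centers, output part → centroid, membership-weighted
per-dimension standard deviation → widths, floored at 1e−3 of the
dimension's data range; V = w = 1. Clusters with essentially no
membership mass are dropped.

**Tuning.** Incremental (per-sample) gradient descent with momentum:
ξ(t+1) = ξ(t) − μ ∂E/∂ξ + ε Δξ(t) on E = ½(y − F(x))², default μ = 0.01,
ε = 0.9, 200 epochs, seeded per-epoch shuffling, and best-epoch model
memory (the returned model minimizes the epoch-mean squared error seen).
All partials are analytic via the chain rule through the SAM quotient
and the factored firing; they match central finite differences to
relative error < 1e−4 at 100 random non-degenerate draws (components
below the finite-difference noise floor ~1e−5 are compared against that
floor — at h = 1e−6 the difference quotient itself carries ~1e−10
absolute noise). Widths, volumes and weights are re-floored after every
update; a vanishing denominator skips that sample's update.

## Genetic rule-structure optimization

Between initialization and tuning, a GA searches over rule bases. The
encoding is mixed: per-rule activation bit plus the real rule parameters,
which reconciles bit-flip mutation with real-valued rules and gives the
GA direct control of the rule count m. Fitness (lower is better):

    fit = ln(σ̄²) + m·ln(n)/n,   σ̄² = training MSE floored at 1e−12

a per-sample BIC/MDL-style complexity penalty — strictly increasing in m
at equal error, reducing to MSE ordering when the penalty is zeroed (the
penalty is a pluggable function). The initial population comes from one
FCM run per individual with cluster counts drawn uniformly from
[C_min, C_max] and distinct derived seeds — varying counts are what let
the GA explore m. Roulette selection uses the minimization transform
g_k = (max fit − fit_k) + 1e−6·spread (uniform when all fitnesses tie);
1-point crossover cuts on rule-block boundaries with the cut uniform on
[0, min(len_a, len_b)], conserving the pair's total block count;
mutation flips each activation bit with probability `mutation_rate` and
jitters each real parameter with the same probability by Gaussian noise
at 5% of its data-derived range; repair guarantees ≥ 1 active rule.
Elitism (default 1) makes the best-fitness trace non-increasing.
Defaults: population 50, 100 generations, crossover 0.8, mutation 0.05,
rule-count range [2, 15].

The fitness is evaluated on the training fold only. Note a structural
caveat demonstrated in the tests: when the target carries no observation
noise, near-interpolating rule bases can drive the *training* MSE down
faster than the penalty grows, and the GA legitimately keeps large rule
bases. The rule-reduction demonstrations therefore use targets with
Gaussian observation noise (σ = 0.2 on the 0/1 coding), giving the
training error an irreducible floor — the regime the penalty is designed
for and the realistic one for noisy expression data.

## Evaluation protocol

Leave-one-out cross-validation of the full pipeline. Per fold: gene
selection on the K−1 training samples (`per_fold`, the default — the
held-out sample never influences selection; `full_data` selects once on
everything, as is common in this literature, and is provided for
comparability), per-gene standardization with training-fold statistics,
FCM → GA → gradient training, prediction of the held-out sample.
Accuracy is exactly (correct folds)/K; sensitivity TP/(TP+FN),
specificity TN/(TN+FP), with absent classes reported as NaN rather
than 0; AUC is the midrank Mann–Whitney statistic of the continuous
scores (the same engine as the ROC criterion, without the |·−½|
transform). Fold seeds derive from (master_seed, fold index) via
`numpy.random.SeedSequence`, so folds are order-independent and the
whole report is reproducible bit-for-bit from the master seed. A fold
whose training portion loses a class is skipped with a warning and
excluded from K.

## Synthetic data

The generator emulates the high-dimensional-low-sample structure:
background genes are class-independent Gaussians (σ = `noise_sd`);
`n_informative` genes receive a between-class mean shift of
`effect_size·noise_sd` with alternating sign so direction-free scoring
is actually exercised; options add equicorrelation within the
informative block and heavy-tailed contamination (random cells replaced
by 5σ draws) to probe the rank-based criteria. Defaults — 200 genes, 60
samples, 5 informative at effect size 3, balanced classes — are the
study conditions used by the end-to-end recovery checks. What passing
on this generator does *not* show: robustness to probe-level artifacts,
batch effects, intensity-dependent variance or realistic microarray
distributions, none of which are simulated.

The end-to-end checks run the GA and tuning at reduced settings
(population 8, 10 generations, rule-count range [2, 4], 40 epochs) —
sufficient for the separable study conditions, where large populations
add nothing.

## Known limitations

* Binary classification only; the SAM output is scalar.
* Sinc is the only membership shape.
* The GA penalty controls training-fold complexity, not generalization
  directly (see the no-noise caveat above).
* CR is a warning, never a rejection; severely inconsistent matrices
  still produce priorities.
* The streaming AHP path is O(n²) per criterion in time, though O(n·block)
  in memory; tens of thousands of genes are feasible, millions are not.
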