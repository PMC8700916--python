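# Methods

## Problem and model

`omicsmkl` classifies samples into two groups (late tumour stage, coded +1,
vs early stage, coded −1) from several omics blocks measured on the same
samples — copy-number calls, DNA methylation, gene expression, miRNA and
protein abundance. The method has two stages.

**Stage 1 — mRMR filter with a wrapper on the feature count.**
Every continuous feature is ternarized against its own mean µ and sample
standard deviation σ: codes −1 / 0 / +1 for values below µ − ασ, inside the
closed band [µ − ασ, µ + ασ], and above µ + ασ, with α = 0.5 by default.
Integer-coded copy-number blocks are already categorical and pass through.
On the codes, features are ranked incrementally by
minimum-redundancy-maximum-relevance: the m-th feature maximizes

    I(x_j; c) − (1/(m−1)) · Σ_{x' ∈ S_{m−1}} I(x_j; x')

over not-yet-selected features, where I is the plug-in mutual information
(bits) and S_{m−1} the features already chosen; ranking stops at a cap of
500. The number N of retained features is then chosen by a wrapper: for
each N on a grid (20, 30, …, 500 by default), the downstream classifier is
cross-validated using the first N ranked features, and the N with the
largest mean validation AUC wins (ties go to the smallest N).

**Stage 2 — multiple kernel learning.** Each block contributes two base
kernels over its selected, per-feature standardized columns: a Gaussian
kernel exp(−‖x − x′‖²/(2σ_b²)) with σ_b from the median heuristic, and a
polynomial kernel (⟨x, x′⟩/q + 1)², q the block's selected-feature count.
All kernels are spherically normalized to unit diagonal. A soft-margin SVM
is trained on the convex combination K = Σ_m d_m K_m with d on the
probability simplex; the weights are learned by the simpleMKL alternation —
solve the SVM dual at fixed d, then take a reduced-gradient step on d using
∂J/∂d_m = −½ Σ_ij a_i a_j K_m(x_i, x_j) with a line search — until the
relative duality gap (max_m S_m − Σ_m d_m S_m)/|J| falls below `tol`.
The simplex constraint drives irrelevant kernels to weight zero, so the
fitted weights indicate which blocks carry signal. The decision function is
f(x) = Σ_i a_i K(x, x_i) + b; its sign is the prediction (0 maps to +1).

## Evaluation protocol

Nested cross-validation separates tuning from assessment: the wrapper runs
only inside each outer-training set, the refit model is scored once on the
held-out fold. Reported AUC is the mean of per-fold AUCs (the pooled-score
AUC is also recorded). Folds are stratified by default — with ~23%
positives, unstratified small folds can lose a class. The experiment suite
reuses one fold assignment across the all-blocks run, the five single-block
runs and the five leave-one-block-out runs, so comparisons are paired.
For interpretation, a single final feature set is produced by a non-nested
CV over the N grid (mRMR re-run per training split) followed by one mRMR
ranking of the whole dataset truncated to the winning N*.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `alpha` | 0.5 | half-width (in sd units) of the ternary zero band; 0.5 leaves ≈38% of a Gaussian feature coded 0 |
| `cap` | 500 | maximum mRMR list length |
| `n_grid` | 20,30,…,500 | wrapper search grid for N |
| `C` | 1.0 | SVM cost; no class weighting by default (a per-class weight dict is accepted) |
| `tol` | 1e-3 | relative duality-gap threshold of simpleMKL |
| `max_iter` | 200 | outer simpleMKL iteration budget |
| `degree`, `offset` | 2, 1 | polynomial kernel shape; inner product scaled by feature count |
| bandwidth | median heuristic | per-kernel Gaussian scale; parameter-free and robust to block width |

σ uses the sample (n−1) estimator. Mutual information uses log base 2 with
maximum-likelihood cell probabilities and 0·log 0 = 0; the base rescales
scores uniformly and cannot change any ranking. mRMR ties are broken by
higher relevance, then by column order, making runs deterministic.

## Leakage discipline

Discretization bands, mRMR rankings, per-feature standardization and kernel
bandwidths are always estimated on training rows only and reused to
transform validation rows. A canary test plants an absurd value in a
held-out sample and asserts the training-fold ranking and wrapper choice do
not move.

## Synthetic data

The generator emulates a five-block staging cohort at desk scale. Labels
have a fixed positive count round(n·prevalence) (default 200 samples at
81/351 ≈ 23%). On a latent Gaussian scale, informative features get a
±effect/2 class mean shift; redundant features are parent + Gaussian noise
with the noise variance chosen so the population parent–child correlation
equals the target (the parent's between-class variance included); the rest
is white noise. Value kinds are produced by transforms: rounding and
clipping to {−2..2} for the copy-number-like block, a logistic squash into
[0, 1] for the methylation-like block. The default "luad-mini" layout has
blocks of 500/400/400/80/50 features with 12 informative (effect 0.8 sd)
plus 6 redundant copies (ρ = 0.9) in each of the methylation-like and
expression-like blocks, and pure noise elsewhere — a regime where the
multi-omics model should beat any single block and where removing a signal
block should hurt.

What the generator does not emulate: real marginal distributions (GISTIC
call frequencies, beta-value bimodality, count overdispersion), batch
effects, block-wise missingness, or cross-block biological coupling (e.g.
methylation suppressing expression of the same gene). Passing tests
therefore show the pipeline's statistical machinery behaves correctly under
a known ground truth, not that any particular AUC would be achieved on
clinical data.

## Numerical choices

- The SVM dual at fixed weights is solved with libsvm (via scikit-learn);
  inside the simpleMKL loop the low-level binding is used for speed, with
  orientation fixed by the dual box constraint and SVC as fallback.
- The line search on the simplex combines a golden-section bracket on
  [0, γ_max] with a geometric backtracking sweep; only strictly improving
  steps are accepted, so the objective is non-increasing by construction.
  If the reduced-gradient direction yields no improvement, a
  conditional-gradient (Frank–Wolfe) step toward the kernel with the
  largest quadratic form is tried — a guaranteed descent direction whenever
  the duality gap is positive.
- Degenerate inputs: zero-variance features code to 0 (band boundaries are
  closed) and standardize with sd 1; a block in which all points coincide
  gets bandwidth 1; blocks with no selected features are dropped from the
  kernel set with a warning, the simplex renormalizing over the rest.
- Composition percentages use half-up rounding to two decimals.

## Reduced desk-scale settings

Heavy experiments (the acceptance suite and `scripts/acceptance.py`) use
the luad-mini fixture with 3 outer and 3 inner folds and the grid
20–100 in steps of 20. These sizes are the package's chosen desk-scale
study conditions; all defaults remain the full 10×10 folds and 20–500 grid.

## Known limitations

- Binary classification only; no multi-class staging.
- The wrapper's N search assumes the mRMR order is informative; with no
  signal at all the chosen N is arbitrary (the permutation-null test covers
  this regime).
- AUC variability across folds is reported but no significance test is
  attempted — cross-validated performance estimates have no unbiased
  variance estimator.
- simpleMKL convergence is to the stated gap tolerance, not to machine
  precision; with duplicated kernels the weight split between them is not
  identifiable (the objective is flat), only their sum is.
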