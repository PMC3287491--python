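# Methods

This note records the model, the numerical conventions, and the design
choices made where the published procedure leaves them open.

## Selection model

RFA is a wrapper method: candidate genes are scored by the training accuracy
of a classifier refit on the current prefix plus the candidate. Two
classifiers are implemented in-house because the selection loop calls them
tens of thousands of times and their tie behaviour must be exact:

- **NBC** — Gaussian naive Bayes: per class and per feature a normal density
  with MLE mean/variance and class-frequency priors.
- **NMSC** — nearest class mean after dividing each feature by its pooled
  within-class standard deviation (pooled variance = within-class sum of
  squares over n − k, k = number of classes present).

Support vector machines and random forests enter only as scikit-learn
adapters (evaluation classifiers; the forest also supplies out-of-bag errors
for the LPPO tie-break). They are never used inside the selection loop's
accuracy scan.

### Accuracy as integer counts

Training accuracy is exchanged as an exact `AccuracyCount` (correct, total)
pair compared by integer cross-multiplication. The candidate set **C** at
each step — "all genes attaining the maximal accuracy" — is therefore defined
without any floating-point tolerance. Leave-one-out on the training samples
is the default mode (resubstitution is available and recorded in output
metadata); with a handful of samples, LOO is what makes single-gene
accuracies differ at all.

### Numerical conventions

- **Variance floor.** Any estimated variance below ε is raised to ε, with
  ε = 1e-9 × the mean per-feature variance of the full matrix handed to the
  routine (absolute fallback 1e-12). The floor is computed once per selection
  run and shared by every fold and every candidate, so the vectorised scorer
  and a per-candidate refit produce identical predictions. Consequence: a
  leave-one-out fold that reduces a class to a single sample gets a floored
  (near-zero) variance and is effectively rejected from that class — LOO with
  fewer than three samples per class is not meaningful and the evaluation
  protocol never produces it.
- **Prediction ties** (equal posterior or equal distance) go to the lower
  class code; class 0 is the first class name encountered in the input.
- **Constant vectors** have squared correlation 0 by definition — a constant
  gene carries no redundancy information.
- **Score ties** after the MSC/MMC criterion break to the lowest gene index;
  the first gene breaks accuracy ties by the smallest prefilter p-value, then
  index. Selection is fully deterministic.
- **Correlations are computed on training samples only**; the held-out half
  never informs selection.

### Cost

Per step, the NBC/NMSC scorers share the prefix log-likelihoods (or scaled
distances) across candidates and add one per-gene term, so a step costs
O(samples² × genes) instead of a refit per candidate; nothing is cached
across steps. Measured selection time grows essentially linearly in the gene
count (empirical exponent ≈ 1.0 over 500→2000 genes).

## Prefilter and normalisation

The prefilter is a load-reduction device, not an inference: genes with Welch
two-sample p > threshold (default 0.05) are dropped, with an optional cap on
the number kept. Undefined statistics (zero variance in both classes) are
reported as p = 1 and removed. No multiplicity correction is applied.
Normalisation rescales each sample column to mean 1 (median optional) — the
array-wise reading of "MA" normalisation; it is idempotent and per-sample, so
it leaks no label information. The published procedure fixes neither the
threshold nor the exact normalisation variant; both are configuration keys,
and the repeated-split protocol recomputes the filter inside each run from
the training half only (a global-filter option exists for replication).

## LPPO

Given the trajectory's accuracy counts, HR is the set of dimensions attaining
the maximum (exact integer comparison). Open details are resolved as follows:

- **"Initial best" exclusion** removes the maximal contiguous leading run of
  HR. If that empties the set (the plateau is one contiguous run — common
  once training saturates), the full HR is used and the result flagged
  `fallback`.
- **Initial half-width** l₀ = 2 (a five-dimension window), configurable.
- **Boundary windows** truncate to [1, D] and average over the dimensions
  present; padding would invent data.
- **Window-mean ties** are detected with exact rational arithmetic over the
  integer counts; OOB-mean ties after rounding to 12 decimals.
- **OOB tie-break**: a 500-tree random forest, seeded, fit on each prefix in
  the tied windows; fits are cached across windows and expansion rounds
  sharing a prefix, so each dimension is fit at most once per optimisation.
- **Termination safeguard**: if ties survive until the half-width reaches the
  trajectory length, the smallest centre wins (fewest genes).

The chosen dimension always carries the maximal training accuracy, because
candidates never leave HR.

## Evaluation protocol

Per run: stratified split sending ⌈n_c/2⌉ of each class to training (the
published ratio is "approximately 1:1"; ceiling keeps training no smaller
than testing), per-run seeds base_seed + i, prefilter on the training half,
selection on the training half, each prefix refit on the full training half
and scored on the test half, LPPO on the training trajectory with the forest
seeded from the run seed. ms_hr equals the expectation of the random
strategy (uniform choice among best-training dimensions) by construction;
the test suite verifies this against Monte-Carlo draws.

## Synthetic data

The generator plants three gene populations: equicorrelated informative
blocks (one latent factor per block; within-block correlation is the single
parameter ρ and its expected value is exact), independent noise genes, and a
positive baseline (default 10) so values sit on an intensity-like scale and
per-sample mean rescaling is well behaved. The class shift is expressed in
within-class SD units. The reference study condition is 1000 genes, five
blocks of ten, effect 2 SD, ρ = 0.8, 30 samples per class.

What the generator does **not** emulate: probe-level artifacts, saturation,
heavy-tailed intensity distributions, batch effects, and class-dependent
covariance. Passing tests on this design show the algorithmic properties
(exact tie handling, redundancy control, lagging selection), not performance
on any real cohort.

### A property worth knowing

On this design, two facts interact: (i) leave-one-out training accuracy
saturates within a few dimensions at 2-SD effects and 60 samples, after which
*every* gene — including pure noise — ties at the maximum; and (ii)
differentially expressed genes are correlated with each other *through the
class signal* (between-block cor² ≈ 0.25 at a 2-SD shift), while noise genes
are uncorrelated with everything. Minimum-correlation tie-breaking therefore
prefers noise genes once the ceiling is reached. This is the published rule
behaving as defined, and it bounds how many planted blocks the first few
selections can cover; the redundancy control's benefit is cleanly visible
only while ties are confined to informative genes (the all-informative
construction in the test suite, where MSC covers 2.95 blocks on average
versus 2.10 for index-tie-break forward selection over 20 seeds). The
acceptance suite asserts the stronger coverage claim on the noisy design as
specified and documents its failure rather than weakening it.

## Problem sizes used in tests

Oracle-equivalence checks run 56 random instances (≤ 40 genes, ≤ 24 samples,
8 steps) against an independently coded brute-force scan and require exact
agreement. The repeated-split contrast runs 20 splits at 30 dimensions on the
reference design — the design has 50 informative genes and roughly 100 genes
survive the prefilter, so 30 dimensions brackets the optimum while keeping
the forest tie-breaks affordable. The scaling check times selection at 500
and 2000 genes and asserts a sub-quadratic exponent.
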