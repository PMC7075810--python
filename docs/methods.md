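# Methods

This note documents the models, algorithmic choices, defaults and
limitations of the `ageguess` toolkit. It is written for users who want
to know precisely what the code computes and why, down to tie-breaks and
seeds.

## Problem setting

Input is a beta-value methylation matrix (CpG probes × samples, values in
[0, 1], missing entries allowed), per-sample chronological age (years) and
sex, and per-probe chromosome annotation. The goal is a compact panel of
age-associated probes and a linear regression model ("epigenetic clock")
predicting age from the panel. Probes on chromosomes X and Y are excluded
before any modelling so panels are comparable across sexes; labels are
normalised by stripping a `chr` prefix and uppercasing, and probes with no
annotation record are dropped with a warning by default (configurable to
`keep` or `error` — array annotation files routinely omit control probes,
and the right treatment is a user decision).

Missing beta values are imputed with per-probe medians. Inside
cross-validation, medians come from the training folds only, so the
held-out fold never leaks into the model.

## MIC estimation

The step-1 filter is the Maximal Information Coefficient:

MIC(x, y) = max over grids G, |cols|·|rows| ≤ B(n) of I_G(x; y) / log₂ min(|cols|, |rows|),

with B(n) = n^α and α = 0.6, the convention of the original MINE
statistic; `clump_factor` = 15 caps candidate cut positions per axis.
The estimator:

- fixes one axis to a partition of its *ranks* into q rows and optimises
  the other axis exactly by dynamic programming over candidate cuts
  (boundaries between consecutive distinct values, merged into
  "superclumps" of balanced occupancy when there are more than
  `clump_factor · p` of them);
- uses the rank equipartition for the fixed axis, except when the number
  of possible cut placements C(boundaries, q−1) is at most
  `enum_cut_limit` (60), in which case every placement is evaluated;
- takes the maximum over both orientations, which makes the score exactly
  symmetric; since both partitions depend only on rank order, the score
  is invariant under strictly increasing transforms of either variable.

For small n the enumeration path makes the estimate *equal* to exhaustive
maximisation over all admissible grids (verified against a brute-force
oracle in the tests). Degenerate inputs: a constant axis scores 0; when
B(n) < 4 no two-by-two grid is admissible and the score is 0 by
convention; fewer than `min_n` = 8 samples is an error. The dynamic
program is JIT-compiled (numba) with an integer-count entropy lookup
table; scoring one probe against age at n = 200 costs well under a
millisecond after compilation.

## Regression backends

Both backends are linear in beta values; predictions are
`X @ coef + intercept` in years.

- **SVR**: epsilon-insensitive linear support vector regression,
  C = 1.0, ε = 0.1 years, tolerance 1e−4, iteration cap 10,000
  (liblinear). liblinear regularises its internal bias term, which
  distorts fits badly when the target mean is ~60 years; the
  implementation therefore centres X and y, solves without an intercept,
  and restores it as `mean(y) − coef · mean(X)`. Two losses are
  available: the classic L1 epsilon-insensitive loss (dual solver) and
  the squared epsilon-insensitive loss (primal solver, roughly an order
  of magnitude faster at the problem sizes used here).
- **Ridge**: L2-penalised least squares, λ = 1.0 by default, solved by
  SVD (deterministic, exact at λ = 0).

Features are z-scored on the training data by default (constant columns
pass through with unit scale). Feature importance is the absolute
coefficient on the standardised scale, so importances are comparable
across probes regardless of raw dynamic range. Models serialise to JSON
with shortest-round-trip float rendering, so a reloaded model reproduces
predictions bit-for-bit on the same platform.

## The three selection steps

1. **MIC filter** keeps the `step1_top_k` (default 10,000) probes with
   the largest MIC against age. Ties anywhere in the toolkit break by
   ascending probe id, making every ranking deterministic.
2. **SVR-RFE**: repeatedly (a) fit the SVR on all samples with the
   current features, (b) score the current set by repeated-CV MAD,
   (c) drop the `step2_k` (default 50) lowest-importance features,
   capped so the terminal set has `step2_floor` (default 50) features.
   The returned subset is the *smallest* one whose CV MAD lies within
   one standard error (computed across fold MADs) of the minimum — the
   classic one-standard-error parsimony rule. The strict
   minimum-MAD-then-fewest-features rule is available by disabling
   `step2_one_se`; it is not the default because with a single CV repeat
   the MAD curve is flat within noise over a wide range of subset sizes,
   and strict argmin then returns arbitrarily large subsets whose only
   effect is to inflate the quadratic cost of step 3.
3. **backFS**: greedy backward elimination minimising
   EI = MAD + FNum/100. At a level with m features all m single-removal
   candidates are scored by CV MAD on a fold partition fixed for that
   level (so candidates are compared on identical splits); the removal
   with the lowest EI wins, ties removing the lexicographically smallest
   probe id. After the winner is chosen, the level's recorded EI is
   re-estimated with `step3_refine_repeats` (default 10) CV repeats; the
   returned subset is the global arg-min of these low-noise records,
   including the untouched starting set, ties preferring fewer features.
   Elimination runs down to one feature, so the full EI trajectory is
   always available for plotting.

**Search speed profile.** Candidate scoring during steps 2–3 uses a
single CV repeat and, when the scoring regressor is an SVR, the squared
epsilon-insensitive loss (`fast_search`, on by default); the final model
and report always use the configured loss and `report_repeats` (default
10) repeats. Rationale: step 3 needs O(m²) CV evaluations, and the L1
dual solver costs 10–50 ms per fit at the problem sizes of interest
versus ~1–4 ms for the squared-loss primal; the two losses give nearly
identical MAD curves (differences well under the CV noise), so the
search ordering is essentially unchanged while the wall-clock drops by
an order of magnitude.

All fold partitions and sub-seeds derive deterministically from the
single configured seed via a 64-bit mixing function, so identical
configurations give byte-identical outputs.

## Evaluation

MAD, MSE, RMSE and R² have their textbook definitions; RMSE ≥ MAD always.
Repeated k-fold CV (default 10 folds × 10 repeats) refits imputation,
standardisation and the model inside each training fold, averages each
sample's held-out prediction over repeats, and computes metrics on the
pooled per-sample means — the same quantity one plots in a predicted-vs-
chronological-age scatter. The per-fold MADs are also retained (they feed
the one-standard-error rule). EI uses the evaluated panel's size.

The cross-gender matrix refits the regressor on each dataset restricted
to each biomarker panel, so a cell measures how age-informative a panel
is *within* a population, not how a fitted model transfers; all cells use
the same CV seed, which makes the matrix exactly permutation-consistent
under relabelling and constant when all inputs coincide.

The learning-curve experiment draws one train/test split (30% test,
stratified by age decile by default), then uses *nested* training subsets
at fractions 20–100%, so curves are monotone-comparable; a plain random
split is a flag.

## Synthetic data

The generator emulates the shape of whole-blood 450k/EPIC studies:

- ages uniform on 19–101 years; sexes Bernoulli(1/2);
- uninformative probes: per-probe mean from a bimodal Beta mixture
  (modes near 0.1 and 0.9, matching the characteristic unmethylated/
  methylated peaks of array data) plus Gaussian noise;
- informative probes: beta = b₀ + b₁·age + ε, with |b₁| uniform on
  0.002–0.008 beta units/year (sign random), σ_ε = 0.01 beta units, and
  b₀ drawn so the noiseless mean stays inside [0.05, 0.95] across the age
  range — clamping to (0.001, 0.999) then almost never touches signal;
- gender-specific probes carry their slope and an additive offset
  (default 0.05) in the target sex *only* and sit at an age-independent
  baseline in the other sex, so sex-specific panels are detectable by
  refitting per sex;
- a configurable fraction (default 2%) of probes is annotated to X/Y,
  always drawn from the uninformative pool, so exclusion never removes
  signal; optional uniform missingness.

`oracle_mad` gives the analytic noise floor: inverting one probe's linear
model yields an age estimate with SD σ/|b₁|; combining k independent
probes by inverse variance gives σ_age = σ/√(Σb₁²), and the MAD of
centred Gaussian error is σ_age·√(2/π). With slopes uniform on [lo, hi]
the expected squared slope (lo² + lo·hi + hi²)/3 is used.

What the generator does **not** emulate: Infinium I/II probe-type
chemistry, batch effects, cell-composition confounding, inter-probe
correlation, or non-linear age trajectories. Passing the planted-recovery
tests therefore demonstrates correctness of the selection machinery under
a known linear model, not performance on real methylomes.

## A structural property of EI worth knowing

EI charges 0.01 years per feature. Under the synthetic model with k
equally informative probes, the noise-limited MAD is ≈ σ_age(1)·√(2/π)/√k,
whose marginal improvement per extra probe falls below 0.01 at
k\* ≈ (σ_age(1)·√(2/π)/0.02)^{2/3}. With per-probe age noise of 2 years,
k\* ≈ 19: EI is then *flat to within ~0.003* across panels of 16–20
probes while any CV MAD estimate at n = 200 carries ~0.02 of sampling
noise. Consequently, when more planted probes exist than k\*, the EI
minimiser legitimately returns a panel smaller than the planted set, and
the exact panel size scatters over roughly 10–16 across seeds. This is a
property of the objective, not an implementation artefact; the recovery
experiments in the test suite document it quantitatively.

## Experiment sizes

Desk-scale defaults used by the tests and the acceptance script: 200–500
samples, 300–2,000 probes, 6–20 planted probes, selection configs scaled
to `top_k` 20–200, `k` 5–10, `floor` 8–20. These sizes exercise every
code path (the algorithms are identical at 450k scale; only the MIC
ranking and the RFE schedule lengthen).

## Known limitations

- backFS is O(m²) CV fits from m features; panels beyond a few hundred
  survivors are impractical without reducing `cv_folds` or accepting long
  runtimes.
- The L1-RFE baseline fixes the lasso penalty at α = 0.01 rather than
  tuning it; it exists as a comparison protocol, not a tuned method.
- MIC values at small n are upward-biased (a well-known property of the
  statistic); rankings are still meaningful because the bias is shared
  across probes at equal n.
- Sex is treated as binary male/female for splitting; records with
  unknown sex participate only in the combined dataset.
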