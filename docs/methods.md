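# Methods

This note records the statistical model behind `dcakit`, the defaults and
why they were chosen, what the simulators do and do not emulate, and the
numerical choices that affect results.

## Observation model and bias correction

The observed datum is an S×K table of cell counts `n[s, j]` (sample s,
cell type j). Cell-type labels come from a clustering or annotation step
that confuses similar types; we model this with a K×K similarity matrix
`M`, `m[i, j] = P(assigned j | genuine i)`, assumed *identical across
samples and conditions* — the confusion is a property of the
feature-space geometry of the types, not of the experimental group. Under
this model the observed counts of a sample with genuine composition `z`
are multinomial with parameter `ν = z·M`, so misclassification shrinks
every between-condition difference toward zero (attenuation, not just
noise), which is why it costs sensitivity rather than specificity.

`em_correct` maximizes the multinomial likelihood of `z` per sample by EM
(posterior responsibilities `μ[j, i] ∝ m[i, j] z[i]` in the E-step, count
reallocation in the M-step). Samples factorize, so each is corrected
independently; corrections are identical whether samples are processed
jointly or alone. The algebraic inverse `z = ν·M⁻¹` is used only as a
test oracle: it can leave the simplex, while EM cannot. Corrected
compositions are converted back to integer counts by largest-remainder
rounding so each sample's total is conserved exactly (the beta-binomial
likelihood is defined on integers).

Convergence: relative log-likelihood gain `|ΔLL|/(|LL|+1) < 1e-8`, at
most 1000 iterations; the trace is monotone by the EM guarantee and
asserted so in tests. Initialization is the observed proportions with a
0.5 pseudocount on zero counts (used only for the start point) so no type
is locked at zero by the first E-step.

## Similarity matrices

Three constructions are provided.

* **Uniform**: `(1 − ε(K+1)/K)·I + ε/K`, default ε = 0.05. The formula is
  used literally, which leaves each row summing to `1 − ε/K` rather
  than 1; `renormalize=True` rescales rows. The literal form is the
  default because the row deficit is tiny at the default ε and the
  renormalized form slightly redistributes the diagonal.
* **KNN**: row i is the frequency of neighbour labels over all cells
  clustered as i, normalized to one. Self-neighbours are counted if the
  supplied graph contains them (the tally sums whatever the graph says);
  both conventions can be produced by the caller since the graph arrives
  precomputed.
* **Classifier**: the out-of-fold confusion matrix of an RBF-kernel SVM
  under stratified 5-fold cross-validation, row-normalized. Features are
  used exactly as given; an optional `n_pcs` projects onto leading
  principal components first (30 is a reasonable choice for expression
  data) but PCA is never applied silently.

## The beta-binomial GLM

Counts `z[s, j]` out of totals follow a beta-binomial parameterized by
mean `p̄` and overdispersion `φ ∈ (0, 1)` (`α = p̄(1/φ−1)`,
`β = (1−p̄)(1/φ−1)`), with `logit(p̄) = x_sᵀw`. φ is the intra-sample
correlation: φ → 0 recovers the binomial, and the variance inflation
factor for a sample of n cells is `1 + (n−1)φ`, so even φ = 0.05 is a
large departure from binomial noise at thousands of cells per sample.

Fitting maximizes the likelihood over `(w, logit φ)` with L-BFGS-B; the
likelihood is evaluated through log-gamma functions, with an exact
sum-of-logs path when `1/φ − 1 > 1e6` where the log-gamma differences
cancel catastrophically. Initialization: intercept at the logit of the
pooled proportion, other weights 0, φ at a method-of-moments estimate
clipped to [1e-4, 0.5]; up to five jittered restarts (seeded) on
failure. `p̄` is floored at 1e-8 from both ends; observations with zero
totals are dropped with a warning; fitted means at the floor are flagged
as possible separation.

**Global overdispersion.** With 2–5 replicates a free φ per cell type is
unstable (typically overestimated, costing power). All (sample, type)
observations are therefore stacked into one joint beta-binomial GLM whose
design is the K cell-type indicators (no separate intercept, so each
type gets its own mean), and the single fitted φ is fixed in every
per-type test. The joint model omits condition covariates: its purpose is
a variance estimate, and letting condition effects soak into the means
would require the very per-type fits the pre-step is meant to stabilize.
The global φ is estimated from the corrected counts when correction is
on, because those are the counts the tests see. `per_type` (free φ) and a
user-fixed value remain available for ablations.

**Testing.** Each (cell type, tested covariate) pair is scored by a
likelihood-ratio test with 1 df: "null mode" compares intercept-only
against intercept + that covariate; "full mode" compares the
all-covariate model with the tested coefficient zeroed against the free
full model (drop-one per tested covariate). With a single covariate the
two modes coincide, which is tested. The alternative fit is warm-started
from the null solution so `LL_alt ≥ LL_null` up to optimizer tolerance;
the statistic is clipped at zero. The chi-square reference is asymptotic:
at 2–3 replicates per group the test is mildly anticonservative (the
null-data false-positive rate measures ≈ 0.07 at α = 0.05 in the
benchmark configuration), approaching nominal as replicates grow. Raw
p-values are the primary output; Benjamini-Hochberg q-values are an extra
column, computed per result table.

**Normalization.** By default successes are `z[s, j]` out of the sample
total (Eq. "total" mode). With a reference group R of confidently stable
types, totals become `z[s, j] + Σ_{r∈R\{j}} z[s, r]`; the tested type is
excluded from its own denominator, and the literal ratio
`z_j / Σ_R z_r` (which can exceed 1 when j ∈ R) is avoided — the logit of
the implemented fraction is the same monotone quantity
`log(z_j / Σ_{R\{j}} z_r)`. `detect_reference` runs the total-mode test,
ranks types from least to most significant, and recommends the shortest
prefix with ≥ 2 types and ≥ 25% of all cells (stability of the
denominator); both thresholds are arguments.

## Simulators

`simulate_dirichlet_multinomial` draws, per sample, a composition from
`Dirichlet(scale × proportions_of_its_condition)` and counts from
`Multinomial(total_cells)`; `apply_misclassification` then reassigns each
genuine type's cells by a multinomial draw over that type's similarity
row, conserving the total. The composition is drawn *per sample*: the
Dirichlet is the model of biological replicate variability (scale 70
corresponds to φ ≈ 1/71 ≈ 0.014 of between-replicate overdispersion).
Defaults are the canonical misclassification scenario: three types at
[1/3, 1/3, 1/3] vs [1/3, 1/2, 1/6], scale 70, 2 + 3 replicates, 2000
cells per sample, and the confusion matrix with `m11 = 1`,
`m22 = m33 = 0.7`, `m23 = m32 = 0.3` — the unique symmetric
two-type confusion consistent with observed mean proportions
[0.33, 0.40, 0.27] in condition 2 while leaving condition 1's uniform
composition invariant.

`simulate_count_units` specifies conditions as per-type count units
([1, 4, ..., 4] vs [20, 4, ..., 4] over eight types by default, 3 + 3
replicates, 3000 cells, scale 70) and normalizes within condition, so
inflating one type's units deflates every other proportion — the
compositional artefact the reference normalization targets. Truth marks
only types whose *units* changed.

`simulate_with_covariates` adds additive age and sex effects on the
concentration scale: age uniform on integer years 15–45, sex
Bernoulli(1/2) (male = 1), and
`α_k = base_k + slope_k·(age − 15) + shift_k·male`, floored at 1e-3.
Defaults: slopes ∓0.05 and shifts ∓2 on types {1, 5} / {2, 6}, base
concentrations 70 × the eight-type default proportions, ten replicates
per condition.

What the simulators do *not* emulate: gene-expression-level noise,
clustering pipelines, doublets, batch effects, or variable per-sample
cell capture (totals are fixed). Misclassification is injected directly
at the count layer with a known matrix, so benchmark results show that
the correction and test work *when the confusion model holds*; they do
not certify performance under real clustering error whose confusion
matrix must itself be estimated.

## Evaluation harness

P-values act as scores (smaller = more evidence); decisions use
`p < 0.05` by default. MCC, F1, sensitivity and specificity come from the
pooled confusion counts; ROC AUC and precision-recall AUC use `1 − p` as
the score (ties midranked). Benchmark AUCs pool all (run, cell type)
pairs; per-run AUCs and run-level bootstrap percentile intervals
(default 50 resamples) are also available. The baseline is Fisher's exact
test on replicate-pooled counts per condition, two-sided by the
minimum-likelihood convention (the scipy/R default, verified against
hypergeometric enumeration and R's `fisher.test`).

A note on Monte-Carlo precision: the pooled ROC AUC of one 50-run
benchmark experiment has a standard deviation of roughly 0.02–0.045
across seed blocks (measured over 1000 runs). The acceptance script
therefore averages six replicate 50-run experiments (300 runs total) so
the reported means are accurate to about ±0.01; single 50-run
realizations can differ from the long-run value by ±0.05.

## Problem sizes used in the test suite

Chosen as the package's own verification budget: the benchmark tests use
50 runs (one experiment), calibration tests 200 null datasets (type-I
band) and 200 LRT repetitions at 40 samples per fit (KS uniformity, the
regime where the chi-square reference applies), EM monotonicity 100
random instances, and grid-search oracles on ≤ 4-observation fits. The
full suite runs in a few minutes on one CPU.

## Known limitations

- The similarity matrix is treated as known and shared across samples;
  uncertainty in an *estimated* M is not propagated into the test.
- EM corrects each sample's point composition; it does not produce a
  posterior over `z`, and corrected integer counts inherit rounding at
  the ±1 cell level.
- The LRT is anticonservative at very small replicate numbers (see
  above); with two replicates per condition, p-values near the threshold
  deserve caution.
- Reference-group normalization presumes the reference types are truly
  stable; a contaminated reference biases all tests toward the
  contaminant's direction.
- `detect_reference` uses the shortest-prefix rule on the p-value
  ranking; when many types change, the prefix can still contain changed
  types.
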