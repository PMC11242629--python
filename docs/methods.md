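# Methods

This note documents the statistical model behind `glmqlmas`, the choices
made where the design was genuinely open, and what the synthetic-data
validation does and does not demonstrate.

## Count model and differential expression

Counts `y_gi` for gene *g* in sample *i* are modeled as negative binomial
with log link,

    log mu_gi = x_i' beta_g + log N_i,      Var(y_gi) = mu_gi + phi mu_gi^2,

where `x_i = (1, group_i)` with the ALNM− group as reference (a positive
group coefficient means higher expression in ALNM+), `N_i` is the TMM
effective library size used as an offset, and `phi >= 0` is the NB
dispersion (`phi = 0` is Poisson). Fitting is iteratively reweighted least
squares with working weights `mu/(1 + phi mu)`, vectorized over genes;
convergence requires both a relative deviance plateau (`< 1e-10`) and the
weighted score equations satisfied below `1e-7` per coefficient, capped at
100 iterations (non-convergence is flagged, never fatal). The linear
predictor is clipped at ±50 so groups with all-zero counts converge to a
finite boundary fit whose score residual is numerically zero.

**Dispersion.** A single common `phi` is estimated by maximizing the summed
Cox–Reid adjusted profile log-likelihood (`sum_g [loglik_g - 0.5 log det
X'W_gX]`) over `log phi` in `[log 1e-8, log 10]` with a bounded scalar
search (tolerance 1e-4 on the log scale; warm-started coefficients). A
method-of-moments estimate is the fallback if the search fails.
Gene-to-gene variance heterogeneity is carried by the quasi-likelihood
layer, not by per-gene `phi`; trended/tagwise dispersion is deliberately
out of scope.

**Quasi-likelihood moderation.** Per-gene dispersions `s2_g = D_g/d_g`
(deviance over residual df) are treated as scaled chi-square draws around a
gene-specific true value with a scaled inverse chi-square prior. The prior
`(d0, s2_0)` comes from moment-matching mean and spread of `log s2_g`
using digamma/trigamma identities (Newton trigamma inversion). When the
observed spread does not exceed the pure chi-square component, `d0` is
infinite and `s2_0` is the plain mean of the `s2_g` — the unbiased scale
estimate in that regime, and the choice that makes a degenerate all-equal
input an exact fixed point of the moderation. Otherwise the moderated value
is the df-weighted average `(d0 s2_0 + d_g s2_g)/(d0 + d_g)`.

**Test.** `F_g = (D_reduced,g − D_full,g)/s2_g,post` referred to
`F(1, d0 + d_g)` (infinite `d0` handled as a very large denominator df).
Deviance differences in `[-1e-8, 0)` are clamped to zero; anything more
negative is a hard numerical error. p-values are clamped at `1e-300` so
`log10 p` stays finite downstream. BH is the step-up procedure
(`min_{j>=i} min(1, m p_(j)/j)` on the sorted scale); Bonferroni is
`min(1, m p)`.

## TMM normalization

For sample *t* against reference *r*, genes positive in both contribute
`M_g = log2((y_t/N_t)/(y_r/N_r))` and `A_g = 0.5 log2((y_t/N_t)(y_r/N_r))`.
The top/bottom 30% by M and 5% by A are trimmed (tie-aware average ranks;
survivors are the intersection), and the factor is `2^(sum w M / sum w)`
with inverse delta-method-variance weights
`w = 1/((N_t−y_t)/(N_t y_t) + (N_r−y_r)/(N_r y_r))`. The reference is the
sample whose 75th percentile of library-scaled counts is closest to the
mean of those quartiles (ties to the lowest index). All factors are
rescaled to geometric mean exactly 1. Degenerate cases (no shared positive
genes, nothing surviving the trim, a non-finite weighted mean) fall back to
factor 1 with a logged warning. Note that because the weights depend on
sequencing depth, the factor is only approximately invariant (to a few
percent) under rescaling one sample's counts and library by a constant;
M, A and the trimming are exactly invariant.

Log-CPM uses `log2(1e6 (y + p_i)/(L_i + 2 p_i))` with effective library
`L_i` and prior `p_i = prior · L_i / mean(L)` (default prior 1), which is
strictly monotone in `y`.

## MAS ranking and the threshold sweep

`MAS = |log2FC|^M |log10 p_adj|^A`, default `M = A = 1`. The gate is
`p_adj < alpha` (default BH, alpha 0.05) and strictly `|log2FC| > t`
(default t = 1; boundary genes excluded). Ties in MAS break by larger
|log2FC|, then lexicographic gene ID — an artifact choice, deterministic
and documented. Because the score itself never depends on `t`, the top-k at
any threshold equals the threshold-0 ranking restricted to genes passing
it; the sweep table makes this stability observable.

## Balanced resampling

Iteration *i* seeds its own generator with `base_seed + i`, draws
`subsample_size` (default: minority size) majority samples without
replacement, and re-runs the full analysis — TMM re-normalization included,
since normalization is part of the pipeline being stress-tested — with BH
applied within the genes analyzed in that iteration. Genes all-zero in a
subsample are dropped for that iteration and count as not significant.
Qualification (strict reading): same-direction significant count
`>= ceil(R/2)` with **zero** opposite-direction occurrences; the laxer
reading (opposite `< ceil(R/2)`) is available via
`allow_opposite_count=True`. Full-consistency genes (count = R) form the
"strongest" tier. Iterations are exchangeable given their derived seeds, so
any execution order reproduces the same summary.

## Over-representation analysis

Hypergeometric upper tail `P(X >= k)` for overlap `k` between an `n`-gene
list and a `K`-member set within an `N`-gene universe; one-sided enrichment
only. The working universe is the analyzed genes intersected with the union
of collection members (the conservative ORA convention; configurable).
q-values are BH-adjusted p within each tested collection — no Storey
estimation. This is an overlap test of the style that reports "overlap
genes" per set; the ranked running-sum enrichment statistic is a non-goal.

## Separability diagnostics

Projections run on gene-standardized log-CPM. PCA is the SVD of the
centered sample-by-gene matrix with signs fixed so each component's
largest-magnitude loading is positive. Logistic regression is unregularized
maximum likelihood (Newton, tolerance 1e-10, cap 100); perfect separation
is detected by diverging fitted log-odds and flagged while metrics are
still reported from the capped fit. Metrics are resubstitution on the full
cohort, by design: these analyses illustrate separability of the data, not
out-of-sample prediction, and are labeled accordingly. AUC uses the
tie-aware rank-sum (Mann–Whitney) formulation. LDA1 is the Fisher direction
`(S_pooled + lambda I)^{-1}(mu_+ − mu_-)` with ridge
`lambda = 1e-6 × mean diag(S_pooled)` (pseudo-inverse fallback), and the
separation fraction is the accuracy of the midpoint-threshold rule on the
projection.

## Synthetic cohorts

The generator emulates the study design the pipeline assumes: a gene
universe with a protein-coding subset, an unbalanced two-group cohort
(default 65 ALNM− vs 42 ALNM+, with optional extra samples carrying
missing status or treatment flags for the cohort filters), gamma-Poisson
(NB) counts with configurable `phi`, log-uniform baseline means over
`e^1..e^8` expected counts (spanning shallow and deep genes so trimming and
discreteness are exercised), log-normal library-size factors (sigma 0.3),
a planted DE fraction with signed log2 fold changes drawn from a configured
magnitude set (planted among coding genes so recovery survives the coding
restriction), and optional composition bias: a fraction of genes expressed
at 20× baseline in the ALNM+ group only, which decouples true sequencing
depth from the library size — precisely the failure mode TMM corrects.
One master seed feeds fixed per-component substream offsets (structure 0,
library sizes 1, counts 2, gene sets 3), so components are independently
reproducible.

What the generator does **not** emulate: batch effects, gene–gene
correlation beyond the shared group effect, length/GC biases, isoform
structure, or read-level noise. Passing tests therefore demonstrate
statistical correctness and calibration of the machinery under the assumed
model, not robustness to every artifact of real cohorts.

## Validation conditions and problem sizes

The test suite and `scripts/acceptance.py` run at desk scale, chosen as the
smallest sizes at which the checked properties are statistically stable:
2,000 genes for calibration and power checks (type-I error on a 21 vs 21
null; recall/FDR on 65 vs 42 with 10% planted |log2FC| = 2 at `phi` = 0.1),
50 balanced resampling iterations as a scaled-down stand-in for the full
500 (the qualification rule scales as `ceil(R/2)`), and a 3,000-gene,
1%-planted, `phi` = 0.4 cohort for the before/after-selection diagnostic —
conditions diluted enough that the full-matrix principal components do not
already separate the groups, so the benefit of selection is visible. That
diagnostic ranks with a 0.5 |log2FC| gate because its planted effects are
at 1–1.5 and the gate is strict. Oracles are independent straight-line
implementations (definitional BH, the TMM formula, combinatorial
hypergeometric enumeration, pairwise AUC counting, Poisson-limit GLM fits
against statsmodels) frozen in the tests.

## Known limitations

* Common (not trended/tagwise) NB dispersion; on real data with a strong
  mean–dispersion trend the QL layer absorbs less of the heterogeneity
  than a trended fit would.
* Deviance-based (not Pearson-based) quasi-dispersions; residual df are
  not adjusted for fitted zeros.
* Single two-level factor only (`df_test = 1`); no covariates.
* ORA ignores gene-set topology and gene length; identifiers are matched
  verbatim.
* The cohort filters assume clean boolean treatment flags; harmonizing
  messy clinical records is out of scope.
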