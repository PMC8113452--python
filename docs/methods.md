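# Methods

This note documents the statistical models, numerical choices, and design
decisions behind `gdprisk`, and what the synthetic-data experiments do and
do not demonstrate about behavior on real data.

## Study design and data model

The package targets retrospective (case-control) genetic association
studies in small, admixed cohorts.  The core container is a sample ×
variant matrix of alternate-allele dosages in [0, 2] (imputed expected
counts or hard-call 0/1/2), joined to per-sample covariates: case/control
status, sex, age, BMI, smoking status, and estimated global ancestry
proportions for four components (EAS, SAS, EUR, AFR) that sum to one.
Variants carry a per-variant imputation quality r² in [0, 1]; directly
genotyped variants carry none and are exempt from the r² filter.

Coordinates are 1-based as in VCF; the alternate allele is the counted
allele for both dosage and effect orientation.  Multiallelic VCF records
are skipped with a logged warning rather than split: every downstream
method is defined on biallelic dosages, and silent splitting invites
allele-orientation mistakes.  Missing dosages are mean-imputed per variant
at analysis time — the standard GWAS convenience that keeps design
matrices complete while leaving MAF estimates unchanged.

## QC filters

Two sequential filters, thresholds strict as printed in study protocols:
imputed variants with r² < 0.3 are removed first, then variants with
MAF < 0.01.  MAF is the folded frequency min(f, 1−f) with f =
mean(dosage)/2, computed on the pooled analysis sample (cases plus
controls); pooling is the common choice where the protocol does not state
otherwise.  Counting is sequential, so a variant failing both filters is
attributed to the r² filter; the retained *set* is order-invariant.

## Marginal scan

Each variant is tested by maximum-likelihood logistic regression of
status on dosage plus covariates, fit by Newton–Raphson with step-halving
(convergence: max |score| < 1e−8 or relative log-likelihood change
< 1e−10, at most 100 iterations; covariance is the inverse observed
information).  P-values are two-sided Wald — the quantity standard GLM
output reports.  Continuous covariates are standardized for conditioning;
this cannot change the dosage effect's Wald statistic (affine
reparameterization), which a test asserts.  The EAS ancestry proportion
is dropped to break the sum-to-one collinearity; SAS/EUR/AFR enter.

Separation (estimates diverging past |β| = 15 with a non-vanishing score)
is flagged and the variant excluded from ranking rather than penalized —
keeping the scan's semantics pure ML.  Genome-wide flagging uses strict
p < 5×10⁻⁸.  Replication lookup matches catalog entries by variant id,
falling back to chromosome + position; effects are re-signed to the
catalog risk allele when it equals REF or ALT, otherwise orientation is
reported unknown.  Replication is flagged at strict p < 0.05.

## Bayes-factor screening

Candidates for the joint model are the top K = 200 variants by a
single-SNP Bayes factor against the covariate-only null, adjusted for
sex, age, BMI and smoking (no ancestry at this stage).  K ≈ n keeps the
joint design workable at the study's sample size.  The default BF is
Wakefield's asymptotic approximation

  BF₁₀ = √(V/(V+W)) · exp(z²W / (2(V+W))),  V = se², z = β̂/se,

with prior effect variance W = 0.25 (SD 0.5 on the log-odds scale, a
conventional weakly-informative choice for disease odds ratios); a
BIC-approximated BF (exp((BIC₀−BIC₁)/2)) is available as an alternative
mode.  Both are computable from the marginal fit; the choice and W are
recorded in output config.  Ranking is deterministic: descending log₁₀ BF,
ties broken by ascending p, then genomic position; non-converged variants
rank last.

## The polygenic model

The joint model is logistic regression of status on an unpenalized
intercept, the covariates (sex, age, BMI, smoking — ancestry excluded by
default, configurable) and the screened SNP dosages, with the generalized
double Pareto (GDP) prior on every non-intercept coefficient:

  f(β) = 1/(2ξ) · (1 + |β|/(αξ))^−(α+1),  ξ = η/α,

a heavy-tailed shrinkage prior whose MAP estimates can be exactly zero.
All non-intercept predictors are standardized internally and coefficients
are reported on the standardized scale (scaling constants stored and
reapplied at prediction); this makes a single penalty scale meaningful
across binary covariates and dosages of widely varying frequency.

### EM-MAP algorithm

The GDP is a Laplace scale mixture with Gamma mixing, so EM over the
latent scales yields an E-step of per-coefficient weights
w_j = (α+1)/(|β_j|+η) and an M-step maximizing
loglik(β) − Σ_j w_j|β_j| — a weighted-L1 (adaptive-lasso-like) problem
whose soft-threshold coordinate updates produce exact zeros.  The
normal-scale-mixture alternative was rejected because its ridge-like
M-step never yields exact zeros.

Each outer iteration refreshes the EM weights and a quadratic surrogate
of the logistic log-likelihood at the current coefficients, then solves
the resulting penalized quadratic by cyclic coordinate descent with
active-set passes (inner tolerance 1e−10 on the largest coefficient move,
at most 200 passes).  Two curvatures are available:

- `bound`: the global bound Hessian ⪯ XᵀX/4 — every step provably
  increases the MAP objective;
- `irls` (default): current IRLS weights p(1−p) floored at 1e−6 —
  Newton-like convergence, safeguarded by an explicit acceptance check on
  the true MAP objective with automatic fallback to the 1/4 bound for any
  step that fails it.

This surrogate-refresh design keeps the exponential out of the inner
loop; it is roughly 20× faster than coordinate descent directly on the
logistic objective at identical solutions (checked to ~2×10⁻⁴), which is
what makes the multi-seed recovery experiments affordable.  The penalized
MAP objective loglik + Σ log f(β_j) is asserted non-decreasing (up to
1e−9 relative rounding slack) at every outer iteration; a decrease is an
error, never a warning.  Outer convergence: relative objective change
below 1e−8, at most 500 iterations.  Coefficients below 1e−8 in magnitude
are reported as exactly zero.

### Hyperparameter selection

Hyperparameters are chosen by BIC = −2·loglik + df·log n with df = the
nonzero-coefficient count including the intercept (the standard L1-path
accounting).  The default search fixes the shape at α = 1 — the canonical
GDP default, giving Cauchy-like tails — and sweeps the rate η over a
25-point geometric path from 0.003 to 10, traversed from the strongest
penalty (empty model) to the weakest with warm starts.  Continuation in
this direction is the standard stabilization for non-convex penalties:
the objective is multimodal, and coarse or cold-started searches proved
chaotically sensitive to the exact grid placement (small grid shifts
flipped solutions between empty, sparse and avalanche modes).  A wide
2-D grid over (α, η) was evaluated and rejected as the default: very
heavy tails (α ≤ 0.5) barely shrink whichever coefficients survive
thresholding, which makes the df ≈ nonzero-count approximation in BIC
overly optimistic and inflates false selections, while the search space
α ∈ {0.1..3} × η ∈ {0.25..10} cannot express the sparse regime at all for
~200 candidates at n in the hundreds (its best BIC sits at the strongest
corner with df in the tens).  `bic_select` accepts any grid for users who
want the 2-D search.  Ties (exactly equal BIC) break toward smaller df,
then larger η.

### A known limitation of BIC here

With m candidate predictors under a global null, the largest single-SNP
improvement in 2·loglik concentrates near 2·ln m, while BIC charges only
ln n per coefficient.  For m ≈ 200 candidates at n ≈ 400, 2·ln m ≈ 10.6 >
ln n ≈ 6, so the BIC-optimal model over a well-searched path genuinely
contains the top one-to-several noise variants; in our pure-noise
experiments the selected model is SNP-free in only ~40% of seeds.  This
is a property of BIC-on-support model selection in the m² > n regime, not
of the optimizer — indeed weaker searches mask it precisely by failing to
find the better-BIC models.  Users wanting conservative null behavior
should prefer a criterion with a multiplicity-aware penalty (e.g. an
extended-BIC-style df·(log n + 2γ·log m)) — deliberately not the default
here, which follows the plain-BIC definition above.  Under planted-effect
conditions (five causal SNPs with |β| ∈ [0.6, 1] among 200 candidates,
n = 400) the default recovers a median 5/5 causal variants with a median
≤ 3 false selections and correct signs across 50 seeds.

### Prediction and reporting

Predicted risk is the logistic inverse link applied to the stored
intercept plus standardized predictors times coefficients; only
predictors with nonzero coefficients are required.  The model report
lists the intercept and covariates first (including exact zeros — their
exclusion is informative), then each nonzero SNP with chromosome,
position, optional gene-context annotation from user-supplied intervals,
reference allele, sample MAF, and the standardized-scale estimate.
Published tables of this kind print covariate effects on unstated scales;
we standardize and say so rather than guessing a per-unit scale.

## Cohort statistics

Continuous characteristics: Welch's unequal-variance t with Satterthwaite
df, computable from raw samples or printed (mean, SD, n) summaries.
Categorical 2×2: Pearson chi-square with Yates continuity correction by
default — required to reproduce conventional published values for
near-null tables (the uncorrected statistic overstates significance at
these counts).  r×c tables: Pearson chi-square, plus a seeded Monte-Carlo
p under fixed margins (default 10⁵ tables via the multivariate
hypergeometric sampler) whenever any expected count is below 5, where the
asymptotic reference is unreliable.  The Monte-Carlo p was cross-checked
against R's `chisq.test(simulate.p.value=TRUE)` during development.
Ancestry-proportion comparisons are reported descriptively (Welch t on
per-sample proportions); proportions are compositional and these rows are
not treated as calibrated tests.

## Synthetic cohorts

The generator emulates the study conditions: default 84 cases / 89
controls; sex ~ Bernoulli(0.57 male); age ~ Normal(52, 14) truncated at
18; BMI ~ Normal(23, 3.5) truncated above 10; smoking ~ Bernoulli(0.25)
in the population; ancestry ~ Dirichlet(92, 7, 1, 0.1), concentrated on
EAS as in the study population.  Default covariate log-odds (sex 0, age
+0.25/SD, BMI −0.8/SD, smoking +1.3) reproduce the study's observed
case-control imbalances — smokers strongly enriched in cases, BMI lower
in cases, age mildly higher — and the default five causal variants carry
|OR| ≈ 1.8–2.2, the magnitude of the study's replicated locus.

Genotypes use a Gaussian-copula threshold model: within each block of 10
variants a latent AR(1) normal vector (ρ = 0.5 by default) is thresholded
at each variant's allele-frequency quantile to give one haplotype;
dosage = sum of two independent haplotypes, so Hardy–Weinberg holds by
construction.  Allele frequencies are uniform on [0.05, 0.5]; simulated
imputation quality is uniform on [0.2, 1.0] so the QC stage has work to
do.  Continuous covariates are standardized inside the risk model using
the generating distribution's nominal moments, making stated effects
per-SD (truncation shifts the realized moments slightly; the discrepancy
is immaterial at the simulated effect sizes).  Disease status follows the
logistic model and the population is drawn in batches until the requested
case and control counts accrue, mirroring retrospective sampling — slopes
are estimable, the intercept absorbs the sampling fractions.

What this does *not* emulate: realistic recombination maps and long-range
LD, allele-frequency spectra from demography, genotyping batch effects,
HWE violations, covariate measurement error, or confounding between
ancestry and genotype (ancestry is drawn independently of the genotype
copula).  Passing recovery tests here therefore demonstrates correctness
of the estimation machinery under the stated model, not robustness to
population-genetic complications — in particular, the scan's clean type-I
calibration on synthetic nulls says nothing about stratification bias in
real admixed data, which is why the ancestry covariates exist.

## Problem sizes and reproducibility

The test-suite experiments use cohorts of n = 400 (200/200) with 200–1000
variants and 50–100 seeded replicates, and the study-scale pipeline runs
at n = 173 with 1000 variants — sizes chosen so the full suite exercises
every stage end-to-end in a few minutes on one core.  All randomness
flows from explicit integer seeds through `numpy.random.default_rng`;
identical config + seed reproduces every output byte-for-byte, and the
CLI stamps each run with a config hash and seed in a JSON manifest.
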