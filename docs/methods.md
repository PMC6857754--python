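# Methods

This note documents the statistical machinery in `mrphewas`: the models, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that matter.

## Study design

The package implements an MR-PheWAS: a weighted multi-SNP score proxies a
quantitative exposure (log 25-hydroxyvitamin D in the motivating
application); the score is scanned against many diagnosis-code phenotypes
(a flat logistic PheWAS and a tree-structured Bayesian scan); outcomes with
adequate power and either a scan signal or prior literature evidence go
forward to formal MR estimation with three estimators. The package's own
contributions are the tree-scan posterior computation, the MR estimator and
power formulas, and the cohort generator; routine model fits (logistic, OLS,
WLS, ANOVA) are delegated to statsmodels/scipy.

## Genetic-risk score and instrument QC

The score is `GRS_i = Σ_j w_j g_ij` with `g_ij ∈ [0, 2]` effect-allele
dosages. Weights are expressed per effect allele; a single `InstrumentPanel`
object is shared by the simulator and the score builder so allele
orientation cannot drift between them. The bundled six-SNP vitamin D panel
carries allele frequencies derived from published biobank genotype counts;
its weights are **documented placeholders** (the source-GWAS per-SNP
estimates are not redistributable here) and should be replaced by users.

Missing dosages are resolved by one of three policies: `mean_impute`
(substitute 2×frequency; the default, mirroring common score pipelines),
`rescale` (per-individual reweighting by observed |w| mass), or `drop`.
The policy is recorded in the QC report.

Hardy–Weinberg equilibrium is tested two ways: a 1-df χ² goodness-of-fit
against expected counts at the sample allele frequency (the headline,
because exact-test conventions vary between tools) and the exact mid-p test
conditioning on allele counts, evaluated over the full heterozygote-count
support with log-gamma arithmetic so biobank-scale counts are exact.
Monomorphic SNPs get p = 1 by convention and a flag.

Confounder balance follows the usual orientation for score QC tables:
continuous covariates are regressed **on** the score (slopes are in
covariate units); categorical covariates use one-way ANOVA of the score
across levels. Instrument strength uses the single-predictor identity
`F = (n−2)R²/(1−R²)`.

## Flat PheWAS

ICD10 records map to phecodes; an individual is a case for a phecode if any
record maps to it, excluded from that phecode's controls if any record maps
into its exclusion range (this removes diagnostically adjacent individuals
from the comparison group), and a control otherwise. Sex-restricted
phecodes drop wrong-sex individuals. Phecodes enter the scan only with
strictly more than 200 cases (the conventional PheWAS power floor).

Each tested phecode is fitted by maximum-likelihood logistic regression of
case status on the score plus covariates (assessment centre one-hot encoded;
coordinates continuous). Non-convergence and separation produce a flagged
row rather than an exception; flagged rows are never called significant.
The multiple-testing denominator is the number of attempted tests.
Significance is Bonferroni at α/m; results with p < 10⁻³ are additionally
flagged "suggestive" for reporting.

The bundled phecode map and ICD10 tree are deliberately small toy fixtures
(≈30 codes, 3 levels) for tests and demos; real maps are user-supplied CSVs
because the curated maps are external resources with their own licences.

## Tree-structured Bayesian scan

Diagnosis codes form a rooted tree; a node's case set is the union of
individuals carrying any descendant-or-self code. Each estimable node v
contributes a summary likelihood: the per-node covariate-adjusted logistic
fit yields `b̂_v` (log-odds per score unit) and `se_v`, treated as
`b̂_v ~ N(β_v, se_v²)`. This large-sample (summary-likelihood) reduction
keeps the scan at one regression per node plus one message pass, instead of
a full per-node genotype likelihood.

The latent effect state `s_v ∈ {0, 1}` follows a Markov process on the tree:
root ~ Bernoulli(π₁); a child copies its parent's state with probability ρ
and otherwise redraws from the stationary law (1−π₁, π₁). This transition
kernel is reversible and leaves the root marginal well defined. Under
`s_v = 0` the node likelihood is `N(b̂_v; 0, se_v)`; under `s_v = 1` it is
the uniform average of `N(b̂_v; e, se_v)` over a discrete effect grid.
Defaults: π₁ = 0.001, ρ = 0.99, grid ±{0.05, 0.1, 0.2, 0.4} on the log-odds
scale — a sparse prior with strong parent-child persistence; all three are
config-overridable and logged. Inestimable nodes (zero cases or failed fits)
carry a flat likelihood rather than being pruned, preserving connectivity.

Per-node posterior probabilities of `s_v = 1` are computed exactly by
upward–downward sum-product message passing with per-message normalization
(posteriors are scale-free, so this only guards against underflow; a
log-space fallback handles far-tail likelihoods). The test suite checks the
pass against exhaustive enumeration over all 2^n state configurations on
random trees up to 12 nodes. Nodes with posterior probability strictly
greater than 0.75 are reported significant. The posterior mean effect
combines the state posterior with the per-node grid posterior; given
`s_v = 1` effects are modelled as independent across nodes, so the grid
posterior uses only the node's own likelihood.

## MR estimators

All effects are per unit log-exposure internally and converted for reporting
via `OR = exp(β·SD)`, `CI = exp((β ± 1.959964·se)·SD)` with SD = 0.430 by
default (the log-exposure SD in the external reference panel).

- **Wald ratio** (building block): `β = b_Y/b_X`, `se = se_Y/|b_X|`
  (first order).
- **IVW**: fixed-effect weighted combination
  `β = Σ(b_X b_Y/σ_Y²) / Σ(b_X²/σ_Y²)`, `se = (Σ b_X²/σ_Y²)^{-1/2}` —
  identical to zero-intercept WLS of b_Y on b_X with weights 1/σ_Y², and to
  the Wald ratio for one SNP.
- **MR-Egger**: WLS of b_Y on b_X with a free intercept, after orienting
  every SNP so b_X > 0 (required for the intercept to mean average
  directional pleiotropy). Standard errors carry a multiplicative
  overdispersion factor floored at 1 — the estimated residual scale is never
  allowed to shrink SEs below the fixed-effect value. Identical b_X across
  SNPs makes the slope non-identifiable and raises.
- **Two-stage**: stage 2 regresses the outcome on the score (logistic for
  binary outcomes — chosen over a control-function formulation for
  transparency — OLS otherwise) with covariates; `β = b₂/b₁` with an
  **external** first-stage coefficient b₁, matching designs where the
  exposure is unmeasured in the analysis cohort and the first stage comes
  from a reference panel. First-stage uncertainty propagates by the delta
  method: `se² ≈ se₂²/b₁² + b₂²·se₁²/b₁⁴`.

p-values use the normal reference throughout. Case sets from electronic
medical records and self-report merge by union with provenance counts
(EMR-only / SR-only / both).

## Power model

For a binary outcome with N individuals, case fraction K, instrument R² and
alternative OR per SD:

    power = Φ( √(N·R²·K(1−K)) · |ln OR| − z_{1−α/2} )

The non-centrality is the expected Wald z of the score coefficient in a
case-control logistic model; using z_{1−α/2} but only the favourable
rejection region gives power α/2 at the null, the convention of the standard
MR power calculators. The continuous-outcome form drops K(1−K). The
minimum-case inversion fixes K = 1/(1+ratio), sets N = cases×(1+ratio), and
bisects on the integer case count; power is monotone in all arguments (and
symmetric in OR ↔ 1/OR), so bisection is exact.

## Synthetic-data generator

The generator reproduces the statistical structure the analysis assumes:

- **Genotypes**: per-SNP dosages ~ Binomial(2, f), independent across SNPs —
  Hardy–Weinberg holds by construction. Default frequencies are the
  bundled panel's biobank-derived values.
- **Exposure**: `x = c·(GRS + ε)` with ε Gaussian, its variance solved so
  var(GRS)/var(GRS+ε) equals the target R² (default 0.0284), and c chosen
  so SD(x) equals the target SD (default 0.430). The realized OLS slope of
  x on GRS is returned as the first-stage coefficient.
- **Outcomes**: `logit P(case) = α + ln(OR)·x/SD + γ'z`; α is solved by
  root-finding (Brent's method on [−30, 30], tolerance 10⁻³ on the marginal
  case probability) so the expected prevalence hits its target exactly
  regardless of the covariate structure.
- **Diagnosis records**: cases emit their mapped leaf codes; optional
  sibling leakage (each case also emits a random sibling leaf with given
  probability) creates the tree-correlated signal the hierarchical scan is
  designed to exploit; background codes are emitted at a configurable rate.
- **Validity switches**: by default covariates are independent of genotype,
  so the instrument is valid and balance tests are true nulls.
  `confounder_effects` adds covariate→exposure and covariate→outcome paths;
  `pleiotropy_effects` adds direct SNP→outcome paths for exercising the
  Egger intercept test.

Not emulated: linkage disequilibrium between panel SNPs, population
structure beyond independent PC covariates, ICD9 coding, coding error /
reporting bias in diagnosis records, and non-collapsibility-scale effects of
rare strong confounders. Passing tests on this generator therefore show the
pipeline's statistical machinery is correct under its stated assumptions —
not that real-biobank data quirks (relatedness, batch effects, phenotype
misclassification) are handled.

## Problem sizes and numerical choices in the test suite

Calibration suites use sizes chosen to make Monte-Carlo error small relative
to the asserted bands: estimator recovery and CI coverage run 200 replicates
at n = 50,000; scan family-wise-error calibration runs 500 replicate scans
of 100 phenotypes at n = 5,000; enumeration oracles cover trees to 12 nodes
(4096 configurations). Estimator-recovery checks use a continuous outcome so
the true causal coefficient is exactly defined (logistic marginal effects
are attenuated by non-collapsibility, which would blur a coverage check);
null-calibration checks use binary outcomes. Fixed seeds make every
stochastic test reproducible.

## Known limitations

- The Egger SE floor makes its intercept test conservative, not exact.
- Phecode map semantics implement the core case/control/exclusion/sex rules;
  niceties of specific released map versions (code ranges expressed as
  patterns, multi-level roll-ups) are out of scope.
- The tree prior's hyperparameters are defaults, not estimates; posterior
  probabilities are only as calibrated as π₁ and ρ are appropriate for the
  phenome at hand.
- The two-stage estimator with a binary outcome targets the logistic
  coefficient scale of the score model; with strong covariates this is not
  numerically identical to the summary-level IVW estimand.
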