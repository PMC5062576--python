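# Methods

## Model and procedure

### Per-study association

Each study's phenotype (case = 1, control = 0) is regressed on variant
dosage under an additive model by maximum-likelihood logistic regression,
with an intercept, study covariates and — in conditional analyses — the
dosages of index variants as extra columns.  The Wald statistic of the
dosage term gives the per-study log-OR β̂, its standard error and a
two-sided p-value.  The Newton–Raphson solver is implemented in the package
(with step-halving, a divergence guard at |coef| > 30 on the logit scale,
and singular-Hessian detection): a locus scan refits every variant in every
study at every conditioning round, and replicate simulations multiply that
by thousands, so per-fit cost matters; the solver is validated against an
independent general-purpose ML fitter in the test suite to 10⁻⁶ on
coefficients and standard errors.  Non-converged or separated fits are
flagged and dropped from meta-analysis for that variant rather than
aborting the pipeline.  A conditioning dosage with r² > 0.95 against the
test variant marks the result a "shadow of index": the fit is still
reported but the variant is barred from lead selection, since it carries no
information beyond the index it shadows.

QC follows the conventional thresholds, all inclusive (≥): per-study
MAF ≥ 0.01 and imputation info ≥ 0.4; variants observed in fewer than 80% of
the total individuals across studies are excluded from meta-analysis.
Inclusive boundaries are a deliberate convention (a variant at exactly the
threshold passes) and are unit-tested.

### Fixed-effects meta-analysis

Inverse-variance weighting: β = Σ w_s β̂_s / Σ w_s with w_s = SE_s⁻²,
SE = (Σ w_s)^(−1/2), OR CI = exp(β ± 1.96 SE).  Heterogeneity is assessed by
Cochran's Q = Σ w_s (β̂_s − β)² against χ²(k−1); a single study returns
(Q = 0, df = 0, p = 1) by convention.  Genome-wide significance is
P < 5×10⁻⁸.

### Bayesian partition-model meta-analysis

Per-study likelihoods use the summary-statistic normal approximation
β̂_s ~ N(b_s, SE_s²).  Studies are grouped by a centre-based partition
model: a non-empty centre subset C of the N studies induces a partition by
assigning every study to its nearest centre under the relatedness distance
(pairwise mean absolute effect-allele-frequency difference over shared
post-QC variants), ties to the lowest-index centre.  The prior over centre
sets is uniform over the number of centres T and uniform over sets of a
given T — (1/N)·C(N,T)⁻¹ — and centre sets inducing the same partition pool
their mass, so partition priors sum to 1.  All 2^N − 1 centre sets are
enumerated exhaustively; the implementation refuses more than 20 studies
(a sampling mode is deliberately out of scope).

Within a cluster, all member studies share one effect b ~ N(0, τ²);
clusters are independent.  The cluster marginal likelihood is therefore a
zero-mean multivariate normal with covariance diag(SE²) + τ²J, evaluated in
closed form via the Sherman–Morrison identity; the null fixes every effect
at zero.  The association Bayes factor is the partition-prior-weighted
marginal likelihood over the null; the heterogeneity Bayes factor compares
the partition-averaged model against the single-cluster model (all studies
sharing one effect).  All Bayes-factor arithmetic is in natural-log space
with max-subtraction; closed forms are verified against adaptive quadrature
to relative error 10⁻⁶ in the tests.

Clade reporting (the per-clade vs all-studies comparison) uses average-
linkage hierarchical clustering of the same relatedness matrix, cut at a
requested clade count or height.

### Distinct signals

Stepwise delineation: at round r every study is refit conditioning on the
current indexes, results are re-meta-analysed, and the lead variant
(maximal log₁₀ BF; ties by smaller position, then identifier) becomes a new
index only if it passes BOTH thresholds — log₁₀ BF ≥ 6 and fixed-effects
P < 5×10⁻⁸ — otherwise delineation stops.  A cap of 10 rounds guards
against pathologies.  Indexes are then refined by leave-one-out
conditioning (each signal re-scanned conditional on all other indexes)
until the index set is stable, with a 10-iteration oscillation guard that
returns the last state with a warning.  Delineation is deterministic given
the data.

### Credible sets

For one signal, π_j = Λ_j / Σ_k Λ_k over the post-filter locus variants,
computed in log space (Λ_j is the variant's conditional association BF for
multi-signal loci, unconditional otherwise).  The 99% credible set is the
minimal prefix of variants ranked by descending π (ties by position, then
identifier) with cumulative mass ≥ 0.99; the inclusive threshold means a
variant carrying exactly 0.99 forms a singleton set.  The reported span is
inclusive: max − min + 1 bp.  Normalizing over post-completeness-filter
variants (rather than all raw variants) is a deliberate choice: variants
the meta-analysis never evaluated cannot carry posterior mass.

### Annotation overlap

Variant positions are 1-based; BED intervals are 0-based half-open, so a
variant at position p overlaps [a, b) iff a ≤ p−1 < b.  The conversion is
fixed and unit-tested in both off-by-one directions.  Per-element summed
π highlights regulatory elements capturing a large share of a signal's
posterior mass.  Element/state labels are treated as opaque strings.

## The synthetic-data generator

The generator reproduces the statistical structure the analysis exploits,
at O(n) cost, without claiming coalescent realism:

- **Ancestral pool** — positions sampled without replacement in a region
  (default 100 kb, 60 variants), latent allele frequencies
  Uniform(0.05, 0.95), haplotypes from a latent Gaussian AR(1) process
  (ρ = 0.92) restarted at block boundaries (block sizes 4–10 variants),
  thresholded at each variant's frequency quantile.  This produces strong
  within-block LD and independent blocks.
- **Population drift** — per-variant target frequencies from the
  Balding–Nichols form Beta(p(1−F)/F, (1−p)(1−F)/F) around the ancestral
  empirical frequency p (target = p when F = 0).  Haplotypes are mosaics of
  ancestral templates with per-gap switch probability 1 − exp(−rate·gap);
  a minimal set of alleles is then flipped to hit the drifted target
  count.  Defining p as the ancestral *empirical* frequency makes the
  F = 0, switch_rate = 0 case an exact identity.  Larger F gives larger
  frequency divergence; different switch rates and seeds give divergent LD.
- **Case-control studies** — individuals pair two haplotypes drawn with
  replacement; disease follows logit P(case) = α + Σ β·g with the same β in
  every ancestry (the homogeneity assumption under test); rejection
  sampling fills the case and control quotas (cap 10⁷ draws).  Baseline
  α = logit(0.10), a typical adult type-2-diabetes prevalence.  Covariates
  are null (standard normal, independent of genotype and phenotype): they
  stand in for the principal components a real analysis adjusts for;
  confounded covariates are out of scope.
- **Causal placement** — planted causal variants must be common
  (MAF ∈ [0.05, 0.95]) in *every* derived population, because the scenario
  the method addresses is a causal variant shared and analysable across
  ancestry groups (common-variant signals are conventionally defined by
  lead MAF ≥ 5%); a variant drifted to rarity in one ancestry would be
  removed by per-study QC and could never be fine-mapped.  Multiple causals
  must be in weak mutual LD (ancestral r² ≤ 0.05).
- **Imputation degradation** — the info metric is the ratio of observed
  dosage variance to the Hardy–Weinberg expectation 2·EAF·(1−EAF), clamped
  to [0, 1] (imputation software outputs differ; this is the package's
  definition).  Degradation shrinks dosages toward 2·EAF by √target, which
  meets any target in (0, 1] exactly (up to HWE sampling noise) while
  preserving EAF and the [0, 2] bounds; a noise blend cannot reach targets
  below 0.5 without violating the bounds, so shrinkage was chosen.  Hard
  genotypes (target = 1) keep info = 1 by definition.
- **Annotation track** — non-overlapping fixed-length elements; with
  probability `enrichment` each causal position is covered by one.

What the generator does *not* emulate: population stratification
confounding, related individuals, X-chromosome dosage, genotyping batch
effects, strand ambiguity, and realistic recombination maps.  Passing tests
therefore demonstrate the statistical machinery is correct under its own
assumptions, not that real-data QC pathologies are handled.

## Numerical choices

- Logistic Newton–Raphson: convergence at max |step| < 10⁻⁸, 50 iterations,
  8 step-halvings; p-values floored at the smallest positive double so
  p ∈ (0, 1].
- Effect prior τ = 0.2 on the log-OR scale (spanning typical complex-trait
  ORs ~1.1–1.5); configurable.  Partition prior uniform over the number of
  centres and over centre sets given the number.  These are the package's
  choices for a partition model whose published description leaves them
  open.
- Tie-breaks are total orders everywhere randomness could creep in: lead
  selection and credible-set ranking break BF ties by position then
  identifier; nearest-centre assignment breaks distance ties by centre
  index.
- Every generator takes an explicit seed; identical arguments and seed give
  bit-identical output, and the pipeline is byte-reproducible end to end.

## Problem sizes

The demonstration scenario and the calibration experiments use: 60 variants
in 100 kb, three ancestries with F = 0.05/0.10/0.15 and distinct mosaic
switch rates, 3000 cases and 3000 controls per ancestry, allelic OR 1.3.
The test suite runs the coverage calibration on 150 loci (bound: nominal
0.99 minus two Monte-Carlo standard errors), the heterogeneity calibration
on 200 replicates at 600/600 per study, the resolution comparison on 100
loci at 1500/1500 with 40 variants, and the two-causal delineation study on
50 seeds at full size.  The acceptance script runs the coverage experiment
at 1000 loci.

## Known limitations

- Exhaustive partition enumeration limits the Bayesian meta-analysis to 20
  studies; beyond that a capacity error is raised by design.
- The summary-statistic normal approximation degrades for very rare
  variants or tiny studies; QC bounds the damage but the package does not
  implement exact genotype likelihoods or score tests.
- Conditional analysis refits each study from genotypes; approximate
  conditioning from summary statistics plus an LD reference is not
  implemented.
- Credible sets assume a single causal variant per (conditioned) signal;
  joint multi-variant configurations are out of scope.
- Allele harmonization trusts identifiers for strand-ambiguous (A/T, C/G)
  variants, which is safe for simulator-controlled data only.
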