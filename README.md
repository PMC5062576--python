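# transmap

Transancestral GWAS meta-analysis and Bayesian fine-mapping of distinct
association signals, with a built-in multi-ancestry case-control simulator.

## The problem

A common-variant association signal discovered by GWAS usually maps to a
broad interval: within one population, extensive linkage disequilibrium (LD)
makes dozens of variants statistically indistinguishable from the causal
one.  When the causal variant is shared across ancestry groups, combining
studies from populations with *different* LD structure sharpens
localization — a proxy variant that tags the causal haplotype perfectly in
one population will tag it imperfectly in another, while the causal variant
itself stays associated everywhere.  `transmap` implements that programme
for case-control traits:

1. **Per-study association** — additive logistic regression of phenotype on
   genotype dosage with study covariates, after per-study QC
   (MAF ≥ 1%, imputation info ≥ 0.4) and an 80%-completeness filter across
   studies.
2. **Fixed-effects meta-analysis** — inverse-variance weighting with
   Cochran's *Q* heterogeneity test.
3. **Bayesian transancestral meta-analysis** — a hybrid of fixed- and
   random-effects meta-analysis.  Studies are clustered by a centre-based
   Bayesian partition model of relatedness (pairwise mean absolute allele-
   frequency difference); within a cluster studies share one allelic
   log-OR *b* ~ N(0, τ²); the marginal likelihood is averaged over all
   partitions.  This yields a Bayes factor for association, Λ, and a Bayes
   factor for heterogeneity (unconstrained clustering vs a single shared
   cluster).
4. **Signal delineation** — stepwise conditional analysis: a variant indexes
   a distinct signal only if it attains log₁₀ Λ ≥ 6 *and* fixed-effects
   *P* < 5×10⁻⁸ in conditional meta-analysis; indexes are then refined by
   leave-one-out conditioning.
5. **Credible sets** — for each signal, the posterior probability that
   variant *j* drives it is π_j = Λ_j / Σ_k Λ_k; the 99% credible set is the
   minimal BF-ranked prefix with cumulative mass ≥ 0.99.
6. **Annotation overlap** — credible-set variants intersected with
   regulatory elements (BED, 0-based half-open), reporting summed π per
   element.

Because the real inputs of such analyses are consortium-held genotypes, the
package ships a first-class generator (`transmap.simdata`) that reproduces
the two properties the method exploits — allele-frequency divergence
(Balding–Nichols drift) and LD divergence (haplotype mosaics) — plus
case-control ascertainment and imputation-quality degradation.

## Worked example

```python
import transmap as tm

bundle = tm.run_pipeline(tm.PipelineConfig(seed=7))
print(bundle.signal_table[["INDEX_SNP", "OR", "P", "LOG10BF", "LOG10BF_HET"]])
```

```
  INDEX_SNP        OR             P    LOG10BF  LOG10BF_HET
0   var0011  1.294232  2.471793e-28  24.767848    -0.402955
1   var0056  1.251238  7.594748e-24  20.401512    -0.387207
```

The default scenario plants two weakly linked causal variants with allelic
OR 1.3 shared across three drifted ancestries (3000 cases / 3000 controls
each).  The pipeline recovers exactly two distinct signals; here both index
SNPs *are* the planted causals (`bundle.provenance["causal_variants"]`).
The negative heterogeneity log-BFs say the allelic effects are consistent
with being identical across ancestries, as simulated.  The conditional ORs
≈ 1.29 and 1.25 estimate the planted 1.3, and each signal's 99% credible set
(`bundle.credset_table`) collapses to a single variant in the combined
analysis — the resolution gain transancestral meta-analysis is built for.

The same run from a shell:

```sh
transmap run-all --seed 7 --out demo_out    # all stages, all TSV outputs
transmap simulate --seed 7 --out demo_out   # or stage by stage
```

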