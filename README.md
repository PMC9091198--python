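# vntrstat

Association testing for VNTR polymorphisms that SNP arrays cannot genotype,
using either individual-level data or nothing but published GWAS summary
statistics.

## The problem

Variable-number-tandem-repeat (VNTR) polymorphisms — the canonical example
being the serotonin transporter promoter repeat (5-HTTLPR), with a long (L)
and short (S) allele — are invisible to SNP genotyping arrays, so they were
left behind by the GWAS era. A VNTR can, however, be predicted from nearby
tag SNPs in linkage disequilibrium with it. Given a small reference panel
genotyped for both the VNTR and its tag SNPs, a linear model

    g = δ + γ₁x₁ + … + γ_m x_m + ε

(with `g` the count of L alleles and `x_j` normalized tag-SNP dosages)
yields weights `γ̂ = (X′X)⁻¹X′G` that transfer to any cohort genotyped for
the tags.

`vntrstat` implements both downstream tests:

* **VNTR.g** (individual-level): regress the phenotype on the predicted
  dosage `Ĝ = Xγ̂` jointly with covariates; report the coefficient, its
  t-statistic and p-value.
* **VNTR.s** (summary-statistics): when only per-SNP marginal GWAS
  statistics are available, combine them through the weights and a
  reference LD matrix `V` — in the spirit of TWAS tests for imputed gene
  expression:

      α̂ = γ̂′β̂ / (γ̂′Vγ̂)        var(α̂) = σ²_y / (n·K_wv),  K_wv = γ̂′Vγ̂
      Z_α = γ̂′Z_β / √(γ̂′Vγ̂)     p = P(U > Z_α²),  U ~ χ²₁

  With `V` estimated on the same sample and marginal Z defined as
  `√n·corr(x_j, Y)`, `Z_α` equals `√n·corr(Ĝ, Y)` *exactly* — the algebraic
  identity that makes the two tests concordant.

The package also ships a synthetic-data generator (Gaussian-copula or
exact moment-matched haplotype pools) that reproduces the published LD
profile of the eight 5-HTTLPR tag SNPs, and a concordance battery
(correlations, paired regressions, KS test of the −log₁₀ p distributions)
with the published 61-phenotype UK Biobank comparison packaged as a
fixture.

## Worked example

```python
import vntrstat as vs

# a full synthetic study: training panel (n=276, VNTR typed), LD reference
# panel (n=503), GWAS cohort (n=10,000) with a standardized VNTR effect 0.1
bundle = vs.generate_study(vs.SimConfig(seed=11, alpha=0.1))

model = vs.fit_prediction_weights(bundle.train_panel)
print(f"training R^2 = {model.r2_train:.3f}")

ld = vs.compute_ld(vs.merge_panels([bundle.train_panel, bundle.ld_panel]))
res_s = vs.test_summary(model, bundle.sumstats, ld)
res_g = vs.run_vntr_g(model, bundle.gwas_panel, bundle.phenotype)
print(f"VNTR.s: alpha={res_s.alpha_hat:.4f} z={res_s.z_alpha:.2f} p={res_s.p_value:.2e}")
print(f"VNTR.g: alpha={res_g.alpha_hat:.4f} z={res_g.z_alpha:.2f} p={res_g.p_value:.2e}")
```

prints

```
training R^2 = 0.870
VNTR.s: alpha=0.1149 z=7.47 p=7.95e-14
VNTR.g: alpha=0.1155 z=7.53 p=5.72e-14
```

The two routes agree although VNTR.s never touched individual-level
phenotype data: the recovered effect (~0.115 per population SD of the true
dosage, versus the simulated 0.1 — the gap reflects the finite training
panel behind `γ̂`) and the Z-scores differ by well under one percent. Both
p-values clear the genome-wide threshold 5×10⁻⁸.

The same pipeline is available from the shell
(`vntrstat simulate | fit | ld | gwas | test-individual | test-summary |
concordance`); every run writes a JSON provenance manifest.

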