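# Methods

## Model and estimators

Let `G ∈ {0,1,2}` be the count of long alleles of a biallelic VNTR and
`x₁…x_m` the dosages of `m` tag SNPs (here the eight published 5-HTTLPR
tags). All genotype normalization uses the denominator-`n` standard
deviation, so the normalized design satisfies `X′X = nV` with `V` the
sample correlation (LD) matrix *exactly*, not up to `(n−1)/n`. This
convention is load-bearing: it makes the summary-statistics chain below an
algebraic identity on a single sample rather than an approximation.

**Prediction.** `γ̂ = (X′X)⁻¹X′G` on the normalized design; the intercept
`δ̂` is the training mean of `G` (predictors are centered) and puts
predicted dosages back on the interpretable 0–2 scale. The intercept
cancels in every association statistic, which re-normalizes `Ĝ`. A ridge
term (`λ ≥ 0`, default 0) is available for small or near-collinear
panels; plain collinearity fails loudly, naming the dependent SNPs.

**Individual-level test (VNTR.g).** OLS of the phenotype on `Ĝ` jointly
with covariates; the reported z is the coefficient t-statistic.

**Marginal GWAS.** For each tag SNP, phenotype and dosage are first
residualized on the covariates (with intercept), then normalized
(denominator-`n`), so the simple-regression effect is exactly
`β̂_j = corr(x_j, Y)` and `X_j′Y = nβ̂_j`. The reported z is the OLS
t-statistic with `n − 2 − k` degrees of freedom. Residualize-then-
normalize is applied identically to `Y` and every `X_j`; this ordering is
what lets summary statistics produced here reproduce the joint-regression
z when fed back into the summary test.

**Summary-statistics test (VNTR.s).**

    α̂   = γ̂′β̂ / K_wv,          K_wv = γ̂′Vγ̂
    var(α̂) = σ²_y / (n·K_wv)
    Z_α = γ̂′Z_β / √K_wv,        p = P(χ²₁ > Z_α²)

`σ²_y` defaults to 1 (the convention for phenotypes normalized before
GWAS); an override rescales `var(α̂)` only. Heterogeneous per-SNP `n` is
collapsed to the median with a logged range. `Z_α` is invariant to
positive rescaling of `γ̂` and to SNP reordering, and sign-equivariant
under `γ̂ → −γ̂`.

**Equivalence.** With `V` from the same cohort and `z_j = √n·corr(x_j,Y)`,
`Z_α = √n·corr(Ĝ,Y)` exactly (machine precision); with OLS t-statistics
the gap is the `O(1/n)` degrees-of-freedom factor, below 1% relative at
`n ≥ 10,000`. This identity is the package's central correctness check.

## Harmonization and LD handling

Summary records whose effect allele is the model's *other* allele have
their `β̂`/`Z` signs flipped (strand complements recognized); pairs
reconcilable neither directly nor by strand complement are an error
naming the SNP. Strand-ambiguous (A/T, C/G) SNPs are retained with
id-based matching and a warning by default; a drop policy is available.
An `LDMatrix` optionally records the allele coding of the panel it was
estimated on; its rows/columns are sign-flipped only when *its* coding
differs from the model's, which makes the combined Z invariant to the LD
panel's allele orientation.

LD is estimated on a pooled sample when several reference panels are
supplied (samples concatenated after allele harmonization), not by
averaging per-panel matrices. Before use in quadratic forms the matrix is
shrunk by `(1−ε)V + εI` with default `ε = 0.001`, guarding `K_wv > 0`
against reference-panel sampling noise; `ε` escalates tenfold (logged)
in the degenerate case of an indefinite input. `K_wv ≤ 1e−10` is treated
as carrying no LD-adjusted signal and raises rather than returning a
meaningless statistic.

Missing-SNP handling: when a target dataset lacks some model SNPs the
default restricts the model keeping the original weights of retained
SNPs (`subset` mode), because the reference procedure treats the training
weights as fixed downstream; a `refit` mode re-estimates weights on a
supplied panel, and the choice is recorded in the result's mode flags.
Samples with any missing genotype are dropped listwise on input.

## Synthetic-data generator

The generator emulates the three-cohort study design: a training panel
with VNTR dosages (default `n = 276`, the size of the Dutch reference
cohort), an LD reference panel without them (default `n = 503`, a
European public-panel size), and a GWAS cohort (default `n = 10,000`)
with phenotype `Y = α·std(G) + Σc_k·C_k + noise`, noise scaled so
`var(Y) = 1`; `α` is the effect per population SD of the VNTR dosage.
Default frequencies: L-allele 0.57 (European-range value for this locus),
tag effect alleles 0.5 (not published; chosen once). Default VNTR–tag
dosage-correlation targets are the published profile
(0.54, 0.37, 0.25, 0.10, −0.02, 0.04, −0.07, 0.17).

Tag–tag LD is not published for this locus, so the default is an
*invented, labelled* structure: an exchangeable correlation calibrated so
that the implied population prediction R² `r′R⁻¹r` equals the reported
full-model accuracy 0.85. The calibration solves on the negative-ρ branch
of the U-shaped ρ→R² map (solution ≈ −0.084 for the default profile):
mutually anticorrelated tags jointly explain more of the VNTR than their
marginal correlations suggest, the regime consistent with high reported
prediction accuracy alongside modest marginal LD. Every manifest labels
this structure as invented.

Two sampling mechanisms, both drawing two i.i.d. haplotypes per sample
(hence Hardy–Weinberg by construction):

* **exact** (default): a linear program finds a distribution over all
  `2^(m+1)` haplotypes matching every allele frequency and pairwise
  dosage correlation exactly; haplotypes are drawn i.i.d. from it. All
  quantities the method depends on are functions of these first and
  second moments.
* **copula**: one latent multivariate normal per haplotype, thresholded
  at each frequency quantile; latent correlations are calibrated by Brent
  inversion of the monotone latent→dosage map (targets beyond the Fréchet
  bound for the given frequencies are rejected with the bound stated).
  Thresholding attenuates *joint* structure, so this path cannot reach
  high multi-SNP prediction R² (it caps near 0.5 for the default
  marginal profile) — the reason the exact mechanism exists and is the
  default. Under the copula the default tag–tag structure is instead the
  one-factor structure induced by the VNTR's own latent (PSD by
  construction).

What the generator does **not** emulate: recombination-map realism,
population structure or relatedness, genotyping error and missingness,
multi-allelic repeat counts, binary traits. Passing tests therefore
establish the estimators' internal correctness and calibration under the
model's own assumptions, not robustness to those real-data complications.

## Concordance battery

Given paired p-values from the two methods, with `y = −log₁₀(P.g)` and
`x = −log₁₀(P.s)`: Pearson and Spearman correlations (average ranks for
ties — printed tables contain many), OLS in both directions with
coefficient SEs (the two slopes and Pearson r satisfy
`slope(y~x)·slope(x~y) = r²`, used as an internal check), and a
*two-sample* Kolmogorov–Smirnov test between `x` and `y`. The exact
small-sample KS distribution is the default (the common statistical
default at n ≈ 61) with the asymptotic variant available; the method used
is recorded in the report. P-values below a configurable floor (default
1e−300) are clamped with a warning before the log transform.

The packaged 61-phenotype comparison stores p-values rounded as printed,
and loads behind a SHA-256 integrity check. Statistics recomputed from it
reproduce the published values at printed precision except the two
regression coefficients most sensitive to input rounding (slope 1.160 vs
1.15; intercept 0.182 vs 0.19), which agree within the ±0.02 propagated
rounding error of the table entries.

## Numerical and design choices

* Denominator-`n` normalization everywhere (see above); correlations are
  computed on dosages without re-phasing.
* Collinearity detection via condition number (>1e10) with QR-pivot
  identification of dependent columns.
* When both `(β̂, se)` and `Z` are supplied and disagree beyond 1e−6
  relative, the test errors rather than silently preferring one: corrupt
  summary files are common.
* Simulation seeds are mandatory for every stochastic call; study-level
  seeds spawn per-cohort seeds deterministically.
* Validation experiment sizes (2,000 null replicates at `n = 2,000`; 200
  recovery replicates at `n = 20,000` against an `n = 500,000` oracle;
  fidelity at `n = 5,000`) were chosen to make Monte-Carlo error small
  relative to the tolerances tested while keeping the whole battery in
  the tens of seconds on one core.
* An optional rank-based inverse-normal transform (Blom offset) of the
  phenotype is available in both individual-level routes, default off.

## Limitations

* Biallelic VNTR coding only; actual repeat counts are out of scope.
* Linear regression only; no logistic route for binary traits, no mixed
  models or relatedness adjustment.
* Weights are assumed to transfer between the training and GWAS
  populations; no transferability diagnostic beyond reporting the
  training R².
* Genome-wide LD, fine-mapping, conditional analysis, and meta-analysis
  across summary files are out of scope.
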