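# Methods

This note documents the models, numerical choices and known limitations of
`etmap`.  Everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`.

## Trait prediction from environments

All methods operate on a standardized phenotype y and standardized
environmental predictors x₁…x_p; means and SDs are always learned on the
fitting set (the phenotyped accessions) and replayed onto any other
accession, so unphenotyped material is expressed on the fitted scale.  No
intercepts are fit.

* **LM (backward AIC).**  Starting from the full no-intercept linear model,
  single-variable deletions are accepted while they lower
  AIC = n·log(RSS/n) + 2k.  The empty model is a legal endpoint; its
  all-zero prediction carries the constant flag.  Raw predictors only: the
  expanded feature set would exceed typical sample sizes.
* **EN.**  Elastic net with fixed L1/L2 mixing 0.5 on the expanded feature
  set (raw + squares + pairwise products, 2p + p(p−1)/2 columns,
  re-standardized on the fitting set).  λ is the cross-validation minimum
  over a 100-point log-spaced path with floor 0.01·λ_max (the usual n < p
  path convention); fold assignment is seeded, so fits are reproducible.
  The printed form of the penalized objective elsewhere carries a 1/σ²
  factor on the loss; this is a reparameterization of λ and is absorbed by
  the CV search, so the standard objective is used.
* **RF.**  500 bootstrap regression trees, p/3 candidate features per
  split, minimum leaf size 5 (the standard regression-forest
  configuration, matching R's randomForest regression defaults), seeded.
  Variable importances are recorded; out-of-bag R² on request.
* **CCA.**  Classical canonical correlation via QR + SVD (not an iterative
  NIPALS approximation): the environment-side weight vector of the first
  canonical pair, oriented to correlate positively with the first trait
  column.  With a single trait the canonical variate is proportional to
  the no-intercept OLS fitted values — this identity is exercised as a
  test oracle.  Raw predictors only, as with LM.

A prediction whose sample SD is below 1e-10 (on the standardized scale) is
**constant** — exact zeros arise from full EN shrinkage and empty
backward-selection models — and every bivariate caller falls back to the
univariate results in that case.

Whether expanded (squared/interaction) columns should be re-standardized
before fitting was an open choice; they are, and the flag
`expand_features(..., standardize=)` exposes it.

## Mixed-model association

**Kinship** is the scaled cross-product K = ZZᵀ/m of column-standardized
markers (missing calls mean-imputed per SNP, monomorphic and MAF-filtered
SNPs dropped), floored to PSD and rescaled to mean diagonal 1.

**Univariate LMM.**  One spectral decomposition of K turns the REML
problem into a 1-D profile likelihood over h²; a 64-point grid plus
bounded refinement makes the fit deterministic to ~1e-8.  Variance
components are estimated once under the no-marker null and reused for all
SNPs (the EMMAX approximation); each marker is tested by GLS F-test with
denominator df = n − 2.  With K = I this reduces exactly to the OLS F-test
(tested to 1e-8).

**Bivariate model.**  Parameters (σ²g1, σ²g2, ρg, σ²e1, σ²e2[, ρe]) are
estimated by REML on (log-variance, atanh-correlation) scale with a fixed
8-point start grid over (h², ρg); the grid is screened by objective value
and the three best starts are polished by L-BFGS-B (convergence 1e-6 on
the log-likelihood), keeping fits deterministic.  When both traits are
complete the 2n×2n system factorizes, after rotation by the eigenvectors
of K, into n independent 2×2 blocks (d_i·Vg + Ve), making one fit ~50 ms
at n = 300; with partially overlapping trait sets the N_obs-sized
covariance is built densely and Cholesky-whitened.  The two code paths are
tested against each other.  ρe is excluded by default and refused when the
traits share no accessions.  Marker tests are GLS F-tests at the null
variance components: common (1 df) and full (2 df), denominator
df = N_obs − fixed-effect count.  Monomorphic markers return p = 1 with a
flag, and ranking ties are broken by (chromosome, position), so ranked
lists are total orders.  A fit with numerically identical traits is
flagged degenerate and refuses marker tests.

λ_GC is the median 1-df chi-square quantile of the p-values over the null
median; the implementation uses `chi2.isf(0.5, 1)` as the denominator so
that all-p = 0.5 gives exactly 1.

## Simulator

The synthetic population is a four-subpopulation (100/100/50/50)
Balding–Nichols draw: ancestral frequencies uniform on (0.1, 0.9),
subpopulation frequencies Beta-distributed with divergence F, haploid
{0,1} alleles, 3000 SNPs.  F defaults to 0.4, calibrated so mean
within-subpopulation kinship is ≈ 0.3 (between-subpopulation means are
then ≈ −0.1, since sample-centered standardization forces the overall mean
off-diagonal toward zero; the two calibration targets cannot hold
simultaneously).

Each replicate draws, in order: (G_env, G_trait) matrix-variate normal
with row covariance K and column covariance V_G (compound-symmetric
correlation 0.5 within the s = 10 gradient variables and within their
complement, zero across; trait–environment genetic correlation 0 or 0.5 on
the gradient set only; environmental genetic variances 0.5, trait genetic
variance equal to the polygenic fraction); X_T = G_env + iid residuals so
each environmental variable has unit variance and heritability 0.5;
observed environments X_O with per-column noise var(X_T)·(1/r² − 1) giving
corr(X_T, X_O) = r (0.8 in the main condition); gradient
y_T = X_T(S)·β with β uniform on [−1, 1]; causal allele frequencies
f = e^{λy_T}/(1 + e^{λy_T}) with λ = 3 and one Bernoulli allele per
accession (f is monotone in y_T — rank correlation exactly 1 — though its
Pearson correlation with y_T is below 1, as for any nonlinear map); and
y_O = β_snp·g + G_trait + E_trait with β_snp scaled by the *realized*
sample variance of g so the SNP's variance share holds per replicate
(a monomorphic g gets effect 0 and a flag).  Matrix square roots are
symmetric eigen-based so PSD-but-singular K is accepted.  Replicates use
spawned seed-sequence substreams: the same (scenario, seed) reproduces a
power table bit-identically.

The power harness tests only the causal SNP per replicate (power is
defined there), fits each requested prediction method on the standardized
(y_O, X_O), and substitutes the univariate p-value whenever a prediction
is constant.

### What the synthetic population does and does not emulate

The four-block kinship reproduces the qualitative findings — bivariate ETM
dominates univariate mapping for every prediction method under the main
condition, loses to it when the SNP is non-adaptive, and is calibrated
under the null — but not the absolute power levels of a real accession
panel.  With discrete subpopulations the environmental gradient, and hence
the causal SNP's frequency cline (the logistic map saturates at λ = 3
times a gradient SD of ≈ 1.8), concentrates on the top ~3 eigenvectors of
K, exactly the directions a kinship-corrected test must discount.
Univariate power at −log10(p) ≥ 5 is ≈ 0.31–0.38 here for any divergence
in [0.05, 0.4] (and for a two-level family-structured variant), versus
≈ 0.64 reported on a real panel whose continuous, fine-grained relatedness
spreads the gradient over many mid-spectrum directions; CCA-based
bivariate ETM reaches ≈ 0.68–0.73 versus ≈ 0.80.  A real kinship matrix
can be supplied to `run_power_experiment` via the `population` argument to
remove this gap.

Parameter-recovery experiments use a smooth AR(1)-type kinship
(0.9^|i−j|, n = 300) rather than the block kinship: with the block design
ρg is weakly identified (~3 informative eigendirections) and shows ≈ +0.11
spread-induced bias even though the estimator is unbiased (bias < 0.01
under the smooth kinship).  Recovery is within ±0.1 for all five bivariate
parameters (200 replicates) and ±0.05 for univariate h².

### Problem sizes

The default suite uses 500 replicates for power levels (Monte-Carlo SE
≈ 0.02), 60 replicates for the four-method ordering checks (the ordering
gap is ≈ 4–5 SE at that size), 2000 replicates for null calibration, and
200 replicates for parameter recovery.  `scripts/acceptance.py` runs 500
replicates (`--reps` to change).

## Enrichment

SNPs are ranked by p (ties by chromosome and position) and the top 2000
(configurable) are assigned to the gene(s) overlapping their position,
else to the nearest gene; equidistant ties keep both genes, and
multi-gene overlaps keep all (window-based assignment exists behind a
flag but is not the default).  Walking the ranked list, each newly seen
gene increments m, recoveries from the known list increment k, and
enrichment is the exact hypergeometric upper tail P(X ≥ k | N, K, m),
computed by log-space summation of the smaller tail (the larger side is
obtained as a complement), which agrees with exact integer arithmetic to
1e-12 relative for all N ≤ 2000.  N defaults to the number of unique genes
assignable from the full SNP panel, recomputed per dataset.  Permutation
envelopes jointly permute trait rows (kinship untouched), rebuild the
curve per permutation, and report 5th/95th percentiles of k per m
(minimum 20 permutations).  Gene deduplication uses the first rank at
which a gene appears.

## Pipelines and reproducibility

`run_bivariate_etm` / `run_univariate_etm` wire the stages together:
standardize on the phenotyped set → optional PC1 reduction of multiple
trait columns (correlation-matrix PCA, sign fixed so the loading sum is
positive; accessions with missing trait values are excluded from the
fitting set) → fit prediction → constant-prediction check (bivariate runs
fall back to the univariate scan of the observed trait) → mixed-model scan
→ ranked results.  Univariate ETM applies the optional range filter
(targets whose prediction exceeds the fitting-set range are dropped, with
counts) before mapping.  Every output directory contains the resolved
config, seed, per-stage log (including λ_GC of each scan) and SHA-256
checksums of the inputs.  One global seed drives CV folds, bootstraps,
simulation substreams and permutations.

## Known limitations

* Genotype dialects are limited to delimited text and PLINK-style
  .ped/.map text; no VCF.
* The bivariate model handles exactly two traits; no multi-locus
  (co-factor) models.
* Per-SNP variance components are approximated by the null fit by default
  (the approximation's calibration is verified by permutation-null and
  simulation-null KS tests); exact per-SNP REML — the marker joins the
  fixed effects of the REML fit — and chi-square LRT-style p-values are
  available behind `exact=` / `distribution=` flags, intended for small
  marker panels.
* The synthetic population's power levels differ from real-panel levels
  for the structural reason discussed above.
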