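# Methods

## The analysis in brief

The package re-implements a replication-style gene-set analysis: does common
variation in the 27 heterotrimeric G-protein genes associate with cognitive
ability? Three statistical layers answer it. A *self-contained* test asks
whether the candidate SNP set associates with the phenotype at all, via
phenotype permutation within each cohort and √N-weighted Stouffer
combination across cohorts. A *competitive* layer asks whether the candidate
genes are more associated than random gene sets, via simulation-based
gene p-values (sum of squared meta-analysed z-scores against an MVN null
with the observed LD) followed by a weighted running-sum Kolmogorov–Smirnov
enrichment statistic. A *power* layer asks how likely the design was to
detect the originally reported effect (3.3% of variance) if real.

## Synthetic cohorts: what they emulate and what they do not

No cohort genotype or phenotype data are public, so every analysis here runs
on synthetic cohorts engineered to carry the features the statistics are
sensitive to:

- **Sample sizes** are the published per-cohort Ns (505/989/350/754/805 for
  fluid ability; 515/1003/420/750/770 crystallised; 464/947 age-11).
- **Candidate panel**: 470 SNPs over the 27 genes — the genotyped panel size
  (per-cohort counts were 468–470) — with per-gene counts allocated by
  largest remainder proportional to the published per-gene SNP-count
  template, positions uniform inside each gene's 2 kb/500 bp window, MAF
  drawn Uniform(0.05, 0.45) as appropriate for a post-QC common-SNP panel.
- **LD**: a Gaussian copula with AR(1) correlation ld_rho between adjacent
  SNPs of the same gene. The real panel's LD is unknown; ld_rho = 0.2
  (adjacent dosage correlation ≈ 0.13) is the documented default. The LD
  strength shifts the headline power only modestly relative to the
  Stouffer/pooled gap discussed below, so it is not the driver of that gap.
- **Phenotype model**: latent ability g ~ N(0,1); battery test j scores
  λ_j g + N(0, 1 − λ_j²) with default loadings 0.7 — the implicit
  single-factor model behind extracting a general factor from a battery.
- **Stratification**: an optional two-subpopulation mixture shifting both
  allele frequencies and the latent mean by `structure_shift`, so the MDS
  covariates have something real to absorb.

Not emulated: realistic allele-frequency spectra, long-range LD, haplotype
structure, imputation error, genuine SNP effects on cognition. Passing tests
therefore certify the statistical machinery (calibration, oracle agreement,
determinism, power behaviour under the assumed model), not properties of the
real cohorts.

## Pipeline conventions

- **QC order**: individuals by call rate (> 0.95), then SNPs by call rate
  (> 0.98), MAF (> 0.01) and exact (Wigginton-style) Hardy–Weinberg test
  (p > 0.001), recomputed on retained individuals. All comparisons strict.
  The exact HWE test is used rather than χ² because it is stable at low
  genotype counts; the enumeration oracle in the tests pins it down.
- **Ancestry axes**: classical (Torgerson) MDS on the 1 − IBS distance
  (mean absolute dosage difference / 2), mean-imputed dosages, top four
  axes, sign fixed by the largest-magnitude coordinate.
- **Fluid factor**: single-factor maximum-likelihood fit (scikit-learn's
  `FactorAnalysis`) with Bartlett scoring computed from the fitted loadings
  and uniquenesses; one unified method for all cohorts (the original mix of
  PCA- and ML-based extraction correlates ~1 for such designs). A
  single-test battery degenerates to z-scores.
- **Residualisation**: OLS on age, sex and the MDS axes; standardised
  residuals (population SD). Age-11 scores are first age-corrected and put
  on the IQ scale (mean 100, SD 15), then residualised on sex + axes.
- **Windows**: 2 kb upstream / 500 bp downstream, strand-aware, for the
  genotyped set test; symmetric ±50 kb, strand ignored, for the gene-based
  stage. Window endpoints inclusive; coordinates 1-based inclusive
  throughout (BED-style input convertible at read time).
- **Per-SNP test**: OLS with intercept on 0/1/2 dosage, p from the t
  distribution at n − 2 df; sporadically missing dosages mean-imputed so the
  permutation algebra stays exact; constant-dosage SNPs flagged and excluded
  from set statistics.

## Permutation engine

The power study needs millions of set tests, so the engine standardises the
set's dosage matrix once, draws one batch of B permutations per cohort
(shared across phenotype replicates — permutations are independent of the
phenotypes, so sharing biases nothing), and computes all per-SNP
correlations as a single matrix product per replicate. Correlations convert
to −log₁₀ p through a 20001-point interpolation table built from the exact
t tail per call (agreement ~1e-7 on the log scale; the scalar path keeps the
exact computation, and the two are cross-checked to 7 digits in the tests).
Empirical p-values use the (1 + count)/(1 + B) correction and therefore
never return zero; p = 1 is nudged inside (0,1) before the normal quantile
in the Stouffer step.

Degenerate inputs are errors, not silent answers: constant phenotypes,
empty SNP sets, zero residual variance, collinear covariates (named),
all-removed QC, empty set unions.

## Gene test and enrichment

The gene statistic Σz² is compared with draws from MVN(0, R); R is the
pooled-cohort dosage correlation, symmetrised, with a diagonal ridge
escalating from 1e-6 until Cholesky succeeds. The simulation count is
adaptive: 10³ draws escalated tenfold (default cap 10⁶) while
p_gene < 10/n_sim. Closed-form limits anchor it: a single SNP reproduces the
χ²₁ tail, perfectly correlated SNPs collapse to one degree of freedom, and
identity LD reproduces χ²_k.

Enrichment weights are w_g = −log₁₀ p_gene (the published description says
"weighted by the p-values" without a formula; unit weights are retained for
oracle testing, where the score equals the classic one-sample K-S
deviation). Ranking ties break by gene name, making results bit-reproducible.
The null redraws candidate-set membership uniformly over the ranked list;
phenotype permutation is not available at this stage of a meta-analysed
pipeline. The empirical p counts permuted ES ≥ observed — the direction in
which large scores mean enrichment; the published wording ("proportion …
smaller than the original") would make strong enrichment yield p ≈ 1 and is
read as an inversion of phrasing.

## Power study

Defaults are desk-scale: 400 phenotype replicates split over 4 effect
allocations at B = 999 (the full-scale design of record is 1000 × 100 at
B = 10000, available via `--full` in the CLI). Noise is scaled by the
empirical within-cohort variance of the predicted score
(σ² = var(g)(1 − v)/v), so the realised R² equals v exactly in expectation;
the theoretical-variance alternative drifts with realised MAF. Effect SNPs
are drawn from the candidate set but the test always uses all 470 set SNPs
(signal subset, full-set statistic). Everything is seeded through a single
`SeedSequence` spawn tree, including the nested permutation streams.

### The Stouffer/pooled gap

At the headline cell (k = 30, v = 3.3%) the faithful procedure — per-cohort
permutation tests combined by √N-weighted Stouffer — yields power ≈ 0.45–0.51
across seeds (0.455 in `analysis/05_power_study.py`; 0.445 from
`scripts/acceptance.py --seed 1`), whereas the published band for this design
is 0.775–0.867. The package's measurements localise the difference precisely:
running the identical permutation test once on the pooled 3403-individual
sample gives power 0.882 (same script, same conditions). The set statistic is quadratic-type — its standardised shift
under the alternative grows roughly linearly with N — so splitting the
sample into five cohorts and averaging Z-scores forfeits a factor ≈ √5 of
that shift, which no weighting can recover. The published band coincides
with the pooled behaviour, not with the per-cohort-then-combine chain under
this generator. Both variants are first-class here
(`PowerConfig(combine="stouffer" | "pooled")`); the Stouffer variant remains
the default because it is the procedure the replication describes. The
qualitative conclusions are unaffected: power is governed by the total
variance explained, with only small fluctuations across the number of SNPs
carrying the effect, under either combination rule.

## Known limitations

- The Gaussian-copula LD model is exchangeable within genes and has no
  inter-gene or long-range structure.
- Mean imputation of missing dosages slightly attenuates per-SNP betas at
  high missingness; post-QC missingness is ≤ 2% by construction.
- The MDS step is O(n²m) in time and O(n²) in memory; fine to a few
  thousand individuals per cohort, not genome-scale.
- Gene p-values below 1/(n_sim_cap + 1) are reported at the floor.
- The enrichment null conditions on the observed ranking; it does not model
  correlation between gene statistics induced by shared SNPs in overlapping
  windows (the published procedure shares this property).
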