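# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `eqtlprio`.

## 1. Association scan

### Preprocessing

Expression preprocessing is applied in a fixed order per cohort:

1. **Quantile normalization** (`quantile_normalize`): each sample's values
   are replaced by the pooled reference distribution — the mean across
   samples of the sorted expression vectors — at the corresponding ranks.
   Ties receive the average of the reference values spanning the tie run,
   so the transform is exactly rank-equivalent (and idempotent on
   tie-free data).
2. **Covariate adjustment** (`adjust_covariates`): OLS residuals against
   an intercept plus the supplied covariate matrix (least squares via
   `numpy.linalg.lstsq`). Collinear covariate columns are detected and
   named in the error.
3. **Expression-PC removal** (`clip_pcs`): the top-k principal components
   of the column-centered expression matrix (via SVD) are subtracted,
   removing broad latent structure (hidden confounders, batch). The PC
   count is chosen by `select_pc_count`, which maximizes the number of cis
   associations at nominal P < 0.05 over a candidate grid (ties favor the
   smaller count).

### Score statistic

Each SNP within ±`cis_radius` (default 100 kb) of a gene's transcript
boundaries is tested against the gene's probe with the 1-df score
statistic

    χ² = n · r²,

where r is the Pearson correlation between dosage and processed expression
and n the cohort sample size. Under the null this is asymptotically χ²₁;
its exact null mean is n/(n−1), a finite-sample inflation that matters for
goodness-of-fit testing (§5). The statistic is invariant to affine
transformations of either variable, hence to allele flipping. Its gap to
the OLS likelihood-ratio statistic is second order: LRT − n·r² =
−n·log(1−r²) − n·r² ≈ (n·r²)²/(2n), about 5% at χ² = 20 and n = 200, and
the test suite asserts this exact bound rather than a blanket tolerance.

Distances are measured to the nearest transcribed base: 0 inside the gene,
`start − pos` to the left, `pos − end + 1` to the right. The cis window is
inclusive at `start − radius` and exclusive at `end + radius` (0-based
half-open convention throughout memory; BED/VCF/GTF conventions are
converted at the I/O boundary).

## 2. Meta-analysis and permutation FDR

Per-cohort statistics for the same (SNP, probe) pair are **summed**; under
the null the sum is χ² with one degree of freedom per contributing cohort
(4 df for the default 4-cohort design). By default only pairs present in
every cohort enter (`intersection` mode); `union` mode keeps all pairs
with df equal to the number of contributors.

**Permutation null.** Each of k permutations (default k = 3) draws an
independent sample-label permutation per cohort — applied to genotype rows
only, preserving LD and the full expression covariance — and reruns the
scan and meta combination. Streams are keyed
`SeedSequence([seed, cohort, permutation])`, so nulls are reproducible and
extendable.

**Plug-in FDR.** At threshold t,

    FDR(t) = [ (1/k) · #{null ≥ t} ] / #{observed ≥ t},

capped at 1. The raw estimate is not monotone in t; the default output is
the q-value min over thresholds t′ ≤ t of FDR(t′), which is nonincreasing
in the statistic (`monotone=False` returns the raw values). Pair-level FDR
pools all cis pairs genome-wide; **gene-wise FDR** applies the same
estimator to each gene's maximum cis statistic against the pooled
permutation null of per-gene maxima, and is the basis for the
"significant gene" counts.

**Known calibration limitation.** Under a global null the observed scan
and its k permuted versions are exchangeable as whole vectors, so the top
observed gene-max exceeds *all* pooled null maxima with probability
1/(k+1). The estimator then reports FDR = 0 for the top gene and the
replicate's realized false-discovery proportion is 1. With k = 3 the
long-run mean null FDP is therefore ≈ 0.25 (measured 0.15–0.20 over
20-replicate batches), not the nominal ≤ 5–10%. This is a property of the
plug-in estimator itself — visible already in its defining toy case, where
the largest observed statistic exceeding every null value yields 0/1 = 0 —
and is deliberately left visible; the corresponding acceptance test is
expected to fail and says so in its docstring. Mitigations (add-one
smoothing of the null count, larger k) change the estimator and are out of
scope.

## 3. Enrichment test

For a candidate gene set of size m inside a universe of size N containing
E eQTL genes, the observed eQTL-gene proportion is compared to
`n_draws = 10,000` uniform without-replacement draws of m genes. The count
of eQTL genes in such a draw is exactly Hypergeometric(N, E, m), so the
null is sampled directly via `rng.hypergeometric` — mathematically
identical to drawing gene lists and orders of magnitude faster. The
empirical p-value uses the add-one (permutation-inclusive) form
(1 + #{null ≥ obs}) / (1 + n_draws), giving a resolution floor of
≈ 1/n_draws and exactly uniform null p-values up to discreteness.
Placeholder identifiers ("intergenic", "NR", pseudogenes) are stripped
from candidate sets before testing.

## 4. GWAS-membership prediction

### Features and labels

Each pair carries factored annotations with declared base levels
(dummy-coded against them):

| factor | levels | base |
|---|---|---|
| distance | 0 kb (within gene), (0–10 kb], (10–50 kb], (50–100 kb] | 0 kb |
| MAF | [1–5%], (5–10%], >10% | >10% |
| chromatin state | 15 ChromHMM-style states + "(-) none" | (13) Heterochromatin |
| structural class | none, intron, coding, UTR | none |
| eQTL FDR | [0–1%), [1–5%), [5–10%), [10–50%), >50% (right-open) | >50% |
| CADD | [0, 5], (5, 10], (10, 20], (20, 30], (30, 60] (first closed, >60 clamped) | [0, 5] |

A SNP is labelled a GWAS hit if it is a catalog entry or its dosage
correlation with a catalog SNP within 250 kb exceeds r² = 0.8 in a
reference panel. Training SNPs come from PLINK-style sliding-window VIF
pruning (window 50, step 5, VIF 2; a tiny ridge keeps the correlation
matrix invertible so exact duplicates get pruned first).

### Models and evaluation

The model menu: M1 (distance + MAF + structural), M2 (distance + MAF +
chromatin state), M3 (M2 + FDR bin), M3B (M3 without distance), M3+CADD.
Fits are maximum-likelihood `statsmodels` Logit; quasi-complete separation
is detected per dummy column and reported by name, with an optional
flagged ridge fallback. Evaluation:

- **Calibration:** equal-width probability bins anchored on the reference
  model's (M3's) range, observed event proportion per bin.
- **ROC/AUC:** scikit-learn `roc_curve`/`roc_auc_score` (tie-corrected
  Mann–Whitney AUC), cross-checked in tests against a brute-force
  pair-counting oracle.
- **Top-bin cross-tab:** pairs in the top two probability bins tabulated
  as 16 chromatin states × 5 FDR bins, with distinct SNP/gene counts.
- **Reporting arithmetic:** search-space reduction
  100·(1 − retained/total) and catalog overlap 100·overlap/retained.

## 5. Synthetic data generator

All generation is driven by `SimConfig`; independent numpy streams are
partitioned by `SeedSequence([seed, tag, ...])` so sub-studies never share
randomness. Defaults (units in parentheses):

| parameter | default | meaning |
|---|---|---|
| `n_cohorts` / `n_samples` | 4 / (73, 113, 198, 202) | cohorts and per-cohort sizes |
| `n_genes`, `n_snps_per_gene` | 300, 20 | disjoint cis windows, SNPs per gene |
| `cis_radius` (bp) | 100,000 | cis window half-width |
| `maf_range` | (0.01, 0.5) | uniform MAF of the shared SNP panel |
| `ld_rho` | 0.0 | AR-style haplotype-copying LD within gene blocks |
| `eqtl_fraction` | 0.3 | genes receiving a causal cis SNP |
| `beta_dist` | (0.55, 0.10) | normal (mean, sd) of causal effect sizes |
| `share_prob` | 0.7 | probability an effect is shared across all cohorts |
| `n_confounders`, `confounder_sd` | 5, 0.3 | latent factors and loading scale |
| `batch_sd`, `noise_sd` | 0.2, 1.0 | per-cohort batch shift, residual noise |
| `state_enrichment` | 0.0 | regulatory-state excess at causal SNPs |
| `gwas_base_rate`, `gwas_coefs` | 0.035, {} | label rate and "col:level" log-odds |

Genotypes are Binomial(2, p) HWE dosages from a panel shared across
cohorts. Expression is `β·dosage + factors·loadings + batch + noise`;
`beta_for_r2(r2, maf, nongenetic_variance(cfg))` converts a target
per-SNP variance fraction into β. Chromatin states tile ~80% of the
chromosome in 15-state segments. GWAS labels are Bernoulli draws from a
logistic annotation model whose intercept is calibrated by root finding
(`brentq`) to hit the marginal base rate exactly. For studies of the label
model alone, `simulate_feature_table` draws factored annotation tables
directly from configurable marginals — the scale-friendly route to
hundreds of thousands of pairs.

## 6. Numerical and design choices

- **Sample size for null-law testing.** The KS check of the meta null
  against χ²₄ uses n = 1000 per cohort: at 10⁴ draws, KS resolves the
  exact n/(n−1) null-mean inflation of the score statistic at n = 100, so
  the asymptotic claim is tested in its asymptotic regime (bias 4·10⁻³ on
  a mean of 4 at n = 1000).
- **Problem sizes** in the validation studies (300 genes × 20 SNPs for FDR
  calibration, 10⁴ pairs for the null law, 200 replicates × 10⁴ draws for
  enrichment, 2·10⁵ pairs for logistic recovery) are the package's own
  choices balancing statistical resolution against a few-minute runtime on
  one CPU.
- **Determinism.** Every stochastic routine takes an explicit seed;
  derived seeds stay below 2³¹. Manifests (`io.write_manifest`) record
  seeds, edges and thresholds for bit-for-bit reproduction.
- **Established libraries** handle standard steps — scipy distributions,
  statsmodels Logit, scikit-learn ROC, cyvcf2 VCF parsing, pandas I/O —
  while the scientific content (score-statistic scan, summed-χ² meta,
  plug-in permutation FDR, draw-based enrichment, binned logistic
  prioritization, VIF pruning) is implemented here and oracle-tested.

## 7. Limitations

- The plug-in FDR calibration defect under sparse/global-null signal
  (§2) is inherent to the estimator at small k.
- The generator plants at most one causal cis SNP per gene, uses a single
  synthetic chromosome with disjoint gene windows, and draws annotation
  marginals independently in `simulate_feature_table` (no LD–annotation
  coupling there).
- Trans effects, allelic heterogeneity, imputation uncertainty in
  dosages, and covariate measurement error are out of scope.
- The enrichment test conditions on a fixed eQTL gene set; it does not
  propagate FDR uncertainty from stage 1.
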