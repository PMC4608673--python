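# eqtlprio

Cis-eQTL meta-analysis across cohorts with permutation plug-in FDR, gene-set
enrichment testing, and logistic prioritization of GWAS-relevant variants
from binned functional annotations — plus a full synthetic-data generator
for validating every stage.

## The scientific problem

Expression quantitative trait loci (eQTLs) are variants whose genotype
associates with a gene's expression level. Single blood-expression cohorts
are individually underpowered, and most trait-associated GWAS variants fall
in non-coding regions where functional interpretation is hard. This package
implements a three-stage analysis:

1. **Cis-eQTL meta-analysis.** Within each cohort, expression is quantile
   normalized against a pooled reference, residualized on known covariates,
   and stripped of top expression principal components (the count chosen by
   maximizing nominal association yield). Every SNP within ±100 kb of a
   gene's transcript is tested with the 1-df score statistic χ² = n·r²
   (squared sample correlation of dosage and processed expression, scaled
   by sample size). Per-cohort statistics are summed across cohorts into a
   meta statistic that is χ² with one degree of freedom per cohort under
   the null. False discovery rates come from whole-genome permutations of
   genotype sample labels (k = 3 by default): the plug-in estimate at
   threshold t is the mean null exceedance count divided by the observed
   exceedance count, applied both pair-wise and to each gene's maximum cis
   statistic against a matched null of per-gene maxima.

2. **Enrichment.** Whether a candidate gene set (e.g. genes implicated by a
   GWAS) is over-represented among eQTL genes is tested by comparing its
   observed eQTL-gene proportion against 10,000 equally sized random draws
   from the gene universe, with the add-one empirical p-value.

3. **GWAS-membership prediction.** Each SNP–probe pair is described by
   factored annotations — distance bin, MAF bin, ChromHMM-style chromatin
   state, structural class, eQTL FDR bin, optionally a CADD bin — and a
   dummy-coded multivariate logistic regression predicts whether the SNP is
   a GWAS-catalog hit or a strong LD proxy (r² > 0.8) of one. Models are
   trained on a VIF-LD-pruned SNP set and evaluated by calibration against
   equal-width probability bins, ROC/AUC, and a chromatin-state × FDR-bin
   cross-tabulation of the top predicted-probability bins.

All stages are validated on synthetic data with known truth: HWE genotypes
with optional LD blocks, expression with planted cis effects plus latent
confounders and batch structure, chromatin-state tilings, and GWAS labels
drawn from a configurable logistic annotation model.

## Worked example

```python
from eqtlprio import SimConfig, pipeline
from eqtlprio.meta_fdr import significant_genes, significance_summary
from eqtlprio.synthetic import beta_for_r2, nongenetic_variance

cfg = SimConfig(n_cohorts=4, n_samples=(100, 100, 100, 100),
                n_genes=100, n_snps_per_gene=10,
                eqtl_fraction=0.3, share_prob=1.0,
                maf_range=(0.3, 0.3), seed=39)
cfg.beta_dist = (beta_for_r2(0.10, 0.3, nongenetic_variance(cfg)), 0.0)

study = pipeline.simulate_study(cfg)
res = pipeline.run_meta_pipeline(study["genos"], study["exprs"],
                                 k=3, seed=39)
print(significance_summary(res["meta"], fdr_cut=0.05))
print(len(significant_genes(res["meta"], 0.05)), "meta-significant genes")
for i, tab in enumerate(res["cohorts"]):
    print(f"cohort {i}:",
          tab.loc[tab["fdr_gene"] < 0.05, "gene_id"].nunique(), "genes")
```

Output:

```
{'total_snps': 1000, 'signif_snps': 310, 'total_genes': 100, 'signif_genes': 31, 'total_pairs': 1000, 'signif_pairs': 310, 'min_signif_p': 9.047229420391968e-15, 'max_signif_p': 0.9997742604135299}
31 meta-significant genes
cohort 0: 9 genes
cohort 1: 19 genes
cohort 2: 20 genes
cohort 3: 15 genes
```

With effects shared across cohorts, the 4-cohort meta-analysis (31 genes at
gene-level FDR < 5%) beats every single cohort's yield (9–20 genes) — the
motivating behavior of the summed-χ² combination.

The prediction stage works off any factored annotation table:

```python
from eqtlprio.prediction import fit_model, predict_probs, roc_auc
from eqtlprio.synthetic import simulate_feature_table, simulate_gwas_catalog

cfg = SimConfig(seed=4000, gwas_coefs={"fdr_bin:[0-1%)": 0.7,
                                       "maf_bin:[1-5%]": -1.6})
feats = simulate_feature_table(200_000, cfg)
catalog, truth = simulate_gwas_catalog(feats, cfg)
m3 = fit_model(catalog, catalog["gwas_hit"], "M3")
print(m3.coefficient_table().head())
print("AUC:", roc_auc(predict_probs(m3, catalog), catalog["gwas_hit"]).auc)
```

A `click` CLI (`eqtlprio simulate/scan/meta/enrich/predict/report`) wraps
the same workflows over TSV/VCF/BED files; see `eqtlprio --help`.

## Layout

- `src/eqtlprio/synthetic.py` — generative models (genotypes, expression,
  annotations, GWAS labels) with known truth
- `src/eqtlprio/association.py` — normalization, covariate/PC removal, cis
  pair enumeration, score-statistic scan
- `src/eqtlprio/meta_fdr.py` — meta combination, permutation nulls,
  plug-in pair/gene FDR
- `src/eqtlprio/enrichment.py` — random-draw gene-set enrichment
- `src/eqtlprio/prediction.py` — annotation binning, GWAS labels, LD
  pruning, logistic models, calibration/ROC/cross-tab reporting
- `src/eqtlprio/io.py` — TSV/VCF/BED/GTF readers and writers, manifests,
  yield accounting
- `src/eqtlprio/pipeline.py` — end-to-end workflows; `cli.py` — CLI
- `docs/methods.md` — statistical methods, parameter reference, and
  limitations
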