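"""High-level workflows wiring the modules together.

These are the entry points used by the command-line interface and by
simulation studies: simulate a complete multi-cohort dataset, run the full
per-cohort scan + meta-analysis + permutation FDR, and build the annotation
table feeding the GWAS-membership models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import association, meta_fdr, prediction
from .synthetic import SimConfig, simulate_annotations, simulate_expression, \
    simulate_gene_models, simulate_genotypes, simulate_gwas_catalog, snp_map


def simulate_study(config: SimConfig) -> dict:
    """Generate a full synthetic study: genotypes per cohort, expression
    with planted effects, gene models, SNP panel, and chromatin
    annotations."""
    genes = simulate_gene_models(config)
    genos = [simulate_genotypes(config, c) for c in range(config.n_cohorts)]
    exprs, truth = simulate_expression(genos, genes, config)
    snps = snp_map(config)
    annots, segments = simulate_annotations(
        snps, genes, config, causal_snp_ids=truth["causal_snp_id"].tolist()
    )
    return {
        "config": config,
        "genes": genes,
        "snps": snps,
        "genos": genos,
        "exprs": exprs,
        "truth": truth,
        "annotations": annots,
        "segments": segments,
    }


def run_meta_pipeline(
    genos: list,
    exprs: list,
    radius: int = 100_000,
    k: int = 3,
    seed: int = 0,
    covars: list | None = None,
    pc_counts: list | None = None,
    mode: str = "intersection",
) -> dict:
    """Preprocess, scan each cohort, meta-combine, and estimate FDRs.

    Returns cohort pair tables (each with its own permutation gene FDR),
    the meta table with ``fdr_pair`` and ``fdr_gene``, and the null
    ensemble.
    """
    exprs_pp = association.preprocess(exprs, covars=covars, pc_counts=pc_counts)
    pairs = [association.cis_pairs(g, e, radius) for g, e in zip(genos, exprs_pp)]
    scans = [association.association_scan(g, e, p)
             for g, e, p in zip(genos, exprs_pp, pairs)]
    meta = meta_fdr.meta_combine(scans, mode=mode)
    ens = meta_fdr.permute_and_scan(genos, exprs_pp, pairs, k=k, seed=seed, mode=mode)
    meta = meta_fdr.plugin_fdr(meta, ens)
    meta = meta_fdr.genewise_fdr(meta, ens)

    # cohort-level gene FDR from the same permutations, per cohort
    cohort_tables = []
    for c, scan in enumerate(scans):
        stat = scan["chi2"].to_numpy()
        gene_obs = scan.groupby("gene_id", sort=True)["chi2"].max()
        null_gene = []
        null_pair = []
        for p in range(k):
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), c, p]))
            perm = rng.permutation(genos[c].n_samples)
            gm = genos[c]
            from .types import GenotypeMatrix
            gperm = GenotypeMatrix(
                sample_ids=gm.sample_ids, snp_ids=gm.snp_ids,
                positions=gm.positions, dosages=gm.dosages[perm], maf=gm.maf,
            )
            nscan = association.association_scan(gperm, exprs_pp[c], pairs[c])
            null_pair.append(nscan["chi2"].to_numpy())
            null_gene.append(nscan.groupby("gene_id", sort=True)["chi2"].max().to_numpy())
        tab = scan.copy()
        tab["fdr_pair"] = meta_fdr.plugin_fdr_values(stat, np.concatenate(null_pair), k)
        gene_fdr = pd.Series(
            meta_fdr.plugin_fdr_values(gene_obs.to_numpy(), np.concatenate(null_gene), k),
            index=gene_obs.index,
        )
        tab["fdr_gene"] = tab["gene_id"].map(gene_fdr)
        cohort_tables.append(tab)
    return {"cohorts": cohort_tables, "meta": meta, "nulls": ens, "pairs": pairs}


def build_annotation_table(
    meta: pd.DataFrame,
    annotations: pd.DataFrame,
    snps: pd.DataFrame,
    cadd_by_snp: pd.Series | None = None,
) -> pd.DataFrame:
    """Factored feature table for the prediction models from meta results."""
    maf_by_snp = snps.set_index("snp_id")["maf"]
    return prediction.bin_features(
        meta, annotations, maf_by_snp=maf_by_snp, cadd_by_snp=cadd_by_snp
    )
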