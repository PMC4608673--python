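"""Cross-cohort meta-analysis and permutation plug-in FDR.

The meta statistic for a SNP-probe pair is the sum of its per-cohort 1-df
chi-square statistics, distributed as chi-square with as many degrees of
freedom as contributing cohorts under the null.  False discovery rates are
estimated by whole-genome permutation: each permutation shuffles sample
labels of the genotype matrix within every cohort (preserving LD and the
expression covariance structure), the full scan and meta combination are
rerun, and the pooled null realizations feed the plug-in estimator

    FDR(t) = [ (1/k) * #{null >= t} ] / #{observed >= t},

capped at 1 and optionally monotonized into q-values (min over thresholds
at or below t).  Gene-wise FDR applies the same estimator to each gene's
maximum cis statistic against a matched permutation null of per-gene
maxima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import association_scan
from .types import GenotypeMatrix, StructuralError

logger = logging.getLogger(__name__)


@dataclass
class NullEnsemble:
    """Null statistics from k genotype permutations.

    ``pair_null`` holds, per permutation, the meta statistics aligned to the
    observed pair table; ``gene_null`` the per-gene maxima (aligned to
    ``gene_ids``).
    """

    k: int
    seed: int
    pair_null: list = field(default_factory=list)  # k arrays, len = n_pairs
    gene_ids: np.ndarray = None
    gene_null: list = field(default_factory=list)  # k arrays, len = n_genes


def meta_combine(tables: list[pd.DataFrame], mode: str = "intersection") -> pd.DataFrame:
    """Sum per-cohort statistics into the meta chi-square.

    Pairs are keyed by (snp_id, probe_id).  In ``intersection`` mode (the
    default, matching the summary-table convention in which the meta SNP
    count sits below every cohort's) only pairs present in all cohorts are
    kept and df equals the cohort count; in ``union`` mode all pairs are
    kept and df counts the contributing cohorts.
    """
    if mode not in ("intersection", "union"):
        raise ValueError(f"unknown mode {mode!r}")
    keys = ["snp_id", "probe_id", "gene_id", "distance"]
    merged = None
    for i, t in enumerate(tables):
        cols = t[keys + ["chi2"]].rename(columns={"chi2": f"chi2_c{i}"})
        if merged is None:
            merged = cols
        else:
            how = "inner" if mode == "intersection" else "outer"
            merged = merged.merge(cols, on=keys, how=how)
    if merged is None or len(merged) == 0:
        raise StructuralError(
            "empty pair intersection across cohorts; consider mode='union'"
        )
    chi_cols = [f"chi2_c{i}" for i in range(len(tables))]
    stat = merged[chi_cols].to_numpy(dtype=float)
    merged["df_meta"] = np.sum(~np.isnan(stat), axis=1)
    merged["chi2_meta"] = np.nansum(stat, axis=1)
    merged["p_meta"] = stats.chi2.sf(merged["chi2_meta"], df=merged["df_meta"])
    return merged


def permute_and_scan(
    genos: list[GenotypeMatrix],
    exprs: list,
    pairs: list[pd.DataFrame],
    k: int = 3,
    seed: int = 0,
    mode: str = "intersection",
) -> NullEnsemble:
    """Build the permutation null ensemble.

    For each of ``k`` permutations, an independent random sample-index
    permutation is drawn per cohort (stream keyed by (seed, cohort,
    permutation)) and applied to the genotype rows; the scan and meta
    combination are rerun on the permuted data.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    for gm in genos:
        if gm.n_samples < 3:
            raise ValueError("permutation requires n_samples >= 3")
    ens = NullEnsemble(k=k, seed=seed)
    for p in range(k):
        null_tables = []
        for c, (gm, em, pt) in enumerate(zip(genos, exprs, pairs)):
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), c, p]))
            perm = rng.permutation(gm.n_samples)
            gm_perm = GenotypeMatrix(
                sample_ids=gm.sample_ids,
                snp_ids=gm.snp_ids,
                positions=gm.positions,
                dosages=gm.dosages[perm],
                maf=gm.maf,
            )
            null_tables.append(association_scan(gm_perm, em, pt))
        null_meta = meta_combine(null_tables, mode=mode)
        ens.pair_null.append(null_meta["chi2_meta"].to_numpy())
        gene_max = null_meta.groupby("gene_id", sort=True)["chi2_meta"].max()
        if ens.gene_ids is None:
            ens.gene_ids = gene_max.index.to_numpy()
        ens.gene_null.append(gene_max.to_numpy())
    return ens


def plugin_fdr_values(
    observed: np.ndarray, null_pooled: np.ndarray, k: int, monotone: bool = True
) -> np.ndarray:
    """Plug-in FDR estimate at each observed statistic's threshold.

    ``null_pooled`` concatenates all k permutations' null statistics.  With
    ``monotone=True`` the raw estimates are converted to q-values:
    q(t) = min over thresholds t' <= t of FDR(t'), which is nonincreasing
    in t.
    """
    observed = np.asarray(observed, dtype=float)
    null_sorted = np.sort(np.asarray(null_pooled, dtype=float))
    obs_sorted = np.sort(observed)
    m = len(observed)
    n_obs_ge = m - np.searchsorted(obs_sorted, observed, side="left")
    n_null_ge = len(null_sorted) - np.searchsorted(null_sorted, observed, side="left")
    raw = np.minimum(1.0, (n_null_ge / k) / n_obs_ge)
    if not monotone:
        return raw
    order = np.argsort(observed, kind="stable")
    q_sorted = np.minimum.accumulate(raw[order])
    q = np.empty_like(raw)
    q[order] = q_sorted
    return q


def plugin_fdr(
    observed: pd.DataFrame,
    nulls: NullEnsemble,
    stat_col: str = "chi2_meta",
    monotone: bool = True,
) -> pd.DataFrame:
    """Attach pair-level plug-in FDR (column ``fdr_pair``).

    Nulls are pooled over all cis pairs genome-wide and all permutations.
    """
    if not nulls.pair_null:
        raise ValueError("empty null ensemble")
    pooled = np.concatenate(nulls.pair_null)
    out = observed.copy()
    out["fdr_pair"] = plugin_fdr_values(
        out[stat_col].to_numpy(), pooled, nulls.k, monotone=monotone
    )
    return out


def genewise_fdr(
    observed: pd.DataFrame,
    nulls: NullEnsemble,
    stat_col: str = "chi2_meta",
    monotone: bool = True,
) -> pd.DataFrame:
    """Gene-level plug-in FDR on each gene's maximum cis statistic.

    The observed gene statistic is the max of ``stat_col`` over the gene's
    cis pairs; the null pools per-gene maxima from every permutation.  The
    resulting FDR is broadcast back to the gene's pairs as ``fdr_gene``.
    """
    if not nulls.gene_null:
        raise ValueError("empty null ensemble")
    gene_obs = observed.groupby("gene_id", sort=True)[stat_col].max()
    pooled = np.concatenate(nulls.gene_null)
    fdr = plugin_fdr_values(gene_obs.to_numpy(), pooled, nulls.k, monotone=monotone)
    gene_fdr = pd.Series(fdr, index=gene_obs.index, name="fdr_gene")
    missing = set(nulls.gene_ids) - set(gene_obs.index) if nulls.gene_ids is not None else set()
    if missing:
        logger.warning("genes with no observed cis pairs excluded: %s", sorted(missing))
    out = observed.copy()
    out["fdr_gene"] = out["gene_id"].map(gene_fdr)
    return out


def significant_genes(table: pd.DataFrame, fdr_cut: float = 0.05) -> set:
    """Genes with at least one cis pair at gene-level FDR below the cutoff."""
    mask = table["fdr_gene"] < fdr_cut
    return set(table.loc[mask, "gene_id"].unique())


def significance_summary(
    table: pd.DataFrame, fdr_cut: float = 0.05, fdr_col: str = "fdr_gene",
    p_col: str = "p_meta",
) -> dict:
    """Counts of significant SNPs/genes/pairs plus min/max nominal P."""
    sig = table[table[fdr_col] < fdr_cut]
    return {
        "total_snps": int(table["snp_id"].nunique()),
        "signif_snps": int(sig["snp_id"].nunique()),
        "total_genes": int(table["gene_id"].nunique()),
        "signif_genes": int(sig["gene_id"].nunique()),
        "total_pairs": int(len(table)),
        "signif_pairs": int(len(sig)),
        "min_signif_p": float(sig[p_col].min()) if len(sig) else float("nan"),
        "max_signif_p": float(sig[p_col].max()) if len(sig) else float("nan"),
    }
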