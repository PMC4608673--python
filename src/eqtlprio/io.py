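"""Readers, writers, run manifests, and yield accounting.

TSV is the canonical interchange format; VCF (v4.2, DS or GT), BED4/BED6
and a gene/transcript GTF subset are supported at the edges.  All on-disk
coordinates follow the conventions of their formats (BED 0-based half-open,
VCF and GTF 1-based); in memory everything is 0-based half-open.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .meta_fdr import significance_summary
from .types import ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def write_genotypes_tsv(genos: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(genos.dosages.T, columns=genos.sample_ids)
    df.insert(0, "position", genos.positions)
    df.insert(0, "snp_id", genos.snp_ids)
    df.to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    sample_cols = [c for c in df.columns if c not in ("snp_id", "position")]
    return GenotypeMatrix(
        sample_ids=sample_cols,
        snp_ids=df["snp_id"].to_numpy(),
        positions=df["position"].to_numpy(),
        dosages=df[sample_cols].to_numpy(dtype=float).T,
    )


def write_vcf(genos: GenotypeMatrix, path, chrom: str = "chrS") -> None:
    """Minimal VCF v4.2 with GT and DS per sample (synthetic alleles A>G)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(genos.sample_ids) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j in range(genos.n_snps):
            calls = []
            for i in range(genos.n_samples):
                ds = genos.dosages[i, j]
                gt = gt_map.get(int(round(ds)), "./.")
                calls.append(f"{gt}:{ds:g}")
            fh.write(
                f"{chrom}\t{genos.positions[j] + 1}\t{genos.snp_ids[j]}"
                f"\tA\tG\t.\tPASS\t.\tGT:DS\t" + "\t".join(calls) + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into a dosage matrix, preferring DS over GT."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    snp_ids, positions, rows = [], [], []
    for v in vcf:
        snp_ids.append(v.ID)
        positions.append(v.POS - 1)  # VCF is 1-based
        try:
            ds = v.format("DS")
        except KeyError:  # DS absent from the FORMAT header
            ds = None
        if ds is not None:
            rows.append(np.asarray(ds, dtype=float).ravel())
        else:
            rows.append(np.array([a + b for a, b, *_ in v.genotypes], dtype=float))
    return GenotypeMatrix(
        sample_ids=sample_ids,
        snp_ids=snp_ids,
        positions=positions,
        dosages=np.array(rows).T,
    )


# ---------------------------------------------------------------------------
# expression / gene models / annotations
# ---------------------------------------------------------------------------

def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(expr.values.T, columns=expr.sample_ids)
    genes = [expr.probe_to_gene[p] for p in expr.probe_ids]
    df.insert(0, "end", [expr.gene_bounds[g][1] for g in genes])
    df.insert(0, "start", [expr.gene_bounds[g][0] for g in genes])
    df.insert(0, "gene_id", genes)
    df.insert(0, "probe_id", expr.probe_ids)
    df.to_csv(path, sep="\t", index=False)


def read_expression_tsv(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t")
    meta = ["probe_id", "gene_id", "start", "end"]
    sample_cols = [c for c in df.columns if c not in meta]
    return ExpressionMatrix(
        sample_ids=sample_cols,
        probe_ids=df["probe_id"].to_numpy(),
        values=df[sample_cols].to_numpy(dtype=float).T,
        probe_to_gene=dict(zip(df["probe_id"], df["gene_id"])),
        gene_bounds={r.gene_id: (int(r.start), int(r.end)) for r in df.itertuples()},
    )


def write_gene_models_bed6(genes: pd.DataFrame, path) -> None:
    genes[["chrom", "start", "end", "gene_id", "score", "strand"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_gene_models_bed6(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
    )
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise ValueError(f"BED records with start >= end at lines {list(bad + 1)}")
    return df


def read_gtf_genes(path) -> pd.DataFrame:
    """Read gene/transcript features from a GTF subset (1-based, inclusive)
    into the internal 0-based half-open convention."""
    cols = ["chrom", "source", "feature", "start", "end", "score", "strand",
            "frame", "attributes"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    df = df[df["feature"].isin(["gene", "transcript"])].copy()
    df["gene_id"] = df["attributes"].str.extract(r'gene_id "([^"]+)"')
    if df["gene_id"].isna().any():
        bad = df.index[df["gene_id"].isna()][0] + 1
        raise ValueError(f"GTF record without gene_id at line {bad}")
    df["start"] = df["start"].astype(int) - 1  # GTF 1-based inclusive -> 0-based half-open
    df["end"] = df["end"].astype(int)
    return df[["chrom", "start", "end", "gene_id", "feature", "strand"]]


def write_states_bed4(segments: pd.DataFrame, path, chrom: str = "chrS") -> None:
    out = segments.copy()
    out.insert(0, "chrom", chrom)
    out[["chrom", "start", "end", "state"]].to_csv(path, sep="\t", index=False, header=False)


def read_states_bed4(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "state"])


def write_catalog_tsv(catalog: pd.DataFrame, path) -> None:
    catalog.to_csv(path, sep="\t", index=False)


def read_catalog_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_manifest(manifest: dict, path) -> None:
    """Run manifest: seeds, bin edges, thresholds -- everything needed to
    reproduce outputs bit-for-bit."""
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# yield accounting
# ---------------------------------------------------------------------------

@dataclass
class YieldSummary:
    """Summary-table-style counts per source plus the overlap partition.

    ``per_source`` maps each cohort name, "UNION" and "META" to count
    dictionaries; ``overlap`` partitions the union of all significant genes
    by how many cohorts detected them (``{m}C``) crossed with meta
    membership, plus the meta-only category.
    """

    fdr_cut: float
    per_source: dict = field(default_factory=dict)
    overlap: dict = field(default_factory=dict)

    def overlap_partition_total(self) -> int:
        total = self.overlap["meta_only"]
        for m in (1, 2, 3, 4):
            cat = self.overlap.get(f"{m}C", {"total": 0})
            total += cat["total"]
        return total


def yield_summary(
    cohort_results: dict,
    meta_results: pd.DataFrame,
    fdr_cut: float = 0.05,
) -> YieldSummary:
    """Compute per-source significance counts and the gene-overlap partition.

    ``cohort_results`` maps cohort name to a scanned pair table carrying
    ``fdr_gene`` and ``p`` columns; ``meta_results`` carries ``fdr_gene``
    and ``p_meta``.
    """
    meta_genes = set(meta_results.columns) >= {"gene_id"}
    if not meta_genes:
        raise ValueError("meta results lack a gene_id column")
    summary = YieldSummary(fdr_cut=fdr_cut)
    sig_sets = {}
    for name, table in cohort_results.items():
        summary.per_source[name] = significance_summary(
            table, fdr_cut, fdr_col="fdr_gene", p_col="p"
        )
        sig_sets[name] = set(table.loc[table["fdr_gene"] < fdr_cut, "gene_id"])
    meta_sig = set(meta_results.loc[meta_results["fdr_gene"] < fdr_cut, "gene_id"])
    summary.per_source["META"] = significance_summary(
        meta_results, fdr_cut, fdr_col="fdr_gene", p_col="p_meta"
    )
    union = set().union(*sig_sets.values()) if sig_sets else set()
    summary.per_source["UNION"] = {
        "signif_genes": len(union),
        "total_genes": int(
            len(set().union(*(set(t["gene_id"]) for t in cohort_results.values())))
        ) if cohort_results else 0,
    }

    n_cohorts = len(cohort_results)
    overlap = {"meta_only": len(meta_sig - union)}
    for m in range(1, n_cohorts + 1):
        in_m = {g for g in union if sum(g in s for s in sig_sets.values()) == m}
        overlap[f"{m}C"] = {"total": len(in_m), "in_meta": len(in_m & meta_sig)}
    summary.overlap = overlap

    # partition identity: categories cover union-with-meta exactly once
    assert summary.overlap_partition_total() == len(union | meta_sig)
    return summary
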