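"""Synthetic multi-cohort eQTL study generator.

Emulates the study design that motivates the pipeline: four blood-derived
cohorts (default sample sizes 73/113/198/202) genotyped on a shared SNP
panel, expression measured on one probe per gene, a fraction of genes
carrying a planted cis-eQTL (shared across cohorts or cohort-specific),
low-rank confounder/batch structure, a 15-state chromatin segmentation with
optional enrichment of regulatory states near causal SNPs, and GWAS-catalog
membership labels drawn from a logistic model on binned annotations with a
configurable marginal base rate (default 3.5%).

Every generator is a pure function of ``(config, seed)``: the same config
yields bit-identical output.  Randomness is partitioned into independent
streams via :class:`numpy.random.SeedSequence` so that, e.g., regenerating
genotypes for cohort 2 never perturbs cohort 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .types import ConfigurationError, ExpressionMatrix, GenotypeMatrix, StructuralError

#: The 15 chromatin-state labels of the GM12878 LCL segmentation, plus the
#: implicit "none" for positions outside every segment.
CHROM_STATES = [
    "(1) Active Promoter",
    "(2) Weak Promoter",
    "(3) Poised Promoter",
    "(4) Strong Enhancer",
    "(5) Strong Enhancer",
    "(6) Weak Enhancer",
    "(7) Weak Enhancer",
    "(8) Insulator",
    "(9) Txn Transition",
    "(10) Txn Elongation",
    "(11) Weak Txn",
    "(12) Repressed",
    "(13) Heterochromatin",
    "(14) Repetitive/CNV",
    "(15) Repetitive/CNV",
]
STATE_NONE = "(-) none"

#: States that preferentially harbor regulatory variants; used when
#: ``state_enrichment > 0`` to re-label segments containing causal SNPs.
REGULATORY_STATES = [
    "(1) Active Promoter",
    "(4) Strong Enhancer",
    "(7) Weak Enhancer",
    "(9) Txn Transition",
    "(10) Txn Elongation",
]

# stream tags for SeedSequence partitioning
_TAG_MAF = 11
_TAG_GENES = 12
_TAG_DOSAGE = 13
_TAG_EXPR = 14
_TAG_ANNOT = 15
_TAG_GWAS = 16


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    ``n_samples`` may be a single int (all cohorts equal) or one int per
    cohort.  ``beta_dist`` is the (mean, sd) of the planted effect size on
    standardized expression; ``share_prob`` is the probability a planted
    effect is shared by all cohorts rather than private to one.
    ``gwas_coefs`` maps ``"column:level"`` strings to log-odds contributions
    of annotation levels in the label-generating logistic model.
    """

    n_cohorts: int = 4
    n_samples: tuple = (73, 113, 198, 202)
    n_genes: int = 300
    n_snps_per_gene: int = 20
    cis_radius: int = 100_000
    eqtl_fraction: float = 0.3
    beta_dist: tuple = (0.55, 0.10)
    share_prob: float = 0.7
    n_confounders: int = 5
    confounder_sd: float = 0.3
    batch_sd: float = 0.2
    noise_sd: float = 1.0
    gwas_base_rate: float = 0.035
    gwas_coefs: dict = field(default_factory=dict)
    seed: int = 0
    maf_range: tuple = (0.01, 0.5)
    ld_rho: float = 0.0
    state_enrichment: float = 0.0
    chrom_length: int | None = None

    def __post_init__(self):
        if isinstance(self.n_samples, (int, np.integer)):
            self.n_samples = tuple([int(self.n_samples)] * self.n_cohorts)
        else:
            self.n_samples = tuple(int(n) for n in self.n_samples)
        if len(self.n_samples) != self.n_cohorts:
            raise ConfigurationError(
                f"n_samples has {len(self.n_samples)} entries for "
                f"{self.n_cohorts} cohorts"
            )
        for name in ("n_cohorts", "n_genes", "n_snps_per_gene", "cis_radius"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if any(n <= 0 for n in self.n_samples):
            raise ConfigurationError("all cohort sample sizes must be > 0")
        for name in ("eqtl_fraction", "share_prob", "gwas_base_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(
                f"maf_range {self.maf_range} must satisfy 0 < lo <= hi <= 0.5"
            )
        if not 0.0 <= self.ld_rho < 1.0:
            raise ConfigurationError("ld_rho must lie in [0, 1)")

    def rng(self, *tags: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), *tags]))


def simulate_gene_models(config: SimConfig) -> pd.DataFrame:
    """Lay out non-overlapping transcripts and their cis SNP slots.

    Genes are spaced so that their cis windows (transcript +/- cis_radius)
    are disjoint, which keeps every SNP assigned to exactly one gene.
    Returns a BED6-like DataFrame (chrom, start, end, gene_id, score,
    strand) sorted by start.
    """
    rng = config.rng(_TAG_GENES)
    lengths = rng.integers(5_000, 50_000, size=config.n_genes)
    # disjoint cis windows: gap between consecutive windows >= 1 kb
    pitch = 2 * config.cis_radius + 1_000
    starts = np.empty(config.n_genes, dtype=np.int64)
    pos = config.cis_radius + 1_000
    for i in range(config.n_genes):
        starts[i] = pos
        pos += lengths[i] + pitch
    required = int(pos)
    if config.chrom_length is not None and config.chrom_length < required:
        raise ConfigurationError(
            f"chrom_length={config.chrom_length} too short to place "
            f"{config.n_genes} genes (need >= {required})"
        )
    strands = rng.choice(["+", "-"], size=config.n_genes)
    return pd.DataFrame(
        {
            "chrom": "chrS",
            "start": starts,
            "end": starts + lengths,
            "gene_id": [f"G{i:05d}" for i in range(config.n_genes)],
            "score": 0,
            "strand": strands,
        }
    )


def snp_map(config: SimConfig) -> pd.DataFrame:
    """Deterministic SNP panel shared by all cohorts.

    Each gene gets ``n_snps_per_gene`` SNPs placed uniformly within its cis
    window, with per-SNP MAF drawn from the configured spectrum.  Columns:
    snp_id, position, maf, gene_id.
    """
    genes = simulate_gene_models(config)
    rng = config.rng(_TAG_MAF)
    rows = []
    for _, g in genes.iterrows():
        lo = g.start - config.cis_radius
        hi = g.end + config.cis_radius  # exclusive
        pos = np.sort(
            rng.choice(np.arange(lo, hi, dtype=np.int64), size=config.n_snps_per_gene, replace=False)
        )
        for p in pos:
            rows.append((g.gene_id, int(p)))
    df = pd.DataFrame(rows, columns=["gene_id", "position"])
    df["snp_id"] = [f"rs{i:07d}" for i in range(len(df))]
    lo, hi = config.maf_range
    df["maf"] = rng.uniform(lo, hi, size=len(df))
    return df[["snp_id", "position", "maf", "gene_id"]]


def simulate_genotypes(config: SimConfig, cohort_index: int) -> GenotypeMatrix:
    """Draw hard-call dosages for one cohort on the shared SNP panel.

    Dosages are binomial(2, p) under Hardy-Weinberg equilibrium with the
    panel's allele frequencies.  With ``ld_rho > 0`` haplotypes are built by
    an autoregressive copying walk within each gene block, inducing
    block-local LD with neighbor correlation ~``ld_rho``.
    """
    if not 0 <= cohort_index < config.n_cohorts:
        raise ConfigurationError(
            f"cohort_index {cohort_index} outside 0..{config.n_cohorts - 1}"
        )
    snps = snp_map(config)
    n = config.n_samples[cohort_index]
    rng = config.rng(_TAG_DOSAGE, cohort_index)
    p = snps["maf"].to_numpy()
    if config.ld_rho == 0.0:
        dos = rng.binomial(2, p[None, :], size=(n, len(p))).astype(float)
    else:
        dos = _ld_block_dosages(rng, p, snps["gene_id"].to_numpy(), n, config.ld_rho)
    sample_ids = [f"C{cohort_index}_S{j:04d}" for j in range(n)]
    return GenotypeMatrix(
        sample_ids=sample_ids,
        snp_ids=snps["snp_id"].to_numpy(),
        positions=snps["position"].to_numpy(),
        dosages=dos,
    )


def _ld_block_dosages(rng, p, gene_ids, n, rho):
    """Haplotype-copying LD: within a gene block, each haplotype allele is
    copied from the previous SNP with probability rho, else redrawn."""
    m = len(p)
    out = np.zeros((n, m))
    new_block = np.r_[True, gene_ids[1:] != gene_ids[:-1]]
    for _hap in range(2):
        h = np.zeros((n, m), dtype=np.int8)
        for j in range(m):
            fresh = rng.random(n) < p[j]
            if new_block[j]:
                h[:, j] = fresh
            else:
                copy = rng.random(n) < rho
                h[:, j] = np.where(copy, h[:, j - 1], fresh)
        out += h
    return out


def beta_for_r2(r2: float, maf: float, total_noise_var: float) -> float:
    """Effect size beta such that the causal SNP explains a fraction ``r2``
    of expression variance at the given MAF, when non-genetic variance
    (noise + confounders + batch) is ``total_noise_var``."""
    var_g = 2.0 * maf * (1.0 - maf)
    return float(np.sqrt(r2 / (1.0 - r2) * total_noise_var / var_g))


def nongenetic_variance(config: SimConfig) -> float:
    """Total variance of the non-genetic part of the expression model."""
    return (
        config.noise_sd**2
        + config.n_confounders * config.confounder_sd**2
        + config.batch_sd**2
    )


def simulate_expression(
    genos: list, genes: pd.DataFrame, config: SimConfig
) -> tuple[list, pd.DataFrame]:
    """Generate per-cohort expression with planted cis effects.

    expression = beta * dosage(causal SNP) + latent factors . loadings
                 + per-(cohort, gene) batch offset + N(0, noise_sd) noise

    An ``eqtl_fraction`` of genes receive a causal SNP chosen uniformly from
    their cis panel; with probability ``share_prob`` the same (SNP, beta)
    acts in every cohort, otherwise in exactly one randomly chosen cohort.
    Returns one ExpressionMatrix per cohort and a truth table with one row
    per planted effect and per-cohort beta columns.
    """
    if len(genos) != config.n_cohorts:
        raise StructuralError(
            f"got {len(genos)} genotype matrices for {config.n_cohorts} cohorts"
        )
    rng = config.rng(_TAG_EXPR)
    snps = snp_map(config)
    gene_ids = genes["gene_id"].to_numpy()
    n_genes = len(gene_ids)
    n_causal = int(round(config.eqtl_fraction * n_genes))
    causal_genes = rng.choice(gene_ids, size=n_causal, replace=False)

    snps_by_gene = {g: grp["snp_id"].to_numpy() for g, grp in snps.groupby("gene_id")}
    mean_b, sd_b = config.beta_dist
    truth_rows = []
    beta_mat = {c: np.zeros(n_genes) for c in range(config.n_cohorts)}
    causal_col = {}  # gene index -> snp_id
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for g in causal_genes:
        snp = rng.choice(snps_by_gene[g])
        beta = rng.normal(mean_b, sd_b)
        shared = rng.random() < config.share_prob
        cohorts = (
            list(range(config.n_cohorts))
            if shared
            else [int(rng.integers(config.n_cohorts))]
        )
        for c in cohorts:
            beta_mat[c][gene_pos[g]] = beta
        causal_col[gene_pos[g]] = snp
        truth_rows.append(
            {
                "gene_id": g,
                "causal_snp_id": snp,
                "shared": shared,
                **{f"beta_c{c}": (beta if c in cohorts else 0.0) for c in range(config.n_cohorts)},
            }
        )

    probe_ids = np.array([f"{g}_p1" for g in gene_ids], dtype=object)
    probe_to_gene = dict(zip(probe_ids, gene_ids))
    gene_bounds = {
        r.gene_id: (int(r.start), int(r.end)) for r in genes.itertuples()
    }

    exprs = []
    for c, gm in enumerate(genos):
        n = gm.n_samples
        snp_idx = gm.snp_index()
        genetic = np.zeros((n, n_genes))
        for gi, snp in causal_col.items():
            b = beta_mat[c][gi]
            if b != 0.0:
                genetic[:, gi] = b * gm.dosages[:, snp_idx[snp]]
        factors = rng.normal(size=(n, config.n_confounders))
        loadings = rng.normal(scale=config.confounder_sd, size=(config.n_confounders, n_genes))
        batch = rng.normal(scale=config.batch_sd, size=n_genes)
        noise = rng.normal(scale=config.noise_sd, size=(n, n_genes))
        values = genetic + factors @ loadings + batch[None, :] + noise
        exprs.append(
            ExpressionMatrix(
                sample_ids=gm.sample_ids,
                probe_ids=probe_ids,
                values=values,
                probe_to_gene=probe_to_gene,
                gene_bounds=gene_bounds,
            )
        )
    truth_cols = ["gene_id", "causal_snp_id", "shared"] + [
        f"beta_c{c}" for c in range(config.n_cohorts)
    ]
    truth = pd.DataFrame(truth_rows, columns=truth_cols)
    return exprs, truth


def simulate_annotations(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    config: SimConfig,
    causal_snp_ids=(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign chromatin states and structural classes to SNPs.

    The chromosome is tiled with segments (lengths uniform 500-5000 bp) each
    bearing one of the 15 states; 20% of the tiling is left unannotated so
    SNPs falling there get "(-) none".  With ``state_enrichment > 0``,
    segments containing a causal SNP are re-labelled to a regulatory state
    with that probability, correlating chromatin annotation with true eQTLs.

    Returns ``(annotations, segments)`` where annotations has columns
    snp_id, position, chrom_state, structural_class and segments is a
    BED4-style table of the emitted state intervals.
    """
    rng = config.rng(_TAG_ANNOT)
    chrom_end = int(genes["end"].max()) + config.cis_radius
    # tile [0, chrom_end) with segments; each segment is annotated with
    # probability 0.8, else a gap ("none")
    seg_rows = []
    pos = 0
    while pos < chrom_end:
        length = int(rng.integers(500, 5_000))
        end = min(pos + length, chrom_end)
        if rng.random() < 0.8:
            state = CHROM_STATES[int(rng.integers(15))]
            seg_rows.append((pos, end, state))
        pos = end
    segments = pd.DataFrame(seg_rows, columns=["start", "end", "state"])

    causal = set(causal_snp_ids)
    if config.state_enrichment > 0 and causal:
        causal_pos = snps.loc[snps["snp_id"].isin(causal), "position"].to_numpy()
        starts = segments["start"].to_numpy()
        ends = segments["end"].to_numpy()
        for cp in causal_pos:
            hit = np.flatnonzero((starts <= cp) & (cp < ends))
            if hit.size and rng.random() < config.state_enrichment:
                segments.loc[hit[0], "state"] = REGULATORY_STATES[
                    int(rng.integers(len(REGULATORY_STATES)))
                ]

    # interval intersection: each SNP falls in at most one segment
    starts = segments["start"].to_numpy()
    ends = segments["end"].to_numpy()
    pos_arr = snps["position"].to_numpy()
    idx = np.searchsorted(starts, pos_arr, side="right") - 1
    state = np.full(len(pos_arr), STATE_NONE, dtype=object)
    valid = idx >= 0
    inside = valid & (pos_arr < ends[np.clip(idx, 0, None)])
    state[inside] = segments["state"].to_numpy()[idx[inside]]

    structural = _structural_classes(snps, genes, rng)
    annotations = pd.DataFrame(
        {
            "snp_id": snps["snp_id"].to_numpy(),
            "position": pos_arr,
            "chrom_state": state,
            "structural_class": structural,
        }
    )
    return annotations, segments


def _structural_classes(snps, genes, rng):
    """SNPs inside a transcript get intron/coding/UTR (85/10/5), else none."""
    gstart = genes["start"].to_numpy()
    gend = genes["end"].to_numpy()
    order = np.argsort(gstart)
    gstart, gend = gstart[order], gend[order]
    pos = snps["position"].to_numpy()
    idx = np.searchsorted(gstart, pos, side="right") - 1
    inside = (idx >= 0) & (pos < gend[np.clip(idx, 0, None)])
    out = np.full(len(pos), "none", dtype=object)
    n_in = int(inside.sum())
    if n_in:
        out[inside] = rng.choice(
            ["intron", "coding", "UTR"], size=n_in, p=[0.85, 0.10, 0.05]
        )
    return out


#: Default marginal frequencies of the factored features used by
#: :func:`simulate_feature_table`.  Most pairs sit far from significance
#: (FDR > 50%) and in non-regulatory chromatin, as in real cis scans.
DEFAULT_FEATURE_MARGINALS = {
    "distance_bin": (
        ["0 kb (within gene)", "(0-10 kb]", "(10-50 kb]", "(50-100 kb]"],
        [0.15, 0.10, 0.35, 0.40],
    ),
    "maf_bin": (["[1-5%]", "(5-10%]", ">10%"], [0.08, 0.10, 0.82]),
    "chrom_state": (
        [STATE_NONE, *CHROM_STATES],
        # none-heavy, heterochromatin-dominated genome with modest
        # regulatory fractions
        [0.20, 0.03, 0.02, 0.01, 0.03, 0.02, 0.02, 0.03, 0.02, 0.03,
         0.06, 0.05, 0.05, 0.35, 0.04, 0.04],
    ),
    "structural_class": (["none", "intron", "coding", "UTR"], [0.60, 0.32, 0.05, 0.03]),
    "fdr_bin": (
        ["[0-1%)", "[1-5%)", "[5-10%)", "[10-50%)", ">50%"],
        [0.04, 0.03, 0.02, 0.11, 0.80],
    ),
    "cadd_bin": (
        ["[0, 5]", "(5, 10]", "(10, 20]", "(20, 30]", "(30, 60]"],
        [0.60, 0.25, 0.10, 0.04, 0.01],
    ),
}


def simulate_feature_table(
    n_pairs: int, config: SimConfig, marginals: dict | None = None
) -> pd.DataFrame:
    """Draw a standalone factored annotation table of SNP-probe pairs.

    Feature levels are drawn independently from the given marginal
    frequencies (defaults above).  This bypasses the genotype/expression
    machinery and is the scale-friendly route for studying the logistic
    label model itself (e.g. coefficient recovery at hundreds of thousands
    of pairs).
    """
    if n_pairs <= 0:
        raise ConfigurationError("n_pairs must be > 0")
    marginals = marginals or DEFAULT_FEATURE_MARGINALS
    rng = config.rng(_TAG_GWAS, 1)
    out = {
        "snp_id": [f"rs{i:07d}" for i in range(n_pairs)],
        "probe_id": [f"P{i:07d}" for i in range(n_pairs)],
        "gene_id": [f"G{i // 30:06d}" for i in range(n_pairs)],
    }
    for col, (levels, probs) in marginals.items():
        probs = np.asarray(probs, dtype=float)
        draw = rng.choice(len(levels), size=n_pairs, p=probs / probs.sum())
        out[col] = pd.Categorical.from_codes(draw, categories=levels)
    return pd.DataFrame(out)


def simulate_gwas_catalog(
    features: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, dict]:
    """Draw GWAS-catalog membership labels from a logistic annotation model.

    ``features`` must hold factored annotation columns (any subset of the
    keys appearing in ``config.gwas_coefs``, which are "column:level"
    strings).  The intercept is calibrated by root finding so the marginal
    label rate matches ``gwas_base_rate``; labels are then independent
    Bernoulli draws.  Returns the labelled catalog (input columns plus
    ``gwas_hit``) and the generating truth (intercept + coefficients).
    """
    rng = config.rng(_TAG_GWAS)
    lin = np.zeros(len(features))
    seen_cols = set()
    for key, coef in config.gwas_coefs.items():
        col, _, level = key.partition(":")
        if col not in features.columns:
            raise ConfigurationError(f"gwas_coefs references unknown column {col!r}")
        col_vals = features[col].astype(object)
        if level not in set(col_vals.unique()) and coef != 0.0:
            # allowed: a configured level absent from this draw contributes nothing,
            # but a typo'd level should fail loudly when it can never match
            known = set()
            if isinstance(features[col].dtype, pd.CategoricalDtype):
                known = set(features[col].cat.categories)
            if known and level not in known:
                raise ConfigurationError(
                    f"gwas_coefs level {level!r} not a level of column {col!r}"
                )
        lin += np.where(col_vals.to_numpy() == level, coef, 0.0)
        seen_cols.add(col)

    def rate(c):
        return expit(c + lin).mean() - config.gwas_base_rate

    intercept = brentq(rate, -40.0, 40.0)
    prob = expit(intercept + lin)
    labels = (rng.random(len(features)) < prob).astype(int)
    catalog = features.copy()
    catalog["gwas_hit"] = labels
    truth = {"intercept": float(intercept), "coefs": dict(config.gwas_coefs)}
    return catalog, truth
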