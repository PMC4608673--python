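"""Logistic prediction of GWAS-catalog membership from binned annotations.

Every SNP-probe pair is described by factored features -- distance from the
target transcript, MAF bin, chromatin state, structural class, eQTL FDR
bin, optionally a CADD-score bin -- and a dummy-coded multivariate logistic
regression predicts whether the SNP is a reported GWAS hit (or a close LD
proxy, r^2 > 0.8).  The model menu:

    M1      distance + MAF + structural class
    M2      distance + MAF + chromatin state
    M3      distance + MAF + chromatin state + FDR bin
    M3B     M3 without distance
    M3+CADD M3 plus CADD bin

Training pairs come from an LD-pruned SNP set (variance-inflation-factor
pruning, PLINK-style defaults); all remaining pairs form the test set.
Evaluation covers calibration against equal-width probability bins anchored
on the widest-ranged model, ROC/AUC, and a chromatin-state x FDR-bin
cross-tabulation of the pairs in the top predicted-probability bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm
from sklearn.metrics import roc_auc_score, roc_curve

from .synthetic import CHROM_STATES, STATE_NONE
from .types import GenotypeMatrix

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# factor level registries (labels and base levels)
# ---------------------------------------------------------------------------

DISTANCE_LEVELS = ["0 kb (within gene)", "(0-10 kb]", "(10-50 kb]", "(50-100 kb]"]
DISTANCE_BASE = "0 kb (within gene)"
DISTANCE_EDGES = [0, 10_000, 50_000, 100_000]  # upper edges of the non-zero bins

MAF_LEVELS = ["[1-5%]", "(5-10%]", ">10%"]
MAF_BASE = ">10%"

FDR_LEVELS = ["[0-1%)", "[1-5%)", "[5-10%)", "[10-50%)", ">50%"]
FDR_BASE = ">50%"
FDR_EDGES = [0.0, 0.01, 0.05, 0.10, 0.50, 1.0 + 1e-12]  # right-open except last

CADD_LEVELS = ["[0, 5]", "(5, 10]", "(10, 20]", "(20, 30]", "(30, 60]"]
CADD_BASE = "[0, 5]"
CADD_EDGES = [0.0, 5.0, 10.0, 20.0, 30.0, 60.0]  # left-closed first bin, then right-closed

STATE_LEVELS = [STATE_NONE, *CHROM_STATES]
STATE_BASE = "(13) Heterochromatin"

STRUCT_LEVELS = ["none", "intron", "coding", "UTR"]
STRUCT_BASE = "none"

MODEL_FACTORS = {
    "M1": ["distance_bin", "maf_bin", "structural_class"],
    "M2": ["distance_bin", "maf_bin", "chrom_state"],
    "M3": ["distance_bin", "maf_bin", "chrom_state", "fdr_bin"],
    "M3B": ["maf_bin", "chrom_state", "fdr_bin"],
    "M3+CADD": ["distance_bin", "maf_bin", "chrom_state", "fdr_bin", "cadd_bin"],
}

FACTOR_LEVELS = {
    "distance_bin": (DISTANCE_LEVELS, DISTANCE_BASE),
    "maf_bin": (MAF_LEVELS, MAF_BASE),
    "chrom_state": (STATE_LEVELS, STATE_BASE),
    "structural_class": (STRUCT_LEVELS, STRUCT_BASE),
    "fdr_bin": (FDR_LEVELS, FDR_BASE),
    "cadd_bin": (CADD_LEVELS, CADD_BASE),
}


# ---------------------------------------------------------------------------
# feature construction
# ---------------------------------------------------------------------------

def bin_distance(distance: np.ndarray) -> pd.Categorical:
    d = np.asarray(distance)
    lab = np.empty(len(d), dtype=object)
    lab[d == 0] = DISTANCE_LEVELS[0]
    lab[(d > 0) & (d <= DISTANCE_EDGES[1])] = DISTANCE_LEVELS[1]
    lab[(d > DISTANCE_EDGES[1]) & (d <= DISTANCE_EDGES[2])] = DISTANCE_LEVELS[2]
    lab[d > DISTANCE_EDGES[2]] = DISTANCE_LEVELS[3]
    return pd.Categorical(lab, categories=DISTANCE_LEVELS)


def bin_maf(maf: np.ndarray) -> pd.Categorical:
    m = np.asarray(maf)
    lab = np.where(m > 0.10, MAF_LEVELS[2], np.where(m > 0.05, MAF_LEVELS[1], MAF_LEVELS[0]))
    return pd.Categorical(lab, categories=MAF_LEVELS)


def bin_fdr(fdr: np.ndarray) -> pd.Categorical:
    f = np.clip(np.asarray(fdr, dtype=float), 0.0, 1.0)
    idx = np.searchsorted(FDR_EDGES[1:-1], f, side="right")  # right-open bins
    return pd.Categorical(np.asarray(FDR_LEVELS, dtype=object)[idx], categories=FDR_LEVELS)


def bin_cadd(cadd: np.ndarray) -> pd.Categorical:
    c = np.asarray(cadd, dtype=float)
    if np.any(c > CADD_EDGES[-1]):
        logger.warning("CADD scores above %s clamped to last bin", CADD_EDGES[-1])
        c = np.minimum(c, CADD_EDGES[-1])
    # first bin closed on both sides, the rest (lo, hi]
    idx = np.clip(np.searchsorted(CADD_EDGES[1:-1], c, side="left"), 0, len(CADD_LEVELS) - 1)
    return pd.Categorical(np.asarray(CADD_LEVELS, dtype=object)[idx], categories=CADD_LEVELS)


def bin_features(
    pairs: pd.DataFrame,
    annots: pd.DataFrame,
    maf_by_snp: pd.Series | None = None,
    cadd_by_snp: pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble the factored annotation table for SNP-probe pairs.

    ``pairs`` needs snp_id, probe_id, gene_id, distance and (if available)
    fdr_pair; ``annots`` maps snp_id to chrom_state / structural_class.
    SNPs missing a chromatin-state overlap get the "none" level.
    """
    out = pairs[["snp_id", "probe_id", "gene_id"]].copy()
    out["distance_bin"] = bin_distance(pairs["distance"].to_numpy())
    if maf_by_snp is not None:
        out["maf_bin"] = bin_maf(pairs["snp_id"].map(maf_by_snp).to_numpy())
    ann = annots.set_index("snp_id")
    state = pairs["snp_id"].map(ann["chrom_state"]).fillna(STATE_NONE)
    out["chrom_state"] = pd.Categorical(state, categories=STATE_LEVELS)
    if "structural_class" in ann.columns:
        struct = pairs["snp_id"].map(ann["structural_class"]).fillna("none")
        out["structural_class"] = pd.Categorical(struct, categories=STRUCT_LEVELS)
    if "fdr_pair" in pairs.columns:
        out["fdr_bin"] = bin_fdr(pairs["fdr_pair"].to_numpy())
    if cadd_by_snp is not None:
        out["cadd_bin"] = bin_cadd(pairs["snp_id"].map(cadd_by_snp).to_numpy())
    return out


def assign_gwas_labels(
    snps: pd.DataFrame,
    catalog_snp_ids,
    reference: GenotypeMatrix,
    r2_threshold: float = 0.8,
    window: int = 250_000,
) -> pd.Series:
    """Label SNPs that are catalog entries or close LD proxies of one.

    A SNP is labelled 1 iff it is itself in the catalog or its dosage
    correlation with a catalog SNP within ``window`` bp exceeds
    ``r2_threshold`` in the reference panel.  Catalog SNPs absent from the
    reference are logged and can only label themselves.
    """
    catalog = set(catalog_snp_ids)
    labels = snps["snp_id"].isin(catalog).to_numpy()
    ref_idx = reference.snp_index()
    pos_by_id = dict(zip(reference.snp_ids, reference.positions))
    D = reference.dosages
    Dc = D - D.mean(axis=0)
    sd = D.std(axis=0)
    snp_pos = snps["position"].to_numpy()
    snp_ids = snps["snp_id"].to_numpy()
    order = np.argsort(snp_pos)
    for cs in sorted(catalog):
        if cs not in ref_idx:
            logger.warning("catalog SNP %s absent from reference; own proxy only", cs)
            continue
        j = ref_idx[cs]
        if sd[j] == 0:
            continue
        cpos = pos_by_id[cs]
        lo = np.searchsorted(snp_pos[order], cpos - window, side="left")
        hi = np.searchsorted(snp_pos[order], cpos + window, side="right")
        for oi in order[lo:hi]:
            sid = snp_ids[oi]
            if labels[oi] or sid not in ref_idx:
                continue
            i = ref_idx[sid]
            if sd[i] == 0:
                continue
            r = (Dc[:, i] @ Dc[:, j]) / (len(D) * sd[i] * sd[j])
            if r * r > r2_threshold:
                labels[oi] = True
    return pd.Series(labels.astype(int), index=snps.index, name="gwas_hit")


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def ld_prune(
    genos: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    vif_threshold: float = 2.0,
) -> set:
    """PLINK-style sliding-window VIF pruning.

    Within each window of ``window`` currently retained SNPs, the SNP with
    the largest variance inflation factor (against the other window SNPs)
    is dropped repeatedly until all pass ``vif_threshold``; the window then
    slides by ``step``.  Returns the retained snp_id set.
    """
    if not (window > step > 0):
        raise ValueError("need window > step > 0")
    if vif_threshold <= 1:
        raise ValueError("vif_threshold must exceed 1")
    D = genos.dosages
    keep = np.ones(genos.n_snps, dtype=bool)
    sd = D.std(axis=0)
    keep[sd == 0] = False  # monomorphic SNPs carry no information
    start = 0
    while True:
        kept_idx = np.flatnonzero(keep)
        in_win = kept_idx[(kept_idx >= start) & (kept_idx < start + window)]
        changed = True
        while changed and len(in_win) > 1:
            changed = False
            X = D[:, in_win]
            R = np.corrcoef(X, rowvar=False)
            # ridge keeps inversion defined for duplicate columns; their VIF
            # is then enormous and they get pruned first
            vif = np.diag(np.linalg.inv(R + 1e-8 * np.eye(len(in_win))))
            worst = int(np.argmax(vif))
            if vif[worst] > vif_threshold:
                keep[in_win[worst]] = False
                in_win = np.delete(in_win, worst)
                changed = True
        if start + window >= genos.n_snps:
            break
        start += step
    return set(genos.snp_ids[keep])


# ---------------------------------------------------------------------------
# model fitting and evaluation
# ---------------------------------------------------------------------------

@dataclass
class PredictionModel:
    """Fitted dummy-coded logistic model with its factor registry."""

    model_name: str
    params: pd.Series  # includes "const"
    bse: pd.Series
    wald_p: pd.Series
    factors: dict = field(default_factory=dict)  # col -> (fitted levels, base)

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.params.drop("const"))

    def coefficient_table(self) -> pd.DataFrame:
        """Forest-plot-ready table: term, log-odds, SE, OR, Wald p."""
        terms = self.params.index.drop("const")
        return pd.DataFrame(
            {
                "term": terms,
                "coef": self.params[terms].to_numpy(),
                "se": self.bse[terms].to_numpy(),
                "odds_ratio": np.exp(self.params[terms].to_numpy()),
                "wald_p": self.wald_p[terms].to_numpy(),
            }
        )


class SeparationError(RuntimeError):
    """Quasi-complete separation: some level perfectly predicts the label."""


def _design(features: pd.DataFrame, factors: dict, strict: bool = True) -> pd.DataFrame:
    """Dummy design against declared base levels.  Column names 'col[level]'."""
    cols = {}
    for col, (levels, base) in factors.items():
        vals = features[col].astype(object).to_numpy()
        known = set(levels) | {base}
        unseen = set(np.unique(vals)) - known
        if unseen:
            if strict:
                raise ValueError(f"unknown levels in {col}: {sorted(unseen)}")
            logger.warning("unseen levels in %s mapped to base: %s", col, sorted(unseen))
        for lev in levels:
            cols[f"{col}[{lev}]"] = (vals == lev).astype(float)
    X = pd.DataFrame(cols, index=features.index)
    X.insert(0, "const", 1.0)
    return X


def fit_model(
    features: pd.DataFrame,
    labels,
    model_name: str = "M3",
    ridge: float = 0.0,
) -> PredictionModel:
    """Maximum-likelihood logistic fit of one model from the menu.

    Factor levels absent from the training data are dropped with a warning;
    quasi-complete separation fails with a diagnostic naming the level
    (unless a small ``ridge`` penalty is requested as a fallback, which is
    flagged in the log).
    """
    if model_name not in MODEL_FACTORS:
        raise ValueError(f"unknown model {model_name!r}; choose from {list(MODEL_FACTORS)}")
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")

    factors = {}
    for col in MODEL_FACTORS[model_name]:
        if col not in features.columns:
            raise ValueError(f"model {model_name} needs feature column {col!r}")
        all_levels, base = FACTOR_LEVELS[col]
        present = set(features[col].astype(object).unique())
        if base not in present:
            raise ValueError(f"base level {base!r} of {col!r} absent from training data")
        fitted = [l for l in all_levels if l != base and l in present]
        dropped = [l for l in all_levels if l != base and l not in present]
        if dropped:
            logger.warning("empty levels dropped from %s: %s", col, dropped)
        factors[col] = (fitted, base)

    X = _design(features, factors)
    sep = _separated_levels(X, y)
    if sep and ridge == 0.0:
        raise SeparationError(
            f"quasi-complete separation in levels: {sep}; "
            "refit with ridge > 0 to regularize"
        )
    model = sm.Logit(y, X)
    if ridge > 0.0:
        logger.warning("fitting with ridge penalty alpha=%g (flagged fallback)", ridge)
        alpha = np.full(X.shape[1], ridge)
        alpha[0] = 0.0  # never penalize the intercept
        res = model.fit_regularized(alpha=alpha, L1_wt=0.0, disp=0)
        bse = pd.Series(np.nan, index=X.columns)
        wald_p = pd.Series(np.nan, index=X.columns)
        params = pd.Series(res.params, index=X.columns)
    else:
        res = model.fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", True):
            raise SeparationError("logistic fit failed to converge")
        params = pd.Series(res.params, index=X.columns)
        bse = pd.Series(res.bse, index=X.columns)
        wald_p = pd.Series(res.pvalues, index=X.columns)
    return PredictionModel(
        model_name=model_name, params=params, bse=bse, wald_p=wald_p, factors=factors
    )


def _separated_levels(X: pd.DataFrame, y: np.ndarray) -> list:
    """Dummy columns whose active rows are single-class (separation risk)."""
    out = []
    for col in X.columns:
        if col == "const":
            continue
        mask = X[col].to_numpy() > 0
        if mask.any() and len(np.unique(y[mask])) == 1:
            out.append(col)
    return out


def predict_probs(model: PredictionModel, features: pd.DataFrame) -> np.ndarray:
    """Predicted membership probabilities; unseen levels map to base."""
    X = _design(features, model.factors, strict=False)
    return expit(X.to_numpy() @ model.params.reindex(X.columns).to_numpy())


def calibration_table(
    probs: dict,
    labels,
    n_bins: int = 10,
    ref_model: str = "M3",
) -> pd.DataFrame:
    """Observed label proportion per equal-width predicted-probability bin.

    Bin edges span [min, max] of the reference model's probabilities (the
    model with the widest dynamic range) and are applied to every model;
    empty bins report count 0 and a missing proportion.
    """
    if ref_model not in probs:
        raise ValueError(f"reference model {ref_model!r} not among supplied models")
    y = np.asarray(labels)
    ref = np.asarray(probs[ref_model])
    edges = np.linspace(ref.min(), ref.max(), n_bins + 1)
    rows = []
    for b in range(n_bins):
        row = {"bin_lo": edges[b], "bin_hi": edges[b + 1]}
        for name, p in probs.items():
            p = np.asarray(p)
            if b < n_bins - 1:
                mask = (p >= edges[b]) & (p < edges[b + 1])
            else:
                mask = (p >= edges[b]) & (p <= edges[b + 1])
            row[f"n_{name}"] = int(mask.sum())
            row[f"obs_prop_{name}"] = float(y[mask].mean()) if mask.any() else np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["edges"] = edges
    return table


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(probs, labels) -> RocCurve:
    """ROC curve and tie-corrected AUC (Mann-Whitney ranking probability)."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class; ROC undefined")
    p = np.asarray(probs)
    fpr, tpr, thr = roc_curve(y, p)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(roc_auc_score(y, p)))


def top_bin_crosstab(
    features: pd.DataFrame,
    probs,
    edges,
    n_top: int = 2,
) -> dict:
    """Cross-tabulate the pairs in the top predicted-probability bins.

    ``edges`` are the calibration bin edges; pairs with probability at or
    above the lower edge of the ``n_top`` highest bins are tabulated as
    chromatin state (16 rows) x FDR bin (5 columns).  Also reports distinct
    SNP and gene counts and the probability threshold.
    """
    edges = np.asarray(edges)
    threshold = float(edges[-1 - n_top])
    p = np.asarray(probs)
    mask = p >= threshold
    top = features.loc[mask]
    if len(top):
        table = (
            pd.crosstab(top["chrom_state"], top["fdr_bin"], dropna=False)
            .reindex(index=STATE_LEVELS, columns=FDR_LEVELS, fill_value=0)
            .fillna(0)
            .astype(int)
        )
    else:
        table = pd.DataFrame(0, index=STATE_LEVELS, columns=FDR_LEVELS)
    return {
        "table": table,
        "threshold": threshold,
        "n_pairs": int(mask.sum()),
        "n_snps": int(top["snp_id"].nunique()),
        "n_genes": int(top["gene_id"].nunique()),
    }


def report_reduction(
    top_bin_pairs: int, region_pair_total: int, catalog_overlap: int
) -> dict:
    """Search-space reduction and catalog-overlap percentages.

    reduction% = 100 * (1 - top_bin_pairs / region_pair_total): the
    fraction of candidate pairs in the implicated gene regions that the
    model screens out.  catalog_overlap% = 100 * overlap / top_bin_pairs:
    the fraction of retained pairs already reported as GWAS hits.
    """
    out = {"top_bin_pairs": top_bin_pairs, "region_pair_total": region_pair_total,
           "catalog_overlap": catalog_overlap}
    out["reduction_pct"] = (
        100.0 * (1.0 - top_bin_pairs / region_pair_total)
        if region_pair_total else float("nan")
    )
    out["catalog_overlap_pct"] = (
        100.0 * catalog_overlap / top_bin_pairs if top_bin_pairs else float("nan")
    )
    return out


def coefficient_z_distance(model: PredictionModel, truth: dict) -> pd.DataFrame:
    """Per-term |fitted - true| / SE, for generative-recovery checks.

    ``truth`` maps "col:level" to true log-odds (plus "intercept")."""
    rows = []
    for term in model.params.index:
        if term == "const":
            true = truth.get("intercept", 0.0)
        else:
            col, lev = term[:-1].split("[", 1)
            true = truth.get("coefs", {}).get(f"{col}:{lev}", 0.0)
        se = model.bse[term]
        z = abs(model.params[term] - true) / se if se > 0 else np.inf
        rows.append({"term": term, "fitted": model.params[term], "true": true,
                     "se": se, "z": z})
    return pd.DataFrame(rows)
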