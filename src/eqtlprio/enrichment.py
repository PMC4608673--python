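"""Permutation test for eQTL-gene over-representation in candidate sets.

Given the set of genes with a significant cis-eQTL, the observed proportion
of a candidate gene set harboring one is compared against a null
distribution built from repeated without-replacement draws of equally many
random genes from the genome-wide universe (10,000 draws by default).  The
empirical p-value uses the add-one correction (1 + #{null >= observed}) /
(1 + n_draws), so the smallest reportable p at 10,000 draws is ~1e-4 and a
null set's p is uniform on (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class EnrichmentResult:
    set_name: str
    set_size: int
    universe_size: int
    observed_prop: float
    null_props: np.ndarray
    empirical_p: float


#: Catalog gene identifiers that denote non-genic loci and are dropped when
#: reading candidate sets (configurable).
DEFAULT_EXCLUDE_TERMS = ("intergenic", "NR", "pseudogene")


def clean_gene_set(genes, exclude_terms=DEFAULT_EXCLUDE_TERMS) -> list:
    """Drop placeholder identifiers (intergenic, not-reported, pseudogenes)."""
    terms = tuple(t.lower() for t in exclude_terms)
    return [g for g in genes if not any(t in str(g).lower() for t in terms)]


def enrichment_test(
    gene_set,
    eqtl_genes,
    universe,
    n_draws: int = 10_000,
    seed: int = 0,
    set_name: str = "gene_set",
) -> EnrichmentResult:
    """Test whether ``gene_set`` is enriched for eQTL genes.

    ``gene_set`` must be a subset of ``universe``.  Draws are uniform
    without-replacement samples of the same size from the universe; ties
    (draw proportion exactly equal to observed) count toward the tail.
    """
    universe = np.asarray(sorted(set(universe)), dtype=object)
    gene_set = sorted(set(gene_set))
    offenders = [g for g in gene_set if g not in set(universe)]
    if offenders:
        raise ValueError(f"gene set members outside universe: {offenders}")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    eqtl = set(eqtl_genes)
    is_eqtl = np.array([g in eqtl for g in universe])
    m = len(gene_set)
    observed = sum(1 for g in gene_set if g in eqtl) / m

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 21]))
    # the eQTL-gene count in a uniform without-replacement draw of m genes
    # is exactly hypergeometric, so sample the count directly
    n_univ = len(universe)
    n_eqtl_in_univ = int(is_eqtl.sum())
    null_counts = rng.hypergeometric(n_eqtl_in_univ, n_univ - n_eqtl_in_univ, m,
                                     size=n_draws)
    null_props = null_counts / m
    empirical_p = (1 + int((null_props >= observed).sum())) / (1 + n_draws)
    return EnrichmentResult(
        set_name=set_name,
        set_size=m,
        universe_size=n_univ,
        observed_prop=observed,
        null_props=null_props,
        empirical_p=empirical_p,
    )
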