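"""Core in-memory containers shared across the pipeline.

Tabular results (cis pair tables, annotation tables, catalogs) are plain
pandas DataFrames with documented column contracts; only the matrix-valued
objects get dedicated classes because they carry aligned axis metadata
(sample/SNP/probe identifiers, genomic positions) that must stay consistent.
All genomic coordinates are 0-based, half-open, on a single chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical column order for cis pair tables produced by ``cis_pairs`` and
#: extended by the association scan and meta-analysis steps.
CIS_PAIR_COLUMNS = ["snp_id", "probe_id", "gene_id", "distance"]


class StructuralError(ValueError):
    """Inputs are structurally inconsistent (misaligned samples, probes...)."""


class ConfigurationError(ValueError):
    """A configuration value is out of its admissible range."""


def _as_str_array(x) -> np.ndarray:
    return np.asarray(x, dtype=object)


@dataclass
class GenotypeMatrix:
    """Dosage matrix for one cohort.

    Attributes
    ----------
    sample_ids : array of str, length n_samples
    snp_ids : array of str, length n_snps
    positions : int array, 0-based positions on the synthetic chromosome
    dosages : float array, shape (n_samples, n_snps), values in [0, 2]
    maf : float array, per-SNP minor allele frequency in [0, 0.5]
    """

    sample_ids: np.ndarray
    snp_ids: np.ndarray
    positions: np.ndarray
    dosages: np.ndarray
    maf: np.ndarray = field(default=None)

    def __post_init__(self):
        self.sample_ids = _as_str_array(self.sample_ids)
        self.snp_ids = _as_str_array(self.snp_ids)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise StructuralError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        if self.maf is None:
            self.maf = self.recompute_maf()
        else:
            self.maf = np.asarray(self.maf, dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def recompute_maf(self) -> np.ndarray:
        freq = self.dosages.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def validate(self, atol: float = 1e-9) -> None:
        if np.any(self.dosages < 0) or np.any(self.dosages > 2):
            raise StructuralError("dosages outside [0, 2]")
        if np.any(self.maf < 0) or np.any(self.maf > 0.5):
            raise StructuralError("MAF outside [0, 0.5]")
        if not np.allclose(self.maf, self.recompute_maf(), atol=atol):
            raise StructuralError("stored MAF inconsistent with dosages")

    def snp_index(self) -> dict:
        return {s: i for i, s in enumerate(self.snp_ids)}


@dataclass
class ExpressionMatrix:
    """Expression values for one cohort with probe-to-gene mapping.

    ``gene_bounds`` maps gene_id -> (start, end) transcript bounds
    (0-based half-open).
    """

    sample_ids: np.ndarray
    probe_ids: np.ndarray
    values: np.ndarray
    probe_to_gene: dict
    gene_bounds: dict

    def __post_init__(self):
        self.sample_ids = _as_str_array(self.sample_ids)
        self.probe_ids = _as_str_array(self.probe_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.probe_ids)):
            raise StructuralError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.probe_ids)} probes"
            )
        for g, (s, e) in self.gene_bounds.items():
            if not s < e:
                raise StructuralError(f"gene {g} has start >= end ({s}, {e})")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def copy_with(self, values: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(
            sample_ids=self.sample_ids.copy(),
            probe_ids=self.probe_ids.copy(),
            values=np.asarray(values, dtype=float),
            probe_to_gene=dict(self.probe_to_gene),
            gene_bounds=dict(self.gene_bounds),
        )

    def probe_index(self) -> dict:
        return {p: i for i, p in enumerate(self.probe_ids)}


def empty_cis_pair_table() -> pd.DataFrame:
    return pd.DataFrame(columns=CIS_PAIR_COLUMNS)
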