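"""Core in-memory containers shared across the pipeline.

Genotypes are stored as an individuals x SNPs alternate-allele dosage matrix
(int8; 0/1/2 with ``MISSING`` = -1 for no-calls) plus a per-SNP metadata frame.
Summary statistics are a plain :class:`pandas.DataFrame` with the fixed column
set in :data:`SUMMARY_COLUMNS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1

#: Fixed column order for summary-statistics tables.
SUMMARY_COLUMNS = ["CHR", "POS", "SNP", "A1", "A2", "FREQ", "BETA", "SE", "P", "N"]


@dataclass
class GenotypeMatrix:
    """Alt-allele dosages with per-SNP metadata.

    Parameters
    ----------
    dosages
        ``(n_individuals, n_snps)`` int8 array of 0/1/2 with ``MISSING`` (-1)
        marking no-calls.
    snps
        Frame with columns ``snp``, ``chrom``, ``pos``, ``a1`` (alt/effect
        allele), ``a2`` (ref allele); one row per dosage column.
    samples
        Individual identifiers, one per dosage row.
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x SNPs)")
        if self.dosages.shape[1] != len(self.snps):
            raise ValueError(
                f"{self.dosages.shape[1]} dosage columns but {len(self.snps)} SNP records"
            )
        if self.dosages.shape[0] != len(self.samples):
            raise ValueError(
                f"{self.dosages.shape[0]} dosage rows but {len(self.samples)} sample ids"
            )
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def dosages_float(self) -> np.ndarray:
        """Dosages as float with missing entries set to NaN."""
        x = self.dosages.astype(float)
        x[self.missing_mask()] = np.nan
        return x

    def allele_frequencies(self) -> np.ndarray:
        """Per-SNP alt-allele frequency from non-missing calls (NaN if all missing)."""
        x = self.dosages_float()
        with np.errstate(invalid="ignore"):
            return np.nanmean(x, axis=0) / 2.0

    def subset(self, individuals=None, snps=None) -> "GenotypeMatrix":
        """Row/column subset by boolean mask or integer index array."""
        ind = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        if ind.dtype == bool:
            ind = np.flatnonzero(ind)
        snp = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        if snp.dtype == bool:
            snp = np.flatnonzero(snp)
        return GenotypeMatrix(
            dosages=self.dosages[np.ix_(ind, snp)],
            snps=self.snps.iloc[snp].reset_index(drop=True),
            samples=[self.samples[i] for i in ind],
        )

    def standardized(self, impute: bool = True) -> np.ndarray:
        """Column-standardized dosages ``(x - 2p) / sqrt(2p(1-p))``.

        Missing calls are mean-imputed per SNP before standardization (so they
        contribute 0 after centring), matching common GRM practice.
        Raises on monomorphic SNPs (``p`` of 0 or 1), naming the first one.
        """
        x = self.dosages_float()
        p = self.allele_frequencies()
        bad = np.flatnonzero(~((p > 0) & (p < 1)))
        if bad.size:
            raise ValueError(
                f"monomorphic SNP cannot be standardized: {self.snps['snp'].iloc[bad[0]]}"
            )
        if impute:
            mu = 2.0 * p
            idx = np.where(np.isnan(x))
            x[idx] = mu[idx[1]]
        return (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))


def empty_summary_stats() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in SUMMARY_COLUMNS})


def validate_summary_stats(stats: pd.DataFrame) -> pd.DataFrame:
    """Check the fixed summary-statistics schema; return the frame."""
    missing = [c for c in SUMMARY_COLUMNS if c not in stats.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    if len(stats):
        se = np.asarray(stats["SE"], dtype=float)
        p = np.asarray(stats["P"], dtype=float)
        if not np.all(se > 0):
            raise ValueError("summary statistics contain non-positive SE")
        if not (np.all(p > 0) and np.all(p <= 1)):
            raise ValueError("summary statistics contain p outside (0, 1]")
    return stats
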