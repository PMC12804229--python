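"""Genetic relationship matrix and genomic principal components.

The GRM is the standardized-dosage cross-product
``A_jk = (1/M) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))``,
with missing dosages mean-imputed per SNP. An optional sparsity cutoff zeroes
small off-diagonal entries, giving the sparse relatedness matrix used as the
random-effect covariance in association while PCs capture broad structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import GenotypeMatrix

__all__ = ["GRM", "compute_grm", "compute_pcs", "ld_prune"]


@dataclass
class GRM:
    matrix: np.ndarray
    ids: list[str]
    n_snps_used: int
    sparse_cutoff: float | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.matrix, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("GRM must be square")
        if not np.all(np.isfinite(A)):
            raise ValueError("GRM contains non-finite entries")
        self.matrix = A

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def compute_grm(
    genotypes: GenotypeMatrix, sparse_cutoff: float | None = None
) -> GRM:
    """Compute the (optionally sparsified) GRM from post-QC genotypes.

    Raises on monomorphic SNPs (standardization would divide by zero),
    naming the offending SNP.
    """
    Z = genotypes.standardized(impute=True)
    m = genotypes.n_snps
    A = (Z @ Z.T) / m
    A = 0.5 * (A + A.T)  # exact symmetry against float round-off
    if sparse_cutoff is not None:
        off = np.abs(A) < sparse_cutoff
        np.fill_diagonal(off, False)
        A[off] = 0.0
    return GRM(matrix=A, ids=list(genotypes.samples), n_snps_used=m, sparse_cutoff=sparse_cutoff)


def ld_prune(
    genotypes: GenotypeMatrix, r2_threshold: float = 0.2, window: int = 50, step: int = 5
) -> np.ndarray:
    """Greedy sliding-window LD pruning; returns indices of retained SNPs.

    Within each window of ``window`` SNPs (advancing by ``step``) the later SNP
    of any retained pair with r^2 > threshold is dropped, per chromosome.
    """
    Z = genotypes.standardized(impute=True)
    Z = (Z - Z.mean(axis=0)) / np.maximum(Z.std(axis=0), 1e-12)
    n = Z.shape[0]
    keep = np.ones(genotypes.n_snps, dtype=bool)
    chroms = np.asarray(genotypes.snps["chrom"])
    for chrom in np.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        for start in range(0, len(idx), step):
            win = idx[start : start + window]
            win = win[keep[win]]
            if len(win) < 2:
                continue
            r2 = (Z[:, win].T @ Z[:, win] / n) ** 2
            for a in range(len(win)):
                if not keep[win[a]]:
                    continue
                for b in range(a + 1, len(win)):
                    if keep[win[b]] and r2[a, b] > r2_threshold:
                        keep[win[b]] = False
    return np.flatnonzero(keep)


def compute_pcs(
    genotypes: GenotypeMatrix,
    k: int,
    prune: bool = True,
    prune_r2: float = 0.2,
    prune_window: int = 50,
    prune_step: int = 5,
) -> np.ndarray:
    """Top-k genomic principal components (n x k, orthonormal columns).

    Columns are eigenvectors of the standardized-genotype covariance, computed
    after optional LD pruning; each column's sign is fixed so its
    largest-magnitude entry is positive.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    gm = genotypes
    if prune:
        kept = ld_prune(genotypes, prune_r2, prune_window, prune_step)
        gm = genotypes.subset(snps=kept)
    Z = gm.standardized(impute=True)
    Z = Z - Z.mean(axis=0)
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds the rank ({rank}) of the genotype matrix")
    pcs = U[:, :k]
    for j in range(k):
        i = np.argmax(np.abs(pcs[:, j]))
        if pcs[i, j] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs
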