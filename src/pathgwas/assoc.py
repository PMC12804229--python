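"""Mixed-linear-model association (LOCO), genetic correlation, diagnostics.

``mlma_loco`` re-estimates variance components per left-out chromosome, then
tests every SNP on that chromosome by generalized least squares in the GRM
eigenbasis: with the null-model covariance rotated to a diagonal, each SNP
reduces to a weighted regression whose residual scale is re-estimated per SNP
(t-test with n - p degrees of freedom). When the genetic variance is zero the
procedure is exactly ordinary least squares.

Genetic correlation uses Haseman-Elston cross-product regression on the GRM
off-diagonal: E[y1_i y2_j] = A_ij * sigma_g12 for i != j on residualized,
standardized traits, with a delete-block jackknife SE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import SUMMARY_COLUMNS, GenotypeMatrix, validate_summary_stats
from .grm import GRM, compute_grm
from .reml import estimate_variance_components

__all__ = [
    "mlma_loco",
    "MlmaResult",
    "GeneticCorrelation",
    "genetic_correlation",
    "InflationStat",
    "genomic_inflation",
    "effect_size_correlation",
]

_CHI2_NULL_MEDIAN = float(sps.chi2.ppf(0.5, df=1))  # 0.4549364...


@dataclass
class MlmaResult:
    """Association results plus provenance of each chromosome's GRM."""

    stats: pd.DataFrame
    grm_chromosomes: dict[int, tuple[int, ...]]
    variance_components: dict[int, tuple[float, float]]  # chrom -> (sigma_g2, sigma_e2)


def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    X = np.ones((n, 1))
    if covariates is not None and np.size(covariates):
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.hstack([X, C])
    return X


def _gls_scan(yt, Xt, Gt, weights):
    """Per-SNP weighted regression with covariates projected out.

    Returns beta, se, p (t-test, dof = n - n_covar - 1) for each column of Gt.
    Equivalent to a full per-SNP weighted least squares by Frisch-Waugh.
    """
    sw = np.sqrt(weights)[:, None]
    yw = yt * sw.ravel()
    Xw = Xt * sw
    Gw = Gt * sw
    Q, _ = np.linalg.qr(Xw)
    yr = yw - Q @ (Q.T @ yw)
    Gr = Gw - Q @ (Q.T @ Gw)
    gg = np.einsum("ij,ij->j", Gr, Gr)
    gy = Gr.T @ yr
    gg_safe = np.where(gg > 0, gg, np.nan)
    beta = gy / gg_safe
    dof = yt.size - Xt.shape[1] - 1
    rss = float(yr @ yr) - beta**2 * gg_safe
    sigma2 = rss / dof
    se = np.sqrt(sigma2 / gg_safe)
    tstat = beta / se
    p = 2.0 * sps.t.sf(np.abs(tstat), df=dof)
    return beta, se, np.clip(p, np.finfo(float).tiny, 1.0)


def mlma_loco(
    genotypes: GenotypeMatrix,
    trait: np.ndarray,
    covariates: np.ndarray | None = None,
    sparse_cutoff: float | None = None,
    loco: bool = True,
    force_sigma_g2: float | None = None,
) -> MlmaResult:
    """Mixed-model association with leave-one-chromosome-out GRMs.

    For each chromosome the GRM is rebuilt from the remaining chromosomes and
    variance components are re-estimated under that GRM before testing the
    chromosome's SNPs. ``force_sigma_g2=0`` bypasses REML and reduces every
    test to ordinary least squares (used for oracle checks and tiny panels).
    ``loco=False`` uses the full-genome GRM for every chromosome.
    """
    y = np.asarray(trait, dtype=float)
    n = genotypes.n_individuals
    if y.size != n:
        raise ValueError("trait length does not match genotype matrix")
    chroms = np.asarray(genotypes.snps["chrom"])
    uniq = np.unique(chroms)
    if loco and uniq.size < 2:
        raise ValueError(
            "LOCO requires at least 2 chromosomes; rerun with loco=False for a "
            "single-chromosome panel"
        )
    X = _design(covariates, n)

    records = []
    provenance: dict[int, tuple[int, ...]] = {}
    vcs: dict[int, tuple[float, float]] = {}
    freqs = genotypes.allele_frequencies()
    xall = genotypes.dosages_float()
    # mean-impute missing dosages so every test uses all n individuals
    mu = 2.0 * freqs
    nan_idx = np.where(np.isnan(xall))
    xall[nan_idx] = mu[nan_idx[1]]

    for chrom in uniq:
        on_c = chroms == chrom
        grm_src = ~on_c if loco else np.ones_like(on_c)
        provenance[int(chrom)] = tuple(
            int(c) for c in np.unique(chroms[grm_src]) if (c != chrom or not loco)
        )
        A = compute_grm(genotypes.subset(snps=grm_src), sparse_cutoff=sparse_cutoff).matrix

        if force_sigma_g2 is not None:
            sg2 = float(force_sigma_g2)
            se2 = float(np.var(y)) or 1.0
        else:
            vc = estimate_variance_components(
                y,
                X[:, 1:],
                GRM(A, list(genotypes.samples), int(grm_src.sum())),
                raise_on_nonconvergence=False,  # scan proceeds with last iterate
            )
            sg2, se2 = float(vc.sigma_g2.sum()), vc.sigma_e2
        vcs[int(chrom)] = (sg2, se2)

        if sg2 > 0:
            d, U = np.linalg.eigh(A)
            weights = 1.0 / (sg2 * np.clip(d, 0.0, None) + se2)
            yt, Xt, Gt = U.T @ y, U.T @ X, U.T @ xall[:, on_c]
        else:  # sigma_g2 = 0: identity covariance, no rotation needed
            weights = np.full(n, 1.0 / se2)
            yt, Xt, Gt = y, X, xall[:, on_c]

        beta, se, p = _gls_scan(yt, Xt, Gt, weights)
        sub = genotypes.snps.loc[on_c]
        records.append(
            pd.DataFrame(
                {
                    "CHR": sub["chrom"].to_numpy(),
                    "POS": sub["pos"].to_numpy(),
                    "SNP": sub["snp"].to_numpy(),
                    "A1": sub["a1"].to_numpy(),
                    "A2": sub["a2"].to_numpy(),
                    "FREQ": freqs[on_c],
                    "BETA": beta,
                    "SE": se,
                    "P": p,
                    "N": n,
                }
            )
        )
    stats = pd.concat(records, ignore_index=True)[SUMMARY_COLUMNS]
    stats = stats.sort_values(["CHR", "POS"], ignore_index=True)
    validate_summary_stats(stats)
    return MlmaResult(stats=stats, grm_chromosomes=provenance, variance_components=vcs)


@dataclass
class GeneticCorrelation:
    rg: float
    se: float
    sigma_g12: float
    sigma_g1: float
    sigma_g2: float
    clipped: bool
    method: str = "he"


def _residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    sd = r.std()
    if sd == 0:
        raise ValueError("trait is constant after covariate adjustment")
    return r / sd


def _he_components(y1, y2, A, iu):
    a = A[iu]
    denom = float(a @ a)
    s11 = float((np.outer(y1, y1)[iu] @ a)) / denom
    s22 = float((np.outer(y2, y2)[iu] @ a)) / denom
    cross = 0.5 * (np.outer(y1, y2) + np.outer(y2, y1))
    s12 = float(cross[iu] @ a) / denom
    return s11, s22, s12


def genetic_correlation(
    trait_a: np.ndarray,
    trait_b: np.ndarray,
    covariates: np.ndarray | None,
    grm: GRM,
    method: str = "he",
    n_jackknife_blocks: int = 20,
) -> GeneticCorrelation:
    """Genetic correlation between two traits by Haseman-Elston regression.

    Cross-products of residualized, standardized traits are regressed on the
    GRM off-diagonal; rG is the genetic covariance over the geometric mean of
    the genetic variances, clipped to [-1, 1] with a flag. SE by delete-block
    jackknife over individuals.
    """
    if method != "he":
        raise NotImplementedError(
            "only Haseman-Elston ('he') genetic correlation is implemented"
        )
    y1 = np.asarray(trait_a, dtype=float)
    y2 = np.asarray(trait_b, dtype=float)
    n = grm.n
    if y1.size != n or y2.size != n:
        raise ValueError("trait length does not match GRM")
    X = _design(covariates, n)
    y1 = _residualize(y1, X)
    y2 = _residualize(y2, X)
    A = grm.matrix

    def rg_of(idx: np.ndarray) -> tuple[float, float, float, float]:
        sub = np.ix_(idx, idx)
        iu = np.triu_indices(idx.size, k=1)
        s11, s22, s12 = _he_components(y1[idx], y2[idx], A[sub], iu)
        if s11 <= 0 or s22 <= 0:
            raise ValueError(
                "estimated genetic variance is non-positive; rG is undefined"
            )
        return s12 / np.sqrt(s11 * s22), s11, s22, s12

    full_idx = np.arange(n)
    rg, s11, s22, s12 = rg_of(full_idx)

    blocks = np.array_split(full_idx, n_jackknife_blocks)
    pseudo = []
    for b in blocks:
        idx = np.setdiff1d(full_idx, b)
        try:
            pseudo.append(rg_of(idx)[0])
        except ValueError:
            continue
    if len(pseudo) >= 3:
        pseudo = np.asarray(pseudo)
        g = len(pseudo)
        se = float(np.sqrt((g - 1) / g * np.sum((pseudo - pseudo.mean()) ** 2)))
    else:
        se = float("nan")

    clipped = not -1.0 <= rg <= 1.0
    return GeneticCorrelation(
        rg=float(np.clip(rg, -1.0, 1.0)),
        se=se,
        sigma_g12=s12,
        sigma_g1=s11,
        sigma_g2=s22,
        clipped=clipped,
    )


@dataclass
class InflationStat:
    lambda_gc: float
    qq_expected: np.ndarray  # -log10 expected quantiles, ascending
    qq_observed: np.ndarray  # -log10 observed p, matched order


def genomic_inflation(p_values: np.ndarray) -> InflationStat:
    """Genomic inflation factor: median association chi-square over the null
    median (chi2_1 quantile at 0.5), plus QQ-plot coordinates."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any(~((p > 0) & (p <= 1))):
        raise ValueError("p-values must lie in (0, 1]")
    chi = sps.chi2.isf(p, df=1)
    lam = float(np.median(chi) / _CHI2_NULL_MEDIAN)
    m = p.size
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    observed = -np.log10(np.sort(p))
    return InflationStat(lambda_gc=lam, qq_expected=expected[::-1], qq_observed=observed[::-1])


_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def effect_size_correlation(
    stats_a: pd.DataFrame, stats_b: pd.DataFrame
) -> tuple[float, float, int]:
    """Pearson correlation of per-SNP effect sizes between two GWAS.

    SNPs are matched on (CHR, POS); the second study's beta is sign-flipped
    where its effect/other alleles are swapped relative to the first, and
    strand-ambiguous A/T and C/G SNPs are dropped. Returns (r, p, n_snps).
    """
    validate_summary_stats(stats_a)
    validate_summary_stats(stats_b)
    a = stats_a[["CHR", "POS", "A1", "A2", "BETA"]]
    b = stats_b[["CHR", "POS", "A1", "A2", "BETA"]]
    merged = a.merge(b, on=["CHR", "POS"], suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("no shared SNPs between the two summary-statistic sets")
    amb = [
        (x, y) in _AMBIGUOUS
        for x, y in zip(merged["A1_a"], merged["A2_a"])
    ]
    merged = merged.loc[~np.asarray(amb)]
    same = (merged["A1_a"] == merged["A1_b"]) & (merged["A2_a"] == merged["A2_b"])
    flipped = (merged["A1_a"] == merged["A2_b"]) & (merged["A2_a"] == merged["A1_b"])
    merged = merged.loc[same | flipped]
    if merged.empty:
        raise ValueError("no allele-consistent shared SNPs after harmonization")
    sign = np.where(same.loc[merged.index], 1.0, -1.0)
    r, p = sps.pearsonr(merged["BETA_a"], sign * merged["BETA_b"])
    return float(r), float(p), int(len(merged))
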