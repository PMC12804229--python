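"""Genotype quality control: call-rate, MAF and Hardy-Weinberg filters.

Thresholds default to the usual GWAS acceptance criteria (MAF > 0.05, SNP and
individual call rate > 0.95, HWE exact p > 1e-6); all comparisons are strict.
Filters run in a fixed order — individual call rate, then SNP call rate, MAF
and HWE on the post-missingness data — and the pass is repeated until stable,
which makes `apply_qc` idempotent even though removing SNPs can alter
individual call rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

from .containers import GenotypeMatrix

__all__ = ["QCThresholds", "QCReport", "hwe_exact_test", "apply_qc"]


@dataclass(frozen=True)
class QCThresholds:
    min_maf: float = 0.05
    min_snp_call_rate: float = 0.95
    min_individual_call_rate: float = 0.95
    min_hwe_p: float = 1e-6

    def __post_init__(self) -> None:
        for name in (
            "min_maf",
            "min_snp_call_rate",
            "min_individual_call_rate",
            "min_hwe_p",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class QCReport:
    """What was filtered and why; totals reconcile per axis."""

    n_snps_in: int = 0
    n_snps_out: int = 0
    n_individuals_in: int = 0
    n_individuals_out: int = 0
    removed_snps: dict[str, list[str]] = field(
        default_factory=lambda: {"call_rate": [], "maf": [], "hwe": []}
    )
    removed_individuals: list[str] = field(default_factory=list)

    @property
    def snp_removal_counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.removed_snps.items()}

    def reconciles(self) -> bool:
        n_removed = sum(len(v) for v in self.removed_snps.values())
        return (
            self.n_snps_in == self.n_snps_out + n_removed
            and self.n_individuals_in == self.n_individuals_out + len(self.removed_individuals)
        )

    def summary(self) -> str:
        lines = [
            f"individuals: {self.n_individuals_in} in, {self.n_individuals_out} kept, "
            f"{len(self.removed_individuals)} removed (call rate)",
            f"SNPs: {self.n_snps_in} in, {self.n_snps_out} kept",
        ]
        for name, ids in self.removed_snps.items():
            lines.append(f"  removed by {name}: {len(ids)}")
        return "\n".join(lines)


def hwe_exact_test(
    n_hom_ref: int, n_het: int, n_hom_alt: int, method: str = "exact"
) -> float:
    """Two-sided Hardy-Weinberg test p-value for one biallelic SNP.

    The exact test enumerates every heterozygote count compatible with the
    observed allele counts and sums the probabilities of configurations no
    more likely than the observed one (conditional on allele counts, the
    standard exact formulation). ``method="chi2"`` gives the 1-df chi-square
    approximation instead.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise ValueError("all genotype counts are zero")

    if method == "chi2":
        p = (2 * n_hom_ref + n_het) / (2 * n)
        exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
        if np.any(exp == 0):
            return 1.0
        obs = np.array(counts, dtype=float)
        stat = float(np.sum((obs - exp) ** 2 / exp))
        return float(chi2.sf(stat, df=1))
    if method != "exact":
        raise ValueError(f"unknown HWE test method: {method!r}")

    n_a = 2 * n_hom_ref + n_het  # ref allele count
    n_b = 2 * n_hom_alt + n_het
    n_minor = min(n_a, n_b)
    # heterozygote counts share the parity of the minor allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = (max(n_a, n_b) - hets) // 2
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hom_major + 1)
        - gammaln(hets + 1)
        - gammaln(hom_minor + 1)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs_prob = probs[np.flatnonzero(hets == n_het)[0]]
    pval = float(probs[probs <= obs_prob * (1.0 + 1e-12)].sum())
    return min(pval, 1.0)


def _genotype_counts(dosages_float: np.ndarray) -> np.ndarray:
    """(3, m) counts of hom-ref / het / hom-alt over non-missing calls."""
    return np.stack(
        [np.nansum(dosages_float == k, axis=0) for k in (0, 1, 2)]
    ).astype(int)


def _qc_pass(
    gm: GenotypeMatrix, thr: QCThresholds, report: QCReport, hwe_method: str
) -> tuple[GenotypeMatrix, bool]:
    changed = False
    x = gm.dosages_float()

    ind_cr = 1.0 - np.isnan(x).mean(axis=1)
    keep_ind = ind_cr > thr.min_individual_call_rate
    if not keep_ind.all():
        report.removed_individuals.extend(
            s for s, k in zip(gm.samples, keep_ind) if not k
        )
        gm = gm.subset(individuals=keep_ind)
        x = gm.dosages_float()
        changed = True

    snp_cr = 1.0 - np.isnan(x).mean(axis=0)
    fail_cr = ~(snp_cr > thr.min_snp_call_rate)

    with np.errstate(invalid="ignore"):
        p = np.nanmean(x, axis=0) / 2.0
    p = np.where(np.isnan(p), 0.0, p)
    maf = np.minimum(p, 1.0 - p)
    fail_maf = ~(maf > thr.min_maf) & ~fail_cr

    counts = _genotype_counts(x)
    fail_hwe = np.zeros(gm.n_snps, dtype=bool)
    for j in np.flatnonzero(~fail_cr & ~fail_maf):
        c = counts[:, j]
        if c.sum() == 0:
            fail_hwe[j] = True
            continue
        fail_hwe[j] = not (
            hwe_exact_test(int(c[0]), int(c[1]), int(c[2]), method=hwe_method)
            > thr.min_hwe_p
        )

    ids = gm.snps["snp"]
    for mask, name in ((fail_cr, "call_rate"), (fail_maf, "maf"), (fail_hwe, "hwe")):
        if mask.any():
            report.removed_snps[name].extend(ids[mask])
            changed = True
    keep_snp = ~(fail_cr | fail_maf | fail_hwe)
    if not keep_snp.all():
        gm = gm.subset(snps=keep_snp)
    return gm, changed


def apply_qc(
    genotypes: GenotypeMatrix,
    thresholds: QCThresholds = QCThresholds(),
    hwe_method: str = "exact",
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter a genotype matrix by the acceptance criteria; return survivors
    and a reconciling report.

    Each removed SNP is attributed to the first filter it failed (call rate,
    then MAF, then HWE). Passes repeat until no further removal occurs, so
    applying QC to its own output changes nothing.
    """
    if genotypes.n_snps == 0 or genotypes.n_individuals == 0:
        raise ValueError("cannot QC an empty genotype matrix")
    report = QCReport(
        n_snps_in=genotypes.n_snps, n_individuals_in=genotypes.n_individuals
    )
    gm = genotypes
    while True:
        gm, changed = _qc_pass(gm, thresholds, report, hwe_method)
        if gm.n_snps == 0 or gm.n_individuals == 0:
            raise ValueError("empty after QC: every SNP or individual was filtered")
        if not changed:
            break
    report.n_snps_out = gm.n_snps
    report.n_individuals_out = gm.n_individuals
    return gm, report
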