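"""Self-contained benchmark runs used to validate the statistical engine.

These routines generate their own synthetic inputs with known truth and
measure how the pipeline behaves on them: mixed-model calibration against
naive least squares on a sib-structured polygenic cohort, and recovery of
heritability and genetic correlation across replicates. They exist so that
the same measurements can be driven from the test suite and from the
reproduction script without duplicating the study design.
"""

from __future__ import annotations

import numpy as np

from .assoc import genetic_correlation, genomic_inflation, mlma_loco
from .grm import compute_grm
from .reml import estimate_variance_components
from .sim import SimConfig, TraitSpec, simulate_genotypes, simulate_traits

__all__ = ["null_calibration", "parameter_recovery"]


def null_calibration(
    seed: int,
    n_individuals: int = 200,
    n_sib_pairs: int = 50,
    n_chromosomes: int = 10,
    blocks_per_chrom: int = 20,
    snps_per_block: int = 10,
    h2: float = 0.7,
    n_traits: int = 5,
) -> dict:
    """Calibration of MLMA-LOCO vs naive OLS on a sib-structured cohort.

    The trait is polygenic: one causal SNP in every even-numbered LD block.
    SNPs in the odd-numbered blocks are exactly null (no LD with any causal
    SNP), so genomic inflation and the empirical type-I error are measured
    there. Naive OLS on the same data is confounded by the sib structure and
    should inflate; the mixed model should not. Inflation is averaged over
    ``n_traits`` independent trait replicates on one genotype panel; the
    type-I error is counted on one representative SNP per null block so the
    binomial reference distribution applies.
    """
    config = SimConfig(
        n_individuals=n_individuals,
        n_chromosomes=n_chromosomes,
        blocks_per_chrom=blocks_per_chrom,
        snps_per_block=snps_per_block,
        within_block_ld=0.15,
        missing_rate=0.0,
        n_sib_pairs=n_sib_pairs,
        seed=seed,
    )
    gm = simulate_genotypes(config)
    n_blocks = n_chromosomes * blocks_per_chrom
    s = snps_per_block
    causal = tuple(int(b * s + s // 2) for b in range(0, n_blocks, 2))
    null_snps = np.array([b * s + j for b in range(1, n_blocks, 2) for j in range(s)])
    rep_snps = np.array([b * s for b in range(1, n_blocks, 2)])
    order = {snp: i for i, snp in enumerate(gm.snps["snp"])}

    lam_mlma, lam_ols, type1 = [], [], []
    for rep in range(n_traits):
        spec = TraitSpec(
            h2=(h2,), n_causal=(len(causal),), causal_snps=(causal,), seed=seed * 1000 + rep
        )
        pheno, _ = simulate_traits(gm, spec)
        y = pheno["trait1"].to_numpy()
        mm = mlma_loco(gm, y)
        ols = mlma_loco(gm, y, force_sigma_g2=0.0)

        def pvals(stats, idx):
            return (
                stats.assign(_i=stats["SNP"].map(order))
                .set_index("_i")
                .loc[idx, "P"]
                .to_numpy()
            )

        lam_mlma.append(genomic_inflation(pvals(mm.stats, null_snps)).lambda_gc)
        lam_ols.append(genomic_inflation(pvals(ols.stats, null_snps)).lambda_gc)
        type1.append(float(np.mean(pvals(mm.stats, rep_snps) < 0.05)))

    n_tests = n_traits * rep_snps.size
    return {
        "mlma_lambda": float(np.mean(lam_mlma)),
        "ols_lambda": float(np.mean(lam_ols)),
        "type1_rate": float(np.mean(type1)),
        "type1_band": 2.0 * float(np.sqrt(0.05 * 0.95 / n_tests)),
        "n_null_snps": int(null_snps.size),
        "n_type1_tests": int(n_tests),
    }


def parameter_recovery(
    seed: int,
    n_replicates: int = 20,
    n_individuals: int = 500,
    n_snps: int = 5000,
    h2: float = 0.5,
    rg: float = 0.6,
    n_causal: int = 100,
    n_sib_pairs: int = 100,
) -> dict:
    """Mean REML heritability and Haseman-Elston genetic-correlation estimates
    across replicate cohorts simulated at known (h2, rG)."""
    h2_hats, rg_hats = [], []
    snps_per_block = 25
    blocks = n_snps // (5 * snps_per_block)
    R = np.array([[1.0, rg], [rg, 1.0]])
    for rep in range(n_replicates):
        config = SimConfig(
            n_individuals=n_individuals,
            n_chromosomes=5,
            blocks_per_chrom=blocks,
            snps_per_block=snps_per_block,
            within_block_ld=0.3,
            missing_rate=0.0,
            n_sib_pairs=n_sib_pairs,
            seed=seed * 10_000 + rep,
        )
        gm = simulate_genotypes(config)
        spec = TraitSpec(
            h2=(h2, h2),
            n_causal=(n_causal, n_causal),
            genetic_corr=R,
            seed=seed * 10_000 + 5000 + rep,
        )
        pheno, _ = simulate_traits(gm, spec)
        grm = compute_grm(gm)
        y1 = pheno["trait1"].to_numpy()
        y2 = pheno["trait2"].to_numpy()
        vc = estimate_variance_components(y1, None, grm, raise_on_nonconvergence=False)
        h2_hats.append(vc.h2)
        rg_hats.append(genetic_correlation(y1, y2, None, grm).rg)
    return {
        "mean_h2_hat": float(np.mean(h2_hats)),
        "mean_rg_hat": float(np.mean(rg_hats)),
        "h2_hats": [float(v) for v in h2_hats],
        "rg_hats": [float(v) for v in rg_hats],
        "true_h2": h2,
        "true_rg": rg,
        "n_replicates": n_replicates,
    }
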