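"""Association stage: OLS reduction, LOCO provenance, diagnostics, rG."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pathgwas import (
    SimConfig,
    TraitSpec,
    compute_grm,
    effect_size_correlation,
    genetic_correlation,
    genomic_inflation,
    mlma_loco,
    simulate_genotypes,
    simulate_traits,
)
from conftest import make_genotypes


class TestMlmaLoco:
    def test_zero_genetic_variance_reduces_to_ols(self):
        import statsmodels.api as sm

        config = SimConfig(
            n_individuals=50,
            n_chromosomes=2,
            blocks_per_chrom=2,
            snps_per_block=5,
            missing_rate=0.0,
            seed=21,
        )
        gm = simulate_genotypes(config)
        rng = np.random.default_rng(22)
        y = rng.standard_normal(50)
        covar = rng.standard_normal((50, 2))
        res = mlma_loco(gm, y, covariates=covar, force_sigma_g2=0.0)
        X0 = np.column_stack([np.ones(50), covar])
        for rec in res.stats.itertuples(index=False):
            j = list(gm.snps["snp"]).index(rec.SNP)
            fit = sm.OLS(y, np.column_stack([X0, gm.dosages[:, j]])).fit()
            assert rec.BETA == pytest.approx(fit.params[-1], rel=1e-6)
            assert rec.SE == pytest.approx(fit.bse[-1], rel=1e-6)
            assert rec.P == pytest.approx(fit.pvalues[-1], rel=1e-6)

    def test_loco_provenance_excludes_own_chromosome(self, family_panel):
        rng = np.random.default_rng(23)
        y = rng.standard_normal(family_panel.n_individuals)
        res = mlma_loco(family_panel, y)
        assert res.grm_chromosomes[1] == (2,)
        assert res.grm_chromosomes[2] == (1,)

    def test_single_chromosome_loco_rejected(self):
        gm = simulate_genotypes(SimConfig(n_individuals=40, n_chromosomes=1, seed=2))
        with pytest.raises(ValueError, match="loco=False"):
            mlma_loco(gm, np.zeros(40))

    def test_null_pvalues_uniform(self):
        config = SimConfig(
            n_individuals=150,
            n_chromosomes=3,
            blocks_per_chrom=5,
            snps_per_block=10,
            missing_rate=0.0,
            seed=25,
        )
        gm = simulate_genotypes(config)
        rng = np.random.default_rng(26)
        res = mlma_loco(gm, rng.standard_normal(150))
        ks = sps.kstest(res.stats["P"], "uniform")
        assert ks.pvalue > 0.01

    def test_output_schema_and_order(self, family_panel):
        rng = np.random.default_rng(27)
        res = mlma_loco(family_panel, rng.standard_normal(family_panel.n_individuals))
        assert len(res.stats) == family_panel.n_snps
        assert (res.stats["SE"] > 0).all()
        assert res.stats["P"].between(0, 1, inclusive="right").all()
        assert res.stats.equals(res.stats.sort_values(["CHR", "POS"], ignore_index=True))


class TestGenomicInflation:
    def test_flat_half_pvalues_give_lambda_one(self):
        stat = genomic_inflation(np.full(101, 0.5))
        assert stat.lambda_gc == pytest.approx(1.0, abs=1e-12)

    def test_uniform_pvalues_near_one(self):
        rng = np.random.default_rng(1)
        stat = genomic_inflation(rng.uniform(size=100_000))
        assert 0.98 < stat.lambda_gc < 1.02

    def test_doubling_chi2_doubles_lambda(self):
        rng = np.random.default_rng(2)
        chi = rng.chisquare(1, size=5000)
        lam1 = genomic_inflation(sps.chi2.sf(chi, 1)).lambda_gc
        lam2 = genomic_inflation(sps.chi2.sf(2 * chi, 1)).lambda_gc
        assert lam2 == pytest.approx(2 * lam1, rel=1e-9)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            genomic_inflation(np.array([0.5, 0.0]))
        with pytest.raises(ValueError):
            genomic_inflation(np.array([]))


def _stats_frame(betas, a1="A", a2="G"):
    m = len(betas)
    return pd.DataFrame(
        {
            "CHR": 1,
            "POS": np.arange(1, m + 1) * 100,
            "SNP": [f"s{j}" for j in range(m)],
            "A1": a1,
            "A2": a2,
            "FREQ": 0.3,
            "BETA": betas,
            "SE": 0.1,
            "P": 0.5,
            "N": 100,
        }
    )


class TestEffectSizeCorrelation:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(3)
        stats = _stats_frame(rng.standard_normal(500))
        r, p, n = effect_size_correlation(stats, stats)
        assert r == pytest.approx(1.0)
        assert n == 500

    def test_independent_betas_uncorrelated(self):
        rng = np.random.default_rng(4)
        a = _stats_frame(rng.standard_normal(10_000))
        b = _stats_frame(rng.standard_normal(10_000))
        r, _, _ = effect_size_correlation(a, b)
        assert abs(r) < 0.03

    def test_allele_swap_harmonized(self):
        rng = np.random.default_rng(5)
        betas = rng.standard_normal(300)
        a = _stats_frame(betas)
        b = _stats_frame(-betas, a1="G", a2="A")  # swapped alleles, flipped sign
        r, _, n = effect_size_correlation(a, b)
        assert r == pytest.approx(1.0)
        assert n == 300

    def test_strand_ambiguous_snps_dropped(self):
        a = _stats_frame(np.ones(10), a1="A", a2="T")
        b = _stats_frame(np.ones(10), a1="A", a2="T")
        with pytest.raises(ValueError):
            effect_size_correlation(a, b)

    def test_disjoint_positions_rejected(self):
        a = _stats_frame(np.ones(5))
        b = _stats_frame(np.ones(5))
        b["POS"] = b["POS"] + 10_000
        with pytest.raises(ValueError, match="shared"):
            effect_size_correlation(a, b)


@pytest.fixture(scope="module")
def sib_cohort():
    config = SimConfig(
        n_individuals=400,
        n_chromosomes=4,
        blocks_per_chrom=10,
        snps_per_block=15,
        n_sib_pairs=100,
        missing_rate=0.0,
        seed=31,
    )
    gm = simulate_genotypes(config)
    return gm, compute_grm(gm)


class TestGeneticCorrelation:
    def test_self_correlation_exactly_one(self, sib_cohort):
        gm, grm = sib_cohort
        pheno, _ = simulate_traits(gm, TraitSpec(h2=(0.6,), n_causal=(50,), seed=32))
        y = pheno["trait1"].to_numpy()
        est = genetic_correlation(y, y, None, grm)
        assert est.rg == pytest.approx(1.0, abs=1e-12)
        assert not est.clipped

    def test_independent_traits_near_zero(self, sib_cohort):
        gm, grm = sib_cohort
        pheno, _ = simulate_traits(
            gm, TraitSpec(h2=(0.6, 0.6), n_causal=(50, 50), seed=33)
        )
        est = genetic_correlation(
            pheno["trait1"].to_numpy(), pheno["trait2"].to_numpy(), None, grm
        )
        assert abs(est.rg) < 3 * est.se

    def test_unknown_method_rejected(self, sib_cohort):
        gm, grm = sib_cohort
        y = np.random.default_rng(0).standard_normal(grm.n)
        with pytest.raises(NotImplementedError):
            genetic_correlation(y, y, None, grm, method="reml")
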