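"""Synthetic-data generator: determinism, LD structure, trait construction."""

import numpy as np
import pytest

from pathgwas import (
    MISSING,
    AnnotationParams,
    SimConfig,
    TraitSpec,
    simulate_annotation_resources,
    simulate_genotypes,
    simulate_traits,
)


class TestSimulateGenotypes:
    def test_same_seed_bit_identical(self):
        config = SimConfig(n_individuals=60, n_sib_pairs=10, missing_rate=0.05, seed=5)
        a = simulate_genotypes(config)
        b = simulate_genotypes(config)
        assert np.array_equal(a.dosages, b.dosages)
        assert a.snps.equals(b.snps)
        assert a.samples == b.samples

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_individuals": 0},
            {"n_chromosomes": -1},
            {"maf_range": (0.0, 0.3)},
            {"maf_range": (0.2, 0.6)},
            {"missing_rate": 1.0},
            {"n_individuals": 10, "n_sib_pairs": 6},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)

    def test_allele_frequency_matches_binomial_sampling(self):
        # at maf fixed to 0.5 the sample frequency is binomial over 2n draws
        config = SimConfig(
            n_individuals=2000,
            n_chromosomes=1,
            blocks_per_chrom=2,
            snps_per_block=10,
            maf_range=(0.5, 0.5),
            within_block_ld=0.2,
            missing_rate=0.0,
            seed=3,
        )
        gm = simulate_genotypes(config)
        freqs = gm.allele_frequencies()
        se = np.sqrt(0.5 * 0.5 / (2 * 2000))
        assert np.all(np.abs(freqs - 0.5) < 3 * se)

    def test_ld_confined_to_blocks(self):
        config = SimConfig(
            n_individuals=800,
            n_chromosomes=2,
            blocks_per_chrom=3,
            snps_per_block=12,
            within_block_ld=0.5,
            missing_rate=0.0,
            seed=9,
        )
        gm = simulate_genotypes(config)
        Z = gm.standardized()
        r2 = np.corrcoef(Z.T) ** 2
        s = config.snps_per_block
        within, between = [], []
        n_blocks = config.n_chromosomes * config.blocks_per_chrom
        for b in range(n_blocks):
            sl = slice(b * s, (b + 1) * s)
            within.append(r2[sl, sl][np.triu_indices(s, 1)].mean())
            if b + 1 < n_blocks:
                between.append(r2[sl, (b + 1) * s :].mean())
        assert np.mean(within) > 10 * np.mean(between)
        assert np.mean(between) < 0.05  # ~1/n sampling floor

    def test_missingness_rate_and_sentinel(self):
        config = SimConfig(n_individuals=300, missing_rate=0.1, seed=2)
        gm = simulate_genotypes(config)
        frac = np.mean(gm.dosages == MISSING)
        assert abs(frac - 0.1) < 0.01
        assert set(np.unique(gm.dosages)) <= {MISSING, 0, 1, 2}

    def test_positions_strictly_increasing_per_chromosome(self):
        gm = simulate_genotypes(SimConfig(n_individuals=20, seed=1))
        for _, sub in gm.snps.groupby("chrom"):
            assert np.all(np.diff(sub["pos"]) > 0)


class TestSimulateTraits:
    def test_h2_zero_trait_independent_of_genetics(self, clean_panel):
        spec = TraitSpec(h2=(0.0,), n_causal=(30,), seed=4)
        pheno, truth = simulate_traits(clean_panel, spec)
        g = truth.genetic_values[:, 0]
        assert np.allclose(g, 0.0)  # scaled by sqrt(h2) = 0
        # regression of trait on the unscaled genetic value is flat
        raw = clean_panel.standardized() @ truth.effects[:, 0]
        slope, intercept = np.polyfit(raw, pheno["trait1"], 1)
        resid = pheno["trait1"] - (slope * raw + intercept)
        se = resid.std() / (raw.std() * np.sqrt(len(raw)))
        assert abs(slope) < 3 * se

    def test_h2_one_trait_equals_genetic_value_plus_covariates(self, clean_panel):
        spec = TraitSpec(h2=(1.0,), n_causal=(30,), age_effect=0.3, sex_effect=0.2, seed=4)
        pheno, truth = simulate_traits(clean_panel, spec)
        age = pheno["age"].to_numpy()
        age_std = (age - age.mean()) / age.std()
        cov_part = 0.3 * age_std + 0.2 * pheno["sex"].to_numpy()
        assert np.allclose(pheno["trait1"], truth.genetic_values[:, 0] + cov_part)

    def test_perfect_genetic_correlation_with_shared_causals(self, clean_panel):
        shared = tuple(range(20))
        spec = TraitSpec(
            h2=(0.8, 0.8),
            n_causal=(20, 20),
            genetic_corr=np.array([[1.0, 1.0], [1.0, 1.0]]),
            causal_snps=(shared, shared),
            seed=6,
        )
        _, truth = simulate_traits(clean_panel, spec)
        r = np.corrcoef(truth.genetic_values.T)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_realized_heritability_calibrated(self):
        # mean realized genetic-variance share over replicates matches h2
        ratios = []
        for rep in range(20):
            config = SimConfig(
                n_individuals=500,
                n_chromosomes=5,
                blocks_per_chrom=40,
                snps_per_block=25,
                within_block_ld=0.3,
                missing_rate=0.0,
                seed=1000 + rep,
            )
            gm = simulate_genotypes(config)
            pheno, truth = simulate_traits(
                gm, TraitSpec(h2=(0.5,), n_causal=(100,), seed=2000 + rep)
            )
            ratios.append(
                truth.genetic_values[:, 0].var() / pheno["trait1"].to_numpy().var()
            )
        assert abs(np.mean(ratios) - 0.5) < 0.05

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"h2": (1.2,), "n_causal": (5,)},
            {"h2": (0.5, 0.5), "n_causal": (5, 5), "genetic_corr": np.array([[1.0, 2.0], [2.0, 1.0]])},
            {"h2": (0.5, 0.5), "n_causal": (5, 5), "genetic_corr": np.array([[1.0, 0.2], [0.3, 1.0]])},
        ],
    )
    def test_invalid_trait_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TraitSpec(**kwargs)

    def test_too_many_causals_rejected(self, clean_panel):
        with pytest.raises(ValueError, match="n_causal"):
            simulate_traits(clean_panel, TraitSpec(h2=(0.5,), n_causal=(10**6,)))


class TestAnnotationResources:
    def test_zero_pathways_gives_empty_valid_databases(self, clean_panel, tmp_path):
        from pathgwas.io import read_gmt, write_gmt

        res = simulate_annotation_resources(
            clean_panel, AnnotationParams(pathways_per_db=0, seed=1)
        )
        assert all(len(db) == 0 for db in res.pathway_db.values())
        path = tmp_path / "empty.gmt"
        write_gmt(res.pathway_db["dbA"], path)
        assert path.read_text() == ""
        assert read_gmt(path) == {}

    def test_gene_intervals_do_not_overlap(self, clean_panel):
        res = simulate_annotation_resources(clean_panel, AnnotationParams(seed=2))
        for _, sub in res.genes.groupby("chrom"):
            sub = sub.sort_values("start")
            assert np.all(sub["end"].to_numpy()[:-1] <= sub["start"].to_numpy()[1:])

    def test_features_lie_within_their_gene(self, clean_panel):
        res = simulate_annotation_resources(clean_panel, AnnotationParams(seed=2))
        merged = res.features.merge(res.genes, on="gene_id", suffixes=("", "_gene"))
        assert (merged["start"] >= merged["start_gene"]).all()
        assert (merged["end"] <= merged["end_gene"]).all()
        assert (merged["start"] < merged["end"]).all()

    def test_eqtl_significant_fraction_calibrated(self, clean_panel):
        res = simulate_annotation_resources(
            clean_panel,
            AnnotationParams(eqtl_significant_fraction=0.3, n_eqtl_rows=1000, seed=7),
        )
        frac = np.mean(res.eqtl["q_value"] < 0.05)
        se = np.sqrt(0.3 * 0.7 / 1000)
        assert abs(frac - 0.3) < 3 * se
        assert res.eqtl["q_value"].between(0, 1).all()

    def test_pathway_gene_sets_nonempty(self, clean_panel):
        res = simulate_annotation_resources(clean_panel, AnnotationParams(seed=3))
        for db in res.pathway_db.values():
            for members in db.values():
                assert members

    def test_cross_database_redundancy_duplicates_sets(self, clean_panel):
        res = simulate_annotation_resources(
            clean_panel, AnnotationParams(cross_db_redundancy=1.0, seed=4)
        )
        sets_a = {frozenset(s) for s in res.pathway_db["dbA"].values()}
        sets_b = {frozenset(s) for s in res.pathway_db["dbB"].values()}
        assert sets_a & sets_b  # dbA sets copied into dbB under new ids

    def test_empty_genotypes_rejected(self, clean_panel):
        empty = clean_panel.subset(snps=np.zeros(clean_panel.n_snps, dtype=bool))
        with pytest.raises(ValueError, match="empty"):
            simulate_annotation_resources(empty)

    def test_determinism(self, clean_panel):
        a = simulate_annotation_resources(clean_panel, AnnotationParams(seed=5))
        b = simulate_annotation_resources(clean_panel, AnnotationParams(seed=5))
        assert a.genes.equals(b.genes)
        assert a.eqtl.equals(b.eqtl)
        assert a.pathway_db == b.pathway_db
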