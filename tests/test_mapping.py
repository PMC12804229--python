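"""Lead selection, LD expansion, and variant-to-gene mapping."""

import numpy as np
import pandas as pd
import pytest

from pathgwas import (
    AnnotationParams,
    MappingConfig,
    ld_expand,
    map_variants_to_genes,
    select_lead_snps,
    simulate_annotation_resources,
)
from pathgwas.sim import ResourceBundle
from conftest import make_genotypes


def _stats(pvals):
    m = len(pvals)
    return pd.DataFrame(
        {
            "CHR": 1,
            "POS": np.arange(1, m + 1) * 1000,
            "SNP": [f"s{j}" for j in range(m)],
            "A1": "A",
            "A2": "G",
            "FREQ": 0.3,
            "BETA": 0.1,
            "SE": 0.05,
            "P": pvals,
            "N": 500,
        }
    )


class TestSelectLeadSnps:
    def test_strict_threshold_boundary(self):
        hits = select_lead_snps(_stats([2e-6, 9e-6, 1e-5, 0.2]), threshold=1e-5)
        assert list(hits["SNP"]) == ["s0", "s1"]  # 1e-5 itself excluded

    def test_no_hits_is_empty_not_error(self):
        hits = select_lead_snps(_stats([0.3, 0.5]), threshold=1e-5)
        assert len(hits) == 0

    def test_all_hits_sorted_ascending(self):
        hits = select_lead_snps(_stats([3e-6, 1e-7, 9e-6]), threshold=1e-5)
        assert list(hits["SNP"]) == ["s1", "s0", "s2"]
        assert hits["P"].is_monotonic_increasing


class TestLdExpand:
    def test_duplicate_column_perfect_ld(self):
        rng = np.random.default_rng(1)
        base = rng.binomial(2, 0.4, size=200).astype(np.int8)
        other = rng.binomial(2, 0.4, size=200).astype(np.int8)
        gm = make_genotypes(np.column_stack([base, base, other]))
        out = ld_expand(["s0"], gm, r2_threshold=0.6)
        assert set(out["snp"]) >= {"s0", "s1"}
        dup = out.loc[out["snp"] == "s1"].iloc[0]
        assert dup["r2"] == pytest.approx(1.0)
        assert dup["lead"] == "s0"

    def test_every_lead_in_its_own_expansion(self):
        rng = np.random.default_rng(2)
        gm = make_genotypes(rng.binomial(2, 0.4, size=(100, 5)).astype(np.int8))
        out = ld_expand(["s2", "s4"], gm, r2_threshold=0.9)
        assert {"s2", "s4"} <= set(out["snp"])

    def test_independent_snp_excluded(self):
        rng = np.random.default_rng(3)
        gm = make_genotypes(rng.binomial(2, 0.4, size=(500, 4)).astype(np.int8))
        out = ld_expand(["s0"], gm, r2_threshold=0.6)
        assert set(out["snp"]) == {"s0"}

    def test_other_chromosome_never_included(self):
        rng = np.random.default_rng(4)
        base = rng.binomial(2, 0.4, size=100).astype(np.int8)
        gm = make_genotypes(np.column_stack([base, base]), chrom=[1, 2])
        out = ld_expand(["s0"], gm, r2_threshold=0.6)
        assert set(out["snp"]) == {"s0"}  # s1 identical but on chrom 2

    def test_absent_lead_rejected_by_name(self):
        gm = make_genotypes([[0, 1], [1, 2]])
        with pytest.raises(KeyError, match="nope"):
            ld_expand(["nope"], gm)


@pytest.fixture()
def toy_resources() -> ResourceBundle:
    """One gene with intron/exon/UTR features plus an eQTL table."""
    genes = pd.DataFrame(
        {
            "gene_id": ["GENE1"],
            "chrom": [1],
            "start": [1000],
            "end": [2000],
            "strand": ["+"],
            "coding": [True],
        }
    )
    features = pd.DataFrame(
        {
            "gene_id": ["GENE1"] * 4,
            "feature": ["UTR5", "exon", "intron", "UTR3"],
            "start": [1000, 1200, 1400, 1800],
            "end": [1200, 1400, 1800, 2000],
            "category": ["UTR5", "exonic", "intronic", "UTR3"],
        }
    )
    eqtl = pd.DataFrame(
        {
            "snp_id": ["snpE", "snpE", "snpF"],
            "gene_id": ["GENE2", "GENE3", "GENE1"],
            "tissue": ["cortex", "cortex", "cortex"],
            "q_value": [0.04, 0.06, 0.2],
        }
    )
    return ResourceBundle(genes=genes, features=features, eqtl=eqtl, pathway_db={})


def _snp_frame(rows):
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos", "lead", "r2"])


class TestMapVariantsToGenes:
    def test_intronic_snp_maps_positionally(self, toy_resources):
        snps = _snp_frame([("snpA", 1, 1501, "snpA", 1.0)])  # 1-based inside intron
        out = map_variants_to_genes(snps, toy_resources)
        assert out.genes == ["GENE1"]
        row = out.annotations.iloc[0]
        assert row["mapping_type"] == "positional"
        assert row["functional_category"] == "intronic"

    def test_intergenic_snp_contributes_nothing(self, toy_resources):
        snps = _snp_frame([("snpB", 1, 900_000, "snpB", 1.0)])
        out = map_variants_to_genes(snps, toy_resources)
        assert out.genes == []
        assert out.unmapped_snps == ["snpB"]

    def test_eqtl_q_threshold_strict(self, toy_resources):
        snps = _snp_frame([("snpE", 1, 500_000, "snpE", 1.0)])
        out = map_variants_to_genes(snps, toy_resources)
        assert out.genes == ["GENE2"]  # q=0.04 kept, q=0.06 dropped
        assert out.annotations.iloc[0]["q_value"] == pytest.approx(0.04)

    def test_positional_and_eqtl_give_one_gene_two_rows(self, toy_resources):
        toy_resources.eqtl.loc[len(toy_resources.eqtl)] = ["snpA", "GENE1", "cortex", 0.01]
        snps = _snp_frame([("snpA", 1, 1501, "snpA", 1.0)])
        out = map_variants_to_genes(snps, toy_resources)
        assert out.genes == ["GENE1"]
        assert len(out.support("GENE1")) == 2
        assert set(out.support("GENE1")["mapping_type"]) == {"positional", "eqtl"}

    def test_category_filter_excludes_flanks_by_default(self, toy_resources):
        snps = _snp_frame([("snpU", 1, 500, "snpU", 1.0)])  # within 2kb upstream
        out = map_variants_to_genes(snps, toy_resources)
        assert out.genes == []
        wide = MappingConfig(
            allowed_categories=frozenset({"upstream", "downstream"})
        )
        out2 = map_variants_to_genes(snps, toy_resources, wide)
        assert out2.genes == ["GENE1"]

    def test_missing_position_rejected(self, toy_resources):
        snps = _snp_frame([("snpA", 1, np.nan, "snpA", 1.0)])
        with pytest.raises(ValueError, match="position"):
            map_variants_to_genes(snps, toy_resources)


class TestMappingMonotonicity:
    def test_stricter_configs_never_add_genes(self, clean_panel):
        res = simulate_annotation_resources(
            clean_panel,
            AnnotationParams(eqtl_fraction=0.4, eqtl_significant_fraction=0.6, seed=41),
        )
        snps = clean_panel.snps.rename(columns={"snp": "snp"})[["snp", "chrom", "pos"]]
        loose = map_variants_to_genes(
            snps,
            res,
            MappingConfig(
                eqtl_q_threshold=0.9999,
                allowed_categories=frozenset(
                    {"exonic", "intronic", "ncRNA_exonic", "ncRNA_intronic",
                     "UTR3", "UTR5", "upstream", "downstream"}
                ),
            ),
        )
        strict = map_variants_to_genes(snps, res, MappingConfig())
        assert set(strict.genes) <= set(loose.genes)

    def test_provenance_chain_reaches_a_lead(self, clean_panel):
        res = simulate_annotation_resources(clean_panel, AnnotationParams(seed=42))
        expanded = ld_expand([clean_panel.snps["snp"].iloc[3]], clean_panel, 0.6)
        out = map_variants_to_genes(expanded, res)
        for gene in out.genes:
            sup = out.support(gene)
            assert (sup["lead_snp"] == clean_panel.snps["snp"].iloc[3]).all()
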