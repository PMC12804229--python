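"""Lenient-threshold lead selection, LD expansion, and gene mapping.

A trait with a few strong causal SNPs is scanned, SNPs below the suggestive
threshold (p < 1e-5) become leads, each lead is expanded with r^2 >= 0.6
proxies from the panel, and the expanded set is mapped to genes through
feature positions and significant eQTLs.
"""

from pathgwas import (
    AnnotationParams,
    MappingConfig,
    SimConfig,
    TraitSpec,
    ld_expand,
    map_variants_to_genes,
    mlma_loco,
    select_lead_snps,
    simulate_annotation_resources,
    simulate_genotypes,
    simulate_traits,
)

genotypes = simulate_genotypes(
    SimConfig(n_individuals=400, n_chromosomes=4, blocks_per_chrom=10,
              snps_per_block=15, within_block_ld=0.5, missing_rate=0.0,
              n_sib_pairs=40, seed=8)
)
resources = simulate_annotation_resources(
    genotypes, AnnotationParams(genic_fraction=0.8, eqtl_fraction=0.2, seed=9)
)
# concentrate the genetic signal in 4 SNPs so a 400-person cohort shows
# suggestive hits, mirroring a large-effect locus in an underpowered study
pheno, truth = simulate_traits(
    genotypes, TraitSpec(h2=(0.6,), n_causal=(4,), equal_effects=True, seed=10)
)

stats = mlma_loco(genotypes, pheno["trait1"].to_numpy()).stats
config = MappingConfig()
leads = select_lead_snps(stats, config.lead_p_threshold)
print(f"{len(leads)} lead SNPs below p < {config.lead_p_threshold:g}")

expanded = ld_expand(leads, genotypes, config.ld_r2_threshold)
print(f"LD expansion at r^2 >= {config.ld_r2_threshold}: "
      f"{expanded['snp'].nunique()} SNPs (leads + proxies)")

genes = map_variants_to_genes(expanded, resources, config, trait="demo")
print(f"candidate genes: {genes.genes}")
print(f"SNPs mapping to no gene: {len(genes.unmapped_snps)}")
print("\nprovenance of the first gene:")
print(genes.support(genes.genes[0]).to_string(index=False))
print("\ntrue causal SNP indices:", sorted(truth.causal_snps[0]))
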