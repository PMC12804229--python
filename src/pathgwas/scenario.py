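"""A fully synthetic three-trait study exercising the whole pipeline.

The scenario mirrors the situation the pipeline is built for: three traits
whose causal genes are disjoint — so single-variant and gene-level results do
not overlap — while the causal genes of different traits sit in the same
pathways, so the shared biology is only visible at the pathway level. Causal
SNPs carry large effects so that a desk-scale cohort yields suggestive
(p < 1e-5) hits; everything downstream (QC, mixed-model association, lead
selection, LD expansion, gene mapping, pathway harvest, overlap matrices and
the Jaccard permutation test) runs exactly as it would on real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import MlmaResult, genomic_inflation, mlma_loco
from .containers import GenotypeMatrix
from .mapping import CandidateGeneList, MappingConfig, ld_expand, map_variants_to_genes, select_lead_snps
from .overlap import OverlapMatrix, PermutationResult, jaccard_permutation_test, overlap_matrices
from .pathways import GenePathwayTable, build_merged_network, harvest_gene_pathway_table
from .qc import QCReport, apply_qc
from .sim import AnnotationParams, ResourceBundle, SimConfig, TraitSpec, simulate_annotation_resources, simulate_genotypes, simulate_traits

__all__ = ["ScenarioResult", "run_shared_pathway_scenario"]

_TRAITS = ("verbal_em", "visual_em", "working_mem")


@dataclass
class ScenarioResult:
    genotypes: GenotypeMatrix
    qc_report: QCReport
    mlma: dict[str, MlmaResult]
    lambdas: dict[str, float]
    leads: dict[str, pd.DataFrame]
    gene_lists: dict[str, CandidateGeneList]
    tables: dict[str, GenePathwayTable]
    resources: ResourceBundle
    overlap: OverlapMatrix
    permutations: dict[tuple[str, str], PermutationResult]
    causal_genes: dict[str, list[str]]

    @property
    def network(self):
        return build_merged_network(
            list(self.tables.values()),
            [self.gene_lists[t].annotations for t in self.tables],
        )


def _pick_causal(
    resources: ResourceBundle,
    genotypes: GenotypeMatrix,
    n_traits: int,
    genes_per_trait: int,
    rng: np.random.Generator,
) -> tuple[list[list[str]], list[list[int]]]:
    """Disjoint causal genes per trait (on distinct LD blocks) and one SNP
    inside an allowed feature of each gene."""
    snp_pos = {(int(c), int(p)): i for i, (c, p) in enumerate(zip(genotypes.snps["chrom"], genotypes.snps["pos"]))}
    gene_chrom = dict(zip(resources.genes["gene_id"], resources.genes["chrom"]))
    usable: dict[str, int] = {}
    for rec in resources.features.itertuples(index=False):
        if rec.category not in ("exonic", "intronic", "ncRNA_exonic", "ncRNA_intronic", "UTR3", "UTR5"):
            continue
        # find a SNP inside this feature (positions are 1-based, features 0-based)
        chrom = gene_chrom[rec.gene_id]
        for pos0 in range(int(rec.start), int(rec.end)):
            i = snp_pos.get((int(chrom), pos0 + 1))
            if i is not None:
                usable.setdefault(rec.gene_id, i)
                break
    candidates = sorted(usable)
    rng.shuffle(candidates)
    need = n_traits * genes_per_trait
    if len(candidates) < need:
        raise ValueError("annotation too sparse to place causal genes")
    genes = [candidates[k * genes_per_trait : (k + 1) * genes_per_trait] for k in range(n_traits)]
    snps = [[usable[g] for g in gs] for gs in genes]
    return genes, snps


def _shared_pathway_db(
    resources: ResourceBundle,
    causal_genes: list[list[str]],
    rng: np.random.Generator,
    n_shared: int = 3,
    n_filler: int = 24,
    filler_size: int = 6,
    n_extra_genes: int = 120,
) -> dict[str, dict[str, set[str]]]:
    """Pathway databases where each 'shared' pathway holds one causal gene of
    every trait, and fillers hold non-causal genes.

    Pathway databases cover far more genes than any one genotyping panel, so
    fillers also draw on ``n_extra_genes`` annotation-only gene ids; this keeps
    the pathway-annotated universe (the permutation-null sampling frame) much
    larger than the candidate lists, as it is in practice.
    """
    all_genes = resources.all_genes()
    causal_flat = {g for gs in causal_genes for g in gs}
    extra = [f"GX{k:03d}" for k in range(n_extra_genes)]
    noncausal = [g for g in all_genes if g not in causal_flat] + extra
    db: dict[str, dict[str, set[str]]] = {"dbA": {}, "dbB": {}, "dbC": {}}
    db_names = list(db)
    for k in range(n_shared):
        members = {gs[k % len(gs)] for gs in causal_genes}
        members |= set(rng.choice(extra, size=2, replace=False))
        db[db_names[k % 3]][f"{db_names[k % 3]}:SHARED{k}"] = members
    for k in range(n_filler):
        name = db_names[k % 3]
        members = set(rng.choice(noncausal, size=min(filler_size, len(noncausal)), replace=False))
        db[name][f"{name}:FILLER{k:02d}"] = members
    return db


def _deliberate_eqtl(
    resources: ResourceBundle,
    genotypes: GenotypeMatrix,
    causal_snps: list[list[int]],
    rng: np.random.Generator,
    n_nonsignificant: int = 40,
) -> pd.DataFrame:
    """eQTL rows: each causal SNP regulates its own gene (q < 0.05), plus
    non-significant rows on random SNPs to exercise the q-value filter."""
    gene_of_snp: dict[int, str] = {}
    snp_pos = {(int(c), int(p)): i for i, (c, p) in enumerate(zip(genotypes.snps["chrom"], genotypes.snps["pos"]))}
    for g in resources.genes.itertuples(index=False):
        for pos0 in range(int(g.start), int(g.end)):
            i = snp_pos.get((int(g.chrom), pos0 + 1))
            if i is not None:
                gene_of_snp[i] = g.gene_id
    rows = []
    for cs in causal_snps:
        for i in cs:
            rows.append(
                {
                    "snp_id": genotypes.snps["snp"].iloc[i],
                    "gene_id": gene_of_snp[i],
                    "tissue": "cortex",
                    "q_value": float(rng.uniform(0.0, 0.05)),
                }
            )
    flat = {i for cs in causal_snps for i in cs}
    pool = [i for i in gene_of_snp if i not in flat]
    for i in rng.choice(pool, size=min(n_nonsignificant, len(pool)), replace=False):
        rows.append(
            {
                "snp_id": genotypes.snps["snp"].iloc[int(i)],
                "gene_id": gene_of_snp[int(i)],
                "tissue": "hippocampus",
                "q_value": float(rng.uniform(0.05, 1.0)),
            }
        )
    return pd.DataFrame(rows, columns=["snp_id", "gene_id", "tissue", "q_value"])


def run_shared_pathway_scenario(
    seed: int = 0,
    n_individuals: int = 400,
    n_chromosomes: int = 4,
    blocks_per_chrom: int = 10,
    snps_per_block: int = 15,
    n_sib_pairs: int = 40,
    genes_per_trait: int = 3,
    h2: float = 0.6,
    n_perm: int = 5_000,
) -> ScenarioResult:
    """Run the full pipeline on the shared-pathway synthetic study.

    Returns every intermediate product. At the defaults the three traits share
    zero candidate genes while their pathway-level Jaccard overlap sits in the
    upper tail of the permutation null; the whole run is a pure function of
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    config = SimConfig(
        n_individuals=n_individuals,
        n_chromosomes=n_chromosomes,
        blocks_per_chrom=blocks_per_chrom,
        snps_per_block=snps_per_block,
        within_block_ld=0.5,
        missing_rate=0.01,
        n_sib_pairs=n_sib_pairs,
        seed=int(rng.integers(2**31)),
    )
    raw = simulate_genotypes(config)
    genotypes, qc_report = apply_qc(raw)

    # genes span whole LD blocks so proxies of a causal SNP stay in its gene
    resources = simulate_annotation_resources(
        genotypes,
        AnnotationParams(
            genic_fraction=0.9,
            snps_per_gene=snps_per_block,
            ncrna_fraction=0.15,
            eqtl_fraction=0.1,
            eqtl_significant_fraction=0.3,
            pathways_per_db=0,  # pathway_db replaced below
            seed=int(rng.integers(2**31)),
        ),
    )
    causal_genes, causal_snps = _pick_causal(
        resources, genotypes, len(_TRAITS), genes_per_trait, rng
    )
    resources.pathway_db = _shared_pathway_db(resources, causal_genes, rng)
    resources.eqtl = _deliberate_eqtl(resources, genotypes, causal_snps, rng)

    spec = TraitSpec(
        h2=(h2,) * len(_TRAITS),
        n_causal=tuple(len(c) for c in causal_snps),
        causal_snps=tuple(tuple(c) for c in causal_snps),
        equal_effects=True,
        age_effect=0.1,
        sex_effect=0.1,
        seed=int(rng.integers(2**31)),
    )
    pheno, _truth = simulate_traits(genotypes, spec)
    covar = pheno[["age", "sex"]].to_numpy()

    mapping_config = MappingConfig()
    mlma: dict[str, MlmaResult] = {}
    lambdas: dict[str, float] = {}
    leads: dict[str, pd.DataFrame] = {}
    gene_lists: dict[str, CandidateGeneList] = {}
    tables: dict[str, GenePathwayTable] = {}
    for k, trait in enumerate(_TRAITS):
        y = pheno[f"trait{k + 1}"].to_numpy()
        res = mlma_loco(genotypes, y, covariates=covar, sparse_cutoff=0.05)
        mlma[trait] = res
        lambdas[trait] = genomic_inflation(res.stats["P"].to_numpy()).lambda_gc
        hits = select_lead_snps(res.stats, mapping_config.lead_p_threshold)
        leads[trait] = hits
        expanded = ld_expand(hits, genotypes, mapping_config.ld_r2_threshold)
        gene_lists[trait] = map_variants_to_genes(
            expanded, resources, mapping_config, trait=trait
        )
        tables[trait] = harvest_gene_pathway_table(gene_lists[trait], resources.pathway_db)

    overlap = overlap_matrices(
        {t: set(gene_lists[t].genes) for t in _TRAITS},
        {t: tables[t].pathway_set for t in _TRAITS},
    )
    permutations: dict[tuple[str, str], PermutationResult] = {}
    for i in range(len(_TRAITS)):
        for j in range(i + 1, len(_TRAITS)):
            a, b = _TRAITS[i], _TRAITS[j]
            permutations[(a, b)] = jaccard_permutation_test(
                set(gene_lists[a].genes),
                set(gene_lists[b].genes),
                resources.pathway_db,
                n_perm=n_perm,
                seed=int(rng.integers(2**31)),
            )
    return ScenarioResult(
        genotypes=genotypes,
        qc_report=qc_report,
        mlma=mlma,
        lambdas=lambdas,
        leads=leads,
        gene_lists=gene_lists,
        tables=tables,
        resources=resources,
        overlap=overlap,
        permutations=permutations,
        causal_genes={t: causal_genes[k] for k, t in enumerate(_TRAITS)},
    )
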