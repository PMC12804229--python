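"""Lenient-threshold lead-SNP selection, LD expansion, and gene mapping.

Leads are SNPs with association p strictly below a suggestive threshold
(default 1e-5); each lead is expanded to same-chromosome proxies with dosage
r^2 >= 0.6 on a reference panel; the expanded set is mapped to genes
positionally (through gene feature sub-intervals, filtered to exonic,
intronic, ncRNA exonic/intronic and UTR categories) and through eQTL rows
with q < 0.05. Every mapped gene carries full provenance back to a lead SNP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .containers import GenotypeMatrix, validate_summary_stats
from .sim import ResourceBundle

__all__ = [
    "MappingConfig",
    "CandidateGeneList",
    "select_lead_snps",
    "ld_expand",
    "map_variants_to_genes",
]

DEFAULT_CATEGORIES = frozenset(
    {"exonic", "intronic", "ncRNA_exonic", "ncRNA_intronic", "UTR3", "UTR5"}
)

_FLANK_BP = 2_000  # up/downstream assignment window; excluded by default


@dataclass(frozen=True)
class MappingConfig:
    lead_p_threshold: float = 1e-5
    ld_r2_threshold: float = 0.6
    eqtl_q_threshold: float = 0.05
    allowed_categories: frozenset[str] = DEFAULT_CATEGORIES

    def __post_init__(self) -> None:
        for name in ("lead_p_threshold", "ld_r2_threshold", "eqtl_q_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass
class CandidateGeneList:
    """Unique candidate genes for one trait with per-gene supporting rows.

    ``annotations`` has one row per (snp, gene, mapping route): columns
    snp_id, gene_id, mapping_type (positional/eqtl), functional_category,
    q_value, lead_snp, r2.
    """

    trait: str
    genes: list[str]
    annotations: pd.DataFrame
    unmapped_snps: list[str] = field(default_factory=list)

    def support(self, gene_id: str) -> pd.DataFrame:
        return self.annotations.loc[self.annotations["gene_id"] == gene_id]


def select_lead_snps(stats: pd.DataFrame, threshold: float = 1e-5) -> pd.DataFrame:
    """SNPs with p strictly below the lenient threshold, sorted by p ascending."""
    validate_summary_stats(stats)
    hits = stats.loc[np.asarray(stats["P"], dtype=float) < threshold]
    return hits.sort_values("P", ignore_index=True)


def ld_expand(
    leads: pd.DataFrame | list[str],
    reference: GenotypeMatrix,
    r2_threshold: float = 0.6,
) -> pd.DataFrame:
    """Expand lead SNPs with same-chromosome proxies at dosage r^2 >= threshold.

    r^2 is the squared Pearson correlation of mean-imputed dosages on the
    reference panel; the inclusive threshold keeps every lead in its own
    expansion (r^2 = 1 with itself). Returns one row per (snp, lead) pair with
    columns snp, chrom, pos, lead, r2.
    """
    lead_ids = list(leads["SNP"]) if isinstance(leads, pd.DataFrame) else list(leads)
    snp_index = {s: i for i, s in enumerate(reference.snps["snp"])}
    for s in lead_ids:
        if s not in snp_index:
            raise KeyError(f"lead SNP {s!r} absent from the reference panel")

    x = reference.dosages_float()
    mu = np.nanmean(x, axis=0)
    idx = np.where(np.isnan(x))
    x[idx] = mu[idx[1]]
    sd = x.std(axis=0)
    chroms = np.asarray(reference.snps["chrom"])
    rows = []
    for lead in lead_ids:
        j = snp_index[lead]
        same = np.flatnonzero(chroms == chroms[j])
        xl = x[:, j] - x[:, j].mean()
        sl = xl.std()
        for k in same:
            if k == j:
                r2 = 1.0
            elif sd[k] == 0 or sl == 0:
                continue
            else:
                r = float(np.mean(xl * (x[:, k] - mu[k]))) / (sl * sd[k])
                r2 = r * r
            if r2 >= r2_threshold:
                rows.append(
                    {
                        "snp": reference.snps["snp"].iloc[k],
                        "chrom": int(chroms[k]),
                        "pos": int(reference.snps["pos"].iloc[k]),
                        "lead": lead,
                        "r2": r2,
                    }
                )
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos", "lead", "r2"])


def _feature_trees(resources: ResourceBundle) -> dict[int, IntervalTree]:
    """Per-chromosome interval trees over gene feature sub-intervals."""
    gene_chrom = dict(zip(resources.genes["gene_id"], resources.genes["chrom"]))
    trees: dict[int, IntervalTree] = {}
    for rec in resources.features.itertuples(index=False):
        chrom = int(gene_chrom[rec.gene_id])
        trees.setdefault(chrom, IntervalTree())
        if rec.end > rec.start:
            trees[chrom].addi(rec.start, rec.end, (rec.gene_id, rec.category))
    # flanks: up/downstream categories, assigned but filtered out by default
    for g in resources.genes.itertuples(index=False):
        chrom = int(g.chrom)
        trees.setdefault(chrom, IntervalTree())
        up, down = ("upstream", "downstream") if g.strand == "+" else ("downstream", "upstream")
        if g.start > 0:
            trees[chrom].addi(max(0, g.start - _FLANK_BP), g.start, (g.gene_id, up))
        trees[chrom].addi(g.end, g.end + _FLANK_BP, (g.gene_id, down))
    return trees


def map_variants_to_genes(
    snps: pd.DataFrame,
    resources: ResourceBundle,
    config: MappingConfig = MappingConfig(),
    trait: str = "trait",
) -> CandidateGeneList:
    """Map an (expanded) SNP set to candidate genes by position and eQTL.

    ``snps`` needs columns snp, chrom, pos (1-based) and optionally lead, r2
    from the LD expansion. Positional hits locate each SNP inside gene feature
    sub-intervals (BED-style 0-based half-open; the 1-based position is
    converted) and keep categories in ``allowed_categories``; eQTL hits take
    rows with q below the threshold, any tissue. The gene list is the
    deduplicated union with one provenance row per (snp, gene, route).
    """
    if "pos" not in snps.columns or snps["pos"].isna().any():
        raise ValueError("every SNP needs a known position")
    trees = _feature_trees(resources)
    eqtl = resources.eqtl
    sig = eqtl.loc[np.asarray(eqtl["q_value"], dtype=float) < config.eqtl_q_threshold]
    by_snp = dict(tuple(sig.groupby("snp_id"))) if len(sig) else {}

    rows = []
    unmapped = []
    for rec in snps.itertuples(index=False):
        pos0 = int(rec.pos) - 1  # 1-based SNP position -> 0-based coordinate
        hit_any = False
        tree = trees.get(int(rec.chrom))
        if tree is not None:
            for iv in sorted(tree.at(pos0), key=lambda i: (i.data[0], i.data[1])):
                gene_id, category = iv.data
                if category not in config.allowed_categories:
                    continue
                rows.append(
                    {
                        "snp_id": rec.snp,
                        "gene_id": gene_id,
                        "mapping_type": "positional",
                        "functional_category": category,
                        "q_value": np.nan,
                        "lead_snp": getattr(rec, "lead", rec.snp),
                        "r2": float(getattr(rec, "r2", 1.0)),
                    }
                )
                hit_any = True
        for erec in by_snp.get(rec.snp, pd.DataFrame()).itertuples(index=False):
            rows.append(
                {
                    "snp_id": rec.snp,
                    "gene_id": erec.gene_id,
                    "mapping_type": "eqtl",
                    "functional_category": "eqtl",
                    "q_value": float(erec.q_value),
                    "lead_snp": getattr(rec, "lead", rec.snp),
                    "r2": float(getattr(rec, "r2", 1.0)),
                }
            )
            hit_any = True
        if not hit_any:
            unmapped.append(rec.snp)

    ann = pd.DataFrame(
        rows,
        columns=[
            "snp_id",
            "gene_id",
            "mapping_type",
            "functional_category",
            "q_value",
            "lead_snp",
            "r2",
        ],
    ).drop_duplicates(subset=["snp_id", "gene_id", "mapping_type"], ignore_index=True)
    genes = list(dict.fromkeys(ann["gene_id"]))
    return CandidateGeneList(trait=trait, genes=genes, annotations=ann, unmapped_snps=unmapped)
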