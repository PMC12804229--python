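"""Gene-pathway harvest, typed gene/pathway/SNP networks, pathway grouping.

The harvest step lists every (gene, pathway, database) membership for a
candidate gene list — an association inventory, not an enrichment test. The
network layer builds typed graphs (gene, pathway and optionally SNP nodes)
per trait and merges them with set semantics, replacing SNP nodes by direct
gene-gene "shared SNP" edges in the reduced view. Redundant pathways (gene
overlap above a threshold across databases) are grouped by single linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import pandas as pd

from .mapping import CandidateGeneList

__all__ = [
    "GenePathwayTable",
    "PathwayGroup",
    "harvest_gene_pathway_table",
    "build_merged_network",
    "group_pathways",
    "shared_pathways",
    "flatten_pathway_db",
]


@dataclass
class GenePathwayTable:
    """Rows of (gene_id, pathway_id, database) for one trait's gene list."""

    trait: str
    rows: pd.DataFrame
    unmapped_genes: list[str] = field(default_factory=list)

    @property
    def pathway_set(self) -> set[str]:
        return set(self.rows["pathway_id"])

    @property
    def gene_set(self) -> set[str]:
        return set(self.rows["gene_id"])


@dataclass
class PathwayGroup:
    members: list[str]
    representative: str
    union_genes: set[str]


def flatten_pathway_db(pathway_db: dict[str, dict[str, set[str]]]) -> dict[str, set[str]]:
    """Flatten {database -> {pathway -> genes}} keeping database-qualified ids."""
    flat: dict[str, set[str]] = {}
    for db in pathway_db.values():
        for pid, genes in db.items():
            flat[pid] = set(genes)
    return flat


def harvest_gene_pathway_table(
    genes: CandidateGeneList | list[str],
    pathway_db: dict[str, dict[str, set[str]]],
    trait: str | None = None,
) -> GenePathwayTable:
    """Every (gene, pathway, database) membership touching the gene list.

    Databases are kept distinct: an identical gene set stored under different
    identifiers in two databases yields one row per database. Genes absent
    from every database are reported as unmapped.
    """
    if isinstance(genes, CandidateGeneList):
        gene_list = genes.genes
        trait = trait if trait is not None else genes.trait
    else:
        gene_list = list(genes)
        trait = trait or "trait"
    rows = []
    mapped: set[str] = set()
    for db_name, db in pathway_db.items():
        for pid, members in db.items():
            for g in gene_list:
                if g in members:
                    rows.append({"gene_id": g, "pathway_id": pid, "database": db_name})
                    mapped.add(g)
    frame = pd.DataFrame(rows, columns=["gene_id", "pathway_id", "database"])
    frame = frame.drop_duplicates(ignore_index=True)
    unmapped = [g for g in gene_list if g not in mapped]
    return GenePathwayTable(trait=trait, rows=frame, unmapped_genes=unmapped)


def _merge_trait(graph: nx.Graph, node: str, kind: str, trait: str) -> None:
    if node in graph:
        graph.nodes[node]["traits"] = graph.nodes[node]["traits"] | {trait}
    else:
        graph.add_node(node, kind=kind, traits={trait})


def build_merged_network(
    tables: list[GenePathwayTable],
    annotations: list[pd.DataFrame] | None = None,
    include_snps: bool = False,
) -> nx.Graph:
    """Union the per-trait gene-pathway networks into one typed graph.

    Nodes carry ``kind`` (gene/pathway/snp) and the set of traits they came
    from. With ``include_snps`` off, gene pairs supported by a common mapped
    SNP are joined by a ``shared_snp`` edge (the reduced, "dashed" view); with
    it on, SNP nodes plus ``positional_map``/``eqtl_map`` edges and lead-proxy
    ``ld`` edges are materialized instead. Merging is idempotent: unioning a
    network's inputs with themselves changes nothing.
    """
    g = nx.Graph()
    for table in tables:
        for rec in table.rows.itertuples(index=False):
            _merge_trait(g, rec.gene_id, "gene", table.trait)
            _merge_trait(g, rec.pathway_id, "pathway", table.trait)
            g.add_edge(rec.gene_id, rec.pathway_id, kind="membership", database=rec.database)

    if annotations is None:
        annotations = []
    traits = [t.trait for t in tables]
    for trait, ann in zip(traits, annotations):
        if ann is None or not len(ann):
            continue
        if include_snps:
            for rec in ann.itertuples(index=False):
                _merge_trait(g, rec.snp_id, "snp", trait)
                _merge_trait(g, rec.gene_id, "gene", trait)
                kind = "positional_map" if rec.mapping_type == "positional" else "eqtl_map"
                g.add_edge(rec.snp_id, rec.gene_id, kind=kind)
                if rec.lead_snp != rec.snp_id:
                    _merge_trait(g, rec.lead_snp, "snp", trait)
                    g.add_edge(rec.lead_snp, rec.snp_id, kind="ld", r2=float(rec.r2))
        else:
            for _, grp in ann.groupby("snp_id"):
                for ga, gb in combinations(sorted(set(grp["gene_id"])), 2):
                    if ga in g and gb in g:
                        g.add_edge(ga, gb, kind="shared_snp")
    return g


def group_pathways(
    pathway_sets: dict[str, set[str]],
    shared_fraction: float = 0.8,
    metric: str = "overlap",
) -> list[PathwayGroup]:
    """Group redundant pathways whose gene overlap reaches ``shared_fraction``.

    Pairwise overlap is ``|A n B| / min(|A|, |B|)`` (overlap coefficient;
    ``metric="jaccard"`` uses ``|A n B| / |A u B|``); pairs at or above the
    threshold are linked and groups are the connected components (single
    linkage), so chains merge. Every pathway lands in exactly one group; the
    representative is the lexicographically smallest member id.
    """
    if not 0.0 < shared_fraction <= 1.0:
        raise ValueError("shared_fraction must lie in (0, 1]")
    if metric not in ("overlap", "jaccard"):
        raise ValueError(f"unknown grouping metric: {metric!r}")
    ids = sorted(pathway_sets)
    g = nx.Graph()
    g.add_nodes_from(ids)
    for a, b in combinations(ids, 2):
        sa, sb = pathway_sets[a], pathway_sets[b]
        inter = len(sa & sb)
        if inter == 0:
            continue
        denom = min(len(sa), len(sb)) if metric == "overlap" else len(sa | sb)
        if denom and inter / denom >= shared_fraction:
            g.add_edge(a, b)
    groups = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        union: set[str] = set()
        for pid in members:
            union |= pathway_sets[pid]
        groups.append(PathwayGroup(members=members, representative=members[0], union_genes=union))
    groups.sort(key=lambda gr: gr.representative)
    return groups


def shared_pathways(network: nx.Graph, min_traits: int = 2) -> list[str]:
    """Pathways whose gene neighbors span at least ``min_traits`` traits."""
    out = []
    for node, data in network.nodes(data=True):
        if data.get("kind") != "pathway":
            continue
        traits: set[str] = set()
        for nb in network.neighbors(node):
            if network.nodes[nb].get("kind") == "gene":
                traits |= set(network.nodes[nb].get("traits", ()))
        if len(traits) >= min_traits:
            out.append(node)
    return sorted(out)
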