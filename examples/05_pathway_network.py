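"""Gene-pathway harvest, merged typed network, and redundancy grouping.

Harvests every (gene, pathway, database) association for two trait gene
lists, merges the per-trait networks into one typed graph (genes, pathways,
shared-SNP links), groups pathways sharing >= 80% of their genes, and
exports the network as TSV/SIF/GraphML for downstream tools.
"""

from pathlib import Path

from pathgwas import (
    build_merged_network,
    flatten_pathway_db,
    group_pathways,
    harvest_gene_pathway_table,
    shared_pathways,
)
from pathgwas.io import write_network

pathway_db = {
    "dbA": {
        "dbA:synaptic_vesicle": {"SYT1", "STX1A", "SNAP25", "VAMP2"},
        "dbA:axon_guidance": {"EPHA4", "EPHB2", "DCC", "ROBO1"},
    },
    "dbB": {
        "dbB:vesicle_cycle": {"SYT1", "STX1A", "SNAP25", "VAMP2", "RAB3A"},
        "dbB:calcium_signaling": {"CACNA1C", "KCNN3", "SYT1"},
    },
}

table_a = harvest_gene_pathway_table(["SYT1", "EPHA4", "NOVELGENE"], pathway_db, trait="traitA")
table_b = harvest_gene_pathway_table(["SNAP25", "KCNN3"], pathway_db, trait="traitB")
print(f"traitA: {len(table_a.rows)} gene-pathway rows, unmapped: {table_a.unmapped_genes}")
print(f"traitB: {len(table_b.rows)} gene-pathway rows")

network = build_merged_network([table_a, table_b])
kinds = [d["kind"] for _, d in network.nodes(data=True)]
print(f"merged network: {kinds.count('gene')} genes, {kinds.count('pathway')} pathways, "
      f"{network.number_of_edges()} edges")
print("pathways touched by both traits:", shared_pathways(network))

groups = group_pathways(flatten_pathway_db(pathway_db), shared_fraction=0.8)
for g in groups:
    if len(g.members) > 1:
        print(f"redundant group (>=80% shared genes): {g.members} "
              f"-> representative {g.representative}")

outdir = Path("scratch/example05")
paths = write_network(network, outdir, stem="memory_pathways")
print(f"exports: {', '.join(p.name for p in paths.values())} under {outdir}/")
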