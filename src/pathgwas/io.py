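"""Readers and writers for the pipeline's file formats.

Genotypes round-trip through VCF (GT field; read back via cyvcf2) and a
dosage-matrix TSV; annotation through BED (0-based half-open) plus a feature
TSV; pathways through GMT; networks through node/edge TSVs, SIF and GraphML.
All text, all tab-separated where tabular.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import MISSING, SUMMARY_COLUMNS, GenotypeMatrix, validate_summary_stats
from .overlap import PermutationResult
from .qc import QCReport
from .sim import ResourceBundle

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_phenotypes",
    "read_phenotypes",
    "write_summary_stats",
    "read_summary_stats",
    "write_resources",
    "read_gmt",
    "write_gmt",
    "write_network",
    "write_qc_report",
    "write_permutation_result",
]

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pathgwas\n")
        for chrom in sorted(set(gm.snps["chrom"])):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j, rec in enumerate(gm.snps.itertuples(index=False)):
            gts = "\t".join(_GT[int(d)] for d in gm.dosages[:, j])
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.snp}\t{rec.a2}\t{rec.a1}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into dosages of the ALT allele (cyvcf2 backend)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    dosage_cols = []
    # cyvcf2 gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
    code = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for v in vcf:
        rows.append(
            {
                "snp": v.ID or f"{v.CHROM}:{v.POS}",
                "chrom": int(v.CHROM),
                "pos": int(v.POS),
                "a1": v.ALT[0] if v.ALT else ".",
                "a2": v.REF,
            }
        )
        dosage_cols.append(code[v.gt_types])
    vcf.close()
    dosages = np.column_stack(dosage_cols) if dosage_cols else np.empty((len(samples), 0), np.int8)
    return GenotypeMatrix(dosages=dosages, snps=pd.DataFrame(rows), samples=samples)


def write_dosage_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    """SNP-per-row dosage matrix: snp, chrom, pos, a1, a2, then one column per
    individual; missing written as NA."""
    meta = gm.snps[["snp", "chrom", "pos", "a1", "a2"]]
    dos = gm.dosages.T.astype(object)
    dos[dos == MISSING] = "NA"
    body = pd.DataFrame(dos, columns=gm.samples)
    pd.concat([meta, body], axis=1).to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    frame = pd.read_csv(path, sep="\t", dtype={"snp": str, "a1": str, "a2": str})
    meta_cols = ["snp", "chrom", "pos", "a1", "a2"]
    samples = [c for c in frame.columns if c not in meta_cols]
    dos = frame[samples].to_numpy(dtype=object)
    out = np.empty(dos.shape, dtype=np.int8)
    for idx, val in np.ndenumerate(dos):
        out[idx] = MISSING if (isinstance(val, float) and np.isnan(val)) or val == "NA" else int(val)
    return GenotypeMatrix(dosages=out.T, snps=frame[meta_cols], samples=samples)


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_summary_stats(stats: pd.DataFrame, path: str | Path) -> None:
    validate_summary_stats(stats)
    stats[SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    return validate_summary_stats(pd.read_csv(path, sep="\t"))


def write_gmt(db: dict[str, set[str]], path: str | Path, description: str = "na") -> None:
    """One pathway per line: id, description, tab-separated gene ids. A
    database with no pathways yields a valid zero-line file."""
    with Path(path).open("w") as fh:
        for pid in sorted(db):
            genes = "\t".join(sorted(db[pid]))
            fh.write(f"{pid}\t{description}\t{genes}\n" if genes else f"{pid}\t{description}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    db: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or not parts[0]:
                continue
            db[parts[0]] = set(g for g in parts[2:] if g)
    return db


def write_resources(resources: ResourceBundle, outdir: str | Path) -> dict[str, Path]:
    """Write a ResourceBundle as BED + feature TSV + eQTL TSV + per-database GMT."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    bed = outdir / "genes.bed"
    with bed.open("w") as fh:
        for g in resources.genes.itertuples(index=False):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
    paths["genes_bed"] = bed

    feat = outdir / "features.tsv"
    resources.features.to_csv(feat, sep="\t", index=False)
    paths["features_tsv"] = feat

    eq = outdir / "eqtl.tsv"
    resources.eqtl.to_csv(eq, sep="\t", index=False)
    paths["eqtl_tsv"] = eq

    for name, db in resources.pathway_db.items():
        p = outdir / f"{name}.gmt"
        write_gmt(db, p)
        paths[f"gmt_{name}"] = p
    return paths


def _stringify(value):
    if isinstance(value, (set, frozenset)):
        return "|".join(sorted(value))
    if isinstance(value, float) and np.isnan(value):
        return ""
    return value


def write_network(graph: nx.Graph, outdir: str | Path, stem: str = "network") -> dict[str, Path]:
    """Export a typed network as node/edge TSVs, SIF, and GraphML.

    Set-valued attributes (trait-of-origin) are serialized as |-joined
    strings so every format round-trips as text.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    nodes = pd.DataFrame(
        [
            {"id": n, **{k: _stringify(v) for k, v in data.items()}}
            for n, data in sorted(graph.nodes(data=True))
        ]
    )
    paths["nodes_tsv"] = outdir / f"{stem}.nodes.tsv"
    nodes.to_csv(paths["nodes_tsv"], sep="\t", index=False)

    edges = pd.DataFrame(
        [
            {"source": a, "target": b, **{k: _stringify(v) for k, v in data.items()}}
            for a, b, data in sorted(graph.edges(data=True))
        ]
    )
    paths["edges_tsv"] = outdir / f"{stem}.edges.tsv"
    edges.to_csv(paths["edges_tsv"], sep="\t", index=False)

    paths["sif"] = outdir / f"{stem}.sif"
    with paths["sif"].open("w") as fh:
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{data.get('kind', 'edge')}\t{b}\n")

    clean = nx.Graph()
    for n, data in graph.nodes(data=True):
        clean.add_node(n, **{k: str(_stringify(v)) for k, v in data.items()})
    for a, b, data in graph.edges(data=True):
        clean.add_edge(a, b, **{k: str(_stringify(v)) for k, v in data.items()})
    paths["graphml"] = outdir / f"{stem}.graphml"
    nx.write_graphml(clean, paths["graphml"])
    return paths


def write_qc_report(report: QCReport, path_tsv: str | Path, path_log: str | Path | None = None) -> None:
    rows = [
        {"axis": "individual", "filter": "call_rate", "removed": len(report.removed_individuals)},
    ] + [
        {"axis": "snp", "filter": name, "removed": len(ids)}
        for name, ids in report.removed_snps.items()
    ]
    pd.DataFrame(rows).to_csv(path_tsv, sep="\t", index=False)
    if path_log is not None:
        Path(path_log).write_text(report.summary() + "\n")


def write_permutation_result(result: PermutationResult, path_tsv: str | Path, path_json: str | Path) -> None:
    pd.DataFrame({"null_jaccard": result.null_values}).to_csv(path_tsv, sep="\t", index=False)
    summary = {
        "observed_jaccard": result.observed_jaccard,
        "n_perm": result.n_perm,
        "percentile": result.percentile,
        "sizes": list(result.sizes),
        "seed": result.seed,
        "caveat": result.caveat,
    }
    Path(path_json).write_text(json.dumps(summary, indent=2) + "\n")
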