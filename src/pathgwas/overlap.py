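"""Cross-trait overlap matrices and the Jaccard permutation null.

Gene-level overlap is a symmetric count matrix; pathway-level overlap is the
asymmetric row-relative percentage (share of the row's pathways also found in
the column's). The permutation test asks whether the observed Jaccard index
of two traits' induced pathway sets is large relative to random gene lists of
the same sizes drawn from the pathway-annotated gene universe — the same
question the pipeline ends on. Note the caveat carried in the result
metadata: observed gene lists come from association, not random draws, so
the null is a calibration reference rather than a strict sampling model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OverlapMatrix",
    "PermutationResult",
    "overlap_matrices",
    "jaccard_index",
    "jaccard_permutation_test",
    "pathway_universe",
]

_CAVEAT = (
    "observed gene lists are association-derived, not random; the permutation "
    "null uses uniformly drawn gene lists of matched size"
)


@dataclass
class OverlapMatrix:
    labels: list[str]
    gene_counts: pd.DataFrame  # symmetric |Gi n Gj|
    pathway_pct: pd.DataFrame  # row-relative 100*|Pi n Pj|/|Pi|
    empty_pathway_rows: list[str] = field(default_factory=list)


def overlap_matrices(
    gene_lists: dict[str, set[str]], pathway_sets: dict[str, set[str]]
) -> OverlapMatrix:
    """Pairwise gene-count and row-relative pathway-percentage matrices.

    The pathway percentage of cell (row, col) is the share of the row's
    pathway set present in the column's; rows with empty pathway sets get 0
    and are flagged.
    """
    labels = list(gene_lists)
    if set(pathway_sets) != set(labels):
        raise ValueError("gene_lists and pathway_sets must share labels")
    counts = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    pct = pd.DataFrame(0.0, index=labels, columns=labels)
    empty = [lab for lab in labels if not pathway_sets[lab]]
    for a in labels:
        for b in labels:
            counts.loc[a, b] = len(gene_lists[a] & gene_lists[b])
            if pathway_sets[a]:
                pct.loc[a, b] = 100.0 * len(pathway_sets[a] & pathway_sets[b]) / len(
                    pathway_sets[a]
                )
    return OverlapMatrix(
        labels=labels, gene_counts=counts, pathway_pct=pct, empty_pathway_rows=empty
    )


def jaccard_index(a: set, b: set) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


@dataclass
class PermutationResult:
    observed_jaccard: float
    null_values: np.ndarray
    n_perm: int
    percentile: float  # 100 * #{null <= observed} / n_perm
    sizes: tuple[int, int]
    seed: int
    caveat: str = _CAVEAT

    def __post_init__(self) -> None:
        assert len(self.null_values) == self.n_perm


def pathway_universe(
    pathway_db: dict[str, dict[str, set[str]]], mode: str = "union"
) -> tuple[list[str], dict[str, set[str]]]:
    """Genes annotated to >= 1 pathway and the gene -> pathway-id index.

    ``mode="union"`` (default) admits a gene annotated in any database;
    ``mode="intersection"`` requires membership in every database.
    """
    per_db: list[set[str]] = []
    gene_to_pw: dict[str, set[str]] = {}
    for db in pathway_db.values():
        seen: set[str] = set()
        for pid, members in db.items():
            for g in members:
                gene_to_pw.setdefault(g, set()).add(pid)
                seen.add(g)
        per_db.append(seen)
    if mode == "union":
        universe = set().union(*per_db) if per_db else set()
    elif mode == "intersection":
        universe = set.intersection(*per_db) if per_db else set()
    else:
        raise ValueError(f"unknown universe mode: {mode!r}")
    return sorted(universe), gene_to_pw


def jaccard_permutation_test(
    genes_a: set[str],
    genes_b: set[str],
    pathway_db: dict[str, dict[str, set[str]]],
    n_perm: int = 100_000,
    seed: int = 0,
    universe_mode: str = "union",
) -> PermutationResult:
    """Permutation test of pathway-level Jaccard overlap between two gene lists.

    The observed statistic is the Jaccard index of the two lists' induced
    pathway sets (every pathway containing >= 1 list gene, all databases).
    Each permutation draws two uniform gene subsets without replacement from
    the pathway-annotated universe, of the same sizes as the observed lists'
    intersections with that universe, and recomputes the statistic. The
    percentile counts null values <= observed (ties count as <=).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    universe, gene_to_pw = pathway_universe(pathway_db, mode=universe_mode)
    in_a = sorted(genes_a & set(universe))
    in_b = sorted(genes_b & set(universe))
    if not in_a or not in_b:
        raise ValueError("an observed gene list is disjoint from the pathway universe")

    pw_ids = sorted({pid for pws in gene_to_pw.values() for pid in pws})
    pw_index = {pid: i for i, pid in enumerate(pw_ids)}
    member = np.zeros((len(universe), len(pw_ids)), dtype=bool)
    for i, g in enumerate(universe):
        for pid in gene_to_pw.get(g, ()):
            member[i, pw_index[pid]] = True
    gene_index = {g: i for i, g in enumerate(universe)}

    def induced(rows: np.ndarray) -> np.ndarray:
        return member[rows].any(axis=0)

    obs_a = induced(np.array([gene_index[g] for g in in_a]))
    obs_b = induced(np.array([gene_index[g] for g in in_b]))
    union = (obs_a | obs_b).sum()
    observed = float((obs_a & obs_b).sum() / union) if union else 0.0

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    n_genes = len(universe)
    for t in range(n_perm):
        ra = induced(rng.choice(n_genes, size=len(in_a), replace=False))
        rb = induced(rng.choice(n_genes, size=len(in_b), replace=False))
        u = (ra | rb).sum()
        null[t] = (ra & rb).sum() / u if u else 0.0
    percentile = 100.0 * float(np.count_nonzero(null <= observed)) / n_perm
    return PermutationResult(
        observed_jaccard=observed,
        null_values=null,
        n_perm=n_perm,
        percentile=percentile,
        sizes=(len(in_a), len(in_b)),
        seed=seed,
    )
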