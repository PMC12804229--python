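"""Synthetic cohort generator: LD-blocked genotypes, polygenic traits, annotation.

The generator emulates the statistical structure a family-based GWAS cohort
presents to the pipeline — LD blocks with a controllable mean r², a MAF
spectrum, missing calls, full-sibling pairs, polygenic traits with specified
heritability and genetic correlation, gene models tiled over SNP positions,
SNP-gene eQTL pairs with q-values, and redundant multi-database pathway
memberships — so that every downstream stage can be exercised and checked
against known truth at desk scale.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MISSING, GenotypeMatrix

__all__ = [
    "SimConfig",
    "TraitSpec",
    "TraitTruth",
    "AnnotationParams",
    "ResourceBundle",
    "simulate_genotypes",
    "simulate_traits",
    "simulate_annotation_resources",
]

_BP_SPACING = 5_000  # uniform SNP spacing, 1-based positions per chromosome

_LATENT_CACHE: dict[tuple[float, float], float] = {}


@dataclass(frozen=True)
class SimConfig:
    """Genotype-simulation parameters.

    ``within_block_ld`` is the target mean r^2 between SNP pairs inside an LD
    block; between-block pairs are independent. ``n_subpopulations=2`` adds a
    discrete allele-frequency split (drift ``fst``) to exercise PC correction.
    """

    n_individuals: int = 200
    n_chromosomes: int = 4
    blocks_per_chrom: int = 5
    snps_per_block: int = 25
    maf_range: tuple[float, float] = (0.05, 0.5)
    within_block_ld: float = 0.4
    missing_rate: float = 0.01
    n_sib_pairs: int = 0
    n_subpopulations: int = 1
    fst: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_individuals", "n_chromosomes", "blocks_per_chrom", "snps_per_block"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0.0 <= self.within_block_ld <= 1.0:
            raise ValueError("within_block_ld must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if 2 * self.n_sib_pairs > self.n_individuals:
            raise ValueError("2 * n_sib_pairs exceeds n_individuals")
        if self.n_subpopulations not in (1, 2):
            raise ValueError("n_subpopulations must be 1 or 2")


def _latent_correlation(target_r2: float, mean_maf: float) -> float:
    """Latent Gaussian correlation whose thresholded binary variables have
    squared correlation ~ target_r2 at allele frequency mean_maf.

    Solved by bisection on the bivariate-normal orthant probability; the
    attenuation from latent to binary correlation depends on the MAF.
    Cached on (target_r2, MAF rounded to 0.01) — the orthant probability is
    smooth in the MAF, so the rounding error is negligible next to sampling
    noise, and the cache keeps large simulations cheap.
    """
    if target_r2 <= 0.0:
        return 0.0
    key = (round(target_r2, 6), round(mean_maf, 2))
    if key in _LATENT_CACHE:
        return _LATENT_CACHE[key]
    mean_maf = key[1]
    target_r = np.sqrt(target_r2)
    p = mean_maf
    z = stats.norm.ppf(p)

    def binary_corr(rho: float) -> float:
        cov = [[1.0, rho], [rho, 1.0]]
        both = stats.multivariate_normal(mean=[0.0, 0.0], cov=cov, allow_singular=True).cdf(
            [z, z]
        )
        return (both - p * p) / (p * (1.0 - p))

    lo, hi = 0.0, 1.0
    if binary_corr(1.0 - 1e-9) <= target_r:
        _LATENT_CACHE[key] = 1.0
        return 1.0
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        if binary_corr(mid) < target_r:
            lo = mid
        else:
            hi = mid
    out = 0.5 * (lo + hi)
    _LATENT_CACHE[key] = out
    return out


def _block_haplotypes(
    rng: np.random.Generator, n_haps: int, mafs: np.ndarray, latent_rho: float
) -> np.ndarray:
    """Haplotypes (n_haps x n_snps, 0/1) with an equicorrelated latent factor."""
    n_snps = mafs.size
    lam = np.sqrt(latent_rho)
    factor = rng.standard_normal((n_haps, 1))
    noise = rng.standard_normal((n_haps, n_snps))
    latent = lam * factor + np.sqrt(1.0 - latent_rho) * noise
    return (latent < stats.norm.ppf(mafs)[None, :]).astype(np.int8)


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Simulate an LD-blocked dosage matrix with sib pairs and missing calls.

    Unrelated individuals receive two fresh founder haplotypes per block; each
    sib pair receives Mendelian transmissions from four fresh parental
    haplotypes, so siblings share a parental haplotype with probability 1/2
    per parent and their expected genomic relatedness is 0.5. LD is induced
    only within blocks, via a shared latent factor on the founder haplotypes
    calibrated to the target mean r^2.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    n_sibs = 2 * config.n_sib_pairs
    n_unrel = n - n_sibs
    m = config.n_chromosomes * config.blocks_per_chrom * config.snps_per_block

    # subpopulation labels for optional structure (sib pairs share a label)
    if config.n_subpopulations == 2:
        pair_labels = rng.integers(0, 2, size=config.n_sib_pairs)
        unrel_labels = rng.integers(0, 2, size=n_unrel)
    else:
        pair_labels = np.zeros(config.n_sib_pairs, dtype=int)
        unrel_labels = np.zeros(n_unrel, dtype=int)

    dosages = np.empty((n, m), dtype=np.int8)
    chroms: list[int] = []
    positions: list[int] = []
    col = 0
    for chrom in range(1, config.n_chromosomes + 1):
        pos_counter = 0
        for _ in range(config.blocks_per_chrom):
            s = config.snps_per_block
            base = rng.uniform(config.maf_range[0], config.maf_range[1], size=s)
            if config.n_subpopulations == 2:
                # Balding-Nichols drift around the base frequency
                a = base * (1.0 - config.fst) / config.fst
                b = (1.0 - base) * (1.0 - config.fst) / config.fst
                pop_mafs = np.stack([rng.beta(a, b), rng.beta(a, b)])
                pop_mafs = np.clip(pop_mafs, 1e-4, 0.9999)
            else:
                pop_mafs = np.stack([base, base])
            rho = _latent_correlation(config.within_block_ld, float(np.mean(base)))

            block = np.empty((n, s), dtype=np.int8)
            for pop in (0, 1):
                u_idx = np.flatnonzero(unrel_labels == pop)
                if u_idx.size:
                    haps = _block_haplotypes(rng, 2 * u_idx.size, pop_mafs[pop], rho)
                    block[u_idx] = haps[: u_idx.size] + haps[u_idx.size :]
                p_idx = np.flatnonzero(pair_labels == pop)
                for k in p_idx:
                    parents = _block_haplotypes(rng, 4, pop_mafs[pop], rho)
                    for sib in range(2):
                        mat = parents[rng.integers(0, 2)]
                        pat = parents[2 + rng.integers(0, 2)]
                        block[n_unrel + 2 * k + sib] = mat + pat
            dosages[:, col : col + s] = block
            for _ in range(s):
                pos_counter += _BP_SPACING
                chroms.append(chrom)
                positions.append(pos_counter)
            col += s

    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = MISSING

    snps = pd.DataFrame(
        {
            "snp": [f"rs{c}_{p}" for c, p in zip(chroms, positions)],
            "chrom": chroms,
            "pos": positions,
            "a1": "A",
            "a2": "G",
        }
    )
    samples = [f"U{i:05d}" for i in range(n_unrel)] + [
        f"S{k:04d}_{sib}" for k in range(config.n_sib_pairs) for sib in range(2)
    ]
    gm = GenotypeMatrix(dosages=dosages, snps=snps, samples=samples)
    gm.sample_info = pd.DataFrame(  # type: ignore[attr-defined]
        {
            "iid": samples,
            "subpop": np.concatenate([unrel_labels, np.repeat(pair_labels, 2)]),
            "family": ["-"] * n_unrel
            + [f"F{k:04d}" for k in range(config.n_sib_pairs) for _ in range(2)],
        }
    )
    return gm


@dataclass(frozen=True)
class TraitSpec:
    """Polygenic trait parameters.

    ``genetic_corr`` is the target correlation of the traits' additive genetic
    values; effects at shared causal SNPs are drawn from a multivariate normal
    with this correlation. ``h2`` is the share of (genetic + environmental)
    variance that is genetic; covariate effects are added on top of that.
    """

    h2: tuple[float, ...] = (0.5,)
    n_causal: tuple[int, ...] = (50,)
    genetic_corr: np.ndarray | None = None
    age_effect: float = 0.0
    sex_effect: float = 0.0
    causal_snps: tuple[tuple[int, ...], ...] | None = None
    equal_effects: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.h2)
        if len(self.n_causal) != k:
            raise ValueError("h2 and n_causal must have equal length")
        if any(not 0.0 <= h <= 1.0 for h in self.h2):
            raise ValueError("h2 values must lie in [0, 1]")
        R = self.corr_matrix()
        if R.shape != (k, k):
            raise ValueError("genetic_corr shape does not match number of traits")
        if not np.allclose(R, R.T):
            raise ValueError("genetic_corr must be symmetric")
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("genetic_corr must have unit diagonal")
        if np.min(np.linalg.eigvalsh(R)) < -1e-8:
            raise ValueError("genetic_corr must be positive semidefinite")

    def corr_matrix(self) -> np.ndarray:
        if self.genetic_corr is None:
            return np.eye(len(self.h2))
        return np.asarray(self.genetic_corr, dtype=float)


@dataclass
class TraitTruth:
    """Ground truth retained for testing: causal indices, per-SNP effects on
    standardized dosages, and the realized (scaled) genetic values."""

    causal_snps: list[np.ndarray]
    effects: np.ndarray  # (n_snps, n_traits), zero off the causal sets
    genetic_values: np.ndarray  # (n_individuals, n_traits), variance h2 by construction


def simulate_traits(
    genotypes: GenotypeMatrix, spec: TraitSpec
) -> tuple[pd.DataFrame, TraitTruth]:
    """Simulate polygenic traits plus age/sex covariates on a genotype panel.

    Each trait is ``sqrt(h2) * g_std + sqrt(1-h2) * e + covariates`` where
    ``g_std`` is the standardized additive genetic value from the trait's
    causal SNPs; the realized genetic variance share (before covariates) is
    h2 by construction. Returns the phenotype/covariate table and the truth.
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.h2)
    n, m = genotypes.n_individuals, genotypes.n_snps
    if any(nc > m for nc in spec.n_causal):
        raise ValueError("n_causal exceeds number of SNPs")

    R = spec.corr_matrix()
    if spec.causal_snps is not None:
        causal = [np.asarray(c, dtype=int) for c in spec.causal_snps]
        if len(causal) != k:
            raise ValueError("causal_snps must give one index set per trait")
    elif np.allclose(R, np.eye(k)):
        causal = [rng.choice(m, size=nc, replace=False) for nc in spec.n_causal]
    else:
        # correlated traits share a causal pool (nested sets); the per-SNP
        # effect correlation then carries through to the genetic values
        pool = rng.choice(m, size=max(spec.n_causal), replace=False)
        causal = [pool[:nc] for nc in spec.n_causal]
    # matrix square root tolerant of singular correlation (e.g. rG = 1)
    w, V = np.linalg.eigh(R)
    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))

    union = np.unique(np.concatenate(causal)) if k else np.array([], dtype=int)
    effects = np.zeros((m, k))
    raw = rng.standard_normal((union.size, k)) @ L.T
    if spec.equal_effects:
        # unit-magnitude effects (random correlated signs): every causal SNP
        # carries an equal share of the genetic variance
        raw = np.where(raw == 0, 1.0, np.sign(raw))
    for j, idx in enumerate(causal):
        member = np.isin(union, idx)
        effects[union[member], j] = raw[member, j]

    Z = genotypes.standardized()
    g = Z @ effects
    g_std = np.zeros_like(g)
    for j in range(k):
        sd = g[:, j].std()
        if sd > 0:
            g_std[:, j] = (g[:, j] - g[:, j].mean()) / sd

    age = rng.integers(22, 37, size=n).astype(float)
    sex = rng.integers(0, 2, size=n).astype(float)
    age_std = (age - age.mean()) / age.std()

    traits = {}
    genetic_values = np.zeros((n, k))
    for j in range(k):
        h2 = spec.h2[j]
        gpart = np.sqrt(h2) * g_std[:, j]
        epart = np.sqrt(1.0 - h2) * rng.standard_normal(n)
        y = gpart + epart + spec.age_effect * age_std + spec.sex_effect * sex
        traits[f"trait{j + 1}"] = y
        genetic_values[:, j] = gpart

    pheno = pd.DataFrame({"IID": genotypes.samples, **traits, "age": age, "sex": sex})
    return pheno, TraitTruth(causal_snps=causal, effects=effects, genetic_values=genetic_values)


@dataclass(frozen=True)
class AnnotationParams:
    """Controls for gene models, eQTL rows, and pathway databases."""

    genic_fraction: float = 0.6
    snps_per_gene: int = 5
    ncrna_fraction: float = 0.2
    eqtl_fraction: float = 0.2
    eqtl_significant_fraction: float = 0.5
    n_eqtl_rows: int | None = None
    db_names: tuple[str, ...] = ("dbA", "dbB", "dbC")
    pathways_per_db: int = 20
    pathway_size_range: tuple[int, int] = (5, 30)
    cross_db_redundancy: float = 0.2
    seed: int = 0


@dataclass
class ResourceBundle:
    """Annotation resources consumed by variant mapping and pathway harvest.

    ``genes``: one row per gene (gene_id, chrom, start, end, strand, coding)
    with 0-based half-open intervals. ``features``: sub-intervals per gene
    (gene_id, feature, start, end, category) lying within the gene interval.
    ``eqtl``: (snp_id, gene_id, tissue, q_value) rows. ``pathway_db``: mapping
    database name -> {pathway_id -> set of gene ids}.
    """

    genes: pd.DataFrame
    features: pd.DataFrame
    eqtl: pd.DataFrame
    pathway_db: dict[str, dict[str, set[str]]]

    def all_genes(self) -> list[str]:
        return list(self.genes["gene_id"])


_TISSUES = ("cortex", "hippocampus", "cerebellum")


def _gene_features(
    gene_id: str, snp_pos: np.ndarray, start: int, end: int, coding: bool
) -> list[dict]:
    """Split a gene interval into feature sub-intervals, boundaries midway
    between consecutive SNPs; first/last SNP slots become UTRs for coding
    genes and exons for ncRNA."""
    cuts = [start]
    for a, b in zip(snp_pos[:-1], snp_pos[1:]):
        cuts.append(int((a + b) // 2))
    cuts.append(end)
    rows = []
    s = len(snp_pos)
    for i in range(s):
        if coding:
            if i == 0 and s > 2:
                feat, cat = "UTR5", "UTR5"
            elif i == s - 1 and s > 2:
                feat, cat = "UTR3", "UTR3"
            else:
                feat = "exon" if i % 2 == 1 else "intron"
                cat = "exonic" if feat == "exon" else "intronic"
        else:
            feat = "exon" if i % 2 == 0 else "intron"
            cat = "ncRNA_exonic" if feat == "exon" else "ncRNA_intronic"
        rows.append(
            {"gene_id": gene_id, "feature": feat, "start": cuts[i], "end": cuts[i + 1], "category": cat}
        )
    return rows


def simulate_annotation_resources(
    genotypes: GenotypeMatrix, params: AnnotationParams = AnnotationParams()
) -> ResourceBundle:
    """Generate gene models tiled over SNP positions, eQTL rows, and GMT-style
    pathway databases with controllable cross-database redundancy.

    Genes are built from disjoint runs of consecutive SNPs (a ``genic_fraction``
    of runs become genes, the rest stay intergenic), so gene intervals never
    overlap. A ``cross_db_redundancy`` fraction of each database's pathways is
    copied into another database under a fresh identifier.
    """
    if genotypes.n_snps == 0:
        raise ValueError("empty genotype input")
    rng = np.random.default_rng(params.seed)
    snps = genotypes.snps

    gene_rows: list[dict] = []
    feat_rows: list[dict] = []
    gi = 0
    span = params.snps_per_gene * _BP_SPACING  # genes tile fixed position windows
    for chrom, sub in snps.groupby("chrom", sort=True):
        pos = np.sort(np.asarray(sub["pos"]))
        for w0 in range(0, int(pos[-1]), span):
            run = pos[(pos > w0) & (pos <= w0 + span)]
            if len(run) < 2:
                continue
            if rng.random() >= params.genic_fraction:
                continue
            coding = rng.random() >= params.ncrna_fraction
            margin = _BP_SPACING // 4
            start = int(run[0]) - 1 - margin  # 1-based SNP pos -> 0-based interval
            end = int(run[-1]) + margin
            gene_id = f"G{gi:04d}"
            gi += 1
            gene_rows.append(
                {
                    "gene_id": gene_id,
                    "chrom": int(chrom),
                    "start": start,
                    "end": end,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "coding": coding,
                }
            )
            feat_rows.extend(_gene_features(gene_id, run - 1, start, end, coding))
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand", "coding"]
    )
    features = pd.DataFrame(feat_rows, columns=["gene_id", "feature", "start", "end", "category"])

    # eQTL rows: a fraction of SNPs each regulate one same-chromosome gene
    eqtl_rows: list[dict] = []
    if len(genes):
        if params.n_eqtl_rows is not None:
            chosen = rng.choice(len(snps), size=params.n_eqtl_rows, replace=True)
        else:
            n_rows = int(round(params.eqtl_fraction * len(snps)))
            chosen = rng.choice(len(snps), size=n_rows, replace=False)
        by_chrom = {c: g["gene_id"].tolist() for c, g in genes.groupby("chrom")}
        for idx in chosen:
            rec = snps.iloc[int(idx)]
            pool = by_chrom.get(int(rec["chrom"])) or genes["gene_id"].tolist()
            q = (
                rng.uniform(0.0, 0.05)
                if rng.random() < params.eqtl_significant_fraction
                else rng.uniform(0.05, 1.0)
            )
            eqtl_rows.append(
                {
                    "snp_id": rec["snp"],
                    "gene_id": pool[rng.integers(0, len(pool))],
                    "tissue": _TISSUES[rng.integers(0, len(_TISSUES))],
                    "q_value": q,
                }
            )
    eqtl = pd.DataFrame(eqtl_rows, columns=["snp_id", "gene_id", "tissue", "q_value"])

    # pathway databases with cross-database redundancy
    pathway_db: dict[str, dict[str, set[str]]] = {name: {} for name in params.db_names}
    universe = genes["gene_id"].tolist()
    if universe and params.pathways_per_db > 0:
        counter = 0
        for name in params.db_names:
            for _ in range(params.pathways_per_db):
                size = int(
                    rng.integers(
                        params.pathway_size_range[0],
                        min(params.pathway_size_range[1], len(universe)) + 1,
                    )
                )
                members = set(rng.choice(universe, size=max(1, size), replace=False))
                pathway_db[name][f"{name}:PW{counter:04d}"] = members
                counter += 1
        if len(params.db_names) > 1 and params.cross_db_redundancy > 0:
            names = list(params.db_names)
            for i, name in enumerate(names):
                for pid, members in list(pathway_db[name].items()):
                    if rng.random() < params.cross_db_redundancy:
                        other = names[(i + 1) % len(names)]
                        pathway_db[other][f"{other}:PW{counter:04d}"] = set(members)
                        counter += 1
    return ResourceBundle(genes=genes, features=features, eqtl=eqtl, pathway_db=pathway_db)
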