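# pathgwas

Pathway-level interpretation of underpowered genome-wide association studies.

Deeply phenotyped cohorts — family studies with rich cognitive or imaging
batteries — are usually too small for individual variants of a complex,
polygenic trait to reach genome-wide significance (p < 5e-8). `pathgwas`
implements the alternative reading of such studies: keep variants below a
*lenient* suggestive threshold (p < 1e-5), expand them through linkage
disequilibrium (r² ≥ 0.6), map the expanded set to genes by position (exonic,
intronic, ncRNA and UTR features) and by eQTL (q < 0.05), harvest every
gene→pathway association across multiple databases, and then ask a
quantitative question: **do different traits converge on the same pathways
even when they share no variants or genes?** Convergence is scored by the
Jaccard index of the traits' induced pathway sets against a permutation null
of randomly drawn gene lists of the same size.

The statistical engine underneath is a family-aware GWAS stack:

- **QC** with the standard acceptance criteria — MAF > 0.05, SNP and
  individual call rate > 0.95, exact Hardy–Weinberg p > 1e-6.
- **GRM** `A_jk = (1/M) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2p_i(1−p_i))`,
  optionally sparsified at |A_jk| < 0.05, plus LD-pruned genomic principal
  components.
- **AI-REML** variance components (`y = Xb + g + e`, `Var(g) = σ_g² A`),
  giving `h² = σ_g²/(σ_g²+σ_e²)`; optional MAF-binned multi-component fits.
- **MLMA-LOCO**: each chromosome's SNPs tested by GLS under a mixed model
  whose GRM excludes that chromosome (no proximal contamination).
- **Genetic correlation** by Haseman–Elston cross-product regression on the
  GRM off-diagonal; genomic inflation λ = median(χ²)/0.4549; per-SNP
  effect-size correlation with allele harmonization.
- **Overlap inference**: gene-count and row-relative pathway-percentage
  matrices across traits, and the seeded Jaccard permutation test.

A first-class synthetic-data module (`pathgwas.sim`) generates LD-blocked
genotypes with full-sib pairs, polygenic traits with chosen h² and genetic
correlation, gene/feature annotation, eQTL tables and redundant pathway
databases — so the entire pipeline is exercisable, with known truth, on a
desk. Restricted cohort data is never required.

## Worked example

`examples/` contains one short script per capability. The capstone,
`examples/06_end_to_end_overlap.py`, simulates three traits whose causal
genes are disjoint but sit in shared pathways, then runs the whole pipeline:

```
$ python examples/06_end_to_end_overlap.py
genomic inflation per trait: {'verbal_em': 1.08, 'visual_em': 1.16, 'working_mem': 0.91}
lead SNPs per trait: {'verbal_em': 41, 'visual_em': 39, 'working_mem': 39}
candidate genes per trait: {'verbal_em': ['G0009', 'G0028', 'G0000'],
                            'visual_em': ['G0018', 'G0029', 'G0004'],
                            'working_mem': ['G0012', 'G0024', 'G0010']}

gene-level overlap (counts; zero off-diagonal = no shared genes):
             verbal_em  visual_em  working_mem
verbal_em            3          0            0
visual_em            0          3            0
working_mem          0          0            3

Jaccard permutation test (random same-size gene lists):
  verbal_em vs visual_em: observed Jaccard 1.00, 100.0th percentile of 5000 permutations
  verbal_em vs working_mem: observed Jaccard 1.00, 100.0th percentile of 5000 permutations
  visual_em vs working_mem: observed Jaccard 1.00, 100.0th percentile of 5000 permutations
```

Read: the three scans share **zero** candidate genes (the off-diagonal of the
count matrix), yet their pathway sets coincide, and that coincidence sits at
the top of the permutation null — the shared biology is recovered at the
pathway level only. That inversion is the package's core claim, demonstrated
end-to-end on data where it is true by construction.

Smaller examples cover cohort simulation (01), QC + REML + MLMA-LOCO (02),
genetic and effect-size correlation (03), variant→gene mapping (04), and
pathway networks with redundancy grouping and TSV/SIF/GraphML export (05).

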