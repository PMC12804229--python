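"""The full pipeline on a three-trait study with shared pathway biology.

Three traits are simulated so their causal genes are disjoint (no gene-level
overlap is possible) but drawn from the same pathways. The pipeline — QC,
MLMA-LOCO, lead selection, LD expansion, gene mapping, pathway harvest —
recovers exactly that structure: zero shared genes, yet pathway-level
Jaccard overlap far above the permutation null of random same-size gene
lists. This is the study design the package exists for: biology invisible at
the variant and gene level becomes visible at the pathway level.
"""

from pathgwas.scenario import run_shared_pathway_scenario

res = run_shared_pathway_scenario(seed=7)

print("genomic inflation per trait:",
      {t: round(l, 2) for t, l in res.lambdas.items()})
print("lead SNPs per trait:", {t: len(v) for t, v in res.leads.items()})
print("candidate genes per trait:",
      {t: v.genes for t, v in res.gene_lists.items()})

print("\ngene-level overlap (counts; zero off-diagonal = no shared genes):")
print(res.overlap.gene_counts.to_string())
print("\npathway-level overlap (% of row's pathways shared with column):")
print(res.overlap.pathway_pct.round(1).to_string())

print("\nJaccard permutation test (random same-size gene lists):")
for (a, b), perm in res.permutations.items():
    print(f"  {a} vs {b}: observed Jaccard {perm.observed_jaccard:.2f}, "
          f"{perm.percentile:.1f}th percentile of {perm.n_perm} permutations")
print("\npercentiles above 95 mean the pathway convergence across traits is "
      "far beyond what same-size random gene lists produce")
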