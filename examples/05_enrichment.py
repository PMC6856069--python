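"""Hypergeometric over-representation of gene sets in common-state genes.

Genes of commonly hypomethylated promoter probes are tested against a
gene-set collection; sets seeded from exactly those genes should dominate,
random sets should not.
"""

import methtopo as mt

study = mt.simulate_study(seed=7)
result = mt.run_pipeline(study, mt.PipelineConfig(seed=7))

query = mt.probes_to_genes(result.common_sets["hypo"], result.universe,
                           region="promoter")
print(f"query: {len(query)} genes from commonly hypomethylated promoters")

res = mt.ora(query, study.gene_sets, result.universe.gene_universe())
print(res.head(6)[["set_id", "k", "K", "n", "N", "p", "q"]].to_string(index=False))

# p = P(X >= k) with X ~ Hypergeom(N, K, n): the chance of drawing at least
# k set members in n query genes from a universe of N.  The PLANTED_* sets
# should top the list at tiny q; RANDOM_* sets should hover near q ~ 1.
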