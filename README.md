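# methtopo

Functional and topographic analysis of DNA methylation states on
Illumina-style arrays (450K/EPIC), built for studies of the CpG island
methylator phenotype of *IDH1/2*-mutant cancers — where the question is not
just *how much* the genome is hyper-methylated, but *where*: which
functional elements (promoters, gene bodies, enhancers), which chromosome
arms, and which cytobands are affected, and which stay untouched.

The package is a library first (everything under `methtopo.*`, short
narrative scripts under `examples/`), with a thin `methtopo` CLI for running
the pipeline from a shell.

## The model

Per-probe methylation is expressed as a beta value β ∈ [0, 1] (fraction
methylated signal) or its logit, the M-value

    M = log2(β / (1 − β)),        β = 2^M / (1 + 2^M)

Statistics run on the M scale. A probe is called **hypermethylated** in a
tumor group when its group-mean M ≥ +2 (β ≥ 0.8) and **hypomethylated**
when mean M ≤ −2 (β ≤ 0.2). From per-group state calls the pipeline
computes:

* **common probes** — in the state in *every* group (set intersection) —
  and **tumor-specific probes** — in the state in exactly one group (set
  difference against the union of the rest), summarized in a specificity
  table (totals, uniques, percent unique, per-state averages) and Venn
  membership-pattern counts;
* **functional partition** — each probe may be annotated to promoter
  (within 200 bp of a TSS), gene body, and/or enhancer; a probe in *k*
  regions counts in each of the *k* region lists;
* **arm ratios** — per chromosome arm, region and state:
  (common state probes of the region on the arm) / (all region probes on
  the arm), with acrocentric short arms (13p/14p/15p/21p/22p on a human
  genome) excluded; region orderings are compared by paired t-tests with
  arms as pairing units, and each arm is compared to the genome-wide ratio
  by Welch tests on bootstrap replicates of probes;
* **desert bands** — cytobands with adequate probe coverage (≥ 50
  region-annotated probes by default) but zero common hyper- *or*
  hypomethylated probes in any of the three regions;
* **differential methylation** — per-probe Welch (unequal-variance) t-test
  between two groups with Benjamini–Hochberg FDR (significant: q < 0.05),
  top-K selection (default 10,000) and deterministic hierarchical
  clustering orders for heatmaps;
* **over-representation** — upper-tail hypergeometric test
  p = P(X ≥ k), X ~ Hypergeom(N, K, n), of common-state gene lists against
  GMT gene-set collections, universe = all genes on the harmonized
  manifest.

Preprocessing follows array practice: samples kept when mean detection
p < 0.01, sex-chromosome probes removed, the analysis universe is the
intersection of the per-platform manifests, beta values are quantile
normalized across samples, then converted to M.

A first-class synthetic generator (`methtopo.synthetic`) builds a genome,
manifest, sample sheet, and beta/detection-p matrices with planted effects
(gene-body/enhancer +3 ΔM, promoter −3 ΔM on affected probes, an enriched
arm, inert desert bands, group-private effects) plus a machine-readable
truth record, so the whole pipeline runs and is validated without any
external download.

## Worked example

```
python examples/01_full_pipeline.py
```

prints (seed 7):

```
samples kept after detection-p QC: 46 (dropped ['tumor4_s03', 'tumor5_s03'])
harmonized analysis universe: 14289 probes
common hypermethylated probes: 5503
common hypomethylated probes:  4151

genome-wide common-state ratios (state probes / all region probes):
  promoter   hyper 0.112   hypo 0.592
  gene_body  hyper 0.547   hypo 0.157
  enhancer   hyper 0.461   hypo 0.212

desert bands (covered but untouched by common methylation changes):
  chr2 q3  (127 annotated probes)
  chr4 q4  (137 annotated probes)
  chr6 p2  (137 annotated probes)
```

Reading the numbers: the two samples with elevated detection p-values fail
QC; the universe is the two-platform probe intersection minus chrX; and the
planted biology is recovered — promoters are dominated by common
hypomethylation (ratio 0.59 vs 0.16/0.21 for bodies/enhancers), gene bodies
and enhancers by common hypermethylation (0.55/0.46 vs 0.11 for promoters),
and the three cytobands the generator left inert are exactly the ones
flagged as deserts. The other examples walk through state calling, set
algebra, arm topography, and ORA individually.

The same run from a shell:

```
methtopo simulate --seed 7 --out study/
methtopo run-all study/ --out reports/ --seed 7
```

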