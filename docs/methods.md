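# Methods

## Scales, cutoffs, and state calling

All statistics run on M-values, M = log2(β/(1−β)); β is clamped to
[ε, 1−ε] (ε = 1e−6, `convert.epsilon` in the config) before the logit so
fully (un)methylated probes stay finite. The conversion pair is strictly
monotone and mutually inverse away from the clamp, and the state cutoffs
are the exact correspondences M = +2 ⇔ β = 0.8 and M = −2 ⇔ β = 0.2.
Cutoff boundaries are inclusive (mean M ≥ +2 is hyper, ≤ −2 is hypo); the
three states partition the probes, and negating M swaps hyper and hypo
exactly.

Two state-calling paths exist and are deliberately kept separate: for
multi-group common/unique analysis, states are called on **all** universe
probes per group; for a two-group differential comparison, states are
called on the FDR-significant subset only (the subset a heatmap/bar-plot
figure would draw from).

## Preprocessing order and choices

QC → sex-probe removal → platform harmonization → quantile normalization →
M conversion. Samples are kept when mean detection p is *strictly* below
0.01. Harmonization intersects the per-platform probe-id sets and orders
the universe by genomic position; normalization therefore runs on a
complete (NaN-free) matrix. Whether to normalize before or after
harmonization is genuinely open; normalizing after keeps the quantile pool
identical across platforms and is what this package does.

Quantile normalization maps every sample onto the mean order-statistic
vector; ties within a column share the mean of the quantile slots they
occupy, which makes the operation idempotent. Probe-chemistry-stratified
normalization (type I vs type II) is available via a `stratify` column when
the manifest carries one; the default is unstratified, since the harmonized
universe schema does not require chemistry types. Intensity-level
background adjustment is out of scope for beta-level inputs.

## Differential methylation

Per-probe two-sided Welch t-test (unequal variances, Welch–Satterthwaite
degrees of freedom) with Benjamini–Hochberg step-up FDR
(config-switchable); significant means q < 0.05 strictly. Probes with zero
variance in both groups get t = 0, p = 1 when means agree, p = 0 otherwise,
and are flagged `degenerate` rather than propagating NaNs. Top-K selection
(default K = 10,000) orders by ascending q, ties broken by larger |ΔM|,
then probe id — fully deterministic. Heatmap leaf orders come from
agglomerative clustering with Euclidean distance and complete linkage
(distance/linkage are conventions, declared in config, not inferences).

## Set algebra and the specificity table

"Common" is the intersection over **all** groups present (a `min_groups`
relaxation exists but defaults to all); "unique" is one group's set minus
the union of the others'. Venn pattern counts are exact tallies over all
2^k − 1 nonempty membership patterns, guarded to k ≤ 7 groups. Percent
unique is computed in exact rational arithmetic and rounded **half-up** to
one decimal; the per-state average rows take the mean of totals (rounded
half-up to an integer), the exact mean of uniques, and the rounded mean of
the per-group rounded percents. Half-up (not banker's) rounding is the
convention that reproduces published tables of this kind digit-for-digit.

## Topography

Arm assignment: a probe is on the p arm when its position precedes the
centromere gap, q when it follows; positions inside the gap get no arm.
Cytobands are half-open [start, end) intervals validated to tile each
chromosome. The arm ratio for (arm, region, state) is
common-state-probes-in-region-on-arm / all-region-probes-on-arm, autosomes
only; probes in several regions count in each. The human acrocentric short
arms (13p, 14p, 15p, 21p, 22p) are excluded by default (configurable);
excluded arms keep their counts so that arm numerators always sum to the
genome-wide numerator.

Region orderings are tested by two-sided paired t-tests with chromosome
arms as pairing units; a constant difference vector (undefined variance)
is flagged degenerate with p = NaN rather than fabricating a value. The
arm-vs-genome comparison needs replicate structure that plain counts lack;
replicates are built by bootstrap-resampling probes within the arm and
genome-wide (B = 200 by default, seeded) and comparing replicate ratio
vectors by Welch tests, BH-adjusted across arms per region/state. This
bootstrap construction is artifact-defined and configurable.

A cytoband is a **desert** iff it carries at least `min_probes`
(default 50) region-annotated probes and zero common hyper- and zero
common hypomethylated probes across all three regions. The coverage guard
prevents probe-free bands from masquerading as biology; raising
`min_probes` can only remove desert flags (monotone).

Track export writes one bedGraph per region × state with the cross-group
mean M clipped sign-preserving to ±[1.9, 7] — a display convention for
karyogram-style plots; analysis always uses unclipped M. All exported
intervals are 0-based half-open; text inputs are read as 1-based inclusive
(Illumina/UCSC-text style) and converted once on ingestion.

## Over-representation

Upper-tail hypergeometric p = P(X ≥ k), X ~ Hypergeom(N, K, n), BH across
sets. The universe is all genes on the harmonized manifest (not the union
of the collection), chosen so that array coverage — not database breadth —
defines the sampling frame; both the universe and the multiple-testing
method are package-defined conventions. Queries are deduplicated gene
lists of common-state probes, optionally restricted to one functional
region; query genes outside the universe are dropped with a logged count.

## The synthetic generator

The generator emulates a six-tumor-type array study: ~20,000 probes on a
nine-chromosome genome (eight autosomes, one acrocentric with no short-arm
probe capacity, plus chrX to exercise sex-probe removal), two platforms
with 80% probe overlap, six groups of eight samples, and a small fraction
of samples with elevated detection p to exercise QC.

Baseline betas come from a three-mode mixture — unmethylated (β ≈ 0.1,
M ≈ −3.17), intermediate (β = 0.5, M = 0), methylated (β ≈ 0.85,
M ≈ +2.50) — with region-specific mode weights: promoters mostly
unmethylated, gene bodies and enhancers tilted toward the methylated mode.
Effects are planted on the M scale, where the cutoffs live, making
cutoff-crossing analytically controllable: an affected fraction (0.3) of
intermediate-mode probes per region receives ΔM = +3 (gene body,
enhancer) or −3 (promoter) in every mutant group; one arm's affected
fraction is multiplied (chr5p × 2.5) as planted enrichment; a further
fraction of intermediate probes receives a single-group-only ±3 shift, the
source of tumor-specific (unique) probes; designated desert bands are
pinned to the intermediate mode with no effects, so their probes can never
cross ±2. Gaussian noise (sd 0.5 M-units) is added per sample and values
are mapped back to beta. With 8 samples per group the group-mean standard
error is ≈ 0.18 M-units, so every planted expected mean sits ≥ 2.8 SEs
from the nearest cutoff — recovery is demanding but not knife-edge.

The truth record stores, per probe and group, the expected noise-free mean
M and the state it implies; "planted common hyper/hypo" means all mutant
groups' expected states agree. What passing recovery tests show is that
the pipeline inverts this generative model at realistic noise; what they
do **not** show is robustness to features real arrays have and the
generator omits: probe-chemistry (type I/II) intensity differences,
dye/batch effects, cell-type admixture, spatially correlated probes, and
non-Gaussian heavy-tailed noise.

## Problem sizes and determinism

Default desk scale: 20,000 probes × 48 samples generates in under a
second and the full pipeline runs in a few seconds; bootstrap B = 200.
Every stochastic step flows from a single integer seed
(`numpy.random.default_rng`), and a rerun with identical inputs and config
is byte-identical, including all written report files.

## Known limitations

* The published genome-scale counts of real cohorts (universe sizes,
  common-probe totals) depend on real manifests and cohorts and are not
  reproduced here; table arithmetic and planted-truth recovery are.
* Beta-level inputs only: no IDAT parsing, no intensity-level
  normalization, no liftover.
* The arm-vs-genome bootstrap treats probes as exchangeable within arm;
  spatial autocorrelation of methylation would widen true replicate
  variance.
* ORA ignores gene-length/probe-density bias and GO-style set redundancy.
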