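"""Synthetic array-study generator with planted functional/topographic truth.

The generator emulates the structure of a multi-tumor methylation-array
study: a small genome with centromere gaps and tiling cytobands, a probe
manifest on two partially overlapping platforms, and per-group beta matrices
in which the known biology is planted —

* baseline betas drawn from a three-mode mixture (unmethylated ~0.1,
  intermediate ~0.5, methylated ~0.85), with promoters biased toward the
  unmethylated mode and gene bodies/enhancers toward the methylated mode;
* additive M-scale shifts for "mutant" groups on an affected fraction of
  intermediate-mode probes (gene body +3, enhancer +3, promoter -3);
* arm-specific multipliers on the affected fraction (planted enrichment);
* designated "desert" cytobands whose probes are pinned to the intermediate
  mode and receive no effects, so they never cross the +/-2 state cutoffs;
* Gaussian noise on the M scale, converted back to beta for output.

Every random draw flows from one seed, so outputs are bit-reproducible.  A
truth record stores the expected (noise-free) mean M and the implied
hyper/hypo/neither state per probe and group, the basis for
parameter-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    PLATFORMS,
    REGIONS,
    GenomeTable,
    MethtopoError,
    MethylationMatrix,
    ProbeManifest,
    SampleSheet,
)
from .preprocess import beta_to_m, m_to_beta
from . import io as mio

_MB = 1_000_000


@dataclass(frozen=True)
class ChromPlan:
    """One synthetic chromosome: length, centromere gap, acrocentric flag.

    Acrocentric chromosomes get no probe capacity on the short arm, like the
    human acrocentrics on real arrays.
    """

    name: str
    length: int
    cen_start: int  # 0-based half-open gap interval
    cen_end: int
    acrocentric: bool = False


def _default_chromosomes() -> tuple[ChromPlan, ...]:
    def mid_cen(name: str, length_mb: int) -> ChromPlan:
        c = length_mb * _MB // 2
        return ChromPlan(name, length_mb * _MB, c - 2_500_000, c + 2_500_000)

    return (
        mid_cen("chr1", 150),
        mid_cen("chr2", 130),
        mid_cen("chr3", 110),
        mid_cen("chr4", 100),
        mid_cen("chr5", 90),
        mid_cen("chr6", 80),
        mid_cen("chr7", 70),
        ChromPlan("chr8", 60 * _MB, 2_500_000, 7_500_000, acrocentric=True),
        mid_cen("chrX", 100),
    )


@dataclass
class TruthSpec:
    """Full parameterization of a synthetic study; the seed lives outside."""

    chromosomes: tuple[ChromPlan, ...] = field(default_factory=_default_chromosomes)
    band_size: int = 8 * _MB
    #: (chrom, band name) pairs forced effect-free at the intermediate mode.
    desert_bands: tuple[tuple[str, str], ...] = (
        ("chr2", "q3"),
        ("chr4", "q4"),
        ("chr6", "p2"),
    )
    n_probes: int = 20_000
    groups: tuple[str, ...] = tuple(f"tumor{i}" for i in range(1, 7))
    #: groups carrying planted effects; defaults to all groups.
    mutant_groups: tuple[str, ...] | None = None
    samples_per_group: int = 8
    noise_sd: float = 0.5
    platform_overlap: float = 0.8
    #: probability of each primary region assignment (must sum to 1).
    region_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "promoter": 0.22, "gene_body": 0.40, "enhancer": 0.22, "none": 0.16
        }
    )
    #: chance that a region-bearing probe carries one extra region.
    region_overlap_p: float = 0.10
    #: beta values of the unmethylated / intermediate / methylated modes.
    mode_betas: tuple[float, float, float] = (0.10, 0.50, 0.85)
    #: per primary region, probabilities of the three baseline modes.
    mode_probs: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "promoter": (0.55, 0.40, 0.05),
            "gene_body": (0.15, 0.40, 0.45),
            "enhancer": (0.20, 0.45, 0.35),
            "none": (0.30, 0.40, 0.30),
        }
    )
    #: planted M-scale shift per primary region (mutant groups only).
    effects: Mapping[str, float] = field(
        default_factory=lambda: {"promoter": -3.0, "gene_body": 3.0, "enhancer": 3.0}
    )
    #: fraction of intermediate-mode probes of each region that are affected.
    affected_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"promoter": 0.3, "gene_body": 0.3, "enhancer": 0.3}
    )
    #: arm label -> multiplier on the affected fraction (planted enrichment).
    arm_multipliers: Mapping[str, float] = field(default_factory=lambda: {"chr5p": 2.5})
    #: fraction of intermediate-mode probes given a one-group-only effect
    #: (random +/- max effect), the source of tumor-specific probes.
    private_fraction: float = 0.25
    qc_fail_fraction: float = 0.04
    gene_bin_bp: int = 200_000
    hyper_min: float = 2.0
    hypo_max: float = -2.0

    def __post_init__(self) -> None:
        if abs(sum(self.region_probs.values()) - 1) > 1e-9:
            raise MethtopoError("region_probs must sum to 1")
        for frac in self.affected_fraction.values():
            if not 0 <= frac <= 1:
                raise MethtopoError("affected fractions must lie in [0, 1]")
        if self.mutant_groups is None:
            self.mutant_groups = self.groups


def two_group_spec(samples_per_group: int = 10, **overrides) -> TruthSpec:
    """A mutant-vs-wildtype design for differential-testing studies."""
    return TruthSpec(
        groups=("mutant", "wildtype"),
        mutant_groups=("mutant",),
        samples_per_group=samples_per_group,
        **overrides,
    )


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


def make_genome(spec: TruthSpec) -> GenomeTable:
    """Build the genome table: centromere gaps and tiling cytobands.

    Arms are split into ~band_size bands named p1, p2, ... / q1, q2, ...
    outward from the telomere; the centromere is covered by two ``acen``
    bands.  Stains cycle through light/dark values, with designated desert
    bands forced to ``gpos100`` (the dark-band look of the real ones).
    """
    cen_rows, band_rows = [], []
    stains = ("gneg", "gpos50", "gneg", "gpos100")
    desert = set(spec.desert_bands)
    for chrom in spec.chromosomes:
        cen_rows.append((chrom.name, chrom.cen_start, chrom.cen_end))

        def tile(start: int, end: int, prefix: str) -> None:
            edges = list(range(start, end, spec.band_size)) + [end]
            if edges[-2] == edges[-1]:
                edges.pop()
            for i, (s, e) in enumerate(zip(edges[:-1], edges[1:]), start=1):
                name = f"{prefix}{i}"
                stain = (
                    "gpos100" if (chrom.name, name) in desert else stains[i % len(stains)]
                )
                band_rows.append((chrom.name, s, e, name, stain))

        tile(0, chrom.cen_start, "p")
        mid = (chrom.cen_start + chrom.cen_end) // 2
        band_rows.append((chrom.name, chrom.cen_start, mid, "p_cen", "acen"))
        band_rows.append((chrom.name, mid, chrom.cen_end, "q_cen", "acen"))
        tile(chrom.cen_end, chrom.length, "q")
    genome = GenomeTable(
        {c.name: c.length for c in spec.chromosomes},
        pd.DataFrame(cen_rows, columns=["chrom", "start", "end"]),
        pd.DataFrame(band_rows, columns=["chrom", "start", "end", "name", "stain"]),
    )
    known = {(r.chrom, r.name) for r in genome.cytobands.itertuples(index=False)}
    missing = desert - known
    if missing:
        raise MethtopoError(f"desert bands not present in genome: {sorted(missing)}")
    return genome


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------


def make_manifest(
    genome: GenomeTable, spec: TruthSpec, rng: np.random.Generator
) -> tuple[ProbeManifest, pd.DataFrame]:
    """Place probes and draw annotations; returns (manifest, truth skeleton).

    Probes are uniform over the placeable genome (outside centromere gaps,
    and outside acrocentric short arms).  The truth skeleton records primary
    region, arm, band, and desert membership per probe.
    """
    segments = []  # (chrom, seg_start, seg_len)
    for chrom in spec.chromosomes:
        if not chrom.acrocentric:
            segments.append((chrom.name, 0, chrom.cen_start))
        segments.append((chrom.name, chrom.cen_end, chrom.length - chrom.cen_end))
    seg_lens = np.array([s[2] for s in segments], dtype=float)
    counts = rng.multinomial(spec.n_probes, seg_lens / seg_lens.sum())

    chroms, pos0 = [], []
    for (name, start, length), k in zip(segments, counts):
        chroms.extend([name] * k)
        pos0.extend(start + np.sort(rng.integers(0, length, size=k)))
    # canonical genome order, then position
    chrom_rank = {c: i for i, c in enumerate(genome.chromosomes)}
    order = np.lexsort((np.array(pos0), np.array([chrom_rank[c] for c in chroms])))
    chroms = np.array(chroms, dtype=object)[order]
    pos0 = np.array(pos0, dtype=np.int64)[order]
    n = len(pos0)
    probe_ids = pd.Index([f"cg{i:08d}" for i in range(1, n + 1)], name="probe_id")

    region_labels = list(spec.region_probs)
    primary = rng.choice(
        region_labels, size=n, p=[spec.region_probs[r] for r in region_labels]
    )
    flags = {r: primary == r for r in REGIONS}
    extra = rng.random(n) < spec.region_overlap_p
    for i in np.flatnonzero(extra & (primary != "none")):
        others = [r for r in REGIONS if r != primary[i]]
        flags[others[rng.integers(0, len(others))]][i] = True

    platform_draw = rng.random(n)
    both = platform_draw < spec.platform_overlap
    only_first = platform_draw < spec.platform_overlap + (1 - spec.platform_overlap) / 2

    genes: list[tuple[str, ...]] = []
    for i in range(n):
        if primary[i] == "none" and not any(flags[r][i] for r in REGIONS):
            genes.append(())
        else:
            genes.append((f"G{chroms[i]}B{pos0[i] // spec.gene_bin_bp}",))

    df = pd.DataFrame(
        {
            "chromosome": chroms,
            "position": pos0 + 1,
            "strand": rng.choice(["+", "-"], size=n),
            **{r: flags[r] for r in REGIONS},
            "genes": genes,
            PLATFORMS[0]: both | only_first,
            PLATFORMS[1]: both | ~only_first,
        },
        index=probe_ids,
    )
    manifest = ProbeManifest(df)

    ann = manifest.annotate(genome)
    desert = set(spec.desert_bands)
    truth = pd.DataFrame(
        {
            "chromosome": ann["chromosome"],
            "position": ann["position"],
            "primary_region": primary,
            "arm": ann["arm"],
            "band": ann["band"],
            "desert": [
                (c, b) in desert for c, b in zip(ann["chromosome"], ann["band"])
            ],
        },
        index=probe_ids,
    )
    return manifest, truth


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------


def simulate_matrices(
    manifest: ProbeManifest,
    truth_skeleton: pd.DataFrame,
    spec: TruthSpec,
    rng: np.random.Generator,
) -> tuple[MethylationMatrix, pd.DataFrame, SampleSheet, pd.DataFrame]:
    """Draw beta and detection-p matrices; complete the truth record.

    Returns ``(beta_matrix, detection_p, sheet, truth)``.  Off-platform
    entries are NaN.  The truth frame gains ``base_m``, ``affected``,
    ``delta_m``, and per-group ``mu_<group>`` / ``state_<group>`` columns
    (state from the expected mean and the +/-2 cutoffs).
    """
    n = len(manifest)
    truth = truth_skeleton.copy()
    mode_m = beta_to_m(np.asarray(spec.mode_betas))

    mode_idx = np.empty(n, dtype=int)
    for region, probs in spec.mode_probs.items():
        mask = (truth["primary_region"] == region).to_numpy()
        mode_idx[mask] = rng.choice(3, size=int(mask.sum()), p=np.asarray(probs) / sum(probs))
    desert = truth["desert"].to_numpy()
    mode_idx[desert] = 1  # deserts pinned to the intermediate mode
    base_m = mode_m[mode_idx]

    affected = np.zeros(n, dtype=bool)
    delta = np.zeros(n)
    eligible = (mode_idx == 1) & ~desert
    for region, eff in spec.effects.items():
        mask = eligible & (truth["primary_region"] == region).to_numpy()
        frac = spec.affected_fraction.get(region, 0.0)
        mult = truth["arm"].map(lambda a: spec.arm_multipliers.get(a, 1.0)).to_numpy()
        p_aff = np.minimum(frac * mult, 0.95)
        hit = mask & (rng.random(n) < p_aff)
        affected |= hit
        delta[hit] = eff

    # one-group-only effects: the planted source of tumor-specific probes
    private_group = np.full(n, "", dtype=object)
    private_delta = np.zeros(n)
    if spec.private_fraction > 0 and len(spec.mutant_groups):
        candidates = eligible & ~affected
        hit = candidates & (rng.random(n) < spec.private_fraction)
        idx = np.flatnonzero(hit)
        private_group[idx] = rng.choice(np.asarray(spec.mutant_groups, dtype=object),
                                        size=len(idx))
        magnitude = max(abs(e) for e in spec.effects.values())
        private_delta[idx] = rng.choice([-magnitude, magnitude], size=len(idx))

    truth["base_m"] = base_m
    truth["affected"] = affected
    truth["delta_m"] = delta
    truth["private_group"] = private_group
    truth["private_delta_m"] = private_delta

    sample_rows, columns = [], []
    values = np.empty((n, len(spec.groups) * spec.samples_per_group))
    col = 0
    platform_mask = {p: manifest.df[p].to_numpy() for p in PLATFORMS}
    for group in spec.groups:
        mutant = group in spec.mutant_groups
        mu = base_m + (delta if mutant else 0.0) + np.where(
            private_group == group, private_delta, 0.0
        )
        truth[f"mu_{group}"] = mu
        truth[f"state_{group}"] = np.where(
            mu >= spec.hyper_min, "hyper", np.where(mu <= spec.hypo_max, "hypo", "neither")
        )
        for i in range(spec.samples_per_group):
            sample_id = f"{group}_s{i + 1:02d}"
            platform = PLATFORMS[i % 2]
            sample_rows.append((sample_id, group, platform))
            columns.append(sample_id)
            vals = m_to_beta(mu + rng.normal(0.0, spec.noise_sd, size=n))
            vals[~platform_mask[platform]] = np.nan
            values[:, col] = vals
            col += 1

    sheet = SampleSheet(
        pd.DataFrame(sample_rows, columns=["sample_id", "group", "platform"]).set_index(
            "sample_id"
        )
    )
    beta = MethylationMatrix(
        pd.DataFrame(values, index=manifest.probe_ids, columns=columns), scale="beta"
    )

    n_samples = len(columns)
    n_fail = int(round(spec.qc_fail_fraction * n_samples))
    fail_cols = rng.choice(n_samples, size=n_fail, replace=False) if n_fail else []
    detection = rng.uniform(0.0, 0.005, size=(n, n_samples))
    for j in fail_cols:
        detection[:, j] = rng.uniform(0.2, 0.6, size=n)
    detection_p = pd.DataFrame(detection, index=manifest.probe_ids, columns=columns)
    return beta, detection_p, sheet, truth


# ---------------------------------------------------------------------------
# Gene sets and the assembled study
# ---------------------------------------------------------------------------


def make_gene_sets(
    manifest: ProbeManifest,
    truth: pd.DataFrame,
    spec: TruthSpec,
    rng: np.random.Generator,
    n_random: int = 15,
    n_planted: int = 3,
) -> dict[str, tuple[str, frozenset[str]]]:
    """Random gene sets plus sets seeded from commonly hypomethylated promoters."""
    universe = manifest.gene_universe()
    state_cols = [f"state_{g}" for g in spec.mutant_groups]
    common_hypo = (truth[state_cols] == "hypo").all(axis=1)
    promoter_hypo_genes = sorted(
        {
            g
            for probe in truth.index[common_hypo & manifest.df["promoter"]]
            for g in manifest.df.loc[probe, "genes"]
        }
    )
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for i in range(n_planted):
        size = min(40, len(promoter_hypo_genes))
        members = rng.choice(promoter_hypo_genes, size=size, replace=False)
        sets[f"PLANTED_{i + 1}"] = (
            f"planted promoter-hypomethylation set {i + 1}",
            frozenset(members),
        )
    for i in range(n_random):
        size = int(rng.integers(10, 51))
        members = rng.choice(universe, size=size, replace=False)
        sets[f"RANDOM_{i + 1:02d}"] = (f"random set {i + 1}", frozenset(members))
    return sets


@dataclass
class SyntheticStudy:
    """Everything one run of the generator produced, plus its truth record."""

    spec: TruthSpec
    genome: GenomeTable
    manifest: ProbeManifest
    sheet: SampleSheet
    beta: MethylationMatrix
    detection_p: pd.DataFrame
    truth: pd.DataFrame
    gene_sets: dict[str, tuple[str, frozenset[str]]]

    def truth_common_probes(self, state: str, universe=None) -> frozenset[str]:
        """Probes planted in ``state`` in every mutant group (optionally
        restricted to a probe universe)."""
        cols = [f"state_{g}" for g in self.spec.mutant_groups]
        mask = (self.truth[cols] == state).all(axis=1)
        ids = frozenset(self.truth.index[mask])
        return ids if universe is None else ids & frozenset(universe)


def simulate_study(spec: TruthSpec | None = None, seed: int = 0) -> SyntheticStudy:
    """Generate a complete synthetic study from one seed."""
    spec = spec or TruthSpec()
    rng = np.random.default_rng(seed)
    genome = make_genome(spec)
    manifest, skeleton = make_manifest(genome, spec, rng)
    beta, detection_p, sheet, truth = simulate_matrices(manifest, skeleton, spec, rng)
    gene_sets = make_gene_sets(manifest, truth, spec, rng)
    return SyntheticStudy(spec, genome, manifest, sheet, beta, detection_p, truth, gene_sets)


def write_study(study: SyntheticStudy, directory: str | Path) -> dict[str, Path]:
    """Write the study in the same text formats the readers consume."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = mio.write_genome(study.genome, directory / "genome")
    paths["manifest"] = directory / "manifest.tsv"
    mio.write_manifest(study.manifest, paths["manifest"])
    paths["beta"] = directory / "beta.tsv"
    mio.write_matrix(study.beta, paths["beta"])
    paths["detection_p"] = directory / "detection_p.tsv"
    study.detection_p.to_csv(paths["detection_p"], sep="\t", index_label="probe_id",
                             float_format="%.6g")
    paths["sample_sheet"] = directory / "sample_sheet.tsv"
    mio.write_sample_sheet(study.sheet, paths["sample_sheet"])
    paths["truth"] = directory / "truth.tsv"
    study.truth.to_csv(paths["truth"], sep="\t", index_label="probe_id")
    paths["gene_sets"] = directory / "gene_sets.gmt"
    mio.write_gmt(study.gene_sets, paths["gene_sets"])
    return paths
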