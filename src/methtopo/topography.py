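"""Topography of common methylation states: arm ratios, deserts, tracks.

The central quantity is the coverage-normalized arm ratio

    ratio(arm, region, state) =
        |common state probes annotated to region on arm| /
        |all region probes on arm|

computed over autosomes, with the acrocentric short arms (13p, 14p, 15p,
21p, 22p on a human genome) excluded.  "Desert" cytobands are bands with
adequate probe coverage but zero common hyper- or hypomethylated probes in
any functional region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    ACROCENTRIC_P_ARMS,
    REGIONS,
    SEX_CHROMOSOMES,
    GenomeTable,
    MethtopoError,
    ProbeManifest,
)
from .diffmeth import bh_fdr
from . import io as mio

log = logging.getLogger(__name__)

CommonSets = Mapping[str, frozenset[str]]  # state -> probe ids


def _autosomal_annotated(manifest: ProbeManifest, genome: GenomeTable) -> pd.DataFrame:
    ann = manifest.annotate(genome)
    ann = ann[~ann["chromosome"].isin(SEX_CHROMOSOMES)]
    return ann[ann["arm"].notna()]  # centromeric-gap probes have no arm


# ---------------------------------------------------------------------------
# Arm ratios
# ---------------------------------------------------------------------------


def arm_ratios(
    common_sets: CommonSets,
    manifest: ProbeManifest,
    genome: GenomeTable,
    excluded_arms: Sequence[str] = ACROCENTRIC_P_ARMS,
) -> pd.DataFrame:
    """Per (arm × region × state) numerator/denominator/ratio records.

    Multi-region probes contribute to every region they carry.  Excluded
    (acrocentric) arms keep their counts but carry no ratio; a zero
    denominator on a non-excluded arm yields an undefined ratio with a
    warning.
    """
    ann = _autosomal_annotated(manifest, genome)
    autosomes = [c for c in genome.chromosomes if c not in SEX_CHROMOSOMES]
    rows = []
    empty: list[str] = []
    for arm in genome.arms(autosomes):
        on_arm = ann[ann["arm"] == arm]
        excluded = arm in excluded_arms
        for region in REGIONS:
            region_probes = on_arm.index[on_arm[region]]
            denom = len(region_probes)
            for state in ("hyper", "hypo"):
                num = len(common_sets[state] & set(region_probes))
                if excluded or denom == 0:
                    ratio = np.nan
                    if not excluded and denom == 0:
                        empty.append(f"{arm}/{region}")
                else:
                    ratio = num / denom
                rows.append((arm, region, state, num, denom, ratio, excluded))
    if empty:
        log.warning(
            "undefined ratios (no probes) on non-excluded arms: %s",
            ", ".join(sorted(set(empty))),
        )
    return pd.DataFrame(
        rows,
        columns=["arm", "region", "state", "numerator", "denominator", "ratio", "excluded"],
    )


def genomewide_region_ratios(
    common_sets: CommonSets,
    manifest: ProbeManifest,
    genome: GenomeTable,
    excluded_arms: Sequence[str] = ACROCENTRIC_P_ARMS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genome-wide region/state ratios plus pairwise paired tests across arms.

    The pairing unit is the chromosome arm: for each state and region pair,
    the two vectors of per-arm ratios (arms where both are defined) are
    compared by a two-sided paired t-test.  A constant difference vector has
    undefined test variance and is flagged ``degenerate`` with p = NaN.
    """
    table = arm_ratios(common_sets, manifest, genome, excluded_arms)
    ann = _autosomal_annotated(manifest, genome)
    ratio_rows = []
    for region in REGIONS:
        region_probes = set(ann.index[ann[region]])
        denom = len(region_probes)
        for state in ("hyper", "hypo"):
            num = len(common_sets[state] & region_probes)
            ratio_rows.append(
                (region, state, num, denom, num / denom if denom else np.nan)
            )
    ratios = pd.DataFrame(
        ratio_rows, columns=["region", "state", "numerator", "denominator", "ratio"]
    )

    usable = table[~table["excluded"] & table["ratio"].notna()]
    pivots = {
        state: usable[usable["state"] == state].pivot(
            index="arm", columns="region", values="ratio"
        )
        for state in ("hyper", "hypo")
    }
    test_rows = []
    for state, pivot in pivots.items():
        for i, ra in enumerate(REGIONS):
            for rb in REGIONS[i + 1 :]:
                pair = pivot[[ra, rb]].dropna()
                if len(pair) < 2:
                    raise MethtopoError(
                        f"fewer than 2 paired arms for {ra} vs {rb} ({state})"
                    )
                diff = pair[ra] - pair[rb]
                if np.ptp(diff.to_numpy()) == 0:
                    test_rows.append((state, ra, rb, len(pair), np.nan, np.nan, True))
                    continue
                t, p = stats.ttest_rel(pair[ra], pair[rb])
                test_rows.append((state, ra, rb, len(pair), float(t), float(p), False))
    tests = pd.DataFrame(
        test_rows, columns=["state", "region_a", "region_b", "n_arms", "t", "p", "degenerate"]
    )
    return ratios, tests


def arm_vs_genome_test(
    common_sets: CommonSets,
    manifest: ProbeManifest,
    genome: GenomeTable,
    n_boot: int = 200,
    seed: int | None = None,
    excluded_arms: Sequence[str] = ACROCENTRIC_P_ARMS,
) -> pd.DataFrame:
    """Welch tests of each arm's ratio against the genome-wide ratio.

    The printed-style test needs replicate structure, which probe counts do
    not provide; replicates are built by bootstrap-resampling probes (B =
    ``n_boot``) within the arm and genome-wide, the ratio recomputed on each
    resample.  Per region/state, arm p-values are BH-adjusted across arms.
    Arms whose replicate ratios are constant on both sides are flagged
    ``degenerate``.
    """
    rng = np.random.default_rng(seed)
    ann = _autosomal_annotated(manifest, genome)
    rows = []
    for region in REGIONS:
        in_region = ann[ann[region]]
        for state in ("hyper", "hypo"):
            member = in_region.index.isin(common_sets[state]).astype(float)
            n_genome = len(member)
            if n_genome == 0:
                continue
            boot_idx = rng.integers(0, n_genome, size=(n_boot, n_genome))
            genome_reps = member[boot_idx].mean(axis=1)
            arm_values = in_region["arm"].to_numpy()
            for arm in genome.arms([c for c in genome.chromosomes if c not in SEX_CHROMOSOMES]):
                if arm in excluded_arms:
                    continue
                arm_member = member[arm_values == arm]
                n_arm = len(arm_member)
                if n_arm == 0:
                    continue
                idx = rng.integers(0, n_arm, size=(n_boot, n_arm))
                arm_reps = arm_member[idx].mean(axis=1)
                degenerate = np.ptp(arm_reps) == 0 and np.ptp(genome_reps) == 0
                if degenerate:
                    t, p = (0.0, 1.0) if arm_reps[0] == genome_reps[0] else (np.nan, np.nan)
                else:
                    t, p = stats.ttest_ind(arm_reps, genome_reps, equal_var=False)
                rows.append(
                    (region, state, arm, n_arm, float(arm_member.mean()),
                     float(member.mean()), float(t), float(p), bool(degenerate))
                )
    out = pd.DataFrame(
        rows,
        columns=["region", "state", "arm", "n_probes", "arm_ratio",
                 "genome_ratio", "t", "p", "degenerate"],
    )
    out["q"] = np.nan
    for (_, _), block in out.groupby(["region", "state"]):
        ok = block["p"].notna()
        out.loc[block.index[ok], "q"] = bh_fdr(block.loc[ok, "p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Desert bands
# ---------------------------------------------------------------------------


def desert_bands(
    common_sets: CommonSets,
    manifest: ProbeManifest,
    genome: GenomeTable,
    min_probes: int = 50,
) -> pd.DataFrame:
    """Flag cytobands devoid of common state probes despite good coverage.

    A band is a desert iff it has zero common hyper AND zero common hypo
    probes in all three functional regions, while carrying at least
    ``min_probes`` region-annotated probes (the coverage guard keeps
    probe-free bands from being mistaken for biology).
    """
    ann = _autosomal_annotated(manifest, genome)
    any_region = ann[list(REGIONS)].any(axis=1)
    annotated = ann[any_region]
    rows = []
    autosomal_bands = genome.cytobands[
        ~genome.cytobands["chrom"].isin(SEX_CHROMOSOMES)
    ]
    for band_row in autosomal_bands.itertuples(index=False):
        in_band = annotated[
            (annotated["chromosome"] == band_row.chrom)
            & (annotated["band"] == band_row.name)
        ]
        coverage = len(in_band)
        counts = {}
        for region in REGIONS:
            region_ids = set(in_band.index[in_band[region]])
            for state in ("hyper", "hypo"):
                counts[f"{region}_{state}"] = len(common_sets[state] & region_ids)
        desert = coverage >= min_probes and sum(counts.values()) == 0
        rows.append(
            {
                "chrom": band_row.chrom,
                "band": band_row.name,
                "start": band_row.start,
                "end": band_row.end,
                "stain": band_row.stain,
                "coverage": coverage,
                **counts,
                "desert": desert,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Track export
# ---------------------------------------------------------------------------


def track_frames(
    common_sets: CommonSets,
    mean_m: pd.Series,
    manifest: ProbeManifest,
    genome: GenomeTable,
    clip: tuple[float, float] = (1.9, 7.0),
) -> dict[str, pd.DataFrame]:
    """bedGraph record frames per (region × state) for the common probes.

    Values are the cross-group mean M-value of each probe, clipped
    sign-preserving to ``[clip[0], clip[1]]`` in magnitude (display range of
    karyogram-style plots); analysis elsewhere always uses unclipped M.
    Records are 0-based half-open single-bp intervals sorted by position.
    """
    lo, hi = clip
    unknown = set(manifest.df["chromosome"]) - set(genome.chrom_lengths)
    if unknown:
        raise MethtopoError(f"manifest chromosomes not in genome: {sorted(unknown)}")
    chrom_order = {c: i for i, c in enumerate(genome.chromosomes)}
    frames: dict[str, pd.DataFrame] = {}
    for region in REGIONS:
        region_ids = set(manifest.region_probe_ids(region))
        for state in ("hyper", "hypo"):
            ids = sorted(common_sets[state] & region_ids)
            sub = manifest.df.loc[ids]
            m = mean_m.loc[ids].to_numpy(dtype=float)
            clipped = np.sign(m) * np.clip(np.abs(m), lo, hi)
            frame = pd.DataFrame(
                {
                    "chrom": sub["chromosome"].to_numpy(),
                    "start": (sub["position"] - 1).to_numpy(),
                    "end": sub["position"].to_numpy(),
                    "value": clipped,
                }
            )
            frame = frame.sort_values(
                ["chrom", "start"],
                key=lambda s: s.map(chrom_order) if s.name == "chrom" else s,
                kind="mergesort",
            ).reset_index(drop=True)
            frames[f"{region}_{state}"] = frame
    return frames


def export_tracks(
    common_sets: CommonSets,
    mean_m: pd.Series,
    manifest: ProbeManifest,
    genome: GenomeTable,
    directory: str | Path,
    clip: tuple[float, float] = (1.9, 7.0),
    desert_report: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write one bedGraph per (region × state), plus a desert-band BED."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, frame in track_frames(common_sets, mean_m, manifest, genome, clip).items():
        path = directory / f"common_{name}.bedGraph"
        mio.write_bedgraph(frame, path)
        paths[name] = path
    if desert_report is not None:
        deserts = desert_report[desert_report["desert"]]
        bed = pd.DataFrame(
            {
                "chrom": deserts["chrom"].to_numpy(),
                "start": deserts["start"].to_numpy(),
                "end": deserts["end"].to_numpy(),
                "name": deserts["band"].to_numpy(),
            }
        )
        path = directory / "desert_bands.bed"
        mio.write_bed(bed, path)
        paths["desert_bands"] = path
    return paths
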