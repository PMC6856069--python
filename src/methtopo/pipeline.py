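"""End-to-end orchestration: config, validation, staged run, report bundle.

The pipeline is a pure function of (inputs, config): preprocess (QC ->
sex-probe drop -> platform harmonization -> quantile normalization -> M
conversion) -> state calling -> set algebra -> topography -> enrichment,
with every threshold carried in a serializable config and every stage
logged with its counts.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (
    ACROCENTRIC_P_ARMS,
    REGIONS,
    GenomeTable,
    MethtopoError,
    MethylationMatrix,
    ProbeManifest,
    SampleSheet,
)
from . import diffmeth, enrichment, preprocess, sets, topography
from . import io as mio

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a named stage fails; message starts with the stage name."""


@dataclass
class PipelineConfig:
    """All thresholds and knobs of one pipeline run; YAML round-trippable."""

    detection_p_threshold: float = 0.01
    hyper_min: float = 2.0
    hypo_max: float = -2.0
    fdr: float = 0.05
    top_k: int = 10_000
    min_probes: int = 50
    n_boot: int = 200
    clamp_epsilon: float = 1e-6
    seed: int = 0
    excluded_arms: tuple[str, ...] = ACROCENTRIC_P_ARMS
    #: optional two-group differential comparison (group_a, group_b).
    diff_groups: tuple[str, str] | None = None
    #: (region, state) queries run through ORA when gene sets are present.
    ora_queries: tuple[tuple[str, str], ...] = (("promoter", "hypo"), ("gene_body", "hyper"))
    track_clip: tuple[float, float] = (1.9, 7.0)

    def __post_init__(self) -> None:
        if not 0 < self.detection_p_threshold <= 1:
            raise MethtopoError("detection_p_threshold must be in (0, 1]")
        if self.hyper_min <= self.hypo_max:
            raise MethtopoError("hyper_min must exceed hypo_max")
        if not 0 < self.fdr < 1:
            raise MethtopoError("fdr must be in (0, 1)")
        if self.top_k <= 0 or self.min_probes < 0 or self.n_boot < 0:
            raise MethtopoError("top_k/min_probes/n_boot out of range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("excluded_arms", "diff_groups", "track_clip"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        if raw.get("ora_queries") is not None:
            raw["ora_queries"] = tuple(tuple(q) for q in raw["ora_queries"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        for key, val in data.items():
            if isinstance(val, tuple):
                data[key] = [list(v) if isinstance(v, tuple) else v for v in val]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


@dataclass
class StudyInputs:
    """The file-level inputs of a run, already parsed into domain objects."""

    manifest: ProbeManifest
    genome: GenomeTable
    sheet: SampleSheet
    beta: MethylationMatrix
    detection_p: pd.DataFrame
    gene_sets: dict[str, tuple[str, frozenset[str]]] | None = None


def load_inputs(directory: str | Path) -> StudyInputs:
    """Load a study bundle written by :func:`methtopo.synthetic.write_study`."""
    directory = Path(directory)
    genome = mio.read_genome(
        directory / "genome" / "chrom_sizes.tsv",
        directory / "genome" / "gap.tsv",
        directory / "genome" / "cytoband.tsv",
    )
    gmt = directory / "gene_sets.gmt"
    return StudyInputs(
        manifest=mio.read_manifest(directory / "manifest.tsv"),
        genome=genome,
        sheet=mio.read_sample_sheet(directory / "sample_sheet.tsv"),
        beta=mio.read_matrix(directory / "beta.tsv", scale="beta"),
        detection_p=mio.read_detection_p(directory / "detection_p.tsv"),
        gene_sets=mio.read_gmt(gmt) if gmt.exists() else None,
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_inputs(inputs: StudyInputs) -> list[str]:
    """Consistency checks across manifest/matrix/sheet/genome; returns
    violation messages (empty when clean) instead of raising."""
    violations: list[str] = []
    matrix_probes = set(inputs.beta.probe_ids)
    manifest_probes = set(inputs.manifest.probe_ids)
    missing = matrix_probes - manifest_probes
    if missing:
        violations.append(f"{len(missing)} matrix probes absent from manifest")
    for col in inputs.beta.sample_ids:
        if col not in inputs.sheet.sample_ids:
            violations.append(f"matrix column {col!r} absent from sample sheet")
    vals = inputs.beta.values.to_numpy(dtype=float)
    finite = vals[~np.isnan(vals)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        violations.append("beta values outside [0, 1]")
    pvals = inputs.detection_p.to_numpy(dtype=float)
    if ((pvals < 0) | (pvals > 1)).any():
        violations.append("detection p-values outside [0, 1]")
    if not inputs.detection_p.columns.equals(inputs.beta.sample_ids):
        violations.append("detection p-value columns do not match matrix columns")
    try:
        inputs.genome.validate()
    except MethtopoError as exc:
        violations.append(f"genome: {exc}")
    unknown = set(inputs.manifest.df["chromosome"]) - set(inputs.genome.chrom_lengths)
    if unknown:
        violations.append(f"manifest chromosomes not in genome: {sorted(unknown)}")
    for group in inputs.sheet.groups:
        if len(inputs.sheet.samples_of(group)) < 1:
            violations.append(f"group {group!r} has no samples")
    return violations


# ---------------------------------------------------------------------------
# Run
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    """In-memory report bundle of one run."""

    config: PipelineConfig
    qc_report: preprocess.QCReport
    universe: ProbeManifest
    state_calls: dict[str, diffmeth.StateCalls]
    collection: sets.StateSetCollection
    common_sets: dict[str, frozenset[str]]
    specificity: pd.DataFrame
    venn: dict[str, dict[tuple[str, ...], int]]
    arm_ratios: pd.DataFrame
    genome_ratios: pd.DataFrame
    region_pair_tests: pd.DataFrame
    arm_vs_genome: pd.DataFrame
    desert_report: pd.DataFrame
    mean_m: pd.Series
    differential: pd.DataFrame | None = None
    top_probes: list[str] | None = None
    region_counts: pd.DataFrame | None = None
    ora_results: dict[str, pd.DataFrame] = field(default_factory=dict)


def run_pipeline(
    inputs: StudyInputs | Any,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage on in-memory inputs; optionally write the report bundle.

    ``inputs`` may be a :class:`StudyInputs` or any object with the same
    attributes (e.g. :class:`methtopo.synthetic.SyntheticStudy`).
    """
    config = config or PipelineConfig()

    def stage(name: str):
        log.info("stage %s", name)
        return name

    name = stage("validate")
    violations = validate_inputs(inputs)
    if violations:
        raise PipelineError(f"{name}: " + "; ".join(violations))

    try:
        name = stage("preprocess")
        qc = preprocess.qc_filter_samples(inputs.detection_p, config.detection_p_threshold)
        sheet = inputs.sheet.subset(qc.kept_samples)
        manifest = preprocess.drop_sex_probes(inputs.manifest)
        per_platform = preprocess.split_by_platform(manifest)
        universe = preprocess.harmonize_platforms(per_platform, inputs.genome)
        log.info("universe: %d probes after QC/sex/harmonization", len(universe))
        beta = inputs.beta.subset(universe.probe_ids, sheet.sample_ids)
        beta = preprocess.quantile_normalize(beta)
        m_matrix = preprocess.matrix_to_m(beta, epsilon=config.clamp_epsilon)

        name = stage("states")
        calls = {
            group: diffmeth.call_states(
                diffmeth.group_mean_m(m_matrix, sheet, group),
                config.hyper_min,
                config.hypo_max,
                group=group,
            )
            for group in sheet.groups
        }
        mean_m = m_matrix.values.mean(axis=1)

        name = stage("set_analysis")
        collection = sets.StateSetCollection.from_state_calls(list(calls.values()))
        common = {s: sets.common_probes(collection, s) for s in ("hyper", "hypo")}
        specificity = sets.specificity_table(collection)
        venn = {s: sets.venn_counts(collection, s) for s in ("hyper", "hypo")}
        log.info(
            "common probes: hyper=%d hypo=%d", len(common["hyper"]), len(common["hypo"])
        )

        name = stage("topography")
        arm_table = topography.arm_ratios(
            common, universe, inputs.genome, config.excluded_arms
        )
        genome_ratios, pair_tests = topography.genomewide_region_ratios(
            common, universe, inputs.genome, config.excluded_arms
        )
        arm_tests = topography.arm_vs_genome_test(
            common, universe, inputs.genome, config.n_boot, config.seed,
            config.excluded_arms,
        )
        deserts = topography.desert_bands(common, universe, inputs.genome, config.min_probes)

        differential = top_probes = region_counts = None
        if config.diff_groups is not None:
            name = stage("diffmeth")
            a, b = config.diff_groups
            differential = diffmeth.differential_analysis(m_matrix, sheet, a, b, config.fdr)
            k = min(config.top_k, len(differential))
            top_probes = diffmeth.top_k_probes(differential, k)
            sig = differential.index[differential["significant"]]
            sig_states = diffmeth.call_states(
                diffmeth.group_mean_m(m_matrix.subset(sig), sheet, a),
                config.hyper_min,
                config.hypo_max,
                group=a,
            ).states
            region_counts, _ = diffmeth.region_direction_counts(sig_states, universe)

        name = stage("enrichment")
        ora_results: dict[str, pd.DataFrame] = {}
        gene_sets = getattr(inputs, "gene_sets", None)
        if gene_sets:
            gene_universe = universe.gene_universe()
            for region, state in config.ora_queries:
                query = enrichment.probes_to_genes(common[state], universe, region)
                ora_results[f"{region}_{state}"] = enrichment.ora(
                    query, gene_sets, gene_universe
                )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(f"{name}: {exc}") from exc

    result = PipelineResult(
        config=config,
        qc_report=qc,
        universe=universe,
        state_calls=calls,
        collection=collection,
        common_sets=common,
        specificity=specificity,
        venn=venn,
        arm_ratios=arm_table,
        genome_ratios=genome_ratios,
        region_pair_tests=pair_tests,
        arm_vs_genome=arm_tests,
        desert_report=deserts,
        mean_m=mean_m,
        differential=differential,
        top_probes=top_probes,
        region_counts=region_counts,
        ora_results=ora_results,
    )
    if outdir is not None:
        write_report(result, inputs.genome, outdir)
    return result


def write_report(result: PipelineResult, genome: GenomeTable, outdir: str | Path) -> None:
    """Write the full report bundle (tables, tracks, resolved config, log)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    cfg.to_yaml(outdir / "config.yaml")

    result.qc_report.per_sample.to_csv(outdir / "qc_report.tsv", sep="\t",
                                       index_label="sample_id")
    (outdir / "universe_probes.txt").write_text(
        "\n".join(result.universe.probe_ids) + "\n"
    )
    states = pd.DataFrame(
        {group: calls.states for group, calls in result.state_calls.items()}
    )
    states.to_csv(outdir / "state_calls.tsv", sep="\t", index_label="probe_id")
    sets.write_specificity_table(result.specificity, outdir / "specificity.tsv")
    for state, counts in result.venn.items():
        sets.write_venn_counts(counts, result.collection.groups,
                               outdir / f"venn_{state}.tsv")
    result.arm_ratios.to_csv(outdir / "arm_ratios.tsv", sep="\t", index=False)
    result.genome_ratios.to_csv(outdir / "genome_ratios.tsv", sep="\t", index=False)
    result.region_pair_tests.to_csv(outdir / "region_pair_tests.tsv", sep="\t", index=False)
    result.arm_vs_genome.to_csv(outdir / "arm_vs_genome.tsv", sep="\t", index=False)
    result.desert_report.to_csv(outdir / "desert_report.tsv", sep="\t", index=False)
    topography.export_tracks(
        result.common_sets, result.mean_m, result.universe, genome,
        outdir / "tracks", cfg.track_clip, result.desert_report,
    )
    if result.differential is not None:
        result.differential.to_csv(outdir / "differential.tsv", sep="\t",
                                   index_label="probe_id")
        (outdir / "top_probes.txt").write_text("\n".join(result.top_probes) + "\n")
        result.region_counts.to_csv(outdir / "region_counts.tsv", sep="\t")
    for key, frame in result.ora_results.items():
        frame.to_csv(outdir / f"ora_{key}.tsv", sep="\t", index=False)

    lines = [
        f"seed\t{cfg.seed}",
        f"detection_p_threshold\t{cfg.detection_p_threshold}",
        f"hyper_min\t{cfg.hyper_min}",
        f"hypo_max\t{cfg.hypo_max}",
        f"fdr\t{cfg.fdr}",
        f"top_k\t{cfg.top_k}",
        f"min_probes\t{cfg.min_probes}",
        f"n_boot\t{cfg.n_boot}",
        f"samples_kept\t{len(result.qc_report.kept_samples)}",
        f"samples_dropped\t{len(result.qc_report.dropped_samples)}",
        f"universe_probes\t{len(result.universe)}",
        f"common_hyper\t{len(result.common_sets['hyper'])}",
        f"common_hypo\t{len(result.common_sets['hypo'])}",
        f"desert_bands\t{int(result.desert_report['desert'].sum())}",
    ]
    (outdir / "run_log.txt").write_text("\n".join(lines) + "\n")
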