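"""Readers and writers for the plain-text formats the pipeline consumes.

All tabular files are tab-separated with a header row unless noted.  Genomic
coordinates in these files are 1-based inclusive (Illumina/UCSC-text style)
and are converted to 0-based half-open on read; BED and bedGraph output is
0-based half-open with no header by default.
"""

from __future__ import annotations

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

# Default mapping from Illumina UCSC_RefGene_Group tokens to region labels.
# TSS200 is "within 200 bp of a transcription start site", i.e. the promoter
# definition used throughout; Body marks gene-body probes.  Unlisted tokens
# (TSS1500, 5'UTR, ...) are ignored.
ILLUMINA_REGION_TOKENS: Mapping[str, str] = {"TSS200": "promoter", "Body": "gene_body"}

_LIST_SEP = ";"


def _split_list(cell: object) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return ()
    return tuple(str(cell).split(_LIST_SEP))


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------


def read_manifest(path: str | Path, column_map: Mapping[str, str] | None = None) -> ProbeManifest:
    """Read a probe manifest from TSV.

    The native dialect has columns ``probe_id, chromosome, position, strand,
    regions, genes, platforms`` where ``regions``/``genes``/``platforms`` are
    ``;``-separated lists (regions drawn from promoter/gene_body/enhancer).

    ``column_map`` adapts other headers, mapping native names to the file's
    names, e.g. ``{"probe_id": "IlmnID", "position": "MAPINFO"}``.  When the
    mapped file carries Illumina-style ``UCSC_RefGene_Group`` and ``Enhancer``
    columns instead of ``regions``, map ``"refgene_group"`` and
    ``"enhancer_flag"`` to them and region flags are derived via
    :data:`ILLUMINA_REGION_TOKENS` plus the enhancer flag column.
    """
    cmap = dict(column_map or {})
    raw = pd.read_csv(path, sep="\t", dtype=str)

    def col(native: str, required: bool = True) -> pd.Series | None:
        name = cmap.get(native, native)
        if name not in raw.columns:
            if required:
                raise MethtopoError(f"manifest file lacks column {name!r} (for {native!r})")
            return None
        return raw[name]

    df = pd.DataFrame(index=pd.Index(col("probe_id"), name="probe_id"))
    df["chromosome"] = col("chromosome").to_numpy()
    df["position"] = col("position").astype(int).to_numpy()
    strand = col("strand", required=False)
    df["strand"] = strand.fillna("unknown").to_numpy() if strand is not None else "unknown"

    regions = col("regions", required=False)
    if regions is not None:
        parsed = [set(_split_list(c)) for c in regions]
        bad = set().union(*parsed) - set(REGIONS)
        if bad:
            raise MethtopoError(f"unknown region labels in manifest: {sorted(bad)}")
    else:
        refgene = col("refgene_group", required=False)
        enh = col("enhancer_flag", required=False)
        if refgene is None:
            raise MethtopoError("manifest needs either a 'regions' or a mapped refgene_group column")
        parsed = []
        for tokens, eflag in zip(refgene, enh if enh is not None else [None] * len(raw)):
            regs = {
                ILLUMINA_REGION_TOKENS[t]
                for t in _split_list(tokens)
                if t in ILLUMINA_REGION_TOKENS
            }
            if eflag is not None and str(eflag).upper() in ("TRUE", "1", "YES"):
                regs.add("enhancer")
            parsed.append(regs)
    for region in REGIONS:
        df[region] = [region in p for p in parsed]

    genes = col("genes", required=False)
    df["genes"] = (
        [tuple(sorted(set(_split_list(c)))) for c in genes] if genes is not None else [()] * len(raw)
    )

    platforms = col("platforms", required=False)
    if platforms is not None:
        pl = [set(_split_list(c)) for c in platforms]
        bad = set().union(*pl) - set(PLATFORMS)
        if bad:
            raise MethtopoError(f"unknown platform labels in manifest: {sorted(bad)}")
    else:
        pl = [set(PLATFORMS)] * len(raw)
    for platform in PLATFORMS:
        df[platform] = [platform in p for p in pl]
    return ProbeManifest(df)


def write_manifest(manifest: ProbeManifest, path: str | Path) -> None:
    df = manifest.df
    out = pd.DataFrame(index=df.index)
    out["chromosome"] = df["chromosome"]
    out["position"] = df["position"]
    out["strand"] = df["strand"]
    out["regions"] = [
        _LIST_SEP.join(r for r in REGIONS if row[r]) for _, row in df[list(REGIONS)].iterrows()
    ]
    out["genes"] = [_LIST_SEP.join(g) for g in df["genes"]]
    out["platforms"] = [
        _LIST_SEP.join(p for p in PLATFORMS if row[p]) for _, row in df[list(PLATFORMS)].iterrows()
    ]
    out.to_csv(path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# Genome tables
# ---------------------------------------------------------------------------


def read_genome(
    chrom_sizes_path: str | Path,
    gap_path: str | Path,
    cytoband_path: str | Path,
) -> GenomeTable:
    """Assemble a :class:`GenomeTable` from three TSV files.

    * chrom sizes: columns ``chrom, length``;
    * gap table: columns ``chrom, start, end, type`` — filtered to rows with
      ``type == "centromere"`` (UCSC gap-table style);
    * cytoband table: columns ``chrom, start, end, name, stain``.

    Starts are 1-based inclusive and converted to 0-based half-open.
    """
    sizes = pd.read_csv(chrom_sizes_path, sep="\t")
    chrom_lengths = dict(zip(sizes["chrom"], sizes["length"].astype(int)))

    gap = pd.read_csv(gap_path, sep="\t")
    if "type" in gap.columns:
        gap = gap[gap["type"] == "centromere"]
    cen = pd.DataFrame(
        {
            "chrom": gap["chrom"].to_numpy(),
            "start": gap["start"].astype(int).to_numpy() - 1,
            "end": gap["end"].astype(int).to_numpy(),
        }
    )

    cyto = pd.read_csv(cytoband_path, sep="\t")
    bands = pd.DataFrame(
        {
            "chrom": cyto["chrom"].to_numpy(),
            "start": cyto["start"].astype(int).to_numpy() - 1,
            "end": cyto["end"].astype(int).to_numpy(),
            "name": cyto["name"].to_numpy(),
            "stain": cyto["stain"].to_numpy(),
        }
    )
    return GenomeTable(chrom_lengths, cen, bands)


def write_genome(genome: GenomeTable, directory: str | Path) -> dict[str, Path]:
    """Write chrom sizes / gap / cytoband TSVs (1-based inclusive starts)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "chrom_sizes": directory / "chrom_sizes.tsv",
        "gap": directory / "gap.tsv",
        "cytoband": directory / "cytoband.tsv",
    }
    pd.DataFrame(
        {"chrom": list(genome.chrom_lengths), "length": list(genome.chrom_lengths.values())}
    ).to_csv(paths["chrom_sizes"], sep="\t", index=False)
    gap = genome.centromeres.copy()
    gap["start"] = gap["start"] + 1
    gap["type"] = "centromere"
    gap.to_csv(paths["gap"], sep="\t", index=False)
    cyto = genome.cytobands.copy()
    cyto["start"] = cyto["start"] + 1
    cyto.to_csv(paths["cytoband"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Matrices and sample sheets
# ---------------------------------------------------------------------------


def read_matrix(path: str | Path, scale: str) -> MethylationMatrix:
    """Read a probes × samples matrix (first column = probe_id)."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index.name = "probe_id"
    return MethylationMatrix(values, scale=scale)


def write_matrix(matrix: MethylationMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="probe_id", float_format="%.10g")


def read_detection_p(path: str | Path) -> pd.DataFrame:
    p = pd.read_csv(path, sep="\t", index_col=0)
    p.index.name = "probe_id"
    if ((p < 0) | (p > 1)).any().any():
        raise MethtopoError("detection p-values outside [0, 1]")
    return p


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", index_col="sample_id", dtype=str)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.df.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a GMT file: one set per line, ``id <TAB> description <TAB> genes...``."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise MethtopoError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = (fields[1], frozenset(g for g in fields[2:] if g))
    return sets


def write_gmt(sets: Mapping[str, tuple[str, frozenset[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id, (name, genes) in sets.items():
            fh.write("\t".join([set_id, name, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# Track export (bedGraph / BED)
# ---------------------------------------------------------------------------


def write_bedgraph(
    records: pd.DataFrame, path: str | Path, track_line: str | None = None
) -> None:
    """Write ``chrom, start, end, value`` records as bedGraph (no header)."""
    with open(path, "w") as fh:
        if track_line:
            fh.write(track_line + "\n")
        for row in records.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value:g}\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("track"):
            continue
        chrom, start, end, value = line.split("\t")
        rows.append((chrom, int(start), int(end), float(value)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bed(records: pd.DataFrame, path: str | Path) -> None:
    """Write ``chrom, start, end, name`` records as BED4 (no header)."""
    with open(path, "w") as fh:
        for row in records.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\n")
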