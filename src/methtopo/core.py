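"""Core domain types: probe manifests, genome tables, sample sheets, matrices.

Coordinate conventions
----------------------
Text inputs (manifests, gap tables, cytoband tables) carry 1-based inclusive
coordinates, the convention of Illumina annotation files and UCSC Table
Browser text exports as consumed here.  On read everything is converted once
to 0-based half-open intervals; all internal arithmetic and all BED/bedGraph
exports use that single convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Functional region labels carried by probe annotations.  A probe may belong
#: to any subset of these; multi-membership probes count once per region.
REGIONS: tuple[str, ...] = ("promoter", "gene_body", "enhancer")

#: Array platform labels.
PLATFORMS: tuple[str, ...] = ("A450K", "EPIC")

#: Recognized cytoband stain values (Giemsa staining intensity classes).
STAINS: frozenset[str] = frozenset(
    {"gneg", "gpos25", "gpos50", "gpos75", "gpos100", "acen", "gvar", "stalk"}
)

#: Chromosomes removed by sex-probe filtering.
SEX_CHROMOSOMES: tuple[str, ...] = ("chrX", "chrY")

#: Short arms of the human acrocentric chromosomes; they carry essentially no
#: array probes and are excluded from arm-ratio analyses by default.
ACROCENTRIC_P_ARMS: tuple[str, ...] = ("chr13p", "chr14p", "chr15p", "chr21p", "chr22p")


class MethtopoError(ValueError):
    """Base class for domain validation errors."""


# ---------------------------------------------------------------------------
# GenomeTable
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeTable:
    """Chromosome sizes, centromere gaps, and a tiling cytoband catalog.

    Parameters
    ----------
    chrom_lengths
        Ordered mapping of chromosome label to length in bp.  The mapping
        order defines the canonical chromosome sort used everywhere.
    centromeres
        Frame with columns ``chrom, start, end`` (0-based half-open), one row
        per chromosome that has a centromere gap.
    cytobands
        Frame with columns ``chrom, start, end, name, stain`` (0-based
        half-open) tiling each chromosome without overlap.
    """

    chrom_lengths: Mapping[str, int]
    centromeres: pd.DataFrame
    cytobands: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise MethtopoError(f"chromosome {chrom} has nonpositive length")
        cen = self.centromeres
        for _, row in cen.iterrows():
            if row["chrom"] not in self.chrom_lengths:
                raise MethtopoError(f"centromere on unknown chromosome {row['chrom']!r}")
            if not (0 <= row["start"] < row["end"] <= self.chrom_lengths[row["chrom"]]):
                raise MethtopoError(
                    f"centromere interval ({row['start']}, {row['end']}) not contained "
                    f"in chromosome {row['chrom']}"
                )
        bad_stain = set(self.cytobands["stain"]) - STAINS
        if bad_stain:
            raise MethtopoError(f"unknown cytoband stain values: {sorted(bad_stain)}")
        for chrom, grp in self.cytobands.groupby("chrom", sort=False):
            if chrom not in self.chrom_lengths:
                raise MethtopoError(f"cytoband on unknown chromosome {chrom!r}")
            grp = grp.sort_values("start")
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if starts[0] != 0 or ends[-1] != self.chrom_lengths[chrom]:
                raise MethtopoError(f"cytobands do not span chromosome {chrom}")
            if not np.array_equal(starts[1:], ends[:-1]):
                raise MethtopoError(f"cytobands do not tile chromosome {chrom} (gap or overlap)")

    # -- lookups ------------------------------------------------------------

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_lengths)

    def centromere_of(self, chrom: str) -> tuple[int, int] | None:
        rows = self.centromeres[self.centromeres["chrom"] == chrom]
        if rows.empty:
            return None
        row = rows.iloc[0]
        return int(row["start"]), int(row["end"])

    def arms(self, chroms: Iterable[str] | None = None) -> list[str]:
        """All ``<chrom><p|q>`` labels, in genome order."""
        out = []
        for chrom in chroms if chroms is not None else self.chromosomes:
            out.extend([f"{chrom}p", f"{chrom}q"])
        return out

    def arm_of_positions(self, chroms: Sequence[str], pos0: Sequence[int]) -> pd.Series:
        """Vectorized arm assignment for 0-based positions.

        Returns ``"<chrom>p"`` / ``"<chrom>q"``, or NA for positions that fall
        inside the centromere gap.  Chromosomes without a recorded centromere
        are treated as entirely q-arm (no gap).  Unknown chromosomes raise.
        """
        chroms = pd.Series(np.asarray(chroms, dtype=object))
        pos0 = np.asarray(pos0, dtype=np.int64)
        unknown = set(chroms.unique()) - set(self.chrom_lengths)
        if unknown:
            raise MethtopoError(f"unknown chromosome(s): {sorted(unknown)}")
        out = pd.Series(pd.NA, index=chroms.index, dtype=object)
        for chrom in chroms.unique():
            mask = (chroms == chrom).to_numpy()
            cen = self.centromere_of(chrom)
            if cen is None:
                out[mask] = f"{chrom}q"
                continue
            cs, ce = cen
            p = pos0[mask]
            lab = np.where(p < cs, f"{chrom}p", np.where(p >= ce, f"{chrom}q", None))
            out[mask] = lab
        return out.where(out.notna(), pd.NA)

    def band_of_positions(self, chroms: Sequence[str], pos0: Sequence[int]) -> pd.Series:
        """Vectorized cytoband lookup under the half-open convention."""
        chroms = pd.Series(np.asarray(chroms, dtype=object))
        pos0 = np.asarray(pos0, dtype=np.int64)
        out = pd.Series(pd.NA, index=chroms.index, dtype=object)
        for chrom in chroms.unique():
            if chrom not in self.chrom_lengths:
                raise MethtopoError(f"unknown chromosome {chrom!r}")
            mask = (chroms == chrom).to_numpy()
            p = pos0[mask]
            if (p < 0).any() or (p >= self.chrom_lengths[chrom]).any():
                raise MethtopoError(f"position beyond chromosome {chrom} length")
            bands = self.cytobands[self.cytobands["chrom"] == chrom].sort_values("start")
            idx = np.searchsorted(bands["start"].to_numpy(), p, side="right") - 1
            out[mask] = bands["name"].to_numpy()[idx]
        return out


def arm_of(chrom: str, position: int, genome: GenomeTable) -> str | None:
    """Arm label of a single 1-based probe position; None inside the gap."""
    res = genome.arm_of_positions([chrom], [position - 1]).iloc[0]
    return None if res is pd.NA else res


def band_of(chrom: str, position: int, genome: GenomeTable) -> str:
    """Cytoband name containing a single 1-based probe position."""
    return genome.band_of_positions([chrom], [position - 1]).iloc[0]


# ---------------------------------------------------------------------------
# ProbeManifest
# ---------------------------------------------------------------------------


@dataclass
class ProbeManifest:
    """Per-probe genomic location, functional-region flags, genes, platforms.

    Backed by a DataFrame indexed by ``probe_id`` with columns::

        chromosome (str)   position (int, 1-based)   strand ({+,-,unknown})
        promoter, gene_body, enhancer (bool)   genes (tuple[str, ...])
        A450K, EPIC (bool)
    """

    df: pd.DataFrame

    _REQUIRED = ("chromosome", "position", "strand", *REGIONS, "genes", *PLATFORMS)

    def __post_init__(self) -> None:
        missing = [c for c in self._REQUIRED if c not in self.df.columns]
        if missing:
            raise MethtopoError(f"manifest missing columns: {missing}")
        if not self.df.index.is_unique:
            dupes = self.df.index[self.df.index.duplicated()].unique().tolist()[:5]
            raise MethtopoError(f"duplicate probe ids in manifest, e.g. {dupes}")
        if (self.df["position"] < 1).any():
            raise MethtopoError("manifest contains positions < 1")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def probe_ids(self) -> pd.Index:
        return self.df.index

    @property
    def pos0(self) -> pd.Series:
        """0-based positions."""
        return self.df["position"] - 1

    def subset(self, probe_ids: Iterable[str]) -> "ProbeManifest":
        return ProbeManifest(self.df.loc[pd.Index(probe_ids)])

    def region_probe_ids(self, region: str) -> pd.Index:
        if region not in REGIONS:
            raise MethtopoError(f"unknown region {region!r}; expected one of {REGIONS}")
        return self.df.index[self.df[region]]

    def platform_probe_ids(self, platform: str) -> pd.Index:
        if platform not in PLATFORMS:
            raise MethtopoError(f"unknown platform {platform!r}")
        return self.df.index[self.df[platform]]

    def sort_by_position(self, genome: GenomeTable | None = None) -> "ProbeManifest":
        """Stable sort by (chromosome, position); genome order when given."""
        if genome is not None:
            order = {c: i for i, c in enumerate(genome.chromosomes)}
            key = self.df["chromosome"].map(order)
        else:
            key = self.df["chromosome"]
        df = self.df.assign(_ck=key).sort_values(["_ck", "position"], kind="mergesort")
        return ProbeManifest(df.drop(columns="_ck"))

    def annotate(self, genome: GenomeTable) -> pd.DataFrame:
        """Return a frame with ``arm`` and ``band`` columns added."""
        df = self.df.copy()
        df["arm"] = genome.arm_of_positions(
            df["chromosome"].to_numpy(), self.pos0.to_numpy()
        ).to_numpy()
        df["band"] = genome.band_of_positions(
            df["chromosome"].to_numpy(), self.pos0.to_numpy()
        ).to_numpy()
        return df

    def gene_universe(self) -> list[str]:
        """Sorted union of all gene symbols on the manifest."""
        seen: set[str] = set()
        for genes in self.df["genes"]:
            seen.update(genes)
        return sorted(seen)


# ---------------------------------------------------------------------------
# SampleSheet and MethylationMatrix
# ---------------------------------------------------------------------------


@dataclass
class SampleSheet:
    """Sample → group/platform bookkeeping; indexed by ``sample_id``."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("group", "platform"):
            if col not in self.df.columns:
                raise MethtopoError(f"sample sheet missing column {col!r}")
        if not self.df.index.is_unique:
            raise MethtopoError("duplicate sample ids in sample sheet")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> pd.Index:
        return self.df.index

    @property
    def groups(self) -> list[str]:
        """Group labels in first-appearance order."""
        return list(dict.fromkeys(self.df["group"]))

    def samples_of(self, group: str) -> pd.Index:
        ids = self.df.index[self.df["group"] == group]
        if len(ids) == 0:
            raise MethtopoError(f"no samples in group {group!r}")
        return ids

    def subset(self, sample_ids: Iterable[str]) -> "SampleSheet":
        return SampleSheet(self.df.loc[pd.Index(sample_ids)])


@dataclass
class MethylationMatrix:
    """A probes × samples value grid on a declared scale (``beta`` or ``M``).

    Beta values live in [0, 1] (checked up to ``clamp_epsilon``); M-values are
    unbounded.  Missing values (off-platform probes) are NaN.
    """

    values: pd.DataFrame
    scale: str
    clamp_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.scale not in ("beta", "M"):
            raise MethtopoError(f"unknown scale {self.scale!r}")
        if self.scale == "beta":
            v = self.values.to_numpy(dtype=float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                bad = np.nanmin(v) < -self.clamp_epsilon or np.nanmax(v) > 1 + self.clamp_epsilon
            if bad:
                raise MethtopoError("beta-scale values outside [0, 1] beyond tolerance")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset(
        self,
        probe_ids: Iterable[str] | None = None,
        sample_ids: Iterable[str] | None = None,
    ) -> "MethylationMatrix":
        vals = self.values
        if probe_ids is not None:
            vals = vals.loc[pd.Index(probe_ids)]
        if sample_ids is not None:
            vals = vals[pd.Index(sample_ids)]
        return replace(self, values=vals)
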