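"""Sample QC, probe filtering, platform harmonization, and normalization.

The canonical preprocessing order is: detection-p QC -> sex-probe removal ->
platform harmonization (intersection universe) -> quantile normalization on
the beta scale -> conversion to M-values for statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    SEX_CHROMOSOMES,
    GenomeTable,
    MethtopoError,
    MethylationMatrix,
    ProbeManifest,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# beta <-> M conversion
# ---------------------------------------------------------------------------


def beta_to_m(beta, epsilon: float = 1e-6):
    """Convert beta values (fraction methylated, in [0,1]) to M-values.

    M = log2(beta / (1 - beta)) after clamping beta to [epsilon, 1-epsilon],
    so that fully (un)methylated probes map to large finite values instead of
    +/-inf.  The cutoff correspondence M = +/-2 <=> beta = 0.8 / 0.2 is exact.

    Accepts scalars, arrays, Series, or DataFrames; NaN passes through.
    """
    arr = np.asarray(beta, dtype=float)
    finite = arr[~np.isnan(arr)] if arr.size else arr
    if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
        raise MethtopoError("beta values outside [0, 1]")
    clamped = np.clip(arr, epsilon, 1 - epsilon)
    m = np.log2(clamped / (1 - clamped))
    m = np.where(np.isnan(arr), np.nan, m)
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index)
    return m if np.ndim(beta) else float(m)


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2^M / (1 + 2^M), in (0, 1)."""
    arr = np.asarray(m, dtype=float)
    beta = 1.0 / (1.0 + np.exp2(-arr))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(beta, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(beta, index=m.index)
    return beta if np.ndim(m) else float(beta)


def matrix_to_m(matrix: MethylationMatrix, epsilon: float = 1e-6) -> MethylationMatrix:
    """Convert a beta-scale matrix to the M scale (identity if already M)."""
    if matrix.scale == "M":
        return matrix
    return MethylationMatrix(beta_to_m(matrix.values, epsilon=epsilon), scale="M")


# ---------------------------------------------------------------------------
# Sample QC on detection p-values
# ---------------------------------------------------------------------------


@dataclass
class QCReport:
    """Per-sample mean detection p-values and the keep/drop decision."""

    per_sample: pd.DataFrame  # columns: mean_detection_p, kept
    threshold: float

    @property
    def kept_samples(self) -> list[str]:
        return list(self.per_sample.index[self.per_sample["kept"]])

    @property
    def dropped_samples(self) -> list[str]:
        return list(self.per_sample.index[~self.per_sample["kept"]])


def qc_filter_samples(detection_p: pd.DataFrame, threshold: float = 0.01) -> QCReport:
    """Keep samples whose mean detection p-value is strictly below ``threshold``.

    A high detection p-value means a probe signal indistinguishable from
    background; samples whose probes fail en masse are unusable.
    """
    if detection_p.size == 0:
        raise MethtopoError("empty detection p-value matrix")
    vals = detection_p.to_numpy(dtype=float)
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise MethtopoError("detection p-values outside [0, 1]")
    means = detection_p.mean(axis=0, skipna=True)
    report = pd.DataFrame({"mean_detection_p": means, "kept": means < threshold})
    dropped = (~report["kept"]).sum()
    if dropped:
        log.info("QC dropped %d/%d samples at mean detection p >= %g",
                 dropped, len(report), threshold)
    return QCReport(report, threshold)


# ---------------------------------------------------------------------------
# Probe filtering and platform harmonization
# ---------------------------------------------------------------------------


def drop_sex_probes(
    manifest: ProbeManifest, sex_chromosomes: Sequence[str] = SEX_CHROMOSOMES
) -> ProbeManifest:
    """Remove probes on the sex chromosomes; autosomal probes are untouched."""
    keep = ~manifest.df["chromosome"].isin(sex_chromosomes)
    return ProbeManifest(manifest.df[keep])


def harmonize_platforms(
    manifests: Sequence[ProbeManifest], genome: GenomeTable | None = None
) -> ProbeManifest:
    """Intersect >= 2 per-platform manifests into the shared analysis universe.

    Returns the first manifest restricted to probes present on every platform,
    stably ordered by genomic position.  Raises on an empty intersection.
    """
    if len(manifests) < 2:
        raise MethtopoError("harmonize_platforms needs at least two manifests")
    shared = set(manifests[0].probe_ids)
    for m in manifests[1:]:
        shared &= set(m.probe_ids)
    if not shared:
        raise MethtopoError("no probes shared between platforms")
    base = manifests[0]
    sub = ProbeManifest(base.df.loc[base.df.index.isin(shared)])
    return sub.sort_by_position(genome)


def split_by_platform(manifest: ProbeManifest) -> list[ProbeManifest]:
    """Split a flag-carrying manifest into one manifest per platform."""
    from .core import PLATFORMS

    return [ProbeManifest(manifest.df[manifest.df[p]]) for p in PLATFORMS]


# ---------------------------------------------------------------------------
# Quantile normalization
# ---------------------------------------------------------------------------


def quantile_normalize(
    matrix: MethylationMatrix, stratify: pd.Series | None = None
) -> MethylationMatrix:
    """Force every sample onto the common mean quantile distribution.

    After normalization every column holds the same sorted multiset (the
    across-sample mean of order statistics); within-column ranks are
    preserved and tied values share the mean of their quantile slots.  With a
    ``stratify`` Series (probe -> stratum, e.g. probe chemistry type) the
    procedure is applied within each stratum separately.

    A single-sample matrix is returned unchanged with a warning.  Missing
    values are not supported (subset to the harmonized universe first).
    """
    values = matrix.values
    if values.shape[1] < 2:
        warnings.warn("quantile_normalize: single sample, returning input unchanged")
        return matrix
    if values.isna().any().any():
        raise MethtopoError("quantile_normalize requires a complete matrix (no NaN)")
    if stratify is not None:
        out = values.copy()
        for _, idx in values.index.to_series().groupby(stratify.reindex(values.index)):
            sub = MethylationMatrix(values.loc[idx.index], scale=matrix.scale)
            out.loc[idx.index] = quantile_normalize(sub).values
        return MethylationMatrix(out, scale=matrix.scale)

    arr = values.to_numpy(dtype=float)
    n, k = arr.shape
    mean_quantiles = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(k):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        slot_values = np.empty(n)
        slot_values[order] = mean_quantiles
        # ties share the mean of the quantile slots they occupy
        out[:, j] = pd.Series(slot_values).groupby(pd.Series(col)).transform("mean").to_numpy()
    return MethylationMatrix(
        pd.DataFrame(out, index=values.index, columns=values.columns), scale=matrix.scale
    )
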