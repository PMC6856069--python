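"""State calling and two-group differential methylation on M-values.

A probe is called hypermethylated in a group when its group-mean M-value is
at or above +2 (beta ~ 0.8) and hypomethylated at or below -2 (beta ~ 0.2);
everything in between is "neither".  Differential analysis is a per-probe
Welch (unequal-variance) t-test with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from statsmodels.stats.multitest import multipletests

from .core import REGIONS, MethtopoError, MethylationMatrix, ProbeManifest, SampleSheet

HYPER_MIN_DEFAULT = 2.0
HYPO_MAX_DEFAULT = -2.0

STATES = ("hyper", "hypo", "neither")


@dataclass
class StateCalls:
    """Per-probe methylation state for one group, from mean M cutoffs."""

    group: str
    means: pd.Series
    states: pd.Series
    hyper_min: float = HYPER_MIN_DEFAULT
    hypo_max: float = HYPO_MAX_DEFAULT

    @property
    def hyper_probes(self) -> frozenset[str]:
        return frozenset(self.states.index[self.states == "hyper"])

    @property
    def hypo_probes(self) -> frozenset[str]:
        return frozenset(self.states.index[self.states == "hypo"])

    def probes_in_state(self, state: str) -> frozenset[str]:
        if state not in STATES:
            raise MethtopoError(f"unknown state {state!r}")
        return frozenset(self.states.index[self.states == state])


def group_mean_m(matrix: MethylationMatrix, sheet: SampleSheet, group: str) -> pd.Series:
    """Arithmetic mean M per probe over a group's samples (NaN excluded)."""
    if matrix.scale != "M":
        raise MethtopoError("group_mean_m expects an M-scale matrix")
    samples = sheet.samples_of(group)
    cols = matrix.values.columns.intersection(samples)
    if len(cols) == 0:
        raise MethtopoError(f"no matrix columns for group {group!r}")
    return matrix.values[cols].mean(axis=1, skipna=True)


def call_states(
    means: pd.Series,
    hyper_min: float = HYPER_MIN_DEFAULT,
    hypo_max: float = HYPO_MAX_DEFAULT,
    group: str = "",
) -> StateCalls:
    """Three-way hyper/hypo/neither partition of probes by mean M-value.

    Boundary values are included: mean M == hyper_min is hyper, mean M ==
    hypo_max is hypo.
    """
    if hyper_min <= hypo_max:
        raise MethtopoError("hyper_min must exceed hypo_max")
    if not np.isfinite(means.to_numpy(dtype=float)).all():
        raise MethtopoError("call_states requires finite mean M-values")
    states = pd.Series("neither", index=means.index, dtype=object)
    states[means >= hyper_min] = "hyper"
    states[means <= hypo_max] = "hypo"
    return StateCalls(group, means, states, hyper_min, hypo_max)


# ---------------------------------------------------------------------------
# Welch t-test and FDR
# ---------------------------------------------------------------------------


def welch_t_per_probe(
    matrix: MethylationMatrix, sheet: SampleSheet, group_a: str, group_b: str
) -> pd.DataFrame:
    """Per-probe two-sided Welch t-test between two groups of M-values.

    Returns a frame indexed by probe_id with columns ``mean_a, mean_b,
    delta_m, t, p, degenerate``.  ``delta_m`` is ``mean_a - mean_b``.  Probes
    with zero variance in both groups get t = 0, p = 1 when the means agree
    (flagged ``degenerate``); with differing means they get p = 0, also
    flagged, since the test statistic is unbounded there.
    """
    if matrix.scale != "M":
        raise MethtopoError("welch_t_per_probe expects an M-scale matrix")
    out = {}
    stats_ab = []
    for group in (group_a, group_b):
        cols = matrix.values.columns.intersection(sheet.samples_of(group))
        vals = matrix.values[cols]
        n = vals.notna().sum(axis=1)
        if (n < 2).any():
            raise MethtopoError(f"group {group!r} has probes with fewer than 2 observations")
        stats_ab.append(
            (vals.mean(axis=1).to_numpy(), vals.var(axis=1, ddof=1).to_numpy(), n.to_numpy())
        )
    (ma, va, na), (mb, vb, nb) = stats_ab
    se2 = va / na + vb / nb
    delta = ma - mb
    degenerate = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / np.sqrt(se2)
        # Welch–Satterthwaite degrees of freedom
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    t = np.where(degenerate & (delta == 0), 0.0, t)
    p = np.where(
        degenerate,
        np.where(delta == 0, 1.0, 0.0),
        2 * stats.t.sf(np.abs(t), np.where(degenerate, 1, df)),
    )
    out = pd.DataFrame(
        {
            "mean_a": ma,
            "mean_b": mb,
            "delta_m": delta,
            "t": t,
            "p": p,
            "degenerate": degenerate,
        },
        index=matrix.values.index,
    )
    return out


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values: q_(i) = min_{j>=i} min(1, m p_(j)/j)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if (p < 0).any() or (p > 1).any():
        raise MethtopoError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_analysis(
    matrix: MethylationMatrix,
    sheet: SampleSheet,
    group_a: str,
    group_b: str,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Welch t per probe + BH FDR + direction of change in group A.

    Adds ``q``, ``significant`` (q < fdr, strict) and ``direction``
    (hyper-in-A / hypo-in-A by the sign of ``delta_m``).
    """
    res = welch_t_per_probe(matrix, sheet, group_a, group_b)
    res["q"] = bh_fdr(res["p"].to_numpy())
    res["significant"] = res["q"] < fdr
    res["direction"] = np.where(res["delta_m"] >= 0, "hyper-in-A", "hypo-in-A")
    return res


def top_k_probes(result: pd.DataFrame, k: int = 10000) -> list[str]:
    """The k most significant probes, ascending by q.

    Ties are broken by larger \\|delta_m\\|, then lexicographic probe id, so
    the selection is fully deterministic.
    """
    if k <= 0:
        raise MethtopoError("k must be positive")
    if k > len(result):
        raise MethtopoError(f"k={k} exceeds number of probes {len(result)}")
    # stable mergesort after a probe-id pre-sort settles full ties deterministically
    ranked = (
        result.assign(_absd=-result["delta_m"].abs())
        .sort_index(kind="mergesort")
        .sort_values(["q", "_absd"], kind="mergesort")
    )
    return list(ranked.index[:k])


# ---------------------------------------------------------------------------
# Clustering and region summaries
# ---------------------------------------------------------------------------


def hierarchical_order(
    matrix: MethylationMatrix,
    metric: str = "euclidean",
    method: str = "complete",
) -> tuple[list[str], list[str]]:
    """Deterministic leaf orders from agglomerative clustering.

    Samples (columns) and probes (rows) are clustered separately with the
    given metric/linkage; returns ``(sample_order, probe_order)``.
    """
    values = matrix.values
    if values.shape[1] < 2:
        raise MethtopoError("hierarchical_order needs at least two samples")
    arr = values.to_numpy(dtype=float)
    if np.ptp(arr) == 0:
        warnings.warn("hierarchical_order: constant matrix, returning input order")
        return list(values.columns), list(values.index)

    def order(data: np.ndarray) -> np.ndarray:
        if data.shape[0] < 2:
            return np.arange(data.shape[0])
        return leaves_list(linkage(data, method=method, metric=metric))

    sample_order = order(arr.T)
    probe_order = order(arr)
    return list(values.columns[sample_order]), list(values.index[probe_order])


def region_direction_counts(
    states: pd.Series,
    manifest: ProbeManifest,
    n_boot: int = 0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Count hyper/hypo probes per functional region, with optional tests.

    ``states`` maps probe_id -> state for the probes of interest (e.g. the
    FDR-significant set).  A probe annotated to several regions is counted in
    each.  With ``n_boot`` > 0 the probe set is bootstrap-resampled to give
    replicate counts, compared between regions (within each state) by Welch
    t-tests; returns ``(counts, tests)`` where tests is None if n_boot == 0.
    """
    sub = manifest.df.reindex(states.index)
    counts = pd.DataFrame(0, index=pd.Index(REGIONS, name="region"), columns=["hyper", "hypo"])
    for region in REGIONS:
        in_region = sub[region].fillna(False).astype(bool)
        for state in ("hyper", "hypo"):
            counts.loc[region, state] = int(((states == state) & in_region).sum())

    if n_boot <= 0:
        return counts, None
    rng = np.random.default_rng(seed)
    n = len(states)
    region_flags = sub[list(REGIONS)].fillna(False).astype(bool).to_numpy()
    state_arr = states.to_numpy()
    reps: dict[tuple[str, str], np.ndarray] = {
        (r, s): np.empty(n_boot) for r in REGIONS for s in ("hyper", "hypo")
    }
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        for i, region in enumerate(REGIONS):
            flags = region_flags[idx, i]
            st = state_arr[idx]
            for state in ("hyper", "hypo"):
                reps[(region, state)][b] = np.sum(flags & (st == state))
    rows = []
    for state in ("hyper", "hypo"):
        for i, ra in enumerate(REGIONS):
            for rb in REGIONS[i + 1 :]:
                t, p = stats.ttest_ind(reps[(ra, state)], reps[(rb, state)], equal_var=False)
                rows.append((state, ra, rb, float(t), float(p)))
    tests = pd.DataFrame(rows, columns=["state", "region_a", "region_b", "t", "p"])
    return counts, tests
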