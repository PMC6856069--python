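"""Cross-group probe-set algebra: common, group-specific, Venn, specificity.

"Common" probes are in the given methylation state in every analyzed group
simultaneously; "unique" (group-specific) probes are in the state in exactly
one group.  The specificity summary tabulates, per group and state, the total
and unique counts and the percent unique, plus column averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import MethtopoError
from .diffmeth import StateCalls

VENN_MAX_GROUPS = 7


@dataclass
class StateSetCollection:
    """group -> {state -> probe set} over a shared probe universe."""

    sets: dict[str, dict[str, frozenset[str]]]

    @classmethod
    def from_state_calls(cls, calls: Sequence[StateCalls]) -> "StateSetCollection":
        return cls(
            {c.group: {"hyper": c.hyper_probes, "hypo": c.hypo_probes} for c in calls}
        )

    @property
    def groups(self) -> list[str]:
        return list(self.sets)

    def get(self, group: str, state: str) -> frozenset[str]:
        if group not in self.sets:
            raise MethtopoError(f"unknown group {group!r}")
        if state not in ("hyper", "hypo"):
            raise MethtopoError(f"unknown state {state!r}")
        return self.sets[group][state]


def common_probes(collection: StateSetCollection, state: str) -> frozenset[str]:
    """Probes in ``state`` in all groups (intersection across every group)."""
    groups = collection.groups
    if len(groups) < 2:
        raise MethtopoError("common_probes needs at least two groups")
    out = collection.get(groups[0], state)
    for g in groups[1:]:
        out &= collection.get(g, state)
    return out


def unique_probes(collection: StateSetCollection, group: str, state: str) -> frozenset[str]:
    """Probes in ``state`` only in ``group`` (setdiff against the rest's union)."""
    own = collection.get(group, state)
    others: set[str] = set()
    for g in collection.groups:
        if g != group:
            others |= collection.get(g, state)
    return own - others


def venn_counts(collection: StateSetCollection, state: str) -> dict[tuple[str, ...], int]:
    """Counts of every nonempty group-membership pattern for ``state``.

    Keys are tuples of member group names (in collection order); all
    2^k - 1 patterns are present, including zero-count ones.  Counts sum to
    the size of the union.  Guarded to at most 7 groups.
    """
    groups = collection.groups
    if len(groups) > VENN_MAX_GROUPS:
        raise MethtopoError(f"venn_counts supports at most {VENN_MAX_GROUPS} groups")
    membership: dict[str, tuple[str, ...]] = {}
    pattern_of: dict[str, list[str]] = {}
    for g in groups:
        for probe in collection.get(g, state):
            pattern_of.setdefault(probe, []).append(g)
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(groups) + 1):
        for combo in combinations(groups, r):
            counts[combo] = 0
    for members in pattern_of.values():
        counts[tuple(members)] += 1
    return counts


# ---------------------------------------------------------------------------
# Specificity table
# ---------------------------------------------------------------------------


def _round_half_up(value: Decimal, places: str) -> Decimal:
    return value.quantize(Decimal(places), rounding=ROUND_HALF_UP)


def percent_unique(unique: int, total: int) -> float | None:
    """100 * unique / total, rounded half-up to one decimal; None if total 0."""
    if total == 0:
        return None
    return float(_round_half_up(Decimal(100 * unique) / Decimal(total), "0.1"))


def specificity_summary(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-group specificity percents plus per-state average rows.

    ``counts`` needs columns ``group, state, total, unique`` (state in
    {hyper, hypo}).  The result appends, per state, an ``Average`` row whose
    total is the rounded-to-nearest mean of totals, whose unique is the exact
    mean of uniques, and whose percent is the rounded mean of the per-group
    rounded percents.  Percent arithmetic is exact rational, rounded half-up.
    """
    required = {"group", "state", "total", "unique"}
    if not required <= set(counts.columns):
        raise MethtopoError(f"counts frame needs columns {sorted(required)}")
    if (counts["unique"] > counts["total"]).any():
        raise MethtopoError("unique count exceeds total count")
    rows = []
    for state in ("hyper", "hypo"):
        block = counts[counts["state"] == state]
        if block.empty:
            continue
        pcts: list[Decimal] = []
        for rec in block.itertuples(index=False):
            pct = percent_unique(int(rec.unique), int(rec.total))
            rows.append((state, rec.group, int(rec.total), float(rec.unique), pct))
            if pct is not None:
                pcts.append(Decimal(str(pct)))
        k = len(block)
        avg_total = float(_round_half_up(Decimal(int(block["total"].sum())) / k, "1"))
        avg_unique = float(block["unique"].sum()) / k
        avg_pct = float(_round_half_up(sum(pcts) / len(pcts), "0.1")) if pcts else None
        rows.append((state, "Average", avg_total, avg_unique, avg_pct))
    return pd.DataFrame(
        rows, columns=["state", "group", "total", "unique", "pct_unique"]
    )


def specificity_table(collection: StateSetCollection) -> pd.DataFrame:
    """Specificity summary computed from a state-set collection."""
    rows = []
    for state in ("hyper", "hypo"):
        for group in collection.groups:
            total = len(collection.get(group, state))
            uniq = len(unique_probes(collection, group, state))
            rows.append((group, state, total, uniq))
    counts = pd.DataFrame(rows, columns=["group", "state", "total", "unique"])
    return specificity_summary(counts)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_specificity_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_venn_counts(
    counts: Mapping[tuple[str, ...], int], groups: Iterable[str], path
) -> None:
    """Write Venn pattern counts with one bitstring per pattern (group order)."""
    groups = list(groups)
    rows = []
    for pattern, count in counts.items():
        bits = "".join("1" if g in pattern else "0" for g in groups)
        rows.append((bits, ";".join(pattern), count))
    pd.DataFrame(rows, columns=["pattern", "groups", "count"]).to_csv(
        path, sep="\t", index=False
    )
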