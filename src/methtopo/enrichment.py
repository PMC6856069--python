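"""Hypergeometric over-representation analysis against gene-set collections.

The query is a deduplicated gene list derived from probes (optionally
restricted to one functional region); the universe is every gene on the
harmonized manifest; significance is the upper-tail hypergeometric
probability P(X >= k) with BH adjustment across sets.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .core import MethtopoError, ProbeManifest
from .diffmeth import bh_fdr

log = logging.getLogger(__name__)

GeneSets = Mapping[str, tuple[str, frozenset[str]]]


def probes_to_genes(
    probe_ids: Iterable[str], manifest: ProbeManifest, region: str | None = None
) -> list[str]:
    """Deduplicated, sorted gene symbols of the probes (optionally one region).

    With ``region`` set, only probes carrying that annotation contribute.
    """
    ids = pd.Index(probe_ids)
    sub = manifest.df.loc[ids]
    if region is not None:
        sub = sub[sub[region]] if region in sub.columns else sub.iloc[0:0]
    genes: set[str] = set()
    for g in sub["genes"]:
        genes.update(g)
    return sorted(genes)


def ora(
    query_genes: Sequence[str],
    gene_sets: GeneSets,
    universe: Sequence[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of each gene set.

    For a universe of N genes containing K set members, a query of n genes
    with k members overlapping the set scores p = P(X >= k), X ~
    Hypergeom(N, K, n).  Query genes outside the universe are dropped (count
    logged); set members are intersected with the universe; empty sets are
    dropped with a warning.  Results carry BH q-values and are sorted by
    (q, p, set_id).
    """
    universe_set = set(universe)
    if not universe_set:
        raise MethtopoError("empty gene universe")
    query = set(query_genes)
    outside = query - universe_set
    if outside:
        log.info("ora: dropping %d query genes outside the universe", len(outside))
        query &= universe_set
    N, n = len(universe_set), len(query)
    rows = []
    for set_id, (name, members) in gene_sets.items():
        members_in = frozenset(members) & universe_set
        if not members_in:
            log.warning("ora: gene set %s has no members in the universe; dropped", set_id)
            continue
        K = len(members_in)
        k = len(query & members_in)
        p = float(hypergeom.sf(k - 1, N, K, n)) if n else 1.0
        rows.append(
            (set_id, name, k, K, n, N, min(p, 1.0), k / n if n else np.nan)
        )
    out = pd.DataFrame(
        rows, columns=["set_id", "name", "k", "K", "n", "N", "p", "gene_ratio"]
    )
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
        out = out.sort_values(["q", "p", "set_id"], kind="mergesort").reset_index(drop=True)
    else:
        out["q"] = []
    return out
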