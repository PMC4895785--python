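"""Local over-representation analysis (ORA) of gene sets.

A one-sided hypergeometric tail test replaces web-service enrichment
tools: given a query gene list, a named collection (GMT-style), and a
gene universe, each set is tested for over-representation of the query
with P(X >= overlap), where X is hypergeometric with population
|universe|, successes |set ∩ universe| and draws |query|. Sets with
p < alpha are returned ranked by ascending p, with Benjamini–Hochberg
adjusted p-values alongside.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError

logger = logging.getLogger(__name__)


def hypergeometric_ora(
    query: Iterable[str],
    collection: dict[str, set[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank ``collection`` sets over-represented in ``query``.

    Returns a DataFrame (pathway, overlap, set_size, query_size,
    universe_size, p, adj_p) restricted to raw p < ``alpha``, sorted by
    ascending p (ties: pathway name). The BH adjustment runs over every
    tested set, not only the significant ones.
    """
    uni = set(universe)
    q = set(query)
    if not q:
        raise InputError("empty query gene set")
    stray = q - uni
    if stray:
        raise InputError(
            f"query genes outside the universe: {sorted(stray)[:10]}"
            + ("..." if len(stray) > 10 else "")
        )
    if not collection:
        raise InputError("empty gene-set collection")

    M, N = len(uni), len(q)
    rows = []
    for name in sorted(collection):
        members = collection[name] & uni
        if not members:
            logger.debug("set %s has no member inside the universe, skipped", name)
            continue
        n = len(members)
        k = len(members & q)
        p = float(stats.hypergeom.sf(k - 1, M, n, N))  # P(X >= k)
        rows.append((name, k, n, N, M, min(p, 1.0)))
    if not rows:
        raise InputError("no collection set intersects the universe")
    frame = pd.DataFrame(
        rows, columns=["pathway", "overlap", "set_size", "query_size", "universe_size", "p"]
    )
    frame["adj_p"] = multipletests(frame["p"].to_numpy(), method="fdr_bh")[1]
    frame = frame[frame["p"] < alpha].sort_values(["p", "pathway"]).reset_index(drop=True)
    return frame


def common_pathways(ml_enriched: pd.DataFrame, topo_enriched: pd.DataFrame) -> pd.DataFrame:
    """Pathways enriched on both key-gene routes, with both p-values.

    Rows carry ``p_M`` (ML route) and ``p_T`` (topology route) and are
    sorted by min(p_M, p_T). An empty intersection is a valid outcome.
    """
    merged = ml_enriched[["pathway", "p"]].merge(
        topo_enriched[["pathway", "p"]], on="pathway", suffixes=("_M", "_T")
    )
    merged = merged.rename(columns={"p_M": "p_M", "p_T": "p_T"})
    merged["min_p"] = merged[["p_M", "p_T"]].min(axis=1)
    merged = merged.sort_values(["min_p", "pathway"]).drop(columns="min_p")
    return merged.reset_index(drop=True)
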