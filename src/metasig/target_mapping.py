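"""Drug-target mapping and hub-neighbor analysis.

Screened common drugs are mapped to their known target genes; only the
targets that are also key genes are retained and prioritized by the number
of distinct common drugs hitting them. A second view ranks non-target PPI
nodes by how many retained targets they touch directly — the analysis that
singles out high-degree connector proteins (a UBC-like hub) adjacent to
most targets while being neither a key gene nor a target itself.
"""

from __future__ import annotations

import logging
from typing import Iterable

import networkx as nx
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)


def map_drug_targets(
    common_drugs: Iterable[str],
    targets: dict[str, set[str]],
    key_genes: Iterable[str],
) -> pd.DataFrame:
    """Retain key-gene targets of the common drugs, ranked by drug count.

    Returns a DataFrame (gene, n_drugs, drugs) sorted descending by the
    number of distinct associated drugs, ties broken by gene id. Drugs
    missing from the target table are logged and skipped.
    """
    keys = set(key_genes)
    counts: dict[str, set[str]] = {}
    for drug in sorted(set(common_drugs)):
        if drug not in targets:
            logger.info("drug %s absent from the target table, skipped", drug)
            continue
        for gene in targets[drug]:
            if gene in keys:
                counts.setdefault(gene, set()).add(drug)
    rows = sorted(counts.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return pd.DataFrame(
        [(g, len(ds), ",".join(sorted(ds))) for g, ds in rows],
        columns=["gene", "n_drugs", "drugs"],
    )


def rank_hub_neighbors(
    target_genes: Iterable[str],
    ppi: nx.Graph,
    top_k: int = 3,
) -> tuple[pd.DataFrame, nx.Graph]:
    """Rank non-target nodes by the number of target genes they touch.

    The ``rank`` column numbers the ``top_k`` largest *distinct* counts
    (rank 1 = most adjacent targets); several nodes may share a rank. Nodes
    that are themselves targets are never ranked. Also returns the subgraph
    induced by the targets plus the ranked neighbors, for plotting.
    """
    tset = set(target_genes)
    if not tset:
        raise InputError("no target genes supplied")
    present = tset & set(ppi.nodes)
    missing = tset - present
    if missing:
        logger.info("%d target(s) absent from the PPI network", len(missing))

    counts: dict[str, int] = {}
    for t in present:
        for u in ppi.neighbors(t):
            if u not in tset:
                counts[u] = counts.get(u, 0) + 1
    if not counts:
        logger.warning("no node is adjacent to any target gene")
        return (
            pd.DataFrame(columns=["gene", "n_targets", "rank"]),
            ppi.subgraph(present).copy(),
        )

    distinct = sorted(set(counts.values()), reverse=True)[:top_k]
    rank_of = {c: i + 1 for i, c in enumerate(distinct)}
    rows = [
        (g, c, rank_of[c])
        for g, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if c in rank_of
    ]
    frame = pd.DataFrame(rows, columns=["gene", "n_targets", "rank"])
    sub = ppi.subgraph(present | set(frame["gene"])).copy()
    return frame, sub
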