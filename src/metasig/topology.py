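"""Topological key-gene selection on regulated PPI sub-networks.

The up- (down-) regulated network is the PPI subgraph induced by the
common DEGs of all datasets plus their first neighbors. Every node is
scored on eight topological parameters arranged in five groups:

    group 1  degree centrality
    group 2  betweenness centrality (shortest-path, unnormalized)
    group 3  bridging centrality = betweenness x bridging coefficient
    group 4  closeness centrality (harmonic) and eccentricity centrality
    group 5  clustering coefficient, brokering coefficient,
             local average connectivity (LAC)

For each parameter, the DEG nodes ranking in the top ``top_frac`` (default
20%, boundary ties included) receive one point; within each group the DEGs
attaining the group's maximum positive score are the group winners, and
the key genes are the union of winners over the five groups. Neighbor
(non-DEG) nodes shape the metric values but are never ranked or selected.

Metric conventions (disconnected networks are allowed):

* harmonic closeness  sum over reachable u of 1/d(v,u);
* eccentricity centrality  1/ecc(v) within v's connected component
  (0 for isolated nodes);
* bridging coefficient  BC(v) = (1/deg v) / sum over neighbors u of 1/deg u;
* brokering coefficient  (1 - CC(v)) * deg(v) / (n - 1);
* LAC  mean degree of N(v) inside the subgraph induced by N(v).

All eight metrics are oriented so that larger means topologically more
important.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

PARAMETERS = (
    "degree",
    "betweenness",
    "bridging_centrality",
    "closeness",
    "eccentricity_centrality",
    "clustering",
    "brokering",
    "lac",
)

GROUPS: dict[int, tuple[str, ...]] = {
    1: ("degree",),
    2: ("betweenness",),
    3: ("bridging_centrality",),
    4: ("closeness", "eccentricity_centrality"),
    5: ("clustering", "brokering", "lac"),
}


@dataclass
class TopoScoreCard:
    node: str
    is_deg: bool
    values: dict[str, float]  # one entry per PARAMETERS name
    group_scores: dict[int, int] = field(default_factory=dict)
    selected: bool = False


def build_regulated_network(
    common_degs: Iterable[str], ppi: nx.Graph
) -> tuple[nx.Graph, set[str]]:
    """Subgraph induced by the common DEGs plus all their first neighbors.

    Returns ``(network, deg_nodes)`` where ``deg_nodes`` are the DEGs that
    mapped into the PPI; DEGs absent from the PPI are excluded and logged.
    """
    if ppi.number_of_nodes() == 0:
        raise InputError("the PPI network is empty")
    degs = set(common_degs)
    present = degs & set(ppi.nodes)
    missing = degs - present
    if missing:
        logger.info("%d DEG(s) absent from the PPI network, excluded", len(missing))
    if not present:
        raise InputError("no common DEG maps into the PPI network")
    nodes = set(present)
    for g in present:
        nodes.update(ppi.neighbors(g))
    sub = ppi.subgraph(nodes).copy()
    return sub, present


def _bridging_coefficient(net: nx.Graph, v) -> float:
    d = net.degree(v)
    if d == 0:
        return 0.0
    denom = sum(1.0 / net.degree(u) for u in net.neighbors(v))
    return (1.0 / d) / denom if denom > 0 else 0.0


def _local_average_connectivity(net: nx.Graph, v) -> float:
    nbrs = list(net.neighbors(v))
    if not nbrs:
        return 0.0
    sub = net.subgraph(nbrs)
    return sum(dict(sub.degree).values()) / len(nbrs)


def compute_topological_parameters(
    net: nx.Graph, deg_nodes: Iterable[str] = ()
) -> list[TopoScoreCard]:
    """Fill the eight parameter values for every node of ``net``."""
    if net.number_of_nodes() < 2:
        raise InputError("topological scoring needs a network with >= 2 nodes")
    deg_set = set(deg_nodes)
    n = net.number_of_nodes()

    degree = dict(net.degree)
    betweenness = nx.betweenness_centrality(net, normalized=False)
    closeness = nx.harmonic_centrality(net)
    clustering = nx.clustering(net)

    ecc_cent: dict = {}
    for comp in nx.connected_components(net):
        if len(comp) == 1:
            node = next(iter(comp))
            ecc_cent[node] = 0.0  # isolated: distance-based metrics 0 by convention
            logger.debug("isolated node %s: distance-based metrics set to 0", node)
            continue
        ecc = nx.eccentricity(net.subgraph(comp))
        for node, e in ecc.items():
            ecc_cent[node] = 1.0 / e if e > 0 else 0.0

    cards = []
    for v in net.nodes:
        bc = _bridging_coefficient(net, v)
        values = {
            "degree": float(degree[v]),
            "betweenness": float(betweenness[v]),
            "bridging_centrality": float(betweenness[v] * bc),
            "closeness": float(closeness[v]),
            "eccentricity_centrality": float(ecc_cent[v]),
            "clustering": float(clustering[v]),
            "brokering": float((1.0 - clustering[v]) * degree[v] / (n - 1)),
            "lac": float(_local_average_connectivity(net, v)),
        }
        cards.append(TopoScoreCard(node=v, is_deg=v in deg_set, values=values))
    return cards


def score_and_select_key_genes(
    cards: list[TopoScoreCard],
    top_frac: float = 0.2,
    rank_pool: str = "deg",
    group_winner_rule: str = "full",
) -> tuple[set[str], dict[int, set[str]]]:
    """Score DEG nodes per parameter and select the key genes.

    Per parameter, the top ``ceil(top_frac * pool size)`` DEGs earn one
    point, with all ties at the boundary value included. Per group, the
    DEGs with the highest score are winners and the key genes are the union
    of group winners. ``group_winner_rule`` fixes what "highest" means in a
    multi-parameter group: ``"full"`` (default) requires the maximal
    attainable score — one point from every parameter of the group — which
    makes the selection monotone in ``top_frac`` (a key gene at the top 10%
    is still one at 20%); ``"max"`` takes the attainers of the maximum
    *observed* positive score, which can drop genes as the quantile widens
    and is provided for comparison only. The two rules coincide on the
    single-parameter groups 1-3.

    ``rank_pool`` chooses whether the ranking pool holds DEG nodes only
    (default) or the full network (``"all"``) — DEG nodes remain the only
    selectable ones either way.

    Mutates ``cards`` in place (group scores and selection flags) and
    returns ``(key_genes, winners_per_group)``.
    """
    if not 0.0 < top_frac <= 1.0:
        raise ConfigurationError("top_frac must lie in (0, 1]")
    if rank_pool not in ("deg", "all"):
        raise ConfigurationError("rank_pool must be 'deg' or 'all'")
    if group_winner_rule not in ("full", "max"):
        raise ConfigurationError("group_winner_rule must be 'full' or 'max'")
    deg_cards = [c for c in cards if c.is_deg]
    if not deg_cards:
        raise InputError("no DEG node to rank")
    pool = deg_cards if rank_pool == "deg" else cards

    points: dict[str, set[str]] = {}
    k = math.ceil(top_frac * len(pool))
    for param in PARAMETERS:
        vals = sorted((c.values[param] for c in pool), reverse=True)
        threshold = vals[k - 1]
        # boundary ties all included; only DEGs can earn a point
        points[param] = {
            c.node for c in deg_cards if c.values[param] >= threshold
        }

    winners: dict[int, set[str]] = {}
    for gid, params in GROUPS.items():
        for c in cards:
            c.group_scores[gid] = sum(c.node in points[p] for p in params) if c.is_deg else 0
        if group_winner_rule == "full":
            best = len(params)
        else:
            best = max((c.group_scores[gid] for c in deg_cards), default=0)
        winners[gid] = (
            {c.node for c in deg_cards if c.group_scores[gid] == best} if best > 0 else set()
        )

    key_genes = set().union(*winners.values())
    for c in cards:
        c.selected = c.node in key_genes
    return key_genes, winners


def cards_to_frame(cards: list[TopoScoreCard]) -> pd.DataFrame:
    rows = []
    for c in cards:
        row = {"node": c.node, "is_deg": c.is_deg, **c.values}
        for gid in GROUPS:
            row[f"S{gid}"] = c.group_scores.get(gid, 0)
        row["selected"] = c.selected
        rows.append(row)
    return pd.DataFrame(rows).set_index("node")
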