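"""Interaction graph construction, centralities and hub screening.

Edge lists are cleaned into a simple undirected graph (duplicate rows and
self-interactions dropped).  Three node centralities are computed on the
unweighted graph: raw degree, betweenness (pairwise shortest-path counting,
each unordered pair counted once, unnormalized) and closeness with
within-component normalization r_v / sum(d(v, u)) over reachable vertices
(an isolated node has closeness 0).  Hub screening takes a gene subset,
induces its subgraph, and flags nodes whose degree reaches the top-fraction
nearest-rank quantile of subgraph degrees (ties included).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from tsgkit._util import nearest_rank_quantile
from tsgkit.formats import EdgeList

logger = logging.getLogger(__name__)


@dataclass
class InteractionGraph:
    """Simple undirected gene graph plus counts of cleaned input rows."""

    graph: nx.Graph
    n_self_dropped: int = 0
    n_duplicate_dropped: int = 0

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_graph(edges: EdgeList, min_score: float | None = None) -> InteractionGraph:
    """Clean an edge list into a simple undirected graph.

    (a, b) and (b, a) are merged, self-edges dropped, and duplicates
    counted.  ``min_score`` optionally filters scored rows (rows without a
    score always pass); scores are kept as edge attributes but ignored for
    topology.
    """
    g = nx.Graph()
    n_self = n_dup = 0
    df = edges.df
    for a, b, score in zip(df["gene_a"], df["gene_b"], df["score"]):
        if min_score is not None and np.isfinite(score) and score < min_score:
            continue
        if a == b:
            n_self += 1
            continue
        if g.has_edge(a, b):
            n_dup += 1
            continue
        g.add_edge(a, b, score=score)
    if n_self or n_dup:
        logger.info("dropped %d self-interactions, %d duplicate rows", n_self, n_dup)
    return InteractionGraph(g, n_self, n_dup)


def centralities(graph) -> pd.DataFrame:
    """Degree, betweenness and closeness per node, sorted by node id."""
    g = graph.graph if isinstance(graph, InteractionGraph) else graph
    deg = dict(g.degree())
    btw = nx.betweenness_centrality(g, normalized=False)
    clo = nx.closeness_centrality(g, wf_improved=False)
    nodes = sorted(g.nodes())
    df = pd.DataFrame(
        {
            "degree": [int(deg[v]) for v in nodes],
            "betweenness": [float(btw[v]) for v in nodes],
            "closeness": [float(clo[v]) for v in nodes],
        },
        index=pd.Index(nodes, name="gene_id"),
    )
    return df


@dataclass
class HubResult:
    """Hub genes of a gene-set-induced subgraph."""

    hubs: list[str]
    degree_threshold: float
    table: pd.DataFrame  # centralities within the induced subgraph
    n_missing_nodes: int = 0
    degenerate: bool = False


def hub_screen(graph, nodes, top_frac: float = 0.05) -> HubResult:
    """Screen hub genes within the subgraph induced by ``nodes``.

    Centralities and the degree threshold are computed on the induced
    subgraph, not the full background graph.  Hubs are nodes whose degree
    is at or above the (1 - top_frac) nearest-rank quantile of subgraph
    degrees; ties at the threshold are included.
    """
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must be in (0, 1]")
    g = graph.graph if isinstance(graph, InteractionGraph) else graph
    wanted = list(dict.fromkeys(nodes))
    present = [v for v in wanted if v in g]
    n_missing = len(wanted) - len(present)
    if n_missing:
        logger.warning("%d requested genes absent from the graph", n_missing)
    if not present:
        logger.warning("empty induced subgraph; no hubs")
        return HubResult([], float("nan"), pd.DataFrame(), n_missing)
    sub = g.subgraph(present)
    table = centralities(sub)
    degrees = table["degree"].to_numpy(dtype=float)
    threshold = nearest_rank_quantile(degrees, 1.0 - top_frac)
    hubs = sorted(table.index[table["degree"] >= threshold])
    degenerate = len(hubs) == len(table)
    if degenerate:
        logger.warning("degenerate hub screen: every node meets the threshold")
    return HubResult(hubs, threshold, table, n_missing, degenerate)
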