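"""Threshold correlation matrices into binary graphs and measure them.

A functional network keeps an edge between two regions iff their correlation is
positive and its p-value falls strictly below the threshold.  All node- and
graph-level measures follow the conventions of brain connectivity analysis:

* active node: degree >= 1; isolated regions are excluded from centrality
  normalisation, path-length averaging and null-model matching;
* betweenness: fraction of shortest paths, normalised by (N-1)(N-2)/2 over
  active nodes;
* characteristic path length: mean shortest path over reachable pairs only
  (thresholded networks are routinely disconnected);
* small-worldness: S = (T / <T_ER>) / (L / <L_ER>) against G(n, m) graphs
  matched on active-node and edge counts (100 draws by default).

Graph computations are delegated to networkx; Markov clustering lives in
:mod:`fosnet.mcl`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import GroupCorrelationMatrix
from .ingest import ValidationError
from .mcl import ClusterAssignment, markov_cluster

__all__ = [
    "FunctionalNetwork", "CentralityTable", "GraphSummary",
    "threshold_network", "degree", "betweenness", "centrality_table",
    "transitivity", "assortativity", "char_path_length", "small_worldness",
    "modularity", "select_inflation", "summarize",
    "DEFAULT_INFLATION_GRID", "markov_cluster", "ClusterAssignment",
]

#: Inflation values scanned when tuning MCL by modularity.
DEFAULT_INFLATION_GRID: tuple[float, ...] = tuple(
    np.round(np.arange(1.1, 3.0 + 1e-9, 0.1), 1))


@dataclass
class FunctionalNetwork:
    """Binary undirected graph over regions plus the threshold that made it."""

    adjacency: pd.DataFrame  # 0/1, symmetric, zero diagonal
    threshold_p: float | None = None
    group: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        a = self.adjacency.to_numpy()
        if not np.array_equal(a, a.T):
            raise ValidationError("adjacency must be symmetric")
        if np.diag(a).any():
            raise ValidationError("adjacency must have a zero diagonal")

    @property
    def region_order(self) -> list[str]:
        return list(self.adjacency.columns)

    @property
    def degrees(self) -> pd.Series:
        return self.adjacency.sum(axis=1).astype(int)

    @property
    def active_nodes(self) -> list[str]:
        d = self.degrees
        return list(d.index[d > 0])

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.to_numpy().sum() // 2)

    def to_networkx(self, active_only: bool = True) -> nx.Graph:
        g = nx.Graph()
        nodes = self.active_nodes if active_only else self.region_order
        g.add_nodes_from(nodes)
        a = self.adjacency
        idx = np.argwhere(np.triu(a.to_numpy(), k=1) > 0)
        g.add_edges_from((a.index[i], a.columns[j]) for i, j in idx)
        return g

    @classmethod
    def from_graph(cls, g: nx.Graph, region_order=None, threshold_p=None,
                   group=None) -> "FunctionalNetwork":
        order = list(region_order) if region_order is not None else list(g.nodes)
        a = pd.DataFrame(0, index=order, columns=order, dtype=np.int8)
        for u, v in g.edges:
            a.loc[u, v] = 1
            a.loc[v, u] = 1
        return cls(adjacency=a, threshold_p=threshold_p, group=group)

    def edge_list(self) -> list[tuple[str, str]]:
        a = self.adjacency
        idx = np.argwhere(np.triu(a.to_numpy(), k=1) > 0)
        return [(a.index[i], a.columns[j]) for i, j in idx]


def threshold_network(corr: GroupCorrelationMatrix,
                      p_thresh: float = 0.05) -> FunctionalNetwork:
    """Edge iff r > 0 and p < p_thresh (strict); undefined entries are non-edges."""
    if not 0 < p_thresh < 1:
        raise ValidationError(f"p_thresh must be in (0, 1), got {p_thresh}")
    r = corr.r.to_numpy()
    p = corr.p.to_numpy()
    with np.errstate(invalid="ignore"):
        adj = (r > 0) & (p < p_thresh)
    adj &= ~np.isnan(r) & ~np.isnan(p)
    np.fill_diagonal(adj, False)
    adjacency = pd.DataFrame(adj.astype(np.int8), index=corr.r.index,
                             columns=corr.r.columns)
    return FunctionalNetwork(adjacency=adjacency, threshold_p=p_thresh,
                             group=corr.group)


# ---------------------------------------------------------------------------
# Node-level measures
# ---------------------------------------------------------------------------

def degree(net: FunctionalNetwork) -> pd.Series:
    """Edge count per region (all regions, zeros included)."""
    return net.degrees


def betweenness(net: FunctionalNetwork) -> pd.Series:
    """Normalised betweenness centrality over active nodes."""
    g = net.to_networkx(active_only=True)
    bc = nx.betweenness_centrality(g, normalized=True)
    return pd.Series(bc, dtype=float).reindex(net.active_nodes)


@dataclass
class CentralityTable:
    """Degree and betweenness with descending ranks, active nodes only."""

    frame: pd.DataFrame  # columns: degree, betweenness, rank_degree, rank_betweenness
    group: tuple[str, str] | None = None
    threshold_p: float | None = None

    @property
    def nodes(self) -> list[str]:
        return list(self.frame.index)


def centrality_table(net: FunctionalNetwork) -> CentralityTable:
    d = degree(net)
    active = d.index[d > 0]
    frame = pd.DataFrame({
        "degree": d.loc[active],
        "betweenness": betweenness(net),
    })
    frame["rank_degree"] = frame["degree"].rank(ascending=False, method="min").astype(int)
    frame["rank_betweenness"] = frame["betweenness"].rank(ascending=False, method="min").astype(int)
    return CentralityTable(frame=frame, group=net.group, threshold_p=net.threshold_p)


# ---------------------------------------------------------------------------
# Graph-level measures
# ---------------------------------------------------------------------------

def _graph_transitivity(g: nx.Graph) -> float:
    triples = sum(d * (d - 1) for _, d in g.degree) / 2
    if triples == 0:
        return math.nan
    return float(nx.transitivity(g))


def transitivity(net: FunctionalNetwork) -> float:
    """3 x triangles / connected triples; NaN when no triples exist."""
    return _graph_transitivity(net.to_networkx())


def assortativity(net: FunctionalNetwork) -> float:
    """Pearson correlation of endpoint degrees; NaN on degree-regular graphs."""
    g = net.to_networkx()
    if g.number_of_edges() == 0:
        return math.nan
    degs = [d for _, d in g.degree]
    if len(set(degs)) == 1:
        return math.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        val = nx.degree_assortativity_coefficient(g)
    return float(val) if np.isfinite(val) else math.nan


def _graph_cpl(g: nx.Graph) -> float:
    active = [n for n, d in g.degree if d > 0]
    sub = g.subgraph(active)
    total, pairs = 0.0, 0
    for comp in nx.connected_components(sub):
        comp = list(comp)
        if len(comp) < 2:
            continue
        lengths = dict(nx.all_pairs_shortest_path_length(sub.subgraph(comp)))
        for u in comp:
            for v, dist in lengths[u].items():
                if u != v:
                    total += dist
                    pairs += 1
    if pairs == 0:
        return math.nan
    return total / pairs


def char_path_length(net: FunctionalNetwork) -> float:
    """Mean shortest-path length over reachable active pairs; NaN if none."""
    return _graph_cpl(net.to_networkx())


def small_worldness(net: FunctionalNetwork, n_random: int = 100,
                    seed: int | None = None,
                    rng: np.random.Generator | None = None) -> float:
    """S = (T/<T_ER>)/(L/<L_ER>) against G(n, m) matched on active nodes/edges."""
    g = net.to_networkx()
    n, m = g.number_of_nodes(), g.number_of_edges()
    t_data = _graph_transitivity(g)
    l_data = _graph_cpl(g)
    if not (np.isfinite(t_data) and np.isfinite(l_data)) or n < 2:
        return math.nan
    rng = rng if rng is not None else np.random.default_rng(seed)
    t_vals, l_vals = [], []
    for _ in range(n_random):
        er = nx.gnm_random_graph(n, m, seed=int(rng.integers(2 ** 31)))
        t = _graph_transitivity(er)
        l = _graph_cpl(er)
        if np.isfinite(t):
            t_vals.append(t)
        if np.isfinite(l):
            l_vals.append(l)
    if not t_vals or not l_vals:
        return math.nan
    t_er = float(np.mean(t_vals))
    l_er = float(np.mean(l_vals))
    if t_er == 0 or l_er == 0:
        return math.nan
    return (t_data / t_er) / (l_data / l_er)


def modularity(net: FunctionalNetwork, assignment: ClusterAssignment) -> float:
    """Newman-Girvan Q = sum_c (e_cc - a_c^2) of a partition of active nodes."""
    g = net.to_networkx()
    labels = assignment.labels
    communities = [set(labels.index[labels == c]) for c in sorted(labels.unique())]
    if g.number_of_edges() == 0:
        return math.nan
    return float(nx.algorithms.community.modularity(g, communities))


def select_inflation(net: FunctionalNetwork,
                     grid=DEFAULT_INFLATION_GRID) -> ClusterAssignment:
    """Run MCL across an inflation grid; keep the partition maximising Q.

    Ties in Q resolve to the smallest inflation.  The returned assignment
    carries both the winning inflation and its modularity.
    """
    grid = list(grid)
    if not grid:
        raise ValidationError("empty inflation grid")
    best: ClusterAssignment | None = None
    for inflation in grid:
        assignment = markov_cluster(net, inflation=inflation)
        assignment.modularity_q = modularity(net, assignment)
        q = assignment.modularity_q
        if best is None or (np.isfinite(q) and
                            (not np.isfinite(best.modularity_q) or q > best.modularity_q)):
            best = assignment
    return best


@dataclass
class GraphSummary:
    """Whole-graph measures for one thresholded network."""

    n_active_nodes: int
    n_edges: int
    transitivity: float
    assortativity: float
    char_path_length: float
    small_worldness: float
    threshold_p: float | None = None
    group: tuple[str, str] | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "n_active_nodes", "n_edges", "transitivity", "assortativity",
            "char_path_length", "small_worldness", "threshold_p")}


def summarize(net: FunctionalNetwork, n_random: int = 100,
              seed: int | None = None,
              include_small_world: bool = True) -> GraphSummary:
    sw = small_worldness(net, n_random=n_random, seed=seed) \
        if include_small_world else math.nan
    return GraphSummary(
        n_active_nodes=len(net.active_nodes),
        n_edges=net.n_edges,
        transitivity=transitivity(net),
        assortativity=assortativity(net),
        char_path_length=char_path_length(net),
        small_worldness=sw,
        threshold_p=net.threshold_p,
        group=net.group,
    )
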