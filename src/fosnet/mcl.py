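"""Markov clustering (MCL) on binary functional networks.

MCL simulates random-walk flow on the graph and alternates two operators until
the flow matrix reaches a fixed point: *expansion* (matrix squaring, spreading
flow along walks) and *inflation* (elementwise power followed by column
renormalisation, sharpening strong flows at the expense of weak ones).  At
convergence the matrix is a union of star-like "attractor" systems whose rows
read out the clusters.  The inflation exponent controls granularity: higher
inflation yields more, smaller clusters.

Conventions used here: self-loops of weight 1 are added before normalisation;
expansion power 2; entries below 1e-10 are pruned each iteration; convergence
is declared when the largest elementwise change falls below 1e-8 (hard stop at
200 iterations); a node supported by several attractor systems is assigned to
the largest cluster, ties to the lowest cluster index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .ingest import ValidationError

__all__ = ["ClusterAssignment", "MCLConvergenceError", "markov_cluster"]


class MCLConvergenceError(RuntimeError):
    """MCL failed to reach a fixed point within the iteration budget."""


@dataclass
class ClusterAssignment:
    """Cluster id per active node, with the inflation that produced it."""

    labels: pd.Series  # node -> int cluster id (0..C-1)
    inflation: float
    n_iterations: int
    modularity_q: float = field(default=float("nan"))

    @property
    def n_clusters(self) -> int:
        return int(self.labels.nunique()) if len(self.labels) else 0

    def members(self, cluster: int) -> list:
        return list(self.labels.index[self.labels == cluster])


def _to_matrix(net) -> tuple[np.ndarray, list]:
    """Accept FunctionalNetwork, nx.Graph, DataFrame or ndarray."""
    if hasattr(net, "adjacency") and hasattr(net, "active_nodes"):
        nodes = net.active_nodes
        a = net.adjacency.loc[nodes, nodes].to_numpy(dtype=float)
        return a, list(nodes)
    if isinstance(net, nx.Graph):
        nodes = [n for n, d in net.degree if d > 0]
        return nx.to_numpy_array(net, nodelist=nodes), nodes
    if isinstance(net, pd.DataFrame):
        return net.to_numpy(dtype=float), list(net.columns)
    a = np.asarray(net, dtype=float)
    return a, list(range(a.shape[0]))


def markov_cluster(net, inflation: float = 2.0, max_iter: int = 200,
                   tol: float = 1e-8, prune: float = 1e-10,
                   self_loop: float = 1.0) -> ClusterAssignment:
    """Cluster the active nodes of a network by MCL.

    Parameters
    ----------
    net : FunctionalNetwork, nx.Graph, DataFrame or array
        Undirected (symmetric) binary or weighted adjacency.
    inflation : float
        Inflation exponent, must exceed 1.
    max_iter, tol, prune, self_loop
        Iteration budget, fixed-point tolerance, per-iteration pruning
        threshold, and the self-loop weight added to the diagonal.

    Raises
    ------
    MCLConvergenceError
        If the flow matrix has not converged after ``max_iter`` iterations.
    """
    if not inflation > 1:
        raise ValidationError(f"inflation must be > 1, got {inflation}")
    a, nodes = _to_matrix(net)
    if a.shape[0] == 0:
        return ClusterAssignment(labels=pd.Series(dtype=int), inflation=inflation,
                                 n_iterations=0)
    m = a + self_loop * np.eye(a.shape[0])
    m = m / m.sum(axis=0, keepdims=True)

    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        new = m @ m                      # expansion
        np.power(new, inflation, out=new)  # inflation
        new[new < prune] = 0.0
        new /= new.sum(axis=0, keepdims=True)
        diff = np.abs(new - m).max()
        m = new
        if diff < tol:
            break
    else:
        raise MCLConvergenceError(
            f"MCL did not converge within {max_iter} iterations (inflation={inflation})")

    return ClusterAssignment(labels=_read_clusters(m, nodes, prune),
                             inflation=float(inflation), n_iterations=n_iter)


def _read_clusters(m: np.ndarray, nodes: list, prune: float) -> pd.Series:
    """Read cluster memberships from the converged flow matrix.

    Attractors are rows with positive diagonal mass; each attractor row's
    support is one (possibly overlapping) cluster.  Duplicate supports are
    merged; overlapping membership goes to the largest cluster, ties broken
    toward the lowest cluster index.
    """
    n = m.shape[0]
    attractors = [i for i in range(n) if m[i, i] > prune]
    clusters: list[frozenset[int]] = []
    for i in attractors:
        support = frozenset(np.flatnonzero(m[i] > prune))
        if support and support not in clusters:
            clusters.append(support)
    # safety net for columns no attractor claims (should not occur at a fixed point)
    claimed = set().union(*clusters) if clusters else set()
    for j in range(n):
        if j not in claimed:
            owner = int(np.argmax(m[:, j]))
            clusters.append(frozenset({owner, j}))
            claimed.update({owner, j})

    labels = np.full(n, -1, dtype=int)
    order = np.argsort([-len(c) for c in clusters], kind="stable")
    for rank in order:  # larger clusters claim first; earlier index wins ties
        for j in clusters[rank]:
            if labels[j] == -1:
                labels[j] = rank
    # relabel 0..C-1 in order of each cluster's smallest member
    firsts = {}
    for j in range(n):
        firsts.setdefault(labels[j], j)
    relabel = {old: new for new, old in
               enumerate(sorted(firsts, key=firsts.get))}
    labels = np.array([relabel[l] for l in labels])
    return pd.Series(labels, index=pd.Index(nodes))
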