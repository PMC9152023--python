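"""Independent brute-force oracles for graph measures and the 2x2 ANOVA.

Everything here is written from the definitions (Floyd-Warshall distances,
explicit path counting, triple/triangle enumeration, design-matrix least
squares) and deliberately shares no code path with the package, which uses
networkx and statsmodels internally.
"""

from __future__ import annotations

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    dist = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def shortest_path_counts(adj: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """sigma[s, t] = number of distinct shortest s-t paths."""
    n = adj.shape[0]
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        order = np.argsort(dist[s])
        for t in order:
            if t == s or not np.isfinite(dist[s, t]):
                continue
            preds = [u for u in range(n)
                     if adj[u, t] and dist[s, u] == dist[s, t] - 1]
            sigma[s, t] = sum(sigma[s, u] for u in preds)
    return sigma


def brute_betweenness(adj: np.ndarray, normalized: bool = True) -> np.ndarray:
    """Betweenness over active nodes by explicit pair-dependency summation."""
    n = adj.shape[0]
    dist = floyd_warshall(adj)
    sigma = shortest_path_counts(adj, dist)
    bc = np.zeros(n)
    for v in range(n):
        for s in range(n):
            for t in range(s + 1, n):
                if v in (s, t) or not np.isfinite(dist[s, t]):
                    continue
                if dist[s, v] + dist[v, t] == dist[s, t] and sigma[s, t] > 0:
                    bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    if normalized:
        active = adj.sum(axis=1) > 0
        m = int(active.sum())
        if m > 2:
            bc = bc / ((m - 1) * (m - 2) / 2.0)
    return bc


def brute_transitivity(adj: np.ndarray) -> float:
    n = adj.shape[0]
    triangles = 0
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                if adj[i, j] and adj[j, k] and adj[i, k]:
                    triangles += 1
    deg = adj.sum(axis=1)
    triples = float(np.sum(deg * (deg - 1) / 2.0))
    if triples == 0:
        return float("nan")
    return 3.0 * triangles / triples


def brute_assortativity(adj: np.ndarray) -> float:
    deg = adj.sum(axis=1)
    xs, ys = [], []
    n = adj.shape[0]
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                xs.append(deg[i])
                ys.append(deg[j])
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    if xs.size == 0 or xs.std() == 0 or ys.std() == 0:
        return float("nan")
    return float(np.corrcoef(xs, ys)[0, 1])


def brute_char_path_length(adj: np.ndarray) -> float:
    active = adj.sum(axis=1) > 0
    dist = floyd_warshall(adj)[np.ix_(active, active)]
    off = dist[~np.eye(dist.shape[0], dtype=bool)]
    finite = off[np.isfinite(off)]
    if finite.size == 0:
        return float("nan")
    return float(finite.mean())


def brute_modularity(adj: np.ndarray, labels: np.ndarray) -> float:
    """Newman-Girvan Q from the definition: sum_c (e_cc - a_c^2)."""
    m2 = float(adj.sum())  # 2 * number of edges
    if m2 == 0:
        return float("nan")
    q = 0.0
    for c in np.unique(labels):
        in_c = labels == c
        e_cc = adj[np.ix_(in_c, in_c)].sum() / m2
        a_c = adj[in_c, :].sum() / m2
        q += e_cc - a_c ** 2
    return q


def reference_mcl_partition(adj: np.ndarray, inflation: float = 2.0,
                            n_iter: int = 300) -> set[frozenset[int]]:
    """Straightforward dense MCL, coded separately: returns the partition.

    Column-stochastic flow with self-loops; fixed iteration count (no pruning,
    no convergence shortcut); clusters read as connected row-supports.
    """
    n = adj.shape[0]
    m = adj.astype(float) + np.eye(n)
    m = m / m.sum(axis=0)
    for _ in range(n_iter):
        m = m @ m
        m = m ** inflation
        m = m / m.sum(axis=0)
    clusters: list[set[int]] = []
    for i in range(n):
        if m[i, i] <= 1e-8:
            continue
        support = set(np.flatnonzero(m[i] > 1e-8))
        merged = False
        for c in clusters:
            if c & support:
                c |= support
                merged = True
                break
        if not merged:
            clusters.append(support)
    return {frozenset(c) for c in clusters}


def brute_anova_type3(y: np.ndarray, female: np.ndarray,
                      trained: np.ndarray) -> dict:
    """Type III 2x2 ANOVA by extra sum of squares on effect-coded least squares."""
    s = np.where(female, 1.0, -1.0)
    c = np.where(trained, 1.0, -1.0)
    X = np.column_stack([np.ones_like(s), s, c, s * c])

    def rss(mat):
        beta, *_ = np.linalg.lstsq(mat, y, rcond=None)
        resid = y - mat @ beta
        return float(resid @ resid)

    rss_full = rss(X)
    df_error = len(y) - 4
    mse = rss_full / df_error
    out = {"mse": mse, "df_error": df_error}
    for name, col in (("sex", 1), ("training", 2), ("interaction", 3)):
        reduced = np.delete(X, col, axis=1)
        out[f"F_{name}"] = (rss(reduced) - rss_full) / mse
    return out
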