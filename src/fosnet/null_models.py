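"""Degree-preserving null networks and threshold-robustness sweeps.

Low per-group sample sizes make thresholded edges individually unreliable, so
graph-level structure is judged against randomized controls: each data network
is rewired by repeated double-edge swaps, which shuffle the connections while
keeping every node's degree (hence active-node count, edge count and degree
distribution) exactly fixed.  Ensembles of such replicates provide null
distributions of transitivity, assortativity and small-worldness, and a sweep
over p-value thresholds (20 values from 0.005 to 0.1 by default) checks that
any data-vs-null separation is not an artifact of one particular threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import GroupCorrelationMatrix
from .ingest import ValidationError
from .network_metrics import (FunctionalNetwork, assortativity,
                              small_worldness, threshold_network,
                              transitivity)

__all__ = ["NullEnsemble", "rewire_preserving_degree", "build_null_ensemble",
           "empirical_quantile", "threshold_sweep", "DEFAULT_P_GRID",
           "DEFAULT_SWAPS_PER_EDGE"]

#: 20 evenly spaced thresholds from p < 0.005 to p < 0.1 (step 0.005).
DEFAULT_P_GRID: tuple[float, ...] = tuple(np.round(np.linspace(0.005, 0.1, 20), 4))

#: Attempted double-edge swaps per edge (Maslov-Sneppen convention).
DEFAULT_SWAPS_PER_EDGE = 10

MEASURES = {
    "transitivity": transitivity,
    "assortativity": assortativity,
    "small_worldness": None,  # needs rng; handled specially
}


def rewire_preserving_degree(net: FunctionalNetwork,
                             swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
                             seed: int | None = None,
                             rng: np.random.Generator | None = None,
                             ) -> FunctionalNetwork:
    """Randomize edges by double-edge swaps; every degree is preserved exactly.

    ``swaps_per_edge * n_edges`` swaps are attempted; a swap that would create
    a self-loop or duplicate edge is skipped.  Graphs with no valid swap (for
    example a triangle) are returned unchanged.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    edges = net.edge_list()
    m = len(edges)
    if m < 2:
        return FunctionalNetwork(adjacency=net.adjacency.copy(),
                                 threshold_p=net.threshold_p, group=net.group)
    present = {frozenset(e) for e in edges}
    attempts = swaps_per_edge * m
    pairs = rng.integers(0, m, size=(attempts, 2))
    flips = rng.random(attempts) < 0.5
    for (i, j), flip in zip(pairs, flips):
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if flip:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        e1, e2 = frozenset((a, d)), frozenset((c, b))
        if e1 in present or e2 in present:
            continue
        present.discard(frozenset((a, b)))
        present.discard(frozenset((c, d)))
        present.update((e1, e2))
        edges[i] = (a, d)
        edges[j] = (c, b)

    order = net.region_order
    pos = {name: k for k, name in enumerate(order)}
    adj = np.zeros((len(order), len(order)), dtype=np.int8)
    for u, v in edges:
        adj[pos[u], pos[v]] = 1
        adj[pos[v], pos[u]] = 1
    return FunctionalNetwork(
        adjacency=pd.DataFrame(adj, index=order, columns=order),
        threshold_p=net.threshold_p, group=net.group)


def empirical_quantile(values, x) -> float:
    """Midpoint-rank quantile of ``x`` within ``values``: (less + equal/2)/n."""
    arr = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if arr.size == 0 or not np.isfinite(x):
        return math.nan
    less = float(np.sum(arr < x))
    equal = float(np.sum(arr == x))
    return (less + 0.5 * equal) / arr.size


@dataclass
class NullEnsemble:
    """Null distributions of graph measures from degree-preserving rewiring."""

    n_replicates: int
    measures: pd.DataFrame          # one row per replicate
    data_values: dict[str, float]   # same measures on the data network
    quantiles: dict[str, float]     # empirical quantile of each data value
    seed: int | None
    swaps_per_edge: int

    def null_mean(self, measure: str) -> float:
        return float(np.nanmean(self.measures[measure])) \
            if measure in self.measures else math.nan

    def null_sd(self, measure: str) -> float:
        return float(np.nanstd(self.measures[measure], ddof=1)) \
            if measure in self.measures else math.nan

    def null_percentile(self, measure: str, q: float) -> float:
        vals = self.measures[measure].dropna()
        return float(np.percentile(vals, q)) if len(vals) else math.nan

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.measures.columns:
            rows.append({
                "measure": m,
                "data_value": self.data_values.get(m, math.nan),
                "null_mean": self.null_mean(m),
                "null_sd": self.null_sd(m),
                "quantile": self.quantiles.get(m, math.nan),
            })
        return pd.DataFrame(rows)


def build_null_ensemble(net: FunctionalNetwork, n_replicates: int = 1000,
                        seed: int | None = None,
                        swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
                        measures: tuple[str, ...] = ("transitivity",
                                                     "assortativity",
                                                     "small_worldness"),
                        n_random_sw: int = 20) -> NullEnsemble:
    """Rewire ``n_replicates`` times and compare graph measures to the data.

    ``n_random_sw`` sets the size of the Erdos-Renyi reference ensemble used
    inside each small-worldness evaluation (data and replicates alike, so the
    comparison is like-for-like).  Undefined measures on a replicate are
    recorded as NaN, not fatal.
    """
    unknown = set(measures) - set(MEASURES)
    if unknown:
        raise ValidationError(f"unknown measures: {sorted(unknown)}")
    rng = np.random.default_rng(seed)

    def evaluate(network: FunctionalNetwork) -> dict[str, float]:
        out = {}
        for m in measures:
            if m == "small_worldness":
                out[m] = small_worldness(network, n_random=n_random_sw, rng=rng)
            else:
                out[m] = MEASURES[m](network)
        return out

    data_values = evaluate(net)
    rows = [evaluate(rewire_preserving_degree(net, swaps_per_edge, rng=rng))
            for _ in range(n_replicates)]
    frame = pd.DataFrame(rows, columns=list(measures))
    quantiles = {m: empirical_quantile(frame[m], data_values[m]) for m in measures}
    return NullEnsemble(n_replicates=n_replicates, measures=frame,
                        data_values=data_values, quantiles=quantiles,
                        seed=seed, swaps_per_edge=swaps_per_edge)


def threshold_sweep(corr: GroupCorrelationMatrix,
                    p_grid=DEFAULT_P_GRID,
                    n_replicates: int = 1000,
                    seed: int | None = None,
                    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
                    measures: tuple[str, ...] = ("transitivity",
                                                 "assortativity",
                                                 "small_worldness"),
                    n_random_sw: int = 20) -> pd.DataFrame:
    """Build a network and null ensemble at each threshold of the grid.

    Returns one row per threshold with the data measures, null means/sds, the
    data value's empirical quantile in the null, and the null 95th percentile.
    Thresholds yielding an empty network produce NaN-valued rows.
    """
    p_grid = list(p_grid)
    if not p_grid:
        raise ValidationError("empty threshold grid")
    child_seeds = np.random.SeedSequence(seed).spawn(len(p_grid))
    rows = []
    for p_thresh, child in zip(p_grid, child_seeds):
        net = threshold_network(corr, p_thresh)
        row: dict = {"p_thresh": p_thresh,
                     "n_active_nodes": len(net.active_nodes),
                     "n_edges": net.n_edges}
        if net.n_edges == 0:
            for m in measures:
                row.update({f"data_{m}": math.nan, f"null_mean_{m}": math.nan,
                            f"null_sd_{m}": math.nan, f"quantile_{m}": math.nan,
                            f"null_p95_{m}": math.nan})
        else:
            ens = build_null_ensemble(
                net, n_replicates=n_replicates,
                seed=int(child.generate_state(1)[0] % (2 ** 31)),
                swaps_per_edge=swaps_per_edge, measures=measures,
                n_random_sw=n_random_sw)
            for m in measures:
                row.update({
                    f"data_{m}": ens.data_values[m],
                    f"null_mean_{m}": ens.null_mean(m),
                    f"null_sd_{m}": ens.null_sd(m),
                    f"quantile_{m}": ens.quantiles[m],
                    f"null_p95_{m}": ens.null_percentile(m, 95),
                })
        rows.append(row)
    return pd.DataFrame(rows)
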