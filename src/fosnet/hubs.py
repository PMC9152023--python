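"""Hub identification and threshold-robustness ranking.

A hub is a region in the top 20% of active nodes for *both* degree and
betweenness.  Because ranks, not raw values, define hubs, the result is
invariant to the betweenness normalisation constant.  Hub robustness counts
how often a region qualifies as the edge threshold is tightened: the base
network (p < 0.05) plus nine pruned networks (p < 0.005 .. 0.045) give each
region a count out of ten; regions with the maximum count are the most robust
hubs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .connectivity import GroupCorrelationMatrix
from .ingest import ValidationError
from .network_metrics import CentralityTable, centrality_table, threshold_network

__all__ = ["HubSet", "RobustHubRanking", "identify_hubs", "hub_robustness",
           "compare_hub_sets", "DEFAULT_PRUNE_GRID"]

#: Nine pruning thresholds below the base p < 0.05 network.
DEFAULT_PRUNE_GRID: tuple[float, ...] = tuple(np.round(np.linspace(0.005, 0.045, 9), 4))


@dataclass
class HubSet:
    """Regions in the top fraction of active nodes for degree AND betweenness."""

    hubs: frozenset
    top_fraction: float
    cutoff_rank: int
    cutoff_values: dict[str, float]
    group: tuple[str, str] | None = None
    threshold_p: float | None = None

    def __contains__(self, region) -> bool:
        return region in self.hubs

    def __len__(self) -> int:
        return len(self.hubs)


def identify_hubs(centrality: CentralityTable,
                  top_fraction: float = 0.2) -> HubSet:
    """Intersect the top-``top_fraction`` sets of degree and betweenness.

    The cutoff index is ``ceil(top_fraction * n_active)``; a node qualifies on
    a measure iff its value is >= the value at the cutoff index, so boundary
    ties are included (deterministic and order-independent).  One exception
    keeps the rule meaningful: if the cutoff value equals the sample minimum
    while higher values exist (e.g. betweenness 0 for most of a sparse graph),
    the bottom-tied nodes do not count as "top" and only strictly greater
    values qualify.  When every node is tied on a measure, all qualify.
    """
    if not 0 < top_fraction <= 1:
        raise ValidationError("top_fraction must be in (0, 1]")
    frame = centrality.frame
    n = len(frame)
    if n == 0:
        return HubSet(hubs=frozenset(), top_fraction=top_fraction,
                      cutoff_rank=0, cutoff_values={},
                      group=centrality.group, threshold_p=centrality.threshold_p)
    k = math.ceil(top_fraction * n)
    cutoffs = {}
    qualifies = pd.Series(True, index=frame.index)
    for measure in ("degree", "betweenness"):
        values = frame[measure]
        cutoff = values.sort_values(ascending=False).iloc[k - 1]
        cutoffs[measure] = float(cutoff)
        if cutoff == values.min() and values.max() > cutoff:
            qualifies &= values > cutoff
        else:
            qualifies &= values >= cutoff
    return HubSet(hubs=frozenset(frame.index[qualifies]),
                  top_fraction=top_fraction, cutoff_rank=k,
                  cutoff_values=cutoffs, group=centrality.group,
                  threshold_p=centrality.threshold_p)


@dataclass
class RobustHubRanking:
    """Per-region count of thresholds at which it qualified as a hub."""

    counts: pd.Series          # region -> count, sorted descending
    thresholds: list[float]
    hub_sets: list[HubSet]
    group: tuple[str, str] | None = None

    @property
    def frame(self) -> pd.DataFrame:
        out = self.counts.rename("n_thresholds_as_hub").to_frame()
        out["rank"] = self.counts.rank(ascending=False, method="min").astype(int)
        return out

    @property
    def top_hubs(self) -> frozenset:
        """Most robust hub(s); plural on ties, empty if nothing ever qualified."""
        if self.counts.empty or self.counts.iloc[0] == 0:
            return frozenset()
        return frozenset(self.counts.index[self.counts == self.counts.iloc[0]])


def hub_robustness(corr: GroupCorrelationMatrix, base_p: float = 0.05,
                   prune_grid=DEFAULT_PRUNE_GRID,
                   top_fraction: float = 0.2) -> RobustHubRanking:
    """Count hub qualifications over the base network plus pruned networks.

    With the defaults this evaluates exactly ten networks per group: the base
    p < 0.05 graph and nine graphs pruned at p < 0.005 .. 0.045.
    """
    thresholds = [base_p] + [p for p in prune_grid]
    counts = pd.Series(0, index=corr.region_order, dtype=int)
    hub_sets: list[HubSet] = []
    any_edges = False
    for p_thresh in thresholds:
        net = threshold_network(corr, p_thresh)
        if net.n_edges == 0:
            hub_sets.append(HubSet(hubs=frozenset(), top_fraction=top_fraction,
                                   cutoff_rank=0, cutoff_values={},
                                   group=corr.group, threshold_p=p_thresh))
            continue
        any_edges = True
        hs = identify_hubs(centrality_table(net), top_fraction=top_fraction)
        hub_sets.append(hs)
        for region in hs.hubs:
            counts[region] += 1
    if not any_edges:
        warnings.warn(f"group {corr.group}: no edges at any threshold; "
                      "empty hub ranking", stacklevel=2)
    order = np.lexsort((counts.index, -counts.to_numpy()))
    counts = counts.iloc[order]
    return RobustHubRanking(counts=counts, thresholds=thresholds,
                            hub_sets=hub_sets, group=corr.group)


def compare_hub_sets(hub_sets: Mapping) -> pd.DataFrame:
    """Pairwise overlap (shared hubs and Jaccard index) between groups.

    Two empty sets count as identical (Jaccard 1).
    """
    def as_set(h) -> frozenset:
        return h.hubs if isinstance(h, HubSet) else frozenset(h)

    rows = []
    for (ga, ha), (gb, hb) in combinations(hub_sets.items(), 2):
        sa, sb = as_set(ha), as_set(hb)
        union = sa | sb
        jaccard = len(sa & sb) / len(union) if union else 1.0
        rows.append({
            "group_a": ga if isinstance(ga, str) else ":".join(ga),
            "group_b": gb if isinstance(gb, str) else ":".join(gb),
            "n_shared": len(sa & sb),
            "shared": ";".join(sorted(sa & sb)),
            "jaccard": jaccard,
        })
    return pd.DataFrame(rows, columns=["group_a", "group_b", "n_shared",
                                       "shared", "jaccard"])
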