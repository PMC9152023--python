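"""Model/Results front end over the analysis modules.

Two estimator-style entry points cover the standard workflow:

``RegionalActivationModel``
    the region-wise 2x2 ANOVA screen; ``fit()`` returns results carrying the
    per-region F/p table, planned contrasts and significance counts.

``FunctionalNetworkModel``
    one group's correlation network; ``fit()`` estimates the correlation
    matrix, thresholds it, computes centrality, Markov clusters and graph
    summaries, and identifies hubs.  Null simulation, the threshold sweep and
    hub robustness hang off the results object.

Both mirror the construct-then-fit idiom of statsmodels: the model holds data
and configuration, the results object holds everything estimated from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import hubs as hub_analysis
from . import network_metrics as nm
from . import null_models
from .connectivity import GroupCorrelationMatrix, correlation_matrix, critical_r
from .ingest import RegionCountTable, ValidationError
from .regional_stats import (DEFAULT_CONTRAST_PAIRS, ScreenResults,
                             screen_all_regions)

__all__ = ["RegionalActivationModel", "RegionalActivationResults",
           "FunctionalNetworkModel", "FunctionalNetworkResults"]


class RegionalActivationModel:
    """Region-wise sex x training activation screen on an animals x regions table."""

    def __init__(self, table: RegionCountTable):
        if table.has_missing():
            raise ValidationError("table has missing cells; run filter_matched first")
        self.table = table

    @classmethod
    def from_dataframe(cls, wide: pd.DataFrame) -> "RegionalActivationModel":
        """Build from a wide frame (animal_id index/column, sex, condition, regions)."""
        return cls(RegionCountTable.from_wide_frame(wide))

    def fit(self, alpha: float = 0.05, contrast_pairs=DEFAULT_CONTRAST_PAIRS,
            gate_on_interaction: bool = True,
            fdr: bool = False) -> "RegionalActivationResults":
        screen = screen_all_regions(self.table, alpha=alpha,
                                    contrast_pairs=contrast_pairs,
                                    gate_on_interaction=gate_on_interaction,
                                    fdr=fdr)
        return RegionalActivationResults(model=self, screen=screen)


@dataclass
class RegionalActivationResults:
    model: RegionalActivationModel
    screen: ScreenResults

    @property
    def anova_frame(self) -> pd.DataFrame:
        return self.screen.frame

    @property
    def contrast_frame(self) -> pd.DataFrame:
        return self.screen.contrast_frame

    @property
    def counts(self) -> dict[str, int]:
        return self.screen.counts

    def significant_regions(self, effect: str = "training") -> list[str]:
        return self.screen.significant_regions(effect)

    def summary(self) -> str:
        return self.screen.summary()

    def plot_region(self, region: str, ax=None):
        """Group-mean bar plot (mean +/- SEM) for one region."""
        import matplotlib.pyplot as plt

        table = self.model.table
        if ax is None:
            _, ax = plt.subplots()
        labels, means, sems = [], [], []
        for g in table.groups_present():
            vals = table.counts.loc[table.group_animals(g), region]
            labels.append(f"{g[0]}\n{g[1]}")
            means.append(vals.mean())
            sems.append(vals.sem())
        ax.bar(labels, means, yerr=sems, capsize=4)
        ax.set_ylabel("c-fos+ cells (mean count)")
        ax.set_title(region)
        return ax


class FunctionalNetworkModel:
    """Thresholded interregional correlation network for one experimental group."""

    def __init__(self, table: RegionCountTable, group: tuple[str, str],
                 alpha: float = 0.05):
        if table.has_missing():
            raise ValidationError("table has missing cells; run filter_matched first")
        self.table = table
        self.group = tuple(group)
        self.alpha = alpha

    @classmethod
    def from_dataframe(cls, wide: pd.DataFrame, group: tuple[str, str],
                       alpha: float = 0.05) -> "FunctionalNetworkModel":
        return cls(RegionCountTable.from_wide_frame(wide), group, alpha=alpha)

    @property
    def critical_r(self) -> float:
        """Correlation magnitude an edge must exceed at this group's n and alpha."""
        n = len(self.table.group_animals(self.group))
        return critical_r(n, self.alpha)

    def fit(self, inflation_grid=nm.DEFAULT_INFLATION_GRID,
            n_random: int = 100, seed: int | None = None,
            cluster: bool = True) -> "FunctionalNetworkResults":
        corr = correlation_matrix(self.table, self.group)
        net = nm.threshold_network(corr, self.alpha)
        centrality = nm.centrality_table(net)
        clusters = None
        if cluster and net.n_edges > 0:
            clusters = nm.select_inflation(net, grid=inflation_grid)
        graph_summary = nm.summarize(net, n_random=n_random, seed=seed)
        hub_set = hub_analysis.identify_hubs(centrality)
        return FunctionalNetworkResults(
            model=self, corr=corr, network=net, centrality=centrality,
            clusters=clusters, graph_summary=graph_summary, hubs=hub_set)


@dataclass
class FunctionalNetworkResults:
    model: FunctionalNetworkModel
    corr: GroupCorrelationMatrix
    network: nm.FunctionalNetwork
    centrality: nm.CentralityTable
    clusters: nm.ClusterAssignment | None
    graph_summary: nm.GraphSummary
    hubs: hub_analysis.HubSet

    def simulate_null(self, n_replicates: int = 1000, seed: int | None = None,
                      **kwargs) -> null_models.NullEnsemble:
        """Degree-preserving null ensemble for this group's network."""
        return null_models.build_null_ensemble(self.network,
                                               n_replicates=n_replicates,
                                               seed=seed, **kwargs)

    def threshold_sweep(self, p_grid=null_models.DEFAULT_P_GRID,
                        n_replicates: int = 1000, seed: int | None = None,
                        **kwargs) -> pd.DataFrame:
        return null_models.threshold_sweep(self.corr, p_grid=p_grid,
                                           n_replicates=n_replicates,
                                           seed=seed, **kwargs)

    def hub_robustness(self, prune_grid=hub_analysis.DEFAULT_PRUNE_GRID,
                       **kwargs) -> hub_analysis.RobustHubRanking:
        return hub_analysis.hub_robustness(self.corr, base_p=self.model.alpha,
                                           prune_grid=prune_grid, **kwargs)

    def summary(self) -> str:
        g = self.graph_summary
        sex, condition = self.model.group
        lines = [
            f"Functional network: {sex} / {condition} "
            f"(n = {self.corr.n_animals} animals)",
            f"  edge rule:        r > 0 and p < {self.model.alpha} "
            f"(critical r = {self.model.critical_r:.3f})",
            f"  active nodes:     {g.n_active_nodes} of {len(self.network.region_order)} regions",
            f"  edges:            {g.n_edges}",
            f"  transitivity:     {g.transitivity:.3f}",
            f"  assortativity:    {g.assortativity:.3f}",
            f"  char path length: {g.char_path_length:.3f}",
            f"  small-worldness:  {g.small_worldness:.3f}",
        ]
        if self.clusters is not None:
            lines.append(f"  MCL clusters:     {self.clusters.n_clusters} "
                         f"(inflation {self.clusters.inflation:.1f}, "
                         f"Q = {self.clusters.modularity_q:.3f})")
        lines.append(f"  hubs (top 20% degree & betweenness): "
                     f"{', '.join(sorted(self.hubs.hubs)) or 'none'}")
        return "\n".join(lines)

    def plot_centrality(self, show_fraction: float = 0.3, ax=None):
        """Ranked degree/betweenness bars with the top-20% hub cutoff line."""
        import matplotlib.pyplot as plt

        frame = self.centrality.frame
        if ax is None:
            _, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        else:
            axes = ax
        n_show = max(1, int(np.ceil(show_fraction * len(frame))))
        cut = self.hubs.cutoff_rank
        for axis, measure in zip(axes, ("degree", "betweenness")):
            top = frame[measure].sort_values(ascending=False).head(n_show)
            colors = ["crimson" if r in self.hubs else "grey" for r in top.index]
            axis.bar(range(len(top)), top.to_numpy(), color=colors)
            axis.set_xticks(range(len(top)))
            axis.set_xticklabels(top.index, rotation=90, fontsize=6)
            axis.axvline(cut - 0.5, ls=":", color="k")
            axis.set_title(measure)
        return axes
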