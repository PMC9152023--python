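"""Per-group interregional Pearson correlation matrices with small-sample p-values.

Functional connectivity is inferred from across-animal covariance of regional
c-fos counts: within one experimental group, each pair of regions gets a sample
Pearson r over that group's animals and a two-tailed p-value from the exact
t transform ``t = r sqrt((n-2)/(1-r^2))`` on ``n-2`` degrees of freedom.  At
the small group sizes typical of such cohorts the implied critical r is steep:
``critical_r(4, 0.05) = 0.95`` and ``critical_r(3, 0.05) = 0.997``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import RegionCountTable, RegionMetadata, ValidationError

__all__ = ["GroupCorrelationMatrix", "correlation_matrix", "critical_r",
           "sort_by_division"]


@dataclass
class GroupCorrelationMatrix:
    """Region x region Pearson r and two-tailed p for one experimental group.

    Regions with zero within-group variance have undefined correlations; those
    rows/columns carry NaN (flagged-missing) off the diagonal and become
    non-edges downstream.
    """

    group: tuple[str, str]
    n_animals: int
    r: pd.DataFrame
    p: pd.DataFrame
    undefined: tuple = ()

    def __post_init__(self) -> None:
        if not (self.r.index.equals(self.r.columns)
                and self.r.index.equals(self.p.index)
                and self.p.index.equals(self.p.columns)):
            raise ValidationError("r and p must be square with matching labels")

    @property
    def region_order(self) -> list[str]:
        return list(self.r.columns)

    def undefined_regions(self) -> list[str]:
        """Regions whose correlations are flagged-missing (zero variance)."""
        return list(self.undefined)


def correlation_matrix(table: RegionCountTable,
                       group: tuple[str, str]) -> GroupCorrelationMatrix:
    """All-pairs Pearson r (and exact two-tailed p) within one group.

    Requires n >= 3 animals in the group (the t reference has n-2 df).
    """
    animals = table.group_animals(group)
    n = len(animals)
    if n < 3:
        raise ValidationError(f"group {group} has n={n} < 3 animals")
    sub = table.subset(animals=animals)
    if sub.has_missing():
        raise ValidationError("correlation requires a complete table; run filter_matched")

    x = sub.counts.to_numpy(dtype=float)
    centered = x - x.mean(axis=0)
    ss = (centered ** 2).sum(axis=0)
    defined = ss > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(np.outer(ss, ss))
        r = (centered.T @ centered) / denom
    r = np.clip(r, -1.0, 1.0)
    r[~defined, :] = np.nan
    r[:, ~defined] = np.nan
    np.fill_diagonal(r, 1.0)

    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.abs(r) >= 1.0] = 0.0  # |r| = 1 limit of the t transform
    p[np.isnan(r)] = np.nan
    np.fill_diagonal(p, 0.0)

    regions = sub.counts.columns
    return GroupCorrelationMatrix(
        group=group, n_animals=n,
        r=pd.DataFrame(r, index=regions, columns=regions),
        p=pd.DataFrame(p, index=regions, columns=regions),
        undefined=tuple(regions[~defined]),
    )


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Smallest |r| reaching two-tailed significance ``alpha`` at sample size n.

    Inverts the t transform at the (1 - alpha/2) quantile of t with n-2 df:
    ``r* = t* / sqrt(t*^2 + n - 2)``.
    """
    if n < 3:
        raise ValidationError(f"critical_r requires n >= 3, got {n}")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    t_star = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(t_star / np.sqrt(t_star ** 2 + n - 2))


def sort_by_division(corr: GroupCorrelationMatrix,
                     metadata: RegionMetadata) -> GroupCorrelationMatrix:
    """Reorder a correlation matrix by major anatomical division (display order)."""
    order = [a for a in metadata.division_order() if a in corr.r.columns]
    leftover = [a for a in corr.r.columns if a not in order]
    order = order + leftover
    return GroupCorrelationMatrix(
        group=corr.group, n_animals=corr.n_animals,
        r=corr.r.loc[order, order], p=corr.p.loc[order, order],
        undefined=corr.undefined,
    )
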