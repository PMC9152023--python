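"""Region-wise 2x2 ANOVA screen (sex x training) with planned contrasts.

Each region's mean counts are modelled as a fully crossed two-factor design
with Type III sums of squares under sum-to-zero coding; with one degree of
freedom per term, the Type III F for a term equals the squared Wald t of the
corresponding coefficient in the full effect-coded model, which is how the
statistics are computed here (on top of an OLS fit).  Planned pairwise
comparisons use Fisher's LSD: an unadjusted t-test with the ANOVA's pooled
error mean square and error degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .ingest import GROUP_ORDER, RegionCountTable, ValidationError

__all__ = ["AnovaResult", "PlannedContrast", "ScreenResults",
           "two_way_anova", "fishers_lsd", "screen_all_regions"]

Group = tuple[str, str]

#: The single planned comparison reported by default: trained male vs female.
DEFAULT_CONTRAST_PAIRS: tuple[tuple[Group, Group], ...] = (
    (("male", "trained"), ("female", "trained")),
)

_DEGENERATE_RTOL = 1e-10


@dataclass
class AnovaResult:
    """Type III two-way ANOVA for one region (1 df per effect)."""

    region: str
    F_training: float
    p_training: float
    F_sex: float
    p_sex: float
    F_interaction: float
    p_interaction: float
    df_effect: int
    df_error: int
    mse: float
    degenerate: bool = False


@dataclass
class PlannedContrast:
    """Fisher's LSD comparison between two cells of the 2x2 design."""

    region: str
    group_a: Group
    group_b: Group
    mean_diff: float
    t: float
    p: float
    df: int


def _design(factors: pd.DataFrame) -> np.ndarray:
    """Effect-coded (sum-to-zero) design matrix: intercept, sex, condition, interaction."""
    s = np.where(factors["sex"] == "female", 1.0, -1.0)
    c = np.where(factors["condition"] == "trained", 1.0, -1.0)
    return np.column_stack([np.ones(len(factors)), s, c, s * c])


def _check_cells(table: RegionCountTable) -> None:
    sizes = table.group_sizes()
    empty = [g for g in GROUP_ORDER if sizes[g] == 0]
    if empty:
        raise ValidationError(f"empty design cell(s): {empty}")
    if table.n_animals - 4 < 1:
        raise ValidationError("two-way ANOVA needs more animals than cells")


def two_way_anova(table: RegionCountTable, region: str,
                  _checked: bool = False) -> AnovaResult:
    """Fit the 2x2 between-subjects ANOVA for one region.

    A region with (numerically) zero error variance is returned flagged
    ``degenerate`` with NaN F and p rather than raising.
    """
    if not _checked:
        _check_cells(table)
    y = table.counts[region].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValidationError(f"region {region} has missing cells")
    X = _design(table.factors)
    fit = sm.OLS(y, X).fit()
    df_error = len(y) - 4
    ss_total = float(np.sum((y - y.mean()) ** 2))
    if fit.ssr <= _DEGENERATE_RTOL * max(ss_total, 1.0):
        return AnovaResult(region=region, F_training=math.nan, p_training=math.nan,
                           F_sex=math.nan, p_sex=math.nan, F_interaction=math.nan,
                           p_interaction=math.nan, df_effect=1, df_error=df_error,
                           mse=float(fit.ssr / df_error), degenerate=True)
    t_vals = fit.params[1:] / fit.bse[1:]
    F = np.asarray(t_vals, dtype=float) ** 2  # sex, condition, interaction
    p = stats.f.sf(F, 1, df_error)
    return AnovaResult(
        region=region,
        F_training=float(F[1]), p_training=float(p[1]),
        F_sex=float(F[0]), p_sex=float(p[0]),
        F_interaction=float(F[2]), p_interaction=float(p[2]),
        df_effect=1, df_error=df_error, mse=float(fit.mse_resid),
    )


def fishers_lsd(anova: AnovaResult, table: RegionCountTable, region: str,
                group_a: Group, group_b: Group) -> PlannedContrast:
    """Unadjusted pairwise t-test using the ANOVA's pooled error mean square."""
    if anova.degenerate:
        raise ValidationError(f"region {region}: degenerate ANOVA, LSD undefined")
    a = table.counts.loc[table.group_animals(group_a), region].to_numpy(dtype=float)
    b = table.counts.loc[table.group_animals(group_b), region].to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError(f"empty group in contrast {group_a} vs {group_b}")
    diff = float(a.mean() - b.mean())
    se = math.sqrt(anova.mse * (1.0 / len(a) + 1.0 / len(b)))
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), anova.df_error)
    return PlannedContrast(region=region, group_a=group_a, group_b=group_b,
                           mean_diff=diff, t=t, p=float(p), df=anova.df_error)


@dataclass
class ScreenResults:
    """Region-wise ANOVA screen over the whole table."""

    anovas: list[AnovaResult]
    contrasts: list[PlannedContrast]
    alpha: float
    fdr: bool = False
    _frame: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def frame(self) -> pd.DataFrame:
        if self._frame is None:
            self._frame = pd.DataFrame([a.__dict__ for a in self.anovas]).set_index("region")
        return self._frame

    @property
    def contrast_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.contrasts:
            rows.append({"region": c.region,
                         "group_a": f"{c.group_a[0]}:{c.group_a[1]}",
                         "group_b": f"{c.group_b[0]}:{c.group_b[1]}",
                         "mean_diff": c.mean_diff, "t": c.t, "p": c.p, "df": c.df})
        return pd.DataFrame(rows, columns=["region", "group_a", "group_b",
                                           "mean_diff", "t", "p", "df"])

    def _effective_p(self, effect: str) -> pd.Series:
        col = f"p_{effect}_fdr" if self.fdr else f"p_{effect}"
        return self.frame[col]

    def significant_regions(self, effect: str) -> list[str]:
        p = self._effective_p(effect)
        return list(p.index[p < self.alpha])

    @property
    def counts(self) -> dict[str, int]:
        return {f"n_{e}": len(self.significant_regions(e))
                for e in ("training", "sex", "interaction")}

    def summary(self) -> str:
        n_reg = len(self.anovas)
        c = self.counts
        lines = [
            "Regional activation screen (2x2 ANOVA, Type III)",
            f"  regions tested:           {n_reg}",
            f"  alpha:                    {self.alpha}" + ("  (BH-FDR adjusted)" if self.fdr else ""),
            f"  main effect of training:  {c['n_training']}",
            f"  main effect of sex:       {c['n_sex']}",
            f"  sex x training:           {c['n_interaction']}",
            f"  planned contrasts run:    {len(self.contrasts)}",
        ]
        return "\n".join(lines)


def screen_all_regions(table: RegionCountTable, alpha: float = 0.05,
                       contrast_pairs=DEFAULT_CONTRAST_PAIRS,
                       gate_on_interaction: bool = True,
                       fdr: bool = False) -> ScreenResults:
    """Run the ANOVA for every region; planned contrasts where configured.

    By default the trained-male vs trained-female contrast is computed only for
    regions whose interaction term reaches ``alpha`` (set
    ``gate_on_interaction=False`` to run it everywhere).  ``fdr=True`` adds
    Benjamini-Hochberg adjusted p-values per effect and bases the significance
    counts on them.
    """
    _check_cells(table)
    anovas = [two_way_anova(table, region, _checked=True)
              for region in table.region_order]

    contrasts: list[PlannedContrast] = []
    for a in anovas:
        if a.degenerate:
            continue
        gate_open = (not gate_on_interaction) or (a.p_interaction < alpha)
        if gate_open:
            for ga, gb in contrast_pairs:
                contrasts.append(fishers_lsd(a, table, a.region, ga, gb))

    res = ScreenResults(anovas=anovas, contrasts=contrasts, alpha=alpha, fdr=fdr)
    if fdr:
        frame = res.frame.copy()
        from statsmodels.stats.multitest import multipletests
        for effect in ("training", "sex", "interaction"):
            p = frame[f"p_{effect}"].to_numpy()
            ok = ~np.isnan(p)
            adj = np.full_like(p, np.nan)
            if ok.any():
                adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
            frame[f"p_{effect}_fdr"] = adj
        res._frame = frame
    return res
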