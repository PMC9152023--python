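"""Seeded synthetic cohorts with the covariance structure the analysis assumes.

Counts are generated from a lognormal latent-factor model: for animal ``a`` in
group ``g`` and region ``r``,

    count = exp( mu_r + beta_r*[trained] + sigma_r*[female]
                 + gamma_r*[female x trained] + sum_k L^g[r,k] f_{k,a}
                 + eps_{a,r} ),

with per-animal factor scores ``f ~ N(0,1)`` and noise ``eps ~ N(0, noise_sd)``.
The factor loadings ``L^g`` plant group-specific blocks of correlated regions;
"hub" regions load on two factors and therefore bridge blocks, which is what
makes them central in the thresholded network.  All randomness comes from one
seeded generator, so the same spec always yields the same cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .ingest import GROUP_ORDER, RegionCountTable, ValidationError

__all__ = ["CohortSpec", "PlantedTruth", "generate_cohort", "planted_truth"]

Group = tuple[str, str]

#: Group sizes after matched-representation filtering in the motivating study.
DEFAULT_N_PER_GROUP: dict[Group, int] = {
    ("male", "naive"): 4,
    ("female", "naive"): 4,
    ("male", "trained"): 3,
    ("female", "trained"): 3,
}

_ABBREV = {("male", "naive"): "MN", ("female", "naive"): "FN",
           ("male", "trained"): "MT", ("female", "trained"): "FT"}


def _default_effect_counts(n_regions: int) -> tuple[int, int, int]:
    """Numbers of regions carrying training / sex / interaction effects.

    Scaled from the 112-region design (93 training-responsive, 5 with a sex
    main effect, 8 with a sex x training interaction).
    """
    n_train = round(n_regions * 93 / 112)
    n_sex = max(1, round(n_regions * 5 / 112))
    n_inter = max(1, round(n_regions * 8 / 112))
    return n_train, n_sex, n_inter


@dataclass
class CohortSpec:
    """Generative description of a synthetic cohort.

    Parameters
    ----------
    n_per_group : mapping (sex, condition) -> int
        Animals per group; default matches the matched dataset (naive 4,
        trained 3 per sex).
    n_regions : int
        Number of brain regions (default 112).
    baseline_log_mean : float or array
        Region baseline on the log scale (default 4.0, i.e. ~55 counts).
    training_effect, sex_effect, interaction_effect : arrays, length n_regions
        Log-scale shifts applied for trained animals, females, and trained
        females respectively.  Defaults plant a positive training effect in
        most regions and sparse sex/interaction effects.
    factor_loadings : mapping group -> (n_regions, K) array, or single array
        Latent-factor loadings defining covariance blocks; a single array is
        shared by all groups.  ``None`` means independent regions.
    noise_sd : float
        Log-scale residual standard deviation (> 0).
    planted_hubs : mapping group -> set of region indices
        Regions designated as hubs; each must load on >= 2 factors in that
        group's loading matrix.
    seed : int
        Master seed for the single random generator.
    """

    n_per_group: Mapping[Group, int] = field(default_factory=lambda: dict(DEFAULT_N_PER_GROUP))
    n_regions: int = 112
    baseline_log_mean: float | np.ndarray = 4.0
    training_effect: np.ndarray | None = None
    sex_effect: np.ndarray | None = None
    interaction_effect: np.ndarray | None = None
    factor_loadings: Mapping[Group, np.ndarray] | np.ndarray | None = None
    noise_sd: float = 0.3
    planted_hubs: Mapping[Group, frozenset] | None = None
    region_names: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.n_regions
        if self.region_names is None:
            width = max(3, len(str(n)))
            self.region_names = [f"R{i:0{width}d}" for i in range(1, n + 1)]
        if len(self.region_names) != n or len(set(self.region_names)) != n:
            raise ValidationError("region_names must be unique and of length n_regions")

        n_train, n_sex, n_inter = _default_effect_counts(n)
        if self.training_effect is None:
            eff = np.zeros(n)
            eff[:n_train] = 0.7
            self.training_effect = eff
        if self.sex_effect is None:
            eff = np.zeros(n)
            eff[max(0, n_train - n_sex):n_train] = 0.35
            self.sex_effect = eff
        if self.interaction_effect is None:
            eff = np.zeros(n)
            eff[max(0, n_train - n_inter):n_train] = 0.5
            self.interaction_effect = eff
        for name in ("training_effect", "sex_effect", "interaction_effect"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValidationError(f"{name} must have length n_regions={n}")
            setattr(self, name, arr)

        self.baseline_log_mean = np.broadcast_to(
            np.asarray(self.baseline_log_mean, dtype=float), (n,)).copy()

        self.validate()

    # -- resolved views ---------------------------------------------------
    def groups(self) -> list[Group]:
        return [g for g in GROUP_ORDER if g in self.n_per_group]

    def loadings_for(self, group: Group) -> np.ndarray:
        """Loading matrix for one group, shape (n_regions, K); zeros if unset."""
        if self.factor_loadings is None:
            return np.zeros((self.n_regions, 1))
        if isinstance(self.factor_loadings, Mapping):
            mat = self.factor_loadings.get(group)
            if mat is None:
                return np.zeros((self.n_regions, 1))
        else:
            mat = self.factor_loadings
        return np.asarray(mat, dtype=float)

    def hubs_for(self, group: Group) -> frozenset:
        if self.planted_hubs is None:
            return frozenset()
        return frozenset(self.planted_hubs.get(group, frozenset()))

    def validate(self) -> None:
        for g, n in self.n_per_group.items():
            if g not in GROUP_ORDER:
                raise ValidationError(f"unknown group {g}")
            if n < 2:
                raise ValidationError(f"group {g} needs >= 2 animals, got {n}")
        if not self.noise_sd > 0:
            raise ValidationError("noise_sd must be > 0")
        for g in self.groups():
            L = self.loadings_for(g)
            if L.ndim != 2 or L.shape[0] != self.n_regions:
                raise ValidationError(f"loadings for {g} must be (n_regions, K)")
            if not np.isfinite(L).all():
                raise ValidationError(f"non-finite loadings for {g}")
            for r in self.hubs_for(g):
                if np.count_nonzero(L[r]) < 2:
                    raise ValidationError(
                        f"planted hub {r} in group {g} must load on >= 2 factors")

    # -- canned block design ----------------------------------------------
    @classmethod
    def with_blocks(cls, n_regions: int = 112, n_blocks: int = 4,
                    block_loading: float = 0.5, hub_loading: float = 0.4,
                    noise_sd: float = 0.25, plant_hubs: bool = True,
                    n_per_group: Mapping[Group, int] | None = None,
                    seed: int = 0, **kwargs) -> "CohortSpec":
        """Spec with contiguous correlated blocks and one bridging hub per group.

        Regions are split into ``n_blocks`` near-equal contiguous blocks, each
        loading ``block_loading`` on its own factor.  For group ``i`` the first
        region of block ``i mod n_blocks`` is re-wired to load ``hub_loading``
        on its own and the next block's factor, planting a bridge whose edges
        span two blocks.
        """
        if n_blocks < 2:
            raise ValidationError("need >= 2 blocks")
        edges = np.linspace(0, n_regions, n_blocks + 1).round().astype(int)
        block_of = np.zeros(n_regions, dtype=int)
        for b in range(n_blocks):
            block_of[edges[b]:edges[b + 1]] = b
        base = np.zeros((n_regions, n_blocks))
        base[np.arange(n_regions), block_of] = block_loading

        n_per_group = dict(n_per_group or DEFAULT_N_PER_GROUP)
        loadings: dict[Group, np.ndarray] = {}
        hubs: dict[Group, frozenset] = {}
        for i, g in enumerate(g for g in GROUP_ORDER if g in n_per_group):
            L = base.copy()
            if plant_hubs:
                b = i % n_blocks
                hub = int(edges[b])
                L[hub] = 0.0
                L[hub, b] = hub_loading
                L[hub, (b + 1) % n_blocks] = hub_loading
                hubs[g] = frozenset({hub})
            loadings[g] = L
        return cls(n_per_group=n_per_group, n_regions=n_regions,
                   factor_loadings=loadings, planted_hubs=hubs or None,
                   noise_sd=noise_sd, seed=seed, **kwargs)


@dataclass
class PlantedTruth:
    """Ground truth implied by a :class:`CohortSpec`, for recovery tests."""

    cluster_labels: dict[Group, pd.Series]  # region -> block label (-1: none)
    hubs: dict[Group, frozenset]            # region names
    training_regions: pd.Series             # boolean, indexed by region
    sex_regions: pd.Series
    interaction_regions: pd.Series

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "training_effect": self.training_regions,
            "sex_effect": self.sex_regions,
            "interaction_effect": self.interaction_regions,
        })
        for g, labels in self.cluster_labels.items():
            tag = f"{g[0]}_{g[1]}"
            out[f"cluster_{tag}"] = labels
            out[f"hub_{tag}"] = out.index.isin(self.hubs.get(g, frozenset()))
        return out


def planted_truth(spec: CohortSpec) -> PlantedTruth:
    """Deterministic readout of the structure a spec plants."""
    names = pd.Index(spec.region_names)
    labels: dict[Group, pd.Series] = {}
    hubs: dict[Group, frozenset] = {}
    for g in spec.groups():
        L = np.abs(spec.loadings_for(g))
        lab = np.where(L.max(axis=1) > 0, L.argmax(axis=1), -1)
        labels[g] = pd.Series(lab, index=names)
        hubs[g] = frozenset(names[i] for i in spec.hubs_for(g))
    return PlantedTruth(
        cluster_labels=labels,
        hubs=hubs,
        training_regions=pd.Series(spec.training_effect != 0, index=names),
        sex_regions=pd.Series(spec.sex_effect != 0, index=names),
        interaction_regions=pd.Series(spec.interaction_effect != 0, index=names),
    )


def generate_cohort(spec: CohortSpec) -> RegionCountTable:
    """Draw one cohort from the given CohortSpec (seed-deterministic)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows, ids, sexes, conds = [], [], [], []
    for g in spec.groups():
        sex, condition = g
        L = spec.loadings_for(g)
        k = L.shape[1]
        trained = 1.0 if condition == "trained" else 0.0
        female = 1.0 if sex == "female" else 0.0
        fixed = (spec.baseline_log_mean
                 + spec.training_effect * trained
                 + spec.sex_effect * female
                 + spec.interaction_effect * female * trained)
        for i in range(spec.n_per_group[g]):
            f = rng.standard_normal(k)
            eps = rng.normal(0.0, spec.noise_sd, spec.n_regions)
            rows.append(np.exp(fixed + L @ f + eps))
            ids.append(f"{_ABBREV[g]}{i + 1:02d}")
            sexes.append(sex)
            conds.append(condition)
    counts = pd.DataFrame(rows, index=ids, columns=spec.region_names)
    factors = pd.DataFrame({"sex": sexes, "condition": conds}, index=ids)
    return RegionCountTable(counts=counts, factors=factors)
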