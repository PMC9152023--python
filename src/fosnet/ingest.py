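"""Read, validate and aggregate per-section c-fos counts into an animals x regions table.

Raw quantification arrives as one row per (animal, region, bregma section) with
separate left- and right-hemisphere counts of c-fos+ nuclei.  Aggregation is
two-stage: hemisphere counts at the same bregma value are averaged into a single
section value, and section values are averaged into a single regional value per
animal.  Animals or regions without complete ("matched") representation are then
removed so that every retained animal has a value for every retained region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "GROUP_ORDER",
    "ValidationError",
    "NoMatchedSubsetError",
    "RawCountRecord",
    "RegionMetadata",
    "RegionCountTable",
    "aggregate_counts",
    "filter_matched",
]

#: The four experimental groups, in canonical order.
GROUP_ORDER: tuple[tuple[str, str], ...] = (
    ("male", "naive"),
    ("female", "naive"),
    ("male", "trained"),
    ("female", "trained"),
)

SEX_LEVELS = ("male", "female")
CONDITION_LEVELS = ("naive", "trained")

#: Anterior-posterior extent of the sampled sections, in mm from bregma.
BREGMA_RANGE = (-3.52, 2.80)


class ValidationError(ValueError):
    """Raised when input data violate a structural contract."""


class NoMatchedSubsetError(ValidationError):
    """Raised when matched-representation filtering removes everything."""


@dataclass(frozen=True)
class RawCountRecord:
    """One quantified section: hemisphere counts for one region of one animal."""

    animal_id: str
    sex: str
    condition: str
    region: str
    bregma_mm: float
    left_count: float | None = None
    right_count: float | None = None


@dataclass
class RegionMetadata:
    """Region lookup: acronym -> (full name, major anatomical division)."""

    frame: pd.DataFrame  # columns: acronym, name, division

    def __post_init__(self) -> None:
        required = {"acronym", "name", "division"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"region metadata missing columns: {sorted(missing)}")
        if self.frame["acronym"].duplicated().any():
            dupes = self.frame.loc[self.frame["acronym"].duplicated(), "acronym"].tolist()
            raise ValidationError(f"duplicate region acronyms in metadata: {dupes}")

    @property
    def acronyms(self) -> set[str]:
        return set(self.frame["acronym"])

    def division_order(self) -> list[str]:
        """Region acronyms sorted by major division (stable within division)."""
        return self.frame.sort_values(["division", "acronym"], kind="stable")["acronym"].tolist()

    @classmethod
    def from_csv(cls, path) -> "RegionMetadata":
        return cls(pd.read_csv(path))


@dataclass
class RegionCountTable:
    """Animals x regions matrix of mean c-fos counts with per-animal factors.

    ``counts`` is indexed by animal id with one column per region acronym;
    ``factors`` is indexed identically with columns ``sex`` and ``condition``.
    Cells may be NaN until :func:`filter_matched` has been applied.
    """

    counts: pd.DataFrame
    factors: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.factors.index):
            raise ValidationError("counts and factors must be indexed by the same animals")
        if self.counts.columns.duplicated().any():
            raise ValidationError("duplicate region columns")
        bad_sex = set(self.factors["sex"]) - set(SEX_LEVELS)
        bad_cond = set(self.factors["condition"]) - set(CONDITION_LEVELS)
        if bad_sex or bad_cond:
            raise ValidationError(f"unknown factor levels: sex={bad_sex}, condition={bad_cond}")
        if (self.counts.to_numpy(dtype=float) < 0).any():
            raise ValidationError("negative counts")

    # -- basic accessors -------------------------------------------------
    @property
    def animals(self) -> list[str]:
        return list(self.counts.index)

    @property
    def region_order(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_animals(self) -> int:
        return len(self.counts)

    @property
    def n_regions(self) -> int:
        return self.counts.shape[1]

    def has_missing(self) -> bool:
        return bool(self.counts.isna().any().any())

    def group_animals(self, group: tuple[str, str]) -> list[str]:
        sex, condition = group
        mask = (self.factors["sex"] == sex) & (self.factors["condition"] == condition)
        return list(self.factors.index[mask])

    def group_sizes(self) -> dict[tuple[str, str], int]:
        return {g: len(self.group_animals(g)) for g in GROUP_ORDER}

    def groups_present(self) -> list[tuple[str, str]]:
        return [g for g in GROUP_ORDER if self.group_animals(g)]

    def subset(self, animals: Iterable[str] | None = None,
               regions: Iterable[str] | None = None) -> "RegionCountTable":
        animals = list(animals) if animals is not None else self.animals
        regions = list(regions) if regions is not None else self.region_order
        return RegionCountTable(
            counts=self.counts.loc[animals, regions].copy(),
            factors=self.factors.loc[animals].copy(),
        )

    # -- I/O --------------------------------------------------------------
    def to_wide_frame(self) -> pd.DataFrame:
        wide = pd.concat([self.factors, self.counts], axis=1)
        wide.index.name = "animal_id"
        return wide

    def to_wide_csv(self, path) -> None:
        self.to_wide_frame().to_csv(path)

    @classmethod
    def from_wide_frame(cls, wide: pd.DataFrame) -> "RegionCountTable":
        if "animal_id" in wide.columns:
            wide = wide.set_index("animal_id")
        wide.index.name = None
        factors = wide[["sex", "condition"]]
        counts = wide.drop(columns=["sex", "condition"]).astype(float)
        return cls(counts=counts, factors=factors)

    @classmethod
    def from_wide_csv(cls, path) -> "RegionCountTable":
        return cls.from_wide_frame(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

_LONG_COLUMNS = ["animal_id", "sex", "condition", "region", "bregma_mm",
                 "left_count", "right_count"]


def _records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        frame = records.copy()
    else:
        frame = pd.DataFrame([r.__dict__ if isinstance(r, RawCountRecord) else r
                              for r in records])
    missing = set(_LONG_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"raw records missing columns: {sorted(missing)}")
    return frame


def aggregate_counts(records, metadata: RegionMetadata | None = None,
                     bregma_range: tuple[float, float] = BREGMA_RANGE) -> RegionCountTable:
    """Collapse per-section hemisphere counts into one value per animal x region.

    Each section contributes the mean of its available hemisphere counts (a
    single hemisphere stands alone if the other is missing); the regional value
    is the mean over that animal's sections.  Sections with both hemispheres
    missing contribute nothing.

    Parameters
    ----------
    records : DataFrame or iterable of RawCountRecord
        Long-format rows with columns ``animal_id, sex, condition, region,
        bregma_mm, left_count, right_count``.
    metadata : RegionMetadata, optional
        When given, every region acronym must be listed in it.
    bregma_range : (low, high)
        Allowed anterior-posterior extent in mm from bregma.

    Returns
    -------
    RegionCountTable
        May contain NaN cells for (animal, region) pairs never observed;
        apply :func:`filter_matched` before correlation analysis.
    """
    frame = _records_to_frame(records)
    if frame.empty:
        raise ValidationError("no raw count records supplied")

    if metadata is not None:
        unknown = sorted(set(frame["region"]) - metadata.acronyms)
        if unknown:
            raise ValidationError(f"unknown region acronym(s): {unknown}")

    lo, hi = min(bregma_range), max(bregma_range)
    bregma = frame["bregma_mm"].astype(float)
    out_of_range = frame.loc[(bregma < lo) | (bregma > hi)]
    if not out_of_range.empty:
        bad = sorted(out_of_range["bregma_mm"].unique())
        raise ValidationError(f"bregma values outside sampled range [{lo}, {hi}]: {bad}")

    counts = frame[["left_count", "right_count"]].astype(float)
    if (counts.to_numpy() < 0).any():
        raise ValidationError("negative hemisphere counts")

    # hemisphere mean per section, then mean over sections
    section_value = counts.mean(axis=1, skipna=True)
    frame = frame.assign(_section_value=section_value).dropna(subset=["_section_value"])
    if frame.empty:
        raise ValidationError("all records have both hemispheres missing")

    per_cell = frame.groupby(["animal_id", "region"], sort=False)["_section_value"].mean()
    wide = per_cell.unstack("region")

    factors = (frame.groupby("animal_id", sort=False)[["sex", "condition"]]
               .agg(lambda s: s.unique()))
    inconsistent = factors.map(lambda v: len(np.atleast_1d(v)) > 1)
    if inconsistent.any().any():
        bad = factors.index[inconsistent.any(axis=1)].tolist()
        raise ValidationError(f"inconsistent factor labels for animals: {bad}")
    factors = factors.map(lambda v: np.atleast_1d(v)[0])

    wide = wide.loc[factors.index]
    return RegionCountTable(counts=wide, factors=factors)


# ---------------------------------------------------------------------------
# Matched-representation filtering
# ---------------------------------------------------------------------------

@dataclass
class ExclusionReport:
    """Which animals/regions were removed to reach matched representation."""

    dropped_animals: list[dict] = field(default_factory=list)
    dropped_regions: list[dict] = field(default_factory=list)
    n_animals_retained: int = 0
    n_regions_retained: int = 0

    def to_dict(self) -> dict:
        return {
            "dropped_animals": self.dropped_animals,
            "dropped_regions": self.dropped_regions,
            "n_animals_retained": self.n_animals_retained,
            "n_regions_retained": self.n_regions_retained,
        }


def filter_matched(table: RegionCountTable,
                   region_missing_cutoff: float = 0.5,
                   ) -> tuple[RegionCountTable, ExclusionReport]:
    """Reduce to the largest complete sub-table under a deterministic policy.

    Regions missing in more than ``region_missing_cutoff`` of animals are
    dropped first (systematically unrepresented regions).  Remaining holes are
    removed by greedy alternating deletion: repeatedly delete the animal or the
    region with the most missing cells (on ties, the animal) until no missing
    cells remain.  The result is complete and maximal under this policy.
    """
    counts = table.counts.copy()
    report = ExclusionReport()

    frac_missing = counts.isna().mean(axis=0)
    for region in counts.columns[frac_missing > region_missing_cutoff]:
        report.dropped_regions.append({
            "region": region,
            "reason": f"missing in {int(counts[region].isna().sum())}/{len(counts)} animals",
        })
    counts = counts.loc[:, frac_missing <= region_missing_cutoff]

    while counts.size and counts.isna().any().any():
        by_animal = counts.isna().sum(axis=1)
        by_region = counts.isna().sum(axis=0)
        if by_region.max() > by_animal.max():
            region = by_region.idxmax()
            report.dropped_regions.append({
                "region": region,
                "reason": f"unmatched in {int(by_region[region])} animal(s)",
            })
            counts = counts.drop(columns=[region])
        else:
            animal = by_animal.idxmax()
            report.dropped_animals.append({
                "animal_id": animal,
                "reason": f"missing {int(by_animal[animal])} region(s)",
            })
            counts = counts.drop(index=[animal])

    if counts.size == 0:
        raise NoMatchedSubsetError("no matched subset: filtering removed all data")

    report.n_animals_retained = len(counts)
    report.n_regions_retained = counts.shape[1]
    filtered = RegionCountTable(counts=counts, factors=table.factors.loc[counts.index].copy())
    return filtered, report
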