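"""Stratum definitions and the population table.

The population is stratified along three dimensions:

* age group: 0-14 (children), 15-24 (young adults), 25-64 (adults),
  65+ (seniors);
* neighborhood socio-economic position (SEP): low / high, an area-based
  index dichotomized at the median;
* education level: middle-low / high (tertiary), an individual-based
  indicator.

Children (0-14) are all classified as middle-low education, so the two
(0-14, *, high-education) strata are empty and excluded: 14 valid strata
remain out of the nominal 4 x 2 x 2 = 16.  The canonical ordering is
age-major, then SEP (low < high), then education (mid_low < high).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

AGE_GROUPS: tuple[str, ...] = ("0-14", "15-24", "25-64", "65+")
SEP_LEVELS: tuple[str, ...] = ("low", "high")
EDU_LEVELS: tuple[str, ...] = ("mid_low", "high")

#: Year bounds of each age group (inclusive); the open-ended senior group
#: is capped at 200 for interval arithmetic.
AGE_BOUNDS: dict[str, tuple[int, int]] = {
    "0-14": (0, 14),
    "15-24": (15, 24),
    "25-64": (25, 64),
    "65+": (65, 200),
}


class GroupKey(NamedTuple):
    """One population stratum: (age group, SEP level, education level)."""

    age: str
    sep: str
    edu: str

    @property
    def label(self) -> str:
        return f"{self.age}|{self.sep}|{self.edu}"

    @classmethod
    def from_label(cls, label: str) -> "GroupKey":
        age, sep, edu = label.split("|")
        key = cls(age, sep, edu)
        if key not in GROUP_INDEX:
            raise ValueError(f"not a valid stratum label: {label!r}")
        return key


def _canonical_keys() -> tuple[GroupKey, ...]:
    keys = []
    for age in AGE_GROUPS:
        for sep in SEP_LEVELS:
            for edu in EDU_LEVELS:
                if age == "0-14" and edu == "high":
                    continue  # children are all middle-low education
                keys.append(GroupKey(age, sep, edu))
    return tuple(keys)


GROUP_KEYS: tuple[GroupKey, ...] = _canonical_keys()
N_GROUPS: int = len(GROUP_KEYS)  # 14
GROUP_INDEX: dict[GroupKey, int] = {k: i for i, k in enumerate(GROUP_KEYS)}

#: Stratum indices belonging to each age group, in canonical order.
AGE_SUBGROUPS: dict[str, tuple[int, ...]] = {
    age: tuple(i for i, k in enumerate(GROUP_KEYS) if k.age == age)
    for age in AGE_GROUPS
}


def age_groups_overlapping(low: float, high: float) -> list[str]:
    """Age groups whose year interval intersects [low, high]."""
    if low > high:
        raise ValueError(f"invalid age range: {low}-{high}")
    return [
        g for g, (lo, hi) in AGE_BOUNDS.items() if not (high < lo or low > hi)
    ]


@dataclass(frozen=True)
class PopulationTable:
    """Population counts N_s for the 14 strata, in canonical order."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (N_GROUPS,):
            raise ValueError(
                f"expected {N_GROUPS} stratum counts, got shape {counts.shape}"
            )
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise ValueError("population counts must be finite and >= 0")
        if counts.sum() <= 0:
            raise ValueError("total population must be positive")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def age_totals(self) -> np.ndarray:
        """N_i for the four age groups."""
        return np.array(
            [self.counts[list(AGE_SUBGROUPS[a])].sum() for a in AGE_GROUPS]
        )

    def level_totals(self, dim: str) -> np.ndarray:
        """N per level of ``dim`` in {'sep', 'edu'} (low/mid_low first)."""
        levels = SEP_LEVELS if dim == "sep" else EDU_LEVELS
        if dim not in ("sep", "edu"):
            raise ValueError(f"unknown dimension {dim!r}")
        return np.array(
            [
                sum(
                    self.counts[i]
                    for i, k in enumerate(GROUP_KEYS)
                    if getattr(k, dim) == lev
                )
                for lev in levels
            ]
        )

    def subset_total(self, keys: Iterable[GroupKey]) -> float:
        return float(sum(self.counts[GROUP_INDEX[k]] for k in keys))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": [k.age for k in GROUP_KEYS],
                "sep": [k.sep for k in GROUP_KEYS],
                "edu": [k.edu for k in GROUP_KEYS],
                "count": self.counts,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PopulationTable":
        required = {"age", "sep", "edu", "count"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"population table missing columns: {sorted(missing)}")
        counts = np.zeros(N_GROUPS)
        seen = set()
        for _, row in frame.iterrows():
            key = GroupKey(str(row["age"]), str(row["sep"]), str(row["edu"]))
            if key not in GROUP_INDEX:
                if key.age == "0-14" and key.edu == "high":
                    if float(row["count"]) != 0:
                        raise ValueError(
                            "children with high education must be empty, "
                            f"got count {row['count']}"
                        )
                    continue
                raise ValueError(f"unknown stratum in population table: {key}")
            if key in seen:
                raise ValueError(f"duplicate stratum in population table: {key}")
            seen.add(key)
            counts[GROUP_INDEX[key]] = float(row["count"])
        if seen != set(GROUP_KEYS):
            absent = sorted(set(GROUP_KEYS) - seen)
            raise ValueError(f"population table missing strata: {absent}")
        return cls(counts)

    @classmethod
    def from_csv(cls, path) -> "PopulationTable":
        return cls.from_frame(pd.read_csv(path))
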