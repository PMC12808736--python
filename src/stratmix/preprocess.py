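"""Survey ingestion and preprocessing.

Turns a raw contact-survey table into an analysis-ready dataset:

* parse participants and their reported contacts (contact ages may be an
  exact age group, a year range possibly spanning several groups, or
  missing entirely);
* truncate heavy-tailed individual contact counts at a cap (default 50);
* impute missing / ranged contact ages from the empirical age
  distribution of known contacts of participants in the same age group;
* classify participants into low/high SEP from a building-level
  municipality SEP table, split at the median;
* compute crude per-stratum mean contact numbers with percentile
  bootstrap confidence intervals.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .groups import (
    AGE_BOUNDS,
    AGE_GROUPS,
    EDU_LEVELS,
    GROUP_KEYS,
    SEP_LEVELS,
    age_groups_overlapping,
)

logger = logging.getLogger(__name__)

PARTICIPANT_COLUMNS = ("part_id", "part_age_group", "part_edu", "municipality")
CONTACT_COLUMNS = ("part_id", "cnt_age")

_RANGE_RE = re.compile(r"^\s*(\d+)\s*-\s*(\d+)\s*$")
_PLUS_RE = re.compile(r"^\s*(\d+)\s*\+\s*$")
_INT_RE = re.compile(r"^\s*(\d+)\s*$")


class SchemaError(ValueError):
    """A required column is missing from an input table."""


@dataclass
class SurveyDataset:
    """A contact survey: one participants frame, one long contacts frame.

    ``participants`` columns: part_id, age, edu, municipality, optional
    sep, plus any covariates preserved verbatim.  ``contacts`` columns:
    part_id, order, cnt_age (raw token), age_group (exact group or NA),
    range_low/range_high (year range, NaN unless ranged), retained.
    """

    participants: pd.DataFrame
    contacts: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    def effective_counts(self) -> pd.Series:
        """Retained (post-truncation) contact count per participant."""
        counts = (
            self.contacts.loc[self.contacts["retained"], "part_id"]
            .value_counts()
            .reindex(self.participants["part_id"], fill_value=0)
        )
        counts.index = self.participants.index
        return counts

    def strata(self) -> pd.DataFrame:
        """Participant (age, sep, edu) labels; requires SEP assigned."""
        if "sep" not in self.participants.columns:
            raise ValueError("SEP not assigned; run assign_sep first")
        return self.participants[["age", "sep", "edu"]]

    def copy(self) -> "SurveyDataset":
        return SurveyDataset(
            self.participants.copy(), self.contacts.copy(), dict(self.meta)
        )


def _parse_age_token(token) -> tuple[str | None, float, float]:
    """Parse one contact-age token.

    Returns (exact_group or None, range_low, range_high); a missing age is
    (None, nan, nan).  Ranges that fall inside a single age group resolve
    to that group immediately.
    """
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return None, np.nan, np.nan
    text = str(token).strip()
    if text == "" or text.lower() in ("nan", "na"):
        return None, np.nan, np.nan
    if text in AGE_GROUPS:
        return text, np.nan, np.nan
    m = _RANGE_RE.match(text)
    if m:
        lo, hi = int(m.group(1)), int(m.group(2))
    else:
        m = _PLUS_RE.match(text)
        if m:
            lo, hi = int(m.group(1)), AGE_BOUNDS["65+"][1]
        else:
            m = _INT_RE.match(text)
            if m:
                lo = hi = int(m.group(1))
            else:
                raise ValueError(f"unparseable age token {text!r}")
    if lo > hi:
        raise ValueError(f"invalid age range {text!r}: lower > upper")
    groups = age_groups_overlapping(lo, hi)
    if not groups:
        raise ValueError(f"age range {text!r} overlaps no age group")
    if len(groups) == 1:
        return groups[0], np.nan, np.nan
    return None, float(lo), float(hi)


def load_survey(
    participants_path,
    contacts_path,
    schema: Mapping[str, str] | None = None,
) -> SurveyDataset:
    """Load a survey from a participants CSV and a long contacts CSV.

    ``schema`` optionally maps canonical column names (part_id,
    part_age_group, part_edu, municipality, cnt_age) to the file's actual
    column names.  Unknown participant columns are preserved verbatim as
    covariates.
    """
    schema = dict(schema or {})
    parts = pd.read_csv(participants_path, dtype={schema.get("part_id", "part_id"): str})
    conts = pd.read_csv(
        contacts_path,
        dtype={
            schema.get("part_id", "part_id"): str,
            schema.get("cnt_age", "cnt_age"): str,
        },
    )
    parts = parts.rename(columns={v: k for k, v in schema.items()})
    conts = conts.rename(columns={v: k for k, v in schema.items()})

    missing = [c for c in PARTICIPANT_COLUMNS if c not in parts.columns]
    if missing:
        raise SchemaError(f"participants table missing columns: {missing}")
    missing = [c for c in CONTACT_COLUMNS if c not in conts.columns]
    if missing:
        raise SchemaError(f"contacts table missing columns: {missing}")

    participants = parts.rename(
        columns={"part_age_group": "age", "part_edu": "edu"}
    ).reset_index(drop=True)
    for col, allowed in (("age", AGE_GROUPS), ("edu", EDU_LEVELS)):
        bad = set(participants[col].astype(str)) - set(allowed)
        if bad:
            raise ValueError(f"unknown participant {col} values: {sorted(bad)}")
    child_high = (participants["age"] == "0-14") & (participants["edu"] == "high")
    if child_high.any():
        raise ValueError(
            "participants aged 0-14 must have mid_low education; offending "
            f"part_ids: {participants.loc[child_high, 'part_id'].tolist()[:5]}"
        )

    unknown = set(conts["part_id"]) - set(participants["part_id"])
    if unknown:
        raise ValueError(f"contacts reference unknown part_ids: {sorted(unknown)[:5]}")

    exact, lo, hi = [], [], []
    for row_number, token in enumerate(conts["cnt_age"]):
        try:
            g, rlo, rhi = _parse_age_token(token)
        except ValueError as err:
            raise ValueError(f"contacts row {row_number}: {err}") from err
        exact.append(g)
        lo.append(rlo)
        hi.append(rhi)

    contacts = pd.DataFrame(
        {
            "part_id": conts["part_id"].astype(str),
            "order": conts.groupby("part_id").cumcount(),
            "cnt_age": conts["cnt_age"],
            "age_group": pd.array(exact, dtype="string"),
            "range_low": lo,
            "range_high": hi,
            "retained": True,
        }
    )
    return SurveyDataset(participants, contacts, meta={"truncation_cap": None})


def truncate_contacts(ds: SurveyDataset, cap: int = 50) -> SurveyDataset:
    """Cap each participant's effective contact count at ``cap``.

    The first ``cap`` contacts in file order are retained (deterministic,
    auditable); dropped rows stay in the table flagged retained=False.
    """
    if cap < 0:
        raise ValueError("cap must be >= 0")
    out = ds.copy()
    out.contacts["retained"] = out.contacts["order"] < cap
    out.meta["truncation_cap"] = cap
    return out


def _empirical_age_distributions(ds: SurveyDataset) -> np.ndarray:
    """Known-contact age distribution per participant age group (4 x 4).

    Rows for participant groups with no age-known contacts anywhere fall
    back to the pooled distribution over all participants (logged).
    """
    part_age = ds.participants.set_index("part_id")["age"]
    known = ds.contacts[ds.contacts["age_group"].notna() & ds.contacts["retained"]]
    pg = known["part_id"].map(part_age)
    counts = np.zeros((4, 4))
    for i, pa in enumerate(AGE_GROUPS):
        sub = known.loc[pg == pa, "age_group"]
        for j, ca in enumerate(AGE_GROUPS):
            counts[i, j] = (sub == ca).sum()
    pooled = counts.sum(axis=0)
    if pooled.sum() == 0:
        raise ValueError("no age-known contacts anywhere; cannot impute")
    dist = np.empty_like(counts)
    for i, pa in enumerate(AGE_GROUPS):
        if counts[i].sum() == 0:
            logger.warning(
                "no age-known contacts for participants aged %s; "
                "falling back to pooled distribution",
                pa,
            )
            dist[i] = pooled / pooled.sum()
        else:
            dist[i] = counts[i] / counts[i].sum()
    return dist


def impute_contact_ages(ds: SurveyDataset, seed: int) -> SurveyDataset:
    """Resolve missing and ranged contact ages to exact age groups.

    Missing ages are drawn from the empirical distribution of age-known
    contacts of participants in the same age group; ranged reports are
    drawn only among the groups the range overlaps, with that same
    distribution restricted and renormalized.
    """
    out = ds.copy()
    unresolved = out.contacts["age_group"].isna()
    if not unresolved.any():
        out.meta["imputation_seed"] = seed
        return out

    rng = np.random.default_rng(seed)
    dist = _empirical_age_distributions(ds)
    part_age = out.participants.set_index("part_id")["age"]
    contact_part_age = out.contacts["part_id"].map(part_age)

    age_array = out.contacts["age_group"].to_numpy(dtype=object)
    for i, pa in enumerate(AGE_GROUPS):
        sel = (unresolved & (contact_part_age == pa)).to_numpy()
        if not sel.any():
            continue
        lo = out.contacts.loc[sel, "range_low"].to_numpy()
        hi = out.contacts.loc[sel, "range_high"].to_numpy()
        # allowed-group mask per contact: all groups if missing, else the
        # groups overlapped by the reported year range
        masks = np.ones((sel.sum(), 4), dtype=bool)
        ranged = ~np.isnan(lo)
        bounds = np.array([AGE_BOUNDS[g] for g in AGE_GROUPS], dtype=float)
        if ranged.any():
            masks[ranged] = ~(
                (hi[ranged, None] < bounds[None, :, 0])
                | (lo[ranged, None] > bounds[None, :, 1])
            )
        weights = masks * dist[i][None, :]
        empty = weights.sum(axis=1) == 0
        if empty.any():
            # range excludes every group with observed mass: fall back to
            # uniform over the allowed groups
            logger.warning(
                "%d ranged contacts of %s participants have zero empirical "
                "mass in range; using uniform weights over the range",
                int(empty.sum()),
                pa,
            )
            weights[empty] = masks[empty].astype(float)
        weights = weights / weights.sum(axis=1, keepdims=True)
        draws = (rng.random(len(weights))[:, None] > np.cumsum(weights, axis=1)).sum(
            axis=1
        )
        age_array[sel] = np.array(AGE_GROUPS, dtype=object)[draws]

    out.contacts["age_group"] = pd.array(age_array, dtype="string")
    out.meta["imputation_seed"] = seed
    return out


def municipality_sep(table: pd.DataFrame) -> pd.Series:
    """Building-weighted mean SEP index per municipality.

    ``table`` columns: municipality, building, sep_index, residents.
    """
    required = {"municipality", "sep_index", "residents"}
    missing = required - set(table.columns)
    if missing:
        raise SchemaError(f"municipality table missing columns: {sorted(missing)}")
    if (table["residents"] < 0).any():
        raise ValueError("residents must be >= 0")
    grouped = table.groupby("municipality")
    residents = grouped["residents"].sum()
    zero = residents[residents == 0]
    if len(zero):
        raise ValueError(
            f"municipalities with zero total residents: {list(zero.index)[:5]}"
        )
    weighted = grouped.apply(
        lambda g: float(np.average(g["sep_index"], weights=g["residents"])),
        include_groups=False,
    )
    return weighted.sort_index()


def assign_sep(ds: SurveyDataset, table: pd.DataFrame) -> SurveyDataset:
    """Label participants low/high SEP by their municipality's mean SEP.

    The threshold is the median of municipality-level SEP values (one
    value per municipality in the table); municipalities at or below the
    median are low SEP.
    """
    sep_m = municipality_sep(table)
    unknown = set(ds.participants["municipality"].astype(str)) - set(
        sep_m.index.astype(str)
    )
    if unknown:
        raise ValueError(
            f"participant municipalities absent from SEP table: {sorted(unknown)[:10]}"
        )
    threshold = float(sep_m.median())
    out = ds.copy()
    values = (
        out.participants["municipality"].astype(str).map(sep_m.rename(index=str))
    )
    out.participants["sep_m"] = values
    out.participants["sep"] = np.where(values <= threshold, "low", "high")
    out.meta["sep_threshold"] = threshold
    return out


def bootstrap_mean_ci(
    values: np.ndarray, n_boot: int, rng: np.random.Generator, level: float = 0.95
) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean of ``values``."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0:
        return np.nan, np.nan
    idx = rng.integers(0, n, size=(n_boot, n))
    means = values[idx].mean(axis=1)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(means, [alpha, 1 - alpha])
    return float(lo), float(hi)


def crude_group_means(
    ds: SurveyDataset, n_boot: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Crude mean contact numbers per stratum with bootstrap 95% CIs.

    Requires truncation and SEP assignment; participants are resampled
    with replacement within each stratum independently.  Empty strata are
    reported with n=0 and null means rather than an error.
    """
    if ds.meta.get("truncation_cap") is None:
        raise ValueError("truncate_contacts must be applied first")
    strata = ds.strata()
    counts = ds.effective_counts()
    rng = np.random.default_rng(seed)
    rows = []
    for key in GROUP_KEYS:
        mask = (
            (strata["age"] == key.age)
            & (strata["sep"] == key.sep)
            & (strata["edu"] == key.edu)
        )
        vals = counts[mask.to_numpy()].to_numpy(dtype=float)
        if len(vals) == 0:
            rows.append((key.age, key.sep, key.edu, 0, np.nan, np.nan, np.nan))
            continue
        mean = float(vals.mean())
        lo, hi = bootstrap_mean_ci(vals, n_boot, rng)
        rows.append((key.age, key.sep, key.edu, len(vals), mean, lo, hi))
    return pd.DataFrame(
        rows,
        columns=["age", "sep", "edu", "n_participants", "mean", "ci_low", "ci_high"],
    )
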