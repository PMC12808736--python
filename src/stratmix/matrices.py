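"""Age-stratified and intermediate contact matrices.

The age-stratified matrix M has entries M_ij = mean number of daily
contacts a participant in age group i reports with individuals in age
group j.  Because contacts are mutual, the total contact volume must
balance: N_i M_ij = N_j M_ji.  Survey estimates violate this, so the
matrix is corrected to

    M^rec_ij = (N_i M_ij + N_j M_ji) / (2 N_i),

which preserves total volume and enforces the symmetry exactly.

The intermediate matrix \\bar M is disaggregated on the participant side
only: rows are the 14 (age, SEP, education) strata, columns the 4 age
groups of the contacts (whose socio-economic attributes the survey does
not record).  It is adjusted, by proportional rescaling within each
(participant-age, contact-age) cell, to aggregate exactly back to M^rec.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .groups import (
    AGE_GROUPS,
    AGE_SUBGROUPS,
    GROUP_KEYS,
    N_GROUPS,
    PopulationTable,
)
from .preprocess import SurveyDataset

#: Relative tolerance for reciprocity / aggregation consistency checks.
SYMMETRY_RTOL = 1e-9


@dataclass(frozen=True)
class AgeContactMatrix:
    """4x4 mean-contacts matrix over age groups."""

    values: np.ndarray
    corrected: bool = False
    population: PopulationTable | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (4, 4):
            raise ValueError(f"expected 4x4 matrix, got {values.shape}")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("matrix entries must be finite and >= 0")
        object.__setattr__(self, "values", values)
        if self.corrected:
            if self.population is None:
                raise ValueError("corrected matrix requires a population table")
            check_age_reciprocity(values, self.population)


@dataclass(frozen=True)
class IntermediateMatrix:
    """14x4 matrix: participant stratum x contact age group."""

    values: np.ndarray
    adjusted: bool = False
    population: PopulationTable | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (N_GROUPS, 4):
            raise ValueError(f"expected {N_GROUPS}x4 matrix, got {values.shape}")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("matrix entries must be finite and >= 0")
        object.__setattr__(self, "values", values)

    def aggregate_to_age(self, pop: PopulationTable | None = None) -> np.ndarray:
        """Population-weighted aggregation of rows to the 4 age groups."""
        pop = pop or self.population
        if pop is None:
            raise ValueError("population table required for aggregation")
        out = np.zeros((4, 4))
        n_age = pop.age_totals()
        for i, age in enumerate(AGE_GROUPS):
            idx = list(AGE_SUBGROUPS[age])
            out[i] = pop.counts[idx] @ self.values[idx] / n_age[i]
        return out


def check_age_reciprocity(
    values: np.ndarray, pop: PopulationTable, rtol: float = SYMMETRY_RTOL
) -> None:
    n_age = pop.age_totals()
    total = n_age[:, None] * values
    scale = max(float(np.abs(total).max()), 1.0)
    if np.abs(total - total.T).max() > rtol * scale:
        raise ValueError("matrix is not reciprocal with respect to the population")


def estimate_age_matrix(ds: SurveyDataset) -> AgeContactMatrix:
    """Raw age matrix: per-participant mean contacts from group i to j.

    Requires imputed contact ages; every age group must have at least one
    participant.
    """
    contacts = ds.contacts[ds.contacts["retained"]]
    if contacts["age_group"].isna().any():
        raise ValueError("contact ages not fully imputed")
    part_age = ds.participants.set_index("part_id")["age"]
    n_by_age = ds.participants["age"].value_counts()
    empty = [a for a in AGE_GROUPS if n_by_age.get(a, 0) == 0]
    if empty:
        raise ValueError(f"age groups with zero participants: {empty}")
    pa = contacts["part_id"].map(part_age)
    M = np.zeros((4, 4))
    for i, ag_i in enumerate(AGE_GROUPS):
        sub = contacts.loc[(pa == ag_i).to_numpy(), "age_group"]
        for j, ag_j in enumerate(AGE_GROUPS):
            M[i, j] = (sub == ag_j).sum() / n_by_age[ag_i]
    return AgeContactMatrix(M, corrected=False)


def reciprocity_correct(M: AgeContactMatrix, pop: PopulationTable) -> AgeContactMatrix:
    """M^rec_ij = (N_i M_ij + N_j M_ji) / (2 N_i)."""
    n_age = pop.age_totals()
    if np.any(n_age <= 0):
        raise ValueError("every age group needs a positive population")
    total = n_age[:, None] * M.values
    corrected = (total + total.T) / (2.0 * n_age[:, None])
    return AgeContactMatrix(corrected, corrected=True, population=pop)


def estimate_intermediate_matrix(ds: SurveyDataset) -> IntermediateMatrix:
    """Raw intermediate matrix: stratum-level mean contacts per age group.

    Every one of the 14 strata must contain at least one participant.
    """
    contacts = ds.contacts[ds.contacts["retained"]]
    if contacts["age_group"].isna().any():
        raise ValueError("contact ages not fully imputed")
    strata = ds.strata()
    labels = strata["age"] + "|" + strata["sep"] + "|" + strata["edu"]
    n_by_stratum = labels.value_counts()
    empty = [k for k in GROUP_KEYS if n_by_stratum.get(k.label, 0) == 0]
    if empty:
        raise ValueError(f"strata with zero participants: {[k.label for k in empty]}")
    part_label = labels.set_axis(ds.participants["part_id"])
    cl = contacts["part_id"].map(part_label)
    M = np.zeros((N_GROUPS, 4))
    for s, key in enumerate(GROUP_KEYS):
        sub = contacts.loc[(cl == key.label).to_numpy(), "age_group"]
        for j, ag_j in enumerate(AGE_GROUPS):
            M[s, j] = (sub == ag_j).sum() / n_by_stratum[key.label]
    return IntermediateMatrix(M, adjusted=False)


def reciprocity_adjust_intermediate(
    bar_M: IntermediateMatrix,
    M_rec: AgeContactMatrix,
    pop: PopulationTable,
) -> IntermediateMatrix:
    """Rescale \\bar M rows to aggregate exactly to M^rec.

    Within each (participant-age i, contact-age j) cell, all subgroup
    entries are multiplied by M^rec_ij / A_ij where A_ij is the
    population-weighted aggregate of the raw entries — the minimal
    adjustment that achieves aggregation consistency while preserving the
    within-cell contact proportions across (SEP, education) subgroups.
    """
    if not M_rec.corrected:
        raise ValueError("M_rec must be reciprocity-corrected")
    A = bar_M.aggregate_to_age(pop)
    adjusted = bar_M.values.copy()
    for i, age in enumerate(AGE_GROUPS):
        idx = list(AGE_SUBGROUPS[age])
        for j in range(4):
            target = M_rec.values[i, j]
            if A[i, j] > 0:
                adjusted[idx, j] *= target / A[i, j]
            elif target > 0:
                raise ValueError(
                    f"cannot rescale zero aggregate mass in cell "
                    f"({age}, {AGE_GROUPS[j]}) to match M^rec={target}"
                )
    return IntermediateMatrix(adjusted, adjusted=True, population=pop)
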