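"""Standalone constraint validation for matrix files.

Checks the declared kind's invariants — positivity always; reciprocity
for corrected age matrices and expanded matrices; aggregation consistency
for expanded (against an intermediate matrix) and adjusted intermediate
(against a corrected age matrix) files — and reports a machine-readable
pass/fail with the maximum violation magnitude per constraint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .groups import PopulationTable
from .matrices import SYMMETRY_RTOL
from . import io as smio


class MatrixParseError(ValueError):
    """The file could not be read as a matrix of the declared kind."""


@dataclass(frozen=True)
class ConstraintResult:
    passed: bool
    max_violation: float
    detail: str = ""


def _positivity(values: np.ndarray) -> ConstraintResult:
    worst = float(values.min())
    if worst < 0:
        a, b = np.unravel_index(int(values.argmin()), values.shape)
        return ConstraintResult(False, -worst, f"negative cell ({a}, {b})")
    return ConstraintResult(True, 0.0)


def _reciprocity(values: np.ndarray, N: np.ndarray, rtol: float) -> ConstraintResult:
    T = N[:, None] * values
    scale = max(float(np.abs(T).max()), 1.0)
    gap = float(np.abs(T - T.T).max() / scale)
    return ConstraintResult(gap <= rtol, gap)


def validate_matrix(
    matrix_path,
    population_path,
    kind: str,
    intermediate_path=None,
    age_matrix_path=None,
    rtol: float = SYMMETRY_RTOL,
) -> dict[str, ConstraintResult]:
    """Validate the invariants of a matrix file of the declared kind.

    kind 'age': positivity; reciprocity if flagged corrected.
    kind 'intermediate': positivity; aggregation to the age matrix if
    flagged adjusted and ``age_matrix_path`` given.
    kind 'expanded': positivity, reciprocity; aggregation if
    ``intermediate_path`` given.
    """
    if kind not in ("age", "intermediate", "expanded"):
        raise ValueError(f"unknown matrix kind {kind!r}")
    try:
        pop = PopulationTable.from_csv(population_path)
    except Exception as err:
        raise MatrixParseError(f"population table unreadable: {err}") from err
    try:
        values, _rl, _cl, meta = smio.read_matrix(matrix_path)
    except Exception as err:
        raise MatrixParseError(f"matrix file unreadable: {err}") from err

    report: dict[str, ConstraintResult] = {"positivity": _positivity(values)}
    if kind == "age":
        if values.shape != (4, 4):
            raise MatrixParseError(f"age matrix must be 4x4, got {values.shape}")
        if meta.get("corrected", False):
            report["reciprocity"] = _reciprocity(values, pop.age_totals(), rtol)
    elif kind == "intermediate":
        if values.shape != (14, 4):
            raise MatrixParseError(
                f"intermediate matrix must be 14x4, got {values.shape}"
            )
        if meta.get("adjusted", False) and age_matrix_path is not None:
            age = smio.read_age_matrix(age_matrix_path, pop)
            from .matrices import IntermediateMatrix

            agg = IntermediateMatrix(
                np.clip(values, 0, None), population=pop
            ).aggregate_to_age(pop)
            scale = max(float(np.abs(age.values).max()), 1.0)
            gap = float(np.abs(agg - age.values).max() / scale)
            report["aggregation"] = ConstraintResult(gap <= rtol, gap)
    else:
        if values.shape != (14, 14):
            raise MatrixParseError(
                f"expanded matrix must be 14x14, got {values.shape}"
            )
        report["reciprocity"] = _reciprocity(values, pop.counts, rtol)
        if intermediate_path is not None:
            inter = smio.read_intermediate_matrix(intermediate_path, pop)
            from .expansion import ExpandedMatrix

            agg = ExpandedMatrix(
                np.clip(values, 0, None), pop
            ).aggregate_rows_to_age()
            scale = max(float(np.abs(inter.values).max()), 1.0)
            gap = float(np.abs(agg - inter.values).max() / scale)
            report["aggregation"] = ConstraintResult(gap <= rtol, gap)
    return report
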