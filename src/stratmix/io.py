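"""CSV round-tripping for matrices and run metadata.

Matrices travel as long-format CSV (row_group, col_group, value) with a
JSON metadata sidecar (kind, corrected/adjusted flags, seeds, input
hashes) next to the CSV as ``<name>.meta.json``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .groups import AGE_GROUPS, GROUP_KEYS, N_GROUPS, PopulationTable
from .matrices import AgeContactMatrix, IntermediateMatrix
from .expansion import ExpandedMatrix

AGE_LABELS = list(AGE_GROUPS)
STRATUM_LABELS = [k.label for k in GROUP_KEYS]


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_matrix(
    values: np.ndarray,
    row_labels: list[str],
    col_labels: list[str],
    path,
    meta: dict | None = None,
) -> None:
    path = Path(path)
    rows = []
    for a, rl in enumerate(row_labels):
        for b, cl in enumerate(col_labels):
            rows.append((rl, cl, values[a, b]))
    pd.DataFrame(rows, columns=["row_group", "col_group", "value"]).to_csv(
        path, index=False
    )
    with open(_meta_path(path), "w") as fh:
        json.dump(meta or {}, fh, indent=1, sort_keys=True)


def read_matrix(path) -> tuple[np.ndarray, list[str], list[str], dict]:
    path = Path(path)
    frame = pd.read_csv(path)
    required = {"row_group", "col_group", "value"}
    if not required <= set(frame.columns):
        raise ValueError(f"matrix CSV missing columns {sorted(required)}")
    row_labels = list(dict.fromkeys(frame["row_group"]))
    col_labels = list(dict.fromkeys(frame["col_group"]))
    values = np.full((len(row_labels), len(col_labels)), np.nan)
    ri = {l: i for i, l in enumerate(row_labels)}
    ci = {l: i for i, l in enumerate(col_labels)}
    for _, row in frame.iterrows():
        values[ri[row["row_group"]], ci[row["col_group"]]] = row["value"]
    if np.isnan(values).any():
        raise ValueError("matrix CSV does not cover all (row, col) cells")
    meta = {}
    mp = _meta_path(path)
    if mp.exists():
        with open(mp) as fh:
            meta = json.load(fh)
    return values, row_labels, col_labels, meta


def write_age_matrix(M: AgeContactMatrix, path, extra_meta: dict | None = None):
    meta = {"kind": "age", "corrected": M.corrected}
    meta.update(extra_meta or {})
    write_matrix(M.values, AGE_LABELS, AGE_LABELS, path, meta)


def write_intermediate_matrix(
    M: IntermediateMatrix, path, extra_meta: dict | None = None
):
    meta = {"kind": "intermediate", "adjusted": M.adjusted}
    meta.update(extra_meta or {})
    write_matrix(M.values, STRATUM_LABELS, AGE_LABELS, path, meta)


def write_expanded_matrix(M: ExpandedMatrix, path, extra_meta: dict | None = None):
    meta = {"kind": "expanded"}
    meta.update(extra_meta or {})
    write_matrix(M.values, STRATUM_LABELS, STRATUM_LABELS, path, meta)


def read_age_matrix(path, pop: PopulationTable | None = None) -> AgeContactMatrix:
    values, rl, cl, meta = read_matrix(path)
    if rl != AGE_LABELS or cl != AGE_LABELS:
        raise ValueError("age matrix CSV must use the four age-group labels")
    return AgeContactMatrix(
        values, corrected=bool(meta.get("corrected", False)), population=pop
    )


def read_intermediate_matrix(
    path, pop: PopulationTable | None = None
) -> IntermediateMatrix:
    values, rl, cl, meta = read_matrix(path)
    if rl != STRATUM_LABELS or cl != AGE_LABELS:
        raise ValueError(
            "intermediate matrix CSV must use stratum rows and age columns"
        )
    return IntermediateMatrix(
        values, adjusted=bool(meta.get("adjusted", False)), population=pop
    )


def read_expanded_matrix(path, pop: PopulationTable) -> ExpandedMatrix:
    values, rl, cl, _meta = read_matrix(path)
    if rl != STRATUM_LABELS or cl != STRATUM_LABELS:
        raise ValueError("expanded matrix CSV must use stratum labels on both axes")
    return ExpandedMatrix(values, pop)
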