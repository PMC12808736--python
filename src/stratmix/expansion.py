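"""Expansion of the intermediate matrix to a fully stratified matrix.

The adjusted intermediate matrix fixes, for every participant stratum s
and contact age group j, the mean number of contacts \\bar M^rec_{s,j} —
but not how those contacts distribute over the (SEP, education) subgroups
of age j.  A fully stratified 14x14 matrix \\hat M must satisfy

  (i)   reciprocity:   N_s \\hat M_{s,t} = N_t \\hat M_{t,s};
  (ii)  aggregation:   sum_{u,c} \\hat M_{(i,v,d),(j,u,c)} = \\bar M^rec_{(i,v,d),j};
  (iii) positivity:    \\hat M_{s,t} >= 0.

In total-contact units T_{s,t} = N_s \\hat M_{s,t} the problem decomposes
into 10 independent blocks, one per unordered age pair: each block is a
transportation problem with fixed row and column margins, whose solution
set is a transportation polytope (symmetric for same-age blocks).  The
free coordinates of each block are exposed as assortativity parameters
q in (0,1):

* the block's null space (margin-preserving directions) is spanned by an
  ordered canonical basis whose leading vectors are *assortativity
  tilts* — mass transfers between cross-level and within-level cells of
  the SEP, education, and joint dimensions, weighted by the independence
  table so that a single coordinate sweeps the block from its minimal to
  its maximal cross-level contact volume — completed by pairwise
  exchange matrices orthogonalized against them;
* coordinates are sampled sequentially, each uniform over the exact
  feasibility interval conditional on the coordinates already fixed, so
  every draw satisfies positivity and the margins exactly.

Assortativity along one social dimension is summarized by aggregating
\\hat M to a 2x2 matrix and taking the trace of its row-normalized
(proportion-of-contacts) form: 2 = fully assortative, 1 = proportional
mixing, 0 = fully disassortative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .groups import (
    AGE_GROUPS,
    AGE_SUBGROUPS,
    EDU_LEVELS,
    GROUP_KEYS,
    N_GROUPS,
    SEP_LEVELS,
    PopulationTable,
)
from .matrices import SYMMETRY_RTOL, AgeContactMatrix, IntermediateMatrix

#: Unordered age pairs, lexicographic: the 10 independent blocks.
BLOCK_PAIRS: tuple[tuple[int, int], ...] = tuple(
    (i, j) for i in range(4) for j in range(i, 4)
)


class InfeasibleMarginsError(ValueError):
    """No nonnegative block solution exists for the given margins."""


class ExpansionRejected(Exception):
    """A sampled draw left the feasible polytope (numerical safeguard)."""

    def __init__(self, block: tuple[int, int]):
        self.block = block
        super().__init__(f"negative entry in block {block}")


@dataclass(frozen=True)
class ExpandedMatrix:
    """14x14 mean-contacts matrix over the full strata, with population."""

    values: np.ndarray
    population: PopulationTable

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (N_GROUPS, N_GROUPS):
            raise ValueError(f"expected {N_GROUPS}x{N_GROUPS}, got {values.shape}")
        object.__setattr__(self, "values", values)

    def totals(self) -> np.ndarray:
        """Total contact volume T_{s,t} = N_s \\hat M_{s,t}."""
        return self.population.counts[:, None] * self.values

    def aggregate_rows_to_age(self) -> np.ndarray:
        """Sum columns over contacted strata by age: the implied 14x4."""
        out = np.zeros((N_GROUPS, 4))
        for j, age in enumerate(AGE_GROUPS):
            out[:, j] = self.values[:, list(AGE_SUBGROUPS[age])].sum(axis=1)
        return out

    def spectral_radius(self) -> float:
        return float(np.abs(np.linalg.eigvals(self.values)).max())

    def validate(
        self,
        bar_M_rec: IntermediateMatrix | None = None,
        rtol: float = SYMMETRY_RTOL,
    ) -> dict[str, float]:
        """Check constraints (i)-(iii); returns max violation magnitudes."""
        T = self.totals()
        scale = max(float(np.abs(T).max()), 1.0)
        report = {
            "positivity": float(max(0.0, -self.values.min())),
            "reciprocity": float(np.abs(T - T.T).max() / scale),
        }
        if bar_M_rec is not None:
            agg = self.aggregate_rows_to_age()
            mscale = max(float(np.abs(bar_M_rec.values).max()), 1.0)
            report["aggregation"] = float(
                np.abs(agg - bar_M_rec.values).max() / mscale
            )
        bad = [
            name
            for name, v in report.items()
            if v > (rtol if name != "positivity" else rtol * scale)
        ]
        if bad:
            raise ValueError(f"expanded-matrix constraints violated: {bad} ({report})")
        return report


@dataclass(frozen=True)
class BlockMargins:
    """Row/column total-contact margins of one age-pair block."""

    age_pair: tuple[int, int]
    row_strata: tuple[int, ...]  # global stratum indices (subgroups of i)
    col_strata: tuple[int, ...]  # global stratum indices (subgroups of j)
    R: np.ndarray  # total contacts from each row subgroup to age j
    C: np.ndarray  # total contacts from each column subgroup to age i
    symmetric: bool


def build_block_margins(
    bar_M_rec: IntermediateMatrix,
    pop: PopulationTable,
    age_pair: tuple[int, int],
    rtol: float = 1e-6,
) -> BlockMargins:
    """Margins R_a = N_a \\bar M^rec_{a,j}, C_b = N_b \\bar M^rec_{b,i}.

    Consistency (sum R = sum C) holds iff the intermediate matrix was
    reciprocity-adjusted; a violation raises InfeasibleMarginsError.
    """
    i, j = age_pair
    rows = tuple(AGE_SUBGROUPS[AGE_GROUPS[i]])
    cols = tuple(AGE_SUBGROUPS[AGE_GROUPS[j]])
    R = pop.counts[list(rows)] * bar_M_rec.values[list(rows), j]
    C = pop.counts[list(cols)] * bar_M_rec.values[list(cols), i]
    if np.any(R < 0) or np.any(C < 0):
        raise InfeasibleMarginsError(f"negative margins in block {age_pair}")
    scale = max(R.sum(), C.sum(), 1.0)
    if abs(R.sum() - C.sum()) > rtol * scale:
        raise InfeasibleMarginsError(
            f"block {age_pair} margins inconsistent "
            f"(sum R = {R.sum():.6g}, sum C = {C.sum():.6g}); "
            "was the intermediate matrix reciprocity-adjusted?"
        )
    return BlockMargins(age_pair, rows, cols, R, C, symmetric=i == j)


def _exchange_basis(m: int, n: int, symmetric: bool) -> list[np.ndarray]:
    """Pairwise +-1 exchange matrices spanning the margin null space.

    Off-diagonal blocks: (m-1)(n-1) exchanges against the last row and
    column, lexicographic in (a,b).  Symmetric blocks: m(m-1)/2
    symmetrized exchanges, +1 at (a,a),(b,b), -1 at (a,b),(b,a), a < b.
    """
    basis = []
    if symmetric:
        for a in range(m):
            for b in range(a + 1, m):
                G = np.zeros((m, m))
                G[a, a] = G[b, b] = 1.0
                G[a, b] = G[b, a] = -1.0
                basis.append(G)
    else:
        for a in range(m - 1):
            for b in range(n - 1):
                G = np.zeros((m, n))
                G[a, b] = G[m - 1, n - 1] = 1.0
                G[a, n - 1] = G[m - 1, b] = -1.0
                basis.append(G)
    return basis


def _tilt_direction(T0: np.ndarray, S: np.ndarray, symmetric: bool) -> np.ndarray:
    """Margin-preserving mass transfer along the cell classes of S.

    Solves for row/column offsets u, v such that D = T0 * (S - u_a - v_b)
    has zero row and column sums; moving along D transfers contact volume
    between the S=1 and S=0 cells proportionally to the independence
    table, so the extreme steps empty one class — the block's minimal or
    maximal cross-level volume.
    """
    m, n = T0.shape
    rw, cw = T0.sum(axis=1), T0.sum(axis=0)
    A = np.zeros((m + n, m + n))
    A[:m, :m] = np.diag(rw)
    A[:m, m:] = T0
    A[m:, :m] = T0.T
    A[m:, m:] = np.diag(cw)
    b = np.concatenate([(T0 * S).sum(axis=1), (T0 * S).sum(axis=0)])
    sol = np.linalg.lstsq(A, b, rcond=None)[0]
    D = T0 * (S - sol[:m, None] - sol[None, m:])
    if symmetric:
        D = (D + D.T) / 2.0
    return D


def _canonical_sign(D: np.ndarray) -> np.ndarray:
    flat = D.ravel()
    nz = np.nonzero(np.abs(flat) > 1e-12 * max(np.abs(flat).max(), 1e-300))[0]
    if len(nz) and flat[nz[0]] < 0:
        return -D
    return D


def block_dof(margins: BlockMargins) -> int:
    m, n = len(margins.row_strata), len(margins.col_strata)
    return m * (m - 1) // 2 if margins.symmetric else (m - 1) * (n - 1)


def _independence_table(margins: BlockMargins) -> np.ndarray:
    S = margins.R.sum()
    if S <= 0:
        return np.zeros((len(margins.R), len(margins.C)))
    return np.outer(margins.R, margins.C) / S


def _block_basis(margins: BlockMargins) -> np.ndarray:
    """Ordered canonical null-space basis of one block.

    Leading candidates are the SEP, education and joint assortativity
    tilts (weighted by the independence table); the basis is completed by
    exchange matrices, all Gram-Schmidt-orthogonalized in order, unit-
    normalized by max entry, sign-canonicalized.  Degenerate candidates
    (zero or linearly dependent) are dropped, so the basis dimension
    always equals the null-space dimension.
    """
    m, n = len(margins.row_strata), len(margins.col_strata)
    T0 = _independence_table(margins)
    candidates: list[np.ndarray] = []
    if T0.sum() > 0:
        for attr in ("sep", "edu"):
            S = np.array(
                [
                    [
                        getattr(GROUP_KEYS[a], attr) != getattr(GROUP_KEYS[b], attr)
                        for b in margins.col_strata
                    ]
                    for a in margins.row_strata
                ],
                dtype=float,
            )
            candidates.append(_tilt_direction(T0, S, margins.symmetric))
        both = np.array(
            [
                [
                    (GROUP_KEYS[a].sep != GROUP_KEYS[b].sep)
                    and (GROUP_KEYS[a].edu != GROUP_KEYS[b].edu)
                    for b in margins.col_strata
                ]
                for a in margins.row_strata
            ],
            dtype=float,
        )
        candidates.append(_tilt_direction(T0, both, margins.symmetric))
    # normalize tilts to unit peak, dropping numerically-zero ones (e.g.
    # the education tilt of the children blocks, where the indicator is
    # constant across rows and the centered direction vanishes)
    t0_scale = max(float(T0.max()), 1.0)
    candidates = [
        D / np.abs(D).max()
        for D in candidates
        if np.abs(D).max() >= 1e-9 * t0_scale
    ]
    candidates.extend(_exchange_basis(m, n, margins.symmetric))
    basis: list[np.ndarray] = []
    dof = block_dof(margins)
    for D in candidates:
        if len(basis) == dof:
            break
        for B in basis:
            D = D - (D * B).sum() / (B * B).sum() * B
        peak = np.abs(D).max()
        if peak > 1e-8:
            basis.append(_canonical_sign(D / peak))
    if len(basis) != dof:
        raise RuntimeError(
            f"basis construction found {len(basis)} of {dof} directions "
            f"for block {margins.age_pair}"
        )
    return np.array(basis) if basis else np.zeros((0, m, n))


def _sequential_draw(
    T0: np.ndarray, basis: np.ndarray, q: np.ndarray
) -> np.ndarray:
    """Walk the null-space coordinates with conditional uniform steps.

    Each coordinate moves uniformly within the feasibility interval of
    its direction given the table accumulated so far, so the final table
    is nonnegative with exact margins for every q in [0,1]^dof.
    """
    T = T0.copy()
    for k in range(len(basis)):
        G = basis[k]
        pos, neg = G > 0, G < 0
        hi = float((T[neg] / -G[neg]).min()) if neg.any() else 0.0
        lo = -float((T[pos] / G[pos]).min()) if pos.any() else 0.0
        T = T + (lo + q[k] * (hi - lo)) * G
    return T


def sample_block(
    margins: BlockMargins, q_block: np.ndarray, rtol: float = 1e-12
) -> np.ndarray:
    """Total-contacts block T with exact margins from coordinates q.

    The q coordinates parameterize the block's transportation polytope
    through the canonical ordered basis and sequential conditional
    intervals; positivity holds by construction (a residual negative
    entry beyond numerical tolerance raises ExpansionRejected).
    """
    q_block = np.asarray(q_block, dtype=float)
    dof = block_dof(margins)
    if q_block.shape != (dof,):
        raise ValueError(f"block {margins.age_pair} expects {dof} q values")
    if np.any(q_block < 0) or np.any(q_block > 1):
        raise ValueError("q values must lie in [0, 1]")
    T0 = _independence_table(margins)
    if T0.sum() <= 0:
        return T0
    T = _sequential_draw(T0, _block_basis(margins), q_block)
    if T.min() < -rtol * max(margins.R.sum(), 1.0):
        raise ExpansionRejected(margins.age_pair)
    return np.clip(T, 0.0, None)


def _q_layout() -> list[tuple[tuple[int, int], int]]:
    """(age_pair, dof) per block in canonical order."""
    layout = []
    for i, j in BLOCK_PAIRS:
        m = len(AGE_SUBGROUPS[AGE_GROUPS[i]])
        n = len(AGE_SUBGROUPS[AGE_GROUPS[j]])
        dof = m * (m - 1) // 2 if i == j else (m - 1) * (n - 1)
        layout.append(((i, j), dof))
    return layout


def total_dof(pop: PopulationTable | None = None) -> int:
    """Number of free assortativity parameters q (55 for the 14 strata)."""
    return sum(d for _, d in _q_layout())


def expand_matrix(
    bar_M_rec: IntermediateMatrix,
    pop: PopulationTable,
    q: np.ndarray,
) -> ExpandedMatrix:
    """Assemble the 14x14 per-capita matrix from the 10 block solutions.

    ``q`` is the flat vector of assortativity parameters in [0,1], in
    canonical block order (total length 55).
    """
    if not bar_M_rec.adjusted:
        raise ValueError("intermediate matrix must be reciprocity-adjusted")
    q = np.asarray(q, dtype=float)
    layout = _q_layout()
    need = sum(d for _, d in layout)
    if q.shape != (need,):
        raise ValueError(f"expected q of length {need}, got {q.shape}")
    N = pop.counts
    if np.any(N <= 0):
        raise ValueError("all 14 strata need positive population")
    hat = np.zeros((N_GROUPS, N_GROUPS))
    pos = 0
    for (i, j), dof in layout:
        margins = build_block_margins(bar_M_rec, pop, (i, j))
        T = sample_block(margins, q[pos : pos + dof])
        pos += dof
        rows, cols = list(margins.row_strata), list(margins.col_strata)
        hat[np.ix_(rows, cols)] = T / N[rows][:, None]
        if i != j:
            hat[np.ix_(cols, rows)] = T.T / N[cols][:, None]
    return ExpandedMatrix(hat, pop)


def homogeneous_expansion(
    M_rec: AgeContactMatrix, pop: PopulationTable
) -> ExpandedMatrix:
    """Expansion with proportional mixing along SEP and education.

    \\hat M_hom_{(i,v,d),(j,u,c)} = M^rec_ij N_{(j,u,c)} / N_j: contacts
    split across contacted subgroups proportionally to their size.
    """
    if not M_rec.corrected:
        raise ValueError("M_rec must be reciprocity-corrected")
    N = pop.counts
    n_age = pop.age_totals()
    hat = np.zeros((N_GROUPS, N_GROUPS))
    for j, age in enumerate(AGE_GROUPS):
        cols = list(AGE_SUBGROUPS[age])
        if n_age[j] <= 0:
            if np.any(M_rec.values[:, j] > 0):
                raise ValueError(f"zero population in age group {age}")
            continue
        for s, key in enumerate(GROUP_KEYS):
            i = AGE_GROUPS.index(key.age)
            hat[s, cols] = M_rec.values[i, j] * N[cols] / n_age[j]
    return ExpandedMatrix(hat, pop)


def aggregate_by_dimension(
    hat_M: ExpandedMatrix, dim: str
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse a 14x14 matrix to 2x2 along 'sep' or 'edu'.

    Columns are summed over contacted strata sharing the level; rows are
    averaged over participant strata sharing the level, weighted by
    stratum population.  Returns (2x2 matrix, level sizes).
    """
    if dim not in ("sep", "edu"):
        raise ValueError(f"unknown dimension {dim!r}")
    levels = SEP_LEVELS if dim == "sep" else EDU_LEVELS
    N = hat_M.population.counts
    member = np.array(
        [[getattr(k, dim) == lev for k in GROUP_KEYS] for lev in levels], dtype=float
    )  # 2 x 14
    col_agg = hat_M.values @ member.T  # 14 x 2
    sizes = member @ N
    agg = (member * N) @ col_agg / sizes[:, None]
    return agg, sizes


def assortativity_index(agg: np.ndarray, sizes: np.ndarray | None = None) -> float:
    """Trace of the row-normalized 2x2 contact matrix.

    Anchors: 2 for a diagonal matrix (fully assortative), 1 for rows
    proportional to contacted-group size (proportional mixing), 0 for a
    zero diagonal (fully disassortative).  ``sizes`` is accepted for
    interface symmetry but the index depends only on contact proportions.
    """
    agg = np.asarray(agg, dtype=float)
    if np.any(agg < 0):
        raise ValueError("aggregated matrix must be nonnegative")
    row_sums = agg.sum(axis=1)
    if np.any(row_sums <= 0):
        raise ValueError("zero row sum: contact proportions undefined")
    P = agg / row_sums[:, None]
    return float(np.trace(P))


def collapse_dimension(hat_M: ExpandedMatrix, dim: str) -> ExpandedMatrix:
    """Make mixing homogeneous along one dimension, keeping the other.

    Contacts toward strata that differ only in ``dim`` are pooled and
    redistributed proportionally to stratum size; participant-side rows
    within a pooled cell are replaced by their population-weighted mean.
    The result is the one-dimensional (age x other-dimension) expansion
    re-embedded on the 14-strata support, reciprocity restored by
    symmetrizing total contacts.
    """
    if dim not in ("sep", "edu"):
        raise ValueError(f"unknown dimension {dim!r}")
    N = hat_M.population.counts
    keep = "edu" if dim == "sep" else "sep"
    cell_of = [(k.age, getattr(k, keep)) for k in GROUP_KEYS]
    cells = sorted(set(cell_of))
    member = np.array([[cell_of[s] == c for s in range(N_GROUPS)] for c in cells])
    vals = np.zeros_like(hat_M.values)
    for c_mask in member:
        pooled = hat_M.values[:, c_mask].sum(axis=1)
        share = N[c_mask] / N[c_mask].sum()
        vals[:, c_mask] = pooled[:, None] * share[None, :]
    for c_mask in member:
        w = N[c_mask] / N[c_mask].sum()
        mean_row = w @ vals[c_mask, :]
        vals[c_mask, :] = mean_row[None, :]
    T = N[:, None] * vals
    T = (T + T.T) / 2.0
    return ExpandedMatrix(T / N[:, None], hat_M.population)


@dataclass(frozen=True)
class _BlockSampler:
    """Precomputed structure of one block's solution set."""

    rows: tuple[int, ...]
    cols: tuple[int, ...]
    T0: np.ndarray
    basis: np.ndarray  # (dof, m, n)
    scale: float

    def draw(self, q: np.ndarray) -> np.ndarray:
        if len(self.basis) == 0:
            return self.T0
        T = _sequential_draw(self.T0, self.basis, q)
        if T.min() < -1e-12 * self.scale:
            raise ExpansionRejected((-1, -1))
        return np.clip(T, 0.0, None)


def _block_samplers(
    bar_M_rec: IntermediateMatrix, pop: PopulationTable
) -> list[_BlockSampler]:
    samplers = []
    for pair in BLOCK_PAIRS:
        margins = build_block_margins(bar_M_rec, pop, pair)
        samplers.append(
            _BlockSampler(
                margins.row_strata,
                margins.col_strata,
                _independence_table(margins),
                _block_basis(margins),
                max(margins.R.sum(), 1.0),
            )
        )
    return samplers


def sample_ensemble(
    bar_M_rec: IntermediateMatrix,
    pop: PopulationTable,
    n: int = 10_000,
    seed: int = 0,
    retry_cap: int = 1000,
    reference: ExpandedMatrix | None = None,
) -> tuple[list[ExpandedMatrix], pd.DataFrame]:
    """Sample ``n`` expanded matrices from uniform q draws.

    Returns the accepted matrices and a summary frame with per-matrix
    assortativity indices along SEP and education and the dominant-
    eigenvalue ratio against the homogeneous expansion (or ``reference``
    when given).  Identical seeds give identical ensembles.  Numerical
    rejections (which the conditional-interval scheme makes exceptional)
    are retried with fresh q up to ``retry_cap`` attempts per matrix.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not bar_M_rec.adjusted:
        raise ValueError("intermediate matrix must be reciprocity-adjusted")
    rng = np.random.default_rng(seed)
    if reference is None:
        M_rec = AgeContactMatrix(
            bar_M_rec.aggregate_to_age(pop), corrected=True, population=pop
        )
        reference = homogeneous_expansion(M_rec, pop)
    rho_ref = reference.spectral_radius()
    N = pop.counts
    if np.any(N <= 0):
        raise ValueError("all 14 strata need positive population")
    samplers = _block_samplers(bar_M_rec, pop)
    matrices: list[ExpandedMatrix] = []
    records = []
    for sample_id in range(n):
        attempts = 0
        while True:
            attempts += 1
            if attempts > retry_cap:
                raise RuntimeError(
                    f"sampling rejection cap exhausted for matrix {sample_id} "
                    f"({len(matrices)} accepted so far)"
                )
            hat = np.zeros((N_GROUPS, N_GROUPS))
            try:
                for sampler in samplers:
                    T = sampler.draw(rng.random(len(sampler.basis)))
                    rows, cols = list(sampler.rows), list(sampler.cols)
                    hat[np.ix_(rows, cols)] = T / N[rows][:, None]
                    if rows != cols:
                        hat[np.ix_(cols, rows)] = T.T / N[cols][:, None]
            except ExpansionRejected:
                continue
            break
        hat_M = ExpandedMatrix(hat, pop)
        agg_sep, _ = aggregate_by_dimension(hat_M, "sep")
        agg_edu, _ = aggregate_by_dimension(hat_M, "edu")
        records.append(
            {
                "sample": sample_id,
                "attempts": attempts,
                "alpha_sep": assortativity_index(agg_sep),
                "alpha_edu": assortativity_index(agg_edu),
                "eigen_ratio": hat_M.spectral_radius() / rho_ref,
                "seed": seed,
            }
        )
        matrices.append(hat_M)
    summary = pd.DataFrame(
        records,
        columns=["sample", "attempts", "alpha_sep", "alpha_edu", "eigen_ratio", "seed"],
    )
    return matrices, summary
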