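"""Stratified SIR dynamics and control-effort analyses.

A structured SIR model over the 14 strata with force of infection

    lambda_s = beta * sigma_s * sum_t \\hat M_{s,t} I_t / N_t,

where beta is the per-contact transmission rate, sigma_s a relative
susceptibility (1 by default; 0.5 for children in the reduced-child-
susceptibility scenario) and gamma the recovery rate (infectious period
3 days by default).  The next-generation matrix

    K_{s,t} = (beta * sigma_s / gamma) * \\hat M_{t,s}

counts expected infections in group s caused by one infectious individual
of group t in a fully susceptible population; R0 = rho(K), its dominant
eigenvalue.  Downstream quantities: per-group elasticity contributions to
R0, final-size attack rates, and type-reproduction numbers T_g giving the
critical fraction 1 - 1/T_g of a target group g that must be immune to
prevent an epidemic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .groups import GROUP_INDEX, GROUP_KEYS, N_GROUPS, GroupKey, PopulationTable
from .expansion import ExpandedMatrix


def _sigma_array(sigma) -> np.ndarray:
    if np.isscalar(sigma):
        return np.full(N_GROUPS, float(sigma))
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != (N_GROUPS,):
        raise ValueError(f"sigma must be scalar or length {N_GROUPS}")
    return sigma


def child_reduced_sigma(reduction: float = 0.5) -> np.ndarray:
    """Susceptibility vector with children (0-14) scaled by ``reduction``."""
    sigma = np.ones(N_GROUPS)
    for s, key in enumerate(GROUP_KEYS):
        if key.age == "0-14":
            sigma[s] = reduction
    return sigma


@dataclass(frozen=True)
class EpidemicParams:
    """Transmission parameters; rates are per day."""

    beta: float = 0.05
    gamma: float = 1.0 / 3.0
    sigma: np.ndarray | float = 1.0
    r0_target: float | None = None

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.gamma <= 0:
            raise ValueError("beta and gamma must be positive")
        sigma = _sigma_array(self.sigma)
        if np.any(sigma < 0) or np.any(sigma > 1):
            raise ValueError("sigma must lie in [0, 1]")
        object.__setattr__(self, "sigma", sigma)


@dataclass(frozen=True)
class NGM:
    """Next-generation matrix (column t = infector, row s = infectee)."""

    values: np.ndarray
    population: PopulationTable | None = None

    def spectral_radius(self) -> float:
        return float(np.abs(np.linalg.eigvals(self.values)).max())


def _as_ngm(K) -> NGM:
    if isinstance(K, NGM):
        return K
    return NGM(np.asarray(K, dtype=float))


def build_ngm(hat_M: ExpandedMatrix, params: EpidemicParams) -> NGM:
    """K_{s,t} = (beta sigma_s / gamma) \\hat M_{t,s}."""
    K = (params.beta / params.gamma) * params.sigma[:, None] * hat_M.values.T
    return NGM(K, hat_M.population)


def calibrate_beta(
    hat_M: ExpandedMatrix,
    sigma: np.ndarray | float,
    gamma: float,
    r0_target: float,
) -> float:
    """Transmission rate giving rho(K) = r0_target exactly."""
    sigma = _sigma_array(sigma)
    A = sigma[:, None] * hat_M.values.T
    rho = float(np.abs(np.linalg.eigvals(A)).max())
    if rho <= 0:
        raise ValueError("degenerate mixing: spectral radius is zero")
    return r0_target * gamma / rho


def eigen_ratio(
    hat_M: ExpandedMatrix,
    reference: ExpandedMatrix,
    sigma: np.ndarray | float | None = None,
) -> float:
    """rho(hat_M) / rho(reference), optionally susceptibility-scaled."""
    if sigma is None:
        num, den = hat_M.spectral_radius(), reference.spectral_radius()
    else:
        sig = _sigma_array(sigma)
        num = float(np.abs(np.linalg.eigvals(sig[:, None] * hat_M.values.T)).max())
        den = float(
            np.abs(np.linalg.eigvals(sig[:, None] * reference.values.T)).max()
        )
    if den <= 0:
        raise ValueError("reference matrix has zero spectral radius")
    return num / den


def _dominant_pair(K: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """(rho, right eigenvector w, left eigenvector v), Perron-normalized."""
    eigvals, eigvecs = np.linalg.eig(K)
    k = int(np.argmax(np.abs(eigvals)))
    rho = float(eigvals[k].real)
    w = eigvecs[:, k].real
    eigvals_l, eigvecs_l = np.linalg.eig(K.T)
    kl = int(np.argmax(np.abs(eigvals_l)))
    v = eigvecs_l[:, kl].real
    if w.sum() < 0:
        w = -w
    if v.sum() < 0:
        v = -v
    return rho, w, v


def elasticity_contributions(K) -> tuple[np.ndarray, np.ndarray]:
    """Elasticities of rho(K) and their infector-side group sums.

    Entry elasticities e_{s,t} = v_s K_{s,t} w_t / (rho <v,w>) measure the
    proportional sensitivity of R0 to K_{s,t}; the contribution of group t
    is the column sum over infectees s.  Contributions sum to 1.
    Accepts an NGM or any square nonnegative matrix; returns (entry
    elasticity matrix, per-group contributions).
    """
    K = _as_ngm(K)
    rho, w, v = _dominant_pair(K.values)
    if rho <= 0:
        raise ValueError("spectral radius must be positive")
    e = (v[:, None] * K.values * w[None, :]) / (rho * float(v @ w))
    return e, e.sum(axis=0)


@dataclass(frozen=True)
class Trajectory:
    """SIR solution over the strata."""

    t: np.ndarray
    S: np.ndarray  # (n_times, 14)
    I: np.ndarray
    R: np.ndarray
    population: PopulationTable

    def final_attack_rates(self) -> np.ndarray:
        return self.R[-1] / self.population.counts


def simulate_sir(
    hat_M: ExpandedMatrix,
    params: EpidemicParams,
    initial_infected: np.ndarray | float,
    initial_immune: np.ndarray | None = None,
    horizon: float | None = None,
    rtol: float = 1e-8,
) -> Trajectory:
    """Integrate the stratified SIR equations.

    ``initial_infected`` is a per-group count (scalar = same count per
    group); ``initial_immune`` optionally moves counts from S to R at
    t=0 (targeted immunization).  Without an explicit ``horizon`` the
    integration continues until total prevalence falls below 1e-9 N.
    """
    N = hat_M.population.counts
    I0 = (
        np.full(N_GROUPS, float(initial_infected))
        if np.isscalar(initial_infected)
        else np.asarray(initial_infected, dtype=float)
    )
    if np.any(I0 < 0) or I0.sum() <= 0:
        raise ValueError("initial infections must be >= 0 with positive total")
    R0_state = np.zeros(N_GROUPS) if initial_immune is None else np.asarray(
        initial_immune, dtype=float
    )
    S0 = N - I0 - R0_state
    if np.any(S0 < 0):
        raise ValueError("initial conditions exceed population")
    M = hat_M.values
    beta, gamma, sigma = params.beta, params.gamma, params.sigma

    def rhs(_t, y):
        S, I = y[:N_GROUPS], y[N_GROUPS : 2 * N_GROUPS]
        lam = beta * sigma * (M @ (I / N))
        dS = -lam * S
        dI = lam * S - gamma * I
        return np.concatenate([dS, dI, gamma * I])

    total_N = N.sum()
    atol = 1e-9 * total_N
    y0 = np.concatenate([S0, I0, R0_state])
    if horizon is not None:
        sol = solve_ivp(rhs, (0.0, horizon), y0, rtol=rtol, atol=atol, dense_output=False)
        ts, ys = sol.t, sol.y
    else:
        ts_list, ys_list = [np.array([0.0])], [y0[:, None]]
        t0, chunk = 0.0, 200.0
        for _ in range(200):
            sol = solve_ivp(rhs, (t0, t0 + chunk), y0, rtol=rtol, atol=atol)
            ts_list.append(sol.t[1:])
            ys_list.append(sol.y[:, 1:])
            t0, y0 = sol.t[-1], sol.y[:, -1]
            if y0[N_GROUPS : 2 * N_GROUPS].sum() < 1e-9 * total_N:
                break
        ts = np.concatenate(ts_list)
        ys = np.concatenate(ys_list, axis=1)
    S, I, R = ys[:N_GROUPS].T, ys[N_GROUPS : 2 * N_GROUPS].T, ys[2 * N_GROUPS :].T
    if min(S.min(), I.min(), R.min()) < -1e-6 * total_N:
        raise RuntimeError("integration produced negative compartments")
    conservation = np.abs(S + I + R - N[None, :]).max()
    if conservation > 1e-6 * total_N:
        raise RuntimeError(f"conservation violated by {conservation}")
    return Trajectory(ts, S, I, R, hat_M.population)


def attack_rates(
    hat_M: ExpandedMatrix,
    params: EpidemicParams,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Final-size attack rates z_s from the multigroup fixed point.

    Solves z_s = 1 - exp(-(beta sigma_s / gamma) sum_t \\hat M_{s,t} z_t)
    by damped fixed-point iteration (damping 0.5) from z = 1, converging
    to the nontrivial branch.
    """
    A = (params.beta / params.gamma) * params.sigma[:, None] * hat_M.values
    z = np.ones(N_GROUPS)
    for _ in range(max_iter):
        z_new = 0.5 * z + 0.5 * (1.0 - np.exp(-A @ z))
        if np.abs(z_new - z).max() < tol:
            return z_new
        z = z_new
    residual = np.abs(z - (1.0 - np.exp(-A @ z))).max()
    raise RuntimeError(f"final-size iteration did not converge (residual {residual})")


@dataclass(frozen=True)
class TypeReproResult:
    """Type-reproduction number for a target set of groups."""

    target: tuple
    feasible: bool
    t_g: float
    critical_fraction: float
    overall_effort: float


def type_reproduction(K, target, pop=None) -> TypeReproResult:
    """T_g = rho(P K (I - (I-P) K)^{-1}) for target projection P.

    Control through group g alone is feasible iff the epidemic cannot
    sustain itself in the non-target groups, i.e. rho((I-P)K) < 1; then
    immunizing a fraction 1 - 1/T_g of g halts the epidemic.  The overall
    effort rescales that fraction by the target's population share.

    ``target`` holds GroupKeys or plain indices into K; ``pop`` may be a
    PopulationTable, a counts array, or None (effort then undefined).
    """
    K = _as_ngm(K)
    n = K.values.shape[0]
    target = tuple(target)
    idx = [GROUP_INDEX[g] if isinstance(g, GroupKey) else int(g) for g in target]
    if pop is None:
        pop = K.population
    if pop is None:
        counts = None
    elif isinstance(pop, PopulationTable):
        counts = pop.counts
    else:
        counts = np.asarray(pop, dtype=float)
    P = np.zeros((n, n))
    P[idx, idx] = 1.0
    Kv = K.values
    Q = (np.eye(n) - P) @ Kv
    rho_rest = float(np.abs(np.linalg.eigvals(Q)).max())
    if rho_rest >= 1.0:
        return TypeReproResult(target, False, np.nan, np.nan, np.nan)
    try:
        core = np.linalg.solve(np.eye(n) - Q, np.eye(n))
    except np.linalg.LinAlgError:
        return TypeReproResult(target, False, np.nan, np.nan, np.nan)
    t_g = float(np.abs(np.linalg.eigvals(P @ Kv @ core)).max())
    critical = max(0.0, 1.0 - 1.0 / t_g) if t_g > 0 else 0.0
    if counts is None:
        effort = np.nan
    else:
        effort = critical * counts[idx].sum() / counts.sum()
    return TypeReproResult(target, True, t_g, critical, effort)


def standard_partitions() -> dict[str, dict[str, tuple[GroupKey, ...]]]:
    """Target partitions: SEP-only, education-only, SEP x education."""
    partitions: dict[str, dict[str, tuple[GroupKey, ...]]] = {
        "sep": {}, "edu": {}, "sep_edu": {},
    }
    for lev in ("low", "high"):
        partitions["sep"][f"sep:{lev}"] = tuple(
            k for k in GROUP_KEYS if k.sep == lev
        )
    for lev in ("mid_low", "high"):
        partitions["edu"][f"edu:{lev}"] = tuple(
            k for k in GROUP_KEYS if k.edu == lev
        )
    for s in ("low", "high"):
        for e in ("mid_low", "high"):
            partitions["sep_edu"][f"sep:{s}|edu:{e}"] = tuple(
                k for k in GROUP_KEYS if k.sep == s and k.edu == e
            )
    return partitions


def control_strategy_report(
    ensemble: Sequence[ExpandedMatrix],
    params: EpidemicParams,
    partitions: dict[str, dict[str, tuple[GroupKey, ...]]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-target control feasibility and effort over an ensemble.

    For each ensemble matrix, beta is recalibrated so that rho(K) equals
    ``params.r0_target`` before computing the type-reproduction number of
    every target.  Returns (per-matrix detail, per-target summary with
    success probability and effort quantiles over the feasible subset).
    """
    if len(ensemble) == 0:
        raise ValueError("ensemble must be non-empty")
    partitions = partitions or standard_partitions()
    r0 = params.r0_target if params.r0_target is not None else 1.5
    pop = ensemble[0].population
    detail = []
    for m, hat in enumerate(ensemble):
        beta = calibrate_beta(hat, params.sigma, params.gamma, r0)
        K = build_ngm(hat, replace(params, beta=beta, r0_target=r0))
        for part_name, targets in partitions.items():
            for target_name, keys in targets.items():
                res = type_reproduction(K, keys, pop)
                detail.append(
                    {
                        "matrix": m,
                        "partition": part_name,
                        "target": target_name,
                        "feasible": res.feasible,
                        "t_g": res.t_g,
                        "critical_fraction": res.critical_fraction,
                        "overall_effort": res.overall_effort,
                    }
                )
    detail_df = pd.DataFrame(detail)
    summaries = []
    for (part_name, target_name), grp in detail_df.groupby(["partition", "target"]):
        feasible = grp[grp["feasible"]]
        eff = feasible["overall_effort"]
        summaries.append(
            {
                "partition": part_name,
                "target": target_name,
                "n_matrices": len(grp),
                "success_probability": len(feasible) / len(grp),
                "effort_min": eff.min() if len(eff) else np.nan,
                "effort_median": eff.median() if len(eff) else np.nan,
                "effort_max": eff.max() if len(eff) else np.nan,
            }
        )
    return detail_df, pd.DataFrame(summaries)
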