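"""Closed-form steady state of the plasticity/buffering model and sweeps.

Setting all time derivatives to zero under a constant drive ``R`` gives

    u* = U*(1 + R*tau_f) / (1 + U*R*tau_f)
    x* = 1 / (1 + u*R*tau_d)
    b* = B*tau_b*lambda_cb*c* / (1 + tau_b*(lambda_bc + lambda_cb*c*))

and, after substituting the bound-pool relation into the free-pool balance,
a quadratic for the steady free calcium c*:

    (tau_b*lambda_cb) c^2
      + [(1 + k_c) + k_b (B - mu*R*tau_b)] c
      - mu*R*tau_c*(1 + k_c) = 0,
    k_b = tau_c*lambda_cb,   k_c = tau_b*lambda_bc.

Exactly one root is dynamically stable; stability is decided numerically by
perturbing the root along the free-calcium nullcline and checking that the
bound-pool derivative pulls back toward it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import ModelParams, release_probability_baseline

__all__ = [
    "SteadyState",
    "SweepResult",
    "SteadyStateError",
    "steady_state_cb",
    "select_stable_root",
    "steady_state_full",
    "sweep_weight_curves",
    "sweep_x_vs_b",
]


class SteadyStateError(RuntimeError):
    """No admissible stable root (signals pathological parameters)."""


@dataclass(frozen=True)
class SteadyState:
    c_star: float
    b_star: float
    U_star: float
    u_star: float
    x_star: float
    w_star: float
    k_b: float
    k_c: float
    quad_coeffs: tuple[float, float, float]
    stable: bool


def _quad_coeffs(p: ModelParams, R: float) -> tuple[float, float, float]:
    k_b = p.tau_c * p.lambda_cb
    k_c = p.tau_b * p.lambda_bc
    A = p.tau_b * p.lambda_cb
    Bc = (1.0 + k_c) + k_b * (p.B - p.mu * R * p.tau_b)
    Cc = -p.mu * R * p.tau_c * (1.0 + k_c)
    return A, Bc, Cc


def _quad_roots(A: float, Bc: float, Cc: float) -> tuple[float, float]:
    # numerically stable quadratic: |Bc| can reach ~1e9 in the model's
    # regimes, so avoid the cancelling branch of the textbook formula
    disc = Bc * Bc - 4.0 * A * Cc
    if disc < 0:
        raise SteadyStateError(f"negative discriminant {disc}")
    sq = math.sqrt(disc)
    if Bc == 0.0:
        r = sq / (2.0 * A)
        return (-r, r)
    q = -0.5 * (Bc + math.copysign(sq, Bc))
    r1 = q / A
    r2 = Cc / q if q != 0.0 else 0.0
    return (min(r1, r2), max(r1, r2))


def _b_on_c_nullcline(c: float, p: ModelParams, R: float) -> float:
    """b(c) solving dc/dt = 0 for given c."""
    return (c / p.tau_c + p.lambda_cb * p.B * c - p.mu * R) / (
        p.lambda_cb * c + p.lambda_bc)


def _db_dt(c: float, b: float, p: ModelParams) -> float:
    return -b / p.tau_b + p.lambda_cb * (p.B - b) * c - p.lambda_bc * b


def select_stable_root(
    roots: tuple[float, float],
    params: ModelParams,
    R: float,
    eps_scale: float = 1e-6,
) -> float:
    """Pick the dynamically stable, non-negative root of the c* quadratic.

    A root c0 is accepted when displacing c slightly above (below) it, with
    b slaved to the free-calcium nullcline, makes db/dt negative (positive),
    i.e. the coupled (c, b) flow is attracted back to the root.  For valid
    parameters with mu*R > 0 the product of roots is negative, so exactly
    one non-negative candidate exists.
    """
    if params.mu * R == 0.0:
        return 0.0
    stable = []
    for c0 in roots:
        if c0 < 0:
            continue
        eps = eps_scale * max(1.0, c0)
        up = _db_dt(c0 + eps, _b_on_c_nullcline(c0 + eps, params, R), params)
        dn = _db_dt(max(c0 - eps, 0.0),
                    _b_on_c_nullcline(max(c0 - eps, 0.0), params, R), params)
        if up < 0.0 < dn:
            stable.append(c0)
    if len(stable) != 1:
        raise SteadyStateError(
            f"{len(stable)} stable non-negative roots among {roots} "
            f"(R={R}, params={params})")
    return stable[0]


def steady_state_cb(params: ModelParams, R: float) -> tuple[float, float, dict]:
    """Steady (c*, b*) with diagnostics (k_b, k_c, quadratic coefficients)."""
    if R < 0:
        raise ValueError("rate R must be non-negative")
    A, Bc, Cc = _quad_coeffs(params, R)
    diagnostics = {
        "k_b": params.tau_c * params.lambda_cb,
        "k_c": params.tau_b * params.lambda_bc,
        "quad_coeffs": (A, Bc, Cc),
    }
    if params.mu * R == 0.0:
        return 0.0, 0.0, diagnostics
    roots = _quad_roots(A, Bc, Cc)
    c_star = select_stable_root(roots, params, R)
    b_star = (params.B * params.tau_b * params.lambda_cb * c_star
              / (1.0 + params.tau_b * (params.lambda_bc
                                       + params.lambda_cb * c_star)))
    return c_star, b_star, diagnostics


def steady_state_full(params: ModelParams, R: float) -> SteadyState:
    """Full fixed point (c*, b*, U*, u*, x*, w*) under constant drive R."""
    c_star, b_star, diag = steady_state_cb(params, R)
    U = release_probability_baseline(c_star, params.lam)
    u_star = U * (1.0 + R * params.tau_f) / (1.0 + U * R * params.tau_f)
    x_star = 1.0 / (1.0 + u_star * R * params.tau_d)
    return SteadyState(
        c_star=c_star, b_star=b_star, U_star=U,
        u_star=u_star, x_star=x_star, w_star=u_star * x_star,
        k_b=diag["k_b"], k_c=diag["k_c"],
        quad_coeffs=diag["quad_coeffs"], stable=True,
    )


@dataclass(frozen=True)
class SweepResult:
    """Steady-state weight curves w*(R) across buffer sizes.

    ``table`` holds one row per (B, R) grid point with the full fixed
    point; ``summary`` one row per B with the grid maximum (w_max, R_max).
    """

    table: pd.DataFrame
    summary: pd.DataFrame


def sweep_weight_curves(
    params: ModelParams,
    B_values,
    R_grid,
) -> SweepResult:
    """w*(R) per buffer size B, with the grid maximum marked per curve.

    In the model's physiological regime the maximal weight w_max decreases
    with buffer size while the rate R_max attaining it increases, and all
    curves converge once the buffer saturates at high drive.
    """
    R_grid = np.asarray(R_grid, dtype=float)
    B_values = np.asarray(B_values, dtype=float)
    if R_grid.size == 0 or B_values.size == 0:
        raise ValueError("B_values and R_grid must be non-empty")
    if np.any(R_grid <= 0) or np.any(np.diff(R_grid) <= 0):
        raise ValueError("R_grid must be positive and strictly increasing")
    if np.any(B_values < 0):
        raise ValueError("B values must be non-negative")
    rows = []
    for B in B_values:
        pB = replace(params, B=float(B))
        for R in R_grid:
            ss = steady_state_full(pB, float(R))
            rows.append((B, R, ss.w_star, ss.x_star, ss.u_star,
                         ss.c_star, ss.b_star))
    table = pd.DataFrame(
        rows, columns=["B", "R", "w_star", "x_star", "u_star",
                       "c_star", "b_star"])
    idx = table.groupby("B")["w_star"].idxmax()
    summary = (table.loc[idx, ["B", "w_star", "R"]]
               .rename(columns={"w_star": "w_max", "R": "R_max"})
               .reset_index(drop=True))
    return SweepResult(table=table, summary=summary)


def sweep_x_vs_b(
    params: ModelParams,
    lam_values,
    R: float = 20.0,
    mu_grid=None,
) -> dict[float, pd.DataFrame]:
    """(b*, x*) curves per sigmoid scale lambda.

    The bound-calcium axis is generated by varying the influx mu at fixed
    buffer size (drive strength is the natural knob for moving along the
    b* axis; the choice of knob is configurable via ``mu_grid``).  Along
    each curve x* is monotone non-increasing in b*.
    """
    lam_values = np.asarray(lam_values, dtype=float)
    if np.any(lam_values <= 0):
        raise ValueError("lam values must be strictly positive")
    if mu_grid is None:
        mu_grid = np.geomspace(params.mu * 1e-2, params.mu * 1e2, 40)
    curves: dict[float, pd.DataFrame] = {}
    for lam in lam_values:
        rows = []
        for mu in mu_grid:
            ss = steady_state_full(replace(params, lam=float(lam),
                                           mu=float(mu)), R)
            rows.append((mu, ss.b_star, ss.x_star, ss.c_star, ss.u_star))
        df = pd.DataFrame(rows, columns=["mu", "b_star", "x_star",
                                         "c_star", "u_star"])
        curves[float(lam)] = df.sort_values("b_star").reset_index(drop=True)
    return curves
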