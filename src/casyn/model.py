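"""Coupled short-term plasticity and presynaptic calcium buffering model.

The presynapse is described by four state variables:

* ``x`` — fraction of the readily releasable vesicle pool (dimensionless),
* ``u`` — release probability (dimensionless),
* ``c`` — free Ca2+ (arbitrary concentration units),
* ``b`` — bound (buffered) Ca2+ (same units).

Vesicle dynamics follow the canonical depression/facilitation scheme

    dx/dt = (1 - x)/tau_d - u*x*R
    du/dt = (U - u)/tau_f + U*(1 - u)*R

where the baseline release probability ``U`` is tied to free calcium through
a saturating sigmoid ``U(c) = 2/(1 + exp(-c/lam)) - 1``, and the two calcium
pools exchange through a finite buffer of capacity ``B``:

    dc/dt = -c/tau_c - lambda_cb*(B - b)*c + lambda_bc*b + mu*R
    db/dt = -b/tau_b + lambda_cb*(B - b)*c - lambda_bc*b

``R`` is the presynaptic drive, either a constant rate in Hz or a spike
train discretized as unit impulses.  The momentary synaptic weight is
``w = u*x``.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ModelParams",
    "SynapseState",
    "DriveSpec",
    "NumericalInstabilityError",
    "release_probability_baseline",
    "synaptic_weight",
    "derivatives",
    "integrate",
    "rest_state",
    "load_params",
    "save_trajectory",
]

#: absolute slack allowed outside the hard state bounds before integration
#: is declared unstable (floating point roundoff near 0/1/B)
BOUND_GUARD = 1e-9


class NumericalInstabilityError(RuntimeError):
    """Raised when integration drives the state outside its invariants."""


@dataclass(frozen=True)
class ModelParams:
    """Kinetic and plasticity constants.

    Times are in seconds; ``c``, ``b``, ``mu``, ``B`` and ``lam`` share one
    arbitrary concentration unit.  ``B``, ``mu`` and ``lam`` have no
    canonical literature values and must always be given explicitly.
    """

    B: float
    mu: float
    lam: float
    tau_d: float = 0.2
    tau_f: float = 1.5
    tau_c: float = 100.0
    tau_b: float = 10_000.0
    lambda_cb: float = 200.0
    lambda_bc: float = 30.0

    def __post_init__(self) -> None:
        for name in ("tau_d", "tau_f", "tau_c", "tau_b", "lambda_cb",
                     "lambda_bc", "mu", "lam"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.B < 0:
            raise ValueError("B must be non-negative")

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class SynapseState:
    """Instantaneous model state at time ``t`` (seconds)."""

    t: float
    x: float
    u: float
    c: float
    b: float

    def validate(self, B: float, guard: float = BOUND_GUARD) -> None:
        if not (-guard <= self.x <= 1 + guard and -guard <= self.u <= 1 + guard):
            raise ValueError(f"x/u out of [0,1]: x={self.x}, u={self.u}")
        if self.c < -guard:
            raise ValueError(f"c negative: {self.c}")
        if not (-guard <= self.b <= B + guard):
            raise ValueError(f"b out of [0,B]: b={self.b}, B={B}")

    @property
    def w(self) -> float:
        return self.u * self.x


@dataclass(frozen=True)
class DriveSpec:
    """Presynaptic drive: constant rate (Hz) or explicit spike times (s)."""

    mode: str = "constant_rate"
    R: float = 0.0
    spikes: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.mode not in ("constant_rate", "spike_times"):
            raise ValueError(f"unknown drive mode {self.mode!r}")
        if self.mode == "constant_rate":
            if self.R < 0:
                raise ValueError("rate R must be non-negative")
        else:
            sp = tuple(float(s) for s in self.spikes)
            if any(b <= a for a, b in zip(sp, sp[1:])):
                raise ValueError("spike times must be strictly increasing")
            object.__setattr__(self, "spikes", sp)

    @classmethod
    def constant(cls, R: float) -> "DriveSpec":
        return cls(mode="constant_rate", R=R)

    @classmethod
    def from_spikes(cls, spikes: Sequence[float]) -> "DriveSpec":
        return cls(mode="spike_times", spikes=tuple(spikes))


def release_probability_baseline(c: float, lam: float) -> float:
    """Baseline release probability ``U(c) = 2/(1+exp(-c/lam)) - 1``.

    Monotone increasing, U(0)=0, saturating to 1 for ``c >> lam``.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("free calcium c must be non-negative")
    if not lam > 0:
        raise ValueError("lam must be strictly positive")
    out = 2.0 / (1.0 + np.exp(-c / lam)) - 1.0
    return float(out) if out.ndim == 0 else out


def synaptic_weight(u: float, x: float) -> float:
    """Normalized synaptic weight ``w = u*x``."""
    u, x = np.asarray(u, float), np.asarray(x, float)
    if np.any((u < 0) | (u > 1)) or np.any((x < 0) | (x > 1)):
        raise ValueError("u and x must lie in [0, 1]")
    w = u * x
    return float(w) if w.ndim == 0 else w


def _rhs(y: np.ndarray, p: ModelParams, R: float) -> np.ndarray:
    x, u, c, b = y
    U = 2.0 / (1.0 + math.exp(-max(c, 0.0) / p.lam)) - 1.0
    bind = p.lambda_cb * (p.B - b) * c
    unbind = p.lambda_bc * b
    return np.array([
        (1.0 - x) / p.tau_d - u * x * R,
        (U - u) / p.tau_f + U * (1.0 - u) * R,
        -c / p.tau_c - bind + unbind + p.mu * R,
        -b / p.tau_b + bind - unbind,
    ])


def derivatives(state: SynapseState, params: ModelParams, R: float) -> tuple[float, float, float, float]:
    """Time derivatives (dx/dt, du/dt, dc/dt, db/dt) at ``state``.

    The baseline release probability entering du/dt is evaluated from the
    instantaneous free calcium, ``U = U(c)``.  The exchange terms cancel in
    the sum so that ``dc/dt + db/dt = mu*R - c/tau_c - b/tau_b`` exactly.
    """
    state.validate(params.B)
    if R < 0:
        raise ValueError("rate R must be non-negative")
    return tuple(_rhs(np.array([state.x, state.u, state.c, state.b]), params, R))


def rest_state(t: float = 0.0) -> SynapseState:
    """Drive-free fixed point: full pool, no facilitation, no calcium."""
    return SynapseState(t=t, x=1.0, u=0.0, c=0.0, b=0.0)


def _clip_state(y: np.ndarray, B: float) -> np.ndarray:
    """Snap roundoff-sized excursions back onto the admissible box."""
    lo = np.array([0.0, 0.0, 0.0, 0.0])
    hi = np.array([1.0, 1.0, np.inf, B])
    if np.any(y < lo - BOUND_GUARD) or np.any(y > hi + BOUND_GUARD):
        raise NumericalInstabilityError(
            f"state left its admissible bounds ({y}); reduce dt")
    return np.clip(y, lo, hi)


def integrate(
    params: ModelParams,
    drive: DriveSpec,
    t_span: tuple[float, float],
    dt: float,
    init: SynapseState | None = None,
    method: str = "adaptive",
) -> pd.DataFrame:
    """Integrate the model over ``t_span``, sampled every ``dt`` seconds.

    With a constant-rate drive the default is adaptive stiff-capable
    integration (LSODA) — the system mixes timescales from ``tau_d``
    (fractions of a second) to ``tau_b`` (hours), and the calcium exchange
    rates make the (c, b) pair stiff.  ``method='fixed'`` selects a
    fixed-step scheme (explicit for the vesicle variables, semi-implicit
    backward-Euler split for the stiff calcium pair, which preserves the
    state bounds unconditionally); spike-train drive always uses it: a
    spike at time s contributes R(t) = 1/dt on the step containing s,
    i.e. a unit impulse of integral one, so constant-rate and Poisson
    spike drive agree in expectation.

    Returns a DataFrame with columns ``t, x, u, c, b, w``.
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not dt > 0:
        raise ValueError("dt must be positive")
    if not t1 > t0:
        raise ValueError("t_span must be a non-empty forward interval")
    if init is None:
        init = rest_state(t0)
    init.validate(params.B)
    y0 = np.array([init.x, init.u, init.c, init.b], dtype=float)
    n = int(round((t1 - t0) / dt))
    ts = t0 + dt * np.arange(n + 1)

    if drive.mode == "constant_rate" and method == "adaptive":
        from scipy.integrate import solve_ivp

        sol = solve_ivp(
            lambda t, y: _rhs(y, params, drive.R),
            (t0, t1), y0, t_eval=ts, method="LSODA",
            rtol=1e-10, atol=1e-12,
        )
        if not sol.success:  # pragma: no cover - LSODA rarely fails here
            raise NumericalInstabilityError(sol.message)
        ys = sol.y.T
        ys = np.stack([_clip_state(y, params.B) for y in ys])
    else:
        if drive.mode == "spike_times":
            counts = np.zeros(n)
            idx = np.floor((np.asarray(drive.spikes) - t0) / dt).astype(int)
            idx = idx[(idx >= 0) & (idx < n)]
            np.add.at(counts, idx, 1.0)
            rates = counts / dt
        else:
            rates = np.full(n, drive.R)
        ys = np.empty((n + 1, 4))
        ys[0] = y0
        y = y0.copy()
        p = params
        for k in range(n):
            R = rates[k]
            x, u, c, b = y
            U = 2.0 / (1.0 + math.exp(-c / p.lam)) - 1.0
            # vesicle pair: explicit update; with R*dt <= 1 (impulses) the
            # increments U*(1-u)*R*dt and -u*x*R*dt cannot leave [0, 1]
            u_new = u + dt * (U - u) / p.tau_f + U * (1.0 - u) * (R * dt)
            x_new = x + dt * (1.0 - x) / p.tau_d - u * x * (R * dt)
            # stiff calcium pair: backward-Euler split, first c with b
            # frozen, then b with the updated c; unconditionally stable
            # and keeps c >= 0, 0 <= b <= B
            c_new = (c + dt * (p.lambda_bc * b + p.mu * R)) / (
                1.0 + dt * (1.0 / p.tau_c + p.lambda_cb * (p.B - b)))
            b_new = (b + dt * p.lambda_cb * c_new * p.B) / (
                1.0 + dt * (1.0 / p.tau_b + p.lambda_bc
                            + p.lambda_cb * c_new))
            y = _clip_state(np.array([x_new, u_new, c_new, b_new]), p.B)
            ys[k + 1] = y

    df = pd.DataFrame(ys, columns=["x", "u", "c", "b"])
    df.insert(0, "t", ts)
    df["w"] = df["u"] * df["x"]
    return df


_PARAM_KEYS = ("tau_d", "tau_f", "tau_c", "tau_b", "lambda_cb",
               "lambda_bc", "mu", "B", "lam")


def load_params(path: str | Path) -> ModelParams:
    """Load a TOML parameter file with exactly the nine model keys.

    Unknown keys are rejected so that silently misspelled constants cannot
    fall back to defaults.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    unknown = set(raw) - set(_PARAM_KEYS)
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return ModelParams(**{k: float(v) for k, v in raw.items()})


def save_trajectory(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=["t", "x", "u", "c", "b", "w"])
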