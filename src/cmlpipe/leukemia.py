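"""Dual normal/leukemic lineage model and CML development.

The eight-component state is ``[S, P, TDl, TDm, SL, PL, TDlL, TDmL]``.
Both lineages share the feedback architecture and are regulated by the
*total* populations (normal + leukemic) of each compartment, so the two
sub-lineages "exhibit feedback together as a single compartment".  The
leukemic lineage has its own parameters; by default the only difference
is a weaker feedback gain on leukemic stem self-renewal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import NormalParameterSet, LeukemicParameterSet, DualParameterSet
from .lineage import Trajectory, SolverError, find_steady_state, RTOL, ATOL

__all__ = [
    "Treatment",
    "rhs_dual",
    "integrate_dual",
    "simulate_cml",
    "fitness",
    "sweep_leukemic_parameters",
    "DUAL_COLUMNS",
]

DUAL_COLUMNS = ("S", "P", "TDl", "TDm", "SL", "PL", "TDlL", "TDmL")

#: horizon for classifying leukemic takeover (days), ~100 months
TAKEOVER_HORIZON = 3000.0
#: leukemic stem cells introduced at CML initiation
DEFAULT_SEED_LSC = 1.0e4


@dataclass(frozen=True)
class Treatment:
    """Active-treatment terms for the dual RHS.

    ``kill_S`` and ``kill_P`` are dimensionless multipliers of the
    leukemic stem/progenitor division rates forming proliferation-
    dependent death fluxes; ``division_factor`` scales the maximal
    leukemic stem division rate (TKI-induced quiescence); ``delta``
    is the differentiation-therapy strength entering both lineages'
    stem self-renewal denominators.
    """

    kill_S: float = 0.0
    kill_P: float = 0.0
    division_factor: float = 1.0
    delta: float = 0.0

    def __post_init__(self) -> None:
        if self.kill_S < 0 or self.kill_P < 0 or self.delta < 0:
            raise ValueError("treatment terms must be non-negative")
        if not (0.0 < self.division_factor <= 1.0):
            raise ValueError("division_factor must lie in (0, 1]")


NO_TREATMENT = Treatment()


def _lineage_rates(
    ps: NormalParameterSet,
    S_tot: float,
    P_tot: float,
    M_tot: float,
    delta: float,
    eta1_scale: float = 1.0,
) -> tuple[float, float, float, float, float]:
    p0 = ps.p0_max / (1.0 + ps.gamma1 * P_tot + delta)
    p1 = ps.p1_max / (1.0 + ps.gamma3 * M_tot)
    q1 = ps.q1_max / (1.0 + ps.gamma4 * M_tot)
    eta1 = eta1_scale * ps.eta1_max / (1.0 + ps.gamma2 * S_tot)
    eta2 = ps.eta2_max / (1.0 + ps.gamma5 * S_tot)
    return p0, p1, q1, eta1, eta2


def rhs_dual(
    state: Sequence[float],
    dual: DualParameterSet,
    treatment: Treatment = NO_TREATMENT,
) -> np.ndarray:
    """Derivative (cells/day) of the eight-compartment dual system.

    Regulators are compartment totals.  Treatment adds proliferation-
    dependent kill fluxes to the leukemic stem and progenitor equations
    only; ``delta`` suppresses self-renewal in both lineages.
    """
    y = np.asarray(state, dtype=float)
    # regulators are clamped at zero; the flux terms use the raw values
    # so sub-cell negative solver overshoot is self-restoring
    Sc, Pc, _Lc, Mc, SLc, PLc, _LLc, MLc = np.maximum(y, 0.0)
    S, P, L, M, SL, PL, LL, ML = y
    S_tot, P_tot, M_tot = Sc + SLc, Pc + PLc, Mc + MLc

    n = dual.normal
    lk = dual.leukemic
    p0, p1, q1, e1, e2 = _lineage_rates(n, S_tot, P_tot, M_tot, treatment.delta)
    p0L, p1L, q1L, e1L, e2L = _lineage_rates(
        lk, S_tot, P_tot, M_tot, treatment.delta, eta1_scale=treatment.division_factor
    )

    return np.array(
        [
            (2.0 * p0 - 1.0) * e1 * S,
            2.0 * (1.0 - p0) * e1 * Sc + (2.0 * p1 - 1.0) * e2 * P,
            2.0 * q1 * e2 * Pc - n.d_l * L,
            2.0 * (1.0 - p1 - q1) * e2 * Pc - n.d_m * M,
            (2.0 * p0L - 1.0) * e1L * SL - treatment.kill_S * e1L * SL,
            2.0 * (1.0 - p0L) * e1L * SLc
            + (2.0 * p1L - 1.0) * e2L * PL
            - treatment.kill_P * e2L * PL,
            2.0 * q1L * e2L * PLc - lk.d_l * LL,
            2.0 * (1.0 - p1L - q1L) * e2L * PLc - lk.d_m * ML,
        ]
    )


def integrate_dual(
    state0: Sequence[float],
    dual: DualParameterSet,
    t_span: float,
    t_eval: Sequence[float] | None = None,
    treatment: Treatment = NO_TREATMENT,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Trajectory:
    """Integrate the dual system for ``t_span`` days."""
    if t_span <= 0:
        raise ValueError("t_span must be positive")
    y0 = np.asarray(state0, dtype=float)
    if y0.shape != (8,) or np.any(y0 < 0):
        raise ValueError("state0 must be 8 non-negative components")

    def f(t, y):
        return rhs_dual(y, dual, treatment)

    sol = solve_ivp(
        f,
        (0.0, float(t_span)),
        y0,
        method="LSODA",
        t_eval=None if t_eval is None else np.asarray(t_eval, dtype=float),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SolverError(sol.message, sol.t[-1] if sol.t.size else 0.0)
    y = sol.y.T
    # sub-cell negative overshoot is solver noise, not a model failure
    if np.any(y < -max(atol, 1.0)):
        raise SolverError("negative populations beyond tolerance", sol.t[-1])
    return Trajectory(t=sol.t, y=np.clip(y, 0.0, None), columns=DUAL_COLUMNS)


def simulate_cml(
    dual: DualParameterSet,
    n_seed_LSC: float = DEFAULT_SEED_LSC,
    t_span: float = TAKEOVER_HORIZON,
    t_eval: Sequence[float] | None = None,
    normal_steady_state: Sequence[float] | None = None,
) -> Trajectory:
    """CML development: seed leukemic stem cells into the normal
    steady state and integrate the dual system."""
    if n_seed_LSC < 0:
        raise ValueError("n_seed_LSC must be non-negative")
    if normal_steady_state is None:
        ss, converged = find_steady_state(dual.normal, [1e3, 0, 0, 0])
        if not converged:
            raise SolverError("normal lineage did not reach steady state", 0.0)
    else:
        ss = np.asarray(normal_steady_state, dtype=float)
    y0 = np.concatenate([ss, [n_seed_LSC, 0.0, 0.0, 0.0]])
    return integrate_dual(y0, dual, t_span, t_eval=t_eval)


def leukemic_fraction(state: Sequence[float]) -> float:
    """Leukemic share of the terminal compartments (TDl + TDm totals)."""
    y = np.asarray(state, dtype=float)
    normal = y[2] + y[3]
    leukemic = y[6] + y[7]
    total = normal + leukemic
    if total <= 0:
        raise ValueError("no terminal cells")
    return leukemic / total


def fitness(dual: DualParameterSet, N_char: float = 1.0e5) -> float:
    """Leukemic-to-normal ratio of characteristic stem self-renewal
    fractions evaluated at the characteristic progenitor level."""
    p0bar = dual.normal.p0_max / (1.0 + dual.normal.gamma1 * N_char)
    p0barL = dual.leukemic.p0_max / (1.0 + dual.leukemic.gamma1 * N_char)
    return p0barL / p0bar


def sweep_leukemic_parameters(
    cohort,
    p0maxL_ratios: Sequence[float] = (0.6, 0.7, 0.8, 0.9, 1.0),
    gamma1L_ratios: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6),
    n_seed_LSC: float = DEFAULT_SEED_LSC,
    horizon: float = TAKEOVER_HORIZON,
    takeover_threshold: float = 0.5,
) -> pd.DataFrame:
    """Leukemic-parameter sweep over a cohort.

    For each grid cell, simulates CML development for every cohort
    member and reports the fraction of members whose terminal
    compartments end at least 50% leukemic at the horizon, plus the
    mean fitness ratio of the cell.
    """
    records = []
    members = [(pid, ps, ss) for pid, ps, ss in cohort.iter_members()]
    if not members:
        raise ValueError("cohort is empty")
    for pr in p0maxL_ratios:
        for gr in gamma1L_ratios:
            n_takeover = 0
            fitness_values = []
            for pid, ps, ss in members:
                dual = DualParameterSet.minimal_difference(
                    ps, gamma1L_ratio=gr, p0maxL_ratio=pr
                )
                traj = simulate_cml(
                    dual,
                    n_seed_LSC=n_seed_LSC,
                    t_span=horizon,
                    t_eval=[horizon],
                    normal_steady_state=ss,
                )
                frac = leukemic_fraction(traj.final_state)
                n_takeover += frac >= takeover_threshold
                fitness_values.append(fitness(dual))
            records.append(
                {
                    "p0maxL_ratio": pr,
                    "gamma1L_ratio": gr,
                    "fraction_takeover": n_takeover / len(members),
                    "mean_fitness": float(np.mean(fitness_values)),
                }
            )
    return pd.DataFrame.from_records(records)
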