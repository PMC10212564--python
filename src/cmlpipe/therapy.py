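"""TKI and combination differentiation therapy on the dual model.

The clinical readout is the transcript ratio computed from terminal
cells (the compartments closest to peripheral blood),

    ratio = (TDlL + TDmL) / (TDlL + TDmL + 2 (TDl + TDm)),

reported on the percent scale.  MR3 (major molecular response) is a
transcript level below 0.1%.

TKI adds proliferation-dependent death to leukemic stem and progenitor
cells and reduces the leukemic stem division rate; differentiation
therapy adds a constant ``delta`` to both lineages' stem self-renewal
denominators.  The kill multipliers are calibrated once on a reference
patient to produce a biphasic transcript decline and then frozen for
the whole cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .params import NormalParameterSet, DualParameterSet, DAYS_PER_MONTH
from .leukemia import (
    Treatment,
    integrate_dual,
    simulate_cml,
    leukemic_fraction,
)
from .lineage import Trajectory, find_steady_state

__all__ = [
    "TherapyConfig",
    "TranscriptSeries",
    "transcript_ratio",
    "simulate_therapy",
    "time_to_mr3",
    "sweep_delta",
    "DEFAULT_TKI",
]

MR3_THRESHOLD_PCT = 0.1


@dataclass(frozen=True)
class TherapyConfig:
    """Therapy schedule and strengths (times in months)."""

    start_month: float = 5.0
    duration_months: float = 50.0
    tki_death_S: float = 0.35
    tki_death_P: float = 10.0
    tki_division_factor: float = 0.5
    delta: float = 0.0

    def __post_init__(self) -> None:
        if self.start_month < 0 or self.duration_months <= 0:
            raise ValueError("therapy times must be non-negative / positive")
        if self.tki_death_S < 0 or self.tki_death_P < 0 or self.delta < 0:
            raise ValueError("therapy strengths must be non-negative")
        if not (0.0 < self.tki_division_factor <= 1.0):
            raise ValueError("tki_division_factor must lie in (0, 1]")

    def treatment(self) -> Treatment:
        return Treatment(
            kill_S=self.tki_death_S,
            kill_P=self.tki_death_P,
            division_factor=self.tki_division_factor,
            delta=self.delta,
        )

    def to_dict(self) -> dict:
        return asdict(self)


#: frozen cohort-wide TKI setting (see calibration notes in the tests)
DEFAULT_TKI = TherapyConfig()


@dataclass(frozen=True)
class TranscriptSeries:
    """Monthly transcript percentages for one (virtual) patient."""

    times: np.ndarray  # months
    values: np.ndarray  # percent, in [0, 100]
    patient_id: int | str = ""
    noise_cv: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D and aligned")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((v < 0) | (v > 100)):
            raise ValueError("transcript percentages must lie in [0, 100]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def at(self, month: float, atol: float = 0.5) -> float:
        idx = np.argmin(np.abs(self.times - month))
        if abs(self.times[idx] - month) > atol:
            raise KeyError(f"no sample within {atol} months of month {month}")
        return float(self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "month": self.times,
                "bcr_abl_pct": self.values,
            }
        )


def transcript_ratio(state: Sequence[float]) -> float:
    """Transcript ratio in [0, 1] from an 8-component dual state."""
    y = np.asarray(state, dtype=float)
    leukemic = y[6] + y[7]
    normal = y[2] + y[3]
    denom = leukemic + 2.0 * normal
    if denom <= 0:
        raise ValueError("transcript ratio undefined: no terminal cells")
    return leukemic / denom


def _transcript_pct(states: np.ndarray) -> np.ndarray:
    """Transcript percentages along a trajectory.

    Time points whose terminal compartments total less than one cell
    (marrow collapse under maximal suppression) carry the last defined
    value forward; an all-empty trajectory is an error.
    """
    leukemic = states[:, 6] + states[:, 7]
    normal = states[:, 2] + states[:, 3]
    denom = leukemic + 2.0 * normal
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(denom >= 1.0, 100.0 * leukemic / np.where(denom > 0, denom, 1.0), np.nan)
    if np.isnan(pct[0]):
        raise ValueError("transcript ratio undefined: no terminal cells")
    pct = pd.Series(pct).ffill().to_numpy()
    return pct


def simulate_therapy(
    dual: DualParameterSet,
    cfg: TherapyConfig,
    n_seed_LSC: float = 1.0e4,
    normal_steady_state: Sequence[float] | None = None,
) -> tuple[TranscriptSeries, Trajectory, dict]:
    """Develop CML for ``cfg.start_month`` months, then treat.

    Returns the monthly transcript series over the treatment period
    (month 0 = treatment start), the treated trajectory, and a summary
    dict including the leukemic stem fraction at treatment start.
    """
    start_days = cfg.start_month * DAYS_PER_MONTH
    if start_days > 0:
        dev = simulate_cml(
            dual,
            n_seed_LSC=n_seed_LSC,
            t_span=start_days,
            t_eval=[start_days],
            normal_steady_state=normal_steady_state,
        )
        y0 = dev.final_state
    else:
        if normal_steady_state is None:
            ss, _ = find_steady_state(dual.normal, [1e3, 0, 0, 0])
        else:
            ss = np.asarray(normal_steady_state, dtype=float)
        y0 = np.concatenate([ss, [n_seed_LSC, 0.0, 0.0, 0.0]])

    s_tot = y0[0] + y0[4]
    hscl_fraction = y0[4] / s_tot if s_tot > 0 else 0.0

    months = np.arange(0.0, cfg.duration_months + 1e-9, 1.0)
    t_eval = months * DAYS_PER_MONTH
    t_eval[0] = 0.0
    traj = integrate_dual(
        y0,
        dual,
        t_span=float(t_eval[-1]),
        t_eval=t_eval,
        treatment=cfg.treatment(),
    )
    # month 0 uses the pre-treatment state itself
    pct = _transcript_pct(traj.y)
    series = TranscriptSeries(times=months, values=np.clip(pct, 0.0, 100.0))
    summary = {
        "hscl_fraction_at_start": float(hscl_fraction),
        "transcript_pct_at_start": float(pct[0]),
        "transcript_pct_final": float(pct[-1]),
    }
    return series, traj, summary


def time_to_mr3(
    series: TranscriptSeries, threshold_pct: float = MR3_THRESHOLD_PCT
) -> float | None:
    """First month at which the transcript percentage falls strictly
    below the threshold, or ``None`` if it never does."""
    below = series.values < threshold_pct
    if not below.any():
        return None
    return float(series.times[np.argmax(below)])


def sweep_delta(
    cohort,
    delta_grid: Sequence[float],
    cfg: TherapyConfig = DEFAULT_TKI,
    gamma1L_ratio: float = 0.4,
    p0maxL_ratio: float = 1.0,
    mr3_horizon_months: float = 50.0,
    n_seed_LSC: float = 1.0e4,
) -> pd.DataFrame:
    """Combination-therapy sweep: MR3-within-horizon proportion per delta.

    The CML development phase is shared across deltas for each member.
    Returns a frame with one row per delta; the ``delta = 0`` column of
    results is exactly TKI monotherapy.
    """
    members = list(cohort.iter_members())
    if not members:
        raise ValueError("cohort is empty")
    start_days = cfg.start_month * DAYS_PER_MONTH
    records = []
    developed = []
    for pid, ps, ss in members:
        dual = DualParameterSet.minimal_difference(
            ps, gamma1L_ratio=gamma1L_ratio, p0maxL_ratio=p0maxL_ratio
        )
        dev = simulate_cml(
            dual,
            n_seed_LSC=n_seed_LSC,
            t_span=start_days,
            t_eval=[start_days],
            normal_steady_state=ss,
        )
        developed.append((pid, dual, dev.final_state))

    months = np.arange(0.0, mr3_horizon_months + 1e-9, 1.0)
    t_eval = months * DAYS_PER_MONTH
    for delta in delta_grid:
        run_cfg = TherapyConfig(
            start_month=cfg.start_month,
            duration_months=mr3_horizon_months,
            tki_death_S=cfg.tki_death_S,
            tki_death_P=cfg.tki_death_P,
            tki_division_factor=cfg.tki_division_factor,
            delta=float(delta),
        )
        n_mr3 = 0
        for pid, dual, y0 in developed:
            traj = integrate_dual(
                y0,
                dual,
                t_span=float(t_eval[-1]),
                t_eval=t_eval,
                treatment=run_cfg.treatment(),
            )
            pct = _transcript_pct(traj.y)
            if (pct < MR3_THRESHOLD_PCT).any():
                n_mr3 += 1
        records.append(
            {
                "delta": float(delta),
                "proportion_mr3": n_mr3 / len(developed),
                "n": len(developed),
            }
        )
    return pd.DataFrame.from_records(records)
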