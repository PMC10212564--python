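"""Prognostic statistics on transcript series and ROC evaluation.

The central statistic is the relative transcript change over a window,

    PF(t1, t2) = (B(t2) - B(t1)) / B(t2),

which is strongly negative for fast responders (``B(6) << B(3)``) and
near zero (or positive) for non-responders.  Classical comparators are
the transcript halving time and the early-molecular-response (EMR)
thresholds: B(3) < 10% and B(6) < 1%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .therapy import TranscriptSeries

__all__ = [
    "ROCResult",
    "pf_relative_change",
    "pf_score",
    "halving_time",
    "emr",
    "roc_evaluate",
    "compare_windows",
    "read_transcript_csv",
]

#: sentinel for "perfect responder" (transcript hit zero): sorts as most
#: responsive under the "responder iff score below threshold" convention
PF_PERFECT = -math.inf
#: sentinel for non-declining series in halving-time
HALVING_NEVER = math.inf

EMR3_THRESHOLD_PCT = 10.0
EMR6_THRESHOLD_PCT = 1.0


def pf_relative_change(b_start: float, b_end: float) -> float:
    """Relative transcript change ``(b_end - b_start) / b_end``.

    ``b_end == 0`` denotes a perfect responder and returns ``-inf``.
    """
    if b_start < 0 or b_end < 0:
        raise ValueError("transcript levels must be non-negative")
    if b_end == 0.0:
        return PF_PERFECT
    return (b_end - b_start) / b_end


def pf_score(series: TranscriptSeries, window: tuple[float, float] = (3.0, 6.0)) -> float:
    """PF statistic from a monthly series over ``window`` months."""
    t1, t2 = window
    return pf_relative_change(series.at(t1), series.at(t2))


def halving_time(series: TranscriptSeries, window: tuple[float, float] = (3.0, 6.0)) -> float:
    """Exponential halving time (months) over the window.

    ``t_half = (t2 - t1) ln 2 / ln(B(t1)/B(t2))``; a non-declining
    series maps to ``+inf``.  Zero endpoints are undefined except for a
    zero end level, which denotes the fastest possible decline (0).
    """
    t1, t2 = window
    b1, b2 = series.at(t1), series.at(t2)
    if b1 <= 0.0:
        raise ValueError("halving time undefined for zero start level")
    if b2 == 0.0:
        return 0.0
    if b2 >= b1:
        return HALVING_NEVER
    return (t2 - t1) * math.log(2.0) / math.log(b1 / b2)


def emr(series: TranscriptSeries) -> tuple[bool, bool]:
    """Early-molecular-response verdicts (strict inequalities):
    EMR3 = B(3) < 10%, EMR6 = B(6) < 1%."""
    return (
        series.at(3.0) < EMR3_THRESHOLD_PCT,
        series.at(6.0) < EMR6_THRESHOLD_PCT,
    )


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    optimal_threshold: float
    sensitivity: float
    specificity: float
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "tpr": self.tpr, "fpr": self.fpr}
        )

    def summary(self) -> dict:
        return {
            "optimal_threshold": self.optimal_threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
        }


def roc_evaluate(scores: Sequence[float], labels: Sequence[bool]) -> ROCResult:
    """ROC over a threshold sweep for "responder iff score < threshold".

    The optimal threshold maximizes Youden's J = TPR - FPR; ties break
    toward higher specificity.  Infinite sentinel scores are supported.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-D arrays")
    if labels.all() or (~labels).all():
        raise ValueError("need at least one member of each class")

    # "more negative score = more responder-like": feed -score to the
    # standard higher-is-positive ROC machinery
    finite_span = 1.0
    neg = -scores
    # map infinities inside the sweep range so they get their own
    # threshold positions
    finite = np.isfinite(neg)
    if finite.any():
        lo, hi = neg[finite].min(), neg[finite].max()
        finite_span = max(hi - lo, 1.0)
    else:
        lo, hi = 0.0, 0.0
    neg = np.where(neg == math.inf, hi + finite_span, neg)
    neg = np.where(neg == -math.inf, lo - finite_span, neg)

    fpr, tpr, thr = roc_curve(labels.astype(int), neg)
    auc = roc_auc_score(labels.astype(int), neg)
    j = tpr - fpr
    # ties toward higher specificity = lower fpr; roc_curve orders by
    # increasing fpr, so the first argmax wins
    best = int(np.argmax(j))
    optimal = -float(thr[best])
    return ROCResult(
        thresholds=-thr,
        tpr=tpr,
        fpr=fpr,
        optimal_threshold=optimal,
        sensitivity=float(tpr[best]),
        specificity=1.0 - float(fpr[best]),
        auc=float(auc),
    )


def _binary_roc(verdicts: np.ndarray, labels: np.ndarray) -> ROCResult:
    # a boolean predictor has a two-point ROC; reuse the sweep with a
    # 0/1 score (responder iff verdict true, i.e. score 0 < 0.5)
    return roc_evaluate(np.where(verdicts, 0.0, 1.0), labels)


def compare_windows(
    series_list: Sequence[TranscriptSeries],
    labels: Sequence[bool],
    windows: Sequence[tuple[float, float]] = ((0.0, 3.0), (3.0, 6.0)),
) -> pd.DataFrame:
    """Evaluate PF, halving time and EMR on each window.

    EMR uses the window's end month with the conventional threshold
    (10% at month 3, 1% at month 6).
    """
    labels = np.asarray(labels, dtype=bool)
    records = []
    for window in windows:
        t1, t2 = window
        pf = np.array([pf_score(s, window) for s in series_list])
        ht = np.array([halving_time(s, window) for s in series_list])
        emr_threshold = EMR3_THRESHOLD_PCT if t2 <= 3.0 else EMR6_THRESHOLD_PCT
        emr_verdicts = np.array([s.at(t2) < emr_threshold for s in series_list])
        for name, result in [
            ("pf", roc_evaluate(pf, labels)),
            ("halving_time", roc_evaluate(ht, labels)),
            ("emr", _binary_roc(emr_verdicts, labels)),
        ]:
            records.append(
                {
                    "statistic": name,
                    "window_start": t1,
                    "window_end": t2,
                    "sensitivity": result.sensitivity,
                    "specificity": result.specificity,
                    "auc": result.auc,
                    "optimal_threshold": result.optimal_threshold,
                }
            )
    return pd.DataFrame.from_records(records)


def read_transcript_csv(
    path,
    schedule: Sequence[float] = tuple(range(0, 51)),
    snap_tol: float = 0.5,
    required_months: Sequence[float] = (3.0, 6.0),
) -> list[TranscriptSeries]:
    """Read clinic-style transcript CSVs (patient_id, month, bcr_abl_pct).

    Month values are snapped to the nearest scheduled visit within
    ``snap_tol`` months; series missing any required visit are dropped.
    """
    df = pd.read_csv(path, comment="#")
    expected = {"patient_id", "month", "bcr_abl_pct"}
    if not expected.issubset(df.columns):
        raise ValueError(f"transcript CSV needs columns {sorted(expected)}")
    schedule = np.asarray(schedule, dtype=float)
    out = []
    for pid, grp in df.groupby("patient_id"):
        months = grp["month"].to_numpy(dtype=float)
        idx = np.argmin(np.abs(months[:, None] - schedule[None, :]), axis=1)
        snapped = schedule[idx]
        keep = np.abs(months - snapped) <= snap_tol
        grp2 = (
            pd.DataFrame(
                {"month": snapped[keep], "pct": grp["bcr_abl_pct"].to_numpy()[keep]}
            )
            .groupby("month", as_index=False)
            .mean()
            .sort_values("month")
        )
        if not all(m in set(grp2["month"]) for m in required_months):
            continue
        out.append(
            TranscriptSeries(
                times=grp2["month"].to_numpy(),
                values=np.clip(grp2["pct"].to_numpy(), 0.0, 100.0),
                patient_id=pid,
            )
        )
    return out
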