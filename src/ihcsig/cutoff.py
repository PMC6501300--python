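"""PPV-maximizing cutoff search under survival and prevalence constraints.

A candidate cutoff labels patients positive when their score is >= the
candidate. Candidates are the sorted unique observed scores — PPV, prevalence
and the log-rank statistics only change at observed values, so this grid is
exhaustive. A candidate is feasible when the positive-group prevalence lies
inside the configured band and the two-group log-rank p-values for both OS
and PFS are at or below their caps; the chosen cutoff is the feasible
candidate with maximal PPV (ties: smaller OS p-value, then smaller cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.stats.proportion import proportion_confint

from . import survival as surv

__all__ = [
    "SearchConstraints",
    "CutoffEvaluation",
    "CutoffSearchResult",
    "candidate_cutoffs",
    "ppv_with_ci",
    "evaluate_cutoff",
    "optimize_cutoff",
    "CutoffOptimizer",
]


@dataclass(frozen=True)
class SearchConstraints:
    max_p_os: float = 0.05
    max_p_pfs: float = 0.05
    prevalence_min: float = 0.30
    prevalence_max: float = 0.70
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if not (0 < self.max_p_os < 1 and 0 < self.max_p_pfs < 1):
            raise ValueError("p-value thresholds must lie in (0, 1)")
        if not (0 < self.prevalence_min < self.prevalence_max < 1):
            raise ValueError("require 0 < prevalence_min < prevalence_max < 1")
        if not (0 < self.confidence < 1):
            raise ValueError("confidence must lie in (0, 1)")


@dataclass(frozen=True)
class CutoffEvaluation:
    cutoff: float
    prevalence: float
    n_positive: int
    n_responders_positive: int
    ppv: float
    ppv_ci: tuple
    p_os: float
    p_pfs: float
    feasible: bool
    reason: str = ""


@dataclass(frozen=True)
class CutoffSearchResult:
    best: CutoffEvaluation | None
    all_evaluations: tuple
    n_candidates: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cutoff": ev.cutoff,
                "prevalence": ev.prevalence,
                "n_positive": ev.n_positive,
                "n_responders_positive": ev.n_responders_positive,
                "ppv": ev.ppv,
                "ppv_ci_lo": ev.ppv_ci[0],
                "ppv_ci_hi": ev.ppv_ci[1],
                "p_os": ev.p_os,
                "p_pfs": ev.p_pfs,
                "feasible": ev.feasible,
                "reason": ev.reason,
            }
            for ev in self.all_evaluations
        ]
        return pd.DataFrame(rows)


def candidate_cutoffs(scores) -> np.ndarray:
    """Sorted unique observed scores (each labels ``>= candidate`` positive)."""
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("no scores provided")
    if not np.all(np.isfinite(arr)):
        raise ValueError("scores must be finite")
    return np.unique(arr)


def ppv_with_ci(n_positive: int, n_responders: int, confidence: float = 0.95):
    """PPV with an exact (Clopper–Pearson) binomial confidence interval.

    Returns ``(ppv, lo, hi)``; all NaN when ``n_positive == 0`` (undefined).
    """
    if n_positive < 0 or n_responders < 0:
        raise ValueError("counts must be non-negative")
    if n_responders > n_positive:
        raise ValueError("n_responders cannot exceed n_positive")
    if n_positive == 0:
        return (float("nan"), float("nan"), float("nan"))
    ppv = n_responders / n_positive
    lo, hi = proportion_confint(n_responders, n_positive, alpha=1 - confidence, method="beta")
    return (ppv, float(lo), float(hi))


def evaluate_cutoff(
    cohort: pd.DataFrame,
    scores,
    cutoff: float,
    constraints: SearchConstraints | None = None,
) -> CutoffEvaluation:
    """Dichotomize at ``cutoff`` and compute PPV, prevalence, log-rank p's."""
    constraints = constraints or SearchConstraints()
    s = np.asarray(scores, dtype=float)
    if len(s) != len(cohort):
        raise ValueError("scores must align with the cohort")
    pos = s >= cutoff
    n = len(s)
    n_pos = int(pos.sum())
    prevalence = n_pos / n
    resp = cohort["response"].to_numpy().astype(int)
    n_resp_pos = int(resp[pos].sum())
    ppv, lo, hi = ppv_with_ci(n_pos, n_resp_pos, constraints.confidence)

    reason = ""
    if n_pos == 0 or n_pos == n:
        p_os = p_pfs = float("nan")
        reason = "degenerate group: one side empty"
    else:
        try:
            p_os = surv.logrank(
                cohort["os_time"].to_numpy()[pos],
                cohort["os_event"].to_numpy()[pos],
                cohort["os_time"].to_numpy()[~pos],
                cohort["os_event"].to_numpy()[~pos],
            ).p_value
            p_pfs = surv.logrank(
                cohort["pfs_time"].to_numpy()[pos],
                cohort["pfs_event"].to_numpy()[pos],
                cohort["pfs_time"].to_numpy()[~pos],
                cohort["pfs_event"].to_numpy()[~pos],
            ).p_value
        except ValueError as exc:
            p_os = p_pfs = float("nan")
            reason = f"log-rank undefined: {exc}"

    feasible = (
        np.isfinite(p_os)
        and np.isfinite(p_pfs)
        and p_os <= constraints.max_p_os
        and p_pfs <= constraints.max_p_pfs
        and constraints.prevalence_min <= prevalence <= constraints.prevalence_max
    )
    if not feasible and not reason:
        parts = []
        if not (constraints.prevalence_min <= prevalence <= constraints.prevalence_max):
            parts.append("prevalence outside band")
        if np.isfinite(p_os) and p_os > constraints.max_p_os:
            parts.append("OS log-rank p above cap")
        if np.isfinite(p_pfs) and p_pfs > constraints.max_p_pfs:
            parts.append("PFS log-rank p above cap")
        reason = "; ".join(parts)
    return CutoffEvaluation(
        cutoff=float(cutoff),
        prevalence=prevalence,
        n_positive=n_pos,
        n_responders_positive=n_resp_pos,
        ppv=ppv,
        ppv_ci=(lo, hi),
        p_os=float(p_os),
        p_pfs=float(p_pfs),
        feasible=bool(feasible),
        reason=reason,
    )


def optimize_cutoff(
    cohort: pd.DataFrame,
    scores,
    constraints: SearchConstraints | None = None,
) -> CutoffSearchResult:
    """Evaluate every candidate cutoff and keep the feasible PPV maximizer."""
    constraints = constraints or SearchConstraints()
    cands = candidate_cutoffs(scores)
    evals = tuple(evaluate_cutoff(cohort, scores, c, constraints) for c in cands)
    feasible = [ev for ev in evals if ev.feasible]
    best = None
    if feasible:
        best = min(feasible, key=lambda ev: (-ev.ppv, ev.p_os, ev.cutoff))
    return CutoffSearchResult(best=best, all_evaluations=evals, n_candidates=len(cands))


class CutoffOptimizer(BaseEstimator):
    """sklearn-style estimator learning a score cutoff by PPV maximization.

    ``fit(X)`` expects a cohort DataFrame carrying ``score_col`` plus the
    ``response``, ``os_time``/``os_event`` and ``pfs_time``/``pfs_event``
    columns; after fitting, ``cutoff_`` holds the learned threshold and
    ``result_`` the full search trace. ``predict`` labels score arrays (or
    frames) 1 = positive, 0 = negative at the learned cutoff.
    """

    def __init__(
        self,
        score_col: str = "signature_score",
        max_p_os: float = 0.05,
        max_p_pfs: float = 0.05,
        prevalence_min: float = 0.30,
        prevalence_max: float = 0.70,
        confidence: float = 0.95,
    ):
        self.score_col = score_col
        self.max_p_os = max_p_os
        self.max_p_pfs = max_p_pfs
        self.prevalence_min = prevalence_min
        self.prevalence_max = prevalence_max
        self.confidence = confidence

    def _constraints(self) -> SearchConstraints:
        return SearchConstraints(
            max_p_os=self.max_p_os,
            max_p_pfs=self.max_p_pfs,
            prevalence_min=self.prevalence_min,
            prevalence_max=self.prevalence_max,
            confidence=self.confidence,
        )

    def fit(self, X: pd.DataFrame, y=None):
        scores = X[self.score_col].to_numpy(dtype=float)
        self.result_ = optimize_cutoff(X, scores, self._constraints())
        self.feasible_ = self.result_.best is not None
        self.cutoff_ = self.result_.best.cutoff if self.feasible_ else float("nan")
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "result_"):
            raise RuntimeError("CutoffOptimizer is not fitted")
        if not self.feasible_:
            raise RuntimeError("no feasible cutoff was found during fit")
        if isinstance(X, pd.DataFrame):
            s = X[self.score_col].to_numpy(dtype=float)
        else:
            s = np.asarray(X, dtype=float)
        return (s >= self.cutoff_).astype(int)
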