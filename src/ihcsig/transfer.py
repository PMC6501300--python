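"""Prevalence-matched transfer of signature positivity to a new cohort.

The signature is transferred without re-optimizing: the target cohort is
ranked by score and the top-q fraction is labeled positive, where q is the
signature-positive prevalence of a reference cohort (e.g. 59/163 = 36%).
The implied per-cohort cutoff is the smallest positive score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .scoring import NEGATIVE, POSITIVE

__all__ = ["TransferResult", "reference_prevalence", "match_prevalence", "PrevalenceMatcher"]


@dataclass(frozen=True)
class TransferResult:
    matched_prevalence: float
    n_positive: int
    derived_cutoff: float
    labels: np.ndarray


def _as_bool_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.size == 0:
        raise ValueError("empty label array")
    if arr.dtype.kind in "USO":
        return arr == POSITIVE
    return arr.astype(bool)


def reference_prevalence(labels) -> float:
    """Fraction of positive labels, at full precision."""
    b = _as_bool_labels(labels)
    return float(b.sum()) / b.size


def _n_positive(q: float, n: int, rounding: str) -> int:
    if rounding == "round":  # half-up, so 71.5 -> 72
        return int(math.floor(q * n + 0.5))
    if rounding == "floor":
        return int(math.floor(q * n))
    if rounding == "ceil":
        return int(math.ceil(q * n))
    raise ValueError("rounding must be 'round', 'floor' or 'ceil'")


def match_prevalence(target_scores, q: float, rounding: str = "round") -> TransferResult:
    """Label the top ``round(q*n)`` scores positive; stable order breaks ties.

    The derived cutoff is the smallest positive score (a sentinel above the
    maximum score when nothing is labeled positive). A tie straddling the
    positivity boundary is resolved by stable input order with a warning.
    """
    s = np.asarray(target_scores, dtype=float)
    if s.size == 0:
        raise ValueError("empty target scores")
    if not (0.0 <= q <= 1.0):
        raise ValueError("q must lie in [0, 1]")
    n = s.size
    n_pos = min(_n_positive(q, n, rounding), n)
    order = np.argsort(-s, kind="stable")
    labels = np.full(n, NEGATIVE, dtype=object)
    if n_pos > 0:
        pos_idx = order[:n_pos]
        labels[pos_idx] = POSITIVE
        derived_cutoff = float(s[pos_idx].min())
        if n_pos < n and s[order[n_pos]] == derived_cutoff:
            warnings.warn(
                "tied scores at the positivity boundary; resolved by stable input order",
                stacklevel=2,
            )
    else:
        derived_cutoff = float(np.nextafter(s.max(), np.inf))
    return TransferResult(
        matched_prevalence=n_pos / n,
        n_positive=n_pos,
        derived_cutoff=derived_cutoff,
        labels=labels.astype(str),
    )


class PrevalenceMatcher(BaseEstimator):
    """sklearn-style estimator: fit on reference labels, transform target scores.

    ``fit`` records the reference positive prevalence (full precision unless
    ``q`` is passed explicitly); ``transform`` returns 0/1 positivity for a
    score vector, and ``match`` the full :class:`TransferResult`.
    """

    def __init__(self, rounding: str = "round"):
        self.rounding = rounding

    def fit(self, reference_labels, y=None):
        self.prevalence_ = reference_prevalence(reference_labels)
        return self

    def match(self, target_scores) -> TransferResult:
        if not hasattr(self, "prevalence_"):
            raise RuntimeError("PrevalenceMatcher is not fitted")
        return match_prevalence(target_scores, self.prevalence_, self.rounding)

    def transform(self, target_scores) -> np.ndarray:
        return (self.match(target_scores).labels == POSITIVE).astype(int)
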