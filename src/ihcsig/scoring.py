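"""The CD8xPD-L1 product signature and dichotomization at cutoffs.

The signature is the plain product of the CD8+ and PD-L1+ cell densities
(cells²/mm⁴) within the annotated tumor region. Dichotomization uses the
boundary convention ``value >= cutoff -> positive`` for every measure,
matching the manual-score convention "TC >= 25%".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "CutoffSpec",
    "compute_score",
    "classify",
    "add_measure_labels",
    "SignatureScorer",
    "POSITIVE",
    "NEGATIVE",
]

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class CutoffSpec:
    """Published default cutoffs for the four measures."""

    cd8_cutoff: float = 297.0  # cells/mm²
    pdl1_cutoff: float = 644.0  # cells/mm²
    signature_cutoff: float = 1.54e5  # cells²/mm⁴
    pdl1_tc_cutoff: float = 25.0  # percent

    def __post_init__(self) -> None:
        for name in ("cd8_cutoff", "pdl1_cutoff", "signature_cutoff", "pdl1_tc_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"CutoffSpec.{name} must be > 0")


def _validate_density(x, name: str):
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")
    return arr


def compute_score(cd8_density, pdl1_density):
    """Signature score = cd8_density * pdl1_density (cells²/mm⁴).

    Accepts scalars or aligned arrays; inputs must be finite and >= 0.
    """
    cd8 = _validate_density(cd8_density, "cd8_density")
    pdl1 = _validate_density(pdl1_density, "pdl1_density")
    out = cd8 * pdl1
    return float(out) if np.isscalar(cd8_density) and np.isscalar(pdl1_density) else out


def classify(value, cutoff: float):
    """Label ``value >= cutoff`` positive (boundary inclusive), else negative."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    arr = np.asarray(value, dtype=float)
    labels = np.where(arr >= cutoff, POSITIVE, NEGATIVE)
    if np.isscalar(value) or arr.ndim == 0:
        return str(labels)
    return labels


def add_measure_labels(cohort: pd.DataFrame, cutoffs: CutoffSpec | None = None) -> pd.DataFrame:
    """Return a copy with ``signature_score`` and the four ``*_label`` columns."""
    cutoffs = cutoffs or CutoffSpec()
    df = cohort.copy()
    df["signature_score"] = compute_score(
        df["cd8_density"].to_numpy(), df["pdl1_density"].to_numpy()
    )
    df["signature_label"] = classify(df["signature_score"].to_numpy(), cutoffs.signature_cutoff)
    df["cd8_label"] = classify(df["cd8_density"].to_numpy(), cutoffs.cd8_cutoff)
    df["pdl1_label"] = classify(df["pdl1_density"].to_numpy(), cutoffs.pdl1_cutoff)
    df["pdl1_tc_label"] = classify(df["pdl1_tc_pct"].to_numpy(), cutoffs.pdl1_tc_cutoff)
    return df


class SignatureScorer(BaseEstimator, TransformerMixin):
    """Stateless transformer adding the score and label columns to a cohort frame."""

    def __init__(
        self,
        cd8_cutoff: float = 297.0,
        pdl1_cutoff: float = 644.0,
        signature_cutoff: float = 1.54e5,
        pdl1_tc_cutoff: float = 25.0,
    ):
        self.cd8_cutoff = cd8_cutoff
        self.pdl1_cutoff = pdl1_cutoff
        self.signature_cutoff = signature_cutoff
        self.pdl1_tc_cutoff = pdl1_tc_cutoff

    def fit(self, X: pd.DataFrame, y=None):
        self.cutoffs_ = CutoffSpec(
            cd8_cutoff=self.cd8_cutoff,
            pdl1_cutoff=self.pdl1_cutoff,
            signature_cutoff=self.signature_cutoff,
            pdl1_tc_cutoff=self.pdl1_tc_cutoff,
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "cutoffs_"):
            self.fit(X)
        return add_measure_labels(X, self.cutoffs_)
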