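"""Survival machinery: Kaplan–Meier, log-rank, Cox PH, nested comparison.

Kaplan–Meier estimation (Greenwood variance, log-log confidence bands,
Brookmeyer–Crowley median CI) and the two-group log-rank test are delegated
to lifelines. The Cox proportional-hazards fit maximizes the partial
likelihood directly with a damped Newton iteration so that both Efron
(default) and Breslow tie handling are available; Wald p-values come from the
observed information. Nested proportional-hazards models are compared with
the partial-likelihood ratio chi-square test.

Significance banding follows the four-symbol convention
``- > 0.05; + <= 0.05; ++ <= 0.005; +++ <= 0.0005``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import median_survival_times as _ll_median_ci
from scipy import stats

__all__ = [
    "KMCurve",
    "MedianSurvival",
    "LogRankResult",
    "CoxFit",
    "NestedComparison",
    "NOT_REACHED",
    "km_curve",
    "km_median",
    "logrank",
    "cox_fit",
    "nested_lr_test",
    "significance_band",
    "km_plot",
]

#: Sentinel for a median (or CI bound) the curve never reaches.
NOT_REACHED = math.inf


def _as_surv_arrays(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if t.size == 0:
        raise ValueError("empty survival input")
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if np.any(t <= 0) or not np.all(np.isfinite(t)):
        raise ValueError("times must be finite and > 0")
    if not np.all(np.isin(e, [0, 1])):
        raise ValueError("events must be binary 0/1")
    return t, e.astype(int)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate with pointwise 95% log-log bands."""

    event_times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_risk: np.ndarray
    n_events: np.ndarray
    _kmf: KaplanMeierFitter = field(repr=False, compare=False, default=None)


def km_curve(times, events, alpha: float = 0.05) -> KMCurve:
    """Kaplan–Meier estimate over the observed (event or censoring) times."""
    t, e = _as_surv_arrays(times, events)
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(t, e)
    table = kmf.event_table
    timeline = np.asarray([x for x in table.index if x > 0], dtype=float)
    surv = kmf.survival_function_at_times(timeline).to_numpy()
    ci = kmf.confidence_interval_survival_function_
    lo = np.interp(timeline, ci.index.to_numpy(), ci.iloc[:, 0].to_numpy())
    hi = np.interp(timeline, ci.index.to_numpy(), ci.iloc[:, 1].to_numpy())
    sub = table.loc[[x for x in table.index if x > 0]]
    return KMCurve(
        event_times=timeline,
        survival=surv,
        ci_lower=lo,
        ci_upper=hi,
        n_risk=sub["at_risk"].to_numpy(),
        n_events=sub["observed"].to_numpy(),
        _kmf=kmf,
    )


@dataclass(frozen=True)
class MedianSurvival:
    """Median survival in months; ``math.inf`` encodes "not reached"."""

    median: float
    ci: tuple


def km_median(curve: KMCurve) -> MedianSurvival:
    """Median = first time survival drops to <= 0.5, CI by inverting the band."""
    kmf = curve._kmf
    med = float(kmf.median_survival_time_)
    ci_df = _ll_median_ci(kmf.confidence_interval_)
    lo = float(ci_df.iloc[0, 0])
    hi = float(ci_df.iloc[0, 1])
    return MedianSurvival(median=med, ci=(lo, hi))


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    p_value: float


def logrank(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-group log-rank chi-square (1 df) via lifelines."""
    ta, ea = _as_surv_arrays(times_a, events_a)
    tb, eb = _as_surv_arrays(times_b, events_b)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank undefined: zero events in both groups")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return LogRankResult(statistic=float(res.test_statistic), p_value=float(res.p_value))


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoxFit:
    names: tuple
    coefficients: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray
    log_partial_likelihood: float
    n: int
    n_events: int
    converged: bool
    tie_method: str = "efron"

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "se": self.standard_errors,
                "p": self.p_values,
                "hr": np.exp(self.coefficients),
            },
            index=list(self.names),
        )


def _cox_loglik(beta, x, times, events, tie_method):
    """Log partial likelihood, gradient and observed information at beta.

    Risk-set sums of exp(eta), exp(eta)·x and exp(eta)·x xᵀ are suffix
    cumulative sums over the time-sorted subjects; untied event times (and
    everything under Breslow) are handled fully vectorized, and Efron's
    correction loops only over the tied event times. The partial likelihood
    is invariant to the common eta shift used as an overflow guard.
    """
    n, p = x.shape
    order = np.argsort(times, kind="stable")
    xs = x[order]
    ts = times[order]
    es = events[order]
    eta = xs @ beta
    eta = eta - eta.max()
    w = np.exp(eta)
    xw = w[:, None] * xs
    xxw = xw[:, :, None] * xs[:, None, :]
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(xw[::-1], axis=0)[::-1]
    s2 = np.cumsum(xxw[::-1], axis=0)[::-1]

    blk = np.cumsum(np.r_[0, (np.diff(ts) != 0).astype(int)])  # block id per position
    starts = np.r_[0, 1 + np.nonzero(np.diff(ts))[0]]
    d_per_block = np.bincount(blk, weights=es).astype(int)

    ev = np.nonzero(es)[0]
    if tie_method == "breslow":
        easy = ev
        hard_blocks = np.array([], dtype=int)
    else:
        easy = ev[d_per_block[blk[ev]] == 1]
        hard_blocks = np.nonzero(d_per_block >= 2)[0]

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    if easy.size:
        bstart = starts[blk[easy]]
        s0v = s0[bstart]
        mvec = s1[bstart] / s0v[:, None]
        ll += eta[easy].sum() - np.log(s0v).sum()
        grad += xs[easy].sum(axis=0) - mvec.sum(axis=0)
        info += (s2[bstart] / s0v[:, None, None]).sum(axis=0) - np.einsum(
            "ij,ik->jk", mvec, mvec
        )
    for b in hard_blocks:
        a = starts[b]
        end = starts[b + 1] if b + 1 < len(starts) else n
        tied = a + np.nonzero(es[a:end])[0]
        d = len(tied)
        s0d = w[tied].sum()
        s1d = xw[tied].sum(axis=0)
        s2d = xxw[tied].sum(axis=0)
        ll += eta[tied].sum()
        grad += xs[tied].sum(axis=0)
        for el in range(d):
            frac = el / d
            phi = s0[a] - frac * s0d
            mvec = (s1[a] - frac * s1d) / phi
            ll -= math.log(phi)
            grad -= mvec
            info += (s2[a] - frac * s2d) / phi - np.outer(mvec, mvec)
    return ll, grad, info


def cox_fit(
    covariates,
    times,
    events,
    tie_method: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxFit:
    """Maximize the Cox partial likelihood by damped Newton iteration.

    ``covariates`` is a DataFrame (column names kept) or 2-D array; constant
    columns are rejected. Monotone likelihood (perfect separation) or a
    singular information matrix yields ``converged=False`` rather than an
    exception.
    """
    if tie_method not in ("efron", "breslow"):
        raise ValueError("tie_method must be 'efron' or 'breslow'")
    if isinstance(covariates, pd.DataFrame):
        names = tuple(covariates.columns)
        x = covariates.to_numpy(dtype=float)
    else:
        x = np.asarray(covariates, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        names = tuple(f"x{i}" for i in range(x.shape[1]))
    t, e = _as_surv_arrays(times, events)
    if x.shape[0] != t.size:
        raise ValueError("covariates and times must align")
    if np.any(x.std(axis=0) == 0):
        raise ValueError("constant covariate column(s); drop before fitting")
    n, p = x.shape
    n_events = int(e.sum())
    if n_events < p:
        raise ValueError(f"need n_events >= n_covariates ({n_events} < {p})")

    beta = np.zeros(p)
    ll, grad, info = _cox_loglik(beta, x, t, e, tie_method)
    converged = False
    # gradient tolerance scaled by the likelihood magnitude (absolute for
    # small problems); a vanishing Newton step also counts as converged
    def _done(g, loglik, step_norm=np.inf):
        return (
            np.linalg.norm(g) < tol * max(1.0, abs(loglik))
            or step_norm < 1e-10
        )

    for _ in range(max_iter):
        if _done(grad, ll):
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        # damping: halve until the partial likelihood does not decrease
        new = None
        for _h in range(30):
            cand = beta + step
            ll_c, grad_c, info_c = _cox_loglik(cand, x, t, e, tie_method)
            if np.isfinite(ll_c) and ll_c >= ll - 1e-10 * max(1.0, abs(ll)):
                new = (cand, ll_c, grad_c, info_c)
                break
            step = step / 2.0
        if new is None:
            break
        beta, ll, grad, info = new
        if _done(grad, ll, np.linalg.norm(step)):
            converged = True
            break
        if np.any(np.abs(beta) > 15):  # monotone likelihood
            converged = False
            break

    if converged and np.any(np.abs(beta) > 15):
        converged = False
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    with np.errstate(divide="ignore", invalid="ignore"):
        zscores = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(zscores))
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    return CoxFit(
        names=names,
        coefficients=beta,
        standard_errors=se,
        p_values=pvals,
        log_partial_likelihood=float(ll),
        n=n,
        n_events=n_events,
        converged=bool(converged),
        tie_method=tie_method,
    )


@dataclass(frozen=True)
class NestedComparison:
    lr_statistic: float
    df: int
    p_value: float


def nested_lr_test(fit_reduced: CoxFit, fit_full: CoxFit) -> NestedComparison:
    """Partial-likelihood ratio test between nested Cox fits.

    This is what an "ANOVA" of nested proportional-hazards models computes:
    ``2 * (logPL_full - logPL_reduced)`` against chi-square with df equal to
    the covariate-count difference.
    """
    if not set(fit_reduced.names) <= set(fit_full.names):
        raise ValueError("reduced model covariates must be a subset of the full model's")
    if fit_reduced.n != fit_full.n or fit_reduced.n_events != fit_full.n_events:
        raise ValueError("nested fits must use the same patients")
    df = len(fit_full.names) - len(fit_reduced.names)
    lr = max(0.0, 2.0 * (fit_full.log_partial_likelihood - fit_reduced.log_partial_likelihood))
    p = 1.0 if df == 0 else float(stats.chi2.sf(lr, df))
    return NestedComparison(lr_statistic=lr, df=df, p_value=max(p, np.finfo(float).tiny))


def significance_band(p_value: float) -> str:
    """Band a p-value as ``-`` (>0.05), ``+`` (<=0.05), ``++`` (<=0.005), ``+++`` (<=0.0005)."""
    if not (0.0 < p_value <= 1.0):
        raise ValueError("p-value must lie in (0, 1]")
    if p_value <= 0.0005:
        return "+++"
    if p_value <= 0.005:
        return "++"
    if p_value <= 0.05:
        return "+"
    return "-"


def km_plot(groups: dict, path, title: str = "") -> None:
    """Render KM curves with shaded 95% bands for ``{label: (times, events)}``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for label, (t, e) in groups.items():
        kmf = KaplanMeierFitter()
        kmf.fit(np.asarray(t, float), np.asarray(e, int), label=str(label))
        kmf.plot_survival_function(ax=ax, ci_show=True)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
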