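"""Full-analysis orchestration: split, optimize, evaluate, transfer, report.

`stratified_split` reproduces a covariate-balanced train/test partition;
`performance_table` emits one positive/negative row pair per measure with
prevalence, PPV (exact binomial CI), median OS/PFS (log-log CI) and two-group
log-rank p-values; `cox_table` adds each measure separately to the seven
fixed clinical covariates, bands the added covariate's Wald p-value and bands
the overall model against the fixed-covariates-only fit via the nested
partial-likelihood ratio test. `run_pipeline` wires the synthetic cohorts
through all stages with a single global seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import cutoff as cutoff_mod
from . import survival as surv
from .scoring import POSITIVE, CutoffSpec, add_measure_labels
from .simulate import CohortConfig, generate_cohort
from .transfer import PrevalenceMatcher

logger = logging.getLogger(__name__)

__all__ = [
    "StratificationSummary",
    "CoxTableRow",
    "stratified_split",
    "performance_table",
    "performance_frame",
    "cox_table",
    "run_pipeline",
    "DEFAULT_FIXED_COVARIATES",
    "MEASURES",
]

#: Fixed clinical covariates of the multivariate Cox model.
DEFAULT_FIXED_COVARIATES = (
    "histology",
    "smoking_status",
    "age",
    "gender",
    "liver_metastasis",
    "tumor_stage",
    "prior_lines",
)

#: measure name -> (value column, CutoffSpec attribute, group labels)
MEASURES = {
    "CD8xPD-L1": ("signature_score", "signature_cutoff", ("positive", "negative")),
    "CD8 density": ("cd8_density", "cd8_cutoff", ("high", "low")),
    "PD-L1 density": ("pdl1_density", "pdl1_cutoff", ("high", "low")),
    "PD-L1 TC": ("pdl1_tc_pct", "pdl1_tc_cutoff", (">=cut", "<cut")),
}


# ---------------------------------------------------------------------------
# Stratified split
# ---------------------------------------------------------------------------


def _balance_key(cohort: pd.DataFrame, balance_variables) -> pd.Series:
    """Joint-stratum key; continuous variables are binned (2 quantile bins)."""
    parts = []
    for var in balance_variables:
        col = cohort[var]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 6:
            binned = pd.qcut(col, 2, duplicates="drop").astype(str)
        else:
            binned = col.astype(str)
        parts.append(binned)
    key = parts[0].str.cat(parts[1:], sep="|") if len(parts) > 1 else parts[0]
    return key


def stratified_split(
    cohort: pd.DataFrame,
    train_fraction: float,
    balance_variables,
    seed: int,
):
    """Partition into (train, test) proportionally within joint strata.

    Within each joint stratum of the balance variables, patients are
    allocated by largest-remainder rounding toward an exact overall train
    size of ``round(n * train_fraction)``; membership within a stratum is
    shuffled by the seed. Strata of size 1 are effectively assigned by the
    seeded remainder draw (logged).
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    missing = [v for v in balance_variables if v not in cohort.columns]
    if missing:
        raise ValueError(f"balance variables not in cohort: {missing}")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    target_train = int(math.floor(train_fraction * n + 0.5))

    key = _balance_key(cohort, balance_variables)
    strata = list(cohort.groupby(key, sort=True).groups.items())
    # seeded stratum order so remainder ties break randomly but reproducibly
    rng.shuffle(strata)

    base, remainders = [], []
    for _, idx in strata:
        quota = len(idx) * train_fraction
        base.append(int(math.floor(quota)))
        remainders.append(quota - math.floor(quota))
    short = target_train - sum(base)
    order = np.argsort(-np.asarray(remainders), kind="stable")
    take = np.array(base)
    for j in order:
        if short <= 0:
            break
        if take[j] < len(strata[j][1]):
            take[j] += 1
            short -= 1

    train_idx = []
    for (name, idx), k in zip(strata, take):
        if len(idx) == 1:
            logger.debug("stratum %r has a single patient; assignment is a seeded draw", name)
        perm = rng.permutation(len(idx))
        chosen = np.asarray(idx)[perm[:k]]
        train_idx.extend(chosen.tolist())
    train_mask = cohort.index.isin(train_idx)
    return cohort.loc[train_mask], cohort.loc[~train_mask]


# ---------------------------------------------------------------------------
# Per-measure stratification performance table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StratificationSummary:
    measure: str
    group: str
    n: int
    prevalence: float
    ppv: float
    ppv_ci: tuple
    median_os: float
    median_os_ci: tuple
    p_os: float
    median_pfs: float
    median_pfs_ci: tuple
    p_pfs: float
    note: str = ""


def _group_medians(sub: pd.DataFrame, time_col: str, event_col: str):
    curve = surv.km_curve(sub[time_col].to_numpy(), sub[event_col].to_numpy())
    med = surv.km_median(curve)
    return med.median, med.ci


def performance_table(
    cohort: pd.DataFrame,
    cutoffs: CutoffSpec | None = None,
    confidence: float = 0.95,
):
    """One positive/negative row pair per measure (signature, CD8, PD-L1, TC)."""
    cutoffs = cutoffs or CutoffSpec()
    df = add_measure_labels(cohort, cutoffs)
    n_total = len(df)
    rows: list[StratificationSummary] = []
    for measure, (col, cut_attr, (pos_name, neg_name)) in MEASURES.items():
        cut = getattr(cutoffs, cut_attr)
        pos_mask = df[col].to_numpy(dtype=float) >= cut
        groups = [(pos_name, pos_mask), (neg_name, ~pos_mask)]
        # shared log-rank p-values between the two groups
        if pos_mask.all() or (~pos_mask).all():
            p_os = p_pfs = float("nan")
            note = "degenerate group: one side empty"
        else:
            note = ""
            try:
                p_os = surv.logrank(
                    df["os_time"][pos_mask], df["os_event"][pos_mask],
                    df["os_time"][~pos_mask], df["os_event"][~pos_mask],
                ).p_value
                p_pfs = surv.logrank(
                    df["pfs_time"][pos_mask], df["pfs_event"][pos_mask],
                    df["pfs_time"][~pos_mask], df["pfs_event"][~pos_mask],
                ).p_value
            except ValueError as exc:
                p_os = p_pfs = float("nan")
                note = f"log-rank undefined: {exc}"
        for gname, mask in groups:
            n_g = int(mask.sum())
            if n_g == 0:
                rows.append(
                    StratificationSummary(
                        measure, gname, 0, 0.0, float("nan"), (float("nan"),) * 2,
                        float("nan"), (float("nan"),) * 2, p_os,
                        float("nan"), (float("nan"),) * 2, p_pfs,
                        note="empty group",
                    )
                )
                continue
            sub = df.loc[mask]
            n_resp = int(sub["response"].sum())
            ppv, lo, hi = cutoff_mod.ppv_with_ci(n_g, n_resp, confidence)
            med_os, ci_os = _group_medians(sub, "os_time", "os_event")
            med_pfs, ci_pfs = _group_medians(sub, "pfs_time", "pfs_event")
            rows.append(
                StratificationSummary(
                    measure=measure,
                    group=gname,
                    n=n_g,
                    prevalence=n_g / n_total,
                    ppv=ppv,
                    ppv_ci=(lo, hi),
                    median_os=med_os,
                    median_os_ci=ci_os,
                    p_os=p_os,
                    median_pfs=med_pfs,
                    median_pfs_ci=ci_pfs,
                    p_pfs=p_pfs,
                    note=note,
                )
            )
    return rows


def performance_frame(rows) -> pd.DataFrame:
    """Flatten StratificationSummary rows to a DataFrame (NR rendered as 'NR')."""

    def fmt(x):
        return "NR" if isinstance(x, float) and math.isinf(x) else x

    return pd.DataFrame(
        [
            {
                "measure": r.measure,
                "group": r.group,
                "n": r.n,
                "prevalence": round(r.prevalence, 2),
                "ppv": round(r.ppv, 2) if np.isfinite(r.ppv) else r.ppv,
                "ppv_ci_lo": r.ppv_ci[0],
                "ppv_ci_hi": r.ppv_ci[1],
                "median_os": fmt(r.median_os),
                "median_os_lo": fmt(r.median_os_ci[0]),
                "median_os_hi": fmt(r.median_os_ci[1]),
                "p_os": r.p_os,
                "median_pfs": fmt(r.median_pfs),
                "median_pfs_lo": fmt(r.median_pfs_ci[0]),
                "median_pfs_hi": fmt(r.median_pfs_ci[1]),
                "p_pfs": r.p_pfs,
                "note": r.note,
            }
            for r in rows
        ]
    )


# ---------------------------------------------------------------------------
# Multiparametric Cox table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoxTableRow:
    added_covariate: str
    band_added: str
    significant_fixed_covariates: dict
    band_model: str
    converged: bool = True


def _encode_covariates(cohort: pd.DataFrame, covariates) -> pd.DataFrame:
    """One-hot encode categoricals against the lexicographically first level."""
    cols = {}
    for cov in covariates:
        s = cohort[cov]
        if pd.api.types.is_numeric_dtype(s):
            cols[cov] = s.astype(float)
        else:
            levels = sorted(s.astype(str).unique())
            for lev in levels[1:]:  # reference = first level
                cols[f"{cov}[{lev}]"] = (s.astype(str) == lev).astype(float)
    return pd.DataFrame(cols, index=cohort.index)


def cox_table(
    cohort: pd.DataFrame,
    fixed_covariates=DEFAULT_FIXED_COVARIATES,
    added_covariates: dict | None = None,
    cutoffs: CutoffSpec | None = None,
    tie_method: str = "efron",
):
    """Add each measure separately to the fixed covariates and band the fits.

    ``added_covariates`` maps display name -> cohort column holding a binary
    (0/1) indicator; by default the four measures dichotomized at ``cutoffs``.
    """
    cutoffs = cutoffs or CutoffSpec()
    df = add_measure_labels(cohort, cutoffs)
    if added_covariates is None:
        added_covariates = {
            "PD-L1 expression": "pdl1_tc_label",
            "CD8+ cell density": "cd8_label",
            "PD-L1+ cell density": "pdl1_label",
            "CD8xPD-L1 signature": "signature_label",
        }
    times = df["os_time"].to_numpy()
    events = df["os_event"].to_numpy()
    x_fixed = _encode_covariates(df, fixed_covariates)
    fit_reduced = surv.cox_fit(x_fixed, times, events, tie_method=tie_method)

    rows: list[CoxTableRow] = []
    for display, col in added_covariates.items():
        s = df[col]
        indicator = (
            (s == POSITIVE).astype(float)
            if not pd.api.types.is_numeric_dtype(s)
            else s.astype(float)
        )
        x_full = x_fixed.copy()
        x_full[display] = indicator.to_numpy()
        fit_full = surv.cox_fit(x_full, times, events, tie_method=tie_method)
        comp = surv.nested_lr_test(fit_reduced, fit_full)
        summ = fit_full.summary()
        sig_fixed = {
            name: surv.significance_band(summ.loc[name, "p"])
            for name in x_fixed.columns
            if summ.loc[name, "p"] <= 0.05
        }
        rows.append(
            CoxTableRow(
                added_covariate=display,
                band_added=surv.significance_band(summ.loc[display, "p"]),
                significant_fixed_covariates=sig_fixed,
                band_model=surv.significance_band(comp.p_value),
                converged=fit_full.converged,
            )
        )
    return rows


# ---------------------------------------------------------------------------
# End-to-end pipeline on synthetic cohorts
# ---------------------------------------------------------------------------

#: Non-ICT (surgery/chemotherapy) cohort: longer baseline survival, no
#: signature effect on hazard (the signature is predictive, not prognostic),
#: lower density scale so the transferred cutoff lands well below 1.54e5.
NON_ICT_OVERRIDES = dict(
    n_patients=199,
    log_mean_cd8=4.60,
    log_mean_pdl1=5.07,
    response_intercept=-2.5,
    baseline_hazard_os=math.log(2) / 50.0,
    baseline_hazard_pfs=math.log(2) / 20.0,
    log_hr_signature=0.0,
    censor_rate=0.008,
)


def run_pipeline(
    seed: int,
    durva_config: CohortConfig | None = None,
    train_fraction: float = 84.0 / 163.0,
    balance_variables=("pdl1_tc_label", "response", "prior_lines", "tumor_stage", "gender"),
    constraints: cutoff_mod.SearchConstraints | None = None,
) -> dict:
    """Simulate, split, optimize, evaluate and transfer; return all artifacts."""
    constraints = constraints or cutoff_mod.SearchConstraints()
    durva_config = durva_config or CohortConfig(seed=seed)
    non_ict_config = replace(durva_config, seed=seed + 1, **NON_ICT_OVERRIDES)

    durva = add_measure_labels(generate_cohort(durva_config))
    non_ict = add_measure_labels(generate_cohort(non_ict_config))

    train, test = stratified_split(durva, train_fraction, balance_variables, seed=seed + 2)

    opt = cutoff_mod.CutoffOptimizer(
        score_col="signature_score",
        max_p_os=constraints.max_p_os,
        max_p_pfs=constraints.max_p_pfs,
        prevalence_min=constraints.prevalence_min,
        prevalence_max=constraints.prevalence_max,
        confidence=constraints.confidence,
    ).fit(train)
    cd8_opt = cutoff_mod.optimize_cutoff(train, train["cd8_density"].to_numpy(), constraints)
    pdl1_opt = cutoff_mod.optimize_cutoff(train, train["pdl1_density"].to_numpy(), constraints)

    learned = CutoffSpec(
        cd8_cutoff=cd8_opt.best.cutoff if cd8_opt.best else CutoffSpec().cd8_cutoff,
        pdl1_cutoff=pdl1_opt.best.cutoff if pdl1_opt.best else CutoffSpec().pdl1_cutoff,
        signature_cutoff=opt.cutoff_ if opt.feasible_ else CutoffSpec().signature_cutoff,
        pdl1_tc_cutoff=25.0,
    )

    tables = {
        name: performance_table(part, learned)
        for name, part in (("train", train), ("test", test), ("combined", durva))
    }
    cox_rows = cox_table(test, cutoffs=learned)

    matcher = PrevalenceMatcher().fit(
        (durva["signature_score"].to_numpy() >= learned.signature_cutoff).astype(int)
    )
    transfer_result = matcher.match(non_ict["signature_score"].to_numpy())

    return {
        "durva": durva,
        "non_ict": non_ict,
        "train": train,
        "test": test,
        "signature_search": opt.result_,
        "cd8_search": cd8_opt,
        "pdl1_search": pdl1_opt,
        "learned_cutoffs": learned,
        "tables": tables,
        "cox_table": cox_rows,
        "reference_prevalence": matcher.prevalence_,
        "transfer": transfer_result,
    }
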