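"""Survival stratification: Kaplan-Meier, log-rank and Cox regression.

Links per-sample diversity ("more"/"less") or expression ("high"/"low")
groups to event-free survival.  Estimation is delegated to lifelines
(Kaplan-Meier product-limit, multivariate log-rank, Cox partial likelihood
with Efron tie handling); this module provides the cohort-table plumbing,
median splits and result containers around it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "CoxResult",
    "km_curve",
    "logrank",
    "cox_fit",
    "median_split",
    "apply_horizon",
]


@dataclass(frozen=True)
class CoxResult:
    """One covariate's Cox regression estimate."""

    term: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.hazard_ratio <= self.ci_high):
            raise ValueError(
                f"CI [{self.ci_low}, {self.ci_high}] does not bracket "
                f"HR {self.hazard_ratio} for {self.term}"
            )


def _check_times(times: np.ndarray) -> None:
    if (times <= 0).any():
        raise ValueError("survival times must be positive")


def km_curve(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns a DataFrame with columns ``time``, ``at_risk``, ``survival``: the
    step function S(t), starting at S(0) = 1, evaluated at each distinct
    observed time.  S is non-increasing and constant between event times.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("need at least one record")
    _check_times(t)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    surv = kmf.survival_function_["KM_estimate"]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    return pd.DataFrame(
        {"time": surv.index.to_numpy(), "at_risk": at_risk.to_numpy(), "survival": surv.to_numpy()}
    )


def logrank(times, events, group_labels) -> tuple[float, float]:
    """Log-rank test across 2+ groups; chi-square statistic with k-1 df."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(group_labels)
    _check_times(t)
    if len(np.unique(g)) < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    clinical: pd.DataFrame,
    terms: list[str],
    time_col: str = "time_days",
    event_col: str = "event",
) -> list[CoxResult]:
    """Cox proportional-hazards fit on the selected covariates.

    One term gives a univariate fit, several a multivariable one.  Categorical
    covariates are one-hot encoded against their first (sorted) level; ties
    are handled by Efron's method (the lifelines default).  Constant
    covariates and missing values in selected columns are rejected.
    """
    cols = [time_col, event_col] + list(terms)
    missing = [c for c in cols if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    df = clinical[cols].copy()
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"missing values in columns: {bad}")
    _check_times(df[time_col].to_numpy(dtype=float))
    for term in terms:
        if df[term].nunique() < 2:
            raise ValueError(f"covariate {term!r} is constant")
    df = pd.get_dummies(df, columns=[t for t in terms if df[t].dtype == object],
                        drop_first=True, dtype=float)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=time_col, event_col=event_col)
    except Exception as exc:  # convergence/separation surfaced with the terms named
        raise RuntimeError(f"Cox fit failed for terms {terms}: {exc}") from exc
    summ = cph.summary
    return [
        CoxResult(
            term=str(idx),
            hazard_ratio=float(row["exp(coef)"]),
            ci_low=float(row["exp(coef) lower 95%"]),
            ci_high=float(row["exp(coef) upper 95%"]),
            p_value=float(row["p"]),
        )
        for idx, row in summ.iterrows()
    ]


def median_split(values, tie: str = "low") -> pd.Series:
    """Label samples "high"/"low" by their value relative to the median.

    Values above the median are "high"; at or below (the tie rule matching the
    diversity split) are "low".  All-equal input degenerates to all "low" with
    a warning.
    """
    vals = pd.Series(values, dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least 2 samples to split")
    med = vals.median()
    if tie == "low":
        labels = np.where(vals > med, "high", "low")
    elif tie == "high":
        labels = np.where(vals < med, "low", "high")
    else:
        raise ValueError(f"tie rule must be 'low' or 'high', got {tie!r}")
    if vals.nunique() == 1:
        warnings.warn("all values equal; the high/low split is degenerate", stacklevel=2)
    return pd.Series(labels, index=vals.index)


def apply_horizon(clinical: pd.DataFrame, horizon_days: float,
                  time_col: str = "time_days", event_col: str = "event") -> pd.DataFrame:
    """Administratively censor follow-up at a horizon (e.g. 5 years for
    5-year event-free survival): times are truncated and later events become
    censorings."""
    if horizon_days <= 0:
        raise ValueError("horizon must be positive")
    out = clinical.copy()
    late = out[time_col] > horizon_days
    out.loc[late, event_col] = 0
    out.loc[late, time_col] = horizon_days
    return out
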