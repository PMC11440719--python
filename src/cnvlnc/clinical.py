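"""Clinical association and survival statistics.

Patients are stratified into expression-low/high groups (median split by
default, median assigned to the low group), associations with categorical
clinicopathological variables use the Pearson chi-square test (no continuity
correction by default), overall survival is compared with the Kaplan-Meier
product-limit estimator and the log-rank test, and hazard ratios come from
Cox proportional-hazards regression (Breslow tie handling by default, Efron
behind a flag) with Wald 95% confidence intervals exp(beta +/- 1.96 SE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from statsmodels.duration.hazard_regression import PHReg

from .network import pearson_with_p

LOW = "low"
HIGH = "high"

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class ContingencyResult:
    table: np.ndarray
    chi2: float
    df: int
    p: float
    correction: bool = False


@dataclass
class SurvivalFit:
    """KM step functions per group plus the log-rank comparison (two groups)."""

    groups: dict[str, pd.DataFrame] = field(default_factory=dict)  # time, survival, at_risk
    logrank_chi2: float | None = None
    logrank_p: float | None = None

    def survival_at(self, group: str, t: float) -> float:
        tab = self.groups[group]
        past = tab[tab["time"] <= t]
        return float(past["survival"].iloc[-1]) if len(past) else 1.0


@dataclass
class CoxResult:
    summary: pd.DataFrame  # covariate, coef, HR, ci_low, ci_high, se, p
    loglik: float
    converged: bool
    ties: str = "breslow"


def dichotomize(values, rule: str = "median", cutoff: float | None = None) -> np.ndarray:
    """Split patients into 'low'/'high' expression groups.

    ``median`` (default): <= median -> low, > median -> high. ``quantile``
    uses ``cutoff`` as the quantile in (0, 1); ``fixed`` compares against an
    absolute cutoff. A constant vector cannot be split and raises.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 patients to dichotomize")
    if np.all(x == x[0]):
        raise ValueError("all values identical: no low/high split possible")
    if rule == "median":
        thr = float(np.median(x))
    elif rule == "quantile":
        if cutoff is None or not 0 < cutoff < 1:
            raise ValueError("quantile rule needs cutoff in (0, 1)")
        thr = float(np.quantile(x, cutoff))
    elif rule == "fixed":
        if cutoff is None:
            raise ValueError("fixed rule needs a cutoff value")
        thr = float(cutoff)
    else:
        raise ValueError(f"unknown dichotomization rule {rule!r}")
    return np.where(x <= thr, LOW, HIGH)


def chi2_assoc(table, correction: bool = False) -> ContingencyResult:
    """Pearson chi-square test of independence on an r x c count table."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2 x 2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero row or column margin")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=correction)
    return ContingencyResult(table=t.astype(int), chi2=float(chi2), df=int(df), p=float(p),
                             correction=correction)


def km_fit(
    groups: dict[str, pd.DataFrame],
    time_col: str = "time",
    event_col: str = "event",
) -> SurvivalFit:
    """Product-limit survival estimate per group, log-rank for two groups."""
    if not groups:
        raise ValueError("at least one group is required")
    fit = SurvivalFit()
    for label in sorted(groups):
        df = groups[label]
        if len(df) < 1:
            raise ValueError(f"group {label!r} is empty")
        times = np.asarray(df[time_col], dtype=float)
        events = np.asarray(df[event_col], dtype=int)
        if np.any(times < 0):
            raise ValueError(f"negative survival time in group {label!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times, event_observed=events)
        et = kmf.event_table
        surv = kmf.survival_function_["KM_estimate"]
        fit.groups[label] = pd.DataFrame(
            {
                "time": surv.index.to_numpy(dtype=float),
                "survival": surv.to_numpy(dtype=float),
                "at_risk": et["at_risk"].reindex(surv.index).to_numpy(dtype=float),
            }
        )
    if len(groups) == 2:
        (la, dfa), (lb, dfb) = sorted(groups.items())
        res = logrank_test(
            np.asarray(dfa[time_col], dtype=float),
            np.asarray(dfb[time_col], dtype=float),
            event_observed_A=np.asarray(dfa[event_col], dtype=int),
            event_observed_B=np.asarray(dfb[event_col], dtype=int),
        )
        fit.logrank_chi2 = float(res.test_statistic)
        fit.logrank_p = float(res.p_value)
    return fit


def cox_fit(
    df: pd.DataFrame,
    covariates: list[str],
    time_col: str = "time",
    event_col: str = "event",
    ties: str = "breslow",
) -> CoxResult:
    """Cox proportional-hazards fit via partial-likelihood maximization.

    Returns per-covariate hazard ratios with Wald 95% CIs and p-values. A fit
    with non-finite or exploding coefficients (monotone likelihood / perfect
    separation) is returned with ``converged=False`` rather than silently.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError(f"ties must be 'breslow' or 'efron', got {ties!r}")
    if not covariates:
        raise ValueError("at least one covariate is required")
    times = np.asarray(df[time_col], dtype=float)
    events = np.asarray(df[event_col], dtype=int)
    if np.any(times < 0):
        raise ValueError("negative survival time")
    if events.sum() < 1:
        raise ValueError("Cox regression requires >= 1 observed event")
    X = df[covariates].to_numpy(dtype=float)
    const = [c for c, col in zip(covariates, X.T) if np.all(col == col[0])]
    if const:
        raise ValueError(f"constant covariates cannot be fit: {const}")

    model = PHReg(times, X, status=events, ties=ties)
    res = model.fit(disp=False)
    coef = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    p = np.asarray(res.pvalues, dtype=float)
    converged = bool(np.all(np.isfinite(coef)) and np.all(np.isfinite(se)) and np.all(np.abs(coef) < 20))
    loglik = float(model.loglike(coef)) if np.all(np.isfinite(coef)) else float("nan")

    summary = pd.DataFrame(
        {
            "covariate": covariates,
            "coef": coef,
            "HR": np.exp(coef),
            "ci_low": np.exp(coef - Z_95 * se),
            "ci_high": np.exp(coef + Z_95 * se),
            "se": se,
            "p": p,
        }
    )
    return CoxResult(summary=summary, loglik=loglik, converged=converged, ties=ties)


def cox_univariate(
    df: pd.DataFrame,
    covariates: list[str],
    time_col: str = "time",
    event_col: str = "event",
    ties: str = "breslow",
) -> pd.DataFrame:
    """One single-covariate Cox fit per variable, concatenated (Table-2 style)."""
    rows = []
    for cov in covariates:
        res = cox_fit(df, [cov], time_col=time_col, event_col=event_col, ties=ties)
        row = res.summary.iloc[0].to_dict()
        row["converged"] = res.converged
        rows.append(row)
    return pd.DataFrame(rows)


def gene_pair_correlation(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p for two per-patient expression vectors."""
    return pearson_with_p(x, y)
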