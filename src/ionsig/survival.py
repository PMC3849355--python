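"""Survival analysis: Kaplan-Meier, log-rank, Cox proportional hazards.

The Cox partial likelihood is maximized by Newton-Raphson with either Efron
(default) or Breslow handling of tied event times; the two coincide exactly
when no event times are tied. Wald confidence intervals use z = 1.959964.
Kaplan-Meier estimation and the two-group log-rank test delegate to
lifelines.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .cohort import ExpressionCohort

logger = logging.getLogger("ionsig")

Z_95 = 1.959964


class SurvivalError(ValueError):
    pass


class ConvergenceError(SurvivalError):
    pass


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step function, S = 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.events,
            }
        )


@dataclass(frozen=True)
class CoxResult:
    """Fitted proportional-hazards model.

    ``summary`` has one row per covariate: coef, hr, se, ci_low, ci_high,
    p (Wald, two-sided).
    """

    summary: pd.DataFrame
    n_used: int
    n_events: int
    ties_method: str
    log_likelihood: float

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


def _check_times_events(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise SurvivalError("empty survival input")
    if t.shape != e.shape:
        raise SurvivalError("times and events must align")
    if np.any(t < 0):
        raise SurvivalError("negative survival time")
    if not np.isin(e, (0, 1)).all():
        raise SurvivalError("events must be 0 or 1")
    return t, e


def kaplan_meier(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan-Meier product-limit estimator; all-censored input gives S = 1."""
    t, e = _check_times_events(times, events)
    if e.sum() == 0:
        return KMCurve(
            event_times=np.array([]), survival=np.array([]),
            at_risk=np.array([], dtype=int), events=np.array([], dtype=int),
        )
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.event_table
    rows = table[table["observed"] > 0]
    event_times = rows.index.to_numpy(dtype=float)
    survival = kmf.survival_function_at_times(event_times).to_numpy(dtype=float)
    return KMCurve(
        event_times=event_times,
        survival=survival,
        at_risk=rows["at_risk"].to_numpy(dtype=int),
        events=rows["observed"].to_numpy(dtype=int),
    )


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> tuple[float, float, int]:
    """Two-group Mantel-Haenszel log-rank test; returns (chi2, p, df=1)."""
    ta, ea = _check_times_events(times_a, events_a)
    tb, eb = _check_times_events(times_b, events_b)
    if ea.sum() + eb.sum() == 0:
        raise SurvivalError("log-rank undefined with zero events")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value), 1


def _partial_lik_derivs(
    beta: np.ndarray, t: np.ndarray, e: np.ndarray, x: np.ndarray, ties: str
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log partial likelihood, gradient and Hessian.

    Risk sets are handled by processing samples sorted by descending time and
    accumulating sufficient statistics; for each distinct event time with d
    tied events, Breslow uses the full risk-set sum d times, while Efron
    subtracts the tied deaths' own contribution in fractions l/d.
    """
    order = np.argsort(-t, kind="stable")
    t, e, x = t[order], e[order], x[order]
    p = x.shape[1]
    eta = x @ beta
    w = np.exp(eta)
    wx = w[:, None] * x
    wxx = w[:, None, None] * (x[:, :, None] * x[:, None, :])

    loglik = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    s0, s1, s2 = 0.0, np.zeros(p), np.zeros((p, p))
    i, n = 0, len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:  # one distinct time block
            j += 1
        s0 += w[i:j].sum()
        s1 += wx[i:j].sum(axis=0)
        s2 += wxx[i:j].sum(axis=0)
        death = e[i:j] == 1
        d = int(death.sum())
        if d:
            xd = x[i:j][death]
            loglik += eta[i:j][death].sum()
            d0 = w[i:j][death].sum()
            d1 = wx[i:j][death].sum(axis=0)
            d2 = wxx[i:j][death].sum(axis=0)
            for l in range(d):
                frac = l / d if ties == "efron" else 0.0
                r0 = s0 - frac * d0
                r1 = s1 - frac * d1
                r2 = s2 - frac * d2
                loglik -= np.log(r0)
                grad -= r1 / r0
                hess -= r2 / r0 - np.outer(r1, r1) / r0**2
            grad += xd.sum(axis=0)
        i = j
    return loglik, grad, hess


def cox_fit(
    times: Sequence[float],
    events: Sequence[int],
    covariates: pd.DataFrame,
    ties: str = "efron",
    max_iter: int = 60,
    tol: float = 1e-8,
) -> CoxResult:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Iterates until the gradient norm falls below ``tol``. A coefficient
    drifting beyond |beta| > 25 is treated as a monotone likelihood
    (complete separation) and reported as an error naming the covariate.
    """
    if ties not in ("efron", "breslow"):
        raise SurvivalError(f"unknown ties method {ties!r}")
    t, e = _check_times_events(times, events)
    if e.sum() == 0:
        raise SurvivalError("Cox model needs at least one event")
    x = covariates.to_numpy(dtype=float)
    if x.ndim != 2 or x.shape[0] != t.size:
        raise SurvivalError("covariate matrix must be n_samples x n_covariates")
    names = list(covariates.columns)
    const = [nm for nm, col in zip(names, x.T) if np.ptp(col) == 0]
    if const:
        raise SurvivalError(f"constant covariate(s): {', '.join(const)}")

    beta = np.zeros(x.shape[1])
    loglik, grad, hess = _partial_lik_derivs(beta, t, e, x, ties)
    for _ in range(max_iter):
        if np.linalg.norm(grad) < tol:
            break
        step = np.linalg.solve(hess, grad)
        new_beta = beta - step
        new_ll, new_grad, new_hess = _partial_lik_derivs(new_beta, t, e, x, ties)
        # backtrack on genuine decreases only; the slack is relative to |loglik|
        # so float noise near the optimum cannot stall the iteration
        slack = 1e-10 * (1.0 + abs(loglik))
        halvings = 0
        while new_ll < loglik - slack and halvings < 30:
            step /= 2.0
            new_beta = beta - step
            new_ll, new_grad, new_hess = _partial_lik_derivs(new_beta, t, e, x, ties)
            halvings += 1
        beta, loglik, grad, hess = new_beta, new_ll, new_grad, new_hess
    else:
        if np.linalg.norm(grad) >= tol:
            raise ConvergenceError("Newton-Raphson did not converge")
    if np.any(np.abs(beta) > 15):
        worst = names[int(np.argmax(np.abs(beta)))]
        raise ConvergenceError(
            f"monotone partial likelihood (complete separation) for covariate {worst!r}"
        )

    se = np.sqrt(np.diag(np.linalg.inv(-hess)))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    summary = pd.DataFrame(
        {
            "coef": beta,
            "hr": np.exp(beta),
            "se": se,
            "ci_low": np.exp(beta - Z_95 * se),
            "ci_high": np.exp(beta + Z_95 * se),
            "p": p,
        },
        index=pd.Index(names, name="covariate"),
    )
    return CoxResult(
        summary=summary,
        n_used=int(t.size),
        n_events=int(e.sum()),
        ties_method=ties,
        log_likelihood=float(loglik),
    )


# Table-6-style contrasts: covariate -> (clinical column, coded-1 rule)
_ENCODERS: Mapping[str, tuple[str, object]] = {
    "ic30": (None, None),  # from the label vector
    "age": ("age_years", "continuous"),
    "node": ("node_status", "positive"),
    "size": ("size_class", "ge_T3"),
    "grade3": ("grade", 3),
    "er": ("er_status", "positive"),
    "pr": ("pr_status", "positive"),
    "p53": ("p53_status", "mutant"),
}

DEFAULT_COVARIATES = ("ic30", "age", "node", "size", "grade3", "er", "pr")


def encode_covariates(
    clinical: pd.DataFrame,
    labels: pd.Series,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Build the regression design matrix from clinical fields and labels.

    Binary contrasts are coded 1 for the first-named level (signature
    positive, node positive, size >= T3, grade 3, ER/PR positive, p53
    mutant); age enters continuously per year. Samples with any unknown
    requested covariate are dropped listwise, with the count logged.
    """
    cols = {}
    for cov in covariates:
        if cov not in _ENCODERS:
            raise SurvivalError(f"unknown covariate {cov!r}")
        if cov == "ic30":
            cols[cov] = (labels.reindex(clinical.index) == "positive").where(
                labels.reindex(clinical.index).notna()
            ).astype(float)
        else:
            field, rule = _ENCODERS[cov]
            col = clinical[field]
            if col.isna().all():
                raise SurvivalError(f"covariate {cov!r} entirely unknown")
            if rule == "continuous":
                cols[cov] = col.astype(float)
            else:
                cols[cov] = (col == rule).astype(float).where(col.notna())
    design = pd.DataFrame(cols, index=clinical.index)
    complete = design.dropna()
    dropped = len(design) - len(complete)
    if dropped:
        logger.info("listwise deletion removed %d sample(s) with unknown covariates",
                    dropped)
    if complete.empty:
        raise SurvivalError("no samples with complete covariates")
    return complete


# stratum label -> (clinical column, predicate)
DEFAULT_STRATA: Mapping[str, list[tuple[str, object]]] = {
    "age": [("age < 50", lambda c: c["age_years"] < 50),
            ("age >= 50", lambda c: c["age_years"] >= 50)],
    "node": [("node negative", lambda c: c["node_status"] == "negative"),
             ("node positive", lambda c: c["node_status"] == "positive")],
    "size": [("size < T3", lambda c: c["size_class"] == "lt_T3"),
             ("size >= T3", lambda c: c["size_class"] == "ge_T3")],
    "grade": [("grade 1-2", lambda c: c["grade"].isin([1, 2])),
              ("grade 3", lambda c: c["grade"] == 3)],
    "er": [("ER negative", lambda c: c["er_status"] == "negative"),
           ("ER positive", lambda c: c["er_status"] == "positive")],
    "pr": [("PR negative", lambda c: c["pr_status"] == "negative"),
           ("PR positive", lambda c: c["pr_status"] == "positive")],
}


def stratified_hazards(
    cohort: ExpressionCohort,
    labels: pd.Series,
    stratifiers: Mapping[str, list[tuple[str, object]]] = DEFAULT_STRATA,
) -> pd.DataFrame:
    """Univariate signature-status Cox fits within clinical subgroups.

    For each stratum of each stratifying factor, fits the signature indicator
    alone on the stratum's samples. Strata without events (or with the
    indicator constant) are skipped with a warning. Returns a long table:
    factor, stratum, n, events, hr, ci_low, ci_high, p.
    """
    clin = cohort.clinical
    rows = []
    for factor, strata in stratifiers.items():
        for name, predicate in strata:
            mask = predicate(clin).fillna(False)
            sub = clin[mask]
            if sub.empty or sub["event"].fillna(0).sum() == 0:
                logger.warning("stratum %r skipped: no samples or no events", name)
                continue
            design = encode_covariates(sub, labels, covariates=("ic30",))
            sub = sub.loc[design.index]
            ok = sub["time"].notna() & sub["event"].notna()
            try:
                fit = cox_fit(sub.loc[ok, "time"], sub.loc[ok, "event"],
                              design.loc[ok])
            except SurvivalError as exc:
                logger.warning("stratum %r skipped: %s", name, exc)
                continue
            s = fit.summary.loc["ic30"]
            rows.append(
                {
                    "factor": factor,
                    "stratum": name,
                    "n": fit.n_used,
                    "events": fit.n_events,
                    "hr": s["hr"],
                    "ci_low": s["ci_low"],
                    "ci_high": s["ci_high"],
                    "p": s["p"],
                }
            )
    return pd.DataFrame(rows)
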