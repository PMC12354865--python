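"""Survival analytics: Kaplan-Meier, log-rank, Cox PH, landmark analyses.

Kaplan-Meier estimation and the log-rank test delegate to lifelines; the Cox
proportional-hazards fit is a Newton-Raphson maximizer of the Breslow
partial likelihood implemented here, because the training loss uses Breslow
tie handling and the two should agree (Efron ties are available through the
``ties`` flag, which delegates to lifelines). Hazard-ratio confidence
intervals are Wald: exp(beta ± 1.96 SE).

Covariate encoding convention for clinical tables: binary covariates (sex,
ACT, MRD, MSI, pM) as 0/1, ordinal integers for pT/pN stage, age in years
continuous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .training import SurvivalLabel

__all__ = ["KMCurve", "CoxFit", "LandmarkSpec", "km_fit", "dfs_at", "logrank",
           "cox_fit", "landmark_filter", "labels_from_frame"]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


def labels_from_frame(df: pd.DataFrame) -> list[SurvivalLabel]:
    """Clinical table (patient_id, dfs_months, dfs_event) -> labels."""
    return [SurvivalLabel(str(r.patient_id), float(r.dfs_months), int(r.dfs_event))
            for r in df.itertuples(index=False)]


@dataclass
class KMCurve:
    event_times: np.ndarray     # distinct event times, sorted
    survival: np.ndarray        # S just after each event time
    at_risk: np.ndarray         # risk-set size at each event time
    n: int
    n_events: int
    max_observed: float         # largest follow-up time (event or censoring)

    def __post_init__(self):
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival function must be non-increasing")


@dataclass
class CoxFit:
    names: list
    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    n: int
    n_events: int
    converged: bool
    flags: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "covariate": self.names, "coef": self.coef, "se": self.se,
            "HR": self.hr, "ci95_low": self.ci_low, "ci95_high": self.ci_high,
            "p": self.p,
        })


@dataclass(frozen=True)
class LandmarkSpec:
    landmark_months: float

    def __post_init__(self):
        if self.landmark_months < 0 or not np.isfinite(self.landmark_months):
            raise ValueError("landmark_months must be finite and >= 0")


def km_fit(labels: list[SurvivalLabel]) -> KMCurve:
    """Product-limit estimator; subjects censored at an event time stay at risk."""
    if not labels:
        raise ValueError("km_fit needs at least one subject")
    times = np.array([l.time_months for l in labels])
    events = np.array([l.event for l in labels])
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    evt = np.unique(times[events == 1])
    if evt.size:
        surv = kmf.survival_function_at_times(evt).to_numpy()
        table = kmf.event_table
        at_risk = table.loc[evt, "at_risk"].to_numpy()
    else:
        surv = np.array([])
        at_risk = np.array([], dtype=int)
    return KMCurve(event_times=evt, survival=surv, at_risk=at_risk,
                   n=len(labels), n_events=int(events.sum()),
                   max_observed=float(times.max()))


def dfs_at(curve: KMCurve, t_months: float) -> tuple[float, bool]:
    """S(t) as a right-continuous step function; flags extrapolation beyond data."""
    extrapolated = t_months > curve.max_observed
    idx = np.searchsorted(curve.event_times, t_months, side="right") - 1
    value = 1.0 if idx < 0 else float(curve.survival[idx])
    return value, extrapolated


def logrank(groups: dict) -> tuple[float, float]:
    """Mantel-Cox test over 2+ labeled samples of SurvivalLabel lists.

    Returns (chi2, p) with k-1 degrees of freedom.
    """
    if len(groups) < 2:
        raise ValueError("log-rank needs at least two groups")
    for name, labels in groups.items():
        if len(labels) == 0:
            raise ValueError(f"group {name!r} is empty")
    times, events, grp = [], [], []
    for name, labels in groups.items():
        times += [l.time_months for l in labels]
        events += [l.event for l in labels]
        grp += [name] * len(labels)
    res = multivariate_logrank_test(np.array(times), np.array(grp), np.array(events))
    return float(res.test_statistic), float(res.p_value)


# -- Cox proportional hazards -------------------------------------------------

def _breslow_loglik(beta, times, events, x):
    """Breslow partial log-likelihood, score vector, information matrix."""
    order = np.argsort(-times, kind="stable")       # descending time
    t, e, xs = times[order], events[order], x[order]
    eta = xs @ beta
    w = np.exp(eta)
    # running sums over the risk set {j: t_j >= t_i} via descending prefix sums
    s0 = np.cumsum(w)
    s1 = np.cumsum(w[:, None] * xs, axis=0)
    s2 = np.cumsum(w[:, None, None] * (xs[:, :, None] * xs[:, None, :]), axis=0)
    # ties: all subjects with the same time share the full risk set
    last_of_time = np.r_[t[1:] != t[:-1], True]
    # idx_full[i] = last index sharing t_i (nearest marked index >= i), so the
    # risk set of subject i is 0..idx_full[i] in descending-time order
    idx_full = np.minimum.accumulate(
        np.where(last_of_time, np.arange(len(t)), len(t))[::-1])[::-1]
    ll, score, info = 0.0, np.zeros_like(beta), np.zeros((len(beta), len(beta)))
    ev = np.where(e == 1)[0]
    for i in ev:
        k = idx_full[i]
        ll += eta[i] - np.log(s0[k])
        xbar = s1[k] / s0[k]
        score += xs[i] - xbar
        info += s2[k] / s0[k] - np.outer(xbar, xbar)
    return ll, score, info


def cox_fit(labels: list[SurvivalLabel], covariates, names=None, *,
            ties: str = "breslow", max_iter: int = 100, tol: float = 1e-10) -> CoxFit:
    """Cox PH fit with Wald 95% CIs.

    ``covariates`` is (n, p); refuses when events < p or a covariate has no
    variation. Monotone-likelihood separation is reported via a flag with the
    coefficient capped. ``ties="efron"`` delegates to lifelines.
    """
    x = np.asarray(covariates, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, p = x.shape
    names = list(names) if names is not None else [f"x{i}" for i in range(p)]
    times = np.array([l.time_months for l in labels], dtype=float)
    events = np.array([l.event for l in labels], dtype=int)
    n_events = int(events.sum())
    if n_events < p:
        raise ValueError(f"{n_events} events cannot support {p} covariates")
    sds = x.std(axis=0)
    flat = [names[i] for i in range(p) if sds[i] == 0]
    if flat:
        raise ValueError(f"no variation in covariate(s) {flat}")

    if ties == "efron":
        from lifelines import CoxPHFitter
        df = pd.DataFrame(x, columns=names)
        df["T"], df["E"] = times, events
        cph = CoxPHFitter()
        cph.fit(df, duration_col="T", event_col="E")
        s = cph.summary
        return CoxFit(names=names, coef=s["coef"].to_numpy(),
                      se=s["se(coef)"].to_numpy(), hr=s["exp(coef)"].to_numpy(),
                      ci_low=np.exp(s["coef"].to_numpy() - Z95 * s["se(coef)"].to_numpy()),
                      ci_high=np.exp(s["coef"].to_numpy() + Z95 * s["se(coef)"].to_numpy()),
                      p=s["p"].to_numpy(), n=n, n_events=n_events, converged=True)
    if ties != "breslow":
        raise ValueError(f"unknown tie method {ties!r}")

    beta = np.zeros(p)
    converged, flags = False, []
    ll_old = -np.inf
    for _ in range(max_iter):
        ll, score, info = _breslow_loglik(beta, times, events, x)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            flags.append("singular information matrix")
            break
        # step-halving safeguard
        scale = 1.0
        for _h in range(30):
            cand = beta + scale * step
            ll_new = _breslow_loglik(cand, times, events, x)[0]
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        if np.max(np.abs(scale * step)) < tol or abs(ll_new - ll_old) < tol:
            converged = True
            break
        ll_old = ll_new
    if np.any(np.abs(beta) > 20):
        beta = np.clip(beta, -20, 20)
        flags.append("separation: monotone likelihood, coefficient capped")
        converged = False
    _, _, info = _breslow_loglik(beta, times, events, x)
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    zval = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2 * stats.norm.sf(np.abs(zval))
    ci_lo = np.exp(np.clip(beta - Z95 * se, -700, 700))
    ci_hi = np.exp(np.clip(beta + Z95 * se, -700, 700))
    return CoxFit(names=names, coef=beta, se=se, hr=np.exp(beta),
                  ci_low=ci_lo, ci_high=ci_hi,
                  p=pvals, n=n, n_events=n_events, converged=converged, flags=flags)


def landmark_filter(labels: list[SurvivalLabel], spec: LandmarkSpec) -> list[SurvivalLabel]:
    """Keep only patients still under observation at the landmark; re-origin times.

    Patients with any follow-up (event or censoring) before the landmark are
    dropped; remaining times become t - landmark.
    """
    kept = [SurvivalLabel(l.patient_id, l.time_months - spec.landmark_months, l.event)
            for l in labels if l.time_months >= spec.landmark_months
            and l.time_months - spec.landmark_months > 0]
    if not kept:
        raise ValueError("landmark excludes every patient")
    return kept
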