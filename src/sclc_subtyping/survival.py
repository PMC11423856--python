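"""Survival machinery and the subtype-stratified clinical analyses.

Implements the product-limit (Kaplan–Meier) estimator with Greenwood
variance, the multi-group log-rank (Mantel–Haenszel) test using the full
covariance matrix of the observed-minus-expected vector, and Cox proportional
hazards by Newton–Raphson maximisation of the partial likelihood with Efron
(default) or Breslow handling of tied event times.  On top of these sit the
clinical analyses of the subtyping study: chemotherapy benefit within TNM
II/III per subtype, immune-checkpoint-inhibitor progression-free survival by
subtype, and the immunohistochemistry H-score.

All times are in years as reals.  P values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "KaplanMeierCurve",
    "LogrankResult",
    "CoxResult",
    "km_estimate",
    "logrank_test",
    "cox_ph",
    "chemo_benefit_analysis",
    "ici_analysis",
    "ihc_score",
    "hazard_order",
    "subtype_names",
]


@dataclass
class KaplanMeierCurve:
    """Step-function survival estimate at the distinct event times."""

    times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): value of the step function at time t (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p_value: float


@dataclass
class CoxResult:
    """Per-covariate partial-likelihood estimates with Wald inference."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    hazard_ratio: np.ndarray
    ci95_low: np.ndarray
    ci95_high: np.ndarray
    wald_p: np.ndarray
    n_iterations: int
    log_likelihood: float
    separation_flag: bool = False

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "HR": self.hazard_ratio,
                "ci95_low": self.ci95_low,
                "ci95_high": self.ci95_high,
                "wald_p": self.wald_p,
            },
            index=self.names,
        )


def _check_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty survival input")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if (times < 0).any():
        raise ValueError("times must be non-negative")
    return times, events


def km_estimate(times, events) -> KaplanMeierCurve:
    """Product-limit estimator over the distinct event times.

    Subjects censored exactly at an event time remain in the risk set at that
    time.  Greenwood's formula gives the variance of S(t).
    """
    times, events = _check_surv(times, events)
    event_times = np.unique(times[events])
    surv = 1.0
    gw_sum = 0.0
    at_risk, n_events, survival, gvar = [], [], [], []
    for t in event_times:
        n_t = int((times >= t).sum())
        d_t = int(((times == t) & events).sum())
        surv *= 1.0 - d_t / n_t
        if n_t > d_t:
            gw_sum += d_t / (n_t * (n_t - d_t))
        else:
            gw_sum = np.inf
        at_risk.append(n_t)
        n_events.append(d_t)
        survival.append(surv)
        gvar.append(surv**2 * gw_sum if np.isfinite(gw_sum) else 0.0)
    return KaplanMeierCurve(
        times=event_times,
        at_risk=np.asarray(at_risk),
        events=np.asarray(n_events),
        survival=np.asarray(survival),
        greenwood_var=np.asarray(gvar),
    )


def logrank_test(times, events, groups) -> LogrankResult:
    """Multi-group Mantel–Haenszel log-rank test with full covariance.

    Accumulates observed minus expected events per group over the distinct
    event times; the chi-square statistic uses the (k-1)x(k-1) covariance
    matrix of the first k-1 groups, giving k-1 degrees of freedom.
    """
    times, events = _check_surv(times, events)
    groups = np.asarray(groups)
    levels, gidx = np.unique(groups, return_inverse=True)
    k = len(levels)
    if k < 2:
        raise ValueError("log-rank test needs at least 2 non-empty groups")
    O_minus_E = np.zeros(k)
    V = np.zeros((k, k))
    for t in np.unique(times[events]):
        at_risk = times >= t
        n_t = int(at_risk.sum())
        d_t = int(((times == t) & events).sum())
        n_g = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_g = np.bincount(gidx[(times == t) & events], minlength=k).astype(float)
        frac = n_g / n_t
        O_minus_E += d_g - d_t * frac
        if n_t > 1:
            scale = d_t * (n_t - d_t) / (n_t - 1)
            V += scale * (np.diag(frac) - np.outer(frac, frac))
    v = V[: k - 1, : k - 1]
    u = O_minus_E[: k - 1]
    stat = float(u @ np.linalg.pinv(v) @ u) if v.size else 0.0
    df = k - 1
    return LogrankResult(statistic=stat, df=df, p_value=float(sps.chi2.sf(stat, df)))


def _cox_loglik(beta, times, events, X, ties):
    """Log partial likelihood with gradient and Hessian (Efron or Breslow)."""
    n, p = X.shape
    eta = X @ beta
    # numerical guard against overflow in exp
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    order = np.argsort(-times, kind="stable")  # decreasing time
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    # cumulative sums over the risk set, built from largest time downward
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    while i < n:
        t = times[order[i]]
        # add everyone with this exact time to the risk set
        tied = []
        while i < n and times[order[i]] == t:
            idx = order[i]
            s0 += w[idx]
            s1 += w[idx] * X[idx]
            s2 += w[idx] * np.outer(X[idx], X[idx])
            if events[idx]:
                tied.append(idx)
            i += 1
        d = len(tied)
        if d == 0:
            continue
        xsum = X[tied].sum(axis=0)
        ll += eta[tied].sum()
        if ties == "breslow":
            for _ in range(d):
                ll -= np.log(s0)
                grad_term = s1 / s0
                grad -= grad_term
                hess -= s2 / s0 - np.outer(grad_term, grad_term)
            grad += xsum
        else:  # efron
            wd = w[tied].sum()
            wd1 = (w[tied, None] * X[tied]).sum(axis=0)
            wd2 = (w[tied, None, None] * X[tied][:, :, None] * X[tied][:, None, :]).sum(
                axis=0
            )
            for l in range(d):
                f = l / d
                z0 = s0 - f * wd
                z1 = s1 - f * wd1
                z2 = s2 - f * wd2
                ll -= np.log(z0)
                g = z1 / z0
                grad -= g
                hess -= z2 / z0 - np.outer(g, g)
            grad += xsum
    return ll, grad, hess


def cox_ph(
    times,
    events,
    covariates: pd.DataFrame | np.ndarray,
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxResult:
    """Cox proportional hazards fit by Newton–Raphson with step halving.

    Returns per-covariate coefficient, standard error from the inverse
    observed information, HR = exp(coef), 95% CI = exp(coef +/- 1.96 se) and
    two-sided Wald p.  Raises on non-convergence; near-separation (runaway
    coefficients) sets ``separation_flag``.
    """
    times, events = _check_surv(times, events)
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[0] != times.size:
            X = X.T
        names = [f"x{i}" for i in range(X.shape[1])]
    if X.ndim != 2 or X.shape[0] != times.size:
        raise ValueError("covariate matrix must be n_subjects x n_covariates")
    if events.sum() < 1:
        raise ValueError("need at least one event")
    const = np.ptp(X, axis=0) == 0
    if const.any():
        raise ValueError(f"constant covariate(s): {[names[i] for i in np.flatnonzero(const)]}")

    beta = np.zeros(X.shape[1])
    ll, grad, hess = _cox_loglik(beta, times, events, X, ties)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.pinv(hess) @ grad
        new_beta = beta - step
        new_ll, new_grad, new_hess = _cox_loglik(new_beta, times, events, X, ties)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 20:
            step /= 2.0
            new_beta = beta - step
            new_ll, new_grad, new_hess = _cox_loglik(new_beta, times, events, X, ties)
            halvings += 1
        delta = abs(new_ll - ll)
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"Cox fit did not converge in {max_iter} iterations (|dll|={delta:.3g})"
        )
    info = -hess
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    with np.errstate(over="ignore"):  # CI bounds may overflow under separation
        return CoxResult(
            names=names,
            coef=beta,
            se=se,
            hazard_ratio=np.exp(beta),
            ci95_low=np.exp(beta - 1.959963984540054 * se),
            ci95_high=np.exp(beta + 1.959963984540054 * se),
            wald_p=2 * sps.norm.sf(np.abs(z)),
            n_iterations=n_iter,
            log_likelihood=float(ll),
            separation_flag=bool((np.abs(beta) > 15).any()),
        )


# ---------------------------------------------------------------------------
# Clinical analyses


def chemo_benefit_analysis(
    clinical: pd.DataFrame, labels: np.ndarray | pd.Series
) -> pd.DataFrame:
    """Per-subtype chemo-vs-no-chemo log-rank restricted to TNM II/III.

    TNM I and IV patients are excluded because stage itself dominates their
    prognosis.  Subtypes in which one arm is empty are reported as
    not-evaluable (NaN p value, evaluable=False).
    """
    labels = np.asarray(labels)
    if len(labels) != len(clinical):
        raise ValueError("labels must align with clinical rows")
    mask = clinical["tnm_stage"].isin(["II", "III"]).to_numpy()
    rows = []
    for subtype in np.unique(labels):
        sel = mask & (labels == subtype)
        sub = clinical.loc[sel]
        chemo = sub["chemotherapy"].to_numpy(dtype=bool)
        n_chemo, n_none = int(chemo.sum()), int((~chemo).sum())
        if n_chemo == 0 or n_none == 0:
            rows.append((subtype, n_chemo, n_none, np.nan, False))
            continue
        res = logrank_test(
            sub["os_years"].to_numpy(), sub["os_event"].to_numpy(dtype=bool), chemo
        )
        rows.append((subtype, n_chemo, n_none, res.p_value, True))
    return pd.DataFrame(
        rows, columns=["subtype", "n_chemo", "n_no_chemo", "logrank_p", "evaluable"]
    ).set_index("subtype")


def ici_analysis(
    clinical: pd.DataFrame, labels: np.ndarray | pd.Series
) -> pd.DataFrame:
    """Pairwise PFS log-rank between subtypes among first-line ICI patients.

    ICI-PFS runs from the first immunotherapy dose to progressive disease.
    Only samples with ``ici_line == "first"`` enter; an ICI-treated sample
    lacking PFS data is a validation error.
    """
    labels = np.asarray(labels)
    if len(labels) != len(clinical):
        raise ValueError("labels must align with clinical rows")
    on_ici = clinical["ici_line"].isin(["first", "later"]).to_numpy()
    if clinical.loc[on_ici, "pfs_years"].isna().any():
        bad = clinical.loc[on_ici & clinical["pfs_years"].isna(), "sample_id"]
        raise ValueError(f"ICI-treated sample(s) missing PFS: {list(bad)[:5]}")
    first = (clinical["ici_line"] == "first").to_numpy()
    rows = []
    subtypes = np.unique(labels)
    for i, a in enumerate(subtypes):
        for b in subtypes[i + 1 :]:
            sel = first & np.isin(labels, [a, b])
            sub = clinical.loc[sel]
            if (labels[sel] == a).sum() == 0 or (labels[sel] == b).sum() == 0:
                rows.append((a, b, int(sel.sum()), np.nan))
                continue
            res = logrank_test(
                sub["pfs_years"].to_numpy(),
                sub["pfs_event"].to_numpy(dtype=float).astype(bool),
                labels[sel],
            )
            rows.append((a, b, int(sel.sum()), res.p_value))
    return pd.DataFrame(rows, columns=["subtype_a", "subtype_b", "n", "logrank_p"])


_IHC_BINS = ((10.0, "0"), (41.0, "1+"), (141.0, "2+"), (301.0, "3+"))


def ihc_score(intensity: int, percent_positive: float) -> tuple[float, str, bool]:
    """Immunohistochemistry H-score: intensity (1-3) x percent positive cells.

    Scores range 0-300 and are binned <10 -> 0, 10-40 -> 1+, 41-140 -> 2+,
    141-300 -> 3+; a sample is called positive iff its score exceeds 10 (a
    score of exactly 10 is bin 1+ but negative — the scoring rubric's own
    boundary convention, kept literally).
    """
    if intensity not in (1, 2, 3):
        raise ValueError(f"staining intensity must be 1, 2 or 3, got {intensity!r}")
    if not 0 <= percent_positive <= 100:
        raise ValueError(f"percent positive must lie in [0, 100], got {percent_positive!r}")
    score = float(intensity * percent_positive)
    for upper, label in _IHC_BINS:
        if score < upper:
            return score, label, score > 10
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Subtype naming by prognosis


_ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")


def hazard_order(times, events, labels) -> list:
    """Cluster labels ordered by ascending crude event hazard (events/person-time)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    labels = np.asarray(labels)
    rates = {}
    for lab in np.unique(labels):
        sel = labels == lab
        persontime = times[sel].sum()
        rates[lab] = events[sel].sum() / persontime if persontime > 0 else np.inf
    return sorted(rates, key=lambda lab: (rates[lab], str(lab)))


def subtype_names(times, events, labels) -> dict:
    """Map each raw cluster label to "S-I", "S-II", ... by ascending hazard.

    "S-I" is the best-prognosis cluster; the ordering makes subtype names
    reproducible across runs and cohorts.
    """
    order = hazard_order(times, events, labels)
    return {lab: f"S-{_ROMAN[i]}" for i, lab in enumerate(order)}
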