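"""Survival machinery: Kaplan-Meier, log-rank, Cox hazard ratio, Harrell's C.

These are implemented directly (product-limit estimator; two-group log-rank
with the hypergeometric variance; Newton iteration on the Breslow partial
likelihood for the univariate Cox hazard ratio; pairwise Harrell
concordance) so the tie-handling and censoring conventions are exactly the
ones documented here:

* censored subjects at time t remain in the risk set at t;
* Breslow tie handling in the Cox partial likelihood;
* two-sided p-values; the two-group log-rank statistic is chi-squared with
  one degree of freedom;
* a dataset with no events yields log-rank p = 1 by convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SurvivalRecord
from .exceptions import UndefinedConcordanceError


def _to_arrays(records: Sequence[SurvivalRecord] | pd.DataFrame
               ) -> tuple[np.ndarray, np.ndarray]:
    """(times, events) from records or a DataFrame with time_days/event."""
    if isinstance(records, pd.DataFrame):
        return (records["time_days"].to_numpy(float),
                records["event"].to_numpy(int))
    times = np.array([r.time_days for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    return times, events


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    survival_prob: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t); right-continuous step function with S(0) = 1."""
        s = 1.0
        for et, sp in zip(self.event_times, self.survival_prob):
            if et <= t:
                s = sp
            else:
                break
        return s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.event_times,
            "survival": self.survival_prob,
            "n_at_risk": self.at_risk,
        })


def kaplan_meier(records) -> KMCurve:
    times, events = _to_arrays(records)
    if times.size == 0:
        raise ValueError("no records")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]

    uniq = np.unique(times[events == 1])
    s = 1.0
    probs, risks = [], []
    n = times.size
    for t in uniq:
        n_at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d / n_at_risk
        probs.append(s)
        risks.append(n_at_risk)
    return KMCurve(event_times=uniq, survival_prob=np.asarray(probs),
                   at_risk=np.asarray(risks, dtype=int))


# ---------------------------------------------------------------------------
# log-rank test
# ---------------------------------------------------------------------------

def logrank_test(records, group_labels: Sequence) -> tuple[float, float]:
    """Two-group log-rank test: (chi2, p) with 1 df.

    Returns p = 1 when there are no events at all.
    """
    times, events = _to_arrays(records)
    labels = np.asarray(group_labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError(f"need exactly 2 groups, got {groups.size}")
    in1 = labels == groups[0]
    if in1.all() or (~in1).all():
        raise ValueError("one group is empty")
    if events.sum() == 0:
        return 0.0, 1.0

    obs_minus_exp = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & in1).sum())
        obs_minus_exp += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0, 1.0
    chi2 = obs_minus_exp**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), max(p, np.finfo(float).tiny)


# ---------------------------------------------------------------------------
# Cox hazard ratio (univariate, binary group)
# ---------------------------------------------------------------------------

def _breslow_neg_loglik_and_derivs(beta: float, times, events, x
                                   ) -> tuple[float, float, float]:
    """Breslow partial log-likelihood, gradient and Hessian for scalar beta."""
    order = np.argsort(-times, kind="stable")  # decreasing time
    t_s, e_s, x_s = times[order], events[order], x[order]
    loglik = grad = hess = 0.0
    s0 = s1 = s2 = 0.0  # running risk-set sums of exp(bx), x exp(bx), x^2 exp(bx)
    i = 0
    n = len(t_s)
    while i < n:
        t = t_s[i]
        while i < n and t_s[i] == t:
            w = math.exp(beta * x_s[i])
            s0 += w
            s1 += x_s[i] * w
            s2 += x_s[i] * x_s[i] * w
            i += 1
        idx = (t_s == t) & (e_s == 1)
        d = int(idx.sum())
        if d:
            xs = x_s[idx].sum()
            loglik += beta * xs - d * math.log(s0)
            grad += xs - d * s1 / s0
            hess -= d * (s2 / s0 - (s1 / s0) ** 2)
    return loglik, grad, hess


def cox_hazard_ratio(records, group_labels: Sequence,
                     max_iter: int = 50, tol: float = 1e-10,
                     beta_cap: float = 15.0) -> tuple[float, tuple[float, float]]:
    """Hazard ratio of group2 vs group1 with a Wald 95% CI.

    Newton iteration on the Breslow partial likelihood of the binary group
    indicator. Complete separation (the likelihood is monotone in beta) is
    reported by capping |beta| at ``beta_cap`` and returning the capped HR;
    the CI is then degenerate and should be treated as a divergence flag.
    """
    times, events = _to_arrays(records)
    labels = np.asarray(group_labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("need exactly 2 groups")
    x = (labels == groups[1]).astype(float)
    if events.sum() == 0:
        raise ValueError("no events: hazard ratio undefined")

    beta = 0.0
    for _ in range(max_iter):
        _, grad, hess = _breslow_neg_loglik_and_derivs(beta, times, events, x)
        if hess >= -1e-14:  # flat likelihood (e.g. separation)
            break
        step = -grad / hess
        beta_new = float(np.clip(beta + step, -beta_cap, beta_cap))
        if abs(beta_new - beta) < tol:
            beta = beta_new
            break
        beta = beta_new

    _, _, hess = _breslow_neg_loglik_and_derivs(beta, times, events, x)
    se = math.sqrt(-1.0 / hess) if hess < -1e-14 else float("inf")
    safe_exp = lambda z: float(np.exp(np.clip(z, -700.0, 700.0)))
    hr = safe_exp(beta)
    ci = (safe_exp(beta - 1.96 * se) if math.isfinite(se) else 0.0,
          safe_exp(beta + 1.96 * se) if math.isfinite(se) else float("inf"))
    return hr, ci


# ---------------------------------------------------------------------------
# Harrell's concordance index
# ---------------------------------------------------------------------------

def concordance_index(risk_scores: Sequence[float], records) -> float:
    """Harrell's C over permissible pairs.

    A pair is permissible when the shorter observed time belongs to a
    subject whose event was observed. Higher risk score predicts shorter
    survival; tied scores credit 1/2. Raises
    :class:`UndefinedConcordanceError` when no pair is permissible.
    """
    times, events = _to_arrays(records)
    scores = np.asarray(risk_scores, dtype=float)
    if scores.shape != times.shape:
        raise ValueError("scores and records are misaligned")

    num = den = 0.0
    n = len(times)
    for i in range(n):
        if events[i] != 1:
            continue
        for j in range(n):
            if j == i:
                continue
            # i is the (observed) earlier failure in a permissible pair
            if times[i] < times[j] or (times[i] == times[j] and events[j] == 0):
                den += 1.0
                if scores[i] > scores[j]:
                    num += 1.0
                elif scores[i] == scores[j]:
                    num += 0.5
    if den == 0:
        raise UndefinedConcordanceError("no permissible pairs")
    return num / den


# ---------------------------------------------------------------------------
# covariate comparison
# ---------------------------------------------------------------------------

def compare_covariate(values: Sequence[float], group_labels: Sequence) -> float:
    """Two-sided Welch t-test p-value between the two groups."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("need exactly 2 groups")
    a = values[labels == groups[0]]
    b = values[labels == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    if np.isnan(p):  # identical constant groups: no evidence of difference
        return 1.0
    return float(p)


# ---------------------------------------------------------------------------
# bundled two-group comparison
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    """All §-style metrics for one low/high risk-group comparison."""

    logrank_chi2: float
    p_value: float
    hazard_ratio: float
    hr_ci95: tuple[float, float]
    c_index: float
    n_low: int
    n_high: int


def compare_groups(records, group_labels: Sequence,
                   risk_scores: Sequence[float] | None = None) -> GroupComparison:
    """Log-rank + Cox HR for the binary grouping; C-index of the continuous
    risk scores (or of the group indicator when no scores are given)."""
    labels = np.asarray(group_labels)
    chi2, p = logrank_test(records, labels)
    hr, ci = cox_hazard_ratio(records, labels)
    groups = np.unique(labels)
    if risk_scores is None:
        risk_scores = (labels == groups[1]).astype(float)
    c = concordance_index(risk_scores, records)
    return GroupComparison(
        logrank_chi2=chi2, p_value=p, hazard_ratio=hr, hr_ci95=ci, c_index=c,
        n_low=int((labels == groups[0]).sum()), n_high=int((labels == groups[1]).sum()),
    )


__all__ = [
    "KMCurve",
    "GroupComparison",
    "kaplan_meier",
    "logrank_test",
    "cox_hazard_ratio",
    "concordance_index",
    "compare_covariate",
    "compare_groups",
]
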