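"""Survival analysis for TACS-3 group comparisons.

Right-censored time-to-event tables (columns ``time`` in months, ``event``
1/0, ``group`` 0/1 with 1 = TACS-3 positive; endpoint tag DSS or DFS) are
summarized by the Kaplan-Meier product-limit estimator, compared by the
two-sample log-rank test, and modeled by univariate Cox proportional-
hazards regression (Newton iterations on the partial likelihood, Breslow
tie handling, Wald inference).  Both the log-rank statistic and the Cox
estimate depend on time ranks only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("time", "event")


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"survival table missing column {col!r}")
    if len(table) < 1:
        raise ValueError("survival table must have >= 1 subject")
    t = table["time"].to_numpy(dtype=float)
    e = table["event"].to_numpy()
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise ValueError("times must be positive and finite")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event flags must be 0 or 1")
    return table


def kaplan_meier(table: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate of the survival function.

    Returns one row per distinct observed time with columns ``time``,
    ``at_risk``, ``events``, ``censored`` and the step value ``S``
    (nonincreasing, S(0) = 1; censoring marks retained).  With no
    censoring, S equals the complement of the ECDF at every event time.
    """
    _validate(table)
    t = table["time"].to_numpy(dtype=float)
    e = table["event"].to_numpy(dtype=int)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    times, idx = np.unique(t, return_index=True)
    n = t.size
    rows = []
    s = 1.0
    for j, tj in enumerate(times):
        at_risk = n - idx[j]
        sel = t == tj
        d = int(e[sel].sum())
        c = int(np.count_nonzero(sel) - d)
        if d > 0:
            s *= 1.0 - d / at_risk
        rows.append((tj, at_risk, d, c, s))
    return pd.DataFrame(rows, columns=["time", "at_risk", "events", "censored", "S"])


def logrank_test(table_a: pd.DataFrame, table_b: pd.DataFrame) -> tuple[float, float]:
    """Two-sample log-rank test; returns (chi-square statistic, p-value).

    Standard observed-vs-expected accumulation over the pooled distinct
    event times with hypergeometric variance; 1 degree of freedom.
    """
    _validate(table_a)
    _validate(table_b)
    ta = table_a["time"].to_numpy(dtype=float)
    ea = table_a["event"].to_numpy(dtype=int)
    tb = table_b["time"].to_numpy(dtype=float)
    eb = table_b["event"].to_numpy(dtype=int)
    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for tj in event_times:
        n1 = int(np.count_nonzero(ta >= tj))
        n2 = int(np.count_nonzero(tb >= tj))
        d1 = int(np.count_nonzero((ta == tj) & (ea == 1)))
        d2 = int(np.count_nonzero((tb == tj) & (eb == 1)))
        n = n1 + n2
        d = d1 + d2
        if n < 2 or d == 0:
            continue
        o_minus_e += d1 - d * n1 / n
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass
class CoxResult:
    """Univariate Cox fit: log-hazard beta, HR, Wald 95% CI and p."""

    beta: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_events: int
    converged: bool
    flagged: str | None = None


def cox_partial_loglik(
    beta: float, time: np.ndarray, event: np.ndarray, x: np.ndarray
) -> float:
    """Breslow partial log-likelihood at ``beta`` (1-d covariate)."""
    ll = 0.0
    for tj in np.unique(time[event == 1]):
        at_risk = time >= tj
        dead = (time == tj) & (event == 1)
        ll += beta * x[dead].sum() - dead.sum() * np.log(
            np.sum(np.exp(beta * x[at_risk]))
        )
    return float(ll)


def cox_univariate(
    table: pd.DataFrame,
    covariate: str = "group",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxResult:
    """Univariate Cox proportional-hazards regression.

    Maximizes the Breslow partial likelihood by Newton iterations
    (tolerance 1e-8, at most 50 iterations).  Tables with no events, or
    with a monotone likelihood (complete separation), are flagged and
    return no estimate (NaN fields).
    """
    _validate(table)
    if covariate not in table.columns:
        raise ValueError(f"missing covariate column {covariate!r}")
    time = table["time"].to_numpy(dtype=float)
    event = table["event"].to_numpy(dtype=int)
    x = table[covariate].to_numpy(dtype=float)
    n, n_events = time.size, int(event.sum())

    def _flagged(reason: str) -> CoxResult:
        nan = float("nan")
        return CoxResult(nan, nan, nan, nan, nan, nan, n, n_events, False, reason)

    if n_events == 0:
        return _flagged("no events")
    if np.ptp(x) == 0:
        return _flagged("constant covariate")

    # sort by time; risk-set sums become suffix cumulative sums
    order = np.argsort(time, kind="stable")
    t_s, e_s, x_s = time[order], event[order], x[order]
    event_times = np.unique(t_s[e_s == 1])
    first_at_risk = np.searchsorted(t_s, event_times, side="left")
    d_j = np.array(
        [np.sum((t_s == tj) & (e_s == 1)) for tj in event_times], dtype=float
    )
    s_j = np.array([x_s[(t_s == tj) & (e_s == 1)].sum() for tj in event_times])

    def _suffix(v: np.ndarray) -> np.ndarray:
        return np.cumsum(v[::-1])[::-1]

    beta = 0.0
    converged = False
    for _ in range(max_iter):
        w = np.exp(beta * x_s)
        sw = _suffix(w)[first_at_risk]
        swx = _suffix(w * x_s)[first_at_risk]
        swx2 = _suffix(w * x_s * x_s)[first_at_risk]
        xbar = swx / sw
        grad = float(np.sum(s_j - d_j * xbar))
        hess = float(-np.sum(d_j * (swx2 / sw - xbar * xbar)))
        if hess >= -1e-12:
            return _flagged("monotone likelihood (complete separation)")
        step = -grad / hess
        beta += step
        if abs(beta) > 50:
            return _flagged("monotone likelihood (complete separation)")
        if abs(step) < tol:
            converged = True
            break
    se = float(np.sqrt(-1.0 / hess))
    z = beta / se
    zcrit = stats.norm.ppf(0.975)
    return CoxResult(
        beta=float(beta),
        se=se,
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - zcrit * se)),
        ci_high=float(np.exp(beta + zcrit * se)),
        p=float(2 * stats.norm.sf(abs(z))),
        n=n,
        n_events=n_events,
        converged=converged,
    )
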