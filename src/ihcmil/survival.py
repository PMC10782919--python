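"""Survival statistics for PFS stratification by predicted PD-L1 status.

Implements the three classical right-censored survival tools used in the
analysis — the Kaplan–Meier product-limit estimator (with median and IQR
crossing times), the two-group log-rank test, and a Cox proportional-hazards
fit for a single covariate — directly from their defining formulas.  The Cox
partial likelihood is maximized by Newton–Raphson with Efron's correction for
tied event times (Breslow available).

Conventions: times are in months and must be positive; ``event == 1`` marks
progression, ``event == 0`` right-censoring at ``time``; at tied times events
are counted before censorings (the standard KM convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "LogRankResult",
    "CoxResult",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "auc_ci_delong",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up: PFS time (months), event flag and group label."""

    patient_id: str
    time: float
    event: int
    group: int

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"time must be > 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


def _as_arrays(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("times and events must be 1-d and of equal length")
    if np.any(t <= 0):
        raise ValueError("all times must be > 0")
    return t, e


def _records_to_arrays(records):
    if len(records) == 0:
        raise ValueError("need at least one record")
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=int)
    return t, e


@dataclass
class KMCurve:
    """Kaplan–Meier product-limit estimate, right-continuous step function."""

    times: np.ndarray          # distinct event times, ascending
    at_risk: np.ndarray        # n_i at risk just before each event time
    n_events: np.ndarray       # d_i events at each time
    survival: np.ndarray       # S(t_i) after the drop at t_i
    ci_lower: np.ndarray       # log-log (exponential Greenwood) 95% band
    ci_upper: np.ndarray
    median: float = np.nan     # nan == not reached
    q25: float = np.nan        # first crossing of S <= 0.75 (IQR lower)
    q75: float = np.nan        # first crossing of S <= 0.25 (IQR upper)
    median_ci: tuple = (np.nan, np.nan)

    def survival_at(self, t) -> np.ndarray:
        """S(t) for arbitrary times (right-continuous)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.times.size == 0:
            return np.ones_like(t)
        idx = np.searchsorted(self.times, t, side="right") - 1
        return np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])

    def quantile_time(self, q: float) -> float:
        """Smallest event time t with S(t) <= q; nan if never reached."""
        below = np.nonzero(self.survival <= q + 1e-12)[0]
        return float(self.times[below[0]]) if below.size else np.nan


def km_estimate(records=None, *, times=None, events=None, alpha=0.05) -> KMCurve:
    """Product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    Accepts either a list of :class:`SurvivalRecord` or ``times=``/``events=``
    arrays.  The median is the smallest event time with S <= 0.5; the IQR is
    reported as the 0.75 and 0.25 crossing times, matching how median PFS with
    IQR is conventionally displayed.  The 95% CI of the median is read off the
    crossing of the log-log Greenwood confidence band with 0.5.
    """
    if records is not None:
        t, e = _records_to_arrays(records)
    else:
        t, e = _as_arrays(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]

    event_times = np.unique(t[e == 1])
    n = t.size
    surv = []
    at_risk = []
    d_list = []
    var_sum = 0.0
    greenwood = []
    s = 1.0
    for et in event_times:
        n_i = int(np.sum(t >= et))
        d_i = int(np.sum((t == et) & (e == 1)))
        s *= 1.0 - d_i / n_i
        if n_i > d_i:
            var_sum += d_i / (n_i * (n_i - d_i))
        else:
            var_sum = np.inf
        surv.append(s)
        at_risk.append(n_i)
        d_list.append(d_i)
        greenwood.append(var_sum)

    surv = np.asarray(surv)
    greenwood = np.asarray(greenwood)
    z = stats.norm.ppf(1 - alpha / 2)
    lo = np.full_like(surv, np.nan)
    hi = np.full_like(surv, np.nan)
    ok = (surv > 0) & (surv < 1) & np.isfinite(greenwood)
    with np.errstate(divide="ignore", invalid="ignore"):
        se_ll = np.sqrt(greenwood[ok]) / np.abs(np.log(surv[ok]))
        lo[ok] = surv[ok] ** np.exp(z * se_ll)
        hi[ok] = surv[ok] ** np.exp(-z * se_ll)
    lo[surv == 0] = 0.0
    hi[surv == 0] = 0.0

    curve = KMCurve(
        times=event_times,
        at_risk=np.asarray(at_risk),
        n_events=np.asarray(d_list),
        survival=surv,
        ci_lower=lo,
        ci_upper=hi,
    )
    curve.median = curve.quantile_time(0.5)
    curve.q25 = curve.quantile_time(0.75)
    curve.q75 = curve.quantile_time(0.25)
    # Median CI: first crossings of the confidence band with 0.5.
    lo_cross = np.nonzero(np.nan_to_num(lo, nan=1.0) <= 0.5)[0]
    hi_cross = np.nonzero(np.nan_to_num(hi, nan=1.0) <= 0.5)[0]
    curve.median_ci = (
        float(event_times[lo_cross[0]]) if lo_cross.size else np.nan,
        float(event_times[hi_cross[0]]) if hi_cross.size else np.nan,
    )
    return curve


@dataclass
class LogRankResult:
    statistic: float           # chi-square, 1 df
    p_value: float
    observed: np.ndarray       # per-group observed events [O_a, O_b]
    expected: np.ndarray       # per-group expected events [E_a, E_b]


def logrank_test(records_a=None, records_b=None, *, times_a=None, events_a=None,
                 times_b=None, events_b=None) -> LogRankResult:
    """Two-group log-rank test.

    At each distinct event time t with d events among n at risk (n_a from
    group a), the contribution is O_a - E_a with E_a = n_a d / n and
    hypergeometric variance d (n_a/n)(n_b/n)(n-d)/(n-1).
    """
    if records_a is not None:
        ta, ea = _records_to_arrays(records_a)
        tb, eb = _records_to_arrays(records_b)
    else:
        ta, ea = _as_arrays(times_a, events_a)
        tb, eb = _as_arrays(times_b, events_b)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")

    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.zeros(ta.size, int), np.ones(tb.size, int)])
    if not np.any(e == 1):
        raise ValueError("no events")

    event_times = np.unique(t[e == 1])
    O_a = E_a = V = 0.0
    d_total = 0.0
    for et in event_times:
        at_risk = t >= et
        n = at_risk.sum()
        n_a = np.sum(at_risk & (g == 0))
        d = np.sum((t == et) & (e == 1))
        d_a = np.sum((t == et) & (e == 1) & (g == 0))
        O_a += d_a
        E_a += n_a * d / n
        d_total += d
        if n > 1:
            V += d * (n_a / n) * ((n - n_a) / n) * (n - d) / (n - 1)
    if V <= 0:
        chi2 = 0.0
    else:
        chi2 = (O_a - E_a) ** 2 / V
    p = float(stats.chi2.sf(chi2, df=1))
    observed = np.array([O_a, d_total - O_a])
    expected = np.array([E_a, d_total - E_a])
    return LogRankResult(statistic=float(chi2), p_value=p,
                         observed=observed, expected=expected)


@dataclass
class CoxResult:
    beta: float
    hr: float
    se: float
    ci: tuple                  # Wald 95% CI for the HR
    p_value: float             # Wald
    n_iter: int
    converged: bool
    log_likelihood: float = np.nan


def _cox_loglik(beta, t, e, x, ties):
    """Partial log-likelihood, score and information for one covariate.

    Risk sets are handled by sorting times descending so suffix sums become
    cumulative sums; Efron's correction subtracts the tied-death averages.
    """
    order = np.argsort(-t, kind="stable")
    t, e, x = t[order], e[order], x[order]
    r = np.exp(beta * x)
    s0 = np.cumsum(r)
    s1 = np.cumsum(x * r)
    s2 = np.cumsum(x * x * r)

    ll = 0.0
    score = 0.0
    info = 0.0
    event_times = np.unique(t[e == 1])
    for et in event_times:
        # last index with time == et gives the full risk set {time >= et}
        idx = np.nonzero(t == et)[0]
        last = idx[-1]
        S0, S1, S2 = s0[last], s1[last], s2[last]
        dead = idx[e[idx] == 1]
        d = dead.size
        xs = x[dead]
        rs = r[dead]
        ll += beta * xs.sum()
        if ties == "efron":
            D0, D1, D2 = rs.sum(), (xs * rs).sum(), (xs * xs * rs).sum()
            for l in range(d):
                f = l / d
                phi0 = S0 - f * D0
                phi1 = S1 - f * D1
                phi2 = S2 - f * D2
                ll -= np.log(phi0)
                score -= phi1 / phi0
                info += phi2 / phi0 - (phi1 / phi0) ** 2
        else:  # breslow
            ll -= d * np.log(S0)
            score -= d * S1 / S0
            info += d * (S2 / S0 - (S1 / S0) ** 2)
        score += xs.sum()
    return ll, score, info


def cox_fit(records=None, *, times=None, events=None, covariate=None,
            ties="efron", max_iter=50, tol=1e-9) -> CoxResult:
    """Cox proportional-hazards fit for a single (typically binary) covariate.

    Maximizes the partial likelihood by Newton–Raphson with step-halving;
    Efron tie correction by default.  Raises on non-convergence and on
    monotone likelihood (complete separation, which would send the HR to
    infinity).
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    if records is not None:
        t, e = _records_to_arrays(records)
        x = np.array([r.group for r in records], dtype=float)
    else:
        t, e = _as_arrays(times, events)
        x = np.asarray(covariate, dtype=float)
    levels = np.unique(x)
    if levels.size < 2:
        raise ValueError("covariate must take at least two values")
    if not np.any(e == 1):
        raise ValueError("no events")
    if levels.size == 2:
        for lv in levels:
            if not np.any((x == lv) & (e == 1)):
                warnings.warn(f"no events at covariate level {lv}", stacklevel=2)

    beta = 0.0
    ll, score, info = _cox_loglik(beta, t, e, x, ties)
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        if info <= 0:
            raise RuntimeError("infinite HR: monotone partial likelihood (complete separation)")
        step = score / info
        new_beta = beta + step
        new_ll, new_score, new_info = _cox_loglik(new_beta, t, e, x, ties)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 20:
            step /= 2
            new_beta = beta + step
            new_ll, new_score, new_info = _cox_loglik(new_beta, t, e, x, ties)
            halvings += 1
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        if abs(beta) > 20:
            raise RuntimeError("infinite HR: monotone partial likelihood (complete separation)")
        if abs(step) < tol or abs(score) < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(f"Cox fit did not converge after {max_iter} iterations; last beta={beta:.4f}")

    se = 1.0 / np.sqrt(info)
    z = beta / se
    p = 2 * float(stats.norm.sf(abs(z)))
    ci = (float(np.exp(beta - 1.959963984540054 * se)),
          float(np.exp(beta + 1.959963984540054 * se)))
    return CoxResult(beta=float(beta), hr=float(np.exp(beta)), se=float(se),
                     ci=ci, p_value=p, n_iter=it, converged=True,
                     log_likelihood=float(ll))


def auc_ci_delong(scores, labels, alpha=0.05):
    """DeLong variance estimate and CI for a single ROC AUC.

    Provided as a utility for AUC confidence intervals; the survival curves
    themselves are compared with the log-rank test.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both classes required")
    # placement values (structural components)
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    auc = v10.mean()
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return float(auc), (float(max(0.0, auc - half)), float(min(1.0, auc + half)))
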