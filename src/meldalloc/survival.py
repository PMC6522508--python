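"""Product-limit survival estimation and log-rank testing.

Implemented from first principles on numpy arrays: the Kaplan-Meier estimator
with Greenwood standard errors, the k-group log-rank chi-square with the
hypergeometric (tie-corrected) variance, and a permutation version of the
log-rank test that serves as a finite-sample oracle for the asymptotic one.

Tie convention: at a tied time, events are processed before censorings, i.e.
an observation censored at t is still at risk for events at t. All estimators
accept either :class:`~meldalloc.registry.SurvivalSample` sequences or plain
(time, event) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InvalidInputError

__all__ = [
    "KMCurve",
    "LogRankResult",
    "km_fit",
    "km_survival_at",
    "logrank_test",
    "logrank_arrays",
    "permutation_logrank",
    "as_time_event",
]


def as_time_event(samples) -> tuple[np.ndarray, np.ndarray]:
    """Coerce samples (SurvivalSample objects or (time, event) pairs) to arrays."""
    times = []
    events = []
    for s in samples:
        if hasattr(s, "time_days"):
            times.append(float(s.time_days))
            events.append(bool(s.event))
        else:
            t, e = s
            times.append(float(t))
            events.append(bool(e))
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise InvalidInputError("empty sample")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise InvalidInputError("times must be finite and non-negative")
    return t, e


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier product-limit estimate.

    ``event_times`` are the distinct times with at least one event, ascending;
    ``at_risk`` and ``events`` the corresponding risk-set sizes and event
    counts; ``survival`` the product-limit values just after each event time;
    ``greenwood_se`` the Greenwood standard errors. ``n`` is the sample size.
    """

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    greenwood_se: np.ndarray
    n: int

    def survival_at(self, t_days: float) -> float:
        return km_survival_at(self, t_days)

    def se_at(self, t_days: float) -> float:
        """Greenwood standard error of S at t (0 before the first event)."""
        idx = np.searchsorted(self.event_times, t_days, side="right") - 1
        return 0.0 if idx < 0 else float(self.greenwood_se[idx])


def km_fit(samples) -> KMCurve:
    """Fit the product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    t, e = as_time_event(samples)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    ut = np.unique(t[e])
    n = t.size
    # risk set at each event time: everyone with observed time >= t (ties: events first)
    at_risk = n - np.searchsorted(t, ut, side="left")
    d = np.bincount(np.searchsorted(ut, t[e]), minlength=ut.size)
    frac = 1.0 - d / at_risk
    survival = np.cumprod(frac)
    # Greenwood: var S(t) = S(t)^2 * sum d / (n (n - d))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(at_risk > d, d / (at_risk * (at_risk - d)), np.inf)
        greenwood = survival**2 * np.cumsum(terms)
    se = np.sqrt(np.where(np.isfinite(greenwood), greenwood, 0.0))
    return KMCurve(
        event_times=ut,
        at_risk=at_risk.astype(int),
        events=d.astype(int),
        survival=survival,
        greenwood_se=se,
        n=n,
    )


def km_survival_at(curve: KMCurve, t_days: float) -> float:
    """Right-continuous step-function evaluation of the KM curve."""
    if t_days < 0:
        raise InvalidInputError("t_days must be >= 0")
    idx = np.searchsorted(curve.event_times, t_days, side="right") - 1
    return 1.0 if idx < 0 else float(curve.survival[idx])


@dataclass(frozen=True)
class LogRankResult:
    """k-group log-rank chi-square with per-group observed/expected events."""

    statistic: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray


def logrank_arrays(time: np.ndarray, event: np.ndarray, group: np.ndarray, k: int) -> LogRankResult:
    """Log-rank test on flat arrays, ``group`` holding codes in 0..k-1."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group, dtype=int)
    if k < 2:
        raise DegenerateInputError("log-rank requires at least 2 groups")
    counts = np.bincount(group, minlength=k)
    if np.any(counts == 0):
        raise DegenerateInputError("log-rank requires non-empty groups")
    if not event.any():
        raise DegenerateInputError("log-rank requires at least one event in the pooled sample")

    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order], group[order]
    ut = np.unique(t[e])
    m = ut.size

    n_total = t.size - np.searchsorted(t, ut, side="left")
    d_total = np.bincount(np.searchsorted(ut, t[e]), minlength=m).astype(float)

    n_ij = np.empty((k, m))
    d_ij = np.zeros((k, m))
    for i in range(k):
        ti = t[g == i]
        n_ij[i] = ti.size - np.searchsorted(ti, ut, side="left")
        ev = ti[e[g == i]] if np.any(e[g == i]) else ti[:0]
        if ev.size:
            d_ij[i] = np.bincount(np.searchsorted(ut, ev), minlength=m)

    observed = d_ij.sum(axis=1)
    p_share = n_ij / n_total  # n_ij / n_j
    expected_j = d_total * p_share
    expected = expected_j.sum(axis=1)

    # hypergeometric variance with tie correction; times with n_j <= 1 contribute nothing
    valid = n_total > 1
    factor = np.zeros(m)
    factor[valid] = d_total[valid] * (n_total[valid] - d_total[valid]) / (n_total[valid] - 1)
    V = np.zeros((k, k))
    for i in range(k):
        for l in range(i, k):
            cross = -(p_share[i] * p_share[l])
            if i == l:
                cross = cross + p_share[i]
            V[i, l] = V[l, i] = float(np.sum(factor * cross))

    diff = (observed - expected)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    try:
        stat = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(Vsub) @ diff)
    stat = max(stat, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(stat, df))
    return LogRankResult(statistic=stat, df=df, p_value=p, observed=observed, expected=expected)


def logrank_test(groups) -> LogRankResult:
    """k-group log-rank test; ``groups`` is a list of sample lists."""
    if len(groups) < 2:
        raise DegenerateInputError("log-rank requires at least 2 groups")
    times, events, codes = [], [], []
    for i, samples in enumerate(groups):
        if len(samples) == 0:
            raise DegenerateInputError(f"group {i} is empty")
        t, e = as_time_event(samples)
        times.append(t)
        events.append(e)
        codes.append(np.full(t.size, i))
    return logrank_arrays(np.concatenate(times), np.concatenate(events), np.concatenate(codes), len(groups))


def permutation_logrank(groups, n_perm: int, seed: int | None = None) -> float:
    """Permutation p-value for the log-rank statistic.

    Group labels are permuted ``n_perm`` times; p = (1 + #{permuted statistic
    >= observed}) / (n_perm + 1). Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise InvalidInputError("n_perm must be >= 1")
    if len(groups) < 2:
        raise DegenerateInputError("log-rank requires at least 2 groups")
    times, events, codes = [], [], []
    for i, samples in enumerate(groups):
        if len(samples) == 0:
            raise DegenerateInputError(f"group {i} is empty")
        t, e = as_time_event(samples)
        times.append(t)
        events.append(e)
        codes.append(np.full(t.size, i))
    time = np.concatenate(times)
    event = np.concatenate(events)
    group = np.concatenate(codes)
    k = len(groups)
    observed = logrank_arrays(time, event, group, k).statistic
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(group)
        stat = logrank_arrays(time, event, perm, k).statistic
        if stat >= observed - 1e-12:
            exceed += 1
    return (1 + exceed) / (n_perm + 1)
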