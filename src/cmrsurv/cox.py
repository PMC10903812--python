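"""The Cox survival core.

A fitted network emits one unbounded scalar per patient — the log-relative
hazard ``x`` in ``h(t | x) = h0(t) * exp(x)``. This module provides the
pieces that surround that scalar:

* the negative log Cox partial likelihood (the training loss) and its
  gradient with respect to the scores,
* the Breslow estimator of the cumulative baseline hazard ``H0(t)``,
* patient-specific survival curves ``S(t | x) = exp(-H0(t) * exp(x))``,
* the Kaplan-Meier product-limit estimator,
* the K-sample log-rank test,
* median-risk stratification.

Conventions (declared, since the original description states none): ties
are handled by the Breslow rule throughout, the risk set at time ``t``
includes subjects with ``t_j >= t``, and the loss is averaged over events
so learning-rate semantics do not depend on cohort size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import logsumexp


class SurvivalDataError(ValueError):
    """Raised for survival inputs on which a quantity is undefined."""


def _validate(scores, time, event):
    scores = np.asarray(scores, dtype=np.float64).ravel()
    time = np.asarray(time, dtype=np.float64).ravel()
    event = np.asarray(event).ravel().astype(np.int64)
    if not (len(scores) == len(time) == len(event)):
        raise SurvivalDataError("scores, time and event must have equal length")
    if np.any(time <= 0):
        raise SurvivalDataError("follow-up times must be > 0")
    if not np.isin(event, (0, 1)).all():
        raise SurvivalDataError("event indicators must be 0 or 1")
    return scores, time, event


def neg_log_partial_likelihood(scores, time, event, reduction="mean"):
    """Negative log Cox partial likelihood under the Breslow tie rule.

    ``-sum over events i of [x_i - log sum_{j: t_j >= t_i} exp(x_j)]``,
    divided by the number of events when ``reduction="mean"``. Computed
    with log-sum-exp over suffix risk sets for numerical stability.
    """
    loss, _ = neg_log_partial_likelihood_grad(scores, time, event, reduction)
    return loss


def neg_log_partial_likelihood_grad(scores, time, event, reduction="mean"):
    """Loss plus its gradient with respect to the scores."""
    scores, time, event = _validate(scores, time, event)
    n_events = int(event.sum())
    if n_events == 0:
        raise SurvivalDataError("partial likelihood undefined with zero events")
    order = np.argsort(time, kind="stable")
    x = scores[order]
    t = time[order]
    e = event[order]

    # log of suffix sums: log sum_{j >= i} exp(x_j), aligned to sorted order
    log_suffix = np.empty(len(x))
    running = -np.inf
    for i in range(len(x) - 1, -1, -1):
        running = np.logaddexp(running, x[i])
        log_suffix[i] = running
    # Breslow ties: every event at a tied time sees the full risk set of
    # that time, i.e. the suffix starting at the first index with t_j >= t_i
    first_idx = np.searchsorted(t, t, side="left")
    log_risk = log_suffix[first_idx]

    ev = e == 1
    loss = -(x[ev] - log_risk[ev]).sum()

    # gradient: dL/dx_j = -[e_j - exp(x_j) * sum_{events i: t_i <= t_j} 1/S_i]
    inv_s = np.zeros(len(x))
    inv_s[ev] = np.exp(-log_risk[ev])
    cum_inv = np.cumsum(inv_s)
    # subject j is in the risk set of event i iff t_j >= t_i; with sorted
    # times that is every event index i with first_idx[i] <= j, i.e. all
    # events up to and including j's tie group
    last_idx = np.searchsorted(t, t, side="right") - 1
    grad_sorted = -(e - np.exp(x) * cum_inv[last_idx])

    if reduction == "mean":
        loss /= n_events
        grad_sorted /= n_events
    elif reduction != "sum":
        raise ValueError("reduction must be 'mean' or 'sum'")
    grad = np.empty_like(grad_sorted)
    grad[order] = grad_sorted
    return float(loss), grad


@dataclass(frozen=True)
class BaselineHazard:
    """Breslow cumulative baseline hazard: a right-continuous step function."""

    event_times: np.ndarray
    increments: np.ndarray

    def __post_init__(self):
        if np.any(self.increments < 0):
            raise ValueError("hazard increments must be >= 0")

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.increments)

    def at(self, times) -> np.ndarray:
        """H0(t), with H0(0) = 0 and right-continuity at event times."""
        idx = np.searchsorted(self.event_times, np.asarray(times, dtype=float), side="right")
        cum = np.concatenate([[0.0], self.cumulative])
        return cum[idx]


def breslow_baseline(scores, time, event) -> BaselineHazard:
    """Breslow estimator: ``dH0(t_i) = d_i / sum_{j in R(t_i)} exp(x_j)``.

    With all scores zero this reduces exactly to the Nelson-Aalen
    estimator ``d_i / n_i``.
    """
    scores, time, event = _validate(scores, time, event)
    if event.sum() == 0:
        raise SurvivalDataError("baseline hazard requires at least one event")
    order = np.argsort(time, kind="stable")
    x, t, e = scores[order], time[order], event[order]
    uniq = np.unique(t[e == 1])
    increments = np.empty(len(uniq))
    for k, tk in enumerate(uniq):
        d_k = int(((t == tk) & (e == 1)).sum())
        at_risk = t >= tk
        increments[k] = d_k / np.exp(logsumexp(x[at_risk]))
    return BaselineHazard(event_times=uniq, increments=increments)


@dataclass(frozen=True)
class SurvivalCurve:
    """A survival function tabulated on a time grid, with censoring ticks."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray | None = None
    censor_times: np.ndarray | None = None

    def __post_init__(self):
        s = np.asarray(self.survival)
        if np.any(s < -1e-12) or np.any(s > 1 + 1e-12):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival must be nonincreasing")

    def at(self, times) -> np.ndarray:
        """Step-function evaluation, S(0) = 1 before the first grid time."""
        idx = np.searchsorted(self.times, np.asarray(times, dtype=float), side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]


def survival_curve(baseline: BaselineHazard, x: float, extra_times=None) -> SurvivalCurve:
    """Patient-specific curve ``S(t | x) = exp(-H0(t) * exp(x))``."""
    grid = np.asarray(baseline.event_times, dtype=float)
    if extra_times is not None:
        grid = np.unique(np.concatenate([grid, np.asarray(extra_times, dtype=float)]))
    s = np.exp(-baseline.at(grid) * np.exp(float(x)))
    return SurvivalCurve(times=grid, survival=s)


def kaplan_meier(time, event) -> SurvivalCurve:
    """Product-limit estimator with censoring tick positions."""
    time = np.asarray(time, dtype=np.float64).ravel()
    event = np.asarray(event).ravel().astype(np.int64)
    if len(time) == 0:
        raise SurvivalDataError("Kaplan-Meier requires at least one subject")
    uniq = np.unique(time)
    surv = np.empty(len(uniq))
    s = 1.0
    for k, tk in enumerate(uniq):
        d_k = int(((time == tk) & (event == 1)).sum())
        n_k = int((time >= tk).sum())
        if d_k:
            s *= 1.0 - d_k / n_k
        surv[k] = s
    at_risk = np.array([(time >= tk).sum() for tk in uniq])
    censor_times = np.unique(time[event == 0])
    return SurvivalCurve(times=uniq, survival=surv, at_risk=at_risk,
                         censor_times=censor_times)


def log_rank_test(time, event, groups):
    """K-sample log-rank test (observed minus expected over shared risk sets).

    Returns ``(chi2, df, p)`` with ``df = K - 1``. Two groups with
    identical (time, event) multisets give a statistic of exactly 0.
    """
    time = np.asarray(time, dtype=np.float64).ravel()
    event = np.asarray(event).ravel().astype(np.int64)
    groups = np.asarray(groups).ravel()
    labels = np.unique(groups)
    if len(labels) < 2:
        raise SurvivalDataError("log-rank needs at least two nonempty groups")
    if event.sum() == 0:
        raise SurvivalDataError("log-rank requires at least one event")
    k = len(labels)
    o_minus_e = np.zeros(k)
    var = np.zeros((k, k))
    member = np.stack([groups == g for g in labels])  # (K, n)
    for tk in np.unique(time[event == 1]):
        at_risk = time >= tk
        n = at_risk.sum()
        d = int(((time == tk) & (event == 1)).sum())
        n_g = member[:, at_risk].sum(axis=1).astype(float)
        d_g = member[:, (time == tk) & (event == 1)].sum(axis=1).astype(float)
        o_minus_e += d_g - d * n_g / n
        if n > 1:
            frac = n_g / n
            hyper = d * (n - d) / (n - 1)
            var += hyper * (np.diag(frac) - np.outer(frac, frac))
    v = var[:-1, :-1]
    u = o_minus_e[:-1]
    chi2 = float(u @ np.linalg.pinv(v) @ u)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def grid_search_cox_coefficient(z, time, event, lo=-5.0, hi=5.0, tol=1e-4):
    """Minimize the partial likelihood over a single coefficient by
    dense grid search with one refinement pass.

    For a linear one-covariate model ``x_i = beta * z_i`` this recovers
    the maximum-partial-likelihood estimate to ``tol`` without any
    gradient machinery — useful as a slow, transparent reference.
    """
    z = np.asarray(z, dtype=np.float64).ravel()

    def loss(beta):
        return neg_log_partial_likelihood(beta * z, time, event, reduction="sum")

    grid = np.arange(lo, hi, tol * 100)
    best = grid[np.argmin([loss(b) for b in grid])]
    fine = np.arange(best - tol * 100, best + tol * 100, tol)
    return float(fine[np.argmin([loss(b) for b in fine])])


def stratify_by_median(scores):
    """Split one split's scores at the within-split median.

    ``score >= median`` is labelled ``"high"``. If every score is
    identical the stratification is degenerate: all subjects go to
    ``"high"`` and a warning is emitted.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    if len(scores) < 2:
        raise SurvivalDataError("stratification needs at least two patients")
    if np.all(scores == scores[0]):
        warnings.warn("all risk scores identical: degenerate stratification, "
                      "all patients assigned to the high-risk stratum")
    med = np.median(scores)
    return np.where(scores >= med, "high", "low")
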