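"""Discrimination metrics under right censoring.

Harrell's concordance index treats the fitted log-risk scores as ranking
statistics: among *comparable* pairs — where we can tell from the data who
failed first — it counts how often the earlier-failing subject carried the
higher score. The horizon AUROC converts the fitted survival curves into a
binary classifier for "event within tau months" and scores it by
Mann-Whitney pair counting, excluding subjects censored before the horizon
(whose label is unknowable without inverse-probability weighting, which is
deliberately out of scope here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cox import SurvivalDataError


@dataclass(frozen=True)
class ConcordanceResult:
    """Harrell's C with a Noether-type standard error and 95% CI.

    ``ci_low``/``ci_high`` are ``c +/- 1.96 * se`` clipped to [0, 1];
    ``sd_paper_style`` bounds (``c +/- sd``) are also provided because some
    reports print that convention. ``sd`` here is the Hanley-McNeil
    binormal-free standard error of the pair statistic.
    """

    c: float
    se: float
    ci_low: float
    ci_high: float
    n_concordant: int
    n_discordant: int
    n_tied_score: int
    n_comparable: int

    @property
    def sd_interval(self):
        return (max(0.0, self.c - self.se), min(1.0, self.c + self.se))

    def as_dict(self) -> dict:
        return {
            "harrell_c": self.c, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "n_concordant": self.n_concordant, "n_discordant": self.n_discordant,
            "n_tied_score": self.n_tied_score, "n_comparable": self.n_comparable,
        }


def _comparable_pairs(time, event):
    """Boolean (n, n) matrix: entry (i, j) true when subject i is the
    comparably-earlier member of pair {i, j}.

    Pair (i, j) is comparable when ``t_i < t_j`` and i had the event, or
    ``t_i == t_j`` with exactly one event (the event subject is the
    earlier member: their failure was observed while the other was still
    event-free).
    """
    t_i = time[:, None]
    t_j = time[None, :]
    e_i = event[:, None]
    e_j = event[None, :]
    earlier = (t_i < t_j) & (e_i == 1)
    tied_time = (t_i == t_j) & (e_i == 1) & (e_j == 0)
    mat = earlier | tied_time
    np.fill_diagonal(mat, False)
    return mat


def harrell_c(scores, time, event) -> ConcordanceResult:
    """Harrell's concordance index with tied scores counted one half.

    The standard error is the Hanley-McNeil (Noether-type) asymptotic
    estimator applied to the pair statistic, with the "positive"/"negative"
    group sizes taken as the numbers of subjects appearing on the earlier
    and later side of at least one comparable pair.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    time = np.asarray(time, dtype=np.float64).ravel()
    event = np.asarray(event).ravel().astype(np.int64)
    mat = _comparable_pairs(time, event)
    n_comp = int(mat.sum())
    if n_comp == 0:
        raise SurvivalDataError("concordance undefined: no comparable pairs")
    s_i = scores[:, None]
    s_j = scores[None, :]
    conc = int((mat & (s_i > s_j)).sum())
    disc = int((mat & (s_i < s_j)).sum())
    tied = n_comp - conc - disc
    c = (conc + 0.5 * tied) / n_comp

    m = int(mat.any(axis=1).sum())   # subjects ever on the earlier side
    n = int(mat.any(axis=0).sum())   # subjects ever on the later side
    q1 = c / (2.0 - c)
    q2 = 2.0 * c * c / (1.0 + c)
    num = c * (1 - c) + max(m - 1, 0) * (q1 - c * c) + max(n - 1, 0) * (q2 - c * c)
    se = float(np.sqrt(max(num, 0.0) / (m * n)))
    return ConcordanceResult(
        c=float(c), se=se,
        ci_low=float(np.clip(c - 1.96 * se, 0.0, 1.0)),
        ci_high=float(np.clip(c + 1.96 * se, 0.0, 1.0)),
        n_concordant=conc, n_discordant=disc, n_tied_score=tied,
        n_comparable=n_comp,
    )


@dataclass(frozen=True)
class HorizonAuc:
    """AUROC for the binary outcome "event within ``horizon`` months"."""

    horizon: float
    auc: float
    n_pos: int
    n_neg: int
    excluded: int

    def as_dict(self) -> dict:
        return {"horizon_months": self.horizon, "auroc": self.auc,
                "n_pos": self.n_pos, "n_neg": self.n_neg, "excluded": self.excluded}


def auc_at_horizon(surv_prob, time, event, horizon) -> HorizonAuc:
    """Horizon AUROC from estimated survival probabilities.

    Positives: event observed at or before ``horizon``. Negatives: still
    under observation past ``horizon``. Subjects censored event-free at or
    before the horizon are excluded. The predictor is the estimated event
    risk ``1 - S(horizon | x)``; ties count one half.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    surv_prob = np.asarray(surv_prob, dtype=np.float64).ravel()
    time = np.asarray(time, dtype=np.float64).ravel()
    event = np.asarray(event).ravel().astype(np.int64)
    risk = 1.0 - surv_prob
    pos = (event == 1) & (time <= horizon)
    neg = time > horizon
    excluded = int(len(time) - pos.sum() - neg.sum())
    if pos.sum() == 0 or neg.sum() == 0:
        raise SurvivalDataError(
            f"AUROC undefined at horizon {horizon}: "
            f"{int(pos.sum())} positives, {int(neg.sum())} negatives")
    rp = risk[pos][:, None]
    rn = risk[neg][None, :]
    wins = (rp > rn).sum() + 0.5 * (rp == rn).sum()
    auc = float(wins / (pos.sum() * neg.sum()))
    return HorizonAuc(horizon=float(horizon), auc=auc,
                      n_pos=int(pos.sum()), n_neg=int(neg.sum()), excluded=excluded)
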