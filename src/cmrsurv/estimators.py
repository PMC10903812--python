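"""Scikit-learn style estimators around the multi-input Cox network.

:class:`CoxNeuralRegressor` follows the fit/predict contract: ``fit``
trains the network on the full split per step (risk sets of the partial
likelihood are then exact), ``predict`` returns log-risk scores, and
``predict_survival_function`` composes them with the Breslow baseline
hazard fitted on the training scores. ``y`` may be a pandas DataFrame
with ``time_months``/``event`` columns, a ``(time, event)`` tuple, or a
scikit-survival style structured array.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .cox import (
    breslow_baseline,
    neg_log_partial_likelihood_grad,
    survival_curve,
)
from .metrics import harrell_c
from .nn import Adam, MultiInputCoxNet, NetworkConfig


def unpack_survival_target(y):
    """Normalize the survival target to ``(time, event)`` float/int arrays."""
    if isinstance(y, pd.DataFrame):
        return y["time_months"].to_numpy(float), y["event"].to_numpy(int)
    if isinstance(y, np.ndarray) and y.dtype.names:
        names = y.dtype.names
        ev = [n for n in names if y[n].dtype == bool or "event" in n.lower()][0]
        tm = [n for n in names if n != ev][0]
        return y[tm].astype(float), y[ev].astype(int)
    time, event = y
    return np.asarray(time, float), np.asarray(event, int)


class CoxNeuralRegressor(BaseEstimator):
    """Neural Cox regression on imaging tensors plus clinical covariates.

    Parameters mirror :class:`~cmrsurv.nn.NetworkConfig`; ``epochs``,
    ``lr`` and ``seed`` control the full-batch Adam optimization of the
    mean negative log partial likelihood (Breslow ties). With
    ``covariates_only=True`` and ``linear_covariates=True`` the model
    degenerates to a plain linear Cox predictor trained by the same loop.

    Fitted attributes: ``net_`` (the network), ``baseline_hazard_``,
    ``history_`` (per-epoch loss/concordance log), ``n_iter_``.
    """

    def __init__(self, epochs=30, lr=1e-2, dropout=0.2, activity_l2=1e-4,
                 batchnorm=True, covariates_only=False, linear_covariates=False,
                 cine_filters=(8, 16), lge_filters=(8, 16), trunk_filters=(16, 16),
                 kernel=3, embed_dim=8, cov_hidden=(8, 8), head_hidden=8,
                 warm_start=False, seed=0):
        self.epochs = epochs
        self.lr = lr
        self.dropout = dropout
        self.activity_l2 = activity_l2
        self.batchnorm = batchnorm
        self.covariates_only = covariates_only
        self.linear_covariates = linear_covariates
        self.cine_filters = cine_filters
        self.lge_filters = lge_filters
        self.trunk_filters = trunk_filters
        self.kernel = kernel
        self.embed_dim = embed_dim
        self.cov_hidden = cov_hidden
        self.head_hidden = head_hidden
        self.warm_start = warm_start
        self.seed = seed

    # -- helpers ----------------------------------------------------------

    def _config(self) -> NetworkConfig:
        return NetworkConfig(
            cine_filters=tuple(self.cine_filters), lge_filters=tuple(self.lge_filters),
            trunk_filters=tuple(self.trunk_filters), kernel=self.kernel,
            embed_dim=self.embed_dim, cov_hidden=tuple(self.cov_hidden),
            head_hidden=self.head_hidden, dropout=self.dropout,
            activity_l2=self.activity_l2, batchnorm=self.batchnorm,
            covariates_only=self.covariates_only,
            linear_covariates=self.linear_covariates, seed=self.seed)

    @staticmethod
    def _as_batch(X) -> dict:
        if isinstance(X, dict):
            return X
        return {"cov": np.asarray(X, dtype=np.float64)}

    def _init_net(self, batch):
        cov = np.asarray(batch["cov"])
        if self.covariates_only:
            self.net_ = MultiInputCoxNet(self._config(), n_cov=cov.shape[1])
        else:
            cine = np.asarray(batch["cine"])
            _, t, c, h, w = cine.shape
            self.net_ = MultiInputCoxNet(self._config(), n_cov=cov.shape[1],
                                         h=h, w=w, c=c, t=t)
        self.optimizer_ = Adam(self.net_.iter_params(), lr=self.lr)

    # -- sklearn API ------------------------------------------------------

    def fit(self, X, y, monitor=None, epochs=None, stage_label=None):
        """Full-batch training; optionally log a monitored split per epoch.

        ``monitor``: optional ``(X_mon, y_mon, name)`` whose loss and
        Harrell's C are evaluated in inference mode after every epoch.
        With ``warm_start=True`` a second call continues from the current
        weights (the two-stage protocol uses this).
        """
        batch = self._as_batch(X)
        time, event = unpack_survival_target(y)
        n_epochs = self.epochs if epochs is None else epochs
        fresh = not (self.warm_start and hasattr(self, "net_"))
        if fresh:
            self._init_net(batch)
            self._history_rows = []

        mon = None
        if monitor is not None:
            x_mon, y_mon, mon_name = monitor
            mon_batch = self._as_batch(x_mon)
            mon_time, mon_event = unpack_survival_target(y_mon)
            mon = (mon_batch, mon_time, mon_event, mon_name)

        start = len(self._history_rows)
        for epoch in range(n_epochs):
            scores = self.net_.forward(batch, train=True)
            loss, grad = neg_log_partial_likelihood_grad(scores, time, event)
            loss_total = loss + self.net_.penalty()
            if not np.isfinite(loss_total):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {start + epoch + 1}")
            self.net_.backward(grad)
            self.optimizer_.step()

            row = {"epoch": start + epoch + 1,
                   "stage": stage_label or "fit",
                   "train_loss": loss,
                   "train_c": harrell_c(self.predict(batch), time, event).c}
            if mon is not None:
                mon_scores = self.predict(mon[0])
                mon_loss, _ = neg_log_partial_likelihood_grad(mon_scores, mon[1], mon[2])
                row.update({"monitor_set": mon[3], "monitor_loss": mon_loss,
                            "monitor_c": harrell_c(mon_scores, mon[1], mon[2]).c})
            self._history_rows.append(row)

        self.history_ = pd.DataFrame(self._history_rows)
        self.n_iter_ = len(self._history_rows)
        final_scores = self.predict(batch)
        self.baseline_hazard_ = breslow_baseline(final_scores, time, event)
        return self

    def predict(self, X) -> np.ndarray:
        """Log-risk scores in inference mode (deterministic)."""
        check_is_fitted(self, "net_")
        return self.net_.forward(self._as_batch(X), train=False)

    def predict_survival_function(self, X, times=None):
        """One survival curve per patient from the Breslow baseline."""
        check_is_fitted(self, "baseline_hazard_")
        scores = self.predict(X)
        return [survival_curve(self.baseline_hazard_, x, extra_times=times)
                for x in scores]

    def score(self, X, y) -> float:
        """Harrell's concordance of predicted log-risk on (X, y)."""
        time, event = unpack_survival_target(y)
        return harrell_c(self.predict(X), time, event).c

    def refit_baseline(self, X, y):
        """Re-estimate the Breslow baseline on a chosen reference split."""
        time, event = unpack_survival_target(y)
        self.baseline_hazard_ = breslow_baseline(self.predict(X), time, event)
        return self


# -- thin functional wrappers over the estimator surface --------------------

def build_network(config: NetworkConfig, n_cov: int, **dims) -> MultiInputCoxNet:
    """Construct a seeded network from a config (opaque parameters)."""
    return MultiInputCoxNet(config, n_cov=n_cov, **dims)


def forward_logrisk(net: MultiInputCoxNet, batch: dict, mode: str = "inference"):
    """Batch of log-risk scores; 'train' mode engages dropout/batch stats."""
    if mode not in ("train", "inference"):
        raise ValueError("mode must be 'train' or 'inference'")
    return net.forward(batch, train=(mode == "train"))


def fit_covariate_encoder(records: pd.DataFrame):
    """Fit the Table-1-schema covariate encoder on a training split."""
    from .covariates import CovariateEncoder
    return CovariateEncoder().fit(records)
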