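"""Clinical covariate schema and encoding.

The baseline covariate table mirrors the standard dilated-cardiomyopathy
risk-factor panel: demographics (age, sex, height, weight), cardiovascular
risk factors (dyslipidaemia, hypertension, smoking, diabetes), familial
history (CAD, cardiomyopathy, sudden cardiac death), comorbidity (COPD),
labs (creatinine in mmol/l, NT-proBNP in pg/l), functional class (NYHA
I-IV) and ECG rhythm (sinus rhythm, atrial fibrillation, LBBB).

:class:`CovariateEncoder` is a scikit-learn transformer producing a fixed
23-column numeric design matrix: 5 standardized continuous + 11 binary +
3 smoker one-hot + 4 NYHA one-hot. All standardization and imputation
statistics come from the *fitting* split only — re-fitting on a larger
split is an explicit, fingerprinted step in the training pipeline.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

CONTINUOUS = ("age", "height", "weight", "creatinine", "nt_probnp")
# strongly right-skewed biomarkers enter on the log scale before
# standardization (the conventional transform for natriuretic peptides)
LOG_SCALE = ("nt_probnp",)
BINARY = (
    "male", "dyslipidaemia", "hypertension", "diabetes",
    "fam_cad", "fam_cardiomyopathy", "fam_scd", "copd",
    "sinus_rhythm", "atrial_fibrillation", "lbbb",
)
CATEGORICAL = {
    "smoker": ("current", "ex", "never"),
    "nyha": (1, 2, 3, 4),
}
N_ENCODED = len(CONTINUOUS) + len(BINARY) + sum(len(v) for v in CATEGORICAL.values())


class SchemaError(ValueError):
    """Raised when a covariate table violates the declared schema."""


class CovariateEncoder(BaseEstimator, TransformerMixin):
    """Encode the covariate table into a fixed-length numeric matrix.

    Continuous fields are standardized by fitting-split mean/SD; missing
    continuous values impute to the fitting-split median, missing
    categorical values to the mode. Unknown categorical levels at
    transform time raise :class:`SchemaError`.
    """

    def fit(self, X: pd.DataFrame, y=None):
        X = self._check_frame(X)
        if len(X) < 2:
            raise SchemaError("encoder needs at least 2 records to fit")
        self.means_, self.sds_, self.medians_ = {}, {}, {}
        for c in CONTINUOUS:
            v = self._continuous_scale(c, X[c].astype(float))
            self.means_[c] = float(v.mean())
            sd = float(v.std(ddof=0))
            self.sds_[c] = sd if sd > 0 else 1.0
            self.medians_[c] = float(v.median())
        self.modes_ = {}
        for c in list(BINARY) + list(CATEGORICAL):
            self.modes_[c] = X[c].mode(dropna=True).iloc[0]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "means_")
        X = self._check_frame(X)
        cols = []
        for c in CONTINUOUS:
            v = self._continuous_scale(c, X[c].astype(float)).fillna(self.medians_[c])
            cols.append(((v - self.means_[c]) / self.sds_[c]).to_numpy())
        for c in BINARY:
            v = X[c].where(X[c].notna(), self.modes_[c])
            bad = ~v.isin([0, 1, True, False])
            if bad.any():
                raise SchemaError(f"binary covariate {c!r} has non-binary values")
            cols.append(v.astype(float).to_numpy())
        for c, levels in CATEGORICAL.items():
            v = X[c].where(X[c].notna(), self.modes_[c])
            unknown = ~v.isin(levels)
            if unknown.any():
                raise SchemaError(
                    f"unknown level(s) {sorted(v[unknown].unique().tolist())} "
                    f"for covariate {c!r}; allowed: {levels}")
            for lev in levels:
                cols.append((v == lev).astype(float).to_numpy())
        out = np.column_stack(cols)
        assert out.shape[1] == N_ENCODED
        return out

    def get_feature_names_out(self, input_features=None):
        names = [f"{c}_std" for c in CONTINUOUS] + list(BINARY)
        for c, levels in CATEGORICAL.items():
            names += [f"{c}_{lev}" for lev in levels]
        return np.asarray(names, dtype=object)

    def fingerprint(self) -> str:
        """Stable hash of the fitted statistics (leakage audit trail)."""
        check_is_fitted(self, "means_")
        payload = json.dumps(
            {"means": self.means_, "sds": self.sds_, "medians": self.medians_,
             "modes": {k: str(v) for k, v in self.modes_.items()}},
            sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_dict(self) -> dict:
        check_is_fitted(self, "means_")
        return {"means": self.means_, "sds": self.sds_, "medians": self.medians_,
                "modes": {k: (int(v) if isinstance(v, (int, np.integer)) else str(v))
                          for k, v in self.modes_.items()}}

    @classmethod
    def from_dict(cls, state: dict) -> "CovariateEncoder":
        enc = cls()
        enc.means_ = dict(state["means"])
        enc.sds_ = dict(state["sds"])
        enc.medians_ = dict(state["medians"])
        enc.modes_ = dict(state["modes"])
        enc.n_features_in_ = len(CONTINUOUS) + len(BINARY) + len(CATEGORICAL)
        return enc

    @staticmethod
    def _continuous_scale(name, values: pd.Series) -> pd.Series:
        if name in LOG_SCALE:
            if (values <= 0).any():
                raise SchemaError(f"{name!r} must be positive for the log scale")
            return np.log(values)
        return values

    @staticmethod
    def _check_frame(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise SchemaError("covariates must be a pandas DataFrame")
        missing = [c for c in (*CONTINUOUS, *BINARY, *CATEGORICAL) if c not in X.columns]
        if missing:
            raise SchemaError(f"covariate table lacks required columns: {missing}")
        return X
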