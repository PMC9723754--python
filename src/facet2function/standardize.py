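"""Two-standard-deviation rescaling of model variables.

Predictors (and, optionally, responses) are centered and divided by twice
their sample standard deviation, so that a coefficient expresses the change
in the response per 2-SD change of the predictor and is directly comparable
across continuous and binary inputs. The resulting variables have mean 0
and SD 0.5.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


class TwoSDScaler(TransformerMixin, BaseEstimator):
    """Center variables and divide by two sample standard deviations.

    Parameters
    ----------
    ddof : int, default 1
        Delta degrees of freedom for the standard deviation; the default is
        the sample SD (n − 1 denominator).

    Attributes
    ----------
    mean_ : ndarray of shape (n_features,)
    scale_ : ndarray of shape (n_features,)
        Twice the per-column sample SD.
    columns_ : list of str or None
        Column names when fitted on a DataFrame.
    """

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def fit(self, X, y=None):
        X_arr, columns = _as_2d(X)
        if X_arr.shape[0] < 2:
            raise ValueError("TwoSDScaler requires at least two observations")
        sd = X_arr.std(axis=0, ddof=self.ddof)
        bad = np.flatnonzero(sd <= 0)
        if bad.size:
            names = [columns[i] if columns else str(i) for i in bad]
            raise ValueError(f"constant variable(s), SD is zero: {', '.join(names)}")
        self.mean_ = X_arr.mean(axis=0)
        self.scale_ = 2.0 * sd
        self.columns_ = columns
        self.n_features_in_ = X_arr.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "scale_")
        X_arr, columns = _as_2d(X)
        out = (X_arr - self.mean_) / self.scale_
        if columns is not None:
            return pd.DataFrame(out, index=X.index, columns=columns)
        return out

    def inverse_transform(self, X):
        check_is_fitted(self, "scale_")
        X_arr, columns = _as_2d(X)
        out = X_arr * self.scale_ + self.mean_
        if columns is not None:
            return pd.DataFrame(out, index=X.index, columns=columns)
        return out


def rescale_two_sd(x, name: str = "x", ddof: int = 1) -> pd.Series:
    """Rescale a single vector to mean 0, SD 0.5.

    Returns a Series whose ``attrs`` carry the original mean and SD and the
    transform tag, so estimates can be mapped back to the raw scale.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("rescale_two_sd expects a 1-D vector")
    sd = arr.std(ddof=ddof)
    if not sd > 0:
        raise ValueError(f"variable {name!r} is constant; cannot rescale by 2 SD")
    mean = arr.mean()
    out = pd.Series((arr - mean) / (2.0 * sd), name=name)
    if isinstance(x, pd.Series):
        out.index = x.index
        out.name = x.name or name
    out.attrs.update({"mean": float(mean), "sd": float(sd), "transform": "2SD"})
    return out


def _as_2d(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, None
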