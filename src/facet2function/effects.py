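"""Standardized linear effect models, functional-form comparison and
stepwise AIC selection.

All models are ordinary least squares under normal-error assumptions.
Predictors (and by default the response) are centered and divided by two
sample standard deviations before fitting, so estimates are standardized
effect sizes: with both sides rescaled, a univariate estimate equals the
Pearson correlation. Non-linear alternatives (quadratic, cubic,
logarithmic) are compared by AIC, keeping the linear form unless a rival
beats it by at least 4 AIC units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .standardize import TwoSDScaler, rescale_two_sd

logger = logging.getLogger(__name__)

#: a rival functional form must beat linear by at least this many AIC units
AIC_LINEAR_PREFERENCE = 4.0


@dataclass
class LinearFit:
    """Result of a standardized linear effect model."""

    response: str
    predictors: list[str]
    estimates: pd.Series          # incl. intercept, on the standardized scale
    se: pd.Series
    pvalues: pd.Series
    r2: float
    adj_r2: float
    aic: float
    nobs: int
    diagnostics: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.estimates, "se": self.se, "p_value": self.pvalues}
        ).rename_axis("term")


class LinearEffectModel(BaseEstimator):
    """OLS effect model on 2-SD-standardized variables.

    Parameters
    ----------
    standardize_response : bool, default True
        Rescale the response to mean 0, SD 0.5 before fitting (the model
        then reports fully standardized effect sizes).
    standardize_predictors : bool, default True
    ddof : int, default 1
        SD convention for the rescaling (sample SD).

    Attributes
    ----------
    result_ : LinearFit
    estimates_, se_, pvalues_ : pd.Series
    r2_, adj_r2_, aic_ : float
    """

    def __init__(self, standardize_response: bool = True,
                 standardize_predictors: bool = True, ddof: int = 1):
        self.standardize_response = standardize_response
        self.standardize_predictors = standardize_predictors
        self.ddof = ddof

    def fit(self, X, y):
        X = _as_frame(X)
        y = _as_series(y)
        X, y = _listwise_delete(X, y)
        n, p = X.shape
        if n <= p + 1:
            raise ValueError(
                f"too few observations ({n}) for {p} predictors plus intercept"
            )
        _check_full_rank(X)

        if self.standardize_predictors and p:
            self._x_scaler = TwoSDScaler(ddof=self.ddof).fit(X)
            Xs = self._x_scaler.transform(X)
        else:
            self._x_scaler = None
            Xs = X
        if self.standardize_response:
            ys = rescale_two_sd(y, name=y.name or "y", ddof=self.ddof)
        else:
            ys = y

        design = sm.add_constant(Xs, has_constant="add")
        res = sm.OLS(np.asarray(ys, dtype=float), design).fit()
        self.model_ = res
        self.response_ = str(y.name or "y")
        self.predictors_ = list(X.columns)
        self.estimates_ = pd.Series(res.params, index=design.columns)
        self.se_ = pd.Series(res.bse, index=design.columns)
        self.pvalues_ = pd.Series(res.pvalues, index=design.columns)
        self.r2_ = float(res.rsquared)
        self.adj_r2_ = float(res.rsquared_adj)
        self.aic_ = float(res.aic)
        self.nobs_ = int(res.nobs)
        self.result_ = LinearFit(
            response=self.response_,
            predictors=self.predictors_,
            estimates=self.estimates_,
            se=self.se_,
            pvalues=self.pvalues_,
            r2=self.r2_,
            adj_r2=self.adj_r2_,
            aic=self.aic_,
            nobs=self.nobs_,
            diagnostics=_residual_diagnostics(res),
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = _as_frame(X)[self.predictors_]
        Xs = self._x_scaler.transform(X) if self._x_scaler is not None else X
        design = sm.add_constant(Xs, has_constant="add")
        return np.asarray(self.model_.predict(design))


def fit_effect_model(y, X, standardize_response: bool = True) -> LinearFit:
    """Fit a standardized linear effect model; see :class:`LinearEffectModel`."""
    est = LinearEffectModel(standardize_response=standardize_response)
    return est.fit(X, y).result_


# ---------------------------------------------------------------------------
# Functional-form comparison
# ---------------------------------------------------------------------------

@dataclass
class FormComparison:
    """AIC comparison of linear vs quadratic / cubic / logarithmic forms."""

    aic: dict[str, float]
    delta_aic: dict[str, float]
    chosen: str
    fits: dict[str, LinearFit] = field(default_factory=dict)


def compare_functional_forms(y, x, poly_degree: int = 3) -> FormComparison:
    """Compare candidate shapes of a single-predictor relation by AIC.

    Fits linear, quadratic, polynomial (default cubic) and logarithmic
    forms of the predictor on identical observations and applies the
    linear-preference rule: the linear form is retained unless the best
    rival has an AIC at least 4 units lower. The logarithmic form is
    skipped with a warning when the predictor is not strictly positive.
    """
    x = _as_series(x, name="x")
    y = _as_series(y, name="y")
    Xfull = pd.DataFrame({"x": x})
    Xfull, y = _listwise_delete(Xfull, y)
    xv = Xfull["x"]

    designs: dict[str, pd.DataFrame] = {
        "linear": pd.DataFrame({"x": xv}),
        "quadratic": pd.DataFrame({"x": xv, "x^2": xv**2}),
        f"polynomial({poly_degree})": pd.DataFrame(
            {f"x^{d}" if d > 1 else "x": xv**d for d in range(1, poly_degree + 1)}
        ),
    }
    if (xv > 0).all():
        designs["logarithmic"] = pd.DataFrame({"log(x)": np.log(xv)})
    else:
        logger.warning("non-positive predictor values; logarithmic form skipped")

    fits = {
        form: LinearEffectModel().fit(design, y).result_
        for form, design in designs.items()
    }
    # AIC from RSS with a floor at numerical precision, so that an exactly
    # noiseless relation does not hand the comparison to a higher-order form
    # on floating-point residue alone
    n = len(y)
    tss = 0.25 * (n - 1)  # standardized response
    aic = {}
    for form, f in fits.items():
        rss = max((1.0 - f.r2) * tss, 1e-14 * tss)
        k = len(f.predictors) + 2  # slopes + intercept + error variance
        aic[form] = n * np.log(rss / n) + 2 * k
    best = min(aic.values())
    delta = {form: a - best for form, a in aic.items()}
    chosen = (
        "linear"
        if delta["linear"] < AIC_LINEAR_PREFERENCE
        else min(aic, key=aic.get)
    )
    return FormComparison(aic=aic, delta_aic=delta, chosen=chosen, fits=fits)


# ---------------------------------------------------------------------------
# Stepwise AIC selection
# ---------------------------------------------------------------------------

class StepwiseSelector(BaseEstimator):
    """Bidirectional stepwise AIC selection over candidate predictors.

    Starts from the full model (intercept-only when the full model is not
    estimable, which is logged); at each step evaluates every single
    addition and deletion and takes the move with the lowest AIC, stopping
    when no move improves. Ties go to the first candidate in column order.

    Attributes
    ----------
    selected_ : list of str
    trace_ : list of (action, variable, aic) triples, first entry the start
    result_ : LinearFit of the final model
    """

    def __init__(self, standardize_response: bool = True, direction: str = "both",
                 start: str = "full"):
        self.standardize_response = standardize_response
        self.direction = direction
        self.start = start

    def fit(self, X, y):
        if self.direction not in ("both", "forward", "backward"):
            raise ValueError("direction must be 'both', 'forward' or 'backward'")
        X = _as_frame(X)
        y = _as_series(y)
        X, y = _listwise_delete(X, y)
        candidates = list(X.columns)

        start_full = self.start == "full" and self.direction != "forward"
        if start_full and len(y) <= len(candidates) + 1:
            logger.warning(
                "full model not estimable (n=%d, p=%d); starting forward from "
                "intercept-only", len(y), len(candidates),
            )
            start_full = False
        current = list(candidates) if start_full else []

        def aic_of(cols: list[str]) -> float:
            if not cols:
                ys = (
                    rescale_two_sd(y, ddof=1)
                    if self.standardize_response
                    else y
                )
                res = sm.OLS(
                    np.asarray(ys, dtype=float), np.ones((len(ys), 1))
                ).fit()
                return float(res.aic)
            return LinearEffectModel(
                standardize_response=self.standardize_response
            ).fit(X[cols], y).aic_

        current_aic = aic_of(current)
        trace = [("start", "+".join(current) or "(intercept)", current_aic)]
        while True:
            moves: list[tuple[float, str, str]] = []
            if self.direction in ("both", "forward"):
                for v in candidates:
                    if v not in current and len(y) > len(current) + 2:
                        moves.append((aic_of(current + [v]), "add", v))
            if self.direction in ("both", "backward"):
                for v in current:
                    moves.append(
                        (aic_of([c for c in current if c != v]), "drop", v)
                    )
            if not moves:
                break
            best_aic, action, var = min(moves, key=lambda m: m[0])
            if best_aic >= current_aic:
                break
            if action == "add":
                current = current + [var]
            else:
                current = [c for c in current if c != var]
            current_aic = best_aic
            trace.append((action, var, current_aic))

        self.selected_ = current
        self.trace_ = trace
        if current:
            final = LinearEffectModel(
                standardize_response=self.standardize_response
            ).fit(X[current], y)
            self.result_ = final.result_
        else:
            ys = rescale_two_sd(y, ddof=1) if self.standardize_response else y
            res = sm.OLS(np.asarray(ys, dtype=float), np.ones((len(ys), 1))).fit()
            self.result_ = LinearFit(
                response=str(y.name or "y"), predictors=[],
                estimates=pd.Series(res.params, index=["const"]),
                se=pd.Series(res.bse, index=["const"]),
                pvalues=pd.Series(res.pvalues, index=["const"]),
                r2=0.0, adj_r2=0.0, aic=float(res.aic), nobs=int(res.nobs),
            )
        return self


def stepwise_select(y, X_candidates, **kwargs):
    """Run stepwise AIC selection; returns ``(LinearFit, trace)``."""
    sel = StepwiseSelector(**kwargs).fit(X_candidates, y)
    return sel.result_, sel.trace_


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return pd.DataFrame(arr, columns=[f"x{i}" for i in range(arr.shape[1])])


def _as_series(y, name: str = "y") -> pd.Series:
    if isinstance(y, pd.Series):
        return y
    return pd.Series(np.asarray(y, dtype=float), name=name)


def _listwise_delete(X: pd.DataFrame, y: pd.Series):
    mask = X.notna().all(axis=1) & y.notna()
    dropped = int((~mask).sum())
    if dropped:
        logger.info("listwise deletion removed %d row(s)", dropped)
    return X.loc[mask], y.loc[mask]


def _check_full_rank(X: pd.DataFrame) -> None:
    if X.shape[1] == 0:
        return
    arr = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify offending columns by incremental rank growth
        bad = []
        cols = [np.ones(len(X))]
        for name in X.columns:
            trial = np.column_stack(cols + [X[name].to_numpy(dtype=float)])
            if np.linalg.matrix_rank(trial) == len(cols):
                bad.append(name)
            else:
                cols.append(X[name].to_numpy(dtype=float))
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def _residual_diagnostics(res) -> dict:
    resid = np.asarray(res.resid)
    out = {}
    if 3 <= len(resid) <= 5000:
        out["shapiro_p"] = float(stats.shapiro(resid)[1])
    try:
        from statsmodels.stats.diagnostic import het_breuschpagan

        if res.model.exog.shape[1] > 1:
            out["breusch_pagan_p"] = float(
                het_breuschpagan(resid, res.model.exog)[1]
            )
    except Exception:  # pragma: no cover - diagnostic only
        pass
    return out
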