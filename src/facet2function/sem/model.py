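"""Maximum-likelihood fitting of recursive path models on covariances.

The model is the standard observed-variable structural equation system

    y = B y + e,   Cov(e) = Psi,   Sigma(theta) = (I-B)^-1 Psi (I-B)^-T

with B holding one free coefficient per declared directed edge and Psi a
symmetric matrix with free diagonal, free covariances among exogenous
variables, and free covariances for every declared ``~~`` edge. The ML
discrepancy

    F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

is minimized by quasi-Newton iteration started from per-equation least
squares; for recursive models with uncorrelated disturbances that start is
already the optimum, which doubles as an internal cross-check. Standard
errors come from the inverse Hessian of F_ML (expected-information
convention, scaled by 2/(n-1)); chi-square uses (n-1) F_ML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .model_spec import PathModelSpec, parse_model

logger = logging.getLogger(__name__)

_PENALTY = 1e10


@dataclass
class StandardizedPaths:
    """Standardized directed-path coefficients with per-path p-values."""

    spec: PathModelSpec
    coef: dict[tuple[str, str], float]
    pvalues: dict[tuple[str, str], float]

    @classmethod
    def from_coefficients(
        cls,
        spec: PathModelSpec | str,
        coef: dict[tuple[str, str], float],
        pvalues: dict[tuple[str, str], float] | None = None,
    ) -> "StandardizedPaths":
        """Wrap an externally reported standardized solution (for effect
        arithmetic on published coefficient tables). Paths without a
        reported p-value are treated as significant."""
        if isinstance(spec, str):
            spec = parse_model(spec)
        unknown = [e for e in coef if e not in set(spec.directed)]
        if unknown:
            raise ValueError(f"coefficients for undeclared edges: {unknown}")
        full = {e: float(coef.get(e, 0.0)) for e in spec.directed}
        pv = {e: 1.0 if coef.get(e) is None else 0.0 for e in spec.directed}
        if pvalues:
            pv.update({e: float(p) for e, p in pvalues.items()})
        return cls(spec=spec, coef=full, pvalues=pv)


@dataclass
class SEMFit:
    """Fitted path model: estimates, implied covariance and fit indices."""

    spec: PathModelSpec
    n: int
    params: pd.DataFrame          # lhs, op, rhs, est, se, z, p_value, std_est
    B: pd.DataFrame               # raw coefficients, rows=target, cols=source
    psi: pd.DataFrame
    sigma: pd.DataFrame           # model-implied covariance
    sample_cov: pd.DataFrame
    fml: float
    chi2: float
    df: int
    baseline_chi2: float
    baseline_df: int
    rmsea: float
    cfi: float
    srmr: float
    fit_pass: dict[str, bool]
    r2: pd.Series                 # per endogenous variable
    converged: bool
    grad_norm: float
    notes: list[str] = field(default_factory=list)

    def standardized_paths(self) -> StandardizedPaths:
        paths = self.params[self.params["op"] == "~"]
        coef = {
            (r.rhs, r.lhs): float(r.std_est) for r in paths.itertuples()
        }
        pv = {(r.rhs, r.lhs): float(r.p_value) for r in paths.itertuples()}
        return StandardizedPaths(spec=self.spec, coef=coef, pvalues=pv)


class PathModel(BaseEstimator):
    """Sklearn-style estimator for recursive observed-variable path models.

    Parameters
    ----------
    spec : PathModelSpec or str
        Model declaration (see :func:`parse_model`).
    gtol : float
        Gradient-norm tolerance for the quasi-Newton optimizer.

    Attributes
    ----------
    fit_ : SEMFit
    """

    def __init__(self, spec=None, gtol: float = 1e-7):
        self.spec = spec
        self.gtol = gtol

    def fit(self, data: pd.DataFrame, y=None, n: int | None = None):
        spec = self.spec
        if isinstance(spec, str):
            spec = parse_model(spec)
        if spec is None:
            raise ValueError("a model spec is required")
        missing = [v for v in spec.variables if v not in data.columns]
        if missing:
            raise KeyError(f"model variables absent from data: {missing}")

        frame = data[list(spec.variables)].dropna()
        dropped = len(data) - len(frame)
        if dropped:
            logger.info("listwise deletion removed %d row(s) before SEM fit", dropped)
        if n is None:
            n = len(frame)
        p = len(spec.variables)
        S = np.cov(frame.to_numpy(dtype=float), rowvar=False, ddof=1)
        sign, logdet_s = np.linalg.slogdet(S)
        if sign <= 0 or not np.isfinite(logdet_s):
            raise ValueError(
                "sample covariance is singular; inputs are collinear or n too small"
            )

        free = _free_parameters(spec)
        if n <= len(free):
            raise ValueError(
                f"n={n} must exceed the number of free parameters ({len(free)})"
            )
        idx = {v: i for i, v in enumerate(spec.variables)}

        theta0 = _ols_start(spec, frame, S, free, idx)

        def unpack(theta):
            B = np.zeros((p, p))
            Psi = np.zeros((p, p))
            for val, (kind, i, j) in zip(theta, free):
                if kind == "beta":
                    B[i, j] = val
                else:
                    Psi[i, j] = val
                    Psi[j, i] = val
            return B, Psi

        eye = np.eye(p)

        def fml(theta):
            B, Psi = unpack(theta)
            try:
                A = np.linalg.inv(eye - B)
            except np.linalg.LinAlgError:
                return _PENALTY
            Sigma = A @ Psi @ A.T
            sgn, logdet = np.linalg.slogdet(Sigma)
            if sgn <= 0 or not np.isfinite(logdet):
                return _PENALTY
            try:
                trace = np.trace(np.linalg.solve(Sigma, S))
            except np.linalg.LinAlgError:
                return _PENALTY
            return logdet + trace - logdet_s - p

        # optimize with log-parameterized variance terms: keeps diagonals
        # positive and conditions the surface even when a disturbance
        # variance is near zero (noiseless equations)
        is_var = np.array([kind == "psi" and i == j for kind, i, j in free])

        def to_internal(th):
            t = np.array(th, dtype=float)
            t[is_var] = np.log(np.maximum(t[is_var], 1e-15))
            return t

        def to_natural(t):
            th = np.array(t, dtype=float)
            th[is_var] = np.exp(np.clip(th[is_var], -60, 60))
            return th

        res = optimize.minimize(
            lambda t: fml(to_natural(t)),
            to_internal(theta0),
            method="BFGS",
            options={"gtol": self.gtol, "maxiter": 2000},
        )
        grad_norm = float(np.max(np.abs(res.jac)))
        converged = bool(res.success) or grad_norm <= 1e-3
        if not converged:
            # stiff surfaces (near-zero disturbance variances) defeat the
            # gradient test even at the optimum; accept stationarity when a
            # probe step along the negative gradient cannot improve F
            fint = lambda t: fml(to_natural(t))
            step = 1e-8 / max(np.linalg.norm(res.jac), 1.0)
            if fint(res.x - step * res.jac) >= res.fun - 1e-12:
                converged = True
        if not converged:
            raise RuntimeError(
                f"SEM optimization did not converge (|grad|={grad_norm:.3g}): "
                f"{res.message}"
            )
        theta = to_natural(res.x)
        B, Psi = unpack(theta)
        A = np.linalg.inv(eye - B)
        Sigma = A @ Psi @ A.T
        f_val = float(fml(theta))

        se = _standard_errors(fml, theta, n, is_var)
        sd = np.sqrt(np.diag(Sigma))
        rows = []
        for val, s_e, (kind, i, j) in zip(theta, se, free):
            z = val / s_e if s_e > 0 else np.nan
            pv = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            if kind == "beta":
                std = val * sd[j] / sd[i] if sd[i] > 0 else np.nan
                rows.append((spec.variables[i], "~", spec.variables[j],
                             val, s_e, z, pv, std))
            else:
                denom = sd[i] * sd[j]
                std = val / denom if denom > 0 else np.nan
                rows.append((spec.variables[i], "~~", spec.variables[j],
                             val, s_e, z, pv, std))
        params = pd.DataFrame(
            rows,
            columns=["lhs", "op", "rhs", "est", "se", "z", "p_value", "std_est"],
        )
        if np.any(sd <= 0):
            raise ValueError("zero model-implied variance; cannot standardize")

        chi2 = max((n - 1) * f_val, 0.0)
        df = p * (p + 1) // 2 - len(free)
        fb = float(np.sum(np.log(np.diag(S))) - logdet_s)
        chi2_b = max((n - 1) * fb, 0.0)
        df_b = p * (p - 1) // 2
        rmsea, cfi, srmr, notes = _fit_indices_from(
            chi2, df, chi2_b, df_b, n, S, Sigma
        )
        r2 = pd.Series(
            {
                v: 1.0 - Psi[idx[v], idx[v]] / Sigma[idx[v], idx[v]]
                for v in spec.endogenous
            },
            name="r2",
        )
        names = list(spec.variables)
        self.fit_ = SEMFit(
            spec=spec,
            n=int(n),
            params=params,
            B=pd.DataFrame(B, index=names, columns=names),
            psi=pd.DataFrame(Psi, index=names, columns=names),
            sigma=pd.DataFrame(Sigma, index=names, columns=names),
            sample_cov=pd.DataFrame(S, index=names, columns=names),
            fml=f_val,
            chi2=chi2,
            df=df,
            baseline_chi2=chi2_b,
            baseline_df=df_b,
            rmsea=rmsea,
            cfi=cfi,
            srmr=srmr,
            fit_pass={
                "rmsea": rmsea < 0.10,
                "cfi": cfi > 0.9,
                "srmr": srmr < 0.08,
            },
            r2=r2,
            converged=converged,
            grad_norm=grad_norm,
            notes=notes,
        )
        return self


def fit_path_model(spec, data: pd.DataFrame, n: int | None = None) -> SEMFit:
    """Fit a path model by ML; see :class:`PathModel`."""
    return PathModel(spec=spec).fit(data, n=n).fit_


def fit_indices(fit: SEMFit) -> dict:
    """Fit indices and acceptance flags (RMSEA < 0.10, CFI > 0.9, SRMR < 0.08)."""
    return {
        "chi2": fit.chi2,
        "df": fit.df,
        "rmsea": fit.rmsea,
        "cfi": fit.cfi,
        "srmr": fit.srmr,
        "pass": dict(fit.fit_pass),
        "acceptable": all(fit.fit_pass.values()),
    }


def rmsea_from_chi2(chi2: float, df: int, n: int) -> float:
    """Closed-form RMSEA = sqrt(max(chi2 - df, 0) / (df (n-1))); 0 when df=0."""
    if df == 0:
        return 0.0
    return float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))


def cfi_from_chi2(chi2: float, df: int, chi2_b: float, df_b: int) -> float:
    """CFI = 1 - max(chi2-df,0) / max(chi2_b-df_b, chi2-df, 0)."""
    num = max(chi2 - df, 0.0)
    den = max(chi2_b - df_b, chi2 - df, 0.0)
    return 1.0 if den == 0 else float(1.0 - num / den)


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _free_parameters(spec: PathModelSpec):
    """Free-parameter layout: one beta per directed edge; psi diagonal for
    every variable, psi off-diagonals for exogenous pairs and declared
    correlation edges."""
    idx = {v: i for i, v in enumerate(spec.variables)}
    free: list[tuple[str, int, int]] = []
    for s, t in spec.directed:
        free.append(("beta", idx[t], idx[s]))
    for v in spec.variables:
        free.append(("psi", idx[v], idx[v]))
    exo = set(spec.exogenous)
    seen = set()
    for i, a in enumerate(spec.variables):
        for b in spec.variables[i + 1:]:
            pair = tuple(sorted((a, b)))
            if pair in seen:
                continue
            if (a in exo and b in exo) or pair in set(spec.correlations):
                free.append(("psi", idx[pair[0]], idx[pair[1]]))
                seen.add(pair)
    return free


def _ols_start(spec, frame, S, free, idx):
    """Per-equation least-squares starting values."""
    p = len(spec.variables)
    B0 = np.zeros((p, p))
    resid = {}
    X_all = frame.to_numpy(dtype=float)
    for v in spec.endogenous:
        parents = spec.parents(v)
        yv = X_all[:, idx[v]]
        X = np.column_stack(
            [np.ones(len(yv))] + [X_all[:, idx[s]] for s in parents]
        )
        beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
        for k, s in enumerate(parents):
            B0[idx[v], idx[s]] = beta[k + 1]
        resid[v] = yv - X @ beta
    theta0 = []
    for kind, i, j in free:
        a, b = spec.variables[i], spec.variables[j]
        if kind == "beta":
            theta0.append(B0[i, j])
        elif i == j:
            if a in resid:
                theta0.append(float(np.var(resid[a], ddof=1)))
            else:
                theta0.append(S[i, i])
        else:
            if a in resid and b in resid:
                theta0.append(float(np.cov(resid[a], resid[b], ddof=1)[0, 1]))
            elif a in resid or b in resid:
                theta0.append(0.0)
            else:
                theta0.append(S[i, j])
    return np.asarray(theta0)


def _standard_errors(fml, theta, n, is_var):
    """SEs from the numerical Hessian of F_ML: ACOV = (2/(n-1)) H^-1.

    Finite-difference steps for variance terms stay strictly relative so a
    near-zero disturbance variance is never pushed negative.
    """
    k = len(theta)
    h = 1e-5 * np.maximum(1.0, np.abs(theta))
    h[is_var] = 1e-5 * np.maximum(np.abs(theta[is_var]), 1e-10)
    H = np.empty((k, k))
    f0 = fml(theta)
    # diagonal
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        H[i, i] = (fml(theta + ei) - 2 * f0 + fml(theta - ei)) / h[i] ** 2
    # off-diagonal
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        for j in range(i + 1, k):
            ej = np.zeros(k); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fml(theta + ei + ej) - fml(theta + ei - ej)
                - fml(theta - ei + ej) + fml(theta - ei - ej)
            ) / (4 * h[i] * h[j])
    try:
        acov = (2.0 / (n - 1)) * np.linalg.inv(H)
        var = np.diag(acov).copy()
    except np.linalg.LinAlgError:
        acov = (2.0 / (n - 1)) * np.linalg.pinv(H)
        var = np.diag(acov).copy()
    var[var < 0] = np.nan
    return np.sqrt(var)


def _fit_indices_from(chi2, df, chi2_b, df_b, n, S, Sigma):
    notes = []
    if df == 0:
        rmsea = 0.0
        notes.append("df = 0 (saturated model); RMSEA reported as 0")
    else:
        rmsea = rmsea_from_chi2(chi2, df, n)
    cfi = cfi_from_chi2(chi2, df, chi2_b, df_b)
    d = np.sqrt(np.diag(S))
    resid = (S - Sigma) / np.outer(d, d)
    iu = np.triu_indices_from(resid)
    srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))
    return rmsea, min(max(cfi, 0.0), 1.0), srmr, notes
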