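"""Second-order response-surface fitting, ANOVA diagnostics and optimization.

The model is the full quadratic polynomial in three process factors,

    y = b0 + sum_i bi*xi + sum_i bii*xi^2 + sum_{i<j} bij*xi*xj,

fitted by ordinary least squares in actual (uncoded) units.  The ANOVA
uses adjusted (drop-term) sums of squares throughout: the SS attributed
to a term or term group is the increase in residual SS when it is
removed from the full ten-term model, computed from the normal-equations
coefficient covariance rather than by refitting.  Residual error is
split into lack-of-fit (between distinct design points) and pure error
(within exact replicate sets), and model adequacy is judged by their
mean-square ratio.  Generalization is summarized by the PRESS statistic
(leave-one-out residuals via leverages) and the predicted R^2 derived
from it.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize as sp_optimize
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .doe import DesignTable, encode

__all__ = [
    "QuadraticResponseSurface",
    "FitSummary",
    "OptimizationResult",
    "fit_quadratic",
    "term_names",
]

_PAIRS = ((0, 1), (0, 2), (1, 2))


def term_names(feature_names) -> list[str]:
    """Names of the 10 polynomial terms for the given feature names."""
    f = list(feature_names)
    return (
        ["intercept"]
        + f
        + [f"{n}^2" for n in f]
        + [f"{f[i]}*{f[j]}" for i, j in _PAIRS]
    )


def _expand(X: np.ndarray) -> np.ndarray:
    """Build the 10-column second-order model matrix for 3 features."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError(f"expected an (n, 3) array of factor levels, got shape {X.shape}")
    x1, x2, x3 = X.T
    return np.column_stack(
        [np.ones(len(X)), x1, x2, x3, x1 ** 2, x2 ** 2, x3 ** 2, x1 * x2, x1 * x3, x2 * x3]
    )


@dataclass(frozen=True)
class FitSummary:
    """Goodness-of-fit summary of a quadratic response-surface fit."""

    r_squared: float
    adj_r_squared: float
    pred_r_squared: float
    root_mse: float
    press: float


@dataclass(frozen=True)
class OptimizationResult:
    """Constrained optimum of a response surface over a factor box."""

    actual: tuple
    coded: tuple          # NaNs when no factor definitions are attached
    predicted: float
    boundary: tuple       # per factor: "interior" | "at-low" | "at-high"
    classification: str   # "maximum" | "minimum" | "saddle" | "boundary"


class QuadraticResponseSurface(RegressorMixin, BaseEstimator):
    """Full second-order polynomial regression in three factors.

    Follows the scikit-learn estimator protocol: :meth:`fit` on an
    ``(n, 3)`` array of factor levels and a response vector, then
    :meth:`predict`; ANOVA, summary statistics, surface grids and the
    constrained optimum are exposed as post-fit methods.

    Parameters
    ----------
    unit_space : {"actual", "coded"}
        Label recording which unit system the training features are in.
        It does not change the computation — predictions must simply be
        requested in the same space the model was fitted in.

    Attributes
    ----------
    coef_ : ndarray of shape (9,)
        Linear, quadratic and interaction coefficients (no intercept),
        ordered x1, x2, x3, x1^2, x2^2, x3^2, x1*x2, x1*x3, x2*x3.
    intercept_ : float
    coefficients_ : pandas.Series
        All ten coefficients indexed by term name.
    residual_variance_ : float
        SSE / (n - 10), the model-independent error variance estimate.
    leverage_ : ndarray
        Hat-matrix diagonal of the training runs.
    """

    def __init__(self, unit_space: str = "actual"):
        self.unit_space = unit_space

    # ------------------------------------------------------------------ fit

    def fit(self, X, y):
        if self.unit_space not in ("actual", "coded"):
            raise ValueError(f"unit_space must be 'actual' or 'coded', got {self.unit_space!r}")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.isnan(y).any() or not np.isfinite(X).all():
            raise ValueError("factor levels and responses must be finite and complete")
        M = _expand(X)
        n = len(y)
        if n < 10:
            raise ValueError(f"need at least 10 runs to fit the 10-term model, got {n}")
        if np.linalg.matrix_rank(M) < 10:
            raise np.linalg.LinAlgError(
                "singular design: the second-order model matrix is rank deficient"
            )
        res = sm.OLS(y, M).fit()
        self.n_features_in_ = 3
        self.X_, self.y_ = X, y
        self.ols_result_ = res
        beta = res.params
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        names = term_names(getattr(self, "feature_names_", ("x1", "x2", "x3")))
        self.coefficients_ = pd.Series(beta, index=names)
        self.fitted_values_ = res.fittedvalues
        self.residuals_ = res.resid
        self.leverage_ = np.diag(M @ np.linalg.solve(M.T @ M, M.T))
        self.sse_ = float(res.ssr)
        self.sst_ = float(((y - y.mean()) ** 2).sum())
        self.ssm_ = self.sst_ - self.sse_
        self.df_error_ = n - 10
        self.residual_variance_ = self.sse_ / self.df_error_ if self.df_error_ > 0 else np.nan
        # unscaled coefficient covariance (X'X)^-1, for drop-term SS
        self._xtx_inv = np.linalg.inv(M.T @ M)
        if self.df_error_ > 0:
            self.standard_errors_ = np.sqrt(
                self.residual_variance_ * np.diag(self._xtx_inv)
            )
        return self

    # -------------------------------------------------------------- predict

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        if single:
            X = X[None, :]
        if not np.isfinite(X).all():
            raise ValueError("prediction points must be finite")
        lo, hi = self.X_.min(axis=0), self.X_.max(axis=0)
        if np.any(X < lo) or np.any(X > hi):
            warnings.warn("predicting outside the fitted design box (extrapolation)")
        out = _expand(X) @ np.concatenate([[self.intercept_], self.coef_])
        return float(out[0]) if single else out

    # ---------------------------------------------------------------- anova

    def _drop_term_ss(self, idx) -> float:
        """Adjusted SS of the coefficient subset ``idx`` (model-matrix columns)."""
        idx = list(idx)
        beta = np.concatenate([[self.intercept_], self.coef_])[idx]
        C = self._xtx_inv[np.ix_(idx, idx)]
        return float(beta @ np.linalg.solve(C, beta))

    def anova(self) -> pd.DataFrame:
        """Full ANOVA with term, group, lack-of-fit and pure-error rows.

        Rows carry a ``kind`` column (model / group / term / error /
        lack-of-fit / pure-error / total).  F for model, groups and terms
        is MS over the residual MS; lack-of-fit F is its MS over the
        pure-error MS.  When no runs are replicated the lack-of-fit and
        pure-error rows are absent.
        """
        check_is_fitted(self, "coef_")
        n = len(self.y_)
        if self.df_error_ < 1:
            raise ValueError("no residual degrees of freedom: ANOVA unavailable")
        mse = self.residual_variance_
        names = term_names(getattr(self, "feature_names_", ("x1", "x2", "x3")))

        rows = []

        def add(source, kind, df, ss, denom_ms=None, denom_df=None):
            ms = ss / df if df > 0 else np.nan
            if denom_ms is None:
                f = p = np.nan
            else:
                f = ms / denom_ms
                p = float(stats.f.sf(f, df, denom_df))
            rows.append((source, kind, df, ss, ms, f, p))

        add("model", "model", 9, self.ssm_, mse, self.df_error_)
        groups = {"linear": [1, 2, 3], "square": [4, 5, 6], "two-way interaction": [7, 8, 9]}
        for gname, idx in groups.items():
            add(gname, "group", 3, self._drop_term_ss(idx), mse, self.df_error_)
            for i in idx:
                add(names[i], "term", 1, self._drop_term_ss([i]), mse, self.df_error_)
        add("error", "error", self.df_error_, self.sse_)

        # replicate split: exact equality of factor-level rows
        _, inverse = np.unique(self.X_, axis=0, return_inverse=True)
        group_means = np.bincount(inverse, weights=self.y_) / np.bincount(inverse)
        ss_pe = float(((self.y_ - group_means[inverse]) ** 2).sum())
        df_pe = n - len(group_means)
        if df_pe > 0:
            ss_lof = self.sse_ - ss_pe
            df_lof = self.df_error_ - df_pe
            ms_pe = ss_pe / df_pe
            ms_lof = ss_lof / df_lof if df_lof > 0 else np.nan
            f_lof = ms_lof / ms_pe
            p_lof = float(stats.f.sf(f_lof, df_lof, df_pe))
            rows.append(("lack-of-fit", "lack-of-fit", df_lof, ss_lof, ms_lof, f_lof, p_lof))
            rows.append(("pure error", "pure-error", df_pe, ss_pe, ms_pe, np.nan, np.nan))
        rows.append(("total", "total", n - 1, self.sst_, np.nan, np.nan, np.nan))

        return pd.DataFrame(rows, columns=["source", "kind", "df", "ss", "ms", "F", "p"])

    # -------------------------------------------------------------- summary

    def summary(self) -> FitSummary:
        """R^2, adjusted R^2, PRESS and the PRESS-based predicted R^2."""
        check_is_fitted(self, "coef_")
        if self.df_error_ < 1:
            raise ValueError("no residual degrees of freedom: summary unavailable")
        if np.any(self.leverage_ > 1 - 1e-10):
            raise ValueError("a run has leverage 1: PRESS is undefined")
        n = len(self.y_)
        press = float(((self.residuals_ / (1 - self.leverage_)) ** 2).sum())
        return FitSummary(
            r_squared=self.ssm_ / self.sst_,
            adj_r_squared=1 - self.residual_variance_ / (self.sst_ / (n - 1)),
            pred_r_squared=1 - press / self.sst_,
            root_mse=float(np.sqrt(self.residual_variance_)),
            press=press,
        )

    # ------------------------------------------------------------- optimize

    def _quadratic_parts(self):
        b = self.coef_
        lin = b[:3]
        A = np.array(
            [
                [2 * b[3], b[6], b[7]],
                [b[6], 2 * b[4], b[8]],
                [b[7], b[8], 2 * b[5]],
            ]
        )  # Hessian of the surface
        return lin, A

    def optimize(self, bounds, direction: str = "maximize") -> OptimizationResult:
        """Global optimum of the fitted quadratic over a factor box.

        Deterministic multi-start local search: the 8 box vertices, the
        box center and the unconstrained stationary point (clipped to the
        box) each seed an L-BFGS-B refinement; the best local optimum is
        returned, ties broken by first-found at 1e-8 relative tolerance.
        """
        check_is_fitted(self, "coef_")
        if direction not in ("maximize", "minimize"):
            raise ValueError("direction must be 'maximize' or 'minimize'")
        bounds = [(float(lo), float(hi)) for lo, hi in bounds]
        if len(bounds) != 3 or not all(np.isfinite(b).all() and b[0] < b[1] for b in map(np.asarray, bounds)):
            raise ValueError("bounds must be three finite (low, high) pairs")
        sign = -1.0 if direction == "maximize" else 1.0
        beta = np.concatenate([[self.intercept_], self.coef_])

        def objective(x):
            return sign * float(_expand(x[None, :])[0] @ beta)

        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        starts = [np.array(v, dtype=float) for v in itertools.product(*bounds)]
        starts.append((lo + hi) / 2)
        lin, A = self._quadratic_parts()
        stationary = None
        if np.linalg.matrix_rank(A) == 3:
            stationary = np.linalg.solve(A, -lin)
            starts.append(np.clip(stationary, lo, hi))

        best_x, best_val = None, np.inf
        for s in starts:
            res = sp_optimize.minimize(
                objective, s, method="L-BFGS-B", bounds=bounds,
                options={"ftol": 1e-14, "gtol": 1e-10},
            )
            # first-found wins among optima equal to 1e-8 relative tolerance
            if best_x is None or res.fun < best_val - 1e-8 * max(1.0, abs(best_val)):
                best_x, best_val = res.x, res.fun

        predicted = sign * best_val
        tol = 1e-6 * (hi - lo)
        flags = tuple(
            "at-low" if x - l <= t else "at-high" if h - x <= t else "interior"
            for x, l, h, t in zip(best_x, lo, hi, tol)
        )
        if any(f != "interior" for f in flags):
            classification = "boundary"
        else:
            eig = np.linalg.eigvalsh(A)
            if np.all(eig < 0):
                classification = "maximum"
            elif np.all(eig > 0):
                classification = "minimum"
            else:
                classification = "saddle"

        coded = (np.nan,) * 3
        factors = getattr(self, "factors_", None)
        if factors is not None and self.unit_space == "actual":
            in_range = all(f.low <= x <= f.high for f, x in zip(factors, best_x))
            if in_range:
                coded = tuple(encode(best_x, factors))
        return OptimizationResult(
            actual=tuple(float(v) for v in best_x),
            coded=coded,
            predicted=float(predicted),
            boundary=flags,
            classification=classification,
        )

    # --------------------------------------------------------- surface grid

    def surface_grid(self, vary, fix, resolution=50, bounds=None) -> pd.DataFrame:
        """Plot-ready rectangular grid of predictions over two factors.

        Parameters
        ----------
        vary : pair of feature names (or indices) spanning the grid.
        fix : mapping of the remaining feature to its fixed level.
        resolution : int or (int, int)
            Nodes along each varied axis.
        bounds : optional mapping feature -> (low, high); defaults to the
            fitted design's observed range.
        """
        check_is_fitted(self, "coef_")
        names = list(getattr(self, "feature_names_", ("x1", "x2", "x3")))
        try:
            vi = [v if isinstance(v, int) else names.index(v) for v in vary]
            fix_items = {(k if isinstance(k, int) else names.index(k)): v for k, v in fix.items()}
        except ValueError as exc:
            raise ValueError(f"unknown factor name in {vary!r} / {fix!r}: {exc}") from None
        if len(vi) != 2 or len(fix_items) != 1 or set(vi) | set(fix_items) != {0, 1, 2}:
            raise ValueError("vary must name two factors and fix the remaining one")
        res = np.broadcast_to(np.asarray(resolution, dtype=int), (2,))
        if np.any(res < 1):
            raise ValueError("resolution must be >= 1 per axis")
        lo, hi = self.X_.min(axis=0), self.X_.max(axis=0)
        if bounds:
            for k, (l, h) in bounds.items():
                k = k if isinstance(k, int) else names.index(k)
                lo[k], hi[k] = l, h
        axes = [
            np.linspace(lo[i], hi[i], r) if r > 1 else np.array([(lo[i] + hi[i]) / 2])
            for i, r in zip(vi, res)
        ]
        xx, yy = np.meshgrid(*axes, indexing="ij")
        pts = np.empty((xx.size, 3))
        pts[:, vi[0]] = xx.ravel()
        pts[:, vi[1]] = yy.ravel()
        (fk, fv), = fix_items.items()
        pts[:, fk] = fv
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z = self.predict(pts)
        out = pd.DataFrame(
            {names[vi[0]]: xx.ravel(), names[vi[1]]: yy.ravel(), "predicted": z}
        )
        out.attrs["fixed"] = {names[fk]: fv}
        out.attrs["shape"] = tuple(int(r) for r in res)
        return out


def fit_quadratic(
    design: DesignTable, response_column: str, unit_space: str = "actual"
) -> QuadraticResponseSurface:
    """Fit the quadratic surface to a design table's response column."""
    y = design.response(response_column)
    X = design.actual if unit_space == "actual" else design.coded
    model = QuadraticResponseSurface(unit_space=unit_space)
    model.feature_names_ = tuple(f.name for f in design.factors)
    model.factors_ = design.factors
    return model.fit(X, y)
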