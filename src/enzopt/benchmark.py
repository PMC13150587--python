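"""Kernel and ensemble regression benchmark over augmented design data.

Three regressor families are compared as surrogates for the response
surface: support vector regression with an RBF kernel (hyperparameters
chosen by seeded grid search with internal 5-fold CV), Gaussian-process
regression with a squared-exponential kernel plus a learned noise term,
and random-forest regression.  Features are the three actual-unit factor
levels; kernel methods standardize them internally (scaler fitted on the
training split only), trees use raw features.  Skill is summarized by
R^2 and RMSE per split, by Taylor-diagram statistics (standard
deviations, correlation, centered RMSE), and by the model's predicted
optimum over the factor box, located by dense grid search since tree and
kernel surfaces are not usefully differentiable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .rsm import OptimizationResult

__all__ = [
    "FAMILIES",
    "ModelSpec",
    "PredictorHandle",
    "ModelMetrics",
    "TaylorStats",
    "train",
    "evaluate",
    "taylor_statistics",
    "search_optimum",
    "run_benchmark",
]

FAMILIES = ("svr-rbf", "gpr-se", "rfr")


@dataclass(frozen=True)
class ModelSpec:
    """One regressor family with its hyperparameters and seed."""

    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; choose from {FAMILIES}")

    @property
    def scale_features(self) -> bool:
        return self.family in ("svr-rbf", "gpr-se")


@dataclass
class PredictorHandle:
    """A trained regressor plus its training provenance."""

    estimator: object
    spec: ModelSpec
    resolved_hyperparameters: dict
    train_fingerprint: str
    degenerate: bool = False

    def predict(self, X):
        return self.estimator.predict(np.asarray(X, dtype=float))


@dataclass(frozen=True)
class ModelMetrics:
    r_squared: float  # NaN when targets are constant (undefined)
    rmse: float
    label: str = ""


@dataclass(frozen=True)
class TaylorStats:
    """Taylor-diagram coordinates for one prediction/reference pair.

    Uses the population (divide-by-n) standard deviation convention.
    The centered RMSE obeys the law-of-cosines identity
    crmse^2 = sd_pred^2 + sd_ref^2 - 2 sd_pred sd_ref rho.
    """

    sd_ref: float
    sd_pred: float
    correlation: float  # NaN when either series has zero variance
    centered_rmse: float


def _fingerprint(X, y) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X, dtype=float).tobytes())
    h.update(np.ascontiguousarray(y, dtype=float).tobytes())
    return h.hexdigest()[:16]


def _build_svr(hp: dict, y: np.ndarray, seed: int):
    y_sd = float(np.std(y))
    fixed = {k: hp[k] for k in ("C", "gamma", "epsilon") if k in hp}
    if len(fixed) == 3:
        est = SVR(kernel="rbf", **fixed)
        grid = None
    else:
        # gamma grid = {0.5, 1, 2} x the 'scale' heuristic, which is
        # 1/(n_features * var) = 1/3 on standardized 3-feature inputs
        grid = {
            "svr__C": hp.get("C_grid", [1.0, 10.0, 100.0]),
            "svr__gamma": hp.get("gamma_grid", [0.5 / 3, 1.0 / 3, 2.0 / 3]),
            "svr__epsilon": hp.get(
                "epsilon_grid", [0.01 * y_sd, 0.1 * y_sd, 1.0 * y_sd]
            ),
        }
        est = SVR(kernel="rbf")
    pipe = Pipeline([("scale", StandardScaler()), ("svr", est)])
    if grid is None:
        return pipe, fixed
    cv = KFold(n_splits=hp.get("cv_folds", 5), shuffle=True, random_state=seed)
    return GridSearchCV(pipe, grid, cv=cv, scoring="neg_mean_squared_error"), None


def _build_gpr(hp: dict, seed: int):
    kernel = ConstantKernel(1.0, (1e-3, 1e4)) * RBF(
        length_scale=hp.get("length_scale", 1.0), length_scale_bounds=(1e-2, 1e3)
    ) + WhiteKernel(noise_level=hp.get("noise_level", 1.0), noise_level_bounds=(1e-8, 1e4))
    gpr = GaussianProcessRegressor(
        kernel=kernel,
        n_restarts_optimizer=hp.get("n_restarts", 5),
        normalize_y=True,
        random_state=seed,
    )
    return Pipeline([("scale", StandardScaler()), ("gpr", gpr)])


def _build_rfr(hp: dict, seed: int):
    return RandomForestRegressor(
        n_estimators=hp.get("n_estimators", 100),
        max_depth=hp.get("max_depth", None),
        bootstrap=hp.get("bootstrap", True),
        random_state=seed,
    )


def train(spec: ModelSpec, X, y) -> PredictorHandle:
    """Fit one regressor family on a training set of (factor levels, response)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(X) == 0:
        raise ValueError("training set is empty")
    degenerate = bool(np.ptp(y) == 0)
    hp = dict(spec.hyperparameters)
    resolved = dict(hp)
    if spec.family == "svr-rbf":
        est, fixed = _build_svr(hp, y, spec.seed)
        est.fit(X, y)
        if fixed is None:  # grid search: record the selected point
            est_best = est.best_estimator_
            resolved.update(
                {k: est.best_params_[f"svr__{k}"] for k in ("C", "gamma", "epsilon")}
            )
            est = est_best
        else:
            resolved.update(fixed)
    elif spec.family == "gpr-se":
        est = _build_gpr(hp, spec.seed)
        est.fit(X, y)
        resolved["kernel_"] = str(est.named_steps["gpr"].kernel_)
    else:
        est = _build_rfr(hp, spec.seed)
        est.fit(X, y)
        resolved.setdefault("n_estimators", est.n_estimators)
    return PredictorHandle(
        estimator=est,
        spec=spec,
        resolved_hyperparameters=resolved,
        train_fingerprint=_fingerprint(X, y),
        degenerate=degenerate,
    )


def evaluate(handle: PredictorHandle, X, y, label: str = "") -> ModelMetrics:
    """R^2 and RMSE of a trained model on a labelled dataset."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) == 0:
        raise ValueError("evaluation set is empty")
    pred = handle.predict(X)
    rmse = float(np.sqrt(mean_squared_error(y, pred)))
    r2 = float(r2_score(y, pred)) if np.ptp(y) > 0 else float("nan")
    return ModelMetrics(r_squared=r2, rmse=rmse, label=label)


def taylor_statistics(predictions, references) -> TaylorStats:
    """Taylor-diagram statistics of predictions against references."""
    p = np.asarray(predictions, dtype=float)
    r = np.asarray(references, dtype=float)
    if p.shape != r.shape or p.ndim != 1 or len(p) < 2:
        raise ValueError("predictions and references must be equal-length 1-d, length >= 2")
    sd_p, sd_r = float(np.std(p)), float(np.std(r))
    pc, rc = p - p.mean(), r - r.mean()
    crmse = float(np.sqrt(np.mean((pc - rc) ** 2)))
    if sd_p == 0 or sd_r == 0:
        rho = float("nan")
    else:
        rho = float(np.mean(pc * rc) / (sd_p * sd_r))
    return TaylorStats(sd_ref=sd_r, sd_pred=sd_p, correlation=rho, centered_rmse=crmse)


def search_optimum(
    handle,
    bounds,
    resolution: int = 101,
    direction: str = "maximize",
    chunk: int = 200_000,
) -> OptimizationResult:
    """Dense-grid optimum of a trained model's surface over a factor box.

    Evaluates the model on a ``resolution^3`` lattice; ties are broken by
    the lowest lexicographic coordinates.  ``chunk`` bounds memory for
    expensive predictors (the grid is streamed through ``predict``).
    """
    if direction not in ("maximize", "minimize"):
        raise ValueError("direction must be 'maximize' or 'minimize'")
    bounds = [(float(lo), float(hi)) for lo, hi in bounds]
    if len(bounds) != 3 or not all(np.isfinite(b).all() and b[0] < b[1] for b in map(np.asarray, bounds)):
        raise ValueError("bounds must be three finite (low, high) pairs")
    if resolution < 2:
        raise ValueError("resolution must be >= 2 per axis")
    axes = [np.linspace(lo, hi, resolution) for lo, hi in bounds]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([m.ravel() for m in mesh])  # C-order = lexicographic
    sign = -1.0 if direction == "minimize" else 1.0
    best_val, best_idx = -np.inf, 0
    for start in range(0, len(pts), chunk):
        block = pts[start : start + chunk]
        vals = sign * np.asarray(handle.predict(block), dtype=float)
        i = int(np.argmax(vals))  # argmax returns the first (lowest-lex) maximum
        if vals[i] > best_val:
            best_val, best_idx = float(vals[i]), start + i
    x = pts[best_idx]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    flags = tuple(
        "at-low" if xi == l else "at-high" if xi == h else "interior"
        for xi, l, h in zip(x, lo, hi)
    )
    return OptimizationResult(
        actual=tuple(float(v) for v in x),
        coded=(np.nan,) * 3,
        predicted=sign * best_val,
        boundary=flags,
        classification="boundary" if any(f != "interior" for f in flags) else "grid-interior",
    )


def run_benchmark(
    train_set: pd.DataFrame,
    test_set: pd.DataFrame,
    feature_columns,
    response_column: str = "response",
    specs=None,
    seed: int = 0,
    bounds=None,
    resolution: int = 101,
) -> dict:
    """Train, evaluate and (optionally) optimize every model family.

    Returns a report dict: per family, train/test metrics, Taylor
    statistics for both splits, the grid optimum when ``bounds`` is
    given, and provenance (spec, seed, resolved hyperparameters).
    """
    if specs is None:
        specs = [ModelSpec(family=f, seed=seed) for f in FAMILIES]
    feature_columns = list(feature_columns)
    Xtr = train_set[feature_columns].to_numpy(float)
    ytr = train_set[response_column].to_numpy(float)
    Xte = test_set[feature_columns].to_numpy(float)
    yte = test_set[response_column].to_numpy(float)
    report = {"seed": seed, "features": feature_columns, "models": {}}
    for spec in specs:
        handle = train(spec, Xtr, ytr)
        entry = {
            "spec": {"family": spec.family, "seed": spec.seed,
                     "hyperparameters": dict(spec.hyperparameters)},
            "resolved_hyperparameters": {
                k: v for k, v in handle.resolved_hyperparameters.items()
            },
            "metrics": {
                "train": evaluate(handle, Xtr, ytr, "train").__dict__,
                "test": evaluate(handle, Xte, yte, "test").__dict__,
            },
            "taylor": {
                "train": taylor_statistics(handle.predict(Xtr), ytr).__dict__,
                "test": taylor_statistics(handle.predict(Xte), yte).__dict__,
            },
        }
        if bounds is not None:
            opt = search_optimum(handle, bounds, resolution=resolution)
            entry["optimum"] = {
                "actual": opt.actual,
                "predicted": opt.predicted,
                "boundary": opt.boundary,
            }
        report["models"][spec.family] = entry
    return report


def metrics_table(report: dict) -> pd.DataFrame:
    """Flatten a benchmark report into a (model, process, R2, RMSE) table."""
    rows = []
    for family, entry in report["models"].items():
        for label in ("train", "test"):
            m = entry["metrics"][label]
            rows.append((family, label, m["r_squared"], m["rmse"]))
    return pd.DataFrame(rows, columns=["model", "process", "r_squared", "rmse"])
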