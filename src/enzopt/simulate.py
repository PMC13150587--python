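"""Synthetic data generators matching the pipeline's input structure.

Every stage of the analysis can be exercised without laboratory data:

* :func:`simulate_bbd_dataset` draws replicated Box-Behnken responses
  from a known quadratic truth surface plus zero-mean Gaussian replicate
  noise.  The default truth is the bundled experiment's published
  coefficient vector, and the default noise SD (37.3 U g^-1) is the
  square root of that experiment's pure-error mean square, i.e. the
  replicate variability actually observed at the center point.
* :func:`simulate_decay` draws activity-time series from first-order
  decay with multiplicative log-normal noise.
* :func:`simulate_reuse_profile` draws per-cycle activities from a
  geometric retention model.

Replicate noise is Gaussian here even though the augmentation stage
injects uniform noise: the generator models lab replicate error, while
augmentation reproduces a described resampling procedure.  Negative
simulated activities are floored at zero and flagged (not resampled) so
the noise model stays simple and the flooring is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import AMYLASE_FACTORS, REPORTED_COEFFICIENTS
from .doe import DesignTable, generate_bbd
from .rsm import _expand

__all__ = [
    "TruthSurface",
    "simulate_bbd_dataset",
    "simulate_decay",
    "simulate_reuse_profile",
]

#: sqrt of the bundled experiment's pure-error mean square (1393).
DEFAULT_NOISE_SD = float(np.sqrt(1393.0))


@dataclass(frozen=True)
class TruthSurface:
    """A known quadratic response surface plus replicate noise level.

    ``coefficients`` are the 10 polynomial coefficients in actual units
    (intercept; linear; quadratic; interactions), defaulting to the
    bundled experiment's published values; ``noise_sd`` is the replicate
    standard deviation in response units.
    """

    coefficients: tuple = REPORTED_COEFFICIENTS
    factors: tuple = AMYLASE_FACTORS
    noise_sd: float = DEFAULT_NOISE_SD

    def __post_init__(self):
        if len(self.coefficients) != 10:
            raise ValueError("a quadratic truth surface needs exactly 10 coefficients")
        if not (self.noise_sd >= 0):
            raise ValueError("noise_sd must be >= 0")

    def predict(self, X) -> np.ndarray:
        return _expand(np.asarray(X, dtype=float)) @ np.asarray(self.coefficients)


def simulate_bbd_dataset(
    truth: TruthSurface = TruthSurface(),
    n_replicates: int = 3,
    center_points: int = 3,
    seed=None,
) -> pd.DataFrame:
    """Replicated BBD responses from a truth surface with Gaussian noise.

    Returns a replicate table (columns ``run``, one actual-unit column
    per factor, ``replicate``, ``response``) with ``n_replicates`` rows
    per design run.  Negative draws are floored at 0;
    ``frame.attrs["floored"]`` counts them.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    design = generate_bbd(truth.factors, center_points=center_points)
    rng = np.random.default_rng(seed)
    X = design.actual
    mu = truth.predict(X)
    n_runs = len(mu)
    draws = mu[:, None] + rng.normal(0.0, truth.noise_sd, size=(n_runs, n_replicates))
    floored = int((draws < 0).sum())
    draws = np.maximum(draws, 0.0)
    frame = pd.DataFrame(
        {
            "run": np.repeat(design.frame["run"].to_numpy(), n_replicates),
            **{
                f.name: np.repeat(X[:, j], n_replicates)
                for j, f in enumerate(truth.factors)
            },
            "replicate": np.tile(np.arange(1, n_replicates + 1), n_runs),
            "response": draws.ravel(),
        }
    )
    frame.attrs["floored"] = floored
    frame.attrs["seed"] = seed
    return frame


def replicate_means_design(replicates: pd.DataFrame, factors) -> DesignTable:
    """Collapse a replicate table to per-run mean responses as a DesignTable."""
    factor_cols = [f.name for f in factors]
    means = (
        replicates.groupby(["run"] + factor_cols, as_index=False)["response"].mean()
    )
    from .doe import encode  # local import to avoid cycle at module load

    coded = encode(means[factor_cols].to_numpy(float), factors)
    data = {"run": means["run"].to_numpy()}
    for j, f in enumerate(factors):
        data[f"{f.name}_coded"] = coded[:, j]
        data[f"{f.name}_actual"] = means[f.name].to_numpy(float)
    data["response"] = means["response"].to_numpy(float)
    return DesignTable(frame=pd.DataFrame(data), factors=tuple(factors))


def simulate_decay(
    kd: float, a0: float, times, noise_sd: float = 0.0, seed=None
) -> pd.DataFrame:
    """Activity-time series A(t) = A0 exp(-kd t) exp(eps), eps ~ N(0, sd)."""
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if kd < 0 or a0 <= 0:
        raise ValueError("need kd >= 0 and a0 > 0")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd, size=len(t)) if noise_sd > 0 else np.zeros(len(t))
    activity = a0 * np.exp(-kd * t) * np.exp(eps)
    return pd.DataFrame({"time_h": t, "activity": activity})


def simulate_reuse_profile(
    retention: float, cycles: int, noise_sd: float = 0.0, seed=None
) -> pd.DataFrame:
    """Per-cycle activities under geometric decay with multiplicative noise.

    Cycle 1 is the reference; noise-free residual activity after cycle n
    is 100 * retention^(n-1) percent.
    """
    if not 0 < retention <= 1:
        raise ValueError("retention must be in (0, 1]")
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    rng = np.random.default_rng(seed)
    n = np.arange(cycles)
    base = retention ** n
    eps = rng.normal(0.0, noise_sd, size=cycles) if noise_sd > 0 else np.zeros(cycles)
    activity = 100.0 * base * np.exp(eps)
    return pd.DataFrame({"cycle": n + 1, "activity": activity})
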