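"""Immobilization bookkeeping and first-order deactivation kinetics.

Covers the standard quantities of an enzyme immobilization study:

* immobilized enzyme amount IE = V (Ci - Cf) / m, the protein depleted
  from solution per gram of support (mg g^-1 of beads);
* specific activity EA / IE of the bound enzyme;
* immobilization yield IY = 100 (EA0 - EAf) / EA0, the fraction of
  initial solution activity removed by binding;
* first-order thermal deactivation A(t) = A0 exp(-kd t), fitted as an
  unweighted least-squares line on (t, ln A); half-life t1/2 = ln 2 / kd
  and the stabilization factor SF = t1/2(immobilized) / t1/2(free);
* per-cycle residual activity, cycle 1 defined as 100 %.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ImmobilizationRecord",
    "DeactivationFit",
    "StabilityComparison",
    "CycleProfile",
    "immobilized_amount",
    "specific_activity",
    "immobilization_yield",
    "FirstOrderDeactivation",
    "fit_deactivation",
    "stabilization_factor",
    "cycle_profile",
]


@dataclass(frozen=True)
class ImmobilizationRecord:
    """Raw measurements of one binding experiment.

    Units: V in mL, protein concentrations Ci/Cf in mg mL^-1, support
    mass m in g, activities EA (beads), EA0/EAf (solution) in U g^-1.
    """

    V: float
    Ci: float
    Cf: float
    m: float
    EA: float = math.nan
    EA0: float = math.nan
    EAf: float = math.nan

    def __post_init__(self):
        for name in ("V", "Ci", "Cf", "m"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


def immobilized_amount(record: ImmobilizationRecord) -> tuple[float, str]:
    """Immobilized enzyme per gram of support: IE = V (Ci - Cf) / m.

    Returns ``(value, unit)`` with unit ``"mg/g"`` (mL x mg/mL / g).  A
    final concentration above the initial one indicates negative binding
    and is flagged with a warning, not an error.
    """
    if record.m == 0:
        raise ZeroDivisionError("support mass m must be positive")
    if record.Cf > record.Ci:
        warnings.warn("Cf > Ci: negative apparent binding", stacklevel=2)
    return record.V * (record.Ci - record.Cf) / record.m, "mg/g"


def specific_activity(EA: float, IE: float) -> float:
    """Bound-enzyme specific activity EA / IE (units propagate from inputs)."""
    if IE == 0:
        raise ZeroDivisionError("IE = 0: specific activity undefined")
    return EA / IE


def immobilization_yield(EA0: float, EAf: float) -> float:
    """Percentage of initial solution activity captured: 100 (EA0 - EAf)/EA0."""
    if EA0 == 0:
        raise ZeroDivisionError("EA0 = 0: yield undefined")
    if EAf > EA0:
        warnings.warn("EAf > EA0: negative apparent yield", stacklevel=2)
    return (EA0 - EAf) * 100.0 / EA0


@dataclass(frozen=True)
class DeactivationFit:
    """First-order deactivation parameters from a log-linear fit."""

    kd: float            # h^-1; 0 for a non-decaying series
    half_life: float     # h; ln2/kd, inf when kd == 0
    log_intercept: float
    r_squared: float
    n_used: int
    time_window: tuple


@dataclass(frozen=True)
class StabilityComparison:
    free: DeactivationFit
    immobilized: DeactivationFit
    sf: float


@dataclass(frozen=True)
class CycleProfile:
    activities: tuple
    residual_percent: tuple  # residual_percent[0] == 100 exactly


class FirstOrderDeactivation:
    """Estimator for the single-exponential decay A(t) = A0 exp(-kd t).

    ``fit(times, activities)`` regresses ln A on t by unweighted least
    squares; non-positive activities are excluded with a warning (their
    logarithm is undefined).  Fitted attributes: ``kd_``, ``half_life_``,
    ``log_intercept_``, ``r_squared_``; :meth:`result` packages them.
    """

    def fit(self, times, activities):
        t = np.asarray(times, dtype=float)
        a = np.asarray(activities, dtype=float)
        if t.ndim != 1 or t.shape != a.shape:
            raise ValueError("times and activities must be equal-length 1-d arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        usable = a > 0
        if not usable.all():
            warnings.warn(
                f"excluding {int((~usable).sum())} non-positive activity point(s)",
                stacklevel=2,
            )
        t, a = t[usable], a[usable]
        if len(t) < 3:
            raise ValueError("need at least 3 positive activity points")
        res = stats.linregress(t, np.log(a))
        self.kd_ = max(0.0, -float(res.slope))
        self.half_life_ = math.log(2) / self.kd_ if self.kd_ > 0 else math.inf
        self.log_intercept_ = float(res.intercept)
        self.r_squared_ = float(res.rvalue) ** 2
        self.n_used_ = len(t)
        self.time_window_ = (float(t[0]), float(t[-1]))
        return self

    def result(self) -> DeactivationFit:
        return DeactivationFit(
            kd=self.kd_,
            half_life=self.half_life_,
            log_intercept=self.log_intercept_,
            r_squared=self.r_squared_,
            n_used=self.n_used_,
            time_window=self.time_window_,
        )


def fit_deactivation(times, activities) -> DeactivationFit:
    """Fit first-order deactivation; see :class:`FirstOrderDeactivation`."""
    return FirstOrderDeactivation().fit(times, activities).result()


def stabilization_factor(
    free: DeactivationFit, immobilized: DeactivationFit
) -> StabilityComparison:
    """SF = half-life(immobilized) / half-life(free)."""
    if not (free.half_life > 0):
        raise ValueError("free half-life must be positive for SF")
    if math.isinf(free.half_life):
        raise ValueError("free enzyme does not decay: SF undefined")
    return StabilityComparison(
        free=free, immobilized=immobilized, sf=immobilized.half_life / free.half_life
    )


def cycle_profile(activities) -> CycleProfile:
    """Residual activity per reuse cycle, relative to cycle 1 (= 100 %)."""
    a = np.asarray(activities, dtype=float)
    if a.ndim != 1 or len(a) < 1:
        raise ValueError("need at least one cycle activity")
    if a[0] <= 0:
        raise ValueError("cycle-1 activity must be positive")
    residual = 100.0 * a / a[0]
    residual[0] = 100.0
    return CycleProfile(activities=tuple(a), residual_percent=tuple(residual))
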