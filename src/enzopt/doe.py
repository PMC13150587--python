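"""Three-level Box-Behnken designs and coded/actual unit conversion.

A Box-Behnken design (BBD) for three factors consists of the 12 edge
midpoints of the factor cube (every +/-1 combination over each factor
pair, third factor at its center) plus replicated center points.  Factor
levels are handled in two unit systems: *coded* units, where the three
levels of each factor are labelled -1 / 0 / +1, and *actual* units, the
physical values.  The mapping between the two is piecewise linear about
the center level, so designs whose levels are not equidistant (e.g.
binding times 6, 16, 24 h with 16 h as the center) are converted exactly
and invertibly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Factor",
    "DesignTable",
    "generate_bbd",
    "decode",
    "encode",
    "UnsupportedDesignError",
]


class UnsupportedDesignError(ValueError):
    """Raised when a design shape outside this release's scope is requested."""


@dataclass(frozen=True)
class Factor:
    """One process factor with its three design levels.

    Parameters
    ----------
    name : str
        Identifier used for design-table columns.
    low, center, high : float
        Actual values mapped to coded -1, 0 and +1.  They must be strictly
        increasing; they need *not* be equidistant (the center label is
        authoritative, and conversion is piecewise linear about it).
    unit : str, optional
        Physical unit, for reporting only.
    """

    name: str
    low: float
    center: float
    high: float
    unit: str = ""

    def __post_init__(self) -> None:
        levels = (self.low, self.center, self.high)
        if not all(math.isfinite(v) for v in levels):
            raise ValueError(f"factor {self.name!r}: levels must be finite, got {levels}")
        if not (self.low < self.center < self.high):
            raise ValueError(
                f"factor {self.name!r}: levels must satisfy low < center < high, got {levels}"
            )

    def decode(self, coded):
        """Map coded values in [-1, +1] to actual units (piecewise linear)."""
        c = np.asarray(coded, dtype=float)
        if np.any(c < -1) or np.any(c > 1):
            raise ValueError(
                f"factor {self.name!r}: coded values must lie in [-1, 1], got {coded!r}"
            )
        lower = self.center + c * (self.center - self.low)   # c <= 0 branch
        upper = self.center + c * (self.high - self.center)  # c >= 0 branch
        out = np.where(c <= 0, lower, upper)
        return out if out.ndim else float(out)

    def encode(self, actual):
        """Inverse of :meth:`decode`; raises for values outside [low, high]."""
        a = np.asarray(actual, dtype=float)
        if np.any(a < self.low) or np.any(a > self.high):
            raise ValueError(
                f"factor {self.name!r}: actual values must lie in "
                f"[{self.low}, {self.high}], got {actual!r}"
            )
        lower = (a - self.center) / (self.center - self.low)
        upper = (a - self.center) / (self.high - self.center)
        out = np.where(a <= self.center, lower, upper)
        return out if out.ndim else float(out)


def decode(coded_point, factors) -> np.ndarray:
    """Convert one coded point (sequence, one value per factor) to actual units."""
    coded_point = np.asarray(coded_point, dtype=float)
    if coded_point.shape[-1] != len(factors):
        raise ValueError("point length does not match the number of factors")
    return np.stack(
        [f.decode(coded_point[..., j]) for j, f in enumerate(factors)], axis=-1
    )


def encode(actual_point, factors) -> np.ndarray:
    """Convert one actual-unit point to coded units (inverse of :func:`decode`)."""
    actual_point = np.asarray(actual_point, dtype=float)
    if actual_point.shape[-1] != len(factors):
        raise ValueError("point length does not match the number of factors")
    return np.stack(
        [f.encode(actual_point[..., j]) for j, f in enumerate(factors)], axis=-1
    )


@dataclass
class DesignTable:
    """A design matrix in both unit systems, backed by a pandas DataFrame.

    ``frame`` holds one row per run with columns ``run``,
    ``<factor>_coded`` and ``<factor>_actual`` per factor, plus any
    response columns.
    """

    frame: pd.DataFrame
    factors: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.factors = tuple(self.factors)
        self.validate()

    @property
    def coded(self) -> np.ndarray:
        return self.frame[[f"{f.name}_coded" for f in self.factors]].to_numpy(float)

    @property
    def actual(self) -> np.ndarray:
        return self.frame[[f"{f.name}_actual" for f in self.factors]].to_numpy(float)

    def response(self, column: str) -> np.ndarray:
        if column not in self.frame.columns:
            raise ValueError(f"response column {column!r} not present in design table")
        return self.frame[column].to_numpy(float)

    def validate(self) -> None:
        """Check BBD structure and coded/actual consistency."""
        for f in self.factors:
            for col in (f"{f.name}_coded", f"{f.name}_actual"):
                if col not in self.frame.columns:
                    raise ValueError(f"design table is missing column {col!r}")
        coded = self.coded
        design_levels = np.isin(coded, (-1.0, 0.0, 1.0)).all(axis=1)
        if not design_levels.all():
            raise ValueError("design runs must use coded levels -1, 0 or +1")
        expected = decode(coded, self.factors)
        if not np.allclose(expected, self.actual, rtol=0, atol=1e-9):
            raise ValueError("actual levels disagree with the coded labels")

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, factors) -> "DesignTable":
        return cls(frame=pd.read_csv(path), factors=tuple(factors))


def generate_bbd(factors, center_points: int = 3) -> DesignTable:
    """Generate a 3-factor Box-Behnken design.

    Produces the 12 edge-midpoint runs — all four (+/-1, +/-1)
    combinations over each of the factor pairs (1,2), (1,3), (2,3) with
    the remaining factor at coded 0 — followed by ``center_points``
    all-zero runs.  Ordering is deterministic: factor pairs in
    lexicographic order, signs in (-,-), (-,+), (+,-), (+,+) order,
    centers last.

    Parameters
    ----------
    factors : sequence of :class:`Factor`
        Exactly three factors (other sizes are out of scope).
    center_points : int
        Number of replicated center runs (>= 1).
    """
    factors = tuple(factors)
    if len(factors) != 3:
        raise UnsupportedDesignError(
            f"only 3-factor Box-Behnken designs are supported, got {len(factors)} factors"
        )
    if center_points < 1:
        raise ValueError("center_points must be >= 1")

    rows = []
    for i, j in ((0, 1), (0, 2), (1, 2)):
        for si in (-1.0, 1.0):
            for sj in (-1.0, 1.0):
                point = [0.0, 0.0, 0.0]
                point[i], point[j] = si, sj
                rows.append(point)
    rows.extend([[0.0, 0.0, 0.0]] * center_points)

    coded = np.array(rows)
    actual = decode(coded, factors)
    data = {"run": np.arange(1, len(rows) + 1)}
    for j, f in enumerate(factors):
        data[f"{f.name}_coded"] = coded[:, j]
        data[f"{f.name}_actual"] = actual[:, j]
    return DesignTable(frame=pd.DataFrame(data), factors=factors)
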