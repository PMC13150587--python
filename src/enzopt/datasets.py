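"""Bundled example data: a published 15-run immobilization experiment.

The dataset comes from a Box-Behnken optimization of alpha-amylase
immobilization onto glutaraldehyde-activated chitosan beads.  Three
factors were varied — chitosan concentration (% w/v), glutaraldehyde
concentration (% v/v) and enzyme binding time (h) — and the response is
the specific activity of the beads (U g^-1).  Note that the binding-time
levels (6, 16, 24 h) are not equidistant: 16 h is the labelled center.

Alongside the raw table, the module exposes the second-order polynomial
coefficients reported for this experiment (in actual units, to the
precision at which they were published) and the corresponding published
model-prediction column, both useful as regression references.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .doe import DesignTable, Factor

__all__ = [
    "AMYLASE_FACTORS",
    "REPORTED_COEFFICIENTS",
    "REPORTED_PREDICTED",
    "RESPONSE_COLUMN",
    "load_amylase_bbd",
]

#: Factor definitions of the bundled experiment.
AMYLASE_FACTORS = (
    Factor("cs", low=2.0, center=2.5, high=3.0, unit="% w/v"),
    Factor("ga", low=0.5, center=1.0, high=1.5, unit="% v/v"),
    Factor("time", low=6.0, center=16.0, high=24.0, unit="h"),
)

#: Name of the response column in the bundled CSV.
RESPONSE_COLUMN = "specific_activity"

#: Published quadratic-model coefficients (actual units), ordered as
#: intercept; cs, ga, time; cs^2, ga^2, time^2; cs*ga, cs*time, ga*time.
REPORTED_COEFFICIENTS = (
    238.0,
    812.0, -393.0, -72.6,
    -133.0, 164.0, 2.999,
    -91.0, -13.66, 12.42,
)

#: Published model predictions per run (U g^-1), in run order 1..15.
#: These equal the rounded reported coefficients evaluated at each run.
REPORTED_PREDICTED = (96, 275, 239, 482, 546, 502, 235, 488, 672, 239, 352, 454, 304, 239, 476)


def load_amylase_bbd() -> DesignTable:
    """Load the bundled 15-run design with its experimental responses."""
    with resources.files("enzopt.data").joinpath("amylase_bbd.csv").open("r") as fh:
        frame = pd.read_csv(fh)
    return DesignTable(frame=frame, factors=AMYLASE_FACTORS)
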