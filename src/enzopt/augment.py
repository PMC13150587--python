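"""Bootstrap-plus-noise augmentation of replicated design data.

Small designed experiments (here 15 runs x 3 replicates = 45
observations) are too small to train flexible regressors directly.  The
augmentation implemented here resamples the observations uniformly with
replacement up to a target size and perturbs each resampled response
with independent uniform noise whose scale is tied to the replicate
spread: the robust replicate standard deviation is estimated as
IQR/1.349 (the normal-consistent rescaling of the interquartile range),
and the uniform half-width is sqrt(3) times that, so the injected
noise's standard deviation matches the robust replicate SD.  A raw-IQR
half-width and a pooled (all runs centered and merged) spread estimate
are available as alternatives, since published descriptions of this
procedure are rarely precise enough to pin down one rule.

Note the caveat: augmented samples derived from the same source
observation are not independent, so a sample-level train/test split
leaks information across the boundary and test metrics read optimistic.
The run-grouped split mode avoids this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import GroupShuffleSplit
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "IQRNoiseAugmenter",
    "SplitDataset",
    "noise_halfwidth",
    "augment",
    "split_samples",
]

#: Normal-consistency constant: IQR of a Gaussian = 1.349 sigma.
IQR_TO_SD = 1.349


def _iqr(values: np.ndarray) -> float:
    q25, q75 = np.percentile(values, [25, 75], method="linear")
    return float(q75 - q25)


def noise_halfwidth(
    replicates: pd.DataFrame,
    pooling: str = "per-run",
    rule: str = "iqr-sd",
    run_column: str = "run",
    response_column: str = "response",
) -> pd.Series:
    """Uniform-noise half-width per run from replicate spread.

    Parameters
    ----------
    replicates : DataFrame with ``run_column`` and ``response_column``.
    pooling : {"per-run", "pooled"}
        Per-run uses each run's own replicates; pooled centers every
        run's replicates on its mean and estimates one spread from the
        merged deviations (applied to all runs).
    rule : {"iqr-sd", "raw-iqr"}
        ``iqr-sd``: half-width w = sqrt(3) * IQR / 1.349, so the uniform
        noise's SD equals the robust replicate SD.  ``raw-iqr``: w = IQR.

    Returns
    -------
    pandas.Series indexed by run id.
    """
    if pooling not in ("per-run", "pooled"):
        raise ValueError(f"pooling must be 'per-run' or 'pooled', got {pooling!r}")
    if rule not in ("iqr-sd", "raw-iqr"):
        raise ValueError(f"rule must be 'iqr-sd' or 'raw-iqr', got {rule!r}")
    groups = replicates.groupby(run_column)[response_column]
    if pooling == "per-run":
        if (groups.size() < 2).any():
            raise ValueError("per-run mode needs >= 2 replicates in every run")
        iqr = groups.apply(lambda v: _iqr(v.to_numpy(float)))
    else:
        centered = replicates[response_column] - groups.transform("mean")
        pooled = _iqr(centered.to_numpy(float))
        iqr = pd.Series(pooled, index=groups.mean().index)
    scale = np.sqrt(3.0) / IQR_TO_SD if rule == "iqr-sd" else 1.0
    return (iqr * scale).rename("halfwidth")


class IQRNoiseAugmenter(BaseEstimator):
    """Resample replicated observations and add IQR-scaled uniform noise.

    Parameters
    ----------
    target_n : int
        Number of augmented samples to draw.
    pooling, rule : see :func:`noise_halfwidth`.
    random_state : int or None
        Seed; identical seeds give bit-identical output.

    After :meth:`fit` on a replicate table, :meth:`sample` draws
    ``target_n`` observations uniformly with replacement from the source
    observations and adds independent Uniform(-w, w) noise with the
    source run's half-width ``w``.
    """

    def __init__(
        self,
        target_n: int = 750,
        pooling: str = "per-run",
        rule: str = "iqr-sd",
        random_state=None,
    ):
        self.target_n = target_n
        self.pooling = pooling
        self.rule = rule
        self.random_state = random_state

    def fit(
        self,
        replicates: pd.DataFrame,
        feature_columns=None,
        run_column: str = "run",
        response_column: str = "response",
    ):
        if len(replicates) == 0:
            raise ValueError("replicate dataset is empty")
        resp = replicates[response_column].to_numpy(float)
        if not np.isfinite(resp).all() or (resp < 0).any():
            raise ValueError("responses must be finite and non-negative")
        if feature_columns is None:
            feature_columns = [
                c
                for c in replicates.columns
                if c not in (run_column, response_column, "replicate")
            ]
        self.feature_columns_ = list(feature_columns)
        self.run_column_, self.response_column_ = run_column, response_column
        self.halfwidths_ = noise_halfwidth(
            replicates, self.pooling, self.rule, run_column, response_column
        )
        self.observations_ = replicates.reset_index(drop=True)
        return self

    def sample(self, target_n=None, random_state=None) -> pd.DataFrame:
        """Draw the augmented dataset (factor levels, response, source run)."""
        check_is_fitted(self, "observations_")
        n = self.target_n if target_n is None else int(target_n)
        if n < 1:
            raise ValueError("target_n must be >= 1")
        seed = self.random_state if random_state is None else random_state
        rng = np.random.default_rng(seed)
        src = rng.integers(0, len(self.observations_), size=n)
        picked = self.observations_.iloc[src].reset_index(drop=True)
        w = self.halfwidths_.loc[picked[self.run_column_]].to_numpy(float)
        noise = rng.uniform(-1.0, 1.0, size=n) * w
        out = picked[self.feature_columns_].copy()
        out["response"] = picked[self.response_column_].to_numpy(float) + noise
        out["source_run"] = picked[self.run_column_].to_numpy()
        out["sample_id"] = np.arange(n)
        out.attrs["provenance"] = {
            "seed": seed,
            "target_n": n,
            "rule": self.rule,
            "pooling": self.pooling,
            "quantile_rule": "linear-interpolation",
        }
        return out


def augment(
    replicates: pd.DataFrame,
    target_n: int = 750,
    seed=None,
    pooling: str = "per-run",
    rule: str = "iqr-sd",
    **fit_kwargs,
) -> pd.DataFrame:
    """One-call augmentation: fit an :class:`IQRNoiseAugmenter` and sample."""
    aug = IQRNoiseAugmenter(
        target_n=target_n, pooling=pooling, rule=rule, random_state=seed
    )
    return aug.fit(replicates, **fit_kwargs).sample()


@dataclass
class SplitDataset:
    """Train/test partition of an augmented dataset."""

    train: pd.DataFrame
    test: pd.DataFrame
    mode: str
    seed: object = None
    metadata: dict = field(default_factory=dict)


def split_samples(
    samples: pd.DataFrame,
    test_fraction: float = 0.2,
    mode: str = "sample",
    seed=None,
    group_column: str = "source_run",
) -> SplitDataset:
    """Split augmented samples into train and test sets.

    ``sample`` mode shuffles the rows and cuts at the fraction (test side
    floored).  ``group`` mode assigns whole source runs to one side, so
    no design point contributes to both — the leakage-safe alternative
    for data whose samples share source observations.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    n = len(samples)
    if mode == "sample":
        n_test = int(np.floor(n * test_fraction))
        if n_test < 1 or n_test >= n:
            raise ValueError("test_fraction leaves an empty side")
        order = np.random.default_rng(seed).permutation(n)
        test = samples.iloc[order[:n_test]]
        train = samples.iloc[order[n_test:]]
        meta = {"leakage_warning": (
            "sample-level split of augmented data: train and test may share "
            "source observations, so test metrics can read optimistic"
        )}
    elif mode == "group":
        groups = samples[group_column]
        if groups.nunique() < 2:
            raise ValueError("group mode needs at least 2 distinct source runs")
        splitter = GroupShuffleSplit(n_splits=1, test_size=test_fraction, random_state=seed)
        (train_idx, test_idx), = splitter.split(samples, groups=groups)
        train, test = samples.iloc[train_idx], samples.iloc[test_idx]
        meta = {}
    else:
        raise ValueError(f"mode must be 'sample' or 'group', got {mode!r}")
    return SplitDataset(
        train=train.reset_index(drop=True),
        test=test.reset_index(drop=True),
        mode=mode,
        seed=seed,
        metadata=meta,
    )
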