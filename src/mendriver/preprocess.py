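"""Loading, trimming and quantile normalization of abundance profiles.

The abundance profile is a features × samples matrix of non-negative
reals (pandas DataFrame; row index = feature ids, columns = sample ids).
Preprocessing follows the usual microbiome workflow: drop features that
are rare in relative abundance, then quantile-normalize samples so every
sample column shares the same empirical distribution.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._validation import as_profile

__all__ = [
    "read_abundance",
    "write_abundance",
    "filter_low_abundance",
    "quantile_normalize",
    "LowAbundanceFilter",
    "QuantileNormalizer",
]


def _delimiter_for(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if os.path.splitext(path)[1].lower() == ".csv" else "\t"


def read_abundance(
    path: str,
    orientation: str = "features_in_rows",
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Read a delimited abundance table into a features × samples DataFrame.

    Parameters
    ----------
    path : str
        Delimited text file with one header row and one leading id column.
        Delimiter is inferred from the extension (``.csv`` → comma, else
        tab) unless given explicitly.
    orientation : {"features_in_rows", "samples_in_rows"}
        Layout of the file; the returned profile is always features × samples.

    Raises
    ------
    ValueError
        On duplicate ids, missing values, negative abundance, or a
        non-numeric cell (reported with its row and column label).
    """
    if orientation not in ("features_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    raw = pd.read_csv(path, sep=_delimiter_for(path, delimiter), index_col=0)
    if orientation == "samples_in_rows":
        raw = raw.T
    try:
        raw = raw.apply(pd.to_numeric)
    except (ValueError, TypeError):
        for col in raw.columns:
            coerced = pd.to_numeric(raw[col], errors="coerce")
            bad = coerced.isna() & raw[col].notna()
            if bad.any():
                row = raw.index[bad][0]
                raise ValueError(
                    f"non-numeric abundance value {raw.at[row, col]!r} "
                    f"at row {row!r}, column {col!r}"
                ) from None
        raise
    profile = as_profile(raw)
    if (profile.to_numpy() < 0).any():
        raise ValueError("abundance values must be non-negative")
    return profile


def write_abundance(profile: pd.DataFrame, path: str, delimiter: str | None = None) -> None:
    """Write a profile back as delimited text (features in rows)."""
    profile.to_csv(path, sep=_delimiter_for(path, delimiter))


class LowAbundanceFilter(TransformerMixin, BaseEstimator):
    """Drop features that are rare in per-sample relative abundance.

    A feature is kept when its mean relative abundance (each sample column
    normalized to sum 1) is at least ``min_mean_rel_abundance`` *and* it is
    nonzero in at least a ``min_prevalence`` fraction of samples.

    Parameters
    ----------
    min_mean_rel_abundance : float, default 1e-5
        Threshold on the across-sample mean of per-sample relative abundance.
    min_prevalence : float, default 0.1
        Minimum fraction of samples in which the feature must be nonzero.

    Attributes
    ----------
    kept_features_ : pandas.Index
        Features surviving the filter, in input order.
    """

    def __init__(self, min_mean_rel_abundance: float = 1e-5, min_prevalence: float = 0.1):
        self.min_mean_rel_abundance = min_mean_rel_abundance
        self.min_prevalence = min_prevalence

    def fit(self, X, y=None):
        for name in ("min_mean_rel_abundance", "min_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        X = as_profile(X)
        colsum = X.sum(axis=0)
        rel = X.div(colsum.where(colsum > 0, np.nan), axis=1).fillna(0.0)
        keep = (rel.mean(axis=1) >= self.min_mean_rel_abundance) & (
            (X > 0).mean(axis=1) >= self.min_prevalence
        )
        if not keep.any():
            raise ValueError(
                "all features removed by abundance filter; "
                "relax min_mean_rel_abundance/min_prevalence"
            )
        self.n_features_in_ = X.shape[0]
        self.kept_features_ = X.index[keep]
        return self

    def transform(self, X):
        X = as_profile(X)
        return X.loc[self.kept_features_]


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Quantile normalization across sample columns.

    ``fit`` learns the reference distribution — the across-sample mean of
    the per-column order statistics. ``transform`` replaces each column's
    values by the reference values at the same within-column ranks, so that
    afterwards every sample column has an identical sorted value vector.
    Tied values receive the mean of the reference values over their tied
    ranks.

    Attributes
    ----------
    reference_ : ndarray of shape (n_features,)
        Sorted reference distribution.
    """

    def fit(self, X, y=None):
        X = as_profile(X, min_samples=2)
        self.n_features_in_ = X.shape[0]
        self.reference_ = np.sort(X.to_numpy(), axis=0).mean(axis=1)
        return self

    def transform(self, X):
        X = as_profile(X)
        if X.shape[0] != self.reference_.size:
            raise ValueError(
                f"profile has {X.shape[0]} features; normalizer was fitted on "
                f"{self.reference_.size}"
            )
        out = np.empty(X.shape, dtype=float)
        V = X.to_numpy()
        for j in range(V.shape[1]):
            out[:, j] = _map_to_reference(V[:, j], self.reference_)
        return pd.DataFrame(out, index=X.index, columns=X.columns)


def _map_to_reference(col: np.ndarray, ref: np.ndarray) -> np.ndarray:
    order = np.argsort(col, kind="mergesort")
    assigned = np.empty(col.size, dtype=float)
    assigned[order] = ref
    # average the reference values over ties so equal inputs map equally
    s = pd.Series(assigned)
    return s.groupby(pd.Series(col), sort=False).transform("mean").to_numpy()


def filter_low_abundance(
    profile,
    min_mean_rel_abundance: float = 1e-5,
    min_prevalence: float = 0.1,
) -> pd.DataFrame:
    """Functional wrapper around :class:`LowAbundanceFilter`."""
    return LowAbundanceFilter(min_mean_rel_abundance, min_prevalence).fit_transform(profile)


def quantile_normalize(profile) -> pd.DataFrame:
    """Functional wrapper around :class:`QuantileNormalizer`."""
    return QuantileNormalizer().fit_transform(profile)
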