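"""Shared input checks for abundance profiles and square matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd


def as_profile(X, *, min_features: int = 1, min_samples: int = 1) -> pd.DataFrame:
    """Coerce to a features × samples DataFrame and validate it.

    Arrays are wrapped with positional string ids. NaNs are rejected
    (missing abundance is an input error, not something to impute here).
    """
    if not isinstance(X, pd.DataFrame):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("abundance profile must be 2-dimensional")
        X = pd.DataFrame(
            X,
            index=[f"f{i}" for i in range(X.shape[0])],
            columns=[f"s{j}" for j in range(X.shape[1])],
        )
    else:
        X = X.astype(float)
    if X.index.has_duplicates:
        dup = X.index[X.index.duplicated()][0]
        raise ValueError(f"duplicate feature id: {dup!r}")
    if X.columns.has_duplicates:
        dup = X.columns[X.columns.duplicated()][0]
        raise ValueError(f"duplicate sample id: {dup!r}")
    if X.isna().any().any():
        rows = X.index[X.isna().any(axis=1)].tolist()
        raise ValueError(f"abundance profile contains missing values (features {rows[:5]})")
    if X.shape[0] < min_features:
        raise ValueError(f"need at least {min_features} features, got {X.shape[0]}")
    if X.shape[1] < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {X.shape[1]}")
    return X


def as_square(M, name: str = "matrix", *, tol: float = 1e-8) -> pd.DataFrame:
    """Validate a symmetric square matrix with matching ids."""
    if not isinstance(M, pd.DataFrame):
        M = np.asarray(M, dtype=float)
        M = pd.DataFrame(M, index=[f"f{i}" for i in range(M.shape[0])],
                         columns=[f"f{i}" for i in range(M.shape[1])])
    if M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square, got {M.shape}")
    if not (M.index == M.columns).all():
        raise ValueError(f"{name} row and column ids differ")
    V = M.to_numpy(dtype=float)
    if not np.allclose(V, V.T, atol=tol, equal_nan=False):
        raise ValueError(f"{name} is not symmetric within {tol}")
    return M.astype(float)


def spawn_rng(seed, n: int):
    """Derive ``n`` independent Generators from one seed (or Generator)."""
    if isinstance(seed, np.random.Generator):
        seed = seed.integers(0, 2**31 - 1)
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]
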