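"""Delegated phenotype: a disease-oriented rotation in phenotype PC space.

The phenotype table (samples × variables, mixed categorical/numeric, one
binary disease-state column with values Y/N) is digitized, standardized
and summarized by PCA. Within the plane of the first two components the
coordinate frame is rotated to the direction that best separates diseased
(Y) from healthy (N) samples: the rotation angle maximizes

    f(theta) = sum_{k: v_k = N} (x_k cos theta + y_k sin theta)
             - sum_{k: v_k = Y} (x_k cos theta + y_k sin theta)

whose unique maximizer is ``theta = atan2(dy, dx)`` with
``dx = sum_N x - sum_Y x`` and ``dy`` analogous. PC scores are scaled to
unit variance before the rotation, so maximizing f(theta) is equivalent
to maximizing the correlation of the projection with the disease
indicator; the per-sample projections on the rotated axis are the
*delegated phenotype*.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._validation import spawn_rng

__all__ = [
    "digitize",
    "filter_and_impute",
    "rotation_angle",
    "delegated_phenotype",
    "DelegatedPhenotypeResult",
    "DelegatedPhenotype",
    "ablate_phenotypes",
]

_EPS_VAR = 1e-12


def _normalize_disease(v: pd.Series) -> pd.Series:
    """Coerce a binary disease column to the canonical {'Y','N'} coding."""
    mapping = {"Y": "Y", "N": "N", "y": "Y", "n": "N", 1: "Y", 0: "N",
               True: "Y", False: "N", "1": "Y", "0": "N"}
    out = v.map(lambda z: mapping.get(z, None))
    if out.isna().any():
        bad = v[out.isna()].unique()[:5]
        raise ValueError(f"disease column must be binary Y/N; found {list(bad)}")
    if out.nunique() < 2:
        raise ValueError("disease column must contain both Y and N samples")
    return out


def filter_and_impute(
    table: pd.DataFrame,
    disease_column: str,
    max_missing_frac: float = 1 / 3,
) -> pd.DataFrame:
    """Drop over-missing variables, impute the rest.

    Variables (other than the disease column) missing in more than
    ``max_missing_frac`` of samples are dropped; remaining missing numeric
    values are imputed by the column median, categorical by the mode
    (smallest value on ties). A missing disease label cannot be imputed
    and raises.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must be in [0, 1]")
    if disease_column not in table.columns:
        raise ValueError(f"disease column {disease_column!r} not in table")
    if table[disease_column].isna().any():
        raise ValueError("disease column has missing values; labels cannot be imputed")
    out = table.copy()
    frac = out.isna().mean(axis=0)
    drop = [c for c in out.columns if c != disease_column and frac[c] > max_missing_frac]
    out = out.drop(columns=drop)
    for c in out.columns:
        if not out[c].isna().any():
            continue
        if pd.api.types.is_numeric_dtype(out[c]):
            out[c] = out[c].fillna(out[c].median())
        else:
            mode = sorted(out[c].mode())[0]
            out[c] = out[c].fillna(mode)
    return out


def digitize(
    table: pd.DataFrame,
    disease_column: str,
    include_disease: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Convert a mixed phenotype table to a standardized numeric matrix.

    Categorical variables are coded as integers in sorted-category order
    (two-level columns become {0, 1}); the disease column is coded Y→1,
    N→0 and, by default, enters the matrix like any other variable. Every
    column is then standardized to zero mean and unit variance; constant
    columns are dropped with a warning.

    Returns the standardized matrix and the Y/N disease labels.
    """
    Z, labels, _ = _digitize_fit(table, disease_column, include_disease)
    return Z, labels


def _digitize_fit(table, disease_column, include_disease):
    labels = _normalize_disease(table[disease_column])
    cols = {}
    meta = {}
    for c in table.columns:
        if c == disease_column:
            if not include_disease:
                continue
            x = labels.map({"Y": 1.0, "N": 0.0})
            meta[c] = {"categories": {"N": 0.0, "Y": 1.0}}
        elif pd.api.types.is_numeric_dtype(table[c]):
            if table[c].isna().any():
                raise ValueError(f"column {c!r} has missing values; run filter_and_impute first")
            x = table[c].astype(float)
            meta[c] = {"categories": None}
        else:
            cats = sorted(table[c].dropna().astype(str).unique())
            codes = {cat: float(i) for i, cat in enumerate(cats)}
            x = table[c].astype(str).map(codes)
            if x.isna().any():
                raise ValueError(f"column {c!r} has missing values; run filter_and_impute first")
            meta[c] = {"categories": codes}
        sd = x.std(ddof=0)
        if sd < np.sqrt(_EPS_VAR):
            warnings.warn(f"dropping constant phenotype variable {c!r}")
            meta.pop(c)
            continue
        mu = x.mean()
        meta[c]["mean"] = float(mu)
        meta[c]["sd"] = float(sd)
        cols[c] = (x - mu) / sd
    if not cols:
        raise ValueError("no informative phenotype variables after digitization")
    return pd.DataFrame(cols, index=table.index), labels, meta


def rotation_angle(x, y, is_disease) -> float:
    """Angle maximizing f(theta) for given PC-plane coordinates.

    ``is_disease`` is a boolean mask (True = Y). Returns theta in
    (-pi, pi]. Raises when the two groups have identical coordinate sums
    (no separating direction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = np.asarray(is_disease, dtype=bool)
    dx = x[~d].sum() - x[d].sum()
    dy = y[~d].sum() - y[d].sum()
    scale = max(np.abs(x).sum() + np.abs(y).sum(), 1.0)
    if np.hypot(dx, dy) <= 1e-12 * scale:
        raise ValueError("disease groups indistinguishable in PC space (dx = dy = 0)")
    theta = float(np.arctan2(dy, dx))
    if theta <= -np.pi:
        theta += 2 * np.pi
    return theta


@dataclass
class DelegatedPhenotypeResult:
    """Rotation output: per-sample scores, the angle, and the PC plane."""

    scores: pd.Series
    theta: float
    pc_scores: pd.DataFrame  # columns PC1, PC2 (unit variance)
    disease_labels: pd.Series
    explained_variance: np.ndarray

    def objective(self, theta: float) -> float:
        """Evaluate f(theta) on the stored PC coordinates."""
        x = self.pc_scores["PC1"].to_numpy()
        y = self.pc_scores["PC2"].to_numpy()
        d = (self.disease_labels == "Y").to_numpy()
        proj = x * np.cos(theta) + y * np.sin(theta)
        return float(proj[~d].sum() - proj[d].sum())


def _pc_plane(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First-two-PC sample scores, scaled to unit variance per axis.

    Returns (scores_2d, components (2, p), explained variance). When the
    data are effectively one-dimensional the second axis is all zeros.
    """
    Zc = Z - Z.mean(axis=0)
    U, S, Vt = np.linalg.svd(Zc, full_matrices=False)
    n = Z.shape[0]
    k = min(2, Vt.shape[0])
    scores = np.zeros((n, 2))
    comps = np.zeros((2, Z.shape[1]))
    ev = np.zeros(2)
    for a in range(k):
        raw = U[:, a] * S[a]
        var = raw.var()
        ev[a] = var
        comps[a] = Vt[a]
        if var > _EPS_VAR:
            scores[:, a] = raw / np.sqrt(var)
        else:
            warnings.warn(f"PC{a + 1} has negligible variance; axis zeroed")
    return scores, comps, ev


def delegated_phenotype(numeric: pd.DataFrame, disease_labels) -> DelegatedPhenotypeResult:
    """Rotate the first-two-PC plane of a digitized phenotype matrix.

    ``numeric`` is the standardized samples × variables matrix from
    :func:`digitize`; ``disease_labels`` the matching Y/N series.
    """
    if numeric.shape[1] < 2:
        raise ValueError("need at least 2 phenotype variables for the PC plane")
    labels = pd.Series(disease_labels, index=numeric.index)
    labels = _normalize_disease(labels)
    scores2d, _, ev = _pc_plane(numeric.to_numpy(dtype=float))
    d = (labels == "Y").to_numpy()
    theta = rotation_angle(scores2d[:, 0], scores2d[:, 1], d)
    proj = scores2d[:, 0] * np.cos(theta) + scores2d[:, 1] * np.sin(theta)
    return DelegatedPhenotypeResult(
        scores=pd.Series(proj, index=numeric.index, name="delegated_phenotype"),
        theta=theta,
        pc_scores=pd.DataFrame(scores2d, index=numeric.index, columns=["PC1", "PC2"]),
        disease_labels=labels,
        explained_variance=ev,
    )


class DelegatedPhenotype(TransformerMixin, BaseEstimator):
    """End-to-end delegated-phenotype transformer.

    ``fit`` runs missing-value filtering/imputation, digitization, PCA and
    the disease-oriented rotation on a raw phenotype table; ``transform``
    projects a table (by default the fitted one) onto the rotated axis.

    Parameters
    ----------
    disease_column : str
        Name of the binary Y/N disease-state column.
    max_missing_frac : float, default 1/3
        Variables missing in more than this fraction of samples are dropped.
    include_disease : bool, default True
        Whether the digitized disease column itself enters the PCA.

    Attributes
    ----------
    scores_ : Series            per-sample delegated phenotype
    theta_ : float              rotation angle, radians, in (-pi, pi]
    pc_scores_ : DataFrame      unit-variance PC1/PC2 sample coordinates
    disease_labels_ : Series    Y/N labels
    result_ : DelegatedPhenotypeResult
    """

    def __init__(
        self,
        disease_column: str = "disease",
        max_missing_frac: float = 1 / 3,
        include_disease: bool = True,
    ):
        self.disease_column = disease_column
        self.max_missing_frac = max_missing_frac
        self.include_disease = include_disease

    def fit(self, X: pd.DataFrame, y=None):
        table = filter_and_impute(X, self.disease_column, self.max_missing_frac)
        Z, labels, meta = _digitize_fit(table, self.disease_column, self.include_disease)
        if Z.shape[1] < 2:
            raise ValueError("need at least 2 phenotype variables after filtering")
        self._meta = meta
        self._columns = list(Z.columns)
        self._center = Z.to_numpy().mean(axis=0)
        scores2d, comps, ev = _pc_plane(Z.to_numpy(dtype=float))
        self._components = comps
        self._pc_sd = np.where(ev > _EPS_VAR, np.sqrt(ev), np.inf)
        d = (labels == "Y").to_numpy()
        self.theta_ = rotation_angle(scores2d[:, 0], scores2d[:, 1], d)
        proj = scores2d[:, 0] * np.cos(self.theta_) + scores2d[:, 1] * np.sin(self.theta_)
        self.scores_ = pd.Series(proj, index=Z.index, name="delegated_phenotype")
        self.pc_scores_ = pd.DataFrame(scores2d, index=Z.index, columns=["PC1", "PC2"])
        self.disease_labels_ = labels
        self.explained_variance_ = ev
        self.result_ = DelegatedPhenotypeResult(
            scores=self.scores_,
            theta=self.theta_,
            pc_scores=self.pc_scores_,
            disease_labels=labels,
            explained_variance=ev,
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.Series:
        cols = {}
        for c in self._columns:
            m = self._meta[c]
            if c == self.disease_column and m["categories"] == {"N": 0.0, "Y": 1.0}:
                x = _normalize_disease(X[c]).map({"Y": 1.0, "N": 0.0})
            elif m["categories"] is None:
                x = X[c].astype(float)
            else:
                x = X[c].astype(str).map(m["categories"])
                if x.isna().any():
                    raise ValueError(f"unseen category in column {c!r}")
            cols[c] = (x - m["mean"]) / m["sd"]
        Z = pd.DataFrame(cols, index=X.index)[self._columns].to_numpy()
        raw = (Z - self._center) @ self._components.T
        scores2d = raw / self._pc_sd
        proj = scores2d[:, 0] * np.cos(self.theta_) + scores2d[:, 1] * np.sin(self.theta_)
        return pd.Series(proj, index=X.index, name="delegated_phenotype")


def ablate_phenotypes(
    table: pd.DataFrame,
    disease_column: str,
    n_remove: int,
    eigengenes,
    max_combinations: int = 200,
    max_missing_frac: float = 1 / 3,
    include_disease: bool = True,
    random_state=0,
) -> pd.DataFrame:
    """Robustness of the delegated phenotype to missing variables.

    For every combination of ``n_remove`` non-disease variables (or a
    random subsample of ``max_combinations`` combinations when the
    combinatorial count exceeds the cap), the delegated phenotype is
    recomputed without them and the absolute Pearson correlation of each
    supplied eigengene with the ablated scores is recorded.

    ``eigengenes`` is a mapping name → per-sample vector (or a list, which
    gets positional names). Returns a long-format DataFrame with columns
    ``removed``, ``eigengene``, ``abs_corr``.
    """
    if isinstance(eigengenes, (list, tuple)):
        eigengenes = {f"eigengene_{i}": v for i, v in enumerate(eigengenes)}
    candidates = sorted(c for c in table.columns if c != disease_column)
    if n_remove < 0 or n_remove >= len(candidates):
        raise ValueError("n_remove must be in [0, number of non-disease variables)")
    total = comb(len(candidates), n_remove)
    if total <= max_combinations:
        combos = list(itertools.combinations(candidates, n_remove))
    else:
        (rng,) = spawn_rng(random_state, 1)
        combos = [
            tuple(sorted(rng.choice(candidates, size=n_remove, replace=False)))
            for _ in range(max_combinations)
        ]
    rows = []
    for combo in combos:
        sub = table.drop(columns=list(combo))
        dp = DelegatedPhenotype(
            disease_column=disease_column,
            max_missing_frac=max_missing_frac,
            include_disease=include_disease,
        ).fit(sub)
        s = dp.scores_.to_numpy()
        for name, vec in eigengenes.items():
            v = np.asarray(vec, dtype=float)
            if v.std() == 0 or s.std() == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(s, v)[0, 1])
            rows.append({"removed": combo, "eigengene": name, "abs_corr": abs(r)})
    return pd.DataFrame(rows)
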