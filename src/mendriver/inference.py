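"""Association-network inference between features.

Two inference routes are provided:

* **Pearson correlation (PCC)** — adjacency ``A_ij = PCC(i, j)`` with the
  sign-blind distance ``D_ij = 1 - |A_ij|``.
* **Multimodal mutual information (MMI)** — each feature's sample vector is
  decomposed into Gaussian-mixture bins; the MI between two features is the
  sum of an *outer* term (discrete MI of the joint bin labels) and an
  *inner* term (bin-proportion-weighted Gaussian MI within joint bins).
  The raw MMI matrix is background-normalized with the CLR z-score scheme
  before clustering, which suppresses features that associate with
  everything.

Zero-variance vectors yield a zero association with a warning rather than
an abort, because trimmed real profiles occasionally retain constant rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.metrics import mutual_info_score
from sklearn.mixture import GaussianMixture

from ._validation import as_profile, as_square, spawn_rng

__all__ = [
    "pcc",
    "pcc_matrix",
    "BinModel",
    "fit_bins",
    "mmi",
    "clr_normalize",
    "mmi_matrix",
    "PearsonNetwork",
    "MixtureMINetwork",
]

#: smallest |rho| kept away from 1 when evaluating -0.5*ln(1 - rho^2)
_RHO_CAP = 1.0 - 1e-12


def pcc(x, y) -> float:
    """Pearson correlation coefficient between two sample vectors.

    Returns 0.0 (with a warning) when either vector has zero variance,
    treating the association as undefined rather than failing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    sx = x.std()
    sy = y.std()
    if sx == 0.0 or sy == 0.0:
        warnings.warn("zero-variance vector: association undefined, returning 0")
        return 0.0
    r = float(np.cov(x, y, bias=True)[0, 1] / (sx * sy))
    return float(np.clip(r, -1.0, 1.0))


def pcc_matrix(profile) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise PCC adjacency and the distance matrix ``D = 1 - |A|``."""
    X = as_profile(profile, min_features=2, min_samples=3)
    V = X.to_numpy()
    sd = V.std(axis=1)
    flat = sd == 0.0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance feature(s): associations set to 0"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.corrcoef(V)
    A[np.isnan(A)] = 0.0
    A = np.clip((A + A.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(A, 1.0)
    D = 1.0 - np.abs(A)
    np.fill_diagonal(D, 0.0)
    ids = X.index
    return (
        pd.DataFrame(A, index=ids, columns=ids),
        pd.DataFrame(D, index=ids, columns=ids),
    )


@dataclass
class BinModel:
    """Gaussian-mixture decomposition of one feature's sample vector.

    ``labels[s]`` is the maximum-posterior component of sample ``s``; empty
    components are dropped so every bin holds at least one sample.
    """

    n_components: int
    proportions: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    labels: np.ndarray
    bic: float = field(default=np.nan)

    def __post_init__(self):
        if abs(self.proportions.sum() - 1.0) > 1e-8:
            raise ValueError("bin proportions must sum to 1")


def fit_bins(x, max_components: int = 3, random_state=0) -> BinModel:
    """Decompose a sample vector into Gaussian-mixture bins.

    Mixtures with 1..``max_components`` components are fitted (k-means
    initialization, fixed seed) and the component count is selected by BIC;
    candidates that the sample size cannot support (fewer than 3 samples
    per component) or that fit degenerately are skipped.
    """
    x = np.asarray(x, dtype=float).reshape(-1, 1)
    n = x.shape[0]
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    if n < 3:
        raise ValueError("need at least 3 samples to fit bins")
    if isinstance(random_state, np.random.Generator):
        random_state = int(random_state.integers(0, 2**31 - 1))

    best = None
    for c in range(1, max_components + 1):
        if c > 1 and n < 3 * c:
            break
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm = GaussianMixture(
                    n_components=c,
                    covariance_type="full",
                    init_params="kmeans",
                    random_state=random_state,
                    n_init=1,
                ).fit(x)
        except ValueError:
            continue  # degenerate fit: fall back to fewer components
        bic = gm.bic(x)
        if best is None or bic < best[0]:
            best = (bic, gm)
    if best is None:
        # everything degenerate (e.g. constant vector): single bin
        labels = np.zeros(n, dtype=int)
        return BinModel(1, np.array([1.0]), np.array([float(x.mean())]),
                        np.array([float(x.var())]), labels)

    bic, gm = best
    labels = gm.predict(x)
    used, labels = np.unique(labels, return_inverse=True)
    props = np.bincount(labels).astype(float) / n
    return BinModel(
        n_components=len(used),
        proportions=props,
        means=gm.means_.ravel()[used],
        variances=gm.covariances_.reshape(-1)[used],
        labels=labels,
        bic=float(bic),
    )


def _gaussian_mi(x: np.ndarray, y: np.ndarray) -> float:
    """Closed-form Gaussian MI, -0.5*ln(1 - rho^2), from the sample rho."""
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    rho = float(np.cov(x, y, bias=True)[0, 1] / (sx * sy))
    rho2 = min(rho * rho, _RHO_CAP**2)
    return -0.5 * float(np.log1p(-rho2))


def mmi(x, y, bx: BinModel, by: BinModel, min_bin_size: int = 4) -> float:
    """Multimodal mutual information between two sample vectors.

    ``MMI = MMI_outer + MMI_inner``: the outer term is the discrete MI of
    the joint bin-label contingency table (maximum-likelihood plug-in
    estimator, natural log); the inner term aggregates the closed-form
    Gaussian MI within each joint bin, weighted by the joint-bin
    proportion. Joint bins with fewer than ``min_bin_size`` samples
    contribute nothing (the within-bin correlation is not estimable).
    The result is clipped below at 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if bx.labels.size != n or by.labels.size != n:
        raise ValueError("bin models do not match the sample vectors")

    outer = float(mutual_info_score(bx.labels, by.labels))

    inner = 0.0
    for k in range(bx.n_components):
        mk = bx.labels == k
        for l in range(by.n_components):
            m = mk & (by.labels == l)
            n_kl = int(m.sum())
            if n_kl < min_bin_size:
                continue
            inner += (n_kl / n) * _gaussian_mi(x[m], y[m])
    return max(0.0, outer + inner)


def clr_normalize(M) -> pd.DataFrame:
    """CLR background normalization of a symmetric association matrix.

    Each entry ``M_ij`` is z-scored against row ``i``'s and row ``j``'s
    off-diagonal background; the normalized weight is
    ``sqrt(max(0, Z_i)^2 + max(0, Z_j)^2)``, i.e. only above-background
    associations count. Rows with zero background spread get zero z-scores
    (with a warning). The diagonal is zero.
    """
    M = as_square(M, "association matrix")
    V = M.to_numpy().copy()
    n = V.shape[0]
    if n < 3:
        raise ValueError("CLR background needs at least 3 features")
    off = ~np.eye(n, dtype=bool)
    mu = np.array([V[i, off[i]].mean() for i in range(n)])
    sd = np.array([V[i, off[i]].std() for i in range(n)])
    flat = sd == 0.0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} row(s) with zero background spread: z-scores set to 0")
    sd_safe = np.where(flat, 1.0, sd)
    Z = (V - mu[:, None]) / sd_safe[:, None]
    Z[flat, :] = 0.0
    Zp = np.maximum(Z, 0.0)
    out = np.sqrt(Zp**2 + Zp.T**2)
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=M.index, columns=M.columns)


def mmi_matrix(
    profile, max_components: int = 3, random_state=0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CLR-normalized MMI adjacency and its clustering distance.

    One :func:`fit_bins` model is fitted per feature (seeds spawned from
    ``random_state``), the pairwise MMI matrix is CLR-normalized, and the
    distance is ``D = (max(CLR) - CLR) / max(CLR)`` (zero diagonal): a
    monotone-decreasing transform that preserves the association ordering
    and maps onto [0, 1], so clustering cut heights mean the same thing
    as for the correlation distance.
    """
    X = as_profile(profile, min_features=3, min_samples=3)
    V = X.to_numpy()
    n = V.shape[0]
    rngs = spawn_rng(random_state, n)
    bins = [fit_bins(V[i], max_components=max_components, random_state=rngs[i]) for i in range(n)]

    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = mmi(V[i], V[j], bins[i], bins[j])
    ids = X.index
    C = clr_normalize(pd.DataFrame(M, index=ids, columns=ids))
    cmax = C.to_numpy().max()
    if cmax > 0:
        D = (cmax - C.to_numpy()) / cmax
    else:
        # degenerate: no association anywhere -> maximal uniform distance
        D = np.ones_like(C.to_numpy())
    np.fill_diagonal(D, 0.0)
    return C, pd.DataFrame(D, index=ids, columns=ids)


class PearsonNetwork(BaseEstimator):
    """MEN inference by Pearson correlation.

    Attributes (after ``fit``)
    --------------------------
    association_ : DataFrame
        Symmetric PCC adjacency, unit diagonal, values in [-1, 1].
    distance_ : DataFrame
        ``1 - |PCC|``, the clustering distance.
    feature_ids_ : pandas.Index
    """

    method = "pcc"

    def fit(self, X, y=None):
        self.association_, self.distance_ = pcc_matrix(X)
        self.feature_ids_ = self.association_.index
        return self

    def edge_weights(self) -> pd.DataFrame:
        """Non-negative edge weights for downstream graphs (|PCC|)."""
        return self.association_.abs()


class MixtureMINetwork(BaseEstimator):
    """MEN inference by CLR-normalized multimodal mutual information.

    Parameters
    ----------
    max_components : int, default 3
        Largest Gaussian-mixture bin count tried per feature (BIC selects).
    random_state : int, default 0
        Seed for mixture initialization; fits are reproducible.
    """

    method = "mmi_clr"

    def __init__(self, max_components: int = 3, random_state=0):
        self.max_components = max_components
        self.random_state = random_state

    def fit(self, X, y=None):
        self.association_, self.distance_ = mmi_matrix(
            X, max_components=self.max_components, random_state=self.random_state
        )
        self.feature_ids_ = self.association_.index
        return self

    def edge_weights(self) -> pd.DataFrame:
        """CLR weights are already non-negative."""
        return self.association_
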