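"""Subnetwork–phenotype association via eigengenes and permutation tests.

Each subnetwork's abundance pattern is summarized by its *eigengene* —
the first principal component of the member × sample matrix — and
correlated with the delegated phenotype. Significance comes from a
permutation null: eigengenes of random feature sets of the same size,
drawn from the post-filter feature universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from ._validation import as_profile, spawn_rng

__all__ = [
    "eigengene",
    "permutation_pvalue",
    "SubnetworkAssociation",
    "associate_subnetworks",
    "extract_relevant",
]


def _eigengene_values(V: np.ndarray) -> np.ndarray:
    """Eigengene of a raw member × sample array (no pandas overhead)."""
    sd = V.std(axis=1, keepdims=True)
    if np.all(sd == 0):
        raise ValueError("subnetwork has zero total variance; eigengene undefined")
    sd_safe = np.where(sd == 0, 1.0, sd)
    Z = (V - V.mean(axis=1, keepdims=True)) / sd_safe
    _, _, Vt = np.linalg.svd(Z, full_matrices=False)
    e = Vt[0]
    if e.std() == 0:
        raise ValueError("degenerate eigengene (zero variance)")
    e = (e - e.mean()) / e.std()
    mean_profile = Z.mean(axis=0)
    if mean_profile.std() > 0 and np.corrcoef(e, mean_profile)[0, 1] < 0:
        e = -e
    return e


def eigengene(profile_subset) -> pd.Series:
    """First-PC sample scores of one subnetwork's member matrix.

    Member rows are standardized, the first right singular vector gives
    the per-sample scores, scaled to unit variance. The sign is fixed so
    the eigengene correlates non-negatively with the mean standardized
    member profile, making it represent the shared abundance pattern.
    """
    X = as_profile(profile_subset, min_features=2, min_samples=3)
    return pd.Series(_eigengene_values(X.to_numpy()), index=X.columns, name="eigengene")


def _abs_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return abs(float(np.corrcoef(a, b)[0, 1]))


def permutation_pvalue(
    k: int,
    profile,
    delegated_scores,
    r_obs: float,
    B: int = 1000,
    random_state=0,
) -> float:
    """Permutation p-value for an eigengene–phenotype correlation.

    For each of ``B`` permutations, ``k`` features are drawn uniformly
    without replacement from the profile, their eigengene computed, and
    its absolute correlation with the delegated phenotype recorded. The
    p-value uses the add-one convention on |r|:

        p = (1 + #{b : |r_b| >= |r_obs|}) / (B + 1)
    """
    X = as_profile(profile)
    if k > X.shape[0]:
        raise ValueError(f"subnetwork size {k} exceeds feature count {X.shape[0]}")
    if B < 1:
        raise ValueError("B must be >= 1")
    scores = np.asarray(delegated_scores, dtype=float)
    (rng,) = spawn_rng(random_state, 1)
    hits = 0
    n_feat = X.shape[0]
    V = X.to_numpy()
    for _ in range(B):
        idx = rng.choice(n_feat, size=k, replace=False)
        try:
            r_b = _abs_corr(_eigengene_values(V[idx]), scores)
        except ValueError:
            r_b = 0.0
        if r_b >= abs(r_obs):
            hits += 1
    return (1 + hits) / (B + 1)


@dataclass
class SubnetworkAssociation:
    """Association of one subnetwork with the delegated phenotype."""

    subnetwork_id: int
    size: int
    eigengene: pd.Series
    r: float
    p: float
    selected: bool = False


def associate_subnetworks(
    profile,
    partition,
    delegated_scores,
    B: int = 1000,
    random_state=0,
) -> list[SubnetworkAssociation]:
    """Eigengene, correlation and permutation p for every subnetwork.

    Permutation draws for each subnetwork use an independent stream
    spawned from ``random_state``, so results do not depend on the order
    in which subnetworks are processed.
    """
    X = as_profile(profile)
    scores = pd.Series(delegated_scores)
    scores = scores.loc[X.columns].to_numpy(dtype=float)
    sids = sorted(partition.subnetworks)
    rngs = spawn_rng(random_state, max(len(sids), 1))
    out = []
    for rng, sid in zip(rngs, sids):
        members = partition.subnetworks[sid]
        e = eigengene(X.loc[members])
        if e.to_numpy().std() == 0 or scores.std() == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(e.to_numpy(), scores)[0, 1])
        p = permutation_pvalue(len(members), X, scores, r, B=B, random_state=rng)
        out.append(SubnetworkAssociation(sid, len(members), e, r, p))
    return out


def extract_relevant(
    associations: list[SubnetworkAssociation],
    alpha: float = 0.05,
    top_k: int | None = None,
    adjust: str = "none",
) -> list[int]:
    """Disease-relevant subnetwork ids: p <= alpha, ordered by |r| desc.

    ``adjust="bh"`` applies Benjamini–Hochberg across subnetworks before
    thresholding (off by default). Selection uses |r|, so it is invariant
    to the global sign of the delegated phenotype. The ``selected`` flag
    of each association is updated in place.
    """
    if adjust not in ("none", "bh"):
        raise ValueError("adjust must be 'none' or 'bh'")
    pvals = np.array([a.p for a in associations])
    if adjust == "bh" and len(pvals):
        pvals = false_discovery_control(pvals, method="bh")
    chosen = [
        a for a, p in zip(associations, pvals) if p <= alpha
    ]
    chosen.sort(key=lambda a: (-abs(a.r), a.subnetwork_id))
    if top_k is not None:
        chosen = chosen[:top_k]
    ids = [a.subnetwork_id for a in chosen]
    if not ids:
        warnings.warn("no subnetwork passed the relevance threshold")
    for a in associations:
        a.selected = a.subnetwork_id in ids
    return ids
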