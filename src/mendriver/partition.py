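"""Hierarchical partitioning of the MEN into subnetworks.

Features are agglomeratively clustered on the inference distance matrix
and the dendrogram is cut either at a fixed height or into a target
number of clusters. Clusters below ``min_size`` are treated as
unassigned background and excluded from association testing. Each
retained subnetwork becomes a complete weighted graph whose edge weights
are the association magnitudes (PageRank consumes the weights directly,
so no edge threshold is applied for analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from ._validation import as_square

__all__ = [
    "SubnetworkPartition",
    "hierarchical_partition",
    "build_subnetwork_graphs",
    "HierarchicalPartitioner",
]

_LINKAGES = ("average", "complete", "ward")


@dataclass
class SubnetworkPartition:
    """Feature → subnetwork assignment.

    ``assignment`` maps every clustered feature to its subnetwork id
    (consecutive integers from 1, ordered by decreasing size); features in
    clusters below the minimum size are listed in ``unassigned``.
    """

    assignment: dict
    subnetworks: dict
    unassigned: list
    linkage_method: str
    cut_parameter: float
    min_size: int

    def __post_init__(self):
        covered = [f for members in self.subnetworks.values() for f in members]
        if len(covered) != len(set(covered)):
            raise ValueError("subnetworks overlap")
        if set(covered) != set(self.assignment):
            raise ValueError("assignment and subnetworks disagree")

    @property
    def n_subnetworks(self) -> int:
        return len(self.subnetworks)

    def to_frame(self) -> pd.DataFrame:
        rows = [(f, sid) for sid, members in self.subnetworks.items() for f in members]
        rows += [(f, -1) for f in self.unassigned]
        return pd.DataFrame(rows, columns=["feature_id", "subnetwork_id"])


def hierarchical_partition(
    D,
    linkage: str = "average",
    cut_height: float | None = 0.8,
    n_clusters: int | None = None,
    min_size: int = 5,
) -> SubnetworkPartition:
    """Cluster features on a distance matrix and cut into subnetworks.

    Exactly one of ``cut_height`` (static dendrogram cut) or ``n_clusters``
    (target cluster count) drives the cut; ``n_clusters`` wins when given.
    Clusters smaller than ``min_size`` become unassigned background.

    Raises
    ------
    ValueError
        If every cluster falls below ``min_size``.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    if n_clusters is None and (cut_height is None or cut_height <= 0):
        raise ValueError("need cut_height > 0 or a target n_clusters")
    D = as_square(D, "distance matrix")
    ids = list(D.index)
    V = D.to_numpy().copy()
    np.fill_diagonal(V, 0.0)
    V = (V + V.T) / 2.0
    Z = scipy_linkage(squareform(V, checks=False), method=linkage)
    if n_clusters is not None:
        raw = fcluster(Z, t=n_clusters, criterion="maxclust")
        cut_param = float(n_clusters)
    else:
        raw = fcluster(Z, t=cut_height, criterion="distance")
        cut_param = float(cut_height)

    clusters: dict[int, list] = {}
    for f, lab in zip(ids, raw):
        clusters.setdefault(int(lab), []).append(f)

    # keep clusters >= min_size; relabel 1..K by decreasing size, then by
    # first member id for determinism
    kept = [m for m in clusters.values() if len(m) >= min_size]
    if not kept:
        raise ValueError(
            f"no cluster reaches min_size={min_size}; lower min_size or raise the cut"
        )
    kept.sort(key=lambda m: (-len(m), str(m[0])))
    subnetworks = {sid: members for sid, members in enumerate(kept, start=1)}
    assignment = {f: sid for sid, members in subnetworks.items() for f in members}
    unassigned = [f for f in ids if f not in assignment]
    return SubnetworkPartition(
        assignment=assignment,
        subnetworks=subnetworks,
        unassigned=unassigned,
        linkage_method=linkage,
        cut_parameter=cut_param,
        min_size=min_size,
    )


def build_subnetwork_graphs(partition: SubnetworkPartition, A) -> list[nx.Graph]:
    """Complete weighted graph per subnetwork.

    Edge weight is the association magnitude ``|A_ij|`` (for CLR weights,
    which are non-negative, this is the weight itself). No self-loops.
    """
    A = as_square(A, "association matrix")
    missing = [f for f in partition.assignment if f not in A.index]
    if missing:
        raise ValueError(f"features missing from association matrix: {missing[:5]}")
    graphs = []
    for sid, members in partition.subnetworks.items():
        G = nx.Graph(subnetwork_id=sid)
        G.add_nodes_from(members)
        sub = A.loc[members, members].abs().to_numpy()
        for i, u in enumerate(members):
            for j in range(i + 1, len(members)):
                G.add_edge(u, members[j], weight=float(sub[i, j]))
        graphs.append(G)
    return graphs


class HierarchicalPartitioner(ClusterMixin, BaseEstimator):
    """Sklearn-style wrapper: ``fit`` on a distance matrix.

    Attributes
    ----------
    partition_ : SubnetworkPartition
    labels_ : ndarray
        Subnetwork id per feature in input order; -1 for unassigned.
    """

    def __init__(
        self,
        linkage: str = "average",
        cut_height: float | None = 0.8,
        n_clusters: int | None = None,
        min_size: int = 5,
    ):
        self.linkage = linkage
        self.cut_height = cut_height
        self.n_clusters = n_clusters
        self.min_size = min_size

    def fit(self, X, y=None):
        X = as_square(X, "distance matrix")
        self.partition_ = hierarchical_partition(
            X,
            linkage=self.linkage,
            cut_height=self.cut_height,
            n_clusters=self.n_clusters,
            min_size=self.min_size,
        )
        self.labels_ = np.array(
            [self.partition_.assignment.get(f, -1) for f in X.index], dtype=int
        )
        return self
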