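"""End-to-end orchestration: abundance + phenotype in, key drivers out.

:class:`KeyDriverAnalysis` is the estimator form of the whole workflow
(preprocess → network inference → partition → delegated phenotype →
association → PageRank key drivers); :func:`run_pipeline` wraps it with
file I/O and a serializable :class:`PipelineConfig` for the CLI. All
stochastic steps (mixture initialization, permutation draws) consume
streams spawned from the single seed, so reruns are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator

from .association import associate_subnetworks, extract_relevant
from .inference import MixtureMINetwork, PearsonNetwork
from .keydriver import pagerank
from .partition import HierarchicalPartitioner, build_subnetwork_graphs
from .phenotype import DelegatedPhenotype
from .preprocess import LowAbundanceFilter, QuantileNormalizer, read_abundance
from ._validation import as_profile

__all__ = ["PipelineConfig", "KeyDriverAnalysis", "run_pipeline", "read_phenotype"]

logger = logging.getLogger("mendriver")

SCHEMA_VERSION = "1.0"


def read_phenotype(path: str, delimiter: str | None = None) -> pd.DataFrame:
    """Read the phenotype table (samples in rows, header row, id column)."""
    sep = delimiter or ("," if os.path.splitext(path)[1].lower() == ".csv" else "\t")
    table = pd.read_csv(path, sep=sep, index_col=0)
    if table.index.has_duplicates:
        dup = table.index[table.index.duplicated()][0]
        raise ValueError(f"duplicate sample id in phenotype table: {dup!r}")
    return table


@dataclass
class PipelineConfig:
    """Serializable configuration of a full run."""

    abundance: str = ""
    phenotype: str = ""
    output_dir: str | None = None
    orientation: str = "features_in_rows"
    method: str = "pcc"
    min_mean_rel_abundance: float = 1e-5
    min_prevalence: float = 0.1
    quantile_norm: bool = True
    max_components: int = 3
    linkage: str = "average"
    cut_height: float | None = 0.8
    n_clusters: int | None = None
    min_size: int = 5
    disease_column: str = "disease"
    max_missing_frac: float = 1 / 3
    include_disease: bool = True
    n_permutations: int = 1000
    alpha: float = 0.05
    top_k: int | None = None
    adjust: str = "none"
    damping: float = 0.85
    top_drivers: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("pcc", "mmi"):
            raise ValueError("method must be 'pcc' or 'mmi'")
        if not 0.0 < self.damping < 1.0:
            raise ValueError("damping must be in (0, 1)")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


class KeyDriverAnalysis(BaseEstimator):
    """Full key-driver workflow as a single estimator.

    ``fit(X, phenotype)`` takes a features × samples abundance DataFrame
    and a samples × variables phenotype DataFrame (with a binary Y/N
    disease column) and populates:

    profile_        preprocessed abundance (trimmed, quantile-normalized)
    network_        fitted PearsonNetwork or MixtureMINetwork
    partition_      SubnetworkPartition
    delegated_      fitted DelegatedPhenotype transformer
    associations_   list of SubnetworkAssociation (one per subnetwork)
    selected_       relevant subnetwork ids, by |r| descending
    key_drivers_    subnetwork id → ranked member list (PageRank)
    report_         JSON-serializable result dict
    """

    def __init__(
        self,
        method: str = "pcc",
        min_mean_rel_abundance: float = 1e-5,
        min_prevalence: float = 0.1,
        quantile_norm: bool = True,
        max_components: int = 3,
        linkage: str = "average",
        cut_height: float | None = 0.8,
        n_clusters: int | None = None,
        min_size: int = 5,
        disease_column: str = "disease",
        max_missing_frac: float = 1 / 3,
        include_disease: bool = True,
        n_permutations: int = 1000,
        alpha: float = 0.05,
        top_k: int | None = None,
        adjust: str = "none",
        damping: float = 0.85,
        top_drivers: int = 1,
        random_state: int = 0,
    ):
        self.method = method
        self.min_mean_rel_abundance = min_mean_rel_abundance
        self.min_prevalence = min_prevalence
        self.quantile_norm = quantile_norm
        self.max_components = max_components
        self.linkage = linkage
        self.cut_height = cut_height
        self.n_clusters = n_clusters
        self.min_size = min_size
        self.disease_column = disease_column
        self.max_missing_frac = max_missing_frac
        self.include_disease = include_disease
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.top_k = top_k
        self.adjust = adjust
        self.damping = damping
        self.top_drivers = top_drivers
        self.random_state = random_state

    def fit(self, X, phenotype: pd.DataFrame):
        X = as_profile(X, min_features=2, min_samples=3)
        common = [s for s in X.columns if s in phenotype.index]
        if len(common) < 3:
            unmatched_a = [s for s in X.columns if s not in phenotype.index]
            unmatched_p = [s for s in phenotype.index if s not in X.columns]
            raise ValueError(
                f"only {len(common)} shared samples between abundance and phenotype; "
                f"abundance-only: {unmatched_a[:5]}, phenotype-only: {unmatched_p[:5]}"
            )
        X = X[common]
        phenotype = phenotype.loc[common]
        ss = np.random.SeedSequence(self.random_state)
        seed_mix, seed_perm = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2)]

        logger.info("preprocessing %d features x %d samples", *X.shape)
        profile = LowAbundanceFilter(
            self.min_mean_rel_abundance, self.min_prevalence
        ).fit_transform(X)
        if self.quantile_norm:
            profile = QuantileNormalizer().fit_transform(profile)
        self.profile_ = profile

        logger.info("inferring %s network on %d features", self.method, profile.shape[0])
        if self.method == "pcc":
            self.network_ = PearsonNetwork().fit(profile)
        else:
            self.network_ = MixtureMINetwork(
                max_components=self.max_components, random_state=seed_mix
            ).fit(profile)

        partitioner = HierarchicalPartitioner(
            linkage=self.linkage,
            cut_height=self.cut_height,
            n_clusters=self.n_clusters,
            min_size=self.min_size,
        ).fit(self.network_.distance_)
        self.partition_ = partitioner.partition_
        logger.info("%d subnetworks of size >= %d", self.partition_.n_subnetworks, self.min_size)

        self.delegated_ = DelegatedPhenotype(
            disease_column=self.disease_column,
            max_missing_frac=self.max_missing_frac,
            include_disease=self.include_disease,
        ).fit(phenotype)

        self.associations_ = associate_subnetworks(
            profile,
            self.partition_,
            self.delegated_.scores_,
            B=self.n_permutations,
            random_state=seed_perm,
        )
        self.selected_ = extract_relevant(
            self.associations_, alpha=self.alpha, top_k=self.top_k, adjust=self.adjust
        )

        graphs = {
            g.graph["subnetwork_id"]: g
            for g in build_subnetwork_graphs(self.partition_, self.network_.edge_weights())
        }
        self.key_drivers_ = {}
        self.node_scores_ = {}
        for sid in self.selected_:
            ns = pagerank(graphs[sid], c=self.damping)
            self.node_scores_[sid] = ns
            self.key_drivers_[sid] = ns.ranked()[: self.top_drivers]
        self.report_ = self._build_report()
        return self

    def _build_report(self) -> dict:
        subnetworks = []
        for a in sorted(self.associations_, key=lambda a: a.subnetwork_id):
            entry = {
                "subnetwork_id": int(a.subnetwork_id),
                "size": int(a.size),
                "r": round(float(a.r), 10),
                "p": round(float(a.p), 10),
                "selected": bool(a.selected),
            }
            if a.selected:
                ns = self.node_scores_[a.subnetwork_id]
                entry["key_drivers"] = list(self.key_drivers_[a.subnetwork_id])
                entry["ranked_members"] = [
                    {"feature_id": u, "pagerank": round(ns.scores[u], 10)}
                    for u in ns.ranked()
                ]
            subnetworks.append(entry)
        return {
            "schema_version": SCHEMA_VERSION,
            "method": self.method,
            "seed": self.random_state,
            "n_features": int(self.profile_.shape[0]),
            "n_samples": int(self.profile_.shape[1]),
            "theta": round(float(self.delegated_.theta_), 10),
            "n_subnetworks": int(self.partition_.n_subnetworks),
            "selected_subnetworks": [int(s) for s in self.selected_],
            "subnetworks": subnetworks,
        }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured workflow on files and write all artifacts.

    Returns the final report dict (also written as ``keydrivers.json``).
    """
    abundance = read_abundance(config.abundance, orientation=config.orientation)
    phenotype = read_phenotype(config.phenotype)
    est = KeyDriverAnalysis(
        method=config.method,
        min_mean_rel_abundance=config.min_mean_rel_abundance,
        min_prevalence=config.min_prevalence,
        quantile_norm=config.quantile_norm,
        max_components=config.max_components,
        linkage=config.linkage,
        cut_height=config.cut_height,
        n_clusters=config.n_clusters,
        min_size=config.min_size,
        disease_column=config.disease_column,
        max_missing_frac=config.max_missing_frac,
        include_disease=config.include_disease,
        n_permutations=config.n_permutations,
        alpha=config.alpha,
        top_k=config.top_k,
        adjust=config.adjust,
        damping=config.damping,
        top_drivers=config.top_drivers,
        random_state=config.seed,
    ).fit(abundance, phenotype)

    if config.output_dir:
        _write_artifacts(est, config)
    return est.report_


def write_report(report: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=2)
        fh.write("\n")


def _write_artifacts(est: KeyDriverAnalysis, config: PipelineConfig) -> None:
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    est.profile_.to_csv(os.path.join(out, "abundance_preprocessed.tsv"), sep="\t")
    est.network_.association_.to_csv(os.path.join(out, "association.tsv"), sep="\t")
    est.network_.distance_.to_csv(os.path.join(out, "distance.tsv"), sep="\t")
    est.partition_.to_frame().to_csv(
        os.path.join(out, "partition.tsv"), sep="\t", index=False
    )
    est.delegated_.scores_.rename("score").to_csv(
        os.path.join(out, "delegated_phenotype.tsv"), sep="\t"
    )
    with open(os.path.join(out, "delegated_phenotype.json"), "w") as fh:
        json.dump(
            {
                "theta": float(est.delegated_.theta_),
                "explained_variance": [float(v) for v in est.delegated_.explained_variance_],
            },
            fh,
            sort_keys=True,
            indent=2,
        )
        fh.write("\n")
    assoc = pd.DataFrame(
        [
            {
                "subnetwork_id": a.subnetwork_id,
                "size": a.size,
                "r": a.r,
                "p": a.p,
                "selected": a.selected,
            }
            for a in est.associations_
        ]
    )
    assoc.to_csv(os.path.join(out, "associations.tsv"), sep="\t", index=False)
    eig = pd.DataFrame({a.subnetwork_id: a.eigengene for a in est.associations_}).T
    eig.index.name = "subnetwork_id"
    eig.to_csv(os.path.join(out, "eigengenes.tsv"), sep="\t")
    write_report(est.report_, os.path.join(out, "keydrivers.json"))
    rows = []
    for sid in est.selected_:
        ns = est.node_scores_[sid]
        for rank, u in enumerate(ns.ranked(), start=1):
            rows.append(
                {
                    "subnetwork_id": sid,
                    "rank": rank,
                    "feature_id": u,
                    "pagerank": ns.scores[u],
                    "is_key_driver": u in est.key_drivers_[sid],
                }
            )
    pd.DataFrame(rows).to_csv(os.path.join(out, "keydrivers.tsv"), sep="\t", index=False)
    config_out = dataclasses.replace(config)
    config_out.to_yaml(os.path.join(out, "config.yaml"))
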