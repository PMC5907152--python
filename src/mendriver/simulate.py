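"""Simulators: tree-structured driven networks and planted-module fixtures.

The tree simulator emulates a key driver propagating its expression down
a regular tree: every gene drives ``k`` sub-genes through ``y = A*x + n``
with per-sample noise variance ``beta * x`` (multiplicative noise level).
The recovery benchmark re-infers a complete |PCC|-weighted network from
the simulated expressions and asks whether PageRank (or weighted degree)
puts the true root on top.

The planted-module generator builds a full synthetic study — an
abundance profile with hub-driven modules among independent background
features, plus a phenotype table with a disease label and nuisance
variables — for end-to-end validation of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .keydriver import pagerank_weights
from ._validation import spawn_rng

__all__ = [
    "SimulatedNetwork",
    "simulate_tree_network",
    "benchmark_recovery",
    "PlantedFixture",
    "generate_planted_fixture",
]

#: floor applied to a gene's expression before it drives offspring,
#: keeping the noise variance beta*x positive
_PARENT_FLOOR = 0.01


@dataclass
class SimulatedNetwork:
    """A driven tree network with its expression matrix."""

    tree: dict  # child id -> parent id (root absent)
    k: int
    depth: int
    beta: float
    A: float
    expressions: pd.DataFrame  # genes x samples
    root_id: str

    @property
    def n_genes(self) -> int:
        return self.expressions.shape[0]


def tree_gene_count(k: int, depth: int) -> int:
    """Total genes in a regular tree: sum of k^d for d = 0..depth."""
    return sum(k**d for d in range(depth + 1))


def simulate_tree_network(
    k: int,
    depth: int,
    beta: float,
    n_samples: int,
    A: float = 1.0,
    seed=None,
) -> SimulatedNetwork:
    """Simulate a regular driven tree of genes.

    The root (the planted key driver) is drawn i.i.d. Uniform(1, 10) per
    sample. Each gene then drives ``k`` sub-genes via ``y = A*x + n`` with
    ``n ~ Normal(0, sqrt(beta*x))`` per sample; a gene's expression is
    floored at a small positive value before it serves as a parent so the
    noise variance stays positive. One gene is driven by exactly one gene.
    """
    if k < 1 or depth < 1:
        raise ValueError("k and depth must be >= 1")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_genes = tree_gene_count(k, depth)
    width = len(str(n_genes - 1))
    ids = [f"g{i:0{width}d}" for i in range(n_genes)]
    expr = np.empty((n_genes, n_samples))
    expr[0] = rng.uniform(1.0, 10.0, size=n_samples)
    tree: dict[str, str] = {}
    frontier = [0]
    next_id = 1
    for _ in range(depth):
        new_frontier = []
        for parent in frontier:
            x = np.maximum(expr[parent], _PARENT_FLOOR)
            for _ in range(k):
                noise = rng.normal(0.0, np.sqrt(beta * x))
                expr[next_id] = A * x + noise
                tree[ids[next_id]] = ids[parent]
                new_frontier.append(next_id)
                next_id += 1
        frontier = new_frontier
    return SimulatedNetwork(
        tree=tree,
        k=k,
        depth=depth,
        beta=beta,
        A=A,
        expressions=pd.DataFrame(expr, index=ids, columns=[f"s{j}" for j in range(n_samples)]),
        root_id=ids[0],
    )


def _top1(scores: np.ndarray, ids: list) -> str:
    # descending score, lexicographic id tie-break
    order = sorted(range(len(ids)), key=lambda i: (-scores[i], ids[i]))
    return ids[order[0]]


def benchmark_recovery(
    k_grid,
    depth_grid,
    beta_grid,
    n_replicates: int = 100,
    n_samples: int = 100,
    A: float = 1.0,
    damping: float = 0.85,
    seed=None,
) -> pd.DataFrame:
    """Root-recovery precision of PageRank vs weighted degree.

    For every (k, depth, beta) cell and replicate, a tree network is
    simulated, the complete |PCC|-weighted graph over all genes is
    re-inferred from the expressions, and each scorer's top-1 node is
    compared with the true root. Returns one row per cell with both
    precisions and the exclusive-correct counts (replicates where exactly
    one scorer succeeds).
    """
    cells = list(product(k_grid, depth_grid, beta_grid))
    if not cells:
        raise ValueError("parameter grids must be nonempty")
    cell_rngs = spawn_rng(seed, len(cells))
    rows = []
    for rng, (k, depth, beta) in zip(cell_rngs, cells):
        pr_hits = deg_hits = pr_only = deg_only = 0
        for _ in range(n_replicates):
            net = simulate_tree_network(k, depth, beta, n_samples, A=A, seed=rng)
            V = net.expressions.to_numpy()
            with np.errstate(invalid="ignore", divide="ignore"):
                C = np.corrcoef(V)
            C[np.isnan(C)] = 0.0
            W = np.abs(C)
            np.fill_diagonal(W, 0.0)
            ids = list(net.expressions.index)
            pr, _ = pagerank_weights(W, c=damping, tol=1e-10, max_iter=1000)
            pr_ok = _top1(pr, ids) == net.root_id
            deg_ok = _top1(W.sum(axis=1), ids) == net.root_id
            pr_hits += pr_ok
            deg_hits += deg_ok
            pr_only += pr_ok and not deg_ok
            deg_only += deg_ok and not pr_ok
        rows.append(
            {
                "k": k,
                "depth": depth,
                "beta": beta,
                "n_replicates": n_replicates,
                "pagerank_precision": pr_hits / n_replicates,
                "degree_precision": deg_hits / n_replicates,
                "pagerank_only": pr_only,
                "degree_only": deg_only,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PlantedFixture:
    """Synthetic study with known ground truth."""

    abundance: pd.DataFrame  # features x samples, non-negative
    phenotype: pd.DataFrame  # samples x variables, includes 'disease'
    disease_column: str
    truth: dict = field(default_factory=dict)


def generate_planted_fixture(
    n_background: int = 200,
    module_sizes=(10,),
    n_samples: int = 100,
    effect_size: float = 2.0,
    beta: float = 0.1,
    n_nuisance_phenotypes: int = 8,
    seed=None,
) -> PlantedFixture:
    """Planted-module abundance profile plus matched phenotype table.

    Background features are i.i.d. lognormal noise. Each module is a hub
    plus ``size - 1`` members driven by the hub (``y = x + n``, noise
    variance ``beta * x``), so module members co-vary and the hub is the
    strongest-connected node. The *first* module's hub is shifted upward
    in disease samples by ``effect_size`` standard deviations of its base
    expression, planting a disease association that propagates to the
    whole module. The phenotype table holds the Y/N disease label, a few
    label-correlated nuisance variables (numeric and categorical) and
    pure-noise variables.
    """
    if n_samples < 6:
        raise ValueError("need at least 6 samples")
    if any(s < 2 for s in module_sizes):
        raise ValueError("modules need at least 2 members (hub + 1)")
    (rng,) = spawn_rng(seed, 1)

    samples = [f"s{j:03d}" for j in range(n_samples)]
    disease = np.zeros(n_samples, dtype=bool)
    disease[rng.permutation(n_samples)[: n_samples // 2]] = True

    features = {}
    truth_modules = {}
    truth_hubs = {}
    for m, size in enumerate(module_sizes, start=1):
        hub_id = f"mod{m}_hub"
        base = rng.uniform(1.0, 10.0, size=n_samples)
        x = base.copy()
        if m == 1 and effect_size != 0.0:
            x = x + effect_size * base.std() * disease
        features[hub_id] = x
        members = [hub_id]
        xp = np.maximum(x, _PARENT_FLOOR)
        for g in range(1, size):
            gid = f"mod{m}_g{g:02d}"
            features[gid] = np.clip(xp + rng.normal(0.0, np.sqrt(beta * xp)), 0.0, None)
            members.append(gid)
        truth_modules[m] = members
        truth_hubs[m] = hub_id
    for b in range(n_background):
        features[f"bg{b:04d}"] = rng.lognormal(mean=1.0, sigma=0.6, size=n_samples)

    abundance = pd.DataFrame(features, index=samples).T

    # half the nuisance variables carry disease signal, half are pure noise;
    # one of each kind is categorical to exercise digitization
    pheno = {"disease": np.where(disease, "Y", "N")}
    n_info = max(1, n_nuisance_phenotypes // 2)
    for i in range(n_nuisance_phenotypes):
        if i < n_info:
            if i == 0 and n_info > 1:
                flip = rng.random(n_samples) < 0.2
                pheno[f"var_cat_info{i}"] = np.where(disease ^ flip, "A", "B")
            else:
                pheno[f"var_info{i}"] = 1.5 * disease + rng.normal(0.0, 1.0, n_samples)
        elif i == n_nuisance_phenotypes - 1:
            pheno[f"var_cat_noise{i}"] = rng.choice(["L", "R"], size=n_samples)
        else:
            pheno[f"var_noise{i}"] = rng.normal(0.0, 1.0, n_samples)
    phenotype = pd.DataFrame(pheno, index=samples)

    return PlantedFixture(
        abundance=abundance,
        phenotype=phenotype,
        disease_column="disease",
        truth={
            "modules": truth_modules,
            "hubs": truth_hubs,
            "disease_module": 1,
            "disease_hub": truth_hubs[1],
        },
    )
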