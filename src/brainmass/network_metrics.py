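"""Weighted graph-theory characterization of structural connectomes.

Covers the metrics retained for analysis — global efficiency, modularity with
partition stability, participation coefficient — plus the candidate metrics
(strength, degree, betweenness, clustering, local efficiency, communicability,
density) that feed the de-correlation selection step.  Distances use the
1/weight edge-length convention common in weighted brain-network analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .connectome import StructuralConnectome

__all__ = [
    "Partition",
    "global_efficiency",
    "modularity_partition",
    "participation_coefficient",
    "select_metrics",
    "candidate_metrics",
]


@dataclass(frozen=True)
class Partition:
    """Node-to-module assignment with its Newman modularity Q."""

    module_of: np.ndarray  # contiguous module ids from 0, length n
    q_value: float

    @property
    def n_modules(self) -> int:
        return int(self.module_of.max()) + 1


def _length_matrix(weights: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lengths = np.where(weights > 0, 1.0 / weights, np.inf)
    np.fill_diagonal(lengths, 0.0)
    return lengths


def global_efficiency(sc: StructuralConnectome) -> float:
    """Average inverse shortest path length over ordered node pairs.

    Edge lengths are 1/weight; unreachable pairs contribute 0 (1/inf).
    """
    w = sc.weights
    n = w.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    lengths = _length_matrix(w)
    finite = np.where(np.isfinite(lengths), lengths, 0.0)
    d = dijkstra(csr_matrix(finite), directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def _to_graph(sc: StructuralConnectome) -> nx.Graph:
    return nx.from_numpy_array(sc.weights)


def modularity_partition(sc: StructuralConnectome, n_iter: int = 100,
                         gamma: float = 1.0, seed: int = 0
                         ) -> tuple[Partition, float]:
    """Best-of-``n_iter`` Louvain modularity maximization, with stability.

    Runs Louvain ``n_iter`` times under distinct sub-seeds and keeps the
    highest-Q partition.  Stability quantifies how reproducible that partition
    is across iterations: for each node, the fraction of iterations in which
    its best-partition module mates are co-assigned with it, averaged over
    mates, then over nodes; reported in percent.  A node alone in its module
    counts as fully stable.

    Returns ``(partition, stability_percent)``.
    """
    g = _to_graph(sc)
    n = sc.n_regions
    labelings = np.empty((n_iter, n), dtype=np.int64)
    qs = np.empty(n_iter)
    for it in range(n_iter):
        comms = nx.community.louvain_communities(
            g, weight="weight", resolution=gamma,
            seed=int((seed * 1009 + it) % (2**31 - 1)),
        )
        lab = np.empty(n, dtype=np.int64)
        for m, nodes in enumerate(comms):
            for v in nodes:
                lab[v] = m
        labelings[it] = lab
        qs[it] = nx.community.modularity(g, comms, weight="weight", resolution=gamma)
    best_it = int(np.argmax(qs))
    best = labelings[best_it]
    # relabel contiguously in order of first appearance
    order = {}
    contiguous = np.empty(n, dtype=np.int64)
    for i, m in enumerate(best):
        if m not in order:
            order[m] = len(order)
        contiguous[i] = order[m]
    # co-classification agreement with the best partition
    same_best = best[:, None] == best[None, :]
    co_frac = np.zeros((n, n))
    for it in range(n_iter):
        co_frac += labelings[it][:, None] == labelings[it][None, :]
    co_frac /= n_iter
    per_node = np.empty(n)
    for i in range(n):
        mates = same_best[i].copy()
        mates[i] = False
        per_node[i] = co_frac[i, mates].mean() if mates.any() else 1.0
    stability = float(per_node.mean() * 100.0)
    return Partition(module_of=contiguous, q_value=float(qs[best_it])), stability


def participation_coefficient(sc: StructuralConnectome,
                              partition: Partition) -> np.ndarray:
    """Weighted participation coefficient P_i = 1 - sum_m (k_im / k_i)^2.

    k_i is node strength, k_im the strength of node i's links into module m.
    Nodes with zero strength get P_i = 0.
    """
    labels = np.asarray(partition.module_of)
    if labels.shape[0] != sc.n_regions:
        raise ValueError("partition does not match the connectome")
    w = sc.weights
    k = w.sum(axis=1)
    n_mod = int(labels.max()) + 1
    k_im = np.zeros((sc.n_regions, n_mod))
    for m in range(n_mod):
        k_im[:, m] = w[:, labels == m].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(k[:, None] > 0, k_im / k[:, None], 0.0)
    p = 1.0 - (frac**2).sum(axis=1)
    p = np.clip(p, 0.0, 1.0)  # guard float cancellation at exactly 0
    return np.where(k > 0, p, 0.0)


def candidate_metrics(sc: StructuralConnectome, seed: int = 0,
                      n_iter: int = 100) -> dict[str, float]:
    """The full candidate metric panel entering the de-correlation selection."""
    g = _to_graph(sc)
    part, _ = modularity_partition(sc, n_iter=n_iter, seed=seed)
    lengths = {
        (u, v): 1.0 / d["weight"]
        for u, v, d in g.edges(data=True)
        if d["weight"] > 0
    }
    nx.set_edge_attributes(g, lengths, "length")
    strength = sc.in_strength()
    return {
        "global_efficiency": global_efficiency(sc),
        "modularity_q": part.q_value,
        "mean_participation": float(participation_coefficient(sc, part).mean()),
        "mean_strength": float(strength.mean()),
        "mean_degree": float((sc.weights > 0).sum(axis=1).mean()),
        "density": float(nx.density(g)),
        "mean_betweenness": float(
            np.mean(list(nx.betweenness_centrality(g, weight="length").values()))
        ),
        "mean_clustering": float(nx.average_clustering(g, weight="weight")),
    }


def select_metrics(metric_matrix, threshold: float = 0.80):
    """Greedy de-correlation of a subjects-by-metrics table.

    Repeatedly finds the most correlated metric pair with |r| >= ``threshold``
    and drops the member of the pair with the larger mean absolute correlation
    to the remaining metrics, until all pairwise |r| < threshold.  Returns
    ``(retained_names, loadings)`` where ``loadings`` is a DataFrame of the
    first two principal-component loadings of the retained, standardized set.
    """
    import pandas as pd

    df = pd.DataFrame(metric_matrix)
    if len(df) < 3:
        raise ValueError("need at least 3 subjects")
    if (df.std(ddof=1) == 0).any():
        bad = df.columns[df.std(ddof=1) == 0].tolist()
        raise ValueError(f"constant metric column(s): {bad}")
    retained = list(df.columns)
    while len(retained) > 1:
        corr = df[retained].corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        if abs(corr[i, j]) < threshold:
            break
        mean_abs = np.abs(corr).sum(axis=1) / (len(retained) - 1)
        drop = i if mean_abs[i] >= mean_abs[j] else j
        retained.pop(drop)
    x = df[retained].to_numpy(dtype=float)
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    n_pc = min(2, vt.shape[0])
    loadings = pd.DataFrame(
        vt[:n_pc].T, index=retained, columns=[f"PC{k+1}" for k in range(n_pc)]
    )
    return retained, loadings
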