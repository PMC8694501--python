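"""Consensus ensemble: fuse M algorithm partitions into one subtyping.

Each algorithm contributes a hard partition; the ensemble consensus matrix
holds the fraction of algorithms that co-cluster each sample pair, and the
final subtype labels come from a Ward-linkage cut of 1 - consensus. The
proportion of ambiguous clustering (PAC, fraction of off-diagonal entries
strictly inside (0.1, 0.9)) and the mean silhouette on the consensus
dissimilarity quantify ensemble stability.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.special import comb
from sklearn.metrics import silhouette_score

from .cluster import ClusteringResult


@dataclass
class ConsensusMatrix:
    """Sample x sample co-clustering frequency across algorithms."""

    values: np.ndarray
    sample_ids: list[str]
    contributing_algorithms: list[str]

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("consensus matrix must be symmetric")
        if v.min() < 0 or v.max() > 1 + 1e-12:
            raise ValueError("consensus entries must lie in [0, 1]")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("consensus diagonal must be 1")


@dataclass
class EnsembleResult:
    """Final consensus subtyping with stability summaries."""

    labels: np.ndarray  # 1-based, numbered by decreasing cluster size
    k: int
    pac: float
    mean_silhouette: float
    sample_ids: list[str]


def build_consensus_matrix(results: list[ClusteringResult]) -> ConsensusMatrix:
    """Co-clustering frequency: entry (i,j) = fraction of partitions in which
    samples i and j share a cluster."""
    if len(results) < 2:
        raise ValueError("need at least 2 partitions")
    ref = results[0].sample_ids
    for r in results[1:]:
        if r.sample_ids != ref:
            raise ValueError(f"partition {r.algorithm!r} has a different sample set")
    n = len(ref)
    M = np.zeros((n, n))
    for r in results:
        lab = r.labels
        M += (lab[:, None] == lab[None, :]).astype(float)
    M /= len(results)
    return ConsensusMatrix(values=M, sample_ids=list(ref),
                           contributing_algorithms=[r.algorithm for r in results])


def _canonical_order(labels: np.ndarray) -> np.ndarray:
    """Renumber clusters 1..k by decreasing size (ties by first appearance)."""
    uniq, counts = np.unique(labels, return_counts=True)
    first_seen = {u: int(np.argmax(labels == u)) for u in uniq}
    order = sorted(uniq, key=lambda u: (-counts[list(uniq).index(u)], first_seen[u]))
    remap = {u: i + 1 for i, u in enumerate(order)}
    return np.array([remap[u] for u in labels])


def ensemble_labels(
    M: ConsensusMatrix, k: int, pac_bounds: tuple[float, float] = (0.1, 0.9),
) -> EnsembleResult:
    """Cut the consensus matrix into k subtypes.

    Ward-linkage hierarchical clustering on the dissimilarity 1 - M; labels
    are renumbered by decreasing cluster size so outputs are reproducible.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    D = 1.0 - M.values
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    if np.unique(raw).size < k:
        warnings.warn(f"ensemble: only {np.unique(raw).size} distinct consensus blocks for k={k}")
    labels = _canonical_order(raw)

    off = ~np.eye(len(M.sample_ids), dtype=bool)
    vals = M.values[off]
    pac = float(((vals > pac_bounds[0]) & (vals < pac_bounds[1])).mean())
    if np.unique(labels).size > 1:
        sil = float(silhouette_score(D, labels, metric="precomputed"))
    else:
        sil = float("nan")
    return EnsembleResult(labels=labels, k=int(np.unique(labels).size), pac=pac,
                          mean_silhouette=sil, sample_ids=M.sample_ids)


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected agreement between two partitions.

    ARI = (sum_ij C(n_ij,2) - E) / (0.5 (sum_i C(a_i,2) + sum_j C(b_j,2)) - E)
    with E the product of marginal pair counts over C(n,2); 1 for identical
    partitions (up to relabeling), ~0 for independent ones.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    n = a.size
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    cont = np.zeros((ua.size, ub.size))
    np.add.at(cont, (ia, ib), 1)
    sum_ij = comb(cont, 2).sum()
    sum_a = comb(cont.sum(axis=1), 2).sum()
    sum_b = comb(cont.sum(axis=0), 2).sum()
    total = comb(n, 2)
    if total == 0:
        return 1.0
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))
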