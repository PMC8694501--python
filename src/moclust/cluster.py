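"""Five integrative clustering algorithms behind a uniform interface.

The algorithms span the main families used for multi-omics subtype
discovery:

* ``snf`` — similarity network fusion: per-layer scaled-exponential
  kernels, cross-layer diffusion, spectral clustering of the fused graph;
* ``cc`` — Monti-style consensus clustering: repeated k-means on 80%
  sample subsamples of the concatenated layers, hierarchical cut of the
  co-clustering frequency matrix;
* ``intnmf`` — joint non-negative matrix factorization with a shared
  sample-factor matrix across layers;
* ``coca`` — cluster-of-clusters: per-layer clustering, one-hot stacking
  of memberships, consensus clustering of the indicator matrix;
* ``spectral`` — spectral clustering of a single kernel on the
  concatenated z-scored continuous layers.

All return a :class:`ClusteringResult` with 1-based labels in which every
index 1..k appears. Evaluation downstream is relabeling-invariant (ARI).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans, spectral_clustering

from .io import MultiOmicsDataset, OmicsLayer

logger = logging.getLogger("moclust")

ALGORITHMS = ("snf", "cc", "intnmf", "coca", "spectral")


@dataclass
class ClusteringResult:
    """One algorithm's hard partition of the samples at a given k."""

    algorithm: str
    k: int
    labels: np.ndarray  # 1-based, every index in 1..k present
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size != len(self.sample_ids):
            raise ValueError("labels length does not match sample_ids")
        present = np.unique(self.labels)
        if present.min() < 1 or present.max() > self.k or present.size != self.k:
            raise ValueError(f"labels must cover 1..{self.k}; got {present}")


@dataclass
class SimilarityMatrix:
    """Symmetric non-negative sample x sample similarity."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.sample_ids):
            raise ValueError("similarity matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("similarity matrix not symmetric within 1e-9")
        if v.min() < 0:
            raise ValueError("similarity matrix has negative entries")


@dataclass
class AlgorithmParams:
    """Tuning knobs shared across the five algorithms.

    ``K_neighbors`` defaults to min(20, n // 10) at call time when unset.
    """

    K_neighbors: int | None = None
    mu: float = 0.5
    t_iterations: int = 20
    n_resamples: int = 100
    subsample_frac: float = 0.8
    n_restarts: int = 10
    max_iter: int = 200
    tol: float = 1e-5
    seed: int = 0

    def resolved_K(self, n: int) -> int:
        K = self.K_neighbors if self.K_neighbors is not None else min(20, max(2, n // 10))
        if K >= n:
            raise ValueError(f"K_neighbors={K} must be < n={n}")
        return K

    def __post_init__(self) -> None:
        if not 0 < self.subsample_frac < 1:
            raise ValueError("subsample_frac must lie in (0, 1)")


def _finalize(labels: np.ndarray, k: int, algorithm: str, sample_ids: list[str]) -> ClusteringResult:
    """Map arbitrary labels to consecutive 1..k'; warn if fewer than k groups."""
    uniq = np.unique(labels)
    remap = {u: i + 1 for i, u in enumerate(uniq)}
    lab = np.array([remap[u] for u in labels])
    if uniq.size != k:
        warnings.warn(f"{algorithm}: produced {uniq.size} clusters instead of {k}")
    return ClusteringResult(algorithm=algorithm, k=uniq.size, labels=lab, sample_ids=sample_ids)


# ---------------------------------------------------------------------------
# kernels


def _layer_distance(layer: OmicsLayer) -> np.ndarray:
    """Sample x sample distances: Euclidean on z-scored features, or Hamming
    fraction for binary layers."""
    if layer.kind == "binary":
        return squareform(pdist(layer.values.to_numpy().T, metric="hamming"))
    return squareform(pdist(layer.zscored().T, metric="euclidean"))


def _scaled_exp_kernel(dist: np.ndarray, K: int, mu: float) -> np.ndarray:
    """Scaled exponential kernel W(i,j) = exp(-d(i,j)^2 / (mu * eps_ij)),
    eps_ij = (mean d to i's K nearest + mean d to j's K nearest + d(i,j)) / 3."""
    n = dist.shape[0]
    sorted_d = np.sort(dist, axis=1)
    # column 0 is the zero self-distance
    knn_mean = sorted_d[:, 1:K + 1].mean(axis=1)
    eps = (knn_mean[:, None] + knn_mean[None, :] + dist) / 3.0
    eps = np.maximum(eps, 1e-12)
    W = np.exp(-(dist ** 2) / (mu * eps))
    return (W + W.T) / 2.0


def affinity(layer: OmicsLayer, params: AlgorithmParams | None = None) -> SimilarityMatrix:
    """Scaled exponential kernel similarity for one layer."""
    params = params or AlgorithmParams()
    n = layer.n_samples
    if n < 3:
        raise ValueError("affinity requires at least 3 samples")
    K = params.resolved_K(n)
    W = _scaled_exp_kernel(_layer_distance(layer), K, params.mu)
    return SimilarityMatrix(values=W, sample_ids=layer.sample_ids)


def affinity_from_matrix(X: np.ndarray, params: AlgorithmParams | None = None) -> np.ndarray:
    """Kernel on a raw samples x features matrix (already scaled)."""
    params = params or AlgorithmParams()
    n = X.shape[0]
    if n < 3:
        raise ValueError("affinity requires at least 3 samples")
    dist = squareform(pdist(X, metric="euclidean"))
    return _scaled_exp_kernel(dist, params.resolved_K(n), params.mu)


# ---------------------------------------------------------------------------
# SNF


def _row_normalize_full(W: np.ndarray) -> np.ndarray:
    """SNF full-kernel normalization: off-diagonal mass 1/2 per row, diagonal 1/2."""
    P = W.copy()
    np.fill_diagonal(P, 0.0)
    rs = P.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    P = P / (2.0 * rs)
    np.fill_diagonal(P, 0.5)
    return P


def _knn_kernel(W: np.ndarray, K: int) -> np.ndarray:
    """Row-normalized K-nearest-neighbour sparsification (local transition)."""
    n = W.shape[0]
    S = np.zeros_like(W)
    Woff = W.copy()
    np.fill_diagonal(Woff, -np.inf)
    idx = np.argsort(Woff, axis=1)[:, ::-1][:, :K]
    rows = np.repeat(np.arange(n), K)
    S[rows, idx.ravel()] = W[rows, idx.ravel()]
    rs = S.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    return S / rs


def _sinkhorn_symmetric(M: np.ndarray, iters: int = 200, tol: float = 1e-12) -> np.ndarray:
    """Symmetric Sinkhorn scaling to a (near) doubly stochastic matrix."""
    M = M.copy()
    for _ in range(iters):
        r = M.sum(axis=1)
        if np.abs(r - 1.0).max() < tol:
            break
        d = 1.0 / np.sqrt(r)
        M = M * d[:, None] * d[None, :]
    return M


def snf_fuse(kernels: list[np.ndarray], K: int, t_iterations: int = 20) -> np.ndarray:
    """Similarity network fusion of per-layer kernels.

    Iterates the cross-diffusion P_v <- S_v . mean(P_w, w != v) . S_v^T with
    row renormalization; the fused matrix is the mean of the diffused
    kernels, symmetrized and Sinkhorn-scaled so it is symmetric with unit
    row sums.
    """
    P = [_row_normalize_full(W) for W in kernels]
    S = [_knn_kernel(W, K) for W in kernels]
    V = len(kernels)
    if V == 1:
        fused = P[0]
    else:
        for _ in range(t_iterations):
            P_new = []
            for v in range(V):
                others = sum(P[w] for w in range(V) if w != v) / (V - 1)
                Pv = S[v] @ others @ S[v].T
                P_new.append(_row_normalize_full((Pv + Pv.T) / 2.0))
            P = P_new
        fused = sum(P) / V
    fused = (fused + fused.T) / 2.0
    return _sinkhorn_symmetric(fused)


def _spectral_on_affinity(W: np.ndarray, k: int, seed: int) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lab = spectral_clustering(W, n_clusters=k, random_state=seed, assign_labels="kmeans")
    return lab


def snf_cluster(
    dataset: MultiOmicsDataset, k: int, params: AlgorithmParams | None = None,
) -> ClusteringResult:
    """Similarity-network-fusion clustering across all layers."""
    params = params or AlgorithmParams()
    n = dataset.n_samples
    K = params.resolved_K(n)
    kernels = [affinity(layer, params).values for layer in dataset.layers]
    if len(kernels) == 1:
        warnings.warn("snf: single layer; falling back to spectral clustering of its kernel")
        fused = kernels[0]
    else:
        fused = snf_fuse(kernels, K, params.t_iterations)
    labels = _spectral_on_affinity(fused, k, params.seed) + 1
    return _finalize(labels, k, "snf", dataset.sample_ids)


# ---------------------------------------------------------------------------
# Monti consensus clustering


def monti_consensus(
    X: np.ndarray, k: int, n_resamples: int, subsample_frac: float, seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Resampled k-means co-clustering.

    Returns the consensus frequency matrix (co-clustered / co-sampled, 0
    where a pair was never co-sampled) and final labels from an
    average-linkage cut of 1 - frequency.
    """
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    m = max(k + 1, int(round(subsample_frac * n)))
    together = np.zeros((n, n))
    sampled = np.zeros((n, n))
    for _ in range(n_resamples):
        idx = rng.choice(n, size=m, replace=False)
        lab = KMeans(k, n_init=2, random_state=int(rng.integers(2 ** 31))).fit_predict(X[idx])
        sampled[np.ix_(idx, idx)] += 1
        for c in range(k):
            members = idx[lab == c]
            together[np.ix_(members, members)] += 1
    never = sampled == 0
    np.fill_diagonal(never, False)
    if never.any():
        warnings.warn("consensus: some sample pairs never co-sampled; raise n_resamples")
    freq = np.divide(together, sampled, out=np.zeros_like(together), where=sampled > 0)
    np.fill_diagonal(freq, 1.0)
    freq = (freq + freq.T) / 2.0
    Z = linkage(squareform(1.0 - freq, checks=False), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return freq, labels


def consensus_kmeans(
    dataset: MultiOmicsDataset, k: int, params: AlgorithmParams | None = None,
) -> ClusteringResult:
    """Monti-style consensus clustering of the concatenated z-scored layers."""
    params = params or AlgorithmParams()
    X = np.vstack([l.zscored() for l in dataset.layers]).T
    _, labels = monti_consensus(X, k, params.n_resamples, params.subsample_frac, params.seed)
    return _finalize(labels, k, "cc", dataset.sample_ids)


# ---------------------------------------------------------------------------
# joint NMF


def _jnmf_once(
    Xs: list[np.ndarray], thetas: np.ndarray, k: int, rng: np.random.Generator,
    max_iter: int, tol: float,
) -> tuple[np.ndarray, float, list[float]]:
    """One joint-NMF run: min sum_v theta_v ||X_v - W H_v||_F^2 over
    non-negative W (n x k, shared) and H_v, by multiplicative updates."""
    n = Xs[0].shape[0]
    eps = 1e-10
    scale = np.mean([X.mean() for X in Xs])
    W = rng.uniform(eps, 1.0, size=(n, k)) * np.sqrt(scale)
    Hs = [rng.uniform(eps, 1.0, size=(k, X.shape[1])) * np.sqrt(scale) for X in Xs]

    def objective() -> float:
        return float(sum(th * np.linalg.norm(X - W @ H, "fro") ** 2
                         for th, X, H in zip(thetas, Xs, Hs)))

    history = [objective()]
    for _ in range(max_iter):
        num = sum(th * (X @ H.T) for th, X, H in zip(thetas, Xs, Hs))
        den = W @ sum(th * (H @ H.T) for th, H in zip(thetas, Hs)) + eps
        W = W * (num / den)
        Hs = [H * ((W.T @ X) / (W.T @ W @ H + eps)) for X, H in zip(Xs, Hs)]
        history.append(objective())
        if abs(history[-2] - history[-1]) <= tol * max(history[-2], eps):
            break
    return W, history[-1], history


def intnmf_cluster(
    dataset: MultiOmicsDataset, k: int, params: AlgorithmParams | None = None,
    return_history: bool = False,
):
    """Joint NMF across layers with a shared sample-factor matrix.

    Layers are min-subtracted per feature to be non-negative and weighted by
    theta_v = 1 / ||X_v||_F^2; labels are the argmax factor per sample; the
    best of ``n_restarts`` random restarts (by objective) is kept.
    """
    params = params or AlgorithmParams()
    Xs = []
    for layer in dataset.layers:
        V = layer.values.to_numpy(dtype=float).T  # samples x features
        Xs.append(V - V.min(axis=0, keepdims=True))
    thetas = np.array([1.0 / max(np.linalg.norm(X, "fro") ** 2, 1e-12) for X in Xs])
    rng = np.random.default_rng(params.seed)
    best = None
    for _ in range(params.n_restarts):
        W, obj, hist = _jnmf_once(Xs, thetas, k, rng, params.max_iter, params.tol)
        if best is None or obj < best[1]:
            best = (W, obj, hist)
    W, obj, hist = best
    labels = W.argmax(axis=1) + 1
    result = _finalize(labels, k, "intnmf", dataset.sample_ids)
    if return_history:
        return result, hist
    return result


# ---------------------------------------------------------------------------
# COCA


def _kmodes_binary(X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 50) -> np.ndarray:
    """k-modes for 0/1 data: Hamming assignment, majority-vote mode update."""
    n = X.shape[0]
    modes = X[rng.choice(n, size=k, replace=False)].astype(float)
    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        d = np.abs(X[:, None, :] - modes[None, :, :]).mean(axis=2)
        new = d.argmin(axis=1)
        if (new == labels).all():
            break
        labels = new
        for c in range(k):
            if (labels == c).any():
                modes[c] = (X[labels == c].mean(axis=0) >= 0.5).astype(float)
    return labels


def coca_cluster(
    dataset: MultiOmicsDataset, k: int, params: AlgorithmParams | None = None,
) -> ClusteringResult:
    """Cluster-of-clusters: per-layer partitions, one-hot stacked, consensus-clustered."""
    params = params or AlgorithmParams()
    if len(dataset.layers) < 2:
        raise ValueError("coca requires at least 2 layers")
    rng = np.random.default_rng(params.seed)
    n = dataset.n_samples
    indicators = []
    for layer in dataset.layers:
        if layer.kind == "binary":
            lab = _kmodes_binary(layer.values.to_numpy().T, k, rng)
        else:
            lab = KMeans(k, n_init=params.n_restarts,
                         random_state=int(rng.integers(2 ** 31))).fit_predict(layer.zscored().T)
        if np.unique(lab).size < k:
            warnings.warn(f"coca: layer {layer.name!r} produced fewer than {k} clusters; dropped")
            continue
        onehot = np.zeros((n, k))
        onehot[np.arange(n), lab] = 1.0
        indicators.append(onehot)
    M = np.hstack(indicators)
    _, labels = monti_consensus(M, k, params.n_resamples, params.subsample_frac, params.seed)
    return _finalize(labels, k, "coca", dataset.sample_ids)


# ---------------------------------------------------------------------------
# spectral on concatenated continuous layers


def spectral_concat_cluster(
    dataset: MultiOmicsDataset, k: int, params: AlgorithmParams | None = None,
) -> ClusteringResult:
    """Spectral clustering of one kernel on the concatenated continuous layers."""
    params = params or AlgorithmParams()
    X = dataset.concat_continuous()
    W = affinity_from_matrix(X, params)
    labels = _spectral_on_affinity(W, k, params.seed) + 1
    return _finalize(labels, k, "spectral", dataset.sample_ids)


_DISPATCH = {
    "snf": snf_cluster,
    "cc": consensus_kmeans,
    "intnmf": intnmf_cluster,
    "coca": coca_cluster,
    "spectral": spectral_concat_cluster,
}


def run_algorithm(
    name: str, dataset: MultiOmicsDataset, k: int, params: AlgorithmParams | None = None,
) -> ClusteringResult:
    """Dispatch one of the five algorithms by name."""
    if name not in _DISPATCH:
        raise KeyError(f"unknown algorithm {name!r}; choose from {ALGORITHMS}")
    return _DISPATCH[name](dataset, k, params)
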