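"""Cluster-number selection: gap statistic and clustering prediction index.

Both criteria operate on the concatenated z-scored continuous layers.

The gap statistic compares the log pooled within-cluster dispersion of the
k-means partition at each k against its expectation under B reference
datasets drawn uniformly over each feature's observed range; the classic
choice rule picks the smallest k whose gap is within one reference standard
error of the next one.

The clustering prediction index (CPI) is a subsample / predict / agree
stability score: cluster an 80% subsample, assign held-out samples to the
nearest subsample centroid, and measure the ARI between the stitched
labels and the full-data clustering; reproducible structure at the right
k yields a high CPI.

The combined rule averages the min-max-normalized curves; an optional
externally supplied prior cluster count breaks ties.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .ensemble import adjusted_rand_index
from .io import MultiOmicsDataset

logger = logging.getLogger("moclust")


@dataclass
class ModelSelectionCurve:
    """Per-k criterion values and the combined choice."""

    k_values: list[int]
    cpi_mean: np.ndarray
    cpi_sd: np.ndarray
    gap: np.ndarray
    gap_sd: np.ndarray
    chosen_k: int
    gap_rule_k: int | None = None  # Tibshirani one-SE choice, if defined

    def __post_init__(self) -> None:
        ks = list(self.k_values)
        if any(b <= a for a, b in zip(ks, ks[1:])):
            raise ValueError("k_values must be strictly increasing")


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, MultiOmicsDataset):
        return data.concat_continuous()
    return np.asarray(data, dtype=float)


def _pooled_within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    """W_k = sum_r (1/(2 n_r)) sum_{i,i' in C_r} d^2(i,i') — equal to the
    within-cluster sum of squared distances to centroids."""
    W = 0.0
    for c in np.unique(labels):
        pts = X[labels == c]
        W += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return W


def _kmeans_labels(X: np.ndarray, k: int, seed: int, n_init: int = 4) -> np.ndarray:
    if k == 1:
        return np.zeros(X.shape[0], dtype=int)
    return KMeans(k, n_init=n_init, random_state=seed).fit_predict(X)


def gap_statistic(
    data, k_range: Sequence[int], B: int = 50, seed: int = 0, n_init: int = 4,
) -> tuple[np.ndarray, np.ndarray, int | None]:
    """Gap(k) = mean_b log W*_kb - log W_k with uniform-box references.

    Returns (gap, s_k, chosen_k) where s_k = sd_b(log W*_kb) sqrt(1 + 1/B)
    and chosen_k is the smallest k with Gap(k) >= Gap(k+1) - s_{k+1}
    (None when the rule never fires within the range).
    """
    if B < 10:
        raise ValueError("B must be >= 10")
    X = _as_matrix(data)
    n = X.shape[0]
    k_range = list(k_range)
    if max(k_range) >= n:
        raise ValueError("max of k_range must be < number of samples")
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)

    log_W = np.empty(len(k_range))
    log_W_ref = np.empty((B, len(k_range)))
    refs = [rng.uniform(lo, hi, size=X.shape) for _ in range(B)]
    for j, k in enumerate(k_range):
        log_W[j] = np.log(_pooled_within_dispersion(X, _kmeans_labels(X, k, seed, n_init)))
        for b, R in enumerate(refs):
            log_W_ref[b, j] = np.log(
                _pooled_within_dispersion(R, _kmeans_labels(R, k, seed + 1 + b, n_init))
            )
    gap = log_W_ref.mean(axis=0) - log_W
    s_k = log_W_ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)

    chosen = None
    for j in range(len(k_range) - 1):
        if gap[j] >= gap[j + 1] - s_k[j + 1]:
            chosen = k_range[j]
            break
    if chosen is None and len(k_range) == 1:
        chosen = k_range[0]
    return gap, s_k, chosen


def _stitched_labels(
    X: np.ndarray, k: int, subsample_frac: float, rng: np.random.Generator, n_init: int,
) -> np.ndarray | None:
    n = X.shape[0]
    m = max(k + 1, int(round(subsample_frac * n)))
    idx = rng.choice(n, size=m, replace=False)
    km = KMeans(k, n_init=n_init, random_state=int(rng.integers(2 ** 31)))
    sub_labels = km.fit_predict(X[idx])
    if np.unique(sub_labels).size < k:
        return None  # subsample lost a cluster; round discarded
    stitched = np.empty(n, dtype=int)
    stitched[idx] = sub_labels
    held = np.setdiff1d(np.arange(n), idx)
    if held.size:
        d = ((X[held][:, None, :] - km.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        stitched[held] = d.argmin(axis=1)
    return stitched


def cluster_prediction_index(
    data, k_range: Sequence[int], B: int = 20, seed: int = 0,
    subsample_frac: float = 0.8, n_init: int = 4,
    algorithm: Callable[[np.ndarray, int, int], np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """CPI(k) = mean over B rounds of ARI(full-data clustering, stitched
    subsample/held-out labels). Returns (mean, sd) per k.

    ``algorithm(X, k, seed) -> labels`` overrides the full-data clustering;
    the subsample/assignment step always runs in k-means representation
    space (centroid assignment of held-out samples).
    """
    if B < 10:
        raise ValueError("B must be >= 10")
    X = _as_matrix(data)
    cpi_mean = np.empty(len(list(k_range)))
    cpi_sd = np.empty_like(cpi_mean)
    for j, k in enumerate(k_range):
        rng = np.random.default_rng(seed + 1000 * k)
        if algorithm is None:
            full = _kmeans_labels(X, k, seed, n_init=max(n_init, 10))
        else:
            full = np.asarray(algorithm(X, k, seed))
        scores = []
        for _ in range(B):
            stitched = _stitched_labels(X, k, subsample_frac, rng, n_init)
            if stitched is None:
                logger.info("CPI: discarded a round at k=%d (subsample lost a cluster)", k)
                continue
            scores.append(adjusted_rand_index(full, stitched))
        scores = np.asarray(scores if scores else [0.0])
        cpi_mean[j] = scores.mean()
        cpi_sd[j] = scores.std(ddof=0)
    return cpi_mean, cpi_sd


def _minmax(v: np.ndarray) -> np.ndarray:
    rng_ = v.max() - v.min()
    if rng_ == 0:
        return np.full_like(v, 0.5)
    return (v - v.min()) / rng_


def select_k(
    data, k_range: Sequence[int] = range(2, 7), B_gap: int = 10, B_cpi: int = 10,
    seed: int = 0, prior_k: int | None = None,
) -> ModelSelectionCurve:
    """Choose the cluster count by combining CPI and gap.

    The chosen k maximizes the average of the min-max-normalized CPI and
    gap curves over ``k_range``; ``prior_k`` (an externally supplied
    expected subtype count) breaks exact ties.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("empty k_range")
    X = _as_matrix(data)
    gap, s_k, gap_k = gap_statistic(X, k_range, B=B_gap, seed=seed)
    cpi_mean, cpi_sd = cluster_prediction_index(X, k_range, B=B_cpi, seed=seed)
    combined = (_minmax(cpi_mean) + _minmax(gap)) / 2.0
    best = combined.max()
    tied = [k for k, v in zip(k_range, combined) if v >= best - 1e-12]
    if prior_k is not None and prior_k in tied:
        chosen = prior_k
    else:
        chosen = tied[0]
    return ModelSelectionCurve(
        k_values=k_range, cpi_mean=cpi_mean, cpi_sd=cpi_sd, gap=gap, gap_sd=s_k,
        chosen_k=int(chosen), gap_rule_k=gap_k,
    )
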