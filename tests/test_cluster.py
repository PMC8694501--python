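"""Integrative clustering algorithms: kernel oracle, recovery, invariances."""
import numpy as np
import pandas as pd
import pytest

from moclust.cluster import (
    ALGORITHMS,
    AlgorithmParams,
    affinity,
    intnmf_cluster,
    monti_consensus,
    run_algorithm,
    snf_fuse,
)
from moclust.ensemble import adjusted_rand_index
from moclust.io import MultiOmicsDataset, OmicsLayer
from moclust.simulate import SimulationConfig, simulate_multiomics
from tests.conftest import small_layer_specs


def _layer_from_points(X, name="toy"):
    df = pd.DataFrame(X.T, index=[f"{name}_f{j}" for j in range(X.shape[1])],
                      columns=[f"S{i:03d}" for i in range(X.shape[0])])
    return OmicsLayer(name=name, kind="gaussian", values=df)


class TestAffinity:
    def test_kernel_matches_brute_force_on_5_sample_toy(self):
        """Direct evaluation of the scaled exponential kernel on hand-set points."""
        X = np.array([[0.0, 0], [1, 0], [0, 2], [3, 1], [2, 2]])
        layer = _layer_from_points(X)
        params = AlgorithmParams(K_neighbors=2, mu=0.5)
        W = affinity(layer, params).values

        # brute force: z-score features, Euclidean distances, eps rule
        Z = (X - X.mean(0)) / X.std(0)
        n = 5
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                d[i, j] = np.sqrt(((Z[i] - Z[j]) ** 2).sum())
        knn_mean = np.array([np.sort(d[i])[1:3].mean() for i in range(n)])
        expected = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                eps = (knn_mean[i] + knn_mean[j] + d[i, j]) / 3
                expected[i, j] = np.exp(-d[i, j] ** 2 / (0.5 * eps))
        assert np.abs(W - expected).max() < 1e-12

    def test_duplicated_sample_is_row_maximum(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 4))
        X[5] = X[2]  # duplicate
        W = affinity(_layer_from_points(X), AlgorithmParams(K_neighbors=3)).values
        off = W[2].copy()
        off[2] = -np.inf
        assert np.argmax(off) == 5

    def test_equidistant_samples_give_equal_affinities(self):
        # equilateral triangle: all pairwise distances equal
        X = np.array([[0.0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        W = affinity(_layer_from_points(X), AlgorithmParams(K_neighbors=1)).values
        off = W[~np.eye(3, dtype=bool)]
        assert np.allclose(off, off[0])

    def test_too_few_samples_rejected(self):
        X = np.zeros((2, 3))
        with pytest.raises(ValueError):
            affinity(_layer_from_points(X))

    def test_K_at_least_n_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(ValueError):
            affinity(_layer_from_points(X), AlgorithmParams(K_neighbors=5))


class TestRecovery:
    @pytest.mark.parametrize("algo", ALGORITHMS)
    def test_perfectly_separated_blobs(self, algo, blobs_dataset):
        ds, truth = blobs_dataset
        result = run_algorithm(algo, ds, 3, AlgorithmParams(seed=0, n_resamples=30))
        assert adjusted_rand_index(truth, result.labels) == 1.0

    @pytest.mark.parametrize("algo", ALGORITHMS)
    def test_small_cohort_recovery(self, algo, small_cohort):
        ds, gt = small_cohort
        result = run_algorithm(algo, ds, 3, AlgorithmParams(seed=0, n_resamples=30))
        floor = 0.7 if algo in ("intnmf", "coca") else 0.8
        assert adjusted_rand_index(gt.true_labels, result.labels) >= floor

    @pytest.mark.parametrize("algo", ALGORITHMS)
    def test_zero_signal_ari_near_zero(self, algo):
        aris = []
        for seed in range(20):
            cfg = SimulationConfig(
                n_samples=45,
                layer_specs=small_layer_specs(effect=0.0, binary_rate=0.05),
                seed=seed)
            ds, gt = simulate_multiomics(cfg)
            result = run_algorithm(algo, ds, 3,
                                   AlgorithmParams(seed=seed, n_resamples=20, n_restarts=3))
            aris.append(adjusted_rand_index(gt.true_labels, result.labels))
        assert -0.1 < np.mean(aris) < 0.1

    @pytest.mark.parametrize("algo", ALGORITHMS)
    def test_order_equivariance(self, algo, blobs_dataset):
        """Permuting sample order permutes the partition (checked via ARI)."""
        ds, truth = blobs_dataset
        rng = np.random.default_rng(4)
        perm = rng.permutation(ds.n_samples)
        layers_p = []
        for layer in ds.layers:
            df = layer.values.iloc[:, perm]
            layers_p.append(OmicsLayer(layer.name, layer.kind, df))
        ds_p = MultiOmicsDataset(layers=layers_p)
        params = AlgorithmParams(seed=0, n_resamples=30)
        lab = run_algorithm(algo, ds, 3, params).labels
        lab_p = run_algorithm(algo, ds_p, 3, params).labels
        assert adjusted_rand_index(lab[perm], lab_p) == 1.0


class TestSNF:
    def test_fused_matrix_symmetric_rows_sum_to_one(self, blobs_dataset):
        ds, _ = blobs_dataset
        params = AlgorithmParams(seed=0)
        kernels = [affinity(l, params).values for l in ds.layers]
        fused = snf_fuse(kernels, K=params.resolved_K(ds.n_samples))
        assert np.abs(fused - fused.T).max() < 1e-9
        assert (fused >= 0).all()
        assert np.abs(fused.sum(axis=1) - 1.0).max() < 1e-6


class TestMontiConsensus:
    def test_frequencies_are_valid_and_extreme_on_separated_blobs(self, blobs_dataset):
        ds, truth = blobs_dataset
        X = np.vstack([l.zscored() for l in ds.layers]).T
        freq, labels = monti_consensus(X, 3, n_resamples=50, subsample_frac=0.8, seed=0)
        assert np.allclose(np.diag(freq), 1.0)
        assert freq.min() >= 0 and freq.max() <= 1
        off = freq[~np.eye(len(freq), dtype=bool)]
        assert np.isin(off, (0.0, 1.0)).all()
        assert adjusted_rand_index(truth, labels) == 1.0

    def test_never_cosampled_pair_warns(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        with pytest.warns(UserWarning, match="co-sampled"):
            monti_consensus(X, 2, n_resamples=1, subsample_frac=0.3, seed=0)


class TestIntNMF:
    def test_objective_non_increasing(self, small_cohort):
        ds, _ = small_cohort
        _, history = intnmf_cluster(ds, 3, AlgorithmParams(seed=0, n_restarts=1),
                                    return_history=True)
        diffs = np.diff(history)
        assert (diffs <= 1e-8 * np.abs(history[:-1])).all()

    def test_k1_single_cluster(self, blobs_dataset):
        ds, _ = blobs_dataset
        result = intnmf_cluster(ds, 1, AlgorithmParams(seed=0, n_restarts=2))
        assert result.k == 1
        assert (result.labels == 1).all()


class TestCOCA:
    def test_agreeing_layers_reproduce_layer_partition(self, blobs_dataset):
        ds, truth = blobs_dataset
        result = run_algorithm("coca", ds, 3, AlgorithmParams(seed=0, n_resamples=30))
        assert adjusted_rand_index(truth, result.labels) == 1.0


def test_labels_are_one_based_and_complete(small_cohort):
    ds, _ = small_cohort
    for algo in ALGORITHMS:
        r = run_algorithm(algo, ds, 3, AlgorithmParams(seed=1, n_resamples=20))
        assert set(np.unique(r.labels)) == set(range(1, r.k + 1))


def test_unknown_algorithm_rejected(small_cohort):
    ds, _ = small_cohort
    with pytest.raises(KeyError):
        run_algorithm("nope", ds, 3)
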