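import numpy as np
import pandas as pd
import pytest

from moclust.io import MultiOmicsDataset, OmicsLayer
from moclust.simulate import LayerSpec, SimulationConfig, simulate_multiomics


def small_layer_specs(effect: float = 1.0, binary_rate: float = 0.35) -> tuple[LayerSpec, ...]:
    """Scaled-down five-layer recipe for fast unit tests."""
    return (
        LayerSpec("mRNA", "gaussian", 200, 20, effect),
        LayerSpec("lncRNA", "gaussian", 60, 6, effect),
        LayerSpec("miRNA", "gaussian", 40, 4, effect),
        LayerSpec("methylation", "beta", 80, 8, effect),
        LayerSpec("mutation", "binary", 30, 3, binary_rate, baseline_rate=0.05),
    )


@pytest.fixture
def small_config() -> SimulationConfig:
    # effect 1.5 compensates for the reduced feature count so per-sample
    # aggregate signal is comparable to the full-scale default cohort
    return SimulationConfig(n_samples=90, layer_specs=small_layer_specs(effect=1.5), seed=11)


@pytest.fixture
def small_cohort(small_config):
    return simulate_multiomics(small_config)


@pytest.fixture
def blobs_dataset():
    """Two identical layers of 3 well-separated Gaussian blobs (n=60, delta=5)."""
    rng = np.random.default_rng(0)
    n_per, d = 20, 9
    centers = np.zeros((3, d))
    for c in range(3):  # orthogonal blocks so no pair of blobs is collinear
        centers[c, 3 * c:3 * (c + 1)] = 5.0
    X = np.vstack([rng.normal(c, 1.0, size=(n_per, d)) for c in centers])
    labels = np.repeat([1, 2, 3], n_per)
    samples = [f"S{i:03d}" for i in range(3 * n_per)]
    layers = []
    for name in ("layerA", "layerB"):
        df = pd.DataFrame(X.T, index=[f"{name}_f{j}" for j in range(d)], columns=samples)
        layers.append(OmicsLayer(name=name, kind="gaussian", values=df))
    return MultiOmicsDataset(layers=layers), labels
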