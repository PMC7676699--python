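import numpy as np
import pytest

from aaeclust import synthetic
from aaeclust.datatypes import PeakMatrix, PeakRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    """3-peak x 2-sample style toy matrix, samples x features in memory."""
    values = np.array([[1.0, 2.0, 0.0], [0.5, 0.0, 3.0]])
    peaks = [
        PeakRecord("chr1", 100, 601, "GENEA"),
        PeakRecord("chr1", 2000, 2501, "GENEB"),
        PeakRecord("chr2", 500, 1001, None),
    ]
    return PeakMatrix(values, ["s1", "s2"], peaks)


@pytest.fixture(scope="session")
def two_cluster_latent():
    """Two planted spherical clusters at (-5,-5) and (5,5), n=500, seed 1."""
    rng = np.random.default_rng(1)
    means = np.array([[-5.0, -5.0], [5.0, 5.0]])
    labels = np.arange(500) % 2
    H = means[labels] + rng.standard_normal((500, 2))
    return H, labels


@pytest.fixture(scope="session")
def small_cohort():
    """Small planted-cluster cohort for stages that do not need p=5000."""
    Z, labels = synthetic.generate_latent_clusters(G=3, n=120, d_true=6, separation=8, seed=1)
    matrix, truth = synthetic.expand_to_peaks(Z, labels, p=300, markers_per_cluster=10, seed=1)
    return matrix, truth
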