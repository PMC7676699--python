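"""Cluster-number selection by the Davies-Bouldin index.

For a partition into K clusters with centroids c_i, per-cluster scatter
S_i = mean Euclidean distance of the cluster's points to c_i, and
between-centroid separation M_ij = ‖c_i − c_j‖, the index is

    DB = (1/K) Σ_i max_{j≠i} (S_i + S_j) / M_ij .

Lower is better; the selected K minimizes DB over the candidate range
(ties go to the smallest K).  The index is evaluated in the latent space
the mixture model clusters in, not on the raw peak matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datatypes import ClusterSolution
from .errors import DegeneratePartitionError, ShapeError, ValidationError
from .gmm import GmmConfig, em_fit, predict_labels

__all__ = ["KScanResult", "davies_bouldin", "select_k"]

logger = logging.getLogger(__name__)


@dataclass
class KScanResult:
    """Davies-Bouldin profile over candidate cluster numbers."""

    k_values: list[int]
    db_scores: list[float]
    solutions: dict[int, ClusterSolution] = field(default_factory=dict)

    @property
    def best_k(self) -> int:
        scores = np.asarray(self.db_scores)
        if not np.isfinite(scores).any():
            raise DegeneratePartitionError("no candidate K produced a valid partition")
        return int(self.k_values[int(np.argmin(scores))])  # argmin keeps smallest K on ties

    @property
    def best_solution(self) -> ClusterSolution:
        return self.solutions[self.best_k]


def davies_bouldin(H: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index of a hard partition of the rows of H."""
    H = np.asarray(H, dtype=float)
    if H.ndim == 1:
        H = H[:, None]
    labels = np.asarray(labels)
    if labels.shape != (H.shape[0],):
        raise ShapeError("labels must align with rows of H")
    uniq = np.unique(labels)
    K = len(uniq)
    if K < 2:
        raise ValidationError("Davies-Bouldin needs at least 2 clusters")
    centroids = np.stack([H[labels == u].mean(axis=0) for u in uniq])
    scatter = np.array(
        [np.linalg.norm(H[labels == u] - centroids[i], axis=1).mean() for i, u in enumerate(uniq)]
    )
    sep = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=-1)
    if np.any((sep + np.eye(K) == 0) & (scatter[:, None] + scatter[None, :] > 0)):
        raise DegeneratePartitionError("coincident centroids with nonzero scatter")
    ratio = np.zeros((K, K))
    mask = ~np.eye(K, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio[mask] = ((scatter[:, None] + scatter[None, :]) / sep)[mask]
    ratio[~np.isfinite(ratio)] = 0.0  # coincident centroids with zero scatter
    return float(np.mean(ratio.max(axis=1)))


def select_k(
    H: np.ndarray,
    k_range=range(2, 31),
    gmm_config: GmmConfig | None = None,
    seed: int = 0,
    sample_ids: list[str] | None = None,
) -> KScanResult:
    """Fit a GMM at every K in k_range and rank the fits by Davies-Bouldin.

    Each K is seeded deterministically from (seed, K), so the scan is
    reproducible and K-wise independent.  A K whose fitted hard labels
    leave a component empty is recorded with a +inf score and can never be
    selected.
    """
    H = np.asarray(H, dtype=float)
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValidationError("k_range is empty")
    if max(ks) > H.shape[0]:
        raise ValidationError("max(k_range) exceeds the number of samples")
    base = gmm_config or GmmConfig()
    result = KScanResult(k_values=[], db_scores=[])
    for K in ks:
        cfg = GmmConfig(
            covariance=base.covariance,
            reg_covar=base.reg_covar,
            tol=base.tol,
            max_iter=base.max_iter,
            n_init=base.n_init,
            seed=int(np.random.default_rng((seed, K)).integers(2**31 - 1)),
        )
        model = em_fit(H, K, cfg)
        sol = predict_labels(model, H, sample_ids)
        occupied = len(np.unique(sol.labels))
        if occupied < K:
            logger.warning("K=%d left %d component(s) empty; excluded", K, K - occupied)
            score = np.inf
        elif K == 1:
            score = np.inf
        else:
            score = davies_bouldin(H, sol.labels)
        sol.db_score = None if np.isinf(score) else score
        result.k_values.append(K)
        result.db_scores.append(score)
        result.solutions[K] = sol
    return result
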