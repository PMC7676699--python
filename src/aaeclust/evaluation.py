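"""Scoring and comparison of clustering solutions.

Survival separation is measured by the K-sample log-rank test (chi-square
with K−1 degrees of freedom) and Kaplan-Meier curves; a permutation scheme
gives distribution-free empirical p-values.  Clinical covariates are tested
for enrichment per type (chi-square / Fisher for categorical,
Kruskal-Wallis for continuous).  Partitions are compared by variation of
information, a metric distance on the lattice of partitions, and by
row-normalized residence matrices.  The latent space is visualized through
its Pearson similarity matrix and a t-SNE map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sklearn.manifold import TSNE

from .datatypes import SurvivalTable
from .errors import ShapeError, ValidationError

__all__ = [
    "LogrankResult",
    "EnrichmentReport",
    "logrank_test",
    "km_curves",
    "permutation_pvalue",
    "clinical_enrichment",
    "variation_of_information",
    "similarity_matrix",
    "residence_matrix",
    "embed_2d",
]


@dataclass
class LogrankResult:
    chi_square: float
    df: int
    p_value: float


@dataclass
class EnrichmentReport:
    """Per-covariate association tests against the clustering."""

    tests: list[tuple[str, str, float, float]]  # (covariate, test name, stat, p)
    alpha: float = 0.05
    n_significant: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_significant = sum(1 for *_, p in self.tests if p < self.alpha)


def _check_survival_args(times, events, labels):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.asarray(labels)
    if not (times.shape == events.shape == labels.shape):
        raise ShapeError("times, events and labels must align")
    if len(np.unique(labels)) < 2:
        raise ValidationError("log-rank test needs at least 2 groups")
    if events.sum() == 0:
        raise ValidationError("log-rank test undefined with zero observed events")
    return times, events, labels


def logrank_test(times, events, labels) -> LogrankResult:
    """K-sample log-rank score test for equality of survival curves."""
    times, events, labels = _check_survival_args(times, events, labels)
    res = multivariate_logrank_test(times, labels, events)
    df = len(np.unique(labels)) - 1
    return LogrankResult(float(res.test_statistic), df, float(res.p_value))


def km_curves(times, events, labels) -> dict:
    """Kaplan-Meier product-limit estimate per group.

    Returns {group: (event_times, survival)} step functions starting at
    S(0) = 1 and non-increasing thereafter.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.asarray(labels)
    if not (times.shape == events.shape == labels.shape):
        raise ShapeError("times, events and labels must align")
    curves = {}
    for g in np.unique(labels):
        mask = labels == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        t = np.asarray(kmf.survival_function_.index, dtype=float)
        s = kmf.survival_function_.iloc[:, 0].to_numpy()
        curves[g] = (t, s)
    return curves


def permutation_pvalue(times, events, labels, R: int = 999, seed: int = 0) -> float:
    """Empirical log-rank p-value: p = (1 + #{perm stat >= observed}) / (1 + R).

    The add-one estimator never returns exactly zero; R = 0 gives p = 1.
    """
    if R < 0:
        raise ValidationError("R must be >= 0")
    times, events, labels = _check_survival_args(times, events, labels)
    observed = logrank_test(times, events, labels).chi_square
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(R):
        perm = rng.permutation(labels)
        stat = multivariate_logrank_test(times, perm, events).test_statistic
        if stat >= observed:
            exceed += 1
    return (1 + exceed) / (1 + R)


def clinical_enrichment(
    table: SurvivalTable, labels, alpha: float = 0.05
) -> EnrichmentReport:
    """Association of each clinical covariate with the cluster labels.

    Categorical covariates use a chi-square test of independence (Fisher's
    exact test for 2x2 tables with any expected count < 5); continuous ones
    use Kruskal-Wallis across clusters.  p-values are raw (the reported
    quantity is the count of significant covariates, not a corrected set).
    """
    labels = np.asarray(labels)
    if len(labels) != len(table.sample_ids):
        raise ShapeError("labels must align with the clinical table")
    tests: list[tuple[str, str, float, float]] = []
    for col in table.covariates.columns:
        values = table.covariates[col]
        if values.nunique(dropna=True) < 2:
            warnings.warn(f"covariate {col!r} is constant; p set to 1", stacklevel=2)
            tests.append((col, "constant", 0.0, 1.0))
            continue
        if table.covariate_types[col] == "categorical":
            contingency = pd.crosstab(labels, values.to_numpy()).to_numpy()
            chi2, p, _, expected = stats.chi2_contingency(contingency)
            if contingency.shape == (2, 2) and (expected < 5).any():
                _, p = stats.fisher_exact(contingency)
                tests.append((col, "fisher", float("nan"), float(p)))
            else:
                tests.append((col, "chi2", float(chi2), float(p)))
        else:
            groups = [
                values.to_numpy(dtype=float)[labels == g] for g in np.unique(labels)
            ]
            stat, p = stats.kruskal(*groups)
            tests.append((col, "kruskal", float(stat), float(p)))
    return EnrichmentReport(tests=tests, alpha=alpha)


def _entropy(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def variation_of_information(labels_a, labels_b) -> float:
    """VI(A, B) = H(A) + H(B) − 2 I(A; B) in nats; 0 iff the partitions match."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ShapeError("partitions must have equal length")
    n = len(a)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    joint = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(joint, (ai, bi), 1.0)
    h_a = _entropy(joint.sum(axis=1))
    h_b = _entropy(joint.sum(axis=0))
    h_ab = _entropy(joint.ravel()[joint.ravel() > 0])
    mi = h_a + h_b - h_ab
    return max(0.0, h_a + h_b - 2.0 * mi)


def similarity_matrix(Z: np.ndarray) -> np.ndarray:
    """Pearson correlation between sample latent vectors (unit diagonal)."""
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[0] < 2 or Z.shape[1] < 2:
        raise ShapeError("need at least 2 samples and 2 latent dimensions")
    sd = Z.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{flat.sum()} zero-variance latent vector(s); correlations set to 0",
            stacklevel=2,
        )
    Zc = Z - Z.mean(axis=1, keepdims=True)
    denom = np.where(flat, 1.0, sd * np.sqrt(Z.shape[1]))
    C = (Zc / denom[:, None]) @ (Zc / denom[:, None]).T
    C[flat, :] = 0.0
    C[:, flat] = 0.0
    np.fill_diagonal(C, 1.0)
    return np.clip(C, -1.0, 1.0)


def residence_matrix(labels_a, labels_b) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Percent of each cluster of A residing in each cluster of B.

    Returns (matrix, clusters_a, clusters_b); each row sums to 100.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ShapeError("labelings must have equal length")
    ua, ai = np.unique(a, return_inverse=True)
    ub, bi = np.unique(b, return_inverse=True)
    counts = np.zeros((len(ua), len(ub)))
    np.add.at(counts, (ai, bi), 1.0)
    return 100.0 * counts / counts.sum(axis=1, keepdims=True), ua, ub


def embed_2d(Z: np.ndarray, seed: int = 0, perplexity: float = 30.0) -> np.ndarray:
    """2-D t-SNE map of the latent vectors (perplexity clamped to (N−1)/3)."""
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[0] < 5:
        raise ValidationError("t-SNE needs at least 5 samples")
    n = Z.shape[0]
    perplexity = min(perplexity, (n - 1) / 3.0)
    if perplexity < 1:
        raise ValidationError(
            f"too few samples (n={n}) for any valid perplexity; need n >= 5"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=1000,
        init="pca",
        random_state=seed,
    )
    return tsne.fit_transform(Z)
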