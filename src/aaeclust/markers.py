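"""Cluster-specific marker peaks via one-vs-rest random forests.

For every cluster, members are recoded as the positive class and a random
forest is fitted on the full peak matrix.  Gini importance (normalized mean
decrease in node impurity) ranks the peaks; the top regions and their
annotation-linked genes are reported per cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .datatypes import PeakMatrix, PeakRecord
from .errors import ShapeError, ValidationError

__all__ = [
    "RfConfig",
    "MarkerRow",
    "one_vs_rest_labels",
    "gini_importances",
    "top_regions",
    "link_genes",
    "discover_markers",
]


@dataclass
class RfConfig:
    """Random-forest hyperparameters for marker selection.

    1000 trees with sqrt(p) candidate features per split and balanced class
    weights (one-vs-rest splits are heavily imbalanced for small clusters).
    """

    n_estimators: int = 1000
    max_features: str | float = "sqrt"
    max_depth: int | None = None
    class_weight: str | None = "balanced"
    n_jobs: int = 1


@dataclass
class MarkerRow:
    """One reported marker region for one cluster."""

    cluster: int
    peak: PeakRecord
    gini_importance: float
    rank: int
    linked_gene: str = "NA"


def one_vs_rest_labels(labels: np.ndarray, target_cluster: int) -> np.ndarray:
    """Binary recoding: 1 for members of ``target_cluster``, 0 otherwise."""
    labels = np.asarray(labels)
    if target_cluster not in labels:
        raise ValidationError(f"cluster {target_cluster} absent from labels")
    return (labels == target_cluster).astype(int)


def gini_importances(
    X: np.ndarray, y: np.ndarray, rf_config: RfConfig | None = None, seed: int = 0
) -> np.ndarray:
    """Normalized mean-decrease-impurity importance per feature (sums to 1)."""
    cfg = rf_config or RfConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ShapeError("X rows must align with y")
    if len(np.unique(y)) < 2:
        raise ValidationError("one-vs-rest labels contain a single class")
    rf = RandomForestClassifier(
        n_estimators=cfg.n_estimators,
        max_features=cfg.max_features,
        max_depth=cfg.max_depth,
        criterion="gini",
        class_weight=cfg.class_weight,
        random_state=seed,
        n_jobs=cfg.n_jobs,
    )
    rf.fit(X, y)
    return rf.feature_importances_


def top_regions(
    importances: np.ndarray,
    peaks: list[PeakRecord],
    n_top: int = 5,
    cluster: int = 0,
) -> list[MarkerRow]:
    """The n_top highest-importance peaks; ties break toward lower index."""
    importances = np.asarray(importances, dtype=float)
    if len(importances) != len(peaks):
        raise ShapeError(
            f"{len(importances)} importances for {len(peaks)} peaks"
        )
    n_top = min(n_top, len(peaks))
    # stable sort on negated importance keeps the lower index first on ties
    order = np.argsort(-importances, kind="stable")[:n_top]
    return [
        MarkerRow(
            cluster=cluster,
            peak=peaks[j],
            gini_importance=float(importances[j]),
            rank=r + 1,
            linked_gene=peaks[j].linked_gene or "NA",
        )
        for r, j in enumerate(order)
    ]


def link_genes(rows: list[MarkerRow], annotation: dict[str, str]) -> list[MarkerRow]:
    """Fill linked_gene from a peak_id -> gene map; absent peaks get "NA"."""
    return [
        replace(row, linked_gene=annotation.get(row.peak.peak_id, "NA")) for row in rows
    ]


def discover_markers(
    matrix: PeakMatrix,
    labels: np.ndarray,
    n_top: int = 5,
    rf_config: RfConfig | None = None,
    seed: int = 0,
    annotation: dict[str, str] | None = None,
) -> list[MarkerRow]:
    """Top marker regions for every cluster present in ``labels``.

    The forest for cluster c is seeded with ``seed + c`` so per-cluster fits
    are reproducible and independent.
    """
    labels = np.asarray(labels)
    rows: list[MarkerRow] = []
    for c in np.unique(labels):
        y = one_vs_rest_labels(labels, c)
        imp = gini_importances(matrix.values, y, rf_config, seed=seed + int(c))
        cluster_rows = top_regions(imp, matrix.peaks, n_top=n_top, cluster=int(c))
        if annotation is not None:
            cluster_rows = link_genes(cluster_rows, annotation)
        rows.extend(cluster_rows)
    return rows
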