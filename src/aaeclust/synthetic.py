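"""Synthetic ATAC-like data with planted cluster structure.

The generator emulates the shape of a normalized chromatin-accessibility
study: a sparse nonnegative peak-score matrix whose samples arise from G
latent clusters, a disjoint set of cluster-specific marker peaks with
elevated accessibility, cluster-dependent exponential survival, and a mix
of cluster-associated and null clinical covariates.  Every stage of the
pipeline can therefore be exercised without any external download.

Default condition: G=6 clusters, n=300 samples, d_true=10 latent
dimensions, p=5000 peaks, cluster separation 8 (in latent Euclidean
distance units, against unit within-cluster noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datatypes import PeakMatrix, PeakRecord, SurvivalTable
from .errors import ValidationError

__all__ = [
    "SimTruth",
    "generate_latent_clusters",
    "expand_to_peaks",
    "simulate_survival",
    "simulate_clinical",
    "default_fixture",
    "DEFAULT_G",
    "DEFAULT_N",
    "DEFAULT_D_TRUE",
    "DEFAULT_P",
    "DEFAULT_SEPARATION",
    "DEFAULT_MARKERS_PER_CLUSTER",
    "DEFAULT_HAZARDS",
]

DEFAULT_G = 6
DEFAULT_N = 300
DEFAULT_D_TRUE = 10
DEFAULT_P = 5000
DEFAULT_SEPARATION = 8.0
DEFAULT_MARKERS_PER_CLUSTER = 20
DEFAULT_MARKER_EFFECT = 2.0
DEFAULT_NOISE_SD = 0.5
DEFAULT_SPARSITY = 0.2
DEFAULT_LIFT_SCALE = 0.2
# Per-cluster daily hazards spanning poor to good prognosis (median survival
# from ~170 days at 0.004/day to ~1700 days at 0.0004/day).
DEFAULT_HAZARDS = (0.004, 0.0025, 0.0015, 0.001, 0.0006, 0.0004)
DEFAULT_CENSOR_RATE = 0.3

_AUTOSOMES = [f"chr{i}" for i in range(1, 23)]


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort (for scoring, never for fitting)."""

    labels: np.ndarray
    latent_means: np.ndarray
    marker_indices: dict[int, np.ndarray] = field(default_factory=dict)
    hazards: np.ndarray | None = None
    associated_covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for idx in self.marker_indices.values():
            s = set(int(i) for i in np.asarray(idx))
            if seen & s:
                raise ValidationError("marker index sets must be disjoint across clusters")
            seen |= s
        if self.hazards is not None and (np.asarray(self.hazards) <= 0).any():
            raise ValidationError("hazards must be positive")


def _separated_means(G: int, d: int, separation: float, rng: np.random.Generator) -> np.ndarray:
    """G mean vectors with pairwise Euclidean distance >= separation.

    When G <= d the means are mutually orthogonal directions scaled so that
    each has norm separation/sqrt(2) and pairwise distance exactly
    `separation`.  Otherwise random directions are rescaled until the
    pairwise floor holds.
    """
    if separation == 0:
        return np.zeros((G, d))
    if G <= d:
        A = rng.standard_normal((d, G))
        Q, _ = np.linalg.qr(A)
        return (Q[:, :G] * (separation / np.sqrt(2.0))).T
    scale = separation
    for _ in range(200):
        M = rng.standard_normal((G, d))
        M *= scale / np.linalg.norm(M, axis=1, keepdims=True)
        diff = np.linalg.norm(M[:, None, :] - M[None, :, :], axis=-1)
        np.fill_diagonal(diff, np.inf)
        if diff.min() >= separation:
            return M
        scale *= 1.3
    raise ValidationError("could not place separated cluster means")


def generate_latent_clusters(
    G: int = DEFAULT_G,
    n: int = DEFAULT_N,
    d_true: int = DEFAULT_D_TRUE,
    separation: float = DEFAULT_SEPARATION,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n latent points from G spherical unit-variance Gaussians.

    Labels are balanced (cluster sizes differ by at most one) and assigned
    in round-robin order, so sample order carries no information beyond the
    label itself.
    """
    if G < 1:
        raise ValidationError("G must be >= 1")
    if n < G:
        raise ValidationError(f"need n >= G, got n={n}, G={G}")
    rng = np.random.default_rng(seed)
    means = _separated_means(G, d_true, separation, rng)
    labels = np.arange(n) % G
    Z = means[labels] + rng.standard_normal((n, d_true))
    return Z, labels


def expand_to_peaks(
    Z_true: np.ndarray,
    labels: np.ndarray,
    p: int = DEFAULT_P,
    markers_per_cluster: int = DEFAULT_MARKERS_PER_CLUSTER,
    marker_effect: float = DEFAULT_MARKER_EFFECT,
    noise_sd: float = DEFAULT_NOISE_SD,
    sparsity: float = DEFAULT_SPARSITY,
    lift_scale: float = DEFAULT_LIFT_SCALE,
    seed: int = 0,
) -> tuple[PeakMatrix, SimTruth]:
    """Lift latent points to a p-dimensional nonnegative peak-score matrix.

    The base signal is softplus(Z_true @ W.T + noise) for a fixed random
    linear lift W; each cluster then receives `marker_effect` extra score on
    its own disjoint block of marker peaks, and a `sparsity` fraction of
    entries is zeroed (dropout-style missing accessibility).

    ``lift_scale`` keeps the diffuse background signal weak per peak: the
    cluster structure remains strong in aggregate (it accumulates over all
    p peaks) while any single background peak separates clusters far less
    than a planted marker does, so the markers are, by construction, the
    most discriminative individual features.
    """
    Z_true = np.asarray(Z_true, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n, d = Z_true.shape
    G = int(labels.max()) + 1
    if p < G * markers_per_cluster:
        raise ValidationError(
            f"p={p} cannot host {G} x {markers_per_cluster} disjoint marker peaks"
        )
    if not 0 <= sparsity <= 1:
        raise ValidationError("sparsity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((p, d)) * (lift_scale / np.sqrt(d))
    raw = Z_true @ W.T + rng.normal(0.0, noise_sd, size=(n, p))
    X = np.logaddexp(0.0, raw)  # softplus keeps scores nonnegative

    marker_indices: dict[int, np.ndarray] = {}
    perm = rng.permutation(p)
    for g in range(G):
        idx = np.sort(perm[g * markers_per_cluster : (g + 1) * markers_per_cluster])
        marker_indices[g] = idx
        X[np.ix_(labels == g, idx)] += marker_effect

    if sparsity > 0:
        X[rng.random((n, p)) < sparsity] = 0.0

    peaks = []
    per_chrom = -(-p // len(_AUTOSOMES))
    for j in range(p):
        chrom = _AUTOSOMES[j // per_chrom]
        start = 10_000 + 1_000 * (j % per_chrom)
        peaks.append(PeakRecord(chrom, start, start + 501, linked_gene=f"GENE{j % 97}"))
    sample_ids = [f"S{i:04d}" for i in range(n)]
    truth = SimTruth(labels=labels, latent_means=np.zeros((G, d)), marker_indices=marker_indices)
    return PeakMatrix(X, sample_ids, peaks), truth


def simulate_survival(
    labels: np.ndarray,
    hazards: np.ndarray | tuple | list = DEFAULT_HAZARDS,
    censor_rate: float = DEFAULT_CENSOR_RATE,
    seed: int = 0,
    sample_ids: list[str] | None = None,
) -> SurvivalTable:
    """Exponential event times with the member's cluster hazard.

    Censoring is independent Uniform(0, c) with c solved numerically so the
    expected censored fraction equals `censor_rate`.
    """
    labels = np.asarray(labels, dtype=int)
    hazards = np.asarray(hazards, dtype=float)
    if (hazards <= 0).any():
        raise ValidationError("hazards must be positive")
    if not 0 <= censor_rate < 1:
        raise ValidationError("censor_rate must lie in [0, 1)")
    if labels.max() >= len(hazards):
        raise ValidationError("need one hazard per cluster")
    rng = np.random.default_rng(seed)
    lam = hazards[labels]
    T = rng.exponential(1.0 / lam)
    if censor_rate == 0:
        time, event = T, np.ones_like(labels)
    else:
        # P(C < T) for C~U(0,c), T~Exp(lam) is (1 - exp(-lam c)) / (lam c),
        # which decreases from 1 (c -> 0) to 0 (c -> inf)
        def censored_frac(c: float) -> float:
            x = lam * c
            return float(np.mean((1.0 - np.exp(-x)) / x))

        hi = 1.0
        while censored_frac(hi) > censor_rate:
            hi *= 2.0
        lo = hi / 2.0
        while censored_frac(lo) < censor_rate:
            lo /= 2.0
        c = brentq(lambda v: censored_frac(v) - censor_rate, lo, hi)
        C = rng.uniform(0.0, c, size=len(labels))
        event = (T <= C).astype(int)
        time = np.minimum(T, C)
    time = np.maximum(time, 1e-3)  # follow-up must be strictly positive
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(len(labels))]
    return SurvivalTable(sample_ids, time, event)


def simulate_clinical(
    labels: np.ndarray,
    n_associated: int = 3,
    n_null: int = 4,
    seed: int = 0,
    shift: float = 0.8,
) -> tuple[pd.DataFrame, dict[str, str], list[str]]:
    """Clinical covariates: `n_associated` depend on the cluster, `n_null` do not.

    Associated covariates alternate binary categorical (preferred level with
    probability `shift` in even clusters, 1-shift in odd ones) and continuous
    (unit-variance normal with mean = cluster index).  Null covariates
    alternate a 3-level uniform categorical and a standard normal.

    Returns (columns, type tags, names of the associated columns).
    """
    if n_associated < 0 or n_null < 0:
        raise ValidationError("covariate counts must be >= 0")
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    n = len(labels)
    cols: dict[str, np.ndarray] = {}
    types: dict[str, str] = {}
    associated = []
    for j in range(n_associated):
        name = f"assoc_{j}"
        if j % 2 == 0:
            p_pos = np.where(labels % 2 == 0, shift, 1.0 - shift)
            cols[name] = np.where(rng.random(n) < p_pos, "pos", "neg")
            types[name] = "categorical"
        else:
            cols[name] = labels + rng.standard_normal(n)
            types[name] = "continuous"
        associated.append(name)
    for j in range(n_null):
        name = f"null_{j}"
        if j % 2 == 0:
            cols[name] = rng.choice(["a", "b", "c"], size=n)
            types[name] = "categorical"
        else:
            cols[name] = rng.standard_normal(n)
            types[name] = "continuous"
    return pd.DataFrame(cols), types, associated


def default_fixture(
    seed: int = 1,
    G: int = DEFAULT_G,
    n: int = DEFAULT_N,
    d_true: int = DEFAULT_D_TRUE,
    p: int = DEFAULT_P,
    separation: float = DEFAULT_SEPARATION,
) -> tuple[PeakMatrix, SurvivalTable, SimTruth]:
    """The standard end-to-end test cohort; all stages derive from one seed."""
    rng = np.random.default_rng(seed)
    s_lat, s_peak, s_surv, s_clin = rng.integers(0, 2**31 - 1, size=4)
    Z, labels = generate_latent_clusters(G, n, d_true, separation, seed=int(s_lat))
    matrix, truth = expand_to_peaks(Z, labels, p=p, seed=int(s_peak))
    hazards = np.asarray(DEFAULT_HAZARDS[:G])
    if G > len(DEFAULT_HAZARDS):
        hazards = np.geomspace(0.004, 0.0004, G)
    surv = simulate_survival(
        labels, hazards, seed=int(s_surv), sample_ids=matrix.sample_ids
    )
    covs, types, associated = simulate_clinical(labels, seed=int(s_clin))
    surv.covariates = covs
    surv.covariate_types = types
    truth.hazards = hazards
    truth.associated_covariates = associated
    truth.latent_means = np.zeros((G, d_true))
    return matrix, surv, truth
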