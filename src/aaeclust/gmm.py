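"""Gaussian mixture clustering of latent vectors by expectation-maximization.

The latent space H is modeled as  p(h) = Σ_i π_i N(h | μ_i, Σ_i)  with M
components.  EM alternates the E step (posterior responsibilities) and the
M step (weighted updates of π, μ, Σ) until the total log-likelihood is
flat.  Hard cluster labels are posterior argmax assignments.

Covariances are diagonal by default: with a 200-dimensional latent space
and a few hundred samples, full covariances are singular; diagonal ones
stay well-posed and are what the cluster geometry needs.  A small floor is
added to every variance each M step, so the likelihood is bounded and EM
monotonicity holds up to that floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .datatypes import ClusterSolution
from .errors import ShapeError, ValidationError

__all__ = ["GmmConfig", "GmmModel", "gmm_log_density", "em_fit", "responsibilities", "predict_labels"]


@dataclass
class GmmConfig:
    covariance: str = "diag"  # "diag" or "full"
    reg_covar: float = 1e-6
    tol: float = 1e-4
    max_iter: int = 500
    n_init: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.covariance not in ("diag", "full"):
            raise ValidationError("covariance must be 'diag' or 'full'")
        if self.n_init < 1 or self.max_iter < 1:
            raise ValidationError("n_init and max_iter must be >= 1")


@dataclass
class GmmModel:
    """Fitted mixture: weights π, means μ (M x d), covariances Σ.

    ``covariances`` has shape (M, d) for diagonal models and (M, d, d)
    for full ones.  ``ll_history`` records the total log-likelihood after
    every EM iteration of the winning restart.
    """

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    covariance_type: str = "diag"
    log_likelihood: float = np.nan
    n_iter: int = 0
    converged: bool = False
    ll_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        if (self.weights < 0).any() or abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValidationError("mixture weights must be a probability vector")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def dim(self) -> int:
        return self.means.shape[1]


def _log_gauss(H: np.ndarray, model: GmmModel) -> np.ndarray:
    """N x M matrix of per-component log densities log N(h_n | μ_i, Σ_i)."""
    N, d = H.shape
    M = model.n_components
    out = np.empty((N, M))
    if model.covariance_type == "diag":
        for i in range(M):
            var = model.covariances[i]
            diff2 = (H - model.means[i]) ** 2 / var
            out[:, i] = -0.5 * (d * np.log(2 * np.pi) + np.log(var).sum() + diff2.sum(axis=1))
    else:
        for i in range(M):
            cov = model.covariances[i]
            chol = np.linalg.cholesky(cov)
            logdet = 2.0 * np.log(np.diag(chol)).sum()
            sol = np.linalg.solve(chol, (H - model.means[i]).T)
            out[:, i] = -0.5 * (d * np.log(2 * np.pi) + logdet + (sol**2).sum(axis=0))
    return out


def _as_matrix(H: np.ndarray, d: int | None = None) -> np.ndarray:
    H = np.asarray(H, dtype=float)
    if H.ndim == 1:
        H = H[None, :]
    if d is not None and H.shape[1] != d:
        raise ShapeError(f"latent width {H.shape[1]} does not match model dim {d}")
    return H


def gmm_log_density(model: GmmModel, h: np.ndarray) -> float | np.ndarray:
    """log p(h) = log Σ_i π_i N(h|μ_i,Σ_i), evaluated via log-sum-exp."""
    single = np.asarray(h).ndim == 1
    H = _as_matrix(h, model.dim)
    lp = logsumexp(_log_gauss(H, model) + np.log(model.weights), axis=1)
    return float(lp[0]) if single else lp


def responsibilities(model: GmmModel, H: np.ndarray) -> np.ndarray:
    """Row-stochastic posterior matrix; entry (n,i) = π_i N(h_n|μ_i,Σ_i)/p(h_n)."""
    H = _as_matrix(H, model.dim)
    logw = _log_gauss(H, model) + np.log(model.weights)
    return np.exp(logw - logsumexp(logw, axis=1, keepdims=True))


def _kmeanspp_centers(H: np.ndarray, M: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: spread initial centers by squared-distance sampling."""
    n = H.shape[0]
    centers = [H[rng.integers(n)]]
    d2 = np.sum((H - centers[0]) ** 2, axis=1)
    for _ in range(1, M):
        total = d2.sum()
        if total <= 0:
            centers.append(H[rng.integers(n)])
            continue
        centers.append(H[rng.choice(n, p=d2 / total)])
        d2 = np.minimum(d2, np.sum((H - centers[-1]) ** 2, axis=1))
    return np.asarray(centers)


def _m_step(H: np.ndarray, resp: np.ndarray, cfg: GmmConfig, rng: np.random.Generator) -> GmmModel:
    n, d = H.shape
    M = resp.shape[1]
    nk = resp.sum(axis=0)
    global_var = H.var(axis=0) + cfg.reg_covar
    # collapsed component: reseed at a random data point with global spread
    for i in np.where(nk < 1e-10)[0]:
        resp[:, i] = 0.0
        resp[rng.integers(n), i] = 1.0
        nk = resp.sum(axis=0)
    weights = nk / nk.sum()
    means = (resp.T @ H) / nk[:, None]
    if cfg.covariance == "diag":
        covs = np.empty((M, d))
        for i in range(M):
            diff = H - means[i]
            covs[i] = (resp[:, i] @ (diff**2)) / nk[i] + cfg.reg_covar
    else:
        covs = np.empty((M, d, d))
        for i in range(M):
            diff = H - means[i]
            covs[i] = (resp[:, i] * diff.T) @ diff / nk[i] + cfg.reg_covar * np.eye(d)
    return GmmModel(weights, means, covs, cfg.covariance)


def _single_fit(H: np.ndarray, M: int, cfg: GmmConfig, rng: np.random.Generator) -> GmmModel:
    n = H.shape[0]
    centers = _kmeanspp_centers(H, M, rng)
    assign = np.argmin(
        ((H[:, None, :] - centers[None, :, :]) ** 2).sum(axis=-1), axis=1
    )
    resp = np.zeros((n, M))
    resp[np.arange(n), assign] = 1.0
    model = _m_step(H, resp, cfg, rng)
    ll_hist: list[float] = []
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        ll = float(gmm_log_density(model, H).sum())
        resp = responsibilities(model, H)
        model = _m_step(H, resp, cfg, rng)
        ll_hist.append(ll)
        if len(ll_hist) >= 2 and abs(ll_hist[-1] - ll_hist[-2]) < cfg.tol:
            converged = True
            break
    final_ll = float(gmm_log_density(model, H).sum())
    ll_hist.append(final_ll)
    model.log_likelihood = final_ll
    model.n_iter = it
    model.converged = converged
    model.ll_history = ll_hist
    return model


def em_fit(H: np.ndarray, M: int, config: GmmConfig | None = None) -> GmmModel:
    """Fit an M-component mixture; best of ``n_init`` seeded restarts.

    Restart r uses the generator spawned from (seed, r), so fits are
    reproducible and independent across restarts.
    """
    cfg = config or GmmConfig()
    H = _as_matrix(H)
    n = H.shape[0]
    if M < 1:
        raise ValidationError("M must be >= 1")
    if n < M:
        raise ValidationError(f"cannot fit {M} components to {n} samples")
    best: GmmModel | None = None
    for r in range(cfg.n_init):
        rng = np.random.default_rng((cfg.seed, r))
        model = _single_fit(H, M, cfg, rng)
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model
    assert best is not None
    return best


def predict_labels(
    model: GmmModel, H: np.ndarray, sample_ids: list[str] | None = None
) -> ClusterSolution:
    """Posterior-argmax hard labels (ties go to the lowest component index)."""
    H = _as_matrix(H, model.dim)
    resp = responsibilities(model, H)
    labels = np.argmax(resp, axis=1)
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(H.shape[0])]
    return ClusterSolution(sample_ids, labels, posteriors=resp, k=model.n_components)
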