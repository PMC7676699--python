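"""Adversarial autoencoder embedding of peak-score matrices.

The model has three parts: a deterministic nonlinear encoder Q mapping a
sample x to a latent code z, a *linear* decoder G mapping z back to x'
(the decoder is deliberately downgraded to an affine map so that all
representational capacity sits in the encoder), and a discriminator D that
scores latent vectors as "prior" vs "encoded".  The three networks are
updated in turn on every batch:

* D update — minimize  L_D = −E_{z'~P(z)} log D(z') − E_{z~Q} log(1 − D(z)),
  i.e. learn to tell prior draws (positives) from encoder outputs.
* Q+G reconstruction update — minimize  λ2·L_REC  with
  L_REC = (1/n) Σ_i ‖x_i − x'_i‖²  (squared reconstruction error).
* Q generator update — minimize  λ1·L_G,  L_G = −E_{z~Q} log D(z)
  (make encoder outputs indistinguishable from the prior).

Each update has its own Adam state: because Adam normalizes per parameter,
decoupling the moments balances the reconstruction gradient (whose raw
scale grows with the feature count) against the O(1) adversarial gradient;
folding both into one step lets reconstruction swamp the prior-matching
term and the min–max game never reaches its equilibrium.

At the equilibrium of this min–max game the pooled encoder outputs match
the latent prior P(z) (standard normal here), which regularizes the code
space that downstream Gaussian-mixture clustering operates on.

The networks are small MLPs, so forward/backward passes are written
directly against numpy (a handful of GEMMs per batch) with Adam updates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ShapeError, TrainingError, ValidationError

__all__ = [
    "EmbedderConfig",
    "EmbedderState",
    "reconstruction_loss",
    "discriminator_loss",
    "generator_loss",
    "gan_loss",
    "total_loss",
    "train",
    "encode",
    "decode",
    "discriminate",
]

logger = logging.getLogger(__name__)

LEAKY_SLOPE = 0.2


# ---------------------------------------------------------------------------
# losses


def _check_probs(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0:
        raise ValidationError(f"{name} is empty")
    if (p < 0).any() or (p > 1).any():
        raise ValidationError(f"{name} contains values outside [0, 1]")
    return p


def reconstruction_loss(X: np.ndarray, X_rec: np.ndarray) -> float:
    """Mean squared Euclidean reconstruction error (1/n) Σ_i ‖x_i − x'_i‖²."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    X_rec = np.atleast_2d(np.asarray(X_rec, dtype=float))
    if X.shape != X_rec.shape:
        raise ShapeError(f"shape mismatch {X.shape} vs {X_rec.shape}")
    return float(np.mean(np.sum((X - X_rec) ** 2, axis=1)))


def discriminator_loss(d_pos: np.ndarray, d_neg: np.ndarray) -> float:
    """L_D = −mean log D(z') − mean log(1 − D(z)); z' from the prior."""
    d_pos = _check_probs(d_pos, "d_pos")
    d_neg = _check_probs(d_neg, "d_neg")
    return float(-np.mean(np.log(d_pos)) - np.mean(np.log1p(-d_neg)))


def generator_loss(d_neg: np.ndarray) -> float:
    """L_G = −mean log D(z) over encoder outputs z (small when D is fooled)."""
    d_neg = _check_probs(d_neg, "d_neg")
    return float(-np.mean(np.log(d_neg)))


def gan_loss(d_pos: np.ndarray, d_neg: np.ndarray) -> float:
    """L_GAN = L_D + L_G."""
    return discriminator_loss(d_pos, d_neg) + generator_loss(d_neg)


def total_loss(
    d_pos: np.ndarray,
    d_neg: np.ndarray,
    X: np.ndarray,
    X_rec: np.ndarray,
    lambda_gan: float = 1.0,
    lambda_rec: float = 1.0,
) -> float:
    """Combined objective L_ALL = λ1·L_GAN + λ2·L_REC."""
    return lambda_gan * gan_loss(d_pos, d_neg) + lambda_rec * reconstruction_loss(X, X_rec)


# ---------------------------------------------------------------------------
# configuration & state


@dataclass
class EmbedderConfig:
    """Training configuration.

    latent_dim is 200 by default: large enough to preserve cluster
    geometry from hundreds of thousands of peaks, small enough for
    mixture-model clustering on cohort-scale sample counts.
    """

    latent_dim: int = 200
    encoder_hidden: tuple[int, ...] = (1024,)
    disc_hidden: tuple[int, ...] = (128, 64)
    lambda_gan: float = 1.0
    lambda_rec: float = 1.0
    batch_size: int = 32
    lr_disc: float = 1e-4
    lr_enc: float = 1e-3
    lr_gen: float = 1e-4
    max_epochs: int = 200
    prior: str = "standard_normal"
    seed: int = 0
    eps: float = 1e-7
    # GAN stabilizers for the small-n, high-d regime where a discriminator
    # could otherwise memorize the finite set of encoder outputs
    disc_input_noise: float = 0.5
    disc_label_smoothing: float = 0.9
    disc_steps: int = 1
    # weight/rate of the latent moment calibration (0 disables it)
    moment_weight: float = 1.0
    lr_moment: float = 2e-4
    early_stop_tol: float = 1e-5
    early_stop_window: int = 10

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValidationError("latent_dim must be >= 1")
        if self.lambda_gan < 0 or self.lambda_rec < 0:
            raise ValidationError("loss weights must be nonnegative")
        if not 0 < self.eps < 0.5:
            raise ValidationError("probability clamp must lie in (0, 0.5)")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        if self.prior != "standard_normal":
            raise ValidationError(f"unsupported prior {self.prior!r}")
        if self.disc_input_noise < 0:
            raise ValidationError("disc_input_noise must be >= 0")
        if self.disc_steps < 1:
            raise ValidationError("disc_steps must be >= 1")
        if not 0.5 < self.disc_label_smoothing <= 1.0:
            raise ValidationError("disc_label_smoothing must lie in (0.5, 1]")


class _Mlp:
    """Fully connected stack with leaky-ReLU hidden layers; linear output."""

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            std = np.sqrt(2.0 / fan_in)
            self.weights.append(rng.normal(0.0, std, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def params(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, list]:
        """Returns (output, cache of (layer input, pre-activation)) pairs."""
        cache = []
        h = X
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            pre = h @ W + b
            cache.append((h, pre))
            h = np.where(pre > 0, pre, LEAKY_SLOPE * pre) if i < self.n_layers - 1 else pre
        return h, cache

    def backward(self, grad_out: np.ndarray, cache: list) -> tuple[list[np.ndarray], np.ndarray]:
        """Gradients of a scalar loss given d(loss)/d(output).

        Returns (grads aligned with params(), d(loss)/d(input)).
        """
        gW = [np.empty(0)] * self.n_layers
        gb = [np.empty(0)] * self.n_layers
        g = grad_out
        for i in range(self.n_layers - 1, -1, -1):
            h_in, pre = cache[i]
            if i < self.n_layers - 1:
                # scalars cast to g's dtype so float32 training stays float32
                one = np.asarray(1.0, dtype=g.dtype)
                slope = np.asarray(LEAKY_SLOPE, dtype=g.dtype)
                g = g * np.where(pre > 0, one, slope)
            gW[i] = h_in.T @ g
            gb[i] = g.sum(axis=0)
            g = g @ self.weights[i].T
        return gW + gb, g


class _Adam:
    """Adam with in-place, buffer-reusing updates (the parameter tensors are
    large enough that temporary allocation dominates a naive implementation)."""

    def __init__(self, params: list[np.ndarray], lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.buf = [np.empty_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for p, g, m, v, buf in zip(self.params, grads, self.m, self.v, self.buf):
            m *= self.b1
            np.multiply(g, 1.0 - self.b1, out=buf)
            m += buf
            v *= self.b2
            np.multiply(g, g, out=buf)
            buf *= 1.0 - self.b2
            v += buf
            np.divide(v, c2, out=buf)
            np.sqrt(buf, out=buf)
            buf += self.eps
            np.divide(m, buf, out=buf)
            buf *= self.lr / c1
            p -= buf


@dataclass
class EmbedderState:
    """Trained parameters plus the per-epoch loss history."""

    encoder: _Mlp
    decoder_w: np.ndarray
    decoder_b: np.ndarray
    disc: _Mlp
    config: EmbedderConfig
    history: dict[str, list[float]] = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.encoder.weights[0].shape[0]

    @property
    def latent_dim(self) -> int:
        return self.encoder.weights[-1].shape[1]


# ---------------------------------------------------------------------------
# forward maps


def encode(state: EmbedderState, X: np.ndarray) -> np.ndarray:
    """Deterministic latent codes Z = Q(X); no sampling at inference."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != state.n_features:
        raise ShapeError(
            f"input has {X.shape[1]} features, encoder expects {state.n_features}"
        )
    z, _ = state.encoder.forward(X)
    return z


def decode(state: EmbedderState, Z: np.ndarray) -> np.ndarray:
    """Affine reconstruction X' = Z W + b."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[1] != state.latent_dim:
        raise ShapeError(
            f"latent width {Z.shape[1]} does not match model d={state.latent_dim}"
        )
    return Z @ state.decoder_w + state.decoder_b


def discriminate(state: EmbedderState, Z: np.ndarray) -> np.ndarray:
    """Clamped discriminator probabilities D(Z) in [ε, 1−ε]."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    logits, _ = state.disc.forward(Z)
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-logits.ravel()))
    eps = state.config.eps
    return np.clip(p, eps, 1.0 - eps)


# ---------------------------------------------------------------------------
# training


def _init_state(
    n_features: int,
    config: EmbedderConfig,
    rng: np.random.Generator,
    X: np.ndarray | None = None,
) -> EmbedderState:
    enc = _Mlp([n_features, *config.encoder_hidden, config.latent_dim], rng)
    disc = _Mlp([config.latent_dim, *config.disc_hidden, 1], rng)
    dec_w = rng.normal(0.0, np.sqrt(1.0 / config.latent_dim), size=(config.latent_dim, n_features))
    dec_b = np.zeros(n_features)
    state = EmbedderState(enc, dec_w.astype(np.float32), dec_b.astype(np.float32), disc, config)
    # single-precision weights: the gradient game tolerates it and the GEMMs
    # that dominate training run twice as fast
    for net in (enc, disc):
        net.weights = [w.astype(np.float32) for w in net.weights]
        net.biases = [b.astype(np.float32) for b in net.biases]
    if X is not None:
        # data-dependent whitening of the output layer: rescale so the
        # initial latents have per-dimension mean 0 and variance 1 on the
        # training data.  Nonnegative inputs give strongly biased initial
        # codes otherwise, further from the prior than gradient steps can
        # travel in a practical number of epochs.
        sample = X[: min(len(X), 512)].astype(np.float32)
        z0, _ = enc.forward(sample)
        mu = z0.mean(axis=0)
        sd = z0.std(axis=0)
        sd[sd == 0] = 1.0
        enc.weights[-1] /= sd
        enc.biases[-1] -= mu
        enc.biases[-1] /= sd
    return state


def train(X: np.ndarray, config: EmbedderConfig | None = None) -> EmbedderState:
    """Fit the embedder by alternating discriminator and encoder/decoder steps.

    Fully deterministic given ``config.seed``: initialization, batch order
    and prior draws all flow from one generator.  Stops early once the
    epoch-mean reconstruction loss is flat (relative change below
    ``early_stop_tol`` across ``early_stop_window`` epochs).
    """
    config = config or EmbedderConfig()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("need a 2-D matrix with at least 2 samples")
    if (X < 0).any():
        raise ValidationError("input scores must be nonnegative")
    X = X.astype(np.float32)
    n, p = X.shape
    batch = config.batch_size
    if batch > n:
        warnings.warn(f"batch_size {batch} > n={n}; reducing to {n}", stacklevel=2)
        batch = n

    rng = np.random.default_rng(config.seed)
    state = _init_state(p, config, rng, X=X)
    enc, disc = state.encoder, state.disc
    # Three optimizers, one per update: decoupled Adam moments keep the
    # reconstruction gradient (scale ~p) from drowning the adversarial
    # gradient (scale ~1) when both pull on the encoder.
    opt_d = _Adam(disc.params(), config.lr_disc)
    opt_rec = _Adam(enc.params() + [state.decoder_w, state.decoder_b], config.lr_enc)
    opt_gen = _Adam(enc.params(), config.lr_gen)
    opt_mm = _Adam(enc.params(), config.lr_moment)
    eps = config.eps
    l1, l2 = config.lambda_gan, config.lambda_rec
    hist: dict[str, list[float]] = {"L_D": [], "L_G": [], "L_REC": []}
    mu_ema = np.zeros(config.latent_dim, dtype=X.dtype)

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        ep_d, ep_g, ep_rec = [], [], []
        for start in range(0, n - batch + 1, batch):
            xb = X[order[start : start + batch]]
            m = xb.shape[0]
            zb, cache_enc = enc.forward(xb)

            # ---- discriminator updates (encoder outputs detached).  Several
            # cheap D steps per batch keep D tracking the moving encoder
            # cloud; otherwise the generator exploits D's lag instead of
            # matching the prior.
            noise = config.disc_input_noise
            t_pos = config.disc_label_smoothing
            if l1 > 0:
                l_d = 0.0
                for _ in range(config.disc_steps):
                    z_prior = rng.standard_normal((m, config.latent_dim)).astype(X.dtype)
                    # instance noise: D sees smoothed clouds, not a finite
                    # set of memorizable points
                    zp_in, zn_in = z_prior, zb
                    if noise > 0:
                        zp_in = zp_in + noise * rng.standard_normal(zp_in.shape).astype(X.dtype)
                        zn_in = zn_in + noise * rng.standard_normal(zn_in.shape).astype(X.dtype)
                    logit_pos, cache_pos = disc.forward(zp_in)
                    logit_neg, cache_neg = disc.forward(zn_in)
                    with np.errstate(over="ignore"):  # saturated logits clip to eps
                        p_pos = np.clip(1 / (1 + np.exp(-logit_pos)), eps, 1 - eps)
                        p_neg = np.clip(1 / (1 + np.exp(-logit_neg)), eps, 1 - eps)
                    l_d = discriminator_loss(p_pos, p_neg)
                    # d/dlogit of cross-entropy at target t is σ(a) − t
                    # (one-sided label smoothing keeps D from saturating)
                    grads_pos, _ = disc.backward(l1 * (p_pos - t_pos) / m, cache_pos)
                    grads_neg, _ = disc.backward(l1 * p_neg / m, cache_neg)
                    opt_d.step([a + b for a, b in zip(grads_pos, grads_neg)])
            else:
                l_d = 0.0

            # ---- reconstruction update of encoder + decoder (D untouched,
            # encoder unchanged since the forward above: reuse zb)
            x_rec = zb @ state.decoder_w + state.decoder_b
            l_rec = reconstruction_loss(xb, x_rec)
            grad_xrec = (2.0 * l2 / m) * (x_rec - xb)
            g_dec_w = zb.T @ grad_xrec
            g_dec_b = grad_xrec.sum(axis=0)
            grads_enc, _ = enc.backward(grad_xrec @ state.decoder_w.T, cache_enc)
            opt_rec.step(grads_enc + [g_dec_w, g_dec_b])

            # ---- generator update of the encoder (fool the discriminator)
            if l1 > 0:
                zb2, cache_enc2 = enc.forward(xb)
                zn_in = zb2
                if noise > 0:
                    zn_in = zn_in + noise * rng.standard_normal(zn_in.shape).astype(X.dtype)
                logit_neg, cache_neg = disc.forward(zn_in)
                with np.errstate(over="ignore"):
                    p_neg = np.clip(1 / (1 + np.exp(-logit_neg)), eps, 1 - eps)
                l_g = generator_loss(p_neg)
                # minimize −log D(z): d/dlogit = σ(a) − 1, then through D to z
                _, g_to_z = disc.backward(l1 * (p_neg - 1.0) / m, cache_neg)
                if config.moment_weight > 0:
                    # drop the translation component: shifting the whole
                    # cloud along D's gradient is the generator's fastest
                    # move but fights the mean calibration below forever
                    g_to_z = g_to_z - g_to_z.mean(axis=0)
                grads_gen, _ = enc.backward(g_to_z, cache_enc2)
                opt_gen.step(grads_gen)
                if config.moment_weight > 0:
                    # per-batch latent moment matching: a pointwise
                    # discriminator cannot pin the first two moments of a
                    # small cohort, so they are calibrated to N(0, I)
                    # explicitly.  The mean is recentered through the output
                    # bias alone — a pure translation that cannot distort
                    # cluster geometry; the variance penalty Σ_k (σ²_k − 1)²
                    # backpropagates normally (dvar/dz = 2(z−μ)/m exactly).
                    zb3, cache_enc3 = enc.forward(xb)
                    mu = zb3.mean(axis=0)
                    var = zb3.var(axis=0)
                    # EMA of the pooled mean: a batch mean is too noisy an
                    # estimator to subtract outright
                    mu_ema = 0.8 * mu_ema + 0.2 * mu
                    # recentering is paired with a compensating decoder-bias
                    # shift (x' = zW + b is unchanged), so reconstruction is
                    # indifferent to it and cannot pull the mean back out
                    delta = (0.3 * config.moment_weight * mu_ema).astype(X.dtype)
                    enc.biases[-1] -= delta
                    state.decoder_b += delta @ state.decoder_w
                    mu_ema = mu_ema - delta
                    g_var = (4.0 * config.moment_weight / m) * (
                        (var - 1.0) * (zb3 - mu)
                    )
                    grads_mm, _ = enc.backward(g_var.astype(X.dtype), cache_enc3)
                    opt_mm.step(grads_mm)
            else:
                l_g = 0.0

            if not (np.isfinite(l_d) and np.isfinite(l_g) and np.isfinite(l_rec)):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}, batch {start // batch}"
                )
            ep_d.append(l_d)
            ep_g.append(l_g)
            ep_rec.append(l_rec)

        hist["L_D"].append(float(np.mean(ep_d)))
        hist["L_G"].append(float(np.mean(ep_g)))
        hist["L_REC"].append(float(np.mean(ep_rec)))
        w = config.early_stop_window
        if epoch >= w:
            prev, cur = hist["L_REC"][-1 - w], hist["L_REC"][-1]
            if abs(cur - prev) < config.early_stop_tol * max(abs(prev), 1.0):
                logger.info("early stop at epoch %d (flat reconstruction loss)", epoch)
                break

    state.history = hist
    return state
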