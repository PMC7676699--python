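import numpy as np
import pytest

from aaeclust.embedder import (
    EmbedderConfig,
    decode,
    discriminator_loss,
    encode,
    gan_loss,
    generator_loss,
    reconstruction_loss,
    total_loss,
    train,
)
from aaeclust.errors import ShapeError, ValidationError


class TestLossFormulas:
    def test_reconstruction_identity_and_hand_values(self):
        assert reconstruction_loss(np.ones((3, 4)), np.ones((3, 4))) == 0.0
        # single row (1,2,2) vs origin: squared norm 1+4+4 = 9
        assert reconstruction_loss([[1.0, 2.0, 2.0]], [[0.0, 0.0, 0.0]]) == 9.0
        # two rows each differing by a unit vector: mean of (1, 1) = 1
        X = np.zeros((2, 3))
        Xr = np.array([[1.0, 0, 0], [0, 1.0, 0]])
        assert reconstruction_loss(X, Xr) == 1.0

    def test_reconstruction_shape_mismatch(self):
        with pytest.raises(ShapeError):
            reconstruction_loss(np.zeros((2, 3)), np.zeros((3, 2)))

    def test_discriminator_loss_values(self):
        eps = 1e-7
        assert discriminator_loss([1 - eps], [eps]) == pytest.approx(0.0, abs=1e-6)
        assert discriminator_loss([0.5], [0.5]) == pytest.approx(2 * np.log(2))
        assert discriminator_loss([0.8], [0.3]) == pytest.approx(
            -np.log(0.8) - np.log(0.7)
        )

    def test_generator_loss_values(self):
        assert generator_loss([1 - 1e-7]) == pytest.approx(0.0, abs=1e-6)
        assert generator_loss([0.5]) == pytest.approx(np.log(2))
        assert generator_loss([np.exp(-1.0)]) == pytest.approx(1.0)

    def test_probability_domain_errors(self):
        with pytest.raises(ValidationError):
            discriminator_loss([1.2], [0.5])
        with pytest.raises(ValidationError):
            generator_loss([-0.1])

    def test_loss_identities_on_random_inputs(self, rng):
        """L_D, L_G, L_REC and L_ALL match direct formula evaluation to 1e-6."""
        for _ in range(100):
            m = rng.integers(1, 20)
            d_pos = rng.uniform(0.01, 0.99, m)
            d_neg = rng.uniform(0.01, 0.99, m)
            X = rng.normal(size=(m, 5))
            Xr = rng.normal(size=(m, 5))
            l_d = -np.mean(np.log(d_pos)) - np.mean(np.log(1 - d_neg))
            l_g = -np.mean(np.log(d_neg))
            l_rec = np.mean(((X - Xr) ** 2).sum(axis=1))
            lam1, lam2 = rng.uniform(0, 2, 2)
            assert discriminator_loss(d_pos, d_neg) == pytest.approx(l_d, abs=1e-6)
            assert generator_loss(d_neg) == pytest.approx(l_g, abs=1e-6)
            assert reconstruction_loss(X, Xr) == pytest.approx(l_rec, abs=1e-6)
            assert gan_loss(d_pos, d_neg) == pytest.approx(l_d + l_g, abs=1e-6)
            assert total_loss(d_pos, d_neg, X, Xr, lam1, lam2) == pytest.approx(
                lam1 * (l_d + l_g) + lam2 * l_rec, abs=1e-6
            )


def _tiny_config(**kw):
    base = dict(
        latent_dim=3,
        encoder_hidden=(16,),
        disc_hidden=(8,),
        batch_size=8,
        max_epochs=5,
        seed=0,
    )
    base.update(kw)
    return EmbedderConfig(**base)


class TestForwardMaps:
    def test_encode_deterministic_and_shaped(self, rng):
        X = rng.uniform(0, 1, size=(20, 12))
        state = train(X, _tiny_config())
        Z1 = encode(state, X[:5])
        Z2 = encode(state, X[:5])
        np.testing.assert_array_equal(Z1, Z2)
        assert Z1.shape == (5, 3)
        with pytest.raises(ShapeError):
            encode(state, X[:, :7])

    def test_encode_zero_weights_is_constant_map(self, rng):
        X = rng.uniform(0, 1, size=(10, 6))
        state = train(X, _tiny_config())
        for w in state.encoder.weights:
            w[:] = 0.0
        for b in state.encoder.biases:
            b[:] = 0.0
        Z = encode(state, X)
        np.testing.assert_array_equal(Z, np.zeros_like(Z))

    def test_decode_is_affine(self, rng):
        X = rng.uniform(0, 1, size=(10, 4))
        state = train(X, _tiny_config())
        state.decoder_w = np.array([[2.0, 0.0], [0.0, 0.0], [0.0, 0.0]])
        state.decoder_b = np.array([1.0, 1.0])
        np.testing.assert_allclose(decode(state, [[3.0, 0.0, 0.0]]), [[7.0, 1.0]])
        # Z = 0 reproduces the bias on every row
        np.testing.assert_allclose(decode(state, np.zeros((4, 3))), np.ones((4, 2)))
        with pytest.raises(ShapeError):
            decode(state, np.zeros((2, 5)))

    def test_decode_encode_shape_contract(self, rng):
        X = rng.uniform(0, 1, size=(7, 9))
        state = train(X, _tiny_config())
        assert decode(state, encode(state, X)).shape == X.shape


class TestTraining:
    def test_same_seed_reproduces_history(self, rng):
        X = rng.uniform(0, 1, size=(30, 10))
        h1 = train(X, _tiny_config(seed=42)).history
        h2 = train(X, _tiny_config(seed=42)).history
        assert h1 == h2

    def test_constant_matrix_reconstruction_vanishes(self):
        X = np.full((40, 6), 3.7)
        state = train(X, _tiny_config(max_epochs=300))
        assert state.history["L_REC"][-1] < 0.05 * state.history["L_REC"][0]

    def test_lambda1_zero_is_plain_autoencoder_on_rank1(self, rng):
        u = rng.uniform(1, 2, size=(50, 1))
        v = rng.uniform(0.5, 1.5, size=(1, 8))
        X = u @ v
        state = train(X, _tiny_config(lambda_gan=0.0, max_epochs=400, batch_size=16))
        assert state.history["L_G"][-1] == 0.0
        assert state.history["L_REC"][-1] < 0.01 * state.history["L_REC"][0]

    def test_batch_size_reduced_with_warning(self, rng):
        X = rng.uniform(0, 1, size=(5, 6))
        with pytest.warns(UserWarning, match="batch_size"):
            train(X, _tiny_config(batch_size=64, max_epochs=2))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            train(np.ones((1, 4)), _tiny_config())

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            train(-np.ones((4, 4)), _tiny_config())


def test_config_invariants():
    with pytest.raises(ValidationError):
        EmbedderConfig(latent_dim=0)
    with pytest.raises(ValidationError):
        EmbedderConfig(lambda_gan=-1)
    with pytest.raises(ValidationError):
        EmbedderConfig(eps=0.7)
    with pytest.raises(ValidationError):
        EmbedderConfig(batch_size=0)
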