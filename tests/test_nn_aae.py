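"""Network core and adversarial-autoencoder contracts."""

import numpy as np
import pytest

from mmaae import NoiseConfig
from mmaae.aae import (
    TrainConfig,
    adversarial_losses,
    build_reconstruction_model,
    build_synthesis_model,
    decode,
    discriminate,
    encode,
    reconstruction_loss,
    train_reconstruction_model,
    train_synthesis_model,
)
from mmaae.data import ModalitySchema
from mmaae.nn import MLP, Adam, bce_with_logits, sigmoid


def test_backprop_matches_finite_differences():
    rng = np.random.default_rng(0)
    mlp = MLP([5, 7, 4, 3], rng, out_activation="sigmoid")
    X = rng.random((6, 5))
    T = rng.random((6, 3))
    s, cache = mlp.forward(X)
    _, d_s = bce_with_logits(s, T)
    grads, dX = mlp.backward(d_s, cache)
    eps = 1e-6
    rng2 = np.random.default_rng(1)
    for i in range(mlp.n_layers):
        for arr, g in ((mlp.W[i], grads[i][0]), (mlp.b[i], grads[i][1])):
            flat = arr.ravel()
            for j in rng2.choice(flat.size, size=min(10, flat.size), replace=False):
                old = flat[j]
                flat[j] = old + eps
                lp, _ = bce_with_logits(mlp.forward(X)[0], T)
                flat[j] = old - eps
                lm, _ = bce_with_logits(mlp.forward(X)[0], T)
                flat[j] = old
                assert abs((lp - lm) / (2 * eps) - g.ravel()[j]) < 1e-7


class TestEncodeDecode:
    def test_reconstruction_latent_dim_128(self):
        model = build_reconstruction_model(166, np.random.default_rng(0))
        z = encode(np.random.default_rng(1).random((4, 166)), model)
        assert z.shape == (4, 128)

    def test_zero_initialized_network_encodes_to_zero(self):
        model = build_reconstruction_model(166, np.random.default_rng(0))
        for i in range(model.encoder.n_layers):
            model.encoder.W[i][:] = 0.0
            model.encoder.b[i][:] = 0.0
        z = encode(np.random.default_rng(1).random((3, 166)), model)
        assert np.all(z == 0.0)

    def test_encode_is_deterministic_in_eval_mode(self):
        model = build_reconstruction_model(166, np.random.default_rng(0))
        x = np.random.default_rng(1).random((5, 166))
        assert np.array_equal(encode(x, model), encode(x, model))

    def test_width_mismatch_rejected(self):
        model = build_reconstruction_model(166, np.random.default_rng(0))
        with pytest.raises(ValueError):
            encode(np.zeros((2, 10)), model)

    def test_synthesis_decoder_input_width(self):
        model = build_synthesis_model(166, 51, np.random.default_rng(0))
        assert model.decoder.in_width == 10 + 51
        assert model.latent_dim == 10

    def test_decoder_output_strictly_inside_unit_interval(self):
        model = build_reconstruction_model(166, np.random.default_rng(0))
        x = decode(np.random.default_rng(1).standard_normal((4, 128)), model)
        assert np.all((x > 0.0) & (x < 1.0))

    def test_conditioned_decoder_requires_and_accepts_labels(self):
        model = build_synthesis_model(20, 5, np.random.default_rng(0))
        z = np.zeros((3, 10))
        with pytest.raises(ValueError):
            decode(z, model)
        y = np.zeros((3, 5))  # fully unreported rows encoded as zeros
        out = decode(z, model, y)
        assert out.shape == (3, 20)
        y_nan = np.full((3, 5), np.nan)
        assert np.array_equal(decode(z, model, y_nan), out)


class TestDiscriminator:
    def test_untrained_discriminator_is_uninformative(self):
        model = build_reconstruction_model(166, np.random.default_rng(0))
        rng = np.random.default_rng(1)
        a = discriminate(rng.standard_normal((1000, 128)), model)
        b = discriminate(rng.standard_normal((1000, 128)), model)
        ba = 0.5 * ((a >= 0.5).mean() + (b < 0.5).mean())
        assert abs(ba - 0.5) < 0.1
        assert np.all((a > 0) & (a < 1))

    def test_learns_analytically_separable_classes(self):
        """Mean-0 vs mean-5 spherical normals are separated with held-out
        accuracy > 0.9 after supervised training."""
        rng = np.random.default_rng(0)
        D = MLP([8, 128, 128, 1], rng, out_activation="sigmoid")
        opt = Adam(D, 3e-4)
        for _ in range(800):
            a = rng.standard_normal((32, 8))
            b = rng.standard_normal((32, 8)) + 5.0
            X = np.vstack([a, b])
            y = np.vstack([np.ones((32, 1)), np.zeros((32, 1))])
            s, c = D.forward(X, train=True)
            _, d_s = bce_with_logits(s, y)
            g, _ = D.backward(d_s, c)
            opt.step(g)
        a = sigmoid(D.forward(rng.standard_normal((1000, 8)))[0])
        b = sigmoid(D.forward(rng.standard_normal((1000, 8)) + 5.0)[0])
        acc = 0.5 * ((a >= 0.5).mean() + (b < 0.5).mean())
        assert acc > 0.9


class TestLosses:
    def test_reconstruction_loss_near_zero_for_confident_match(self):
        x = np.array([[0.0, 1.0, 1.0, 0.0]])
        pred = np.abs(x - 1e-9)
        assert reconstruction_loss(x, pred) < 1e-6

    def test_half_probability_single_entry(self):
        assert reconstruction_loss(np.array([[1.0]]), np.array([[0.5]])) == \
            pytest.approx(np.log(2), abs=1e-9)

    def test_symmetry(self):
        p = np.array([[0.37]])
        assert reconstruction_loss(np.array([[0.0]]), p) == pytest.approx(
            reconstruction_loss(np.array([[1.0]]), 1.0 - p), abs=1e-12
        )

    def test_target_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_loss(np.array([[1.5]]), np.array([[0.5]]))

    def test_chance_discriminator_gives_two_log_two(self):
        rng = np.random.default_rng(0)
        D = MLP([4, 8, 1], rng, out_activation="sigmoid")
        for i in range(D.n_layers):
            D.W[i][:] = 0.0
            D.b[i][:] = 0.0  # output logit 0 -> D == 0.5 everywhere
        d_loss, g_loss = adversarial_losses(
            rng.standard_normal((100, 4)), rng.standard_normal((100, 4)), D
        )
        assert d_loss == pytest.approx(2 * np.log(2), abs=1e-12)
        assert g_loss == pytest.approx(np.log(2), abs=1e-12)

    def test_generator_loss_vanishes_when_discriminator_fooled(self):
        rng = np.random.default_rng(0)
        D = MLP([4, 8, 1], rng, out_activation="sigmoid")
        D.b[-1][:] = 50.0  # D(z) -> 1 everywhere
        _, g_loss = adversarial_losses(
            rng.standard_normal((10, 4)), rng.standard_normal((10, 4)), D
        )
        assert g_loss < 1e-9

    def test_training_discriminator_on_fixed_inputs_decreases_d_loss(self):
        rng = np.random.default_rng(0)
        D = MLP([2, 16, 1], rng, out_activation="sigmoid")
        z_fake = rng.standard_normal((64, 2)) + 3.0
        z_real = rng.standard_normal((64, 2))
        before, _ = adversarial_losses(z_fake, z_real, D)
        opt = Adam(D, 1e-3)
        for _ in range(50):
            s_r, c_r = D.forward(z_real, train=True)
            s_f, c_f = D.forward(z_fake, train=True)
            g_r, _ = D.backward(-sigmoid(-s_r) / 64, c_r)
            g_f, _ = D.backward(sigmoid(s_f) / 64, c_f)
            opt.step([(a + c, b + d) for (a, b), (c, d) in zip(g_r, g_f)])
        after, _ = adversarial_losses(z_fake, z_real, D)
        assert after < before


def test_phase_isolation():
    """A discriminator update leaves encoder/decoder parameters
    untouched and a generator update leaves the discriminator untouched
    (verified on the same primitives the trainer composes)."""
    rng = np.random.default_rng(0)
    model = build_reconstruction_model(12, rng, latent_dim=4, hidden=8)
    x = rng.random((16, 12))
    h_enc, h_dec, h_disc = (model.encoder.params_hash(),
                            model.decoder.params_hash(),
                            model.discriminator.params_hash())
    # discriminator phase
    z_fake = encode(x, model)
    z_real = rng.standard_normal((16, 4))
    opt_disc = Adam(model.discriminator, 1e-3)
    s_r, c_r = model.discriminator.forward(z_real, train=True)
    s_f, c_f = model.discriminator.forward(z_fake, train=True)
    g_r, _ = model.discriminator.backward(-sigmoid(-s_r) / 16, c_r)
    g_f, _ = model.discriminator.backward(sigmoid(s_f) / 16, c_f)
    opt_disc.step([(a + c, b + d) for (a, b), (c, d) in zip(g_r, g_f)])
    assert model.encoder.params_hash() == h_enc
    assert model.decoder.params_hash() == h_dec
    assert model.discriminator.params_hash() != h_disc
    # generator phase
    h_disc = model.discriminator.params_hash()
    opt_enc = Adam(model.encoder, 1e-3)
    z, c_enc = model.encoder.forward(x, train=True)
    s_g, c_g = model.discriminator.forward(z, train=False)
    _, d_z = model.discriminator.backward(-sigmoid(-s_g) / 16, c_g)
    g_enc, _ = model.encoder.backward(d_z, c_enc)
    opt_enc.step(g_enc)
    assert model.discriminator.params_hash() == h_disc
    assert model.encoder.params_hash() != h_enc
    assert model.decoder.params_hash() == h_dec


SCHEMA_SMALL = ModalitySchema((("A", 6), ("B", 6), ("C", 6)))


def _small_clean(rows=400, seed=0):
    rng = np.random.default_rng(seed)
    f = rng.random((rows, 3))
    X = np.empty((rows, 18))
    for b in range(3):
        W = rng.standard_normal((3, 6))
        X[:, 6 * b:6 * (b + 1)] = sigmoid(f @ W + 0.1 * rng.standard_normal((rows, 6)))
    return X


class TestTraining:
    def test_validation_loss_improves_over_initialization(self):
        X = _small_clean()
        noise = NoiseConfig(n_drop_min=1, n_drop_max=2)
        cfg = TrainConfig.reconstruction_defaults(seed=1, max_epochs=8)
        model = train_reconstruction_model(X, noise, cfg, schema=SCHEMA_SMALL)
        init = model.history[0]["val_recon"]
        best = model.history[-1]["best_val_recon"]
        assert best < init

    def test_plain_denoising_autoencoder_also_learns(self):
        """With adversarial phases disabled the loop reduces to the
        denoising-autoencoder objective and still decreases loss."""
        X = _small_clean()
        noise = NoiseConfig(n_drop_min=1, n_drop_max=2)
        cfg = TrainConfig.reconstruction_defaults(
            seed=1, max_epochs=8, adversarial=False
        )
        model = train_reconstruction_model(X, noise, cfg, schema=SCHEMA_SMALL)
        assert model.history[-1]["best_val_recon"] < model.history[0]["val_recon"]
        assert all(np.isnan(h["d_loss"]) for h in model.history[1:-1])

    def test_synthesis_model_contract(self):
        X = _small_clean()
        rng = np.random.default_rng(3)
        labels = (rng.random((X.shape[0], 5)) < 0.3).astype(float)
        labels[rng.random(labels.shape) < 0.3] = np.nan  # unreported
        cfg = TrainConfig.synthesis_defaults(seed=1, max_epochs=8)
        model = train_synthesis_model(X, labels, cfg)
        assert model.latent_dim == 10
        assert model.label_conditioned
        assert model.history[-1]["best_val_recon"] < model.history[0]["val_recon"]

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_reconstruction_model(
                np.zeros((0, 18)), NoiseConfig(n_drop_min=1, n_drop_max=2),
                TrainConfig.reconstruction_defaults(), schema=SCHEMA_SMALL,
            )

    def test_seeded_training_is_reproducible(self):
        X = _small_clean(rows=200)
        noise = NoiseConfig(n_drop_min=1, n_drop_max=2)
        cfg = TrainConfig.reconstruction_defaults(seed=9, max_epochs=3)
        a = train_reconstruction_model(X, noise, cfg, schema=SCHEMA_SMALL)
        b = train_reconstruction_model(X, noise, cfg, schema=SCHEMA_SMALL)
        assert a.encoder.params_hash() == b.encoder.params_hash()
        assert a.decoder.params_hash() == b.decoder.params_hash()


def test_model_save_load_round_trip(tmp_path):
    model = build_synthesis_model(18, 5, np.random.default_rng(0))
    model.trained = True
    path = tmp_path / "model.npz"
    model.save(path)
    from mmaae.aae import AAEModel

    back = AAEModel.load(path)
    assert back.encoder.params_hash() == model.encoder.params_hash()
    assert back.label_conditioned and back.n_labels == 5
    x = np.random.default_rng(1).random((3, 18))
    assert np.array_equal(encode(x, back), encode(x, model))
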