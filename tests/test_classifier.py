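"""Instance weighting, weighted multi-label loss and classifier training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mmaae import GeneratorConfig, NoiseConfig, generate_dataset, make_user_folds
from mmaae.aae import TrainConfig, encode, train_reconstruction_model
from mmaae.classifier import (
    ClassifierSpec,
    compute_instance_weights,
    predict_labels,
    train_embedding_classifier,
    train_extended_classifier,
    weighted_multilabel_loss,
)
from mmaae.data import apply_normalizer, fit_normalizer
from mmaae.metrics import label_metrics
from mmaae.nn import MLP, bce_with_logits


class TestInstanceWeights:
    def test_balanced_label_is_weight_neutral(self):
        labels = np.array([[1.0], [1.0], [0.0], [0.0]])
        psi = compute_instance_weights(labels).weights
        assert np.all(psi == 1.0)

    def test_unreported_entries_weigh_zero(self):
        labels = np.array([[1.0], [np.nan], [0.0]])
        psi = compute_instance_weights(labels).weights
        assert psi[1, 0] == 0.0

    def test_four_observed_one_positive(self):
        labels = np.array([[1.0], [0.0], [0.0], [0.0]])
        psi = compute_instance_weights(labels).weights
        assert psi[0, 0] == pytest.approx(2.0)
        assert psi[1, 0] == pytest.approx(2.0 / 3.0)

    def test_one_class_label_flagged_with_zero_weights(self):
        labels = np.array([[1.0, 1.0], [1.0, 0.0], [np.nan, 1.0]])
        w = compute_instance_weights(labels)
        assert 0 in w.flagged_labels
        assert np.all(w.weights[:, 0] == 0.0)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_positive_and_negative_mass_balance(self, seed):
        """For every fully observed two-class label, the weighted count
        of positives equals that of negatives (each N_obs/2)."""
        rng = np.random.default_rng(seed)
        labels = (rng.random((rng.integers(4, 40), 3)) < 0.4).astype(float)
        labels[rng.random(labels.shape) < 0.2] = np.nan
        psi = compute_instance_weights(labels).weights
        for c in range(3):
            obs = ~np.isnan(labels[:, c])
            pos = obs & (labels[:, c] == 1.0)
            neg = obs & (labels[:, c] == 0.0)
            if pos.any() and neg.any():
                assert psi[pos, c].sum() == pytest.approx(obs.sum() / 2)
                assert psi[neg, c].sum() == pytest.approx(obs.sum() / 2)


class TestWeightedLoss:
    def test_unit_weights_reduce_to_plain_bce(self):
        rng = np.random.default_rng(0)
        P = rng.uniform(0.05, 0.95, (6, 4))
        L = (rng.random((6, 4)) < 0.5).astype(float)
        psi = np.ones_like(P)
        plain = -(L * np.log(P) + (1 - L) * np.log1p(-P)).mean()
        assert weighted_multilabel_loss(P, L, psi) == pytest.approx(plain)

    def test_flipping_unreported_targets_is_bit_identical(self):
        rng = np.random.default_rng(1)
        P = rng.uniform(0.05, 0.95, (8, 5))
        L = (rng.random((8, 5)) < 0.4).astype(float)
        L[rng.random(L.shape) < 0.3] = np.nan
        psi = compute_instance_weights(L).weights
        flipped = L.copy()
        unrep = np.isnan(L)
        flipped[unrep] = rng.integers(0, 2, unrep.sum())
        base = weighted_multilabel_loss(P, np.nan_to_num(L), psi)
        alt = weighted_multilabel_loss(P, flipped, psi)
        assert base == alt  # bit-identical, not approximately equal

    def test_hand_computed_single_entry(self):
        loss = weighted_multilabel_loss(
            np.array([[0.5]]), np.array([[1.0]]), np.array([[2.0]])
        )
        assert loss == pytest.approx(2 * np.log(2), abs=1e-9)

    def test_unreported_gradient_invariance_on_tiny_network(self):
        """Permuting targets at zero-weight entries leaves every
        parameter gradient of a tiny classifier bit-identical."""
        rng = np.random.default_rng(2)
        net = MLP([4, 6, 3], rng, out_activation="sigmoid")
        X = rng.random((10, 4))
        L = (rng.random((10, 3)) < 0.5).astype(float)
        L[rng.random(L.shape) < 0.4] = np.nan
        psi = compute_instance_weights(L).weights

        def grads_for(targets):
            s, c = net.forward(X)
            _, d_s = bce_with_logits(s, targets, weights=psi)
            g, _ = net.backward(d_s, c)
            return g

        g1 = grads_for(np.nan_to_num(L, nan=0.0))
        perm = L.copy()
        perm[np.isnan(L)] = 1.0
        g2 = grads_for(perm)
        for (w1, b1), (w2, b2) in zip(g1, g2):
            assert np.array_equal(w1, w2) and np.array_equal(b1, b2)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_multilabel_loss(np.zeros((2, 2)) + 0.5, np.zeros((2, 3)),
                                     np.zeros((2, 3)))


class TestPredict:
    def _clf(self):
        rng = np.random.default_rng(0)
        from mmaae.classifier import ContextClassifier

        head = MLP([3, 4, 51], rng, out_activation="sigmoid")
        return ContextClassifier(head=head, n_labels=51)

    def test_threshold_rule(self):
        from mmaae.classifier import ContextClassifier

        clf = self._clf()
        proba = np.array([[0.6, 0.4, 0.5]])
        out = (proba >= clf.spec.threshold).astype(float)
        assert out.tolist() == [[1.0, 0.0, 1.0]]  # 0.5 ties go to 1

    def test_prediction_shape_default_label_space(self):
        clf = self._clf()
        X = np.random.default_rng(1).random((7, 3))
        assert predict_labels(clf, X).shape == (7, 51)


EASY_CONFIG = dict(
    n_users=12, instances_per_user=(160, 200), n_labels=4,
    label_signal=20.0, label_prevalence=0.5, noise_sd=0.02,
    label_missing_rate=0.0, modality_missing_rates={},
    user_nonwear_rate=0.0, user_factor_weight=0.3, seed=3,
)


@pytest.fixture(scope="module")
def easy_benchmark():
    ds, _ = generate_dataset(GeneratorConfig(**EASY_CONFIG))
    plan = make_user_folds(ds.user_ids, 4, np.random.default_rng(0))
    train = ds.subset_users(plan[0][0])
    test = ds.subset_users(plan[0][1])
    norm = fit_normalizer(train)
    return apply_normalizer(train, norm), apply_normalizer(test, norm)


class TestExtendedClassifier:
    def test_near_separable_labels_reach_high_balanced_accuracy(self, easy_benchmark):
        """On a benchmark with near-separable labels the extended
        classifier exceeds macro BA 0.9 on held-out users."""
        train, test = easy_benchmark
        model = train_reconstruction_model(
            train, NoiseConfig(),
            TrainConfig.reconstruction_defaults(seed=1, max_epochs=10),
        )
        clf = train_extended_classifier(
            model, train, None, TrainConfig.reconstruction_defaults(seed=2)
        )
        rep = label_metrics(test.labels, predict_labels(clf, test.features))
        assert rep.macro["balanced_accuracy"] > 0.9
        assert clf.history[-1]["train_loss"] < clf.history[0]["train_loss"]

    def test_training_survives_structured_noise(self, easy_benchmark):
        train, _ = easy_benchmark
        sub = train.subset(np.arange(200))
        model = train_reconstruction_model(
            sub, NoiseConfig(),
            TrainConfig.reconstruction_defaults(seed=1, max_epochs=2),
        )
        clf = train_extended_classifier(
            model, sub, NoiseConfig(),
            TrainConfig.reconstruction_defaults(seed=2, max_epochs=3),
        )
        assert predict_labels(clf, sub.features).shape == sub.labels.shape


class TestEmbeddingClassifier:
    def test_consumes_128_dim_embeddings(self, easy_benchmark):
        train, _ = easy_benchmark
        model = train_reconstruction_model(
            train, NoiseConfig(),
            TrainConfig.reconstruction_defaults(seed=1, max_epochs=2),
        )
        emb = encode(train.features, model)
        assert emb.shape[1] == 128
        clf = train_embedding_classifier(
            emb, train.labels,
            TrainConfig.reconstruction_defaults(seed=2, max_epochs=3),
        )
        assert clf.head.in_width == 128

    def test_deterministic_given_seed(self, easy_benchmark):
        train, _ = easy_benchmark
        X = train.features[:300]
        L = train.labels[:300]
        cfg = TrainConfig.reconstruction_defaults(seed=5, max_epochs=3)
        a = train_embedding_classifier(X, L, cfg)
        b = train_embedding_classifier(X, L, cfg)
        assert a.head.params_hash() == b.head.params_hash()

    def test_misaligned_labels_rejected(self):
        with pytest.raises(ValueError):
            train_embedding_classifier(
                np.zeros((5, 4)), np.zeros((6, 2)),
                TrainConfig.reconstruction_defaults(),
            )


def test_embedding_classifier_close_to_raw_features(fold_artifacts):
    """A classifier on frozen 128-d codes performs within 0.05 macro BA
    of an identical-capacity classifier on the raw 166 features."""
    from mmaae.data import split_clean_noisy

    art = fold_artifacts
    clean_tr, _ = split_clean_noisy(art.combined.subset(
        np.arange(art.combined.n_instances)))
    clean_te, _ = split_clean_noisy(art.test_norm)
    cfg = TrainConfig.reconstruction_defaults(seed=2)
    emb_clf = train_embedding_classifier(
        encode(clean_tr.features, art.model), clean_tr.labels, cfg)
    raw_clf = train_embedding_classifier(clean_tr.features, clean_tr.labels, cfg)
    ba_emb = label_metrics(
        clean_te.labels,
        predict_labels(emb_clf, encode(clean_te.features, art.model)),
    ).macro["balanced_accuracy"]
    ba_raw = label_metrics(
        clean_te.labels, predict_labels(raw_clf, clean_te.features)
    ).macro["balanced_accuracy"]
    assert ba_emb > ba_raw - 0.05
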