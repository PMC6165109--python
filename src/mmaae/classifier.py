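"""Multi-label context classification with instance weighting.

The loss is a per-(instance, label) weighted binary cross-entropy:
positives of label c weigh N_obs/(2·N_pos), negatives N_obs/(2·N_neg),
and unreported entries weigh exactly zero, so a balanced fully-observed
label is weight-neutral and missing labels contribute nothing to any
gradient.  The classification head (one 64-unit hidden layer, C sigmoid
outputs, threshold 0.5) can be stacked on a trained encoder and
fine-tuned end-to-end under structured input noise, or trained alone on
frozen embeddings / raw features.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .aae import AAEModel, TrainConfig
from .corruption import NoiseConfig, corrupt
from .data import ModalitySchema, MultimodalDataset
from .metrics import label_metrics
from .nn import MLP, Adam, bce_with_logits, sigmoid


@dataclass
class ClassifierSpec:
    """Head architecture: hidden widths, sigmoid outputs, 0.5 threshold."""

    hidden: tuple[int, ...] = (64,)
    threshold: float = 0.5
    activation: str = "lrelu"  # "relu" variant for the synthetic-data classifier

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0,1)")


@dataclass
class InstanceWeightMatrix:
    """N × C nonnegative weights, zero at unreported label entries."""

    weights: np.ndarray
    flagged_labels: list[int] = field(default_factory=list)


def compute_instance_weights(labels: np.ndarray) -> InstanceWeightMatrix:
    """Inverse-class-frequency weights in the balanced two-sided form.

    For label c with N_obs reported entries, N_pos positives and N_neg
    negatives: positives weigh N_obs/(2·N_pos) and negatives
    N_obs/(2·N_neg).  One-class labels (N_pos or N_neg zero) get all-zero
    weights and are flagged rather than fatal.
    """
    L = np.asarray(labels, dtype=np.float64)
    N, C = L.shape
    psi = np.zeros((N, C))
    flagged = []
    rep = ~np.isnan(L)
    for c in range(C):
        obs = rep[:, c]
        n_obs = int(obs.sum())
        pos = obs & (L[:, c] == 1.0)
        neg = obs & (L[:, c] == 0.0)
        n_pos, n_neg = int(pos.sum()), int(neg.sum())
        if n_pos == 0 or n_neg == 0:
            flagged.append(c)
            continue
        psi[pos, c] = n_obs / (2.0 * n_pos)
        psi[neg, c] = n_obs / (2.0 * n_neg)
    return InstanceWeightMatrix(psi, flagged)


def weighted_multilabel_loss(
    predictions: np.ndarray, labels: np.ndarray, psi: np.ndarray
) -> float:
    """(1/(N·C)) Σ Ψ[i,c] · BCE(ŷ[i,c], y[i,c]); unreported targets
    contribute exactly zero through their zero weights."""
    P = np.asarray(predictions, dtype=np.float64)
    L = np.asarray(labels, dtype=np.float64)
    psi = np.asarray(psi, dtype=np.float64)
    if P.shape != L.shape or P.shape != psi.shape:
        raise ValueError("shape mismatch between predictions, labels, weights")
    if np.any((P <= 0.0) | (P >= 1.0)):
        raise ValueError("predictions must lie strictly in (0,1)")
    y = np.nan_to_num(L, nan=0.0)
    per = -(y * np.log(P) + (1.0 - y) * np.log1p(-P))
    return float((psi * per).sum() / per.size)


@dataclass
class ContextClassifier:
    """Optional encoder trunk plus a sigmoid-output classification head."""

    head: MLP
    encoder: MLP | None = None
    spec: ClassifierSpec = field(default_factory=ClassifierSpec)
    n_labels: int = 0
    history: list = field(default_factory=list)

    def save(self, path) -> None:
        import json

        arrays = self.head.to_arrays("head")
        if self.encoder is not None:
            arrays.update(self.encoder.to_arrays("enc"))
        meta = {
            "has_encoder": self.encoder is not None,
            "n_labels": self.n_labels,
            "threshold": self.spec.threshold,
            "activation": self.spec.activation,
            "hidden": list(self.spec.hidden),
        }
        arrays["clf_meta"] = np.array([json.dumps(meta, sort_keys=True)])
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "ContextClassifier":
        import json

        with np.load(path, allow_pickle=False) as data:
            arrays = {k: data[k] for k in data.files}
        meta = json.loads(str(arrays["clf_meta"][0]))
        spec = ClassifierSpec(
            hidden=tuple(meta["hidden"]),
            threshold=float(meta["threshold"]),
            activation=meta["activation"],
        )
        encoder = MLP.from_arrays(arrays, "enc") if meta["has_encoder"] else None
        return cls(
            head=MLP.from_arrays(arrays, "head"),
            encoder=encoder,
            spec=spec,
            n_labels=int(meta["n_labels"]),
        )

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if self.encoder is not None:
            z, _ = self.encoder.forward(X, train=False)
            X = z
        s, _ = self.head.forward(X, train=False)
        return s

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return sigmoid(self.decision_scores(X))


def predict_labels(classifier: ContextClassifier, X: np.ndarray) -> np.ndarray:
    """Binary N × C predictions; ties at the threshold go to 1."""
    proba = classifier.predict_proba(X)
    return (proba >= classifier.spec.threshold).astype(np.float64)


def _resolve_train_inputs(train, labels):
    if isinstance(train, MultimodalDataset):
        return train.features, train.labels, train.schema
    return np.asarray(train, dtype=np.float64), np.asarray(labels, dtype=np.float64), None


def _train_weighted(
    encoder: MLP | None,
    head: MLP,
    X: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig,
    spec: ClassifierSpec,
    noise: NoiseConfig | None,
    schema: ModalitySchema | None,
) -> ContextClassifier:
    N, C = labels.shape
    if N == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    n_val = max(1, int(round(cfg.val_fraction * N))) if N > 1 else 0
    perm = rng.permutation(N)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if tr_idx.size == 0:
        tr_idx, val_idx = perm, perm
    Xtr, Ltr = X[tr_idx], labels[tr_idx]
    Xval, Lval = X[val_idx], labels[val_idx]
    if noise is not None:
        # fixed corrupted view of the validation split, so early stopping
        # selects for robustness under the training-time input regime
        val_rng = np.random.default_rng(cfg.seed + 1)
        Xval = corrupt(Xval, schema, noise, val_rng)
    psi_tr = compute_instance_weights(Ltr).weights
    Ytr = np.nan_to_num(Ltr, nan=0.0)

    opt_head = Adam(head, cfg.lr_classification, cfg.weight_decay)
    opt_enc = (
        Adam(encoder, cfg.lr_classification, cfg.weight_decay)
        if encoder is not None
        else None
    )
    clf = ContextClassifier(head=head, encoder=encoder, spec=spec, n_labels=C)

    def val_ba() -> float:
        pred = (clf.predict_proba(Xval) >= spec.threshold).astype(float)
        ba = label_metrics(Lval, pred).macro["balanced_accuracy"]
        return ba if np.isfinite(ba) else 0.0

    best_ba = -np.inf
    best_params = None
    stale = 0
    n_tr = Xtr.shape[0]
    history = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n_tr)
        ep_loss, n_batches = 0.0, 0
        for start in range(0, n_tr, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            x, y, w = Xtr[idx], Ytr[idx], psi_tr[idx]
            xin = corrupt(x, schema, noise, rng) if noise is not None else x
            if encoder is not None:
                z, c_enc = encoder.forward(xin, train=True)
                s, c_head = head.forward(z, train=True)
            else:
                s, c_head = head.forward(xin, train=True)
            loss, d_s = bce_with_logits(s, y, weights=w)
            g_head, d_z = head.backward(d_s, c_head)
            opt_head.step(g_head)
            if encoder is not None:
                g_enc, _ = encoder.backward(d_z, c_enc)
                opt_enc.step(g_enc)
            ep_loss += loss
            n_batches += 1
        ba = val_ba()
        history.append({"epoch": epoch, "train_loss": ep_loss / n_batches,
                        "val_macro_ba": ba})
        if ba > best_ba + 1e-9:
            best_ba = ba
            best_params = (
                head.get_params(),
                encoder.get_params() if encoder is not None else None,
            )
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    if best_params is not None:
        head.set_params(best_params[0])
        if encoder is not None and best_params[1] is not None:
            encoder.set_params(best_params[1])
    clf.history = history
    return clf


def train_extended_classifier(
    base: AAEModel,
    train: MultimodalDataset,
    noise: NoiseConfig | None,
    cfg: TrainConfig,
    spec: ClassifierSpec | None = None,
) -> ContextClassifier:
    """Stack a classification head on (a copy of) the base encoder and
    fine-tune the whole stack on the weighted loss, applying structured
    noise to the inputs each batch when ``noise`` is given."""
    spec = spec or ClassifierSpec()
    X, labels, schema = _resolve_train_inputs(train, None)
    if X.shape[1] != base.n_features:
        raise ValueError("dataset width does not match the base model")
    encoder = copy.deepcopy(base.encoder)
    rng = np.random.default_rng(cfg.seed)
    widths = [base.latent_dim, *spec.hidden, labels.shape[1]]
    head = MLP(widths, rng, hidden_activation=spec.activation,
               out_activation="sigmoid")
    return _train_weighted(encoder, head, X, labels, cfg, spec, noise, schema)


def train_embedding_classifier(
    embeddings: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig,
    spec: ClassifierSpec | None = None,
) -> ContextClassifier:
    """Train the head alone on frozen embeddings (or raw features); the
    encoder that produced the embeddings is untouched."""
    spec = spec or ClassifierSpec()
    X = np.asarray(embeddings, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if X.shape[0] != labels.shape[0]:
        raise ValueError("embeddings and labels are misaligned")
    rng = np.random.default_rng(cfg.seed)
    widths = [X.shape[1], *spec.hidden, labels.shape[1]]
    head = MLP(widths, rng, hidden_activation=spec.activation,
               out_activation="sigmoid")
    return _train_weighted(None, head, X, labels, cfg, spec, None, None)
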