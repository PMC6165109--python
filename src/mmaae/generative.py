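"""Class-conditional synthesis and its evaluation.

Synthetic feature vectors are produced by feeding prior draws z plus a
(real) label vector to the supervised decoder, with heavy stochastic
dropout (rate 0.75 on decoder hidden layers) to diversify samples.
Labels are always copied from real splits, never sampled arbitrarily —
independently sampled multi-labels can describe impossible contexts.

Quality is judged two ways: moment/correlation fidelity against real
data, and the train-on-synthetic/test-on-real (TSTR) and
train-on-real/test-on-synthetic (TRTS) classification protocols, which
share the exact metric code path with real-real evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aae import AAEModel, TrainConfig
from .classifier import ClassifierSpec, predict_labels, train_embedding_classifier
from .data import MultimodalDataset
from .metrics import MetricReport, label_metrics


@dataclass
class SynthesisRequest:
    """Conditioning labels (rows reused from a real split), samples per
    row, sampling-dropout rate on decoder hidden layers, and a seed."""

    labels: np.ndarray
    samples_per_row: int = 1
    dropout: float = 0.75
    seed: int = 0

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.float64)
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("sampling dropout must lie in [0,1)")
        if self.samples_per_row < 1:
            raise ValueError("samples_per_row must be positive")


def sample_synthetic(
    model: AAEModel, req: SynthesisRequest
) -> tuple[np.ndarray, np.ndarray]:
    """Decode prior draws conditioned on the requested labels.

    Returns (features in [0,1]^n, the conditioning labels row-aligned).
    Only labels and prior noise are consumed — never real features.
    """
    if not model.label_conditioned:
        raise ValueError("synthesis requires a label-conditioned model")
    if req.labels.shape[1] != model.n_labels:
        raise ValueError("label width does not match the model")
    rng = np.random.default_rng(req.seed)
    labels = np.repeat(req.labels, req.samples_per_row, axis=0)
    y = np.nan_to_num(labels, nan=0.0)
    z = model.prior.sample(labels.shape[0], rng)
    dec_in = np.concatenate([z, y], axis=1)
    s, _ = model.decoder.forward(
        dec_in, train=req.dropout > 0, rng=rng, hidden_dropout=req.dropout
    )
    return model.decoder.output(s), labels


def binarize_block(X: np.ndarray, cols: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Optionally snap a binary modality's synthetic outputs to {0,1}."""
    out = X.copy()
    out[:, cols] = (out[:, cols] >= threshold).astype(np.float64)
    return out


def _fit_and_score(
    train_X, train_labels, test_X, test_labels, cfg: TrainConfig,
    spec: ClassifierSpec,
) -> MetricReport:
    clf = train_embedding_classifier(train_X, train_labels, cfg, spec)
    pred = predict_labels(clf, test_X)
    return label_metrics(test_labels, pred)


def _unpack(split) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(split, MultimodalDataset):
        return split.features, split.labels
    X, L = split
    return np.asarray(X, dtype=np.float64), np.asarray(L, dtype=np.float64)


def tstr(
    synth_train, real_test, cfg: TrainConfig, spec: ClassifierSpec | None = None
) -> MetricReport:
    """Train a fresh 1-hidden-layer (plain-rectifier) classifier on
    synthetic data, evaluate on real data."""
    spec = spec or ClassifierSpec(activation="relu")
    Xs, Ls = _unpack(synth_train)
    Xr, Lr = _unpack(real_test)
    if Ls.shape[1] != Lr.shape[1]:
        raise ValueError("label spaces of the two splits differ")
    return _fit_and_score(Xs, Ls, Xr, Lr, cfg, spec)


def trts(
    real_train, synth_test, cfg: TrainConfig, spec: ClassifierSpec | None = None
) -> MetricReport:
    """Train on real data, evaluate on synthetic data."""
    spec = spec or ClassifierSpec(activation="relu")
    Xr, Lr = _unpack(real_train)
    Xs, Ls = _unpack(synth_test)
    if Ls.shape[1] != Lr.shape[1]:
        raise ValueError("label spaces of the two splits differ")
    return _fit_and_score(Xr, Lr, Xs, Ls, cfg, spec)


def fidelity_summary(real: np.ndarray, synth: np.ndarray) -> pd.DataFrame:
    """Per-feature discrepancies between real and synthetic marginals:
    |Δmean|, |ΔSD| and the mean absolute difference of each feature's
    pairwise-correlation profile (zero for identical inputs)."""
    R = np.asarray(real, dtype=np.float64)
    S = np.asarray(synth, dtype=np.float64)
    if R.shape[1] != S.shape[1]:
        raise ValueError("real and synthetic feature widths differ")
    mean_r, mean_s = R.mean(axis=0), S.mean(axis=0)
    sd_r, sd_s = R.std(axis=0), S.std(axis=0)

    def _corr(X):
        sd = X.std(axis=0)
        keep = sd > 0
        C = np.zeros((X.shape[1], X.shape[1]))
        if keep.sum() >= 2:
            sub = np.corrcoef(X[:, keep], rowvar=False)
            C[np.ix_(keep, keep)] = sub
        return C

    Cr, Cs = _corr(R), _corr(S)
    n = R.shape[1]
    off = ~np.eye(n, dtype=bool)
    corr_disc = np.abs(Cr - Cs)[off].reshape(n, n - 1).mean(axis=1)
    return pd.DataFrame({
        "feature": np.arange(n),
        "real_mean": mean_r, "synth_mean": mean_s,
        "mean_discrepancy": np.abs(mean_r - mean_s),
        "real_sd": sd_r, "synth_sd": sd_s,
        "sd_discrepancy": np.abs(sd_r - sd_s),
        "corr_discrepancy": corr_disc,
    })
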