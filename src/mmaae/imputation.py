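"""Restoring missing feature blocks.

Methods: the trained denoising AAE (decoder output substituted at
missing positions only), a PCA baseline (project onto the leading
principal components of the clean training data and invert, iterated
to convergence from a training-mean pre-fill), and constant fills
(mean / median / sentinel).  No method ever modifies an observed entry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .aae import AAEModel, decode, encode
from .corruption import drop_modalities
from .data import SENTINEL, MultimodalDataset
from .metrics import rmse


# ---------------------------------------------------------------------------
# AAE imputation


def impute_with_model(
    dataset_norm: MultimodalDataset, model: AAEModel
) -> MultimodalDataset:
    """Replace missing entries with the decoder's reconstruction; observed
    entries are preserved bit-exactly and no sentinel remains."""
    if not model.trained:
        raise ValueError("model must be trained before imputation")
    if dataset_norm.n_features != model.n_features:
        raise ValueError("dataset width does not match the model")
    out = dataset_norm.copy()
    miss = out.missing_mask
    if miss.any():
        z = encode(out.features, model)
        xhat = decode(z, model)
        out.features = np.where(miss, xhat, out.features)
    return out


def impute_features_with_model(X: np.ndarray, model: AAEModel) -> np.ndarray:
    """Array-level variant: sentinel positions replaced by the decoder."""
    X = np.asarray(X, dtype=np.float64)
    miss = X == SENTINEL
    if not miss.any():
        return X.copy()
    xhat = decode(encode(X, model), model)
    return np.where(miss, xhat, X)


# ---------------------------------------------------------------------------
# PCA baseline


@dataclass
class PcaImputer:
    """Principal-component restoration fitted on clean training data.

    In the default ``"single"`` mode, missing entries are initialized at
    the per-feature training means, the vector is projected onto the
    component subspace and inverse-transformed, and the missing positions
    take the inverse-transform values.  The ``"lstsq"`` mode instead
    solves the least-squares subspace completion (the fixpoint of
    iterating project-and-reimpose), which on data lying exactly in the
    component subspace recovers a dropped block exactly.
    """

    pca: PCA
    train_means: np.ndarray
    n_components: int
    mode: str = "single"

    def project_invert(self, X: np.ndarray) -> np.ndarray:
        """Forward-then-inverse transform: the orthogonal projection of
        each (centered) row onto the component subspace."""
        return self.pca.inverse_transform(self.pca.transform(X))


def fit_pca_imputer(
    clean_train: MultimodalDataset | np.ndarray,
    n_components: int = 75,
    mode: str = "single",
) -> PcaImputer:
    X = (
        clean_train.features
        if isinstance(clean_train, MultimodalDataset)
        else np.asarray(clean_train, dtype=np.float64)
    )
    if isinstance(clean_train, MultimodalDataset) and clean_train.missing_mask.any():
        raise ValueError("PCA imputer must be fitted on fully observed data")
    if n_components > X.shape[1]:
        raise ValueError("n_components exceeds the feature count")
    if mode not in ("single", "lstsq"):
        raise ValueError(f"unknown PCA imputation mode {mode!r}")
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    return PcaImputer(pca, X.mean(axis=0), n_components, mode)


def _pca_complete(imputer: PcaImputer, X: np.ndarray, miss: np.ndarray) -> np.ndarray:
    if imputer.mode == "single":
        filled = np.where(miss, imputer.train_means, X)
        recon = imputer.project_invert(filled)
        return np.where(miss, recon, X)
    # least-squares completion, grouped by missingness pattern; component
    # scores are solved in variance-weighted coordinates so directions
    # with (near-)zero explained variance cannot inject spurious signal
    V = imputer.pca.components_  # (k, n)
    mu = imputer.pca.mean_
    w = np.sqrt(np.maximum(imputer.pca.explained_variance_, 0.0))
    out = X.copy()
    patterns = np.unique(miss, axis=0)
    for pat in patterns:
        if not pat.any():
            continue
        rows = np.where((miss == pat).all(axis=1))[0]
        obs = ~pat
        A = V[:, obs].T * w[None, :]  # (n_obs, k), weighted
        R = (X[np.ix_(rows, obs)] - mu[obs]).T  # (n_obs, n_rows)
        B, *_ = np.linalg.lstsq(A, R, rcond=None)  # (k, n_rows)
        C = w[:, None] * B
        out[np.ix_(rows, pat)] = (mu[pat][:, None] + V[:, pat].T @ C).T
    return out


def impute_pca(
    imputer: PcaImputer, dataset_norm: MultimodalDataset
) -> MultimodalDataset:
    out = dataset_norm.copy()
    miss = out.missing_mask
    if miss.any():
        out.features = _pca_complete(imputer, out.features, miss)
    return out


def impute_features_pca(imputer: PcaImputer, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    miss = X == SENTINEL
    if not miss.any():
        return X.copy()
    return _pca_complete(imputer, X, miss)


# ---------------------------------------------------------------------------
# Constant fills


def fit_feature_statistics(
    train: MultimodalDataset | np.ndarray,
) -> dict[str, np.ndarray]:
    """Per-feature mean and median over observed training entries."""
    if isinstance(train, MultimodalDataset):
        X = np.where(train.missing_mask, np.nan, train.features)
    else:
        X = np.asarray(train, dtype=np.float64)
        X = np.where(X == SENTINEL, np.nan, X)
    return {
        "mean": np.nanmean(X, axis=0),
        "median": np.nanmedian(X, axis=0),
    }


def impute_constant(
    dataset_norm: MultimodalDataset,
    strategy: str,
    statistics: dict[str, np.ndarray] | None = None,
) -> MultimodalDataset:
    """Fill missing entries with the training mean, median or the
    sentinel value itself (fill -1)."""
    out = dataset_norm.copy()
    miss = out.missing_mask
    if strategy == "sentinel":
        out.features[miss] = SENTINEL
        return out
    if strategy not in ("mean", "median"):
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    if statistics is None:
        raise ValueError("mean/median fills require training statistics")
    fill = statistics[strategy]
    out.features = np.where(miss, fill, out.features)
    return out


def impute_features_constant(
    X: np.ndarray, strategy: str, statistics: dict[str, np.ndarray] | None = None
) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    miss = X == SENTINEL
    if strategy == "sentinel":
        return X.copy()
    if strategy not in ("mean", "median"):
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    if statistics is None:
        raise ValueError("mean/median fills require training statistics")
    return np.where(miss, statistics[strategy], X)


# ---------------------------------------------------------------------------
# Drop-and-restore protocol


def restore_modality(
    clean_test: MultimodalDataset | np.ndarray,
    modality: str,
    method,
) -> tuple[np.ndarray, float]:
    """Drop the named modality from fully-observed data, restore it with
    ``method`` (a callable on the sentineled matrix, or the string
    "identity"), and report RMSE over the dropped block only."""
    if isinstance(clean_test, MultimodalDataset):
        if clean_test.missing_mask.any():
            raise ValueError("drop-and-restore requires fully observed data")
        X = clean_test.features
        schema = clean_test.schema
    else:
        raise ValueError("restore_modality requires a MultimodalDataset")
    dropped = drop_modalities(X, schema, [modality])
    if method == "identity":
        restored = X.copy()
    elif callable(method):
        restored = method(dropped)
    else:
        raise ValueError(f"unknown restoration method {method!r}")
    block = np.zeros_like(dropped, dtype=bool)
    block[:, schema.block(modality)] = True
    return restored, rmse(X, restored, block)


def build_combined_training_set(
    clean: MultimodalDataset, noisy_imputed: MultimodalDataset
) -> MultimodalDataset:
    """Row-concatenate the clean split with the imputed noisy split,
    preserving user ids and labels."""
    if clean.schema != noisy_imputed.schema:
        raise ValueError("schema mismatch between clean and imputed parts")
    if np.any(noisy_imputed.features == SENTINEL):
        raise ValueError("imputed part still contains sentinel values")
    if noisy_imputed.n_instances == 0:
        return clean.copy()
    return MultimodalDataset(
        np.concatenate([clean.features, noisy_imputed.features]),
        np.zeros(
            (clean.n_instances + noisy_imputed.n_instances, clean.n_features),
            dtype=bool,
        ),
        np.concatenate([clean.labels, noisy_imputed.labels]),
        np.concatenate([clean.user_ids, noisy_imputed.user_ids]),
        clean.schema,
        list(clean.label_names),
        normalized=clean.normalized,
    )
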