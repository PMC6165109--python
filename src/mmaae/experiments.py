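"""End-to-end experiment protocols.

All protocols are train/test honest: normalizers, imputers, weight
matrices, autoencoders and classifiers are fitted on the training users
of the active fold only, and evaluated on held-out users.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aae import AAEModel, TrainConfig, encode, train_reconstruction_model, \
    train_synthesis_model
from .classifier import (
    ClassifierSpec,
    ContextClassifier,
    predict_labels,
    train_extended_classifier,
)
from .corruption import NoiseConfig, drop_modalities
from .data import (
    FoldPlan,
    MultimodalDataset,
    apply_normalizer,
    fit_normalizer,
    split_clean_noisy,
)
from .generative import SynthesisRequest, sample_synthetic, trts, tstr
from .imputation import (
    build_combined_training_set,
    fit_feature_statistics,
    fit_pca_imputer,
    impute_features_constant,
    impute_features_pca,
    impute_features_with_model,
    impute_with_model,
)
from .metrics import MetricReport, aggregate_reports, label_metrics

#: Missing-modality scenario grid: each single modality plus the
#: multi-modality combinations of interest.
DEFAULT_SCENARIOS: dict[str, tuple[str, ...]] = {
    "Acc": ("Acc",),
    "Gyro": ("Gyro",),
    "WAcc": ("WAcc",),
    "Loc": ("Loc",),
    "Aud": ("Aud",),
    "PS": ("PS",),
    "Acc+Gyro+Aud": ("Acc", "Gyro", "Aud"),
    "Gyro+WAcc+Loc+Aud": ("Gyro", "WAcc", "Loc", "Aud"),
    "WAcc+Loc+Aud": ("WAcc", "Loc", "Aud"),
    "WAcc+Loc": ("WAcc", "Loc"),
}

DEFAULT_METHODS = ("aae", "pca", "mean", "median", "fill")


@dataclass
class PipelineConfig:
    """Shared configuration of the full train/evaluate pipeline."""

    noise: NoiseConfig = field(default_factory=NoiseConfig)
    recon_cfg: TrainConfig = field(
        default_factory=TrainConfig.reconstruction_defaults
    )
    clf_cfg: TrainConfig = field(
        default_factory=TrainConfig.reconstruction_defaults
    )
    synth_cfg: TrainConfig = field(default_factory=TrainConfig.synthesis_defaults)
    classifier_spec: ClassifierSpec = field(default_factory=ClassifierSpec)
    pca_components: int = 75


@dataclass
class FoldArtifacts:
    """Everything fitted on one fold's training users."""

    normalizer: object
    model: AAEModel
    combined: MultimodalDataset
    classifiers: dict[str, ContextClassifier]
    statistics: dict[str, np.ndarray]
    pca_imputer: object
    test_norm: MultimodalDataset


def _check_no_leakage(train: MultimodalDataset, test: MultimodalDataset) -> None:
    shared = np.intersect1d(np.unique(train.user_ids), np.unique(test.user_ids))
    if shared.size:
        raise RuntimeError(f"leakage guard tripped: shared users {shared!r}")


def fit_fold(
    dataset: MultimodalDataset,
    train_users,
    test_users,
    cfg: PipelineConfig,
    methods=("aae",),
) -> FoldArtifacts:
    """Fit the pipeline on one fold: normalizer → clean/noisy split →
    reconstruction AAE → imputation of the noisy part → combined set →
    one classifier per requested method."""
    train = dataset.subset_users(train_users)
    test = dataset.subset_users(test_users)
    _check_no_leakage(train, test)

    norm = fit_normalizer(train)
    train_n = apply_normalizer(train, norm)
    test_n = apply_normalizer(test, norm)
    clean, noisy = split_clean_noisy(train_n)

    model = train_reconstruction_model(clean, cfg.noise, cfg.recon_cfg)
    stats = fit_feature_statistics(clean)
    n_comp = min(cfg.pca_components, clean.n_features, clean.n_instances)
    pca_imp = fit_pca_imputer(clean, n_components=n_comp)

    classifiers: dict[str, ContextClassifier] = {}
    combined_aae = None
    for method in methods:
        if method == "aae":
            noisy_imp = impute_with_model(noisy, model)
            combined = build_combined_training_set(clean, noisy_imp)
            combined_aae = combined
            clf = train_extended_classifier(
                model, combined, cfg.noise, cfg.clf_cfg, cfg.classifier_spec
            )
        elif method == "fill":
            # the sentinel IS the imputation: keep -1 in the features
            combined = _combine_fill(clean, noisy)
            clf = train_extended_classifier(
                _fresh_base(model, cfg), combined, None, cfg.clf_cfg,
                cfg.classifier_spec,
            )
        else:
            noisy_imp = _impute_dataset(noisy, method, stats, pca_imp, model)
            combined = build_combined_training_set(clean, noisy_imp)
            # baseline: same trunk+head capacity trained from scratch,
            # no corruption noise (the method handles missingness instead)
            clf = train_extended_classifier(
                _fresh_base(model, cfg), combined, None, cfg.clf_cfg,
                cfg.classifier_spec,
            )
        classifiers[method] = clf
    return FoldArtifacts(
        norm, model, combined_aae if combined_aae is not None else clean,
        classifiers, stats, pca_imp, test_n,
    )


def _fresh_base(model: AAEModel, cfg: PipelineConfig) -> AAEModel:
    from .aae import build_reconstruction_model

    rng = np.random.default_rng(cfg.clf_cfg.seed + 17)
    fresh = build_reconstruction_model(model.n_features, rng,
                                       latent_dim=model.latent_dim)
    fresh.trained = True
    return fresh


def _impute_dataset(ds, method, stats, pca_imp, model):
    from .imputation import impute_constant, impute_pca

    if method in ("mean", "median"):
        return impute_constant(ds, method, stats)
    if method == "pca":
        return impute_pca(pca_imp, ds)
    if method == "aae":
        return impute_with_model(ds, model)
    raise ValueError(f"unknown method {method!r}")


def _combine_fill(clean: MultimodalDataset, noisy: MultimodalDataset):
    out_feats = np.concatenate([clean.features, noisy.features])
    return MultimodalDataset(
        out_feats,
        np.zeros_like(out_feats, dtype=bool),
        np.concatenate([clean.labels, noisy.labels]),
        np.concatenate([clean.user_ids, noisy.user_ids]),
        clean.schema,
        list(clean.label_names),
        normalized=True,
    )


def evaluate_fold_scenario(
    art: FoldArtifacts,
    drop: tuple[str, ...],
    method: str,
) -> MetricReport:
    """Sentinel the scenario's modalities on the test features, handle
    them with the method, classify, and score."""
    test = art.test_norm
    X = drop_modalities(test.features, test.schema, drop) if drop else test.features.copy()
    if method == "aae":
        pass  # extended classifier consumes sentineled input directly
    elif method == "fill":
        pass  # sentinel is the imputation
    elif method in ("mean", "median"):
        X = impute_features_constant(X, method, art.statistics)
    elif method == "pca":
        X = impute_features_pca(art.pca_imputer, X)
    else:
        raise ValueError(f"unknown method {method!r}")
    clf = art.classifiers[method]
    pred = predict_labels(clf, X)
    return label_metrics(test.labels, pred, test.label_names)


def run_cv(
    dataset: MultimodalDataset,
    plan: FoldPlan,
    cfg: PipelineConfig,
    method: str = "aae",
) -> MetricReport:
    """User-grouped cross-validation of the full pipeline; the aggregate
    macro metrics are means ± SD across folds."""
    reports = []
    for train_users, test_users in plan:
        art = fit_fold(dataset, train_users, test_users, cfg, methods=(method,))
        reports.append(evaluate_fold_scenario(art, (), method))
    return aggregate_reports(reports)


def run_missing_scenarios(
    dataset: MultimodalDataset,
    plan: FoldPlan,
    cfg: PipelineConfig,
    scenarios: dict[str, tuple[str, ...]] | None = None,
    methods=DEFAULT_METHODS,
    folds: list[int] | None = None,
) -> pd.DataFrame:
    """Scenario × method grid of macro metrics (mean ± SD over folds)."""
    scenarios = scenarios or DEFAULT_SCENARIOS
    for name, drop in scenarios.items():
        for mod in drop:
            if mod not in dataset.schema.names:
                raise ValueError(f"unknown modality {mod!r} in scenario {name!r}")
    fold_ids = folds if folds is not None else list(range(plan.k))
    rows = []
    for fi in fold_ids:
        train_users, test_users = plan[fi]
        art = fit_fold(dataset, train_users, test_users, cfg, methods=methods)
        for sname, drop in scenarios.items():
            for method in methods:
                rep = evaluate_fold_scenario(art, drop, method)
                rows.append({
                    "fold": fi, "scenario": sname, "method": method,
                    **{k: rep.macro[k] for k in (
                        "balanced_accuracy", "sensitivity",
                        "specificity", "accuracy",
                    )},
                })
    raw = pd.DataFrame(rows)
    agg = (
        raw.groupby(["scenario", "method"], sort=False)
        .agg(
            balanced_accuracy=("balanced_accuracy", "mean"),
            balanced_accuracy_sd=("balanced_accuracy", "std"),
            sensitivity=("sensitivity", "mean"),
            specificity=("specificity", "mean"),
            accuracy=("accuracy", "mean"),
            n_folds=("fold", "count"),
        )
        .reset_index()
    )
    return agg


def run_tstr_experiment(
    dataset: MultimodalDataset,
    plan: FoldPlan,
    cfg: PipelineConfig,
    fold: int = 0,
    include_null: bool = False,
) -> pd.DataFrame:
    """Real / TSTR / TRTS comparison on one fold's clean splits.

    The synthesis model is trained on the clean training users; synthetic
    training data reuses the real training labels, synthetic test data
    the real test labels.  ``include_null`` adds a label-ignoring control
    generator (prior noise decoded with all-zero labels).
    """
    train_users, test_users = plan[fold]
    train = dataset.subset_users(train_users)
    test = dataset.subset_users(test_users)
    _check_no_leakage(train, test)
    norm = fit_normalizer(train)
    clean_train, _ = split_clean_noisy(apply_normalizer(train, norm))
    clean_test, _ = split_clean_noisy(apply_normalizer(test, norm))

    model = train_synthesis_model(clean_train, cfg=cfg.synth_cfg)
    seed = cfg.synth_cfg.seed
    Xs_tr, Ls_tr = sample_synthetic(
        model, SynthesisRequest(clean_train.labels, seed=seed + 101)
    )
    Xs_te, Ls_te = sample_synthetic(
        model, SynthesisRequest(clean_test.labels, seed=seed + 202)
    )
    spec = ClassifierSpec(activation="relu")
    clf_cfg = cfg.clf_cfg

    real = tstr((clean_train.features, clean_train.labels),
                (clean_test.features, clean_test.labels), clf_cfg, spec)
    rep_tstr = tstr((Xs_tr, Ls_tr), (clean_test.features, clean_test.labels),
                    clf_cfg, spec)
    rep_trts = trts((clean_train.features, clean_train.labels),
                    (Xs_te, Ls_te), clf_cfg, spec)
    rows = [
        {"protocol": "Real", **_macro_row(real)},
        {"protocol": "TSTR", **_macro_row(rep_tstr)},
        {"protocol": "TRTS", **_macro_row(rep_trts)},
    ]
    if include_null:
        zero_labels = np.zeros_like(clean_train.labels)
        Xn, _ = sample_synthetic(
            model, SynthesisRequest(zero_labels, seed=seed + 303)
        )
        rep_null = tstr((Xn, clean_train.labels),
                        (clean_test.features, clean_test.labels), clf_cfg, spec)
        rows.append({"protocol": "TSTR-null", **_macro_row(rep_null)})
    return pd.DataFrame(rows)


def _macro_row(rep: MetricReport) -> dict:
    return {k: rep.macro[k] for k in (
        "balanced_accuracy", "sensitivity", "specificity", "accuracy",
    )}


def latent_moments(model: AAEModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-dimension mean and SD of the latent codes of X."""
    z = encode(X, model)
    return z.mean(axis=0), z.std(axis=0)
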