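"""Shared fixtures.

The heavyweight fixtures (benchmark dataset, trained models, fold
artifacts) are session-scoped and shared between the unit suite and the
acceptance suite so each model is trained exactly once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from mmaae import (
    GeneratorConfig,
    NoiseConfig,
    generate_dataset,
    make_user_folds,
)
from mmaae.aae import TrainConfig
from mmaae.experiments import PipelineConfig, fit_fold, run_tstr_experiment

#: Benchmark study conditions: a reduced-size draw of the default
#: population (the full default is 60 users / ~20,000 instances).
BENCHMARK_CONFIG = dict(n_users=30, instances_per_user=(160, 220), seed=11)


@pytest.fixture(scope="session")
def benchmark():
    """Seeded benchmark dataset with ground truth."""
    dataset, truth = generate_dataset(GeneratorConfig(**BENCHMARK_CONFIG))
    return dataset, truth


@pytest.fixture(scope="session")
def fold_plan(benchmark):
    dataset, _ = benchmark
    return make_user_folds(dataset.user_ids, k=5, rng=np.random.default_rng(0))


@pytest.fixture(scope="session")
def pipeline_config():
    cfg = PipelineConfig()
    cfg.recon_cfg = TrainConfig.reconstruction_defaults(seed=1)
    cfg.clf_cfg = TrainConfig.reconstruction_defaults(seed=2)
    cfg.synth_cfg = TrainConfig.synthesis_defaults(seed=3)
    return cfg


@pytest.fixture(scope="session")
def fold_artifacts(benchmark, fold_plan, pipeline_config):
    """Pipeline fitted on fold 0 of the benchmark with the AAE and the
    PCA / fill(-1) baselines."""
    dataset, _ = benchmark
    train_users, test_users = fold_plan[0]
    return fit_fold(
        dataset, train_users, test_users, pipeline_config,
        methods=("aae", "pca", "fill"),
    )


@pytest.fixture(scope="session")
def nonadversarial_model(benchmark, fold_plan, pipeline_config):
    """Identically seeded reconstruction run with adversarial phases
    disabled (plain denoising autoencoder)."""
    from mmaae import (
        apply_normalizer,
        fit_normalizer,
        split_clean_noisy,
        train_reconstruction_model,
    )

    dataset, _ = benchmark
    train_users, _ = fold_plan[0]
    train = dataset.subset_users(train_users)
    norm = fit_normalizer(train)
    clean, _ = split_clean_noisy(apply_normalizer(train, norm))
    cfg = TrainConfig.reconstruction_defaults(seed=1, adversarial=False)
    return train_reconstruction_model(clean, NoiseConfig(), cfg)


@pytest.fixture(scope="session")
def tstr_table(benchmark, fold_plan, pipeline_config):
    dataset, _ = benchmark
    return run_tstr_experiment(
        dataset, fold_plan, pipeline_config, fold=0, include_null=True
    )


@pytest.fixture()
def tiny_dataset():
    """Small dataset for cheap unit tests (8 users, 8 labels)."""
    cfg = GeneratorConfig(
        n_users=8, instances_per_user=(40, 60), n_labels=8, seed=2
    )
    return generate_dataset(cfg)
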