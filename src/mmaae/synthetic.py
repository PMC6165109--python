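"""Seeded synthetic multimodal datasets.

Emulates the statistical structure of in-the-wild smartphone/smartwatch
context-recognition feature sets: six modality blocks whose continuous
features are cross-modally correlated (all driven by shared latent
factors), one binary phone-state-like block, sparse imbalanced
multi-labels drawn from a logistic model on the same factors,
user-grouped structure, and block-wise missingness with roughly half
of the instances fully clean.

Each modality is a fixed (seed-determined) nonlinear map of the mixed
user/instance factors — a random projection through a tanh hidden layer,
squashed into [0,1] — so that linear reconstruction (PCA) is beatable by
a nonlinear model, while a least-squares predictor of one modality from
the others still finds signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .data import (
    DEFAULT_N_LABELS,
    ModalitySchema,
    MultimodalDataset,
    default_label_names,
)

_HIDDEN_DIM = 10  # width of each modality's random hidden projection


def _sigmoid(x):
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class GeneratorConfig:
    """Conditions of the synthetic benchmark.

    Defaults mirror the study population the method targets: 60 users,
    ~20,000 instances, the 166-feature six-modality layout, 51 sparse
    imbalanced labels, and per-modality block loss calibrated so the
    overall fully-clean fraction is 0.5.
    """

    n_users: int = 60
    instances_per_user: tuple[int, int] = (240, 420)
    schema: ModalitySchema = field(default_factory=ModalitySchema)
    n_labels: int = DEFAULT_N_LABELS
    factor_dim: int = 12
    user_factor_weight: float = 0.5
    label_prevalence: np.ndarray | float | None = None
    label_signal: float = 2.5
    label_missing_rate: float = 0.3
    modality_missing_rates: dict[str, float] | None = None
    user_nonwear_rate: float = 0.1
    nonlinearity: float = 1.0
    noise_sd: float = 0.15
    binary_modality: str | None = "PS"
    watch_modality: str | None = "WAcc"
    seed: int = 0

    def __post_init__(self):
        if self.n_users <= 0 or self.n_labels <= 0 or self.factor_dim <= 0:
            raise ValueError("counts must be positive")
        lo, hi = self.instances_per_user
        if lo <= 0 or hi < lo:
            raise ValueError("instances_per_user must be a positive range")
        for p in (
            self.user_factor_weight,
            self.label_missing_rate,
            self.user_nonwear_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0,1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        prev = self.resolved_prevalence()
        if np.any(prev <= 0.0) or np.any(prev >= 1.0):
            raise ValueError("label prevalence must lie strictly in (0,1)")
        rates = self.resolved_missing_rates()
        for name, r in rates.items():
            if name not in self.schema.names:
                raise ValueError(f"unknown modality in missing rates: {name!r}")
            if not 0.0 <= r <= 1.0:
                raise ValueError("modality missing rates must lie in [0,1]")
        if self.binary_modality is not None and self.binary_modality not in self.schema.names:
            raise ValueError(f"unknown binary modality {self.binary_modality!r}")

    def resolved_prevalence(self) -> np.ndarray:
        if self.label_prevalence is None:
            # imbalanced sparse labels: log-spaced positive rates 2%..30%
            return np.geomspace(0.02, 0.30, self.n_labels)
        prev = np.asarray(self.label_prevalence, dtype=np.float64)
        if prev.ndim == 0:
            prev = np.full(self.n_labels, float(prev))
        if prev.shape != (self.n_labels,):
            raise ValueError("label_prevalence must be scalar or length n_labels")
        return prev

    def resolved_missing_rates(self) -> dict[str, float]:
        if self.modality_missing_rates is None:
            return calibrate_missing_rates(
                self.schema, target_clean_fraction=0.5,
                user_nonwear_rate=self.user_nonwear_rate,
            )
        return dict(self.modality_missing_rates)

    def to_mapping(self) -> dict:
        rates = self.resolved_missing_rates()
        return {
            "n_users": self.n_users,
            "instances_per_user_min": self.instances_per_user[0],
            "instances_per_user_max": self.instances_per_user[1],
            "schema": self.schema.to_string(),
            "n_labels": self.n_labels,
            "factor_dim": self.factor_dim,
            "user_factor_weight": self.user_factor_weight,
            "label_prevalence": self.resolved_prevalence().tolist(),
            "label_signal": self.label_signal,
            "label_missing_rate": self.label_missing_rate,
            "modality_missing_rates": {k: float(v) for k, v in rates.items()},
            "user_nonwear_rate": self.user_nonwear_rate,
            "nonlinearity": self.nonlinearity,
            "noise_sd": self.noise_sd,
            "binary_modality": self.binary_modality,
            "watch_modality": self.watch_modality,
            "seed": self.seed,
        }

    @classmethod
    def from_mapping(cls, m: dict) -> "GeneratorConfig":
        m = dict(m)
        kwargs = {}
        if "schema" in m:
            kwargs["schema"] = ModalitySchema.from_string(m.pop("schema"))
        lo = m.pop("instances_per_user_min", None)
        hi = m.pop("instances_per_user_max", None)
        if lo is not None:
            kwargs["instances_per_user"] = (int(lo), int(hi))
        prev = m.pop("label_prevalence", None)
        if prev is not None:
            kwargs["label_prevalence"] = np.asarray(prev, dtype=float)
        for key in (
            "n_users", "n_labels", "factor_dim", "seed",
        ):
            if key in m:
                kwargs[key] = int(m.pop(key))
        for key in (
            "user_factor_weight", "label_signal", "label_missing_rate",
            "user_nonwear_rate", "nonlinearity", "noise_sd",
        ):
            if key in m:
                kwargs[key] = float(m.pop(key))
        for key in ("binary_modality", "watch_modality"):
            if key in m:
                kwargs[key] = m.pop(key)
        if "modality_missing_rates" in m:
            kwargs["modality_missing_rates"] = {
                k: float(v) for k, v in m.pop("modality_missing_rates").items()
            }
        if m:
            raise ValueError(f"unknown generator config keys: {sorted(m)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})


@dataclass
class GroundTruth:
    """Pre-missingness state of a generated dataset."""

    factors: np.ndarray
    clean_features: np.ndarray
    label_logits: np.ndarray


#: Relative propensity of each modality to go missing.  Watch features
#: disappear with non-wear and location features when the location
#: service is switched off; phone-internal sensors are lost only through
#: occasional malfunction.
DEFAULT_MISSING_PROPENSITY: dict[str, float] = {
    "Acc": 1.0,
    "Gyro": 1.0,
    "Aud": 1.0,
    "PS": 1.0,
    "Loc": 14.0,
    "WAcc": 8.0,
}


def calibrate_missing_rates(
    schema: ModalitySchema,
    target_clean_fraction: float = 0.5,
    user_nonwear_rate: float = 0.0,
    watch_modality: str | None = "WAcc",
    propensity: dict[str, float] | None = None,
) -> dict[str, float]:
    """Per-modality block-loss rates proportional to each modality's
    missing propensity, scaled so the overall fully-clean instance
    fraction equals ``target_clean_fraction`` (accounting for whole-user
    watch non-wear).  Unequal default propensities concentrate the loss
    on the watch and location blocks, mirroring the dominant real-world
    causes (non-wear, location service off)."""
    if not 0.0 < target_clean_fraction < 1.0:
        raise ValueError("target_clean_fraction must lie in (0,1)")
    wear = 1.0 - user_nonwear_rate
    if watch_modality is None or watch_modality not in schema.names:
        wear = 1.0
    if target_clean_fraction >= wear:
        raise ValueError("target clean fraction unreachable under non-wear rate")
    if propensity is None:
        if set(schema.names) == set(DEFAULT_MISSING_PROPENSITY):
            propensity = DEFAULT_MISSING_PROPENSITY
        else:
            propensity = {name: 1.0 for name in schema.names}
    prop = np.array([propensity.get(name, 1.0) for name in schema.names])
    target = target_clean_fraction / wear

    def clean_given(scale: float) -> float:
        rates = np.clip(scale * prop, 0.0, 0.999)
        return float(np.prod(1.0 - rates))

    lo, hi = 0.0, 1.0 / prop.max()
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if clean_given(mid) > target:
            lo = mid
        else:
            hi = mid
    scale = 0.5 * (lo + hi)
    return {
        name: float(np.clip(scale * p, 0.0, 0.999))
        for name, p in zip(schema.names, prop)
    }


def _calibrate_intercept(scores: np.ndarray, prevalence: float) -> float:
    """Intercept b such that mean(sigmoid(scores + b)) == prevalence."""
    lo, hi = -40.0, 40.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _sigmoid(scores + mid).mean() < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[MultimodalDataset, GroundTruth]:
    """Draw a seeded dataset and its pre-missingness ground truth.

    Per instance a user-level and an instance-level factor vector are
    mixed; each modality is a fixed nonlinear map of the mixed factors
    plus noise, squashed into [0,1]; the phone-state-like block is
    thresholded to {0,1}; labels come from a logistic model on the
    factors with intercepts calibrated to the target prevalences; label
    entries are hidden completely at random; whole modality blocks are
    hidden per modality and per non-wearing user.
    """
    rng = np.random.default_rng(config.seed)
    schema = config.schema
    f = config.factor_dim

    counts = rng.integers(
        config.instances_per_user[0], config.instances_per_user[1] + 1,
        size=config.n_users,
    )
    m = int(counts.sum())
    user_index = np.repeat(np.arange(config.n_users), counts)
    user_ids = np.array([f"u{int(u):03d}" for u in user_index])

    # mixed factors with unit marginal variance
    w = config.user_factor_weight
    U = rng.standard_normal((config.n_users, f))
    E = rng.standard_normal((m, f))
    F = np.sqrt(w) * U[user_index] + np.sqrt(1.0 - w) * E

    # modality maps: factors -> tanh hidden -> linear -> sigmoid squash;
    # nonlinearity=0 switches to a purely affine map into [0,1] (for
    # studying linear-structure baselines)
    X = np.empty((m, schema.n_features))
    alpha = config.nonlinearity
    for name, count in schema.modalities:
        A = rng.standard_normal((f, _HIDDEN_DIM)) / np.sqrt(f)
        B = rng.standard_normal((_HIDDEN_DIM, count))
        bias = 0.5 * rng.standard_normal(count)
        noise = config.noise_sd * rng.standard_normal((m, count))
        if alpha == 0.0:
            M = A @ B  # factors -> features, affine
            col_sd = np.sqrt((M**2).sum(axis=0) + config.noise_sd**2)
            raw = F @ M + noise
            block = np.clip(0.5 + raw / (8.0 * col_sd), 0.0, 1.0)
        else:
            hidden = np.tanh(1.5 * alpha * (F @ A))
            raw = hidden @ B + bias + noise
            block = _sigmoid(2.0 * raw)
        if name == config.binary_modality:
            block = (block >= 0.5).astype(np.float64)
        X[:, schema.block(name)] = block

    # labels: logistic on factors, prevalence-calibrated intercepts
    prev = config.resolved_prevalence()
    Wlab = rng.standard_normal((f, config.n_labels))
    Wlab /= np.linalg.norm(Wlab, axis=0, keepdims=True)
    Wlab *= config.label_signal
    scores = F @ Wlab
    logits = np.empty_like(scores)
    for c in range(config.n_labels):
        logits[:, c] = scores[:, c] + _calibrate_intercept(scores[:, c], prev[c])
    labels = (rng.random((m, config.n_labels)) < _sigmoid(logits)).astype(np.float64)
    if config.label_missing_rate > 0:
        hide = rng.random(labels.shape) < config.label_missing_rate
        labels[hide] = np.nan

    # block-wise missingness
    mask = np.zeros((m, schema.n_features), dtype=bool)
    rates = config.resolved_missing_rates()
    for name in schema.names:
        r = rates.get(name, 0.0)
        if r > 0:
            hit = rng.random(m) < r
            mask[np.ix_(hit, schema.columns(name))] = True
    if (
        config.watch_modality is not None
        and config.watch_modality in schema.names
        and config.user_nonwear_rate > 0
    ):
        nonwear = rng.random(config.n_users) < config.user_nonwear_rate
        hit = nonwear[user_index]
        mask[np.ix_(hit, schema.columns(config.watch_modality))] = True

    feats = X.copy()
    feats[mask] = np.nan
    dataset = MultimodalDataset(
        feats, mask, labels, user_ids, schema,
        default_label_names(config.n_labels),
    )
    truth = GroundTruth(factors=F, clean_features=X, label_logits=logits)
    return dataset, truth


def inject_modality_missingness(
    dataset: MultimodalDataset,
    rates: dict[str, float],
    rng: np.random.Generator,
) -> MultimodalDataset:
    """Hide whole modality blocks per instance with the given per-modality
    probabilities; existing missingness is preserved."""
    for name in rates:
        if name not in dataset.schema.names:
            raise ValueError(f"unknown modality name {name!r}")
    out = dataset.copy()
    m = out.n_instances
    for name in dataset.schema.names:  # schema order for determinism
        r = rates.get(name, 0.0)
        if r <= 0:
            continue
        hit = rng.random(m) < r
        cols = dataset.schema.columns(name)
        out.missing_mask[np.ix_(hit, cols)] = True
    fill = -1.0 if out.normalized else np.nan
    out.features[out.missing_mask] = fill
    return out


@dataclass
class DatasetSummary:
    modality_missing_rate: dict[str, float]
    label_prevalence: dict[str, float]
    labels_without_observations: list[str]
    clean_fraction: float
    instances_per_user: dict[str, int]

    def to_frame(self):
        import pandas as pd

        rows = [
            {"quantity": f"missing_rate[{k}]", "value": v}
            for k, v in self.modality_missing_rate.items()
        ]
        rows.append({"quantity": "clean_fraction", "value": self.clean_fraction})
        return pd.DataFrame(rows)


def summarize_dataset(dataset: MultimodalDataset) -> DatasetSummary:
    """Per-modality missing rates, observed label prevalences (labels with
    no observations flagged rather than reported as 0), clean-instance
    fraction and per-user counts."""
    mod_rates = {}
    for name in dataset.schema.names:
        block = dataset.missing_mask[:, dataset.schema.block(name)]
        mod_rates[name] = float(block.mean())
    prevalence = {}
    no_obs = []
    rep = dataset.label_mask
    for c, name in enumerate(dataset.label_names):
        n_obs = int(rep[:, c].sum())
        if n_obs == 0:
            no_obs.append(name)
            prevalence[name] = float("nan")
        else:
            prevalence[name] = float(np.nanmean(dataset.labels[:, c]))
    clean = float((~dataset.missing_mask.any(axis=1)).mean())
    users, counts = np.unique(dataset.user_ids, return_counts=True)
    per_user = {str(u): int(c) for u, c in zip(users, counts)}
    return DatasetSummary(mod_rates, prevalence, no_obs, clean, per_user)
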