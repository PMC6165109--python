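"""Data model for multimodal context-recognition datasets.

A dataset is a feature matrix partitioned into named modality blocks
(features extracted from one sensor, which go missing as a unit), a
boolean missingness mask, a sparse ternary multi-label matrix
(positive / negative / unreported), and per-instance user identifiers.

Normalization follows the min-max-to-[0,1] convention with a sentinel
value (-1) substituted at missing positions; the mask is authoritative
and the sentinel is a derived encoding.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Default modality layout: 166 features from six phone/watch sensors.
DEFAULT_MODALITIES: tuple[tuple[str, int], ...] = (
    ("Acc", 26),
    ("Gyro", 26),
    ("WAcc", 46),
    ("Loc", 6),
    ("Aud", 28),
    ("PS", 34),
)

SENTINEL = -1.0
DEFAULT_N_LABELS = 51


@dataclass(frozen=True)
class ModalitySchema:
    """Ordered mapping of modality names to contiguous feature-column blocks."""

    modalities: tuple[tuple[str, int], ...] = DEFAULT_MODALITIES

    def __post_init__(self):
        if len(self.modalities) == 0:
            raise ValueError("schema must contain at least one modality")
        seen = set()
        for name, count in self.modalities:
            if count <= 0:
                raise ValueError(f"modality {name!r} has non-positive feature count")
            if name in seen:
                raise ValueError(f"duplicate modality name {name!r}")
            seen.add(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.modalities)

    @property
    def n_features(self) -> int:
        return sum(count for _, count in self.modalities)

    @property
    def n_modalities(self) -> int:
        return len(self.modalities)

    def block(self, name: str) -> slice:
        """Column slice of modality ``name``."""
        start = 0
        for mod, count in self.modalities:
            if mod == name:
                return slice(start, start + count)
            start += count
        raise KeyError(f"unknown modality {name!r}")

    def columns(self, name: str) -> np.ndarray:
        sl = self.block(name)
        return np.arange(sl.start, sl.stop)

    def feature_count(self, name: str) -> int:
        sl = self.block(name)
        return sl.stop - sl.start

    def feature_names(self) -> list[str]:
        out = []
        for name, count in self.modalities:
            out.extend(f"{name}:{i}" for i in range(count))
        return out

    def to_string(self) -> str:
        return ",".join(f"{n}:{c}" for n, c in self.modalities)

    @classmethod
    def from_string(cls, text: str) -> "ModalitySchema":
        mods = []
        for part in text.split(","):
            name, count = part.split(":")
            mods.append((name.strip(), int(count)))
        return cls(tuple(mods))


def default_label_names(n_labels: int) -> list[str]:
    return [f"ctx_{i:02d}" for i in range(n_labels)]


@dataclass
class MultimodalDataset:
    """Feature matrix + missingness mask + ternary labels + user ids + schema.

    ``labels`` is a float matrix with entries 1.0 (positive), 0.0
    (negative) and NaN (unreported).  ``features`` at missing positions
    hold NaN on raw data and the sentinel (-1) once normalized.
    """

    features: np.ndarray
    missing_mask: np.ndarray
    labels: np.ndarray
    user_ids: np.ndarray
    schema: ModalitySchema
    label_names: list[str] = field(default_factory=list)
    normalized: bool = False

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.labels = np.asarray(self.labels, dtype=np.float64)
        self.user_ids = np.asarray(self.user_ids)
        m, n = self.features.shape
        if self.missing_mask.shape != (m, n):
            raise ValueError("missing_mask shape does not match features")
        if self.labels.shape[0] != m:
            raise ValueError("labels row count does not match features")
        if self.user_ids.shape[0] != m:
            raise ValueError("user_ids length does not match features")
        if n != self.schema.n_features:
            raise ValueError(
                f"schema expects {self.schema.n_features} features, got {n}"
            )
        if not self.label_names:
            self.label_names = default_label_names(self.labels.shape[1])
        elif len(self.label_names) != self.labels.shape[1]:
            raise ValueError("label_names length does not match label columns")

    @property
    def n_instances(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_labels(self) -> int:
        return self.labels.shape[1]

    @property
    def label_mask(self) -> np.ndarray:
        """Boolean mask of reported label entries."""
        return ~np.isnan(self.labels)

    def copy(self) -> "MultimodalDataset":
        return MultimodalDataset(
            self.features.copy(),
            self.missing_mask.copy(),
            self.labels.copy(),
            self.user_ids.copy(),
            self.schema,
            list(self.label_names),
            self.normalized,
        )

    def subset(self, index: np.ndarray) -> "MultimodalDataset":
        return MultimodalDataset(
            self.features[index],
            self.missing_mask[index],
            self.labels[index],
            self.user_ids[index],
            self.schema,
            list(self.label_names),
            self.normalized,
        )

    def subset_users(self, users) -> "MultimodalDataset":
        sel = np.isin(self.user_ids, np.asarray(list(users)))
        return self.subset(sel)


# ---------------------------------------------------------------------------
# Normalization


@dataclass
class Normalizer:
    """Per-feature min-max scaling fitted on observed training entries.

    Features whose observed values all lie in {0, 1} are flagged binary
    and passed through unscaled; constant features map to 0.  Missing
    entries are encoded with the sentinel after scaling.
    """

    feature_min: np.ndarray
    feature_max: np.ndarray
    is_binary: np.ndarray
    is_constant: np.ndarray
    sentinel: float = SENTINEL
    n_features: int = 0

    def __post_init__(self):
        if not (self.sentinel < 0.0 or self.sentinel > 1.0):
            raise ValueError("sentinel must lie strictly outside [0,1]")


def fit_normalizer(train: MultimodalDataset, sentinel: float = SENTINEL) -> Normalizer:
    """Compute per-feature min/max over observed training entries only."""
    if train.n_instances == 0:
        raise ValueError("cannot fit a normalizer on an empty training set")
    X = train.features
    obs = ~train.missing_mask
    n = train.n_features
    fmin = np.zeros(n)
    fmax = np.zeros(n)
    binary = np.zeros(n, dtype=bool)
    constant = np.zeros(n, dtype=bool)
    for j in range(n):
        vals = X[obs[:, j], j]
        if vals.size == 0:
            constant[j] = True
            continue
        fmin[j] = vals.min()
        fmax[j] = vals.max()
        if np.all((vals == 0.0) | (vals == 1.0)):
            binary[j] = True
        elif fmax[j] == fmin[j]:
            constant[j] = True
    return Normalizer(fmin, fmax, binary, constant, sentinel, n)


def apply_normalizer(dataset: MultimodalDataset, norm: Normalizer) -> MultimodalDataset:
    """Return a normalized view: observed continuous entries min-max scaled
    and clipped to [0,1], binary entries passed through, missing entries set
    to the sentinel.  Idempotent: an already-normalized dataset is returned
    unchanged (as a copy)."""
    if norm.n_features != dataset.n_features:
        raise ValueError("normalizer was fitted on a different schema width")
    out = dataset.copy()
    if dataset.normalized:
        return out
    X = out.features
    span = norm.feature_max - norm.feature_min
    scale_cols = ~(norm.is_binary | norm.is_constant)
    with np.errstate(invalid="ignore"):
        scaled = (X - norm.feature_min) / np.where(span == 0.0, 1.0, span)
    scaled = np.clip(scaled, 0.0, 1.0)
    X = np.where(scale_cols, scaled, X)
    X[:, norm.is_constant] = 0.0
    X[out.missing_mask] = norm.sentinel
    out.features = X
    out.normalized = True
    return out


# ---------------------------------------------------------------------------
# Fold construction


@dataclass(frozen=True)
class FoldPlan:
    """k ordered (train_users, test_users) pairs partitioning all users."""

    folds: tuple[tuple[tuple, tuple], ...]

    @property
    def k(self) -> int:
        return len(self.folds)

    def __iter__(self):
        return iter(self.folds)

    def __getitem__(self, i):
        return self.folds[i]


def make_user_folds(user_ids, k: int, rng: np.random.Generator) -> FoldPlan:
    """Partition distinct users into k near-equal test groups; the train
    set of each fold is the complement.  Whole users are held out so no
    person contributes to both training and testing."""
    if k < 2:
        raise ValueError("k must be at least 2")
    users = np.unique(np.asarray(user_ids))
    if users.size < k:
        raise ValueError(f"need at least k={k} distinct users, got {users.size}")
    order = rng.permutation(users.size)
    shuffled = users[order]
    groups = np.array_split(shuffled, k)
    folds = []
    for g in groups:
        test = tuple(sorted(g.tolist()))
        train = tuple(sorted(np.setdiff1d(users, g).tolist()))
        folds.append((train, test))
    return FoldPlan(tuple(folds))


def split_clean_noisy(
    dataset: MultimodalDataset,
) -> tuple[MultimodalDataset, MultimodalDataset]:
    """Split into instances with zero missing feature entries (clean) and
    the rest (noisy)."""
    any_missing = dataset.missing_mask.any(axis=1)
    return dataset.subset(~any_missing), dataset.subset(any_missing)


# ---------------------------------------------------------------------------
# CSV round-tripping
#
# Dialect: UTF-8, mandatory header, column order user_id, features in
# schema order named "<modality>:<index>", then "label:<name>" columns.
# Empty cells encode missing features / unreported labels.


def write_dataset(dataset: MultimodalDataset, path) -> None:
    feat_cols = dataset.schema.feature_names()
    label_cols = [f"label:{name}" for name in dataset.label_names]
    X = dataset.features.astype(object)
    X[dataset.missing_mask] = None
    rep = dataset.label_mask
    L = np.empty(dataset.labels.shape, dtype=object)
    L[rep] = dataset.labels[rep].astype(int)
    L[~rep] = None
    frame = pd.DataFrame(X, columns=feat_cols)
    frame.insert(0, "user_id", dataset.user_ids)
    lab = pd.DataFrame(L, columns=label_cols)
    out = pd.concat([frame, lab], axis=1)
    out.to_csv(path, index=False, lineterminator="\n")


def read_dataset(path) -> MultimodalDataset:
    frame = pd.read_csv(path, dtype={"user_id": str},
                        float_precision="round_trip")
    cols = list(frame.columns)
    if not cols or cols[0] != "user_id":
        raise ValueError("first column must be 'user_id'")
    feat_cols, label_cols = [], []
    modalities: list[tuple[str, int]] = []
    for c in cols[1:]:
        if c.startswith("label:"):
            label_cols.append(c)
        elif ":" in c:
            if label_cols:
                raise ValueError(f"feature column {c!r} appears after label columns")
            mod, idx = c.rsplit(":", 1)
            try:
                idx = int(idx)
            except ValueError as exc:
                raise ValueError(f"malformed feature column {c!r}") from exc
            if modalities and modalities[-1][0] == mod:
                if idx != modalities[-1][1]:
                    raise ValueError(f"non-contiguous feature index in column {c!r}")
                modalities[-1] = (mod, idx + 1)
            else:
                if idx != 0:
                    raise ValueError(f"modality {mod!r} does not start at index 0")
                modalities.append((mod, 1))
            feat_cols.append(c)
        else:
            raise ValueError(f"unknown column prefix in {c!r}")
    if not feat_cols:
        raise ValueError("no feature columns found")
    schema = ModalitySchema(tuple(modalities))
    try:
        feats = frame[feat_cols].to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise ValueError(f"non-numeric feature cell: {exc}") from exc
    mask = np.isnan(feats)
    labels = frame[label_cols].to_numpy(dtype=np.float64)
    label_names = [c.split(":", 1)[1] for c in label_cols]
    return MultimodalDataset(
        feats, mask, labels, frame["user_id"].to_numpy(), schema, label_names
    )


def dataset_to_csv_bytes(dataset: MultimodalDataset) -> bytes:
    buf = io.StringIO()
    write_dataset(dataset, buf)
    return buf.getvalue().encode("utf-8")


def datasets_equal(a: MultimodalDataset, b: MultimodalDataset) -> bool:
    """Equality on observed values, masks, labels (incl. unreported
    positions), user ids and schema."""
    if a.schema != b.schema or a.features.shape != b.features.shape:
        return False
    if not np.array_equal(a.missing_mask, b.missing_mask):
        return False
    obs = ~a.missing_mask
    if not np.array_equal(a.features[obs], b.features[obs]):
        return False
    if not np.array_equal(np.isnan(a.labels), np.isnan(b.labels)):
        return False
    rep = ~np.isnan(a.labels)
    if not np.array_equal(a.labels[rep], b.labels[rep]):
        return False
    return np.array_equal(a.user_ids.astype(str), b.user_ids.astype(str))
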