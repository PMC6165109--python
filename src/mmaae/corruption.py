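"""Structured corruption of normalized feature batches.

The denoising target is built by corrupting a clean input three ways,
in fixed order: (1) masked noise — a fixed count of randomly chosen
feature positions set to the mask value (0); (2) whole-modality drops —
a random number of randomly chosen modality blocks set to the sentinel
(-1), emulating missing sensors; (3) input dropout — remaining entries
zeroed independently.  Sentineled entries are exempt from step (3) so
dropped blocks stay exactly at the sentinel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import SENTINEL, ModalitySchema


@dataclass
class NoiseConfig:
    """Parameters of the structured noise.

    ``n_drop_max=None`` resolves to (number of modalities - 1) at use:
    at least one modality is always left observed, since an all-missing
    input carries no information to reconstruct from.
    """

    mask_fraction: float = 0.05
    mask_value: float = 0.0
    n_drop_min: int = 3
    n_drop_max: int | None = None
    input_dropout: float = 0.2
    sentinel: float = SENTINEL

    def __post_init__(self):
        if not 0.0 <= self.mask_fraction <= 1.0:
            raise ValueError("mask_fraction must lie in [0,1]")
        if not 0.0 <= self.input_dropout < 1.0:
            raise ValueError("input_dropout must lie in [0,1)")
        if self.n_drop_min < 0:
            raise ValueError("n_drop_min must be nonnegative")

    def resolved_drop_range(self, n_modalities: int) -> tuple[int, int]:
        hi = self.n_drop_max if self.n_drop_max is not None else n_modalities - 1
        lo = self.n_drop_min
        if lo > hi:
            raise ValueError("n_drop_min exceeds n_drop_max")
        if hi >= n_modalities:
            raise ValueError("n_drop_max must be smaller than the modality count")
        return lo, hi

    def to_mapping(self) -> dict:
        return {
            "mask_fraction": self.mask_fraction,
            "mask_value": self.mask_value,
            "n_drop_min": self.n_drop_min,
            "n_drop_max": self.n_drop_max,
            "input_dropout": self.input_dropout,
            "sentinel": self.sentinel,
        }

    @classmethod
    def from_mapping(cls, m: dict) -> "NoiseConfig":
        return cls(**m)


def _check_normalized(batch: np.ndarray, sentinel: float) -> None:
    ok = ((batch >= 0.0) & (batch <= 1.0)) | (batch == sentinel)
    if not np.all(ok):
        raise ValueError(
            "corrupt() expects a normalized batch: entries in [0,1] or sentinel"
        )


def corrupt(
    batch: np.ndarray,
    schema: ModalitySchema,
    cfg: NoiseConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply the three-step structured noise row-wise; the input batch is
    not modified."""
    batch = np.asarray(batch, dtype=np.float64)
    _check_normalized(batch, cfg.sentinel)
    B, n = batch.shape
    lo, hi = cfg.resolved_drop_range(schema.n_modalities)
    out = batch.copy()

    # (1) masked noise at exactly floor(mask_fraction * n) positions per row
    n_mask = math.floor(cfg.mask_fraction * n)
    if n_mask > 0:
        order = rng.random((B, n)).argsort(axis=1, kind="stable")
        cols = order[:, :n_mask]
        rows = np.repeat(np.arange(B), n_mask)
        out[rows, cols.ravel()] = cfg.mask_value

    # (2) whole-modality drops to the sentinel
    dropped = np.zeros((B, n), dtype=bool)
    if hi > 0:
        ks = rng.integers(lo, hi + 1, size=B) if hi > lo else np.full(B, lo)
        names = np.array(schema.names)
        for i in range(B):
            if ks[i] == 0:
                continue
            chosen = rng.choice(len(names), size=int(ks[i]), replace=False)
            for j in chosen:
                dropped[i, schema.block(names[j])] = True
        out[dropped] = cfg.sentinel

    # (3) input dropout on remaining (non-sentineled) entries
    if cfg.input_dropout > 0.0:
        drop = rng.random((B, n)) < cfg.input_dropout
        out[drop & ~dropped] = 0.0

    return out


def drop_modalities(
    batch: np.ndarray,
    schema: ModalitySchema,
    names,
    sentinel: float = SENTINEL,
) -> np.ndarray:
    """Deterministically set the named modality blocks to the sentinel."""
    for name in names:
        if name not in schema.names:
            raise ValueError(f"unknown modality name {name!r}")
    out = np.asarray(batch, dtype=np.float64).copy()
    for name in names:
        out[:, schema.block(name)] = sentinel
    return out
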