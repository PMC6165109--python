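"""Evaluation metrics: RMSE for restoration, per-label confusion
statistics and balanced accuracy for multi-label classification.

Metrics are computed independently per label over *reported* entries
only, then macro-averaged; labels with no reported positives (or no
reported negatives) have undefined sensitivity (specificity), are
flagged, and are excluded from the macro averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def rmse(
    truth: np.ndarray,
    estimate: np.ndarray,
    positions_mask: np.ndarray | None = None,
) -> float:
    """Root mean square error over the selected positions."""
    truth = np.asarray(truth, dtype=np.float64)
    estimate = np.asarray(estimate, dtype=np.float64)
    if truth.shape != estimate.shape:
        raise ValueError("shapes of truth and estimate differ")
    if positions_mask is None:
        diff = truth - estimate
    else:
        positions_mask = np.asarray(positions_mask, dtype=bool)
        if positions_mask.shape != truth.shape:
            raise ValueError("positions_mask shape mismatch")
        if not positions_mask.any():
            raise ValueError("empty evaluation mask")
        diff = truth[positions_mask] - estimate[positions_mask]
    return float(np.sqrt(np.mean(diff**2)))


@dataclass
class MetricReport:
    """Per-label confusion counts and rates plus macro averages."""

    per_label: pd.DataFrame
    macro: dict[str, float]
    flagged_labels: list[str] = field(default_factory=list)
    per_fold: pd.DataFrame | None = None

    @property
    def macro_balanced_accuracy(self) -> float:
        return self.macro["balanced_accuracy"]


def label_metrics(
    true_labels: np.ndarray,
    predictions: np.ndarray,
    label_names: list[str] | None = None,
) -> MetricReport:
    """Confusion counts over reported entries; sensitivity = tp/(tp+fn),
    specificity = tn/(tn+fp), BA = their mean, accuracy = (tp+tn)/n_obs."""
    T = np.asarray(true_labels, dtype=np.float64)
    P = np.asarray(predictions, dtype=np.float64)
    if T.shape != P.shape:
        raise ValueError("label and prediction shapes differ")
    C = T.shape[1]
    names = label_names or [f"ctx_{c:02d}" for c in range(C)]
    rep = ~np.isnan(T)
    rows = []
    flagged = []
    for c in range(C):
        t = T[rep[:, c], c]
        p = P[rep[:, c], c]
        tp = int(np.sum((t == 1) & (p == 1)))
        fn = int(np.sum((t == 1) & (p == 0)))
        tn = int(np.sum((t == 0) & (p == 0)))
        fp = int(np.sum((t == 0) & (p == 1)))
        n_pos, n_neg = tp + fn, tn + fp
        sens = tp / n_pos if n_pos else np.nan
        spec = tn / n_neg if n_neg else np.nan
        valid = bool(n_pos and n_neg)
        if not valid:
            flagged.append(names[c])
        ba = (sens + spec) / 2.0 if valid else np.nan
        acc = (tp + tn) / (n_pos + n_neg) if (n_pos + n_neg) else np.nan
        rows.append({
            "label": names[c], "tp": tp, "fp": fp, "tn": tn, "fn": fn,
            "sensitivity": sens, "specificity": spec,
            "balanced_accuracy": ba, "accuracy": acc, "valid": valid,
        })
    per_label = pd.DataFrame(rows)
    valid_rows = per_label[per_label["valid"]]
    macro = {
        k: float(valid_rows[k].mean()) if len(valid_rows) else float("nan")
        for k in ("sensitivity", "specificity", "balanced_accuracy", "accuracy")
    }
    return MetricReport(per_label, macro, flagged)


def aggregate_reports(reports: list[MetricReport]) -> MetricReport:
    """Mean ± SD of macro metrics across folds; the aggregate macro is
    the mean of per-fold macros."""
    keys = ("sensitivity", "specificity", "balanced_accuracy", "accuracy")
    per_fold = pd.DataFrame([{k: r.macro[k] for k in keys} for r in reports])
    macro = {k: float(per_fold[k].mean()) for k in keys}
    macro.update({f"{k}_sd": float(per_fold[k].std(ddof=1)) for k in keys})
    flagged = sorted({name for r in reports for name in r.flagged_labels})
    return MetricReport(
        per_label=pd.concat(
            [r.per_label.assign(fold=i) for i, r in enumerate(reports)],
            ignore_index=True,
        ),
        macro=macro,
        flagged_labels=flagged,
        per_fold=per_fold,
    )
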