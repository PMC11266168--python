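"""Binder-classification metrics, ROC/AUC and the k-fold CV protocol.

Predicted and measured transformed scores are binarized at the 500 nM
binder cutoff (strictly greater = binder) and summarized as accuracy,
sensitivity, specificity and Matthews correlation; metrics with a zero
denominator are reported as undefined (None) rather than zero so fold
averages are not silently deflated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score

from .errors import ContractError
from .gcn_model import BINDER_SCORE_CUTOFF, GCNConfig, predict, train


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion(pred_scores, true_scores, cutoff: float = BINDER_SCORE_CUTOFF) -> ConfusionCounts:
    """Binarize both sides at the binder cutoff and tally the counts."""
    pred = np.asarray(pred_scores, dtype=float)
    true = np.asarray(true_scores, dtype=float)
    if pred.shape != true.shape or pred.ndim != 1 or pred.size < 1:
        raise ContractError(
            f"score vectors must be equal-length 1-D, got {pred.shape} vs {true.shape}"
        )
    p = pred > cutoff
    t = true > cutoff
    return ConfusionCounts(
        TP=int(np.sum(p & t)),
        TN=int(np.sum(~p & ~t)),
        FP=int(np.sum(p & ~t)),
        FN=int(np.sum(~p & t)),
    )


def metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Acc, Sn, Sp and MCC; zero-denominator metrics are None (undefined)."""
    if c.total < 1:
        raise ContractError("metrics need at least one prediction")
    out: dict[str, float | None] = {}
    out["Acc"] = (c.TP + c.TN) / c.total
    out["Sn"] = c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else None
    out["Sp"] = c.TN / (c.TN + c.FP) if (c.TN + c.FP) > 0 else None
    denom = (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    out["MCC"] = (
        (c.TN * c.TP - c.FN * c.FP) / math.sqrt(denom) if denom > 0 else None
    )
    return out


def roc_auc(pred_scores, true_labels) -> float:
    """Area under the ROC curve (rank statistic with midrank tie handling)."""
    labels = np.asarray(true_labels).astype(int)
    if len(set(labels.tolist())) < 2:
        raise ContractError("ROC AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(pred_scores, dtype=float)))


@dataclass(frozen=True)
class FoldAssignment:
    n: int
    k: int
    fold_of: tuple[int, ...]
    seed: int

    def indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(np.array(self.fold_of) == fold)


def kfold_split(n: int, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Seeded shuffle then contiguous chunking; fold sizes differ by <= 1."""
    if n < k:
        raise ContractError(f"cannot split {n} items into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    sizes = [n // k + (1 if f < n % k else 0) for f in range(k)]
    start = 0
    for f, size in enumerate(sizes):
        fold_of[order[start: start + size]] = f
        start += size
    return FoldAssignment(n=n, k=k, fold_of=tuple(int(x) for x in fold_of), seed=seed)


def cross_validate(
    dataset,
    config: GCNConfig,
    k: int = 10,
    seed: int = 0,
    cutoff: float = BINDER_SCORE_CUTOFF,
) -> dict:
    """k-fold CV of the affinity model on (hla, pep, score) triples.

    Each fold in turn is the validation set; the rest trains a fresh model
    with the shared config.  Returns per-fold and mean metrics (undefined
    metrics are excluded from means) plus AUC where both classes occur.
    """
    folds = kfold_split(len(dataset), k=k, seed=seed)
    per_fold = []
    for f in range(k):
        val_idx = set(folds.indices(f).tolist())
        train_set = [s for i, s in enumerate(dataset) if i not in val_idx]
        val_set = [dataset[i] for i in sorted(val_idx)]
        model = train(train_set, config)
        preds = np.array([predict(model, h, p) for h, p, _ in val_set])
        truth = np.array([y for _, _, y in val_set])
        result = metrics(confusion(preds, truth, cutoff))
        labels = truth > cutoff
        result["AUC"] = (
            roc_auc(preds, labels) if len(set(labels.tolist())) == 2 else None
        )
        result["fold"] = f
        result["n_val"] = len(val_set)
        per_fold.append(result)
    mean = {}
    for key in ("Acc", "Sn", "Sp", "MCC", "AUC"):
        defined = [r[key] for r in per_fold if r[key] is not None]
        mean[key] = float(np.mean(defined)) if defined else None
    return {"k": k, "seed": seed, "folds": per_fold, "mean": mean}


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
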