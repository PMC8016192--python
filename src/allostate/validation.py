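"""Evaluation protocol: k-fold CV, confusion metrics, group aggregation.

Frames classified I count as positives and frames classified A as
negatives, so over a labeled evaluation set

    Q   = (TP + TN) / N          accuracy
    TPR = TP / (TP + FN)         sensitivity on bound frames
    TNR = TN / (TN + FP)         specificity on free frames
    FPR = FP / (FP + TN) = 1 - TNR

Cross-validation reports the mean of per-fold accuracies alongside
TPR/TNR pooled over the five validation subsets.  Splitting is at the
record level (random 80:20 folds), which ignores the temporal
autocorrelation of MD frames and therefore flatters internal accuracy;
a blocked-by-replicate alternative is provided for sanity checks.

Group-level aggregation expresses predictions as TPR% for the pooled
replicates of each ligand and FPR% for each block of inhibitor-free
replicates: in both cases 100 times the fraction of frames predicted I.
A rate whose reference class is absent is reported as missing (NaN),
never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts", "MetricsReport", "CrossValidationReport",
    "kfold_split", "blocked_kfold_split", "compute_metrics",
    "cross_validate", "aggregate_by_group",
]

POSITIVE, NEGATIVE = "I", "A"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class MetricsReport:
    q: float
    tpr: float  # NaN if no positives in truth
    tnr: float  # NaN if no negatives in truth
    fpr: float  # 1 - TNR; NaN alongside TNR
    counts: ConfusionCounts
    level: str = "pooled"
    group_id: str | None = None


@dataclass(frozen=True)
class CrossValidationReport:
    fold_metrics: tuple[MetricsReport, ...]
    mean_q: float
    pooled: MetricsReport  # TP/TN summed over the validation subsets


def kfold_split(n_rows: int, k: int = 5, rng_seed: int = 0
                ) -> list[np.ndarray]:
    """Random disjoint row partitions with sizes differing by at most 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_rows < k:
        raise ValueError(f"need at least k={k} rows, got {n_rows}")
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(n_rows)
    return [np.sort(fold) for fold in np.array_split(order, k)]


def blocked_kfold_split(block_ids: np.ndarray, k: int = 5, rng_seed: int = 0
                        ) -> list[np.ndarray]:
    """Folds that keep whole blocks (e.g. replicates) together.

    Blocks are shuffled and dealt round-robin into k folds, so temporally
    autocorrelated frames never straddle a train/validation boundary.
    """
    block_ids = np.asarray(block_ids)
    blocks = pd.unique(block_ids)
    if len(blocks) < k:
        raise ValueError(f"need at least k={k} blocks, got {len(blocks)}")
    rng = np.random.default_rng(rng_seed)
    shuffled = blocks[rng.permutation(len(blocks))]
    folds = [[] for _ in range(k)]
    for i, b in enumerate(shuffled):
        folds[i % k].append(b)
    return [np.sort(np.flatnonzero(np.isin(block_ids, fold)))
            for fold in folds]


def compute_metrics(truth, predicted, level: str = "pooled",
                    group_id: str | None = None) -> MetricsReport:
    """Confusion counts and Q/TPR/TNR/FPR for one set of predictions."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError(
            f"truth ({truth.shape}) and predictions ({predicted.shape}) "
            "differ in length")
    bad = set(np.unique(truth)) - {POSITIVE, NEGATIVE}
    if bad:
        raise ValueError(f"unexpected truth labels {sorted(bad)}")
    is_pos = truth == POSITIVE
    pred_pos = predicted == POSITIVE
    counts = ConfusionCounts(
        tp=int(np.sum(is_pos & pred_pos)),
        tn=int(np.sum(~is_pos & ~pred_pos)),
        fp=int(np.sum(~is_pos & pred_pos)),
        fn=int(np.sum(is_pos & ~pred_pos)))
    q = (counts.tp + counts.tn) / counts.total if counts.total else np.nan
    n_pos = counts.tp + counts.fn
    n_neg = counts.tn + counts.fp
    tpr = counts.tp / n_pos if n_pos else np.nan
    tnr = counts.tn / n_neg if n_neg else np.nan
    fpr = 1.0 - tnr if n_neg else np.nan
    return MetricsReport(q=q, tpr=tpr, tnr=tnr, fpr=fpr, counts=counts,
                         level=level, group_id=group_id)


def cross_validate(matrix: pd.DataFrame,
                   trainer: Callable[[pd.DataFrame], object],
                   predictor: Callable[[object, pd.DataFrame], pd.DataFrame],
                   k: int = 5, rng_seed: int = 0,
                   blocked_by: str | None = None) -> CrossValidationReport:
    """k-fold CV of an arbitrary trainer/predictor pair.

    ``predictor`` must return a DataFrame with a ``predicted`` column.
    ``blocked_by`` names a column (e.g. ``system_id``) for block-level
    folds instead of record-level ones.
    """
    matrix = matrix.reset_index(drop=True)
    if blocked_by is None:
        folds = kfold_split(len(matrix), k=k, rng_seed=rng_seed)
    else:
        folds = blocked_kfold_split(matrix[blocked_by].to_numpy(), k=k,
                                    rng_seed=rng_seed)
    fold_reports = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for fold_idx, valid_rows in enumerate(folds):
        train_rows = np.setdiff1d(np.arange(len(matrix)), valid_rows)
        model = trainer(matrix.iloc[train_rows])
        pred = predictor(model, matrix.iloc[valid_rows])
        report = compute_metrics(
            matrix["label"].to_numpy()[valid_rows],
            pred["predicted"].to_numpy(),
            level="fold", group_id=f"fold-{fold_idx + 1}")
        fold_reports.append(report)
        pooled = pooled + report.counts
    pooled_report = MetricsReport(
        q=(pooled.tp + pooled.tn) / pooled.total,
        tpr=pooled.tp / (pooled.tp + pooled.fn)
        if pooled.tp + pooled.fn else np.nan,
        tnr=pooled.tn / (pooled.tn + pooled.fp)
        if pooled.tn + pooled.fp else np.nan,
        fpr=pooled.fp / (pooled.fp + pooled.tn)
        if pooled.tn + pooled.fp else np.nan,
        counts=pooled, level="pooled")
    mean_q = float(np.mean([r.q for r in fold_reports]))
    return CrossValidationReport(tuple(fold_reports), mean_q, pooled_report)


def aggregate_by_group(predictions: pd.DataFrame, manifest: pd.DataFrame
                       ) -> pd.DataFrame:
    """Pool per-row predictions into per-group percent-I rates.

    ``predictions`` needs ``system_id`` and ``predicted`` columns;
    ``manifest`` maps every system to a ``state`` (A or I), ``ligand_id``
    and ``group_id`` (ligand groups pool the ligand's replicates;
    inhibitor-free groups pool blocks of replicates).  Returns one row
    per group with ``pct_I`` and its role (TPR% for bound groups, FPR%
    for free groups).
    """
    required = {"system_id", "predicted"}
    if not required <= set(predictions.columns):
        raise ValueError(f"predictions need columns {sorted(required)}")
    known = set(manifest["system_id"])
    unknown = set(predictions["system_id"]) - known
    if unknown:
        raise ValueError(f"systems missing from manifest: {sorted(unknown)}")
    merged = predictions.merge(
        manifest[["system_id", "state", "ligand_id", "group_id"]],
        on="system_id", how="left", validate="many_to_one")
    rows = []
    for group_id, block in merged.groupby("group_id", sort=True):
        pct_i = 100.0 * float(np.mean(block["predicted"] == POSITIVE))
        state = block["state"].iloc[0]
        rows.append({
            "group_id": group_id,
            "state": state,
            "ligand_id": block["ligand_id"].iloc[0],
            "n_rows": len(block),
            "n_systems": block["system_id"].nunique(),
            "pct_I": pct_i,
            "metric": "TPR%" if state == POSITIVE else "FPR%",
        })
    return pd.DataFrame(rows)
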