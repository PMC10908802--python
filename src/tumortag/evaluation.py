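"""Evaluation metrics: per-dataset accuracy/similarity ratios, their
size-weighted aggregate, standard binary classification metrics, and the
spatial co-localization call.

For dataset i with N_i cells, ratio_i = (TP_i + TN_i) / N_i (malignant is the
positive class); across n datasets the aggregate is the size-weighted mean
ratio_weighted = sum_i(ratio_i * N_i) / sum_i N_i, which equals the pooled
ratio on the concatenated data. The same formula is reported as "accuracy"
against gold-standard labels and "similarity" against silver-standard
(inherited) labels — the distinction is metadata only.

A spot is in the co-localization state when at least k of a gene signature's
genes have nonzero UMI counts (default 9 of 10).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sklearn.metrics

from .io import LAYER_RAW, ExpressionMatrix


@dataclass
class DatasetCounts:
    dataset_id: str
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def ratio(self) -> float:
        return (self.tp + self.tn) / self.n


def dataset_ratio(calls, truth, dataset_id: str = "", mask=None) -> DatasetCounts:
    """Confusion counts and ratio = (TP + TN) / N for one dataset; malignant
    (1) is the positive class.

    ``mask`` optionally marks cells a tool declined to call; masked cells are
    excluded from N.
    """
    calls = np.asarray(calls, dtype=np.int64)
    truth = np.asarray(truth, dtype=np.int64)
    if calls.shape != truth.shape:
        raise ValueError("calls and truth must have equal length")
    if mask is not None:
        keep = np.asarray(mask, dtype=bool)
        calls, truth = calls[keep], truth[keep]
    if calls.size == 0:
        raise ValueError("no called cells to evaluate")
    tp = int(np.sum((calls == 1) & (truth == 1)))
    tn = int(np.sum((calls == 0) & (truth == 0)))
    fp = int(np.sum((calls == 1) & (truth == 0)))
    fn = int(np.sum((calls == 0) & (truth == 1)))
    return DatasetCounts(dataset_id, tp, tn, fp, fn)


def weighted_ratio(rows) -> float:
    """Size-weighted mean of per-dataset ratios: sum(ratio_i * N_i) / sum N_i.

    ``rows`` is a list of (ratio_i, N_i) pairs or DatasetCounts. Equals the
    pooled (sum TP + sum TN) / sum N when the rows come from dataset_ratio.
    """
    if not rows:
        raise ValueError("weighted_ratio needs at least one dataset row")
    num = 0.0
    den = 0.0
    for row in rows:
        ratio, n = (row.ratio, row.n) if isinstance(row, DatasetCounts) else row
        if n < 1:
            raise ValueError("dataset sizes must be >= 1")
        num += ratio * n
        den += n
    return num / den


UNDEFINED = "undefined"


@dataclass
class BinaryMetrics:
    precision: float
    recall: float
    f1: float
    auroc: float | str
    auprc: float | str


def binary_metrics(scores, truth, threshold: float = 0.5) -> BinaryMetrics:
    """Precision/recall/F1 at the given threshold plus AUROC (rank statistic,
    ties averaged) and AUPRC (step interpolation) from continuous scores.

    With single-class truth the rank metrics are reported as the explicit
    marker "undefined" rather than NaN.
    """
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.int64)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have equal length")
    calls = (scores > threshold).astype(np.int64)
    precision = sklearn.metrics.precision_score(truth, calls, zero_division=0)
    recall = sklearn.metrics.recall_score(truth, calls, zero_division=0)
    f1 = sklearn.metrics.f1_score(truth, calls, zero_division=0)
    if len(np.unique(truth)) < 2:
        auroc: float | str = UNDEFINED
        auprc: float | str = UNDEFINED
    else:
        auroc = float(sklearn.metrics.roc_auc_score(truth, scores))
        auprc = float(sklearn.metrics.average_precision_score(truth, scores))
    return BinaryMetrics(float(precision), float(recall), float(f1), auroc, auprc)


def evaluation_report(calls, truth, datasets) -> pd.DataFrame:
    """Per-dataset confusion rows plus the size-weighted aggregate, as a
    table (last row is the aggregate)."""
    calls = np.asarray(calls, dtype=np.int64)
    truth = np.asarray(truth, dtype=np.int64)
    datasets = np.asarray(datasets)
    rows = []
    counts = []
    for d in pd.unique(datasets):
        sel = datasets == d
        c = dataset_ratio(calls[sel], truth[sel], dataset_id=str(d))
        counts.append(c)
        rows.append(
            {
                "dataset_id": c.dataset_id,
                "TP": c.tp,
                "TN": c.tn,
                "FP": c.fp,
                "FN": c.fn,
                "N": c.n,
                "ratio": c.ratio,
            }
        )
    rows.append(
        {
            "dataset_id": "weighted",
            "TP": sum(c.tp for c in counts),
            "TN": sum(c.tn for c in counts),
            "FP": sum(c.fp for c in counts),
            "FN": sum(c.fn for c in counts),
            "N": sum(c.n for c in counts),
            "ratio": weighted_ratio(counts),
        }
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spatial co-localization
# ---------------------------------------------------------------------------

@dataclass
class SignatureSpec:
    """A gene signature and the number of its genes that must be expressed
    (UMI count > 0) for a spot to be in the co-localization state."""

    genes: list[str]
    min_expressed: int = 9

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("signature must contain at least one gene")
        if not (1 <= self.min_expressed <= len(self.genes)):
            raise ValueError("min_expressed must be between 1 and |genes|")

    @classmethod
    def from_file(cls, path, min_expressed: int = 9) -> "SignatureSpec":
        genes = [
            line.strip() for line in open(path) if line.strip()
        ]
        return cls(genes, min_expressed)


def colocalization_call(spot_counts: ExpressionMatrix, sig: SignatureSpec) -> np.ndarray:
    """Per-spot boolean: True when at least ``min_expressed`` signature genes
    have UMI count > 0 in the spot.

    Signature genes absent from the matrix count as not expressed (warned).
    Monotone: adding counts never turns a co-localized spot off.
    """
    if spot_counts.layer_tag != LAYER_RAW:
        raise ValueError("colocalization_call expects raw UMI counts")
    col = {g: j for j, g in enumerate(spot_counts.gene_ids)}
    present = [g for g in sig.genes if g in col]
    missing = [g for g in sig.genes if g not in col]
    if missing:
        warnings.warn(
            f"{len(missing)} signature gene(s) absent from the matrix and "
            f"counted as not expressed: {missing[:5]}"
        )
    if present:
        expressed = (spot_counts.values[:, [col[g] for g in present]] > 0).sum(axis=1)
    else:
        expressed = np.zeros(spot_counts.n_cells, dtype=np.int64)
    return expressed >= sig.min_expressed
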