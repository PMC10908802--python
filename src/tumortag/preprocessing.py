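"""Expression preprocessing: global-scaling log normalization, highly variable
gene (HVG) selection, per-domain class balancing, stratified splits, k-fold
partitions, and feature alignment for inference on new data.

The pipeline mirrors standard single-cell practice: each cell's counts are
rescaled so its pre-log total equals ``scale_factor`` (default 10,000), then
natural log(1 + x) is applied; genes are ranked by the variance of the
normalized values across cells and the top ``n_hvgs`` are kept (4572 in
single-cell mode, 5000 in spatial mode); within each domain the majority
class is down-sampled to a 1:1 ratio; the balanced cells are split 4:1 into
training and validation, stratified by domain x label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import LAYER_NORMALIZED, LAYER_RAW, AnnotationTable, ExpressionMatrix

N_HVGS_SINGLE_CELL = 4572
N_HVGS_SPATIAL = 5000
DEFAULT_SCALE_FACTOR = 10_000.0


@dataclass
class PreprocessConfig:
    """Preprocessing parameters, serialized into the model archive so that
    inference replays the training-time transform."""

    scale_factor: float = DEFAULT_SCALE_FACTOR
    n_hvgs: int = N_HVGS_SINGLE_CELL
    balance_ratio: float = 1.0
    split_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        if self.n_hvgs <= 0:
            raise ValueError("n_hvgs must be positive")
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split_fraction must lie in (0, 1)")


def domain_partition(ann: AnnotationTable) -> dict[str, np.ndarray]:
    """Map domain name -> ordered array of row indices; blocks are disjoint,
    non-empty, and cover every annotated cell."""
    part: dict[str, list[int]] = {}
    for i, d in enumerate(ann.domains):
        part.setdefault(d, []).append(i)
    return {d: np.asarray(ix, dtype=np.int64) for d, ix in part.items()}


def normalize_cells(
    raw: ExpressionMatrix, scale_factor: float = DEFAULT_SCALE_FACTOR
) -> ExpressionMatrix:
    """Global-scaling log normalization: rescale each cell so its total equals
    ``scale_factor``, then apply natural log(1 + x).

    Cells with zero total counts are rejected (their ids are listed) rather
    than silently dropped.
    """
    if raw.layer_tag != LAYER_RAW:
        raise ValueError("normalize_cells expects a raw_counts matrix")
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    if (raw.values < 0).any():
        raise ValueError("raw counts must be non-negative")
    totals = raw.values.sum(axis=1)
    zero = totals == 0
    if zero.any():
        ids = [raw.cell_ids[i] for i in np.flatnonzero(zero)[:10]]
        raise ValueError(
            f"{int(zero.sum())} cell(s) have zero total counts "
            f"(e.g. {ids}); drop them before normalizing"
        )
    scaled = raw.values * (scale_factor / totals)[:, None]
    return ExpressionMatrix(
        np.log1p(scaled), list(raw.cell_ids), list(raw.gene_ids), LAYER_NORMALIZED
    )


def select_hvgs(normalized: ExpressionMatrix, n_hvgs: int) -> list[str]:
    """The ``n_hvgs`` genes with largest variance of the normalized values
    across all cells, in descending-variance order; ties resolved by input
    gene order (stable). Variance uses the population denominator N."""
    if normalized.layer_tag != LAYER_NORMALIZED:
        raise ValueError("select_hvgs expects a normalized matrix")
    if n_hvgs > normalized.n_genes:
        raise ValueError(
            f"n_hvgs={n_hvgs} exceeds the {normalized.n_genes} available genes"
        )
    var = normalized.values.var(axis=0, ddof=0)
    order = np.argsort(-var, kind="stable")[:n_hvgs]
    return [normalized.gene_ids[j] for j in order]


def balance_classes_per_domain(
    ann: AnnotationTable, partition: dict[str, np.ndarray] | None = None, seed: int = 0
) -> AnnotationTable:
    """Down-sample the majority class within each domain (without replacement)
    to the minority count, giving an exact 1:1 class ratio per domain.

    A domain missing one of the two classes is an error naming the domain —
    such tissues must be discarded by the caller beforehand.
    """
    if partition is None:
        partition = domain_partition(ann)
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for domain, idx in partition.items():
        labels = ann.labels[idx]
        pos = idx[labels == 1]
        neg = idx[labels == 0]
        if len(pos) == 0 or len(neg) == 0:
            missing = "malignant" if len(pos) == 0 else "non-malignant"
            raise ValueError(
                f"domain {domain!r} has no {missing} cells and cannot be balanced"
            )
        n = min(len(pos), len(neg))
        pos_keep = pos if len(pos) == n else rng.choice(pos, size=n, replace=False)
        neg_keep = neg if len(neg) == n else rng.choice(neg, size=n, replace=False)
        keep.extend(int(i) for i in pos_keep)
        keep.extend(int(i) for i in neg_keep)
    keep.sort()
    return ann.subset(keep)


def _strata(ann: AnnotationTable) -> dict[tuple[str, int], list[int]]:
    strata: dict[tuple[str, int], list[int]] = {}
    for i, (d, y) in enumerate(zip(ann.domains, ann.labels)):
        strata.setdefault((d, int(y)), []).append(i)
    return strata


def split_train_val(
    ann: AnnotationTable, split_fraction: float = 0.8, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Stratified (domain x label) train/validation split; per stratum the
    train share is within one cell of ``split_fraction``. Returns disjoint
    (train_ids, val_ids). A stratum of size 1 goes to train with a warning."""
    if not (0.0 < split_fraction < 1.0):
        raise ValueError("split_fraction must lie strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    train_ix: list[int] = []
    val_ix: list[int] = []
    for (domain, label), idx in _strata(ann).items():
        idx = np.asarray(idx)
        if len(idx) == 1:
            warnings.warn(
                f"stratum ({domain!r}, label={label}) has a single cell; "
                "placed in the training split"
            )
            train_ix.extend(idx.tolist())
            continue
        perm = rng.permutation(idx)
        n_train = int(round(split_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)  # keep both sides non-empty
        train_ix.extend(perm[:n_train].tolist())
        val_ix.extend(perm[n_train:].tolist())
    train_ix.sort()
    val_ix.sort()
    return [ann.cell_ids[i] for i in train_ix], [ann.cell_ids[i] for i in val_ix]


def kfold_partition(
    ann: AnnotationTable, k: int, seed: int = 0
) -> list[tuple[list[str], list[str]]]:
    """Stratified (domain x label) k-fold partition: k disjoint test folds
    covering all cells. Errors if k exceeds the smallest stratum."""
    if k < 2:
        raise ValueError("k must be >= 2")
    strata = _strata(ann)
    smallest = min(len(v) for v in strata.values())
    if k > smallest:
        raise ValueError(
            f"k={k} exceeds the smallest (domain x label) stratum size {smallest}"
        )
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(ann), dtype=np.int64)
    for idx in strata.values():
        perm = rng.permutation(np.asarray(idx))
        for pos, cell_ix in enumerate(perm):
            fold_of[cell_ix] = pos % k
    folds: list[tuple[list[str], list[str]]] = []
    for f in range(k):
        test = [ann.cell_ids[i] for i in range(len(ann)) if fold_of[i] == f]
        train = [ann.cell_ids[i] for i in range(len(ann)) if fold_of[i] != f]
        folds.append((train, test))
    return folds


def align_features(
    new: ExpressionMatrix,
    feature_list: list[str],
    hard_fail: bool = False,
) -> tuple[ExpressionMatrix, float]:
    """Reorder columns of ``new`` to ``feature_list``; genes absent from the
    input become all-zero columns, extra genes are dropped.

    Returns (aligned matrix, fraction of features zero-filled). More than 50%
    missing raises a warning, or an error when ``hard_fail`` is set; zero
    overlap is always an error.
    """
    if new.layer_tag != LAYER_NORMALIZED:
        raise ValueError("align_features expects a normalized matrix")
    col = {g: j for j, g in enumerate(new.gene_ids)}
    out = np.zeros((new.n_cells, len(feature_list)), dtype=np.float64)
    missing = 0
    for j, gene in enumerate(feature_list):
        src = col.get(gene)
        if src is None:
            missing += 1
        else:
            out[:, j] = new.values[:, src]
    frac_missing = missing / len(feature_list)
    if missing == len(feature_list):
        raise ValueError("no overlap between input genes and the model feature list")
    if frac_missing > 0.5:
        msg = (
            f"{frac_missing:.1%} of the model's features are missing from the "
            "input and were zero-filled"
        )
        if hard_fail:
            raise ValueError(msg)
        warnings.warn(msg)
    aligned = ExpressionMatrix(
        out, list(new.cell_ids), list(feature_list), LAYER_NORMALIZED
    )
    return aligned, frac_missing
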