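"""Saliency-based gene attribution.

Genes are ranked by the gradient of the malignant-vs-non-malignant score
margin (g_malignant - g_non_malignant) with respect to the input expression
vector, aggregated as the mean absolute per-cell gradient. Because the
network has no nonlinear activations this gradient is the same for every
cell — it equals the effective linear map W1 @ W2 @ (w3_mal - w3_non) — so
the ranking is exact rather than a local approximation; the per-cell
computation is kept so non-affine variants can reuse the same interface.

By default attribution is computed over the cells the model itself calls
malignant (what drives a malignant call); mitochondrial genes ("MT-" prefix)
are excluded from rankings by default.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import MALIGNANT, NON_MALIGNANT, ModelState, _as_matrix, _backward, _forward, predict

DEFAULT_EXCLUDE_PATTERNS = ("MT-",)


@dataclass
class SalienceReport:
    """Non-negative per-gene importance scores, in the model's feature order,
    plus metadata on how many cells contributed."""

    gene_ids: list[str]
    scores: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if len(self.gene_ids) != self.scores.size:
            raise ValueError("gene/score length mismatch")
        if (self.scores < 0).any():
            raise ValueError("salience scores must be non-negative")

    def ranking(self) -> list[str]:
        """All genes in descending-score order, ties by input gene order."""
        order = np.argsort(-self.scores, kind="stable")
        return [self.gene_ids[j] for j in order]

    def to_frame(self) -> pd.DataFrame:
        order = np.argsort(-self.scores, kind="stable")
        return pd.DataFrame(
            {
                "gene_id": [self.gene_ids[j] for j in order],
                "score": self.scores[order],
                "rank": np.arange(1, len(order) + 1),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def saliency_scores(
    model: ModelState,
    X,
    target: str = "malignant_margin",
    cells: str = "predicted_malignant",
) -> SalienceReport:
    """Per-gene importance: mean absolute gradient of the malignant score
    margin with respect to each input gene, over the selected cells.

    ``cells`` chooses the cell set: "predicted_malignant" (default; falls
    back to all cells with a warning if the model calls none malignant) or
    "all". The gradient is obtained by backpropagating the margin through the
    network per cell.
    """
    if target != "malignant_margin":
        raise ValueError(f"unknown attribution target {target!r}")
    X = _as_matrix(X)
    if X.shape[0] == 0:
        raise ValueError("saliency requires at least one cell")
    if model.feature_list is not None and len(model.feature_list) != X.shape[1]:
        raise ValueError("input width does not match the model feature list")

    if cells == "predicted_malignant":
        _, _, calls = predict(model, X)
        mask = calls == 1
        if not mask.any():
            warnings.warn(
                "model predicts no malignant cells in this input; computing "
                "saliency over all cells instead"
            )
            mask = np.ones(X.shape[0], dtype=bool)
        X_used = X[mask]
    elif cells == "all":
        X_used = X
    else:
        raise ValueError(f"unknown cell selection {cells!r}")

    # backprop the margin g_mal - g_non through the (dropout-free) forward
    g, cache = _forward(model.params, X_used)
    dg = np.zeros_like(g)
    dg[:, MALIGNANT] = 1.0
    dg[:, NON_MALIGNANT] = -1.0
    _, dX = _backward(model.params, cache, dg)
    scores = np.abs(dX).mean(axis=0)

    gene_ids = (
        list(model.feature_list)
        if model.feature_list is not None
        else [f"feature_{j}" for j in range(X.shape[1])]
    )
    return SalienceReport(
        gene_ids=gene_ids,
        scores=scores,
        metadata={
            "n_cells_used": int(X_used.shape[0]),
            "cell_selection": cells,
            "target": target,
        },
    )


def rank_genes(
    report: SalienceReport,
    top_k: int,
    exclude_patterns: tuple[str, ...] = DEFAULT_EXCLUDE_PATTERNS,
) -> list[str]:
    """Top-k genes by descending salience after removing genes matching any
    exclusion pattern (prefix-anchored regex; default drops mitochondrial
    "MT-" genes). Ties resolved by input gene order."""
    compiled = [re.compile(p) for p in exclude_patterns]
    kept = [
        (j, g)
        for j, g in enumerate(report.gene_ids)
        if not any(c.match(g) for c in compiled)
    ]
    if top_k > len(kept):
        raise ValueError(
            f"top_k={top_k} exceeds the {len(kept)} genes remaining after exclusion"
        )
    order = sorted(kept, key=lambda jg: (-report.scores[jg[0]], jg[0]))
    return [g for _, g in order[:top_k]]
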