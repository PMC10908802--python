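"""Readers and writers for expression matrices, annotations, predictions and
model archives.

Two matrix formats are supported: dense delimited text (header row of gene or
cell identifiers, first column identifiers) and Matrix Market coordinate
triplets with sidecar gene/barcode lists. Annotations and predictions are
delimited tables with a named header. A trained model is stored as a single
archive file with an embedded schema version so that inference elsewhere
replays the exact training-time state.
"""

from __future__ import annotations

import io as _io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

ARCHIVE_VERSION = "1"

LAYER_RAW = "raw_counts"
LAYER_NORMALIZED = "normalized"

#: label tokens accepted in annotation tables (matched case-insensitively)
LABEL_TOKENS = {
    "malignant": 1,
    "1": 1,
    "non-malignant": 0,
    "non_malignant": 0,
    "0": 0,
}


class FormatError(ValueError):
    """Raised when an input file violates a format or validation contract."""


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A cells/spots x genes expression matrix with ordered identifiers.

    ``values`` is always oriented cells-in-rows. ``layer_tag`` records whether
    the matrix holds raw counts or log-normalized values; operations that
    require one or the other check it.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    layer_tag: str = LAYER_RAW

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.cell_ids):
            raise FormatError(
                f"row count {n} does not match {len(self.cell_ids)} cell ids"
            )
        if p != len(self.gene_ids):
            raise FormatError(
                f"column count {p} does not match {len(self.gene_ids)} gene ids"
            )
        _check_unique(self.cell_ids, "cell id")
        _check_unique(self.gene_ids, "gene id")
        if not np.isfinite(self.values).all():
            raise FormatError("expression matrix contains non-finite values")
        if self.layer_tag not in (LAYER_RAW, LAYER_NORMALIZED):
            raise FormatError(f"unknown layer_tag {self.layer_tag!r}")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, indices) -> "ExpressionMatrix":
        indices = np.asarray(indices, dtype=int)
        return ExpressionMatrix(
            self.values[indices],
            [self.cell_ids[i] for i in indices],
            list(self.gene_ids),
            self.layer_tag,
        )

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        col = {g: j for j, g in enumerate(self.gene_ids)}
        idx = [col[g] for g in genes]
        return ExpressionMatrix(
            self.values[:, idx], list(self.cell_ids), list(genes), self.layer_tag
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


@dataclass
class AnnotationTable:
    """Per-cell/spot binary malignancy label and domain assignment.

    ``labels`` are 0 (non-malignant) / 1 (malignant). ``domains`` name the
    tissue (single-cell) or slide (spatial) each observation comes from.
    Optional ``coords`` carry spatial spot positions (n x 2).
    """

    cell_ids: list[str]
    labels: np.ndarray
    domains: list[str]
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.domains = [str(d) for d in self.domains]
        _check_unique(self.cell_ids, "cell id")
        if not (len(self.cell_ids) == len(self.labels) == len(self.domains)):
            raise FormatError("annotation columns have unequal lengths")
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise FormatError(f"labels must be 0/1, found {sorted(bad)}")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=np.float64)
            if self.coords.shape != (len(self.cell_ids), 2):
                raise FormatError("coords must be an (n, 2) array")

    def __len__(self) -> int:
        return len(self.cell_ids)

    @property
    def domain_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for d in self.domains:
            seen.setdefault(d, None)
        return list(seen)

    def subset(self, indices) -> "AnnotationTable":
        indices = np.asarray(indices, dtype=int)
        return AnnotationTable(
            [self.cell_ids[i] for i in indices],
            self.labels[indices],
            [self.domains[i] for i in indices],
            None if self.coords is None else self.coords[indices],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"cell_id": self.cell_ids, "label": self.labels, "domain": self.domains}
        )
        if self.coords is not None:
            df["x"] = self.coords[:, 0]
            df["y"] = self.coords[:, 1]
        return df


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise FormatError(f"duplicate {what} {dup!r}")


# ---------------------------------------------------------------------------
# dense delimited matrices
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    header = Path(path).open().readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_dense_matrix(
    path, orientation: str = "cells_in_rows", layer_tag: str = LAYER_RAW
) -> ExpressionMatrix:
    """Read a dense delimited matrix; returns cells-in-rows regardless of the
    orientation on disk.

    The delimiter (comma or tab) is auto-detected from the header line.
    Identifier order of the source axes is preserved.
    """
    if orientation not in ("cells_in_rows", "genes_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    sep = _sniff_sep(path)
    # pandas silently renames duplicate header columns, so check them raw
    header_ids = path.open().readline().rstrip("\n").split(sep)[1:]
    if len(set(header_ids)) != len(header_ids):
        dup = [h for h in header_ids if header_ids.count(h) > 1]
        raise FormatError(f"duplicate identifiers in {path.name}: {dup[:5]}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].tolist()
        raise FormatError(f"duplicate identifiers in {path.name}: {dup[:5]}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise FormatError(
                f"non-numeric value in {path.name} at row {row!r}, column {col!r}"
            )
    if orientation == "genes_in_rows":
        df = df.T
    return ExpressionMatrix(
        df.to_numpy(dtype=np.float64),
        df.index.tolist(),
        df.columns.tolist(),
        layer_tag,
    )


def write_dense_matrix(matrix: ExpressionMatrix, path, sep: str = ",") -> None:
    """Write a dense matrix cells-in-rows with a header row of gene ids."""
    matrix.to_frame().to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# Matrix Market triplets
# ---------------------------------------------------------------------------

def _read_id_list(path) -> list[str]:
    with Path(path).open() as fh:
        # feature files may carry extra tab-separated columns; keep the first
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_mtx_triplet(
    matrix_path, genes_path, barcodes_path, layer_tag: str = LAYER_RAW
) -> ExpressionMatrix:
    """Read a Matrix Market coordinate matrix (genes x barcodes, the 10x
    convention) with sidecar identifier lists; returns the dense equivalent,
    cells-in-rows, with absent entries as zero.
    """
    mat = scipy.io.mmread(str(matrix_path))
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=np.float64)
    genes = _read_id_list(genes_path)
    barcodes = _read_id_list(barcodes_path)
    n_genes, n_cells = mat.shape
    if n_genes != len(genes):
        raise FormatError(
            f"matrix has {n_genes} rows but gene list has {len(genes)} entries"
        )
    if n_cells != len(barcodes):
        raise FormatError(
            f"matrix has {n_cells} columns but barcode list has {len(barcodes)} entries"
        )
    return ExpressionMatrix(mat.T, barcodes, genes, layer_tag)


def write_mtx_triplet(matrix: ExpressionMatrix, matrix_path, genes_path, barcodes_path) -> None:
    sparse = scipy.sparse.coo_matrix(matrix.values.T)
    scipy.io.mmwrite(str(matrix_path), sparse)
    Path(genes_path).write_text("".join(g + "\n" for g in matrix.gene_ids))
    Path(barcodes_path).write_text("".join(c + "\n" for c in matrix.cell_ids))


# ---------------------------------------------------------------------------
# annotations and predictions
# ---------------------------------------------------------------------------

def read_annotations(path) -> AnnotationTable:
    """Read a delimited annotation table with columns cell_id, label, domain
    (optionally x, y spot coordinates).

    Label tokens "malignant"/"non-malignant"/"1"/"0" are accepted
    case-insensitively and mapped to 1/0.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    required = {"cell_id", "label", "domain"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"annotation file missing columns: {sorted(missing)}")
    labels = []
    for raw in df["label"]:
        token = str(raw).strip().lower()
        if token not in LABEL_TOKENS:
            raise FormatError(
                f"unknown label token {raw!r}; allowed: "
                f"{sorted(set(LABEL_TOKENS))} (case-insensitive)"
            )
        labels.append(LABEL_TOKENS[token])
    coords = None
    if {"x", "y"} <= set(df.columns):
        coords = df[["x", "y"]].to_numpy(dtype=np.float64)
    return AnnotationTable(
        df["cell_id"].astype(str).tolist(),
        np.array(labels),
        df["domain"].astype(str).tolist(),
        coords,
    )


def write_annotations(ann: AnnotationTable, path, sep: str = "\t") -> None:
    ann.to_frame().to_csv(path, sep=sep, index=False)


def write_predictions(rows: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write prediction rows (cell_id, g_malignant, g_non_malignant, softmax,
    call) as a delimited file with header, preserving input order."""
    required = ["cell_id", "g_malignant", "g_non_malignant", "softmax", "call"]
    missing = [c for c in required if c not in rows.columns]
    if missing:
        raise FormatError(f"prediction rows missing columns: {missing}")
    rows.to_csv(path, sep=sep, index=False)


def read_predictions(path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sniff_sep(path))


# ---------------------------------------------------------------------------
# model archives
# ---------------------------------------------------------------------------

_ARCHIVE_ARRAYS = ("W1", "b1", "W2", "b2", "W3", "b3")


def save_model_archive(model, path) -> None:
    """Serialize a trained model (weights, feature list, preprocessing config,
    threshold, metadata) into a single archive file."""
    meta = {
        "version": ARCHIVE_VERSION,
        "preprocess": dict(model.preprocess),
        "threshold": float(model.threshold),
        "metadata": dict(model.metadata),
        "spec": model.spec.to_dict(),
    }
    arrays = {k: np.asarray(model.params[k]) for k in _ARCHIVE_ARRAYS}
    if model.feature_list is None:
        raise FormatError("cannot archive a model without a feature_list")
    buf = _io.BytesIO()
    np.savez(
        buf,
        meta_json=np.array(json.dumps(meta)),
        feature_list=np.array(model.feature_list, dtype=object),
        **arrays,
    )
    Path(path).write_bytes(buf.getvalue())


def load_model_archive(path):
    """Load a model archive written by :func:`save_model_archive`.

    Round-trips bitwise: predictions from the loaded model equal those of the
    saved one on the same platform.
    """
    from .model import ModelSpec, ModelState  # local import to avoid a cycle

    path = Path(path)
    if not path.exists():
        raise FormatError(f"model archive not found: {path}")
    with np.load(path, allow_pickle=True) as npz:
        names = set(npz.files)
        if "meta_json" not in names:
            raise FormatError("not a model archive: missing metadata block")
        meta = json.loads(str(npz["meta_json"]))
        if meta.get("version") != ARCHIVE_VERSION:
            raise FormatError(
                f"archive version {meta.get('version')!r} != supported {ARCHIVE_VERSION!r}"
            )
        missing = [k for k in (*_ARCHIVE_ARRAYS, "feature_list") if k not in names]
        if missing:
            raise FormatError(f"model archive missing fields: {missing}")
        params = {k: np.asarray(npz[k], dtype=np.float64) for k in _ARCHIVE_ARRAYS}
        feature_list = [str(g) for g in npz["feature_list"]]
    spec = ModelSpec.from_dict(meta["spec"])
    state = ModelState(
        spec=spec,
        params=params,
        feature_list=feature_list,
        preprocess=meta["preprocess"],
        threshold=float(meta["threshold"]),
        metadata=meta["metadata"],
    )
    state.validate_shapes()
    return state
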