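"""Labeled-matrix containers and TSV input/output.

The canonical on-disk format for every matrix (association, similarity,
prediction) is tab-separated UTF-8 text with a "." decimal separator: the
first row holds the column (disease) labels with an empty first cell, the
first column holds the row (miRNA) labels, and the body holds the values.
Rows are miRNAs, columns are diseases throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import LabelError, MatrixFormatError, MatrixValidationError

__all__ = [
    "AssociationMatrix",
    "SimilarityMatrix",
    "PredictionMatrix",
    "RankedList",
    "load_association_matrix",
    "save_association_matrix",
    "load_similarity_matrix",
    "save_similarity_matrix",
    "save_prediction_matrix",
    "load_dag_edges",
    "rank_candidates",
    "save_ranked_list",
]

#: maximum asymmetry accepted (and repaired by averaging) in a similarity file
SYMMETRY_TOL = 1e-8


def _check_unique(labels: Sequence[str], axis: str) -> None:
    seen = set()
    for lab in labels:
        if lab in seen:
            raise MatrixValidationError(f"duplicate {axis} label: {lab!r}")
        seen.add(lab)


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary bipartite adjacency Y: rows are miRNAs, columns are diseases."""

    values: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 1:
            raise MatrixValidationError(f"association matrix must be 2-D non-empty, got shape {v.shape}")
        if not np.isin(v, (0.0, 1.0)).all():
            bad = np.argwhere(~np.isin(v, (0.0, 1.0)))[0]
            raise MatrixValidationError(
                f"association entries must be 0 or 1; offending cell at row "
                f"{self.row_labels[bad[0]]!r}, column {self.col_labels[bad[1]]!r}"
            )
        if v.shape != (len(self.row_labels), len(self.col_labels)):
            raise MatrixValidationError("label counts do not match matrix shape")
        _check_unique(self.row_labels, "miRNA")
        _check_unique(self.col_labels, "disease")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "row_labels", tuple(self.row_labels))
        object.__setattr__(self, "col_labels", tuple(self.col_labels))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric similarity in [0, 1] with unit diagonal."""

    values: np.ndarray
    labels: tuple[str, ...]
    kind: str  # "miRNA" or "disease"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise MatrixValidationError(f"similarity matrix must be square, got shape {v.shape}")
        if v.shape[0] != len(self.labels):
            raise MatrixValidationError("label count does not match matrix shape")
        if self.kind not in ("miRNA", "disease"):
            raise MatrixValidationError(f"kind must be 'miRNA' or 'disease', got {self.kind!r}")
        if (v < 0).any() or (v > 1).any():
            raise MatrixValidationError("similarity entries must lie in [0, 1]")
        if np.abs(v - v.T).max(initial=0.0) > 1e-10:
            raise MatrixValidationError("similarity matrix is not symmetric (tolerance 1e-10)")
        if not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise MatrixValidationError("similarity diagonal must equal 1")
        _check_unique(self.labels, self.kind)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))


@dataclass(frozen=True)
class PredictionMatrix:
    """Real-valued score matrix with the same labeling as the association matrix."""

    values: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    provenance: tuple[str, ...] = ()

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.row_labels), len(self.col_labels)):
            raise MatrixValidationError("label counts do not match matrix shape")
        if not np.isfinite(v).all():
            raise MatrixValidationError("prediction matrix contains non-finite entries")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "row_labels", tuple(self.row_labels))
        object.__setattr__(self, "col_labels", tuple(self.col_labels))


@dataclass(frozen=True)
class RankedList:
    """Top candidate miRNAs for one disease: (miRNA, score, was_known) triples."""

    disease: str
    entries: tuple[tuple[str, float, bool], ...] = field(default_factory=tuple)

    def __post_init__(self):
        scores = [e[1] for e in self.entries]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise MatrixValidationError("ranked-list scores must be non-increasing")
        object.__setattr__(self, "entries", tuple(tuple(e) for e in self.entries))


def _read_labeled_tsv(path: str | Path) -> pd.DataFrame:
    # pandas mangles duplicate header labels; check them on the raw line
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    _check_unique(header, "column")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    except pd.errors.ParserError as e:
        raise MatrixFormatError(f"{path}: not a rectangular TSV matrix ({e})") from e
    if df.isna().any().any():
        r = df.index[df.isna().any(axis=1)][0]
        raise MatrixFormatError(f"{path}: missing value(s), e.g. in row {r!r} (ragged file?)")
    return df


def load_association_matrix(path: str | Path) -> AssociationMatrix:
    """Read a binary association matrix from labeled TSV.

    The header row carries disease labels (first cell empty), the first
    column miRNA labels, and every body cell must be exactly ``0`` or ``1``.
    """
    df = _read_labeled_tsv(path)
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j].strip()
            if cell not in ("0", "1"):
                raise MatrixFormatError(
                    f"{path}: non-binary cell {cell!r} at row {df.index[i]!r}, "
                    f"column {df.columns[j]!r}"
                )
            values[i, j] = float(cell)
    return AssociationMatrix(values, tuple(map(str, df.index)), tuple(map(str, df.columns)))


def _write_labeled_tsv(path, values, row_labels, col_labels, fmt) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t" + "\t".join(col_labels) + "\n")
        for lab, row in zip(row_labels, values):
            fh.write(lab + "\t" + "\t".join(fmt(x) for x in row) + "\n")


def save_association_matrix(Y: AssociationMatrix, path: str | Path) -> None:
    _write_labeled_tsv(path, Y.values, Y.row_labels, Y.col_labels, lambda x: str(int(x)))


def load_similarity_matrix(path: str | Path, kind: str) -> SimilarityMatrix:
    """Read a square labeled similarity TSV, enforcing symmetry.

    Asymmetry up to ``SYMMETRY_TOL`` (1e-8) is repaired by averaging the
    matrix with its transpose; anything larger is rejected.
    """
    df = _read_labeled_tsv(path)
    if df.shape[0] != df.shape[1]:
        raise MatrixFormatError(f"{path}: similarity matrix must be square, got {df.shape}")
    if list(df.index) != list(df.columns):
        raise MatrixValidationError(f"{path}: row labels must equal column labels in order")
    try:
        v = df.to_numpy(dtype=float)
    except ValueError as e:
        raise MatrixFormatError(f"{path}: non-numeric cell ({e})") from e
    if (v < 0).any() or (v > 1).any():
        bad = np.argwhere((v < 0) | (v > 1))[0]
        raise MatrixValidationError(
            f"{path}: entry {v[bad[0], bad[1]]} at ({df.index[bad[0]]!r}, "
            f"{df.columns[bad[1]]!r}) outside [0, 1]"
        )
    asym = np.abs(v - v.T).max(initial=0.0)
    if asym > SYMMETRY_TOL:
        raise MatrixValidationError(f"{path}: asymmetry {asym:.3g} exceeds tolerance {SYMMETRY_TOL}")
    v = (v + v.T) / 2.0
    np.fill_diagonal(v, 1.0)
    return SimilarityMatrix(v, tuple(map(str, df.index)), kind)


def _float_fmt(x: float) -> str:
    return repr(float(x))


def save_similarity_matrix(S: SimilarityMatrix, path: str | Path) -> None:
    _write_labeled_tsv(path, S.values, S.labels, S.labels, _float_fmt)


def save_prediction_matrix(P: PredictionMatrix, path: str | Path) -> None:
    _write_labeled_tsv(path, P.values, P.row_labels, P.col_labels, _float_fmt)


def load_dag_edges(path: str | Path) -> list[tuple[str, str]]:
    """Read a DAG edge list TSV with columns ``child_id`` and ``parent_id``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("child_id", "parent_id"):
        if col not in df.columns:
            raise MatrixFormatError(f"{path}: missing column {col!r}")
    return [(str(c), str(p)) for c, p in zip(df["child_id"], df["parent_id"])]


def rank_candidates(
    Y: AssociationMatrix,
    scores: PredictionMatrix,
    disease: str,
    top_n: int,
) -> RankedList:
    """Return the ``top_n`` miRNAs for one disease by descending score.

    Ties are broken by input row order; miRNAs already associated with the
    disease in ``Y`` are flagged ``was_known``.
    """
    if (Y.row_labels, Y.col_labels) != (scores.row_labels, scores.col_labels):
        raise LabelError("association and prediction matrices must share labels")
    if disease not in Y.col_labels:
        raise LabelError(f"unknown disease label: {disease!r}")
    if top_n < 1:
        raise MatrixValidationError("top_n must be positive")
    j = Y.col_labels.index(disease)
    if top_n > Y.n:
        warnings.warn(f"top_n={top_n} exceeds the number of miRNAs ({Y.n}); clipping")
        top_n = Y.n
    col = scores.values[:, j]
    order = np.argsort(-col, kind="stable")[:top_n]
    entries = tuple(
        (Y.row_labels[i], float(col[i]), bool(Y.values[i, j] == 1)) for i in order
    )
    return RankedList(disease, entries)


def save_ranked_list(rl: RankedList, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("rank\tmiRNA\tscore\tknown\n")
        for rank, (mirna, score, known) in enumerate(rl.entries, start=1):
            fh.write(f"{rank}\t{mirna}\t{_float_fmt(score)}\t{int(known)}\n")
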