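"""Reading, validation and binarization of class-labelled expression matrices.

The input contract is a CSV with one row per cell, one Boolean column per
gene, and a ``Class`` column holding the cell type or time point label used
to pick initial and target states for synthesis.  Raw counts are binarized
upstream of synthesis: a measurement above the limit of detection (0 for
read counts) maps to true, everything else to false.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import BinaryState, GeneSet, make_state
from .errors import BooleanParseError, FormatError

_TRUE = {"true", "1"}
_FALSE = {"false", "0"}
#: headers recognised as an optional leading cell-identifier column
_ID_HEADERS = {"", "cell", "name"}


@dataclass(frozen=True)
class Cell:
    cell_id: str
    class_label: str
    state: BinaryState


@dataclass(frozen=True)
class ExpressionDataset:
    genes: GeneSet
    cells: tuple

    def __init__(self, genes: GeneSet, cells: Iterable[Cell]):
        cells = tuple(cells)
        if not cells:
            raise ValueError("dataset must contain at least one cell")
        for c in cells:
            if len(c.state) != genes.n:
                raise ValueError(f"cell {c.cell_id!r}: state width != number of genes")
            if not c.class_label:
                raise ValueError(f"cell {c.cell_id!r}: empty class label")
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "cells", cells)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells)

    def __len__(self) -> int:
        return len(self.cells)

    def class_labels(self) -> list[str]:
        return sorted({c.class_label for c in self.cells})

    def matrix(self) -> np.ndarray:
        """cells x genes int (0/1) matrix in dataset order."""
        return np.array([c.state for c in self.cells], dtype=int)


@dataclass(frozen=True)
class ClassSpec:
    """Which class labels supply the initial (I) and target (F) states."""

    initial_classes: frozenset
    target_classes: frozenset

    def __init__(self, initial_classes: Iterable[str], target_classes: Iterable[str]):
        ini, tgt = frozenset(initial_classes), frozenset(target_classes)
        if not ini or not tgt:
            raise ValueError("initial and target class sets must be non-empty")
        if ini & tgt:
            warnings.warn(
                f"initial and target classes overlap: {sorted(ini & tgt)}", stacklevel=2
            )
        object.__setattr__(self, "initial_classes", ini)
        object.__setattr__(self, "target_classes", tgt)


def _parse_bool(token: str, row: int, column: str) -> int:
    t = str(token).strip().lower()
    if t in _TRUE:
        return 1
    if t in _FALSE:
        return 0
    raise BooleanParseError(
        f"row {row}, column {column!r}: cannot parse {token!r} as Boolean "
        "(accepted: true/false any case, 1/0)",
        row=row,
        column=column,
    )


def load_expression_csv(path) -> ExpressionDataset:
    """Load a cells x genes Boolean CSV with a Class column.

    Gene columns are every column that is neither the Class column nor an
    optional leading identifier column (header 'Cell', 'Name' or empty),
    in file order.  Cell ids fall back to the row index.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        raw_header = next(csv.reader(fh))
    seen = [h for h in raw_header if raw_header.count(h) > 1 and h.strip()]
    if seen:
        raise FormatError(f"{path}: duplicate gene column name(s): {sorted(set(seen))}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    columns = list(df.columns)
    lowered = [str(c).strip().lower() for c in columns]
    # pandas mangles empty/duplicate headers to 'Unnamed: k'
    lowered = ["" if c.startswith("unnamed:") else c for c in lowered]

    class_idx = [i for i, c in enumerate(lowered) if c == "class"]
    if not class_idx:
        raise FormatError(f"{path}: no 'Class' column found (case-insensitive)")
    if len(class_idx) > 1:
        raise FormatError(f"{path}: multiple 'Class' columns")
    class_col = columns[class_idx[0]]

    id_col = None
    if lowered and lowered[0] in _ID_HEADERS and class_idx[0] != 0:
        id_col = columns[0]

    gene_cols = [c for c in columns if c != class_col and c != id_col]
    if len(set(gene_cols)) != len(gene_cols):
        dupes = sorted({c for c in gene_cols if gene_cols.count(c) > 1})
        raise FormatError(f"{path}: duplicate gene column name(s): {dupes}")
    genes = GeneSet(gene_cols)

    cells = []
    for row_pos, (_, row) in enumerate(df.iterrows()):
        cid = str(row[id_col]) if id_col is not None else str(row_pos)
        label = str(row[class_col]).strip()
        bits = [_parse_bool(row[g], row_pos, g) for g in gene_cols]
        cells.append(Cell(cell_id=cid, class_label=label, state=make_state(bits)))
    return ExpressionDataset(genes=genes, cells=cells)


def write_expression_csv(ds: ExpressionDataset, path) -> None:
    """Write a dataset back in the same CSV dialect (round-trip safe)."""
    rows = []
    for c in ds.cells:
        rows.append([c.cell_id, c.class_label] + list(c.state))
    df = pd.DataFrame(rows, columns=["Cell", "Class"] + list(ds.genes.names))
    df.to_csv(path, index=False)


def discretize_counts(
    raw,
    limit_of_detection=0,
    gene_names: Optional[Sequence[str]] = None,
    class_labels: Optional[Sequence[str]] = None,
    cell_ids: Optional[Sequence[str]] = None,
) -> ExpressionDataset:
    """Binarize a cells x genes numeric matrix: value > limit -> true.

    ``limit_of_detection`` may be a scalar or a per-gene vector.  With the
    default limit of 0 this is the read-count rule (zero reads -> false,
    positive reads -> true); for qPCR pass the experimentally determined
    limit of detection per gene.
    """
    if isinstance(raw, pd.DataFrame):
        gene_names = gene_names or list(raw.columns)
        values = raw.to_numpy(dtype=float)
    else:
        values = np.asarray(raw, dtype=float)
        if gene_names is None:
            gene_names = [f"G{j}" for j in range(values.shape[1])]
    if not np.all(np.isfinite(values)):
        raise ValueError("expression values must be finite")
    limit = np.broadcast_to(np.asarray(limit_of_detection, dtype=float), values.shape[1:])
    if np.isscalar(limit_of_detection) and limit_of_detection == 0 and np.any(values < 0):
        raise ValueError("negative counts with the default limit of detection 0")
    binary = values > limit

    n_cells = values.shape[0]
    if class_labels is None:
        class_labels = ["all"] * n_cells
    if cell_ids is None:
        cell_ids = [str(i) for i in range(n_cells)]
    cells = [
        Cell(cell_id=str(cid), class_label=str(lbl), state=make_state(row))
        for cid, lbl, row in zip(cell_ids, class_labels, binary.astype(int))
    ]
    return ExpressionDataset(genes=GeneSet(gene_names), cells=cells)


@dataclass
class ValidationIssue:
    severity: str  # 'error' | 'warning' | 'info'
    code: str
    message: str


@dataclass
class ValidationReport:
    issues: list = field(default_factory=list)
    class_counts: dict = field(default_factory=dict)

    def add(self, severity: str, code: str, message: str) -> None:
        self.issues.append(ValidationIssue(severity, code, message))

    @property
    def errors(self):
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self):
        return [i for i in self.issues if i.severity == "warning"]

    def ok(self) -> bool:
        return not self.errors


def validate_dataset(ds: ExpressionDataset, spec: Optional[ClassSpec] = None) -> ValidationReport:
    """Sanity report: class membership, constant genes, conflicting duplicates."""
    report = ValidationReport()
    counts: dict = {}
    for c in ds.cells:
        counts[c.class_label] = counts.get(c.class_label, 0) + 1
    report.class_counts = counts

    if spec is not None:
        for label in sorted(spec.initial_classes):
            if counts.get(label, 0) == 0:
                report.add("error", "empty-initial-class", f"empty initial class {label!r}")
        for label in sorted(spec.target_classes):
            if counts.get(label, 0) == 0:
                report.add("error", "empty-target-class", f"empty target class {label!r}")

    mat = ds.matrix()
    for j, g in enumerate(ds.genes.names):
        col = mat[:, j]
        if col.min() == col.max():
            status = "expressed in every cell" if col[0] else "expressed in no cell"
            report.add("warning", "constant-gene", f"gene {g!r} {status}; its rule is unlearnable")

    by_state: dict = {}
    for c in ds.cells:
        by_state.setdefault(c.state, set()).add(c.class_label)
    for state, labels in by_state.items():
        if len(labels) > 1:
            report.add(
                "info",
                "conflicting-classes",
                f"identical state shared by classes {sorted(labels)}",
            )
    return report
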