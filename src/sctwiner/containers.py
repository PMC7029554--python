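"""Core containers and text I/O for expression matrices, annotations and signatures.

All matrices are cells-in-rows internally. Expression values are assumed to be
already normalized, log-scale and nonnegative; no library-size normalization is
performed here. Identifiers are case-sensitive opaque strings.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

CELL_TYPES = ("neoplastic", "normal")
LOCATIONS = ("core", "periphery")

#: (cell_type, location) pair, e.g. ("neoplastic", "core")
Population = tuple[str, str]

#: The three astrocyte populations used throughout: tumor-core neoplastic,
#: tumor-periphery neoplastic (infiltrating), tumor-periphery normal.
T_CORE: Population = ("neoplastic", "core")
T_PERIPHERY: Population = ("neoplastic", "periphery")
N_PERIPHERY: Population = ("normal", "periphery")

STUDY_POPULATIONS = (T_CORE, T_PERIPHERY, N_PERIPHERY)


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {kind} identifier: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Cells × genes log-expression matrix with aligned identifiers."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.cell_ids):
            raise ValueError(
                f"matrix has {n} rows but {len(self.cell_ids)} cell identifiers"
            )
        if p != len(self.gene_ids):
            raise ValueError(
                f"matrix has {p} columns but {len(self.gene_ids)} gene identifiers"
            )
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at cell {self.cell_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def subset_cells(self, cell_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cell_ids if c not in pos]
        if missing:
            raise KeyError(f"cells not in matrix: {missing[:5]}")
        idx = [pos[c] for c in cell_ids]
        return ExpressionMatrix(self.values[idx], list(cell_ids), list(self.gene_ids))

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {g: j for j, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        idx = [pos[g] for g in gene_ids]
        return ExpressionMatrix(self.values[:, idx], list(self.cell_ids), list(gene_ids))


@dataclass(frozen=True)
class CellAnnotation:
    """Cell type and tissue location of one cell."""

    cell_id: str
    cell_type: str
    location: str

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValueError(
                f"unknown cell_type {self.cell_type!r}; expected one of {CELL_TYPES}"
            )
        if self.location not in LOCATIONS:
            raise ValueError(
                f"unknown location {self.location!r}; expected one of {LOCATIONS}"
            )

    @property
    def population(self) -> Population:
        return (self.cell_type, self.location)


@dataclass
class LabelVector:
    """Binary class labels aligned to a list of cell identifiers."""

    values: np.ndarray
    cell_ids: list[str]
    class1_name: str = "class1"
    class0_name: str = "class0"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("labels must be 0/1")
        if len(self.values) != len(self.cell_ids):
            raise ValueError("labels and cell_ids differ in length")

    def counts(self) -> tuple[int, int]:
        """(#class1, #class0)."""
        n1 = int(self.values.sum())
        return n1, len(self.values) - n1


@dataclass
class GeneSignature:
    """An ordered gene list with per-gene selection statistics."""

    gene_ids: list[str]
    selection_frequency: np.ndarray | None = None
    direction: list[str] | None = None
    mean_weight: np.ndarray | None = None

    def __post_init__(self) -> None:
        _check_unique(self.gene_ids, "gene")
        if self.selection_frequency is not None:
            self.selection_frequency = np.asarray(self.selection_frequency, float)
            if np.any((self.selection_frequency < 0) | (self.selection_frequency > 1)):
                raise ValueError("selection frequencies must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"gene_id": self.gene_ids})
        if self.selection_frequency is not None:
            df["selection_frequency"] = self.selection_frequency
        if self.direction is not None:
            df["direction"] = self.direction
        if self.mean_weight is not None:
            df["mean_weight"] = self.mean_weight
        return df


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_expression(
    path: str | Path,
    format: str = "tsv",
    *,
    transpose: bool = False,
    row_labels: str | Path | None = None,
    col_labels: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from delimited text or MatrixMarket triplets.

    ``tsv``/``csv``: header row of gene identifiers, first column cell
    identifiers. ``mtx_triplet``: coordinate MatrixMarket file with sidecar
    one-identifier-per-line files for rows (cells) and columns (genes);
    defaults are ``<stem>_rows.txt`` / ``<stem>_cols.txt``. Set ``transpose``
    for genes-in-rows files.
    """
    path = Path(path)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
        for col in df.columns:
            if not pd.api.types.is_numeric_dtype(df[col]):
                bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
                row = bad.index[0] if len(bad) else "?"
                raise ValueError(
                    f"non-numeric expression value at row {row!r}, column {col!r}"
                )
        if transpose:
            df = df.T
        return ExpressionMatrix.from_dataframe(df)
    if format == "mtx_triplet":
        rows_path = Path(row_labels) if row_labels else path.with_name(path.stem + "_rows.txt")
        cols_path = Path(col_labels) if col_labels else path.with_name(path.stem + "_cols.txt")
        for p in (rows_path, cols_path):
            if not p.exists():
                raise FileNotFoundError(f"missing label sidecar file: {p}")
        mat = scipy.io.mmread(path)
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, float)
        row_ids = rows_path.read_text().split()
        col_ids = cols_path.read_text().split()
        if transpose:
            dense = dense.T
            row_ids, col_ids = col_ids, row_ids
        if dense.shape != (len(row_ids), len(col_ids)):
            raise ValueError(
                f"matrix shape {dense.shape} does not match label files "
                f"({len(row_ids)} rows, {len(col_ids)} columns)"
            )
        return ExpressionMatrix(dense, row_ids, col_ids)
    raise ValueError(f"unknown format {format!r}")


def write_expression(
    expr: ExpressionMatrix, path: str | Path, format: str = "tsv"
) -> None:
    path = Path(path)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        expr.to_dataframe().to_csv(path, sep=sep, float_format="%.17g")
        return
    if format == "mtx_triplet":
        sparse = scipy.sparse.coo_matrix(expr.values)
        scipy.io.mmwrite(path, sparse)
        path.with_name(path.stem + "_rows.txt").write_text(
            "\n".join(expr.cell_ids) + "\n"
        )
        path.with_name(path.stem + "_cols.txt").write_text(
            "\n".join(expr.gene_ids) + "\n"
        )
        return
    raise ValueError(f"unknown format {format!r}")


def read_annotations(
    path: str | Path, *, expr: ExpressionMatrix | None = None, sep: str = "\t"
) -> list[CellAnnotation]:
    """Read cell annotations (columns: cell_id, cell_type, location).

    If ``expr`` is given, every annotated cell must be present in the matrix.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"cell_id", "cell_type", "location"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation file must contain columns {sorted(required)}")
    ann = [
        CellAnnotation(r.cell_id, r.cell_type, r.location)
        for r in df.itertuples(index=False)
    ]
    _check_unique([a.cell_id for a in ann], "cell")
    if expr is not None:
        known = set(expr.cell_ids)
        missing = [a.cell_id for a in ann if a.cell_id not in known]
        if missing:
            raise ValueError(f"annotated cells absent from matrix: {missing[:5]}")
    return ann


def write_annotations(ann: Iterable[CellAnnotation], path: str | Path) -> None:
    df = pd.DataFrame(
        [(a.cell_id, a.cell_type, a.location) for a in ann],
        columns=["cell_id", "cell_type", "location"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_signature(path: str | Path) -> GeneSignature:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return GeneSignature(
        list(df["gene_id"]),
        df["selection_frequency"].to_numpy() if "selection_frequency" in df else None,
        list(df["direction"]) if "direction" in df else None,
        df["mean_weight"].to_numpy() if "mean_weight" in df else None,
    )


def write_signature(sig: GeneSignature, path: str | Path) -> None:
    sig.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# population handling
# ---------------------------------------------------------------------------


def subset_population(
    expr: ExpressionMatrix,
    ann: Sequence[CellAnnotation],
    population: Population | Iterable[Population],
) -> ExpressionMatrix:
    """Row-subset the matrix to the cells of one (or several) populations.

    Cell order of the input matrix is preserved; gene order unchanged.
    """
    pops = {population} if isinstance(population, tuple) and len(population) == 2 and isinstance(population[0], str) else set(population)
    wanted = {a.cell_id for a in ann if a.population in pops}
    keep = [c for c in expr.cell_ids if c in wanted]
    if not keep:
        raise ValueError(f"no cells belong to population(s) {sorted(pops)}")
    return expr.subset_cells(keep)


def make_labels(
    ann: Sequence[CellAnnotation],
    class1: Iterable[Population],
    class0: Iterable[Population],
    *,
    class1_name: str | None = None,
    class0_name: str | None = None,
) -> tuple[LabelVector, list[str]]:
    """Build a binary label vector from population sets.

    Returns the labels (covering only cells in either class, in annotation
    order) and the list of excluded cell ids.
    """
    class1, class0 = set(class1), set(class0)
    if class1 & class0:
        raise ValueError(f"class definitions overlap: {sorted(class1 & class0)}")
    cells, values, excluded = [], [], []
    for a in ann:
        if a.population in class1:
            cells.append(a.cell_id)
            values.append(1)
        elif a.population in class0:
            cells.append(a.cell_id)
            values.append(0)
        else:
            excluded.append(a.cell_id)
    if 1 not in values or 0 not in values:
        raise ValueError("both classes must be non-empty after intersection with data")

    def _name(pops: set[Population]) -> str:
        return "+".join(f"{t}-{l}" for t, l in sorted(pops))

    lv = LabelVector(
        np.array(values),
        cells,
        class1_name or _name(class1),
        class0_name or _name(class0),
    )
    return lv, excluded


def align_expression(expr: ExpressionMatrix, labels: LabelVector) -> ExpressionMatrix:
    """Subset/reorder the matrix rows to match the label vector's cells."""
    return expr.subset_cells(labels.cell_ids)
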