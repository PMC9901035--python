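"""Domain types and on-disk formats.

The package works with five objects: an expression matrix (cells x genes),
a ranked marker table (one ordered, weighted gene list per cell type), the
result of a one-vs-rest differential-expression run, the cell-type score
matrix that replaces a learned latent space, and the final per-cell
annotation. All on-disk formats are plain text: Matrix Market triplets with
barcode/feature TSVs, wide or long marker CSVs, and TSVs for labels, scores
and annotations.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

LAYER_COUNTS = "counts"
LAYER_LOGNORM = "lognorm"
LAYER_TRANSFORMED = "transformed"
_LAYERS = (LAYER_COUNTS, LAYER_LOGNORM, LAYER_TRANSFORMED)


def _as_str_array(ids: Sequence[str]) -> np.ndarray:
    return np.asarray(list(ids), dtype=object)


@dataclass
class ExpressionMatrix:
    """Cells x genes expression values with identifiers and a layer tag.

    ``values`` may be a scipy sparse matrix or a dense ndarray; rows are
    cells everywhere in this package. ``layer`` records what the entries
    mean: raw ``counts``, log-normalized expression (``lognorm``), or the
    output of a downstream transform (``transformed``).
    """

    values: sp.spmatrix | np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    batch: np.ndarray | None = None
    layer: str = LAYER_COUNTS

    def __post_init__(self) -> None:
        self.cell_ids = _as_str_array(self.cell_ids)
        self.gene_ids = _as_str_array(self.gene_ids)
        if sp.issparse(self.values):
            self.values = self.values.tocsr()
        else:
            self.values = np.asarray(self.values, dtype=float)
        n_cells, n_genes = self.values.shape
        if n_cells != len(self.cell_ids):
            raise ValueError(
                f"matrix has {n_cells} rows but {len(self.cell_ids)} cell ids"
            )
        if n_genes != len(self.gene_ids):
            raise ValueError(
                f"matrix has {n_genes} columns but {len(self.gene_ids)} gene ids"
            )
        for name, ids in (("cell", self.cell_ids), ("gene", self.gene_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name} identifiers")
        if self.layer not in _LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.batch is not None:
            self.batch = _as_str_array(self.batch)
            if len(self.batch) != n_cells:
                raise ValueError("batch labels do not match number of cells")
        if self.min() < 0:
            raise ValueError("expression values must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def min(self) -> float:
        v = self.values
        if sp.issparse(v):
            return float(v.data.min()) if v.nnz else 0.0
        return float(v.min()) if v.size else 0.0

    def dense(self) -> np.ndarray:
        v = self.values
        return np.asarray(v.todense()) if sp.issparse(v) else v

    def subset_cells(self, mask_or_idx) -> "ExpressionMatrix":
        idx = np.asarray(mask_or_idx)
        return ExpressionMatrix(
            self.values[idx],
            self.cell_ids[idx],
            self.gene_ids,
            batch=None if self.batch is None else self.batch[idx],
            layer=self.layer,
        )

    def subset_genes(self, mask_or_idx) -> "ExpressionMatrix":
        idx = np.asarray(mask_or_idx)
        return ExpressionMatrix(
            self.values[:, idx],
            self.cell_ids,
            self.gene_ids[idx],
            batch=self.batch,
            layer=self.layer,
        )

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass
class MarkerTable:
    """Ranked, weighted marker genes per cell type.

    ``genes[t]`` is the ordered marker list of cell type ``t`` (rank 1
    first); ``weights[t]`` holds the matching rank-discount weights in
    (0, 1]. Weights are attached by :func:`masi.marker_discovery.assign_weights`.
    """

    genes: dict = field(default_factory=dict)
    weights: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, gl in self.genes.items():
            gl = list(gl)
            if len(set(gl)) != len(gl):
                raise ValueError(f"duplicate gene in marker list of {t!r}")
            self.genes[t] = gl
            if t in self.weights:
                w = np.asarray(self.weights[t], dtype=float)
                if len(w) != len(gl):
                    raise ValueError(f"weights of {t!r} do not match gene count")
                self.weights[t] = w

    @property
    def cell_types(self) -> list:
        return list(self.genes)

    def n_markers(self, cell_type: str) -> int:
        return len(self.genes[cell_type])

    def all_genes(self) -> list:
        seen: dict = {}
        for gl in self.genes.values():
            for g in gl:
                seen.setdefault(g, None)
        return list(seen)

    def concat(self, other: "MarkerTable") -> "MarkerTable":
        """Union of cell types; column-wise concatenation of a second table."""
        dup = set(self.genes) & set(other.genes)
        if dup:
            raise ValueError(f"duplicate cell types in concatenation: {sorted(dup)}")
        genes = {**self.genes, **other.genes}
        weights = {**self.weights, **other.weights}
        return MarkerTable(genes=genes, weights=weights)


@dataclass
class RankedDEResult:
    """One differential-expression run: per cell type, a full gene ranking.

    ``tables[t]`` is a DataFrame with columns ``gene``, ``score`` and
    (for p-value-bearing methods) ``pvalue``/``qvalue``, sorted by
    descending score with lexicographic gene tie-break.
    """

    method: str
    tables: dict

    @property
    def cell_types(self) -> list:
        return list(self.tables)

    @property
    def has_pvalues(self) -> bool:
        return all("pvalue" in t.columns for t in self.tables.values())


@dataclass
class CellTypeScoreMatrix:
    """Cells x cell-types nonnegative scores: MASI's integration space."""

    scores: np.ndarray
    cell_ids: np.ndarray
    cell_type_names: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.cell_ids = _as_str_array(self.cell_ids)
        self.cell_type_names = _as_str_array(self.cell_type_names)
        if self.scores.shape != (len(self.cell_ids), len(self.cell_type_names)):
            raise ValueError("score matrix shape does not match identifiers")
        if self.scores.size and self.scores.min() < 0:
            raise ValueError("cell-type scores must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.scores.shape[0]

    def subset_cells(self, idx) -> "CellTypeScoreMatrix":
        idx = np.asarray(idx)
        return CellTypeScoreMatrix(
            self.scores[idx], self.cell_ids[idx], self.cell_type_names
        )


@dataclass
class AnnotationResult:
    """Per-cell consensus label, certainty and per-run mapped labels."""

    cell_ids: np.ndarray
    labels: np.ndarray
    certainty: np.ndarray | None = None
    tie_flag: np.ndarray | None = None
    mapped_labels: np.ndarray | None = None  # cells x clustering runs

    def __post_init__(self) -> None:
        self.cell_ids = _as_str_array(self.cell_ids)
        self.labels = _as_str_array(self.labels)
        n = len(self.cell_ids)
        if len(self.labels) != n:
            raise ValueError("labels do not match cell ids")
        if self.certainty is not None:
            self.certainty = np.asarray(self.certainty, dtype=float)
            if len(self.certainty) != n:
                raise ValueError("certainty does not match cell ids")
            if self.certainty.size and (
                self.certainty.min() < -1e-12 or self.certainty.max() > 1 + 1e-12
            ):
                raise ValueError("certainty must lie in [0, 1]")
        if self.tie_flag is None:
            self.tie_flag = np.zeros(n, dtype=bool)
        else:
            self.tie_flag = np.asarray(self.tie_flag, dtype=bool)


@dataclass
class MetricsReport:
    """Named evaluation values with the context each was computed in."""

    values: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def add(self, name: str, value: float, **meta) -> None:
        self.values[name] = float(value)
        if meta:
            self.metadata[name] = dict(meta)

    def to_dict(self) -> dict:
        return {
            "metrics": dict(self.values),
            "metadata": {k: dict(v) for k, v in self.metadata.items()},
        }


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _find_one(directory: Path, stems: Sequence[str], suffixes: Sequence[str]) -> Path:
    for stem in stems:
        for suf in suffixes:
            p = directory / f"{stem}{suf}"
            if p.exists():
                return p
    raise FileNotFoundError(
        f"none of {[s + x for s in stems for x in suffixes]} found in {directory}"
    )


def _read_id_column(path: Path) -> list:
    # 10x-style TSVs: first column is the identifier, no header
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def read_mtx(dir_path) -> ExpressionMatrix:
    """Read a Matrix Market directory (matrix + features/genes + barcodes TSVs).

    The on-disk orientation is inferred from the TSV lengths: whichever axis
    matches the barcode count becomes the cell axis. Returns a counts-layer
    matrix oriented cells x genes.
    """
    directory = Path(dir_path)
    mtx_path = _find_one(directory, ["matrix"], [".mtx"])
    genes_path = _find_one(directory, ["features", "genes"], [".tsv", ".txt"])
    barcodes_path = _find_one(directory, ["barcodes"], [".tsv", ".txt"])
    mat = sp.csr_matrix(mmread(str(mtx_path)))
    genes = _read_id_column(genes_path)
    barcodes = _read_id_column(barcodes_path)
    n_rows, n_cols = mat.shape
    if (n_rows, n_cols) == (len(barcodes), len(genes)):
        values = mat
    elif (n_rows, n_cols) == (len(genes), len(barcodes)):
        values = mat.T.tocsr()
    else:
        raise ValueError(
            f"matrix shape {mat.shape} matches neither "
            f"(cells={len(barcodes)}, genes={len(genes)}) nor its transpose"
        )
    return ExpressionMatrix(values, barcodes, genes, layer=LAYER_COUNTS)


def write_mtx(expr: ExpressionMatrix, dir_path) -> None:
    """Write genes x cells MTX plus features.tsv/barcodes.tsv (10x convention)."""
    directory = Path(dir_path)
    directory.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(
        expr.values.T if sp.issparse(expr.values) else sp.csr_matrix(expr.values).T
    )
    mmwrite(str(directory / "matrix.mtx"), mat)
    (directory / "features.tsv").write_text(
        "".join(f"{g}\n" for g in expr.gene_ids)
    )
    (directory / "barcodes.tsv").write_text(
        "".join(f"{c}\n" for c in expr.cell_ids)
    )


def read_dense(path, sep: str | None = None, layer: str = LAYER_COUNTS) -> ExpressionMatrix:
    """Read a dense cells-in-rows TSV/CSV with a header of gene names."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(df.to_numpy(dtype=float), df.index, df.columns, layer=layer)


_LONG_COLUMNS = {"cell_type", "gene", "rank"}


def read_marker_table(path, case_fold: bool = False) -> "MarkerTable":
    """Read a marker-gene table CSV and attach rank-discount weights.

    Two layouts are auto-detected from the header: the wide layout (one
    column per cell type, rows ordered by marker rank, ragged columns padded
    with empty cells) and a long layout with columns cell_type, gene, rank.
    """
    from .marker_discovery import assign_weights

    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    rows = [r for r in rows if any(c.strip() for c in r)]
    if not rows:
        raise ValueError(f"empty marker table file: {path}")
    header = [h.strip() for h in rows[0]]
    if {h.lower() for h in header} >= _LONG_COLUMNS:
        df = pd.read_csv(path)
        df.columns = [c.lower() for c in df.columns]
        df = df.sort_values(["cell_type", "rank"], kind="stable")
        genes = {
            str(t): [str(g) for g in grp["gene"]]
            for t, grp in df.groupby("cell_type", sort=False)
        }
    else:
        if len(set(header)) != len(header):
            raise ValueError("duplicate cell-type column names in marker table")
        genes = {t: [] for t in header}
        for row in rows[1:]:
            for t, cell in zip(header, row):
                cell = cell.strip()
                if cell:
                    genes[t].append(cell)
        genes = {t: gl for t, gl in genes.items() if gl}
    if case_fold:
        genes = {t: [g.upper() for g in gl] for t, gl in genes.items()}
    table = MarkerTable(genes=genes)
    return assign_weights(table)


def write_marker_table(table: MarkerTable, path) -> None:
    """Write the wide-CSV layout (cell types as columns, ranks as rows)."""
    types = table.cell_types
    depth = max((len(table.genes[t]) for t in types), default=0)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(types)
        for i in range(depth):
            writer.writerow(
                [table.genes[t][i] if i < len(table.genes[t]) else "" for t in types]
            )


def read_labels(path, expr: ExpressionMatrix | None = None) -> pd.Series:
    """Read a per-cell label TSV (columns cell_id, label).

    When ``expr`` is given, every labelled cell must exist in the matrix and
    every cell must be labelled; the result is aligned to ``expr.cell_ids``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("labels file needs at least two columns (cell_id, label)")
    labels = pd.Series(
        df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].to_numpy(), name="label"
    )
    if labels.index.duplicated().any():
        dup = labels.index[labels.index.duplicated()][0]
        raise ValueError(f"duplicate cell_id in labels file: {dup!r}")
    if expr is not None:
        known = set(expr.cell_ids)
        extra = [c for c in labels.index if c not in known]
        if extra:
            raise ValueError(f"cell_id {extra[0]!r} in labels file is absent from the matrix")
        missing = [c for c in expr.cell_ids if c not in labels.index]
        if missing:
            raise ValueError(f"cell {missing[0]!r} has no label")
        labels = labels.reindex(expr.cell_ids)
    return labels


def write_labels(cell_ids, labels, path, column: str = "label") -> None:
    pd.DataFrame({"cell_id": list(cell_ids), column: list(labels)}).to_csv(
        path, sep="\t", index=False
    )


def write_scores(matrix: CellTypeScoreMatrix, path) -> None:
    """Write the score matrix as a TSV: cell_id column plus one per cell type."""
    df = pd.DataFrame(
        matrix.scores, index=matrix.cell_ids, columns=matrix.cell_type_names
    )
    df.to_csv(path, sep="\t", index_label="cell_id")


def read_scores(path) -> CellTypeScoreMatrix:
    df = pd.read_csv(path, sep="\t", index_col="cell_id")
    return CellTypeScoreMatrix(df.to_numpy(dtype=float), df.index, df.columns)


def write_annotation(result: AnnotationResult, path) -> None:
    """Write per-cell annotation TSV: cell_id, label, certainty, tie_flag.

    Per-run mapped labels, when present, follow as ``mapped_0..mapped_k``.
    """
    data = {
        "cell_id": result.cell_ids,
        "label": result.labels,
        "certainty": (
            np.full(len(result.cell_ids), np.nan)
            if result.certainty is None
            else result.certainty
        ),
        "tie_flag": result.tie_flag.astype(int),
    }
    df = pd.DataFrame(data)
    if result.mapped_labels is not None:
        for j in range(result.mapped_labels.shape[1]):
            df[f"mapped_{j}"] = result.mapped_labels[:, j]
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_annotation(path) -> AnnotationResult:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "label": str})
    certainty = df["certainty"].to_numpy(dtype=float)
    if np.isnan(certainty).all():
        certainty = None
    mapped_cols = [c for c in df.columns if c.startswith("mapped_")]
    mapped = df[mapped_cols].to_numpy(dtype=object) if mapped_cols else None
    return AnnotationResult(
        cell_ids=df["cell_id"].to_numpy(),
        labels=df["label"].to_numpy(),
        certainty=certainty,
        tie_flag=df["tie_flag"].to_numpy(dtype=bool),
        mapped_labels=mapped,
    )
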