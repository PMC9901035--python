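"""Conversion of a log-normalized expression matrix to a cell-type score matrix.

Step 2 of the MASI workflow and its core idea: instead of learning a latent
space, each cell gets one nonnegative score per reference cell type, the
weighted sum of that type's marker-gene expression. Two variants exist:

* ``raw`` — the weighted marker sum on the log-normalized matrix;
* ``pliner`` — the same sum after suppressing each marker's expression
  below its X-percentile across cells (default X = 0.25) and applying a
  TF-IDF transform, which sharpens type-specific signal.

The resulting low-dimensional score matrix doubles as the integration
space: summing tens of markers per type averages out gene-level batch
distortion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_model import (
    LAYER_LOGNORM,
    LAYER_TRANSFORMED,
    CellTypeScoreMatrix,
    ExpressionMatrix,
    MarkerTable,
)

logger = logging.getLogger(__name__)


@dataclass
class ScoringConfig:
    mode: str = "pliner"
    percentile: float = 0.25
    use_weights: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("raw", "pliner"):
            raise ValueError(f"unknown scoring mode {self.mode!r}")
        if not 0 <= self.percentile < 1:
            raise ValueError("percentile must lie in [0, 1)")


def pliner_transform(
    expr: ExpressionMatrix, marker_genes, percentile: float = 0.25
) -> ExpressionMatrix:
    """Percentile suppression + TF-IDF on the marker-gene submatrix.

    Per marker gene g: values strictly below the linear-interpolation
    ``percentile`` quantile of g over all cells (zeros included) are set to
    0; the survivors are multiplied by idf(g) = ln(1 + n_cells / (1 + number
    of cells expressing g after suppression)). Marker genes absent from the
    matrix are dropped with a warning so cross-dataset gene-panel
    mismatches degrade gracefully.
    """
    if expr.layer != LAYER_LOGNORM:
        raise ValueError("pliner_transform expects a log-normalized matrix")
    gene_idx = expr.gene_index()
    present, missing = [], []
    for g in marker_genes:
        (present if g in gene_idx else missing).append(g)
    if missing:
        logger.warning(
            "%d marker genes absent from the matrix (e.g. %s)",
            len(missing),
            missing[:5],
        )
    if not present:
        raise ValueError("no marker gene overlaps the matrix gene_ids")
    cols = np.array([gene_idx[g] for g in present])
    sub = expr.dense()[:, cols].copy()
    n_cells = sub.shape[0]
    if percentile > 0:
        thresholds = np.quantile(sub, percentile, axis=0)  # linear interpolation
        sub[sub < thresholds[None, :]] = 0.0
    expressing = (sub > 0).sum(axis=0)
    idf = np.log1p(n_cells / (1.0 + expressing))
    sub *= idf[None, :]
    return ExpressionMatrix(
        sub,
        expr.cell_ids,
        np.asarray(present, dtype=object),
        batch=expr.batch,
        layer=LAYER_TRANSFORMED,
    )


def score_cells(
    expr: ExpressionMatrix,
    markers: MarkerTable,
    config: ScoringConfig | None = None,
) -> CellTypeScoreMatrix:
    """Weighted marker-sum score of every cell for every reference cell type."""
    config = config or ScoringConfig()
    if expr.layer != LAYER_LOGNORM:
        raise ValueError("score_cells expects a log-normalized matrix")
    types = markers.cell_types
    if not types or all(len(markers.genes[t]) == 0 for t in types):
        raise ValueError("empty marker table")
    if config.mode == "pliner":
        base = pliner_transform(expr, markers.all_genes(), config.percentile)
    else:
        base = expr
    dense = base.dense()
    gene_idx = base.gene_index()
    scores = np.zeros((expr.n_cells, len(types)))
    for j, t in enumerate(types):
        genes = markers.genes[t]
        weights = (
            markers.weights.get(t)
            if config.use_weights and t in markers.weights
            else np.ones(len(genes))
        )
        hit = [(gene_idx[g], w) for g, w in zip(genes, weights) if g in gene_idx]
        if not hit:
            logger.warning("no marker of cell type %r present in the matrix", t)
            continue
        idx = np.array([i for i, _ in hit])
        w = np.array([wt for _, wt in hit])
        scores[:, j] = dense[:, idx] @ w
    return CellTypeScoreMatrix(scores, expr.cell_ids, np.asarray(types, dtype=object))
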