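"""Consensus annotation on the cell-type score matrix (MACA-style).

Step 3 of the MASI workflow. Every cell first gets Label 1, the argmax of
its score vector. The score matrix is then deliberately over-clustered —
a k-nearest-neighbor graph (cosine distance) and Louvain community
detection over a grid of resolutions {3, 5, 7} and neighborhood sizes
{5, 10, 15} — giving nine partitions (Label 2s). Each cluster of each
partition is mapped to the majority Label 1 among its cells, and the final
annotation is the per-cell mode over the nine mapped labelings. Large
datasets are handled by splitting cells into blocks and annotating each
block independently (per-cell scoring is unaffected by blocking).

A certainty score C = 1 - D_1st/D_Nth contrasts each cell's Euclidean
distance to its nearest and farthest reference cell-type centroid; low
certainty flags cell types absent from the reference, which
``apply_unassigned`` relabels as "unassigned".
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import scipy.sparse as sp
from joblib import Parallel, delayed
from scipy.spatial.distance import cdist
from sklearn.neighbors import kneighbors_graph

from .celltype_scoring import ScoringConfig, score_cells
from .data_model import (
    LAYER_COUNTS,
    LAYER_LOGNORM,
    AnnotationResult,
    CellTypeScoreMatrix,
    ExpressionMatrix,
    MarkerTable,
)
from .preprocess import log_normalize

logger = logging.getLogger(__name__)

DEFAULT_RESOLUTIONS = (3.0, 5.0, 7.0)
DEFAULT_NEIGHBORS = (5, 10, 15)


@dataclass
class ClusteringEnsemble:
    """Partitions from the over-clustering grid: (resolution, k, labels)."""

    runs: list = field(default_factory=list)

    @property
    def n_runs(self) -> int:
        return len(self.runs)


@dataclass
class CentroidSet:
    """Mean reference score vector per reference cell type."""

    centroids: np.ndarray  # types x score dimensions
    cell_type_names: np.ndarray
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.cell_type_names = np.asarray(list(self.cell_type_names), dtype=object)
        if self.centroids.shape[0] != len(self.cell_type_names):
            raise ValueError("one centroid per cell type required")


@dataclass
class AnnotationConfig:
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    resolutions: tuple = DEFAULT_RESOLUTIONS
    n_neighbors: tuple = DEFAULT_NEIGHBORS
    graph_metric: str = "cosine"
    seed: int = 0


def label1_argmax(scores: CellTypeScoreMatrix):
    """Per-cell argmax label with first-column tie-break and a tie flag."""
    if scores.scores.shape[1] < 1:
        raise ValueError("score matrix has no cell-type columns")
    idx = np.argmax(scores.scores, axis=1)
    maxval = scores.scores[np.arange(scores.n_cells), idx]
    ties = (scores.scores == maxval[:, None]).sum(axis=1) > 1
    labels = scores.cell_type_names[idx]
    return labels, ties


def overcluster(
    scores: CellTypeScoreMatrix,
    resolutions=DEFAULT_RESOLUTIONS,
    n_neighbors=DEFAULT_NEIGHBORS,
    seed: int = 0,
    metric: str = "cosine",
) -> ClusteringEnsemble:
    """Louvain partitions of the score-space kNN graph over a parameter grid.

    Cells are processed in canonical (sorted cell_id) order so the result
    is invariant to the input cell ordering; partitions are returned in the
    input order.
    """
    n = scores.n_cells
    kmax = max(n_neighbors)
    if n < kmax + 1:
        raise ValueError(f"need at least {kmax + 1} cells for k={kmax} neighbors")
    canon = np.argsort(scores.cell_ids)
    inv = np.empty(n, dtype=int)
    inv[canon] = np.arange(n)
    X = scores.scores[canon]
    # cosine distance is undefined on zero vectors; nudge them onto a tiny sphere
    norms = np.linalg.norm(X, axis=1)
    if metric == "cosine" and (norms == 0).any():
        X = X.copy()
        X[norms == 0] = 1e-12
    runs = []
    run_idx = 0
    for k in n_neighbors:
        dist = kneighbors_graph(X, n_neighbors=k, metric=metric, mode="distance")
        dist.data = np.maximum(1.0 - dist.data, 0.0)  # similarity edge weights
        adj = dist.maximum(dist.T).tocoo()
        upper = adj.row < adj.col
        graph = ig.Graph(
            n=n, edges=list(zip(adj.row[upper], adj.col[upper])), directed=False
        )
        weights = list(adj.data[upper])
        for res in resolutions:
            # distinct seed per run keeps the ensemble's errors decorrelated
            ig.set_random_number_generator(random.Random(int(seed) + run_idx))
            membership = np.asarray(
                graph.community_multilevel(
                    weights=weights, resolution=float(res)
                ).membership
            )
            runs.append((float(res), int(k), membership[inv]))
            run_idx += 1
    return ClusteringEnsemble(runs=runs)


def _majority_map(cluster_labels, label1, scores: CellTypeScoreMatrix):
    """Map each cluster to its majority Label 1 (ties -> higher mean score)."""
    mapped = np.empty(len(cluster_labels), dtype=object)
    type_col = {t: j for j, t in enumerate(scores.cell_type_names)}
    for c in np.unique(cluster_labels):
        members = np.flatnonzero(cluster_labels == c)
        types, counts = np.unique(label1[members], return_counts=True)
        best = types[counts == counts.max()]
        if len(best) > 1:
            means = [scores.scores[members, type_col[t]].mean() for t in best]
            best = [best[int(np.argmax(means))]]
        mapped[members] = best[0]
    return mapped


def maca_consensus(
    label1, ensemble: ClusteringEnsemble, scores: CellTypeScoreMatrix
):
    """Per-cell mode of the cluster-mapped labels over all clustering runs.

    Ties in the per-cluster majority vote go to the tied type with the
    higher mean score within the cluster; ties in the per-cell mode go to
    the tied type with the higher score for that cell.
    """
    label1 = np.asarray(list(label1), dtype=object)
    n = len(label1)
    mapped = np.empty((n, ensemble.n_runs), dtype=object)
    for j, (_, _, part) in enumerate(ensemble.runs):
        if len(part) != n:
            raise ValueError("clustering run does not cover all cells")
        mapped[:, j] = _majority_map(part, label1, scores)
    type_col = {t: j for j, t in enumerate(scores.cell_type_names)}
    final = np.empty(n, dtype=object)
    for i in range(n):
        types, counts = np.unique(mapped[i].astype(str), return_counts=True)
        best = types[counts == counts.max()]
        if len(best) > 1:
            vals = [scores.scores[i, type_col[t]] for t in best]
            best = [best[int(np.argmax(vals))]]
        final[i] = best[0]
    return final, mapped


def compute_centroids(scores: CellTypeScoreMatrix, labels) -> CentroidSet:
    """Per-reference-type mean score vector (the reference's own score space)."""
    labels = np.asarray(list(labels), dtype=object)
    types = sorted(set(labels))
    cents = np.vstack(
        [scores.scores[labels == t].mean(axis=0) for t in types]
    )
    return CentroidSet(cents, types)


def certainty_score(cell_scores: np.ndarray, centroids: CentroidSet) -> np.ndarray:
    """C = 1 - D_1st/D_Nth per cell (0 when all centroid distances vanish)."""
    if centroids.centroids.shape[0] < 2:
        raise ValueError("certainty needs at least 2 centroids")
    arr = np.asarray(cell_scores, dtype=float)
    single = arr.ndim == 1
    d = cdist(np.atleast_2d(arr), centroids.centroids, metric="euclidean")
    d1 = d.min(axis=1)
    dn = d.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(dn > 0, 1.0 - d1 / dn, 0.0)
    return float(c[0]) if single else c


def _consensus_on_scores(
    scores: CellTypeScoreMatrix, config: AnnotationConfig
) -> AnnotationResult:
    label1, ties = label1_argmax(scores)
    ensemble = overcluster(
        scores,
        resolutions=config.resolutions,
        n_neighbors=config.n_neighbors,
        seed=config.seed,
        metric=config.graph_metric,
    )
    final, mapped = maca_consensus(label1, ensemble, scores)
    return AnnotationResult(
        cell_ids=scores.cell_ids,
        labels=final,
        tie_flag=ties,
        mapped_labels=mapped,
    )


def _ensure_lognorm(expr: ExpressionMatrix) -> ExpressionMatrix:
    if expr.layer == LAYER_COUNTS:
        return log_normalize(expr)
    if expr.layer == LAYER_LOGNORM:
        return expr
    raise ValueError("annotate expects a counts or log-normalized matrix")


def annotate(
    expr: ExpressionMatrix,
    markers: MarkerTable,
    config: AnnotationConfig | None = None,
    centroids: CentroidSet | None = None,
) -> AnnotationResult:
    """Score, over-cluster and consensus-label a dataset.

    Chains score_cells (PlinerScore by default) -> Label 1 argmax ->
    over-clustering -> MACA consensus; attaches certainty scores when a
    reference centroid set is supplied.
    """
    config = config or AnnotationConfig()
    expr = _ensure_lognorm(expr)
    scores = score_cells(expr, markers, config.scoring)
    result = _consensus_on_scores(scores, config)
    if centroids is not None:
        result.certainty = certainty_score(scores.scores, centroids)
    return result


def annotate_parallel(
    expr: ExpressionMatrix,
    markers: MarkerTable,
    n_batches: int = 1,
    n_workers: int = 1,
    config: AnnotationConfig | None = None,
    centroids: CentroidSet | None = None,
) -> AnnotationResult:
    """Block-parallel annotation: scoring is global, clustering per block.

    Cells are shuffled (seeded, re-based on sorted cell_ids so the blocking
    is independent of input order) and split into ``n_batches`` contiguous
    blocks; the consensus step runs independently per block and results are
    returned in the original cell order. With ``n_batches=1`` this is
    identical to :func:`annotate`.
    """
    config = config or AnnotationConfig()
    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    if n_batches > expr.n_cells:
        raise ValueError("n_batches exceeds the number of cells")
    expr = _ensure_lognorm(expr)
    scores = score_cells(expr, markers, config.scoring)
    canon = np.argsort(scores.cell_ids)
    perm = canon[np.random.default_rng(config.seed).permutation(expr.n_cells)]
    blocks = np.array_split(perm, n_batches)

    def _run(block_idx, block):
        cfg = AnnotationConfig(
            scoring=config.scoring,
            resolutions=config.resolutions,
            n_neighbors=config.n_neighbors,
            graph_metric=config.graph_metric,
            seed=config.seed + block_idx,
        )
        return _consensus_on_scores(scores.subset_cells(block), cfg)

    if n_workers > 1:
        partials = Parallel(n_jobs=n_workers)(
            delayed(_run)(i, b) for i, b in enumerate(blocks)
        )
    else:
        partials = [_run(i, b) for i, b in enumerate(blocks)]

    n = expr.n_cells
    labels = np.empty(n, dtype=object)
    ties = np.zeros(n, dtype=bool)
    n_runs = partials[0].mapped_labels.shape[1]
    mapped = np.empty((n, n_runs), dtype=object)
    for block, part in zip(blocks, partials):
        labels[block] = part.labels
        ties[block] = part.tie_flag
        mapped[block] = part.mapped_labels
    result = AnnotationResult(
        cell_ids=scores.cell_ids, labels=labels, tie_flag=ties, mapped_labels=mapped
    )
    if centroids is not None:
        result.certainty = certainty_score(scores.scores, centroids)
    return result


def apply_unassigned(result: AnnotationResult, threshold: float = 0.55) -> AnnotationResult:
    """Relabel cells with certainty below ``threshold`` as "unassigned".

    The default threshold 0.55 sits in the 0.5-0.6 band that retrieves
    unseen cell types without flagging the bulk of seen-type cells.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    if result.certainty is None:
        raise ValueError("certainty scores are not populated")
    labels = result.labels.copy()
    labels[result.certainty < threshold] = "unassigned"
    return AnnotationResult(
        cell_ids=result.cell_ids,
        labels=labels,
        certainty=result.certainty,
        tie_flag=result.tie_flag,
        mapped_labels=result.mapped_labels,
    )
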