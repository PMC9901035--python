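"""Annotation-accuracy and integration-quality metrics.

Accuracy and macro F1 grade label transfer against a ground truth; ARI and
NMI grade agreement between labelings when naming styles differ; the
cell-type silhouette (rescaled to [0, 1]) measures how well a
representation preserves cell-type structure; and the batch entropy mixing
score measures how well batches are mixed in local regions of a 2-D UMAP
of that representation. A good integration scores high on both silhouette
and entropy mixing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (
    adjusted_rand_score,
    f1_score,
    normalized_mutual_info_score,
    silhouette_score,
)
from sklearn.neighbors import NearestNeighbors

from .data_model import MetricsReport


def _check_lengths(a, b):
    a = np.asarray(list(a), dtype=object)
    b = np.asarray(list(b), dtype=object)
    if len(a) != len(b):
        raise ValueError(f"label vectors differ in length: {len(a)} vs {len(b)}")
    return a, b


def overall_accuracy(pred, truth) -> float:
    """Fraction of cells whose predicted label matches the truth."""
    pred, truth = _check_lengths(pred, truth)
    return float(np.mean(pred == truth))


def macro_f1(pred, truth) -> float:
    """Unweighted mean F1 over the cell types present in the truth.

    A truth class never predicted contributes F1 = 0, so minor cell types
    weigh as much as dominant ones.
    """
    pred, truth = _check_lengths(pred, truth)
    classes = np.unique(truth.astype(str))
    return float(
        f1_score(
            truth.astype(str),
            pred.astype(str),
            labels=classes,
            average="macro",
            zero_division=0,
        )
    )


def celltype_silhouette(representation, labels) -> float:
    """Mean silhouette S of cells under their type labels, rescaled (1+S)/2."""
    X = np.asarray(representation, dtype=float)
    labels = np.asarray(list(labels), dtype=object).astype(str)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs at least 2 distinct labels")
    s = silhouette_score(X, labels, metric="euclidean")
    return float((1.0 + s) / 2.0)


@dataclass
class RegionSampler:
    """How local regions are drawn for the batch entropy mixing score."""

    n_regions: int = 50
    region_size: int = 100
    seed: int = 0


def umap_embed(representation, seed: int = 0, n_neighbors: int = 15, min_dist: float = 0.1):
    """2-D UMAP of a representation (cosine metric), for mixing metrics and plots."""
    import umap  # deferred: heavy import

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2,
            metric="cosine",
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            random_state=seed,
        )
        return reducer.fit_transform(np.asarray(representation, dtype=float))


def batch_entropy_mixing(
    representation,
    batch_labels,
    sampler: RegionSampler | None = None,
    coords=None,
) -> float:
    """Mean normalized batch entropy over local regions of a 2-D embedding.

    Regions are the ``region_size`` nearest cells (in 2-D) of ``n_regions``
    sampled seed cells; per region E = -sum_i x_i ln x_i over batch
    proportions x_i, normalized by ln(number of batches) so the score lies
    in [0, 1]. 0 means every region is single-batch; 1 means uniform
    mixing. Pass ``coords`` to reuse a precomputed embedding (the UMAP step
    is otherwise computed here).
    """
    sampler = sampler or RegionSampler()
    batch_labels = np.asarray(list(batch_labels), dtype=object).astype(str)
    batches = np.unique(batch_labels)
    if len(batches) < 2:
        raise ValueError("batch entropy mixing needs at least 2 batches")
    n = len(batch_labels)
    if sampler.region_size > n:
        raise ValueError("region_size exceeds the number of cells")
    if coords is None:
        coords = umap_embed(representation, seed=sampler.seed)
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] != n:
        raise ValueError("coordinates do not match the number of cells")
    rng = np.random.default_rng(sampler.seed)
    seeds = rng.choice(n, size=min(sampler.n_regions, n), replace=False)
    nn = NearestNeighbors(n_neighbors=sampler.region_size).fit(coords)
    _, idx = nn.kneighbors(coords[seeds])
    entropies = []
    for region in idx:
        _, counts = np.unique(batch_labels[region], return_counts=True)
        x = counts / counts.sum()
        entropies.append(-np.sum(x * np.log(x)))
    return float(np.mean(entropies) / np.log(len(batches)))


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index between two labelings (pair-counting form)."""
    a, b = _check_lengths(labels_a, labels_b)
    return float(adjusted_rand_score(a.astype(str), b.astype(str)))


def nmi(labels_a, labels_b, average: str = "geometric") -> float:
    """Normalized mutual information I(P,T)/sqrt(H(P) H(T)) (or arithmetic)."""
    a, b = _check_lengths(labels_a, labels_b)
    return float(
        normalized_mutual_info_score(a.astype(str), b.astype(str), average_method=average)
    )


def evaluate_annotation(
    pred,
    truth,
    representation=None,
    batch_labels=None,
    sampler: RegionSampler | None = None,
    representation_name: str = "cell_type_scores",
) -> MetricsReport:
    """Assemble the full metric suite into a MetricsReport."""
    sampler = sampler or RegionSampler()
    report = MetricsReport()
    report.add("overall_accuracy", overall_accuracy(pred, truth), labels="truth")
    report.add("macro_f1", macro_f1(pred, truth), labels="truth")
    report.add("ari", ari(pred, truth), labels="truth")
    report.add("nmi", nmi(pred, truth), labels="truth", normalization="geometric")
    if representation is not None:
        report.add(
            "celltype_silhouette",
            celltype_silhouette(representation, truth),
            representation=representation_name,
        )
        if batch_labels is not None:
            report.add(
                "batch_entropy_mixing",
                batch_entropy_mixing(representation, batch_labels, sampler),
                representation=representation_name,
                n_regions=sampler.n_regions,
                region_size=sampler.region_size,
                normalized_by="ln(n_batches)",
            )
    return report
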