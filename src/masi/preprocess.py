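"""Normalization and the optional batch-standardization transform.

``log_normalize`` is the standard library-size normalization: each cell's
counts are divided by the cell total, multiplied by a scale factor (10 000
by default) and log1p-transformed. ``batchnorm_activation`` mimics the
batch-normalization + non-linear-activation layers of deep-learning
integrators without any weight learning: cells are shuffled into contiguous
mini-batches, each gene standardized within its mini-batch, and an
activation applied. It is OFF in the default annotation chain.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .data_model import (
    LAYER_COUNTS,
    LAYER_LOGNORM,
    LAYER_TRANSFORMED,
    ExpressionMatrix,
)


def log_normalize(expr: ExpressionMatrix, scale: float = 10000.0) -> ExpressionMatrix:
    """Library-size normalize counts: entry -> ln(1 + count/total * scale)."""
    if expr.layer != LAYER_COUNTS:
        raise ValueError(f"log_normalize expects a counts layer, got {expr.layer!r}")
    if scale <= 0:
        raise ValueError("scale factor must be positive")
    values = expr.values
    totals = np.asarray(values.sum(axis=1)).ravel()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        ids = ", ".join(map(str, expr.cell_ids[zero[:10]]))
        raise ValueError(f"cells with zero total count: {ids}")
    if sp.issparse(values):
        out = values.tocsr().astype(float, copy=True)
        row_scale = scale / totals
        out.data *= np.repeat(row_scale, np.diff(out.indptr))
        out.data = np.log1p(out.data)
    else:
        out = np.log1p(values / totals[:, None] * scale)
    return ExpressionMatrix(
        out, expr.cell_ids, expr.gene_ids, batch=expr.batch, layer=LAYER_LOGNORM
    )


_ACTIVATIONS = {
    "relu": lambda x: np.maximum(x, 0.0),
    "softplus": lambda x: np.logaddexp(0.0, x),
}


def batchnorm_activation(
    expr: ExpressionMatrix,
    minibatch_size: int = 256,
    activation: str = "relu",
    eps: float = 1e-6,
    seed: int = 0,
) -> ExpressionMatrix:
    """Per-mini-batch gene standardization followed by a non-linear activation.

    Cells are partitioned into contiguous mini-batches after a seeded
    shuffle; within each mini-batch every gene is standardized to mean 0 and
    (population) variance 1, guarded by ``eps``; the activation is applied
    elementwise and the original cell order restored.
    """
    if expr.layer != LAYER_LOGNORM:
        raise ValueError("batchnorm_activation expects a log-normalized layer")
    if minibatch_size < 2:
        raise ValueError("minibatch_size must be at least 2")
    if activation not in _ACTIVATIONS:
        raise ValueError(f"unknown activation {activation!r}")
    act = _ACTIVATIONS[activation]
    n = expr.n_cells
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    dense = expr.dense()[perm]
    out = np.empty_like(dense)
    for start in range(0, n, minibatch_size):
        block = dense[start : start + minibatch_size]
        mu = block.mean(axis=0)
        sd = np.sqrt(block.var(axis=0) + eps)
        out[start : start + minibatch_size] = act((block - mu) / sd)
    unperm = np.empty(n, dtype=int)
    unperm[perm] = np.arange(n)
    return ExpressionMatrix(
        out[unperm],
        expr.cell_ids,
        expr.gene_ids,
        batch=expr.batch,
        layer=LAYER_TRANSFORMED,
    )
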