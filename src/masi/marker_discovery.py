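"""Ensemble discovery of ranked, weighted cell-type markers from a reference.

Step 1 of the MASI workflow. Each registered differential-expression score
is run one-vs-rest per cell type, and the per-method rankings are combined
by one of two schemes:

* ``top_k_rra`` — compile each method's top-k genes and search a consensus
  ordering with robust rank aggregation (minimum Beta order-statistic
  p-value over the normalized ranks);
* ``significant_lancaster`` — keep only genes significant after BH
  correction of a Lancaster (weighted Fisher) combination of the methods'
  p-values.

The final ranked list per cell type gets rank-discount weights: the top
marker contributes 100% of its expression to the cell-type score, the
bottom marker 50%, linearly in between.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import LAYER_LOGNORM, ExpressionMatrix, MarkerTable, RankedDEResult

logger = logging.getLogger(__name__)

_EXACT_MAX = 8  # largest group size for exact rank-sum enumeration


@dataclass
class AggregationConfig:
    """How per-method rankings are combined into one marker table."""

    scheme: str = "top_k_rra"
    top_k: int = 20
    alpha: float = 0.05
    methods: list = field(default_factory=lambda: ["wilcoxon", "welch_t", "logfc", "cosg"])
    lancaster_weights: dict | None = None
    cosg_lambda: float = 0.5

    def __post_init__(self) -> None:
        if self.scheme not in ("top_k_rra", "significant_lancaster"):
            raise ValueError(f"unknown aggregation scheme {self.scheme!r}")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not self.methods:
            raise ValueError("at least one DE method is required")


# ---------------------------------------------------------------------------
# One-vs-rest DE scores
# ---------------------------------------------------------------------------


def _sorted_table(genes, score, pvalue=None) -> pd.DataFrame:
    df = pd.DataFrame({"gene": genes, "score": score})
    if pvalue is not None:
        df["pvalue"] = pvalue
        df["qvalue"] = multipletests(pvalue, method="fdr_bh")[1]
    # descending score, lexicographic gene tie-break
    df = df.sort_values(["score", "gene"], ascending=[False, True], kind="stable")
    return df.reset_index(drop=True)


def _wilcoxon(dense: np.ndarray, in_group: np.ndarray):
    """One-vs-rest rank-sum per gene: normal approximation with tie
    correction, exact enumeration when both groups have <= 8 cells."""
    n1 = int(in_group.sum())
    n2 = dense.shape[0] - n1
    if n1 <= _EXACT_MAX and n2 <= _EXACT_MAX:
        p = np.empty(dense.shape[1])
        z = np.empty(dense.shape[1])
        for j in range(dense.shape[1]):
            a, b = dense[in_group, j], dense[~in_group, j]
            if np.ptp(dense[:, j]) == 0:
                z[j], p[j] = 0.0, 1.0
                continue
            # exact enumeration is only valid without ties
            method = "exact" if len(np.unique(dense[:, j])) == dense.shape[0] else "asymptotic"
            res = stats.mannwhitneyu(
                a, b, alternative="two-sided", method=method, use_continuity=False
            )
            z[j] = res.statistic - n1 * n2 / 2.0
            p[j] = res.pvalue
        return z, p
    ranks = np.apply_along_axis(stats.rankdata, 0, dense)
    r1 = ranks[in_group].sum(axis=0)
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    # tie correction to the rank-sum variance
    tie_term = np.zeros(dense.shape[1])
    for j in range(dense.shape[1]):
        _, counts = np.unique(dense[:, j], return_counts=True)
        tie_term[j] = np.sum(counts**3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, (r1 - mu) / np.sqrt(var), 0.0)
    p = 2 * stats.norm.sf(np.abs(z))
    return z, np.clip(p, 0.0, 1.0)


def _welch_t(dense: np.ndarray, in_group: np.ndarray):
    t, p = stats.ttest_ind(dense[in_group], dense[~in_group], equal_var=False, axis=0)
    t = np.nan_to_num(t, nan=0.0)
    p = np.nan_to_num(p, nan=1.0)
    return t, p


def _logfc(dense: np.ndarray, in_group: np.ndarray):
    # difference of group means of log-normalized values
    return dense[in_group].mean(axis=0) - dense[~in_group].mean(axis=0), None


def rank_genes(
    expr: ExpressionMatrix,
    labels,
    method: str = "wilcoxon",
    cosg_lambda: float = 0.5,
) -> RankedDEResult:
    """One-vs-rest ranking of every gene for every cell type.

    ``wilcoxon`` and ``welch_t`` carry BH-adjusted p-values; ``logfc`` and
    ``cosg`` are score-only. Genes are sorted by descending score with
    lexicographic gene-id tie-break.
    """
    if expr.layer != LAYER_LOGNORM:
        raise ValueError("rank_genes expects a log-normalized matrix")
    labels = np.asarray(list(labels), dtype=object)
    if len(labels) != expr.n_cells:
        raise ValueError("labels do not match number of cells")
    types, counts = np.unique(labels, return_counts=True)
    small = types[counts < 2]
    if small.size:
        raise ValueError(f"cell types with fewer than 2 cells: {list(small)}")
    dense = expr.dense()
    genes = expr.gene_ids

    tables: dict = {}
    if method == "cosg":
        sims = _cosg_similarities(dense, labels, types)
        for i, t in enumerate(types):
            penalty = (sims**2).sum(axis=0) - sims[i] ** 2
            score = sims[i] - cosg_lambda * penalty
            tables[str(t)] = _sorted_table(genes, score)
    elif method in ("wilcoxon", "welch_t", "logfc"):
        fn = {"wilcoxon": _wilcoxon, "welch_t": _welch_t, "logfc": _logfc}[method]
        for t in types:
            score, p = fn(dense, labels == t)
            tables[str(t)] = _sorted_table(genes, score, p)
    else:
        raise ValueError(f"unknown DE method {method!r}")
    return RankedDEResult(method=method, tables=tables)


def _cosg_similarities(dense: np.ndarray, labels, types) -> np.ndarray:
    """Cosine similarity of each gene's expression vector with each type's
    one-hot indicator; rows are cell types."""
    gene_norm = np.linalg.norm(dense, axis=0)
    gene_norm[gene_norm == 0] = 1.0
    sims = np.empty((len(types), dense.shape[1]))
    for i, t in enumerate(types):
        mask = labels == t
        sims[i] = dense[mask].sum(axis=0) / (gene_norm * np.sqrt(mask.sum()))
    return sims


# ---------------------------------------------------------------------------
# Rank aggregation
# ---------------------------------------------------------------------------


def rra_rho(normalized_ranks: np.ndarray) -> float:
    """Robust-rank-aggregation score of one gene.

    ``normalized_ranks`` holds the gene's normalized rank in each of the m
    input lists (1.0 when absent). The score is the minimum over k of the
    Beta(k, m-k+1) CDF at the k-th smallest normalized rank — the p-value of
    observing that order statistic under m independent uniform ranks.
    """
    r = np.sort(np.asarray(normalized_ranks, dtype=float))
    m = len(r)
    k = np.arange(1, m + 1)
    return float(stats.beta.cdf(r, k, m - k + 1).min())


def _check_same_types(results) -> list:
    ref = results[0].cell_types
    for res in results[1:]:
        if set(res.cell_types) != set(ref):
            raise ValueError(
                f"cell-type sets differ between DE results: "
                f"{sorted(set(res.cell_types) ^ set(ref))}"
            )
    return ref


def aggregate_rra(results, top_k: int = 20) -> MarkerTable:
    """Combine per-method rankings via robust rank aggregation.

    Per cell type, each method contributes its top-k genes; the candidate
    set is their union. A gene's normalized rank under method j is its
    position in that method's full ranking divided by the number of ranked
    genes, or 1 when the gene is outside method j's top-k compilation.
    Genes are ordered by ascending RRA score min(rho * m, 1) and truncated
    to the top k, then weighted.
    """
    if not results:
        raise ValueError("at least one DE result is required")
    types = _check_same_types(results)
    m = len(results)
    genes_out: dict = {}
    for t in types:
        ranks_per_method = []
        candidates: set = set()
        for res in results:
            order = res.tables[t]["gene"].to_numpy()
            pos = {g: (i + 1) / len(order) for i, g in enumerate(order)}
            top = set(order[:top_k])
            candidates |= top
            ranks_per_method.append((pos, top))
        rows = []
        for g in candidates:
            r = [pos[g] if g in top else 1.0 for pos, top in ranks_per_method]
            rows.append((g, min(rra_rho(np.asarray(r)) * m, 1.0)))
        rows.sort(key=lambda x: (x[1], x[0]))
        genes_out[t] = [g for g, _ in rows[:top_k]]
    return assign_weights(MarkerTable(genes=genes_out))


def lancaster_combine(pvalues: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Lancaster combination of p-values along the last axis.

    T = sum_j Q(1 - p_j; df = w_j) with Q the chi-square quantile function;
    the combined p is the upper chi-square tail of T at df = sum w_j. With
    all weights 2 this is Fisher's method.
    """
    pvalues = np.asarray(pvalues, dtype=float)
    weights = np.asarray(weights, dtype=float)
    T = stats.chi2.isf(np.clip(pvalues, 0.0, 1.0), weights).sum(axis=-1)
    return stats.chi2.sf(T, weights.sum())


def aggregate_lancaster(
    results, alpha: float = 0.05, weights: dict | None = None
) -> MarkerTable:
    """Combine p-value-bearing methods via Lancaster; keep BH-significant genes.

    Score-only methods are dropped with a warning. Per cell type, every
    gene's per-method p-values are Lancaster-combined (default weight 2 per
    method, i.e. Fisher), BH-corrected across genes, and genes with FDR <
    alpha are retained in order of ascending combined p.
    """
    usable = [r for r in results if r.has_pvalues]
    skipped = [r.method for r in results if not r.has_pvalues]
    if skipped:
        logger.warning("excluding score-only methods from Lancaster: %s", skipped)
    if not usable:
        raise ValueError("Lancaster aggregation needs at least one p-value-bearing method")
    types = _check_same_types(usable)
    w = np.array(
        [2.0 if weights is None else float(weights.get(r.method, 2.0)) for r in usable]
    )
    genes_out: dict = {}
    for t in types:
        gene_names = usable[0].tables[t].set_index("gene").index
        # realign every method to the first method's gene universe
        pmat = np.column_stack(
            [
                r.tables[t].set_index("gene")["pvalue"].reindex(gene_names).to_numpy()
                for r in usable
            ]
        )
        combined = lancaster_combine(pmat, w)
        qvals = multipletests(combined, method="fdr_bh")[1]
        keep = qvals < alpha
        rows = sorted(
            zip(gene_names[keep], combined[keep]), key=lambda x: (x[1], x[0])
        )
        if not rows:
            logger.warning("no significant markers for cell type %r at alpha=%g", t, alpha)
        genes_out[t] = [g for g, _ in rows]
    return assign_weights(MarkerTable(genes=genes_out))


def assign_weights(table: MarkerTable) -> MarkerTable:
    """Attach rank-discount weights: w_1 = 1, w_i = 1 - (i/N)/2 for i >= 2.

    The top-ranked marker contributes 100% of its expression to the
    cell-type score and the rank-N marker 50%, decreasing linearly with
    rank in between.
    """
    for t, gl in table.genes.items():
        n = len(gl)
        if n == 0:
            table.weights[t] = np.empty(0)
            continue
        i = np.arange(1, n + 1, dtype=float)
        w = 1.0 - (i / n) * 0.5
        w[0] = 1.0
        table.weights[t] = w
    return table


def discover_markers(
    expr: ExpressionMatrix, labels, config: AggregationConfig | None = None
) -> MarkerTable:
    """Run the configured DE methods and aggregation scheme end to end."""
    config = config or AggregationConfig()
    results = [
        rank_genes(expr, labels, method=m, cosg_lambda=config.cosg_lambda)
        for m in config.methods
    ]
    if config.scheme == "top_k_rra":
        return aggregate_rra(results, top_k=config.top_k)
    return aggregate_lancaster(
        results, alpha=config.alpha, weights=config.lancaster_weights
    )
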