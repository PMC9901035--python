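# Methods

## Overview

`masi` annotates and integrates multi-batch single-cell RNA-seq data without
fitting a model. Given a labelled reference, it (1) discovers a ranked,
weighted marker-gene list per cell type by combining several one-vs-rest
differential-expression scores, (2) converts any log-normalized expression
matrix into a cells × cell-types *score matrix* — each entry a weighted sum
of that type's marker expression — and (3) assigns consensus labels by
over-clustering the score matrix and mapping clusters onto per-cell argmax
labels. The score matrix replaces a learned latent space: because each
column pools tens of genes, gene-level batch distortion partially averages
out, which is what makes the same low-dimensional space usable for both
annotation and batch integration.

## Preprocessing

Counts are library-size normalized: entry → ln(1 + count/total × s) with
scale factor s = 10 000. Cells with zero total are rejected (callers filter
first). No highly-variable-gene selection is performed: only marker genes
enter downstream computation.

An optional, non-learned transform mimicking the batch-normalization +
activation layers of deep-learning integrators is provided
(`batchnorm_activation`): cells are shuffled (seeded) into contiguous
mini-batches of 256, each gene standardized within its mini-batch
(population variance, eps = 1e-6 guard) and passed through relu (softplus
available). It trades cell-type structure for batch mixing and is therefore
OFF in the default chain; mini-batch size 256 is this package's choice, a
typical deep-learning batch size.

## Marker discovery

Four self-contained one-vs-rest scores are built in, covering the
rank-based, parametric, effect-size and similarity families:

* `wilcoxon` — rank-sum with normal approximation and tie correction,
  vectorized across genes; exact enumeration (no continuity correction)
  when both groups have ≤ 8 cells and no ties. Two-sided p, BH-adjusted
  within each type's test family.
* `welch_t` — unequal-variance t test, BH-adjusted.
* `logfc` — difference of group means of log-normalized values (score only).
* `cosg` — cosine similarity between a gene's expression vector and the
  type's one-hot indicator, penalized by λ·Σ(similarity to other types)²
  with λ = 0.5 (score only).

Additional scores can be supplied as `RankedDEResult` objects.

Two aggregation schemes combine the per-method rankings per cell type:

* **Robust rank aggregation** (default): each method contributes its top
  k = 20 genes; a candidate's normalized rank under method j is its position
  in j's full ranking divided by the number of ranked genes (1.0 when
  outside j's top-k). With sorted normalized ranks r₍₁₎ ≤ … ≤ r₍ₘ₎, the
  score is ρ = minₖ BetaCDF(r₍ₖ₎; k, m−k+1), Bonferroni-capped at min(ρ·m, 1);
  genes are kept in ascending order, truncated to k. Absent-gene rank 1.0 is
  the standard robust-rank-aggregation convention.
* **Lancaster combination**: per gene, T = Σⱼ Q(1−pⱼ; dfⱼ) with Q the
  chi-square quantile and per-method df (default 2, reducing to Fisher's
  method); combined p is the upper chi-square tail at Σdf. Genes with
  BH-FDR < α = 0.05 are retained, ordered by combined p. Score-only methods
  are excluded with a warning.

Ties everywhere break by descending score then lexicographic gene id, so
outputs are deterministic.

**Weights.** The rank-i marker of an N-long list receives
w₁ = 1 and wᵢ = 1 − (i/N)/2 for i ≥ 2: the top marker contributes 100% of
its expression to the type score, the bottom marker 50%. (Evaluating the
discount formula at i = 1 would give 1 − 1/(2N); the endpoints are taken as
authoritative and w₁ is pinned to 1.) Weighting matters when subtypes share
markers; with fully disjoint marker sets it mostly rescales columns.

## Cell-type scoring

`raw` mode: score(c, A) = Σ_{g ∈ markers(A)} w_g · x(c, g) on the
log-normalized matrix. `pliner` mode (default) first sharpens the marker
submatrix: per marker gene, values strictly below the linear-interpolation
X-quantile (X = 0.25) of that gene over *all* cells (zeros included) are
zeroed, then each gene is multiplied by idf = ln(1 + n_cells/(1 + cells
expressing it after suppression)). Document frequency is computed after
suppression; values exactly at the threshold survive. On sparse UMI data
the 25th percentile of a mostly-zero gene is 0, so suppression is often
inactive and the transform reduces to TF-IDF. Markers absent from the
matrix are dropped with a warning rather than an error, so cross-dataset
gene-panel mismatches degrade gracefully; the quantile is computed per
input matrix independently when reference and query are scored separately.

## Consensus annotation

Label 1 is the per-cell argmax of the score vector (ties → first column,
flagged). Label 2s come from over-clustering: for each neighborhood size
k ∈ {5, 10, 15}, a kNN graph on the score matrix (cosine distance,
similarity-weighted edges, symmetrized by union) is clustered with Louvain
at resolutions {3, 5, 7} — nine partitions. Cells are processed in sorted
cell-id order internally, so results are invariant to input ordering;
each run seeds the igraph RNG with seed + run index, so runs are
individually reproducible and their residual randomness is decorrelated.
Each cluster maps to the majority Label 1 among its cells (ties → the tied
type with the higher mean score within the cluster); the final label is the
per-cell mode over the nine mapped labelings (ties → the tied type with the
higher score for that cell).

For large data, cells are shuffled (seeded, re-based on sorted cell ids)
into contiguous blocks annotated independently, optionally on multiple
workers. Scoring is computed once globally — it is per-cell — so only the
clustering is blocked; one block reproduces the serial path exactly.

**Certainty and unassigned cells.** Reference centroids are the per-type
mean score vectors of the reference's own score matrix. For a cell with
nearest/farthest centroid Euclidean distances D_1st and D_Nth, the
certainty is C = 1 − D_1st/D_Nth ∈ [0, 1] (0 when all distances vanish).
Cells of a type present in the reference sit near one centroid (C → 1);
cells of an unseen type sit in the low-score bulk, roughly equidistant from
all centroids (C → 0). `apply_unassigned` relabels cells with C below a
threshold (default 0.55, the midpoint of the useful 0.5–0.6 band) as
"unassigned"; flagging is off unless requested.

## Evaluation metrics

* overall accuracy — matches / n.
* macro F1 — unweighted mean of per-class F1 over classes present in the
  truth (undefined F1 counted as 0), so minor types weigh as much as major
  ones.
* cell-type silhouette — mean silhouette S (Euclidean) of the
  representation under the truth labels, rescaled to (1+S)/2 ∈ [0, 1].
* batch entropy mixing — a 2-D UMAP of the representation (cosine metric,
  15 neighbors, min_dist 0.1, seeded); 50 seed cells are sampled and each
  region is its 100 nearest cells in 2-D; per region E = −Σ xᵢ ln xᵢ over
  batch proportions, averaged and divided by ln(#batches) so the score is
  comparable across batch counts. The sign convention (entropy negated so
  higher = better mixed) and the ln(c) normalization are this package's;
  sampler settings are recorded in the report metadata. A precomputed 2-D
  embedding can be supplied directly.
* ARI / NMI — pair-counting adjusted Rand index and mutual information
  normalized by the geometric mean √(H(P)H(T)) (arithmetic available),
  for comparing labelings with different naming styles or resolutions.

All metrics accept any representation, so external embeddings can be
evaluated with the same code.

## Synthetic data

`simulate_multibatch` draws UMI-like counts: gene g in a cell of type t and
batch b is negative binomial with mean base_mean · f^{1[g marker of t]} ·
b(batch, gene), where ln b ~ Normal(0, σ_b²) i.i.d. per (batch, gene),
fixed dispersion θ (variance μ + μ²/θ), followed by i.i.d. dropout.
Defaults — 5 types × 3 batches × 300 cells/type/batch, 1000 genes, 20
disjoint markers/type, f = 4, σ_b = 1, base_mean = 0.5, θ = 2, 10%
dropout — give sparse (~64% zeros), overdispersed counts with strong type
signal confounded by strong batch effects; a marker-overlap knob exists to
stress the weighting scheme. `hold_out_reference` removes one type from the
reference while the query keeps all cells, the setting for unseen-type
detection.

What the generator does *not* emulate: correlated (library- or
platform-wide) batch effects, mean–variance trends, cell-size variation,
doublets, ambient RNA, or manifold-shaped cell-type geometry. Two
consequences matter for interpreting test results. First, because batch
factors are independent per gene, summing 20 markers averages them out —
the score matrix mixes batches almost completely, likely more cleanly than
on real data. Second, because types are overlapping ellipsoidal blobs in
score space rather than tight manifolds, the over-clustering consensus has
no structure to exploit beyond the per-cell argmax and tracks it within a
fraction of a percent instead of improving on it; on real data the
cluster-level smoothing is what stabilizes noisy per-cell labels. Passing
tests therefore demonstrate correctness of the machinery and
batch-robustness of the score representation, not real-data accuracy.

Under the default conditions the full chain reaches ~95–97% accuracy;
residual errors are draw-dependent (a batch in which one type's markers all
draw low factors loses that type's score margin, which no labelling step
can recover), so recovery checks average over a few generator seeds.

## Numerical choices

* Population variance with eps guard in the mini-batch transform.
* Suppression threshold comparison is strict (<); quantiles use numpy's
  linear interpolation.
* Cosine distance on all-zero score vectors is undefined; such cells are
  nudged by 1e-12 before graph construction.
* Lancaster at p = 1 contributes Q(0) = 0; at p = 0 the combined p is 0.
* Louvain is igraph's multilevel implementation; determinism comes from
  seeding igraph's RNG per run.
* All randomness (simulation, shuffles, clustering, UMAP, region sampling)
  flows from explicit integer seeds; the CLI derives per-stage seeds from
  one global seed by fixed offsets.

## Limitations

* Annotation quality is bounded by reference quality and marker
  transferability; types absent from the reference can only be flagged, not
  named.
* The certainty score is purely geometric in score space; correlated
  subtypes compress the D_1st/D_Nth contrast and can blur the unassigned
  threshold.
* Lancaster aggregation uses only p-value-bearing methods; with the default
  method set that means half the scores are ignored under that scheme.
* The batch-entropy score inherits UMAP's stochastic layout; compare values
  only at identical sampler settings and seeds.
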