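# masi

Marker-assisted standardization and integration of single-cell RNA-seq
data: a fast, model-free pipeline for reference-based cell-type annotation
and batch integration.

## The problem

Single-cell datasets of the same tissue produced by different labs disagree
in cell-type naming, annotation resolution and batch structure. Most tools
that transfer labels or remove batch effects fit a large model (SVMs,
neural networks, matrix factorizations), which is expensive and opaque.
`masi` instead leans on the one thing that transfers between studies:
marker genes. It converts expression into a **cell-type score matrix** and
does everything — annotation, integration, uncertainty flagging — in that
small, interpretable space. Intended users are computational biologists who
have a well-annotated reference and want to standardize labels across query
datasets without training anything.

## The method

1. **Marker discovery.** One-vs-rest differential-expression scores
   (Wilcoxon rank-sum, Welch t, logFC, COSG) are computed per cell type on
   the reference and combined either by robust rank aggregation over each
   method's top-k genes — gene score ρ = minₖ BetaCDF(r₍ₖ₎; k, m−k+1) over
   its sorted normalized ranks — or by Lancaster (weighted Fisher) p-value
   combination with BH-FDR filtering.
2. **Weighting.** The rank-i marker of N gets weight w₁ = 1,
   wᵢ = 1 − (i/N)/2: the top marker contributes 100% of its expression to
   the type score, the bottom one 50%.
3. **Scoring.** score(c, A) = Σ_{g ∈ markers(A)} w_g · x(c, g) on
   log-normalized expression; the default PlinerScore variant first zeroes
   marker values below their 25th percentile across cells and applies a
   TF-IDF transform. Summing tens of markers per type averages out
   gene-level batch distortion, so the score matrix doubles as an
   integration space.
4. **Consensus annotation.** Each cell's Label 1 is the argmax of its
   score vector; the score matrix is over-clustered (cosine kNN graph,
   k ∈ {5, 10, 15}; Louvain at resolutions {3, 5, 7}); each cluster maps to
   its majority Label 1 and the final label is the per-cell mode over the
   nine runs. Certainty C = 1 − D_1st/D_Nth (nearest vs farthest reference
   centroid) flags cells of types unseen in the reference: those below a
   threshold (default 0.55) can be relabelled "unassigned".

Evaluation metrics from the same tradition are included: overall accuracy,
macro F1, cell-type silhouette (1+S)/2, batch entropy mixing on a 2-D UMAP,
ARI and NMI. A negative-binomial multi-batch simulator with known markers
and log-normal per-(batch, gene) distortions provides ground-truthed data
for all of it. Details, assumptions and limitations: `docs/methods.md`.

## Worked example

```python
import numpy as np
from masi import (RegionSampler, SimulationConfig, annotate, discover_markers,
                  evaluate_annotation, log_normalize, score_cells,
                  simulate_multibatch)

cfg = SimulationConfig(n_types=3, n_cells_per_type_per_batch=100, n_batches=2,
                       n_genes=400, n_markers_per_type=10, seed=0)
expr, truth = simulate_multibatch(cfg)          # 600 cells, 2 batches
lognorm = log_normalize(expr)
markers = discover_markers(lognorm, truth.cell_types)
print("markers for type_0:", markers.genes["type_0"][:5], "...")
print("weights:", np.round(markers.weights["type_0"][:5], 3), "...")

scores = score_cells(lognorm, markers)          # 600 x 3 score matrix
result = annotate(expr, markers)                # consensus labels
report = evaluate_annotation(result.labels, truth.cell_types,
                             representation=scores.scores,
                             batch_labels=truth.batches,
                             sampler=RegionSampler(n_regions=30,
                                                   region_size=50, seed=0))
for k, v in report.values.items():
    print(f"{k:>22s}  {v:.3f}")
```

Output:

```
markers for type_0: ['gene_0001', 'gene_0000', 'gene_0005', 'gene_0007', 'gene_0003'] ...
weights: [1.    0.95  0.925 0.9   0.875] ...
      overall_accuracy  0.893
              macro_f1  0.893
                   ari  0.705
                   nmi  0.629
   celltype_silhouette  0.673
  batch_entropy_mixing  0.947
```

The discovered markers are the genes planted for `type_0` (ranks within the
list vary with noise), and their weights decay from 1.0 toward 0.5.
Accuracy and macro F1 say ~89% of cells get their true type on this small,
noisy fixture; silhouette 0.67 means cell-type structure is preserved in
score space while batch-entropy 0.95 means the two batches are nearly
perfectly mixed there — the balance the score representation is for. ARI
and NMI compare the predicted and true partitions (useful when label
vocabularies differ).

## Command line

Every step is also a subcommand (`masi simulate | markers | score |
annotate | evaluate | run`):

```sh
masi simulate --seed 0 -o data/
masi markers --ref data/ --labels data/labels.tsv -o markers.csv
masi annotate --ref data/ --ref-labels data/labels.tsv \
              --query data/ --markers markers.csv -o annotation.tsv
masi run --config run.yaml -o out/      # markers -> scores -> annotation -> report
```

`run` writes `markers.csv`, `scores.tsv`, `annotation.tsv` and
`report.json`, and is byte-reproducible for a fixed config and seed.

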