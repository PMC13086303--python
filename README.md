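# coexfp

Co-expression-based automated gene function prediction with cross-validated
feedforward neural networks.

`coexfp` predicts which genes participate in curated biological processes
(e.g., Gene Ontology slim terms in *Saccharomyces cerevisiae*) from a
compendium of gene-expression datasets. It is aimed at computational
biologists who want testable, per-process gene rankings from co-expression
alone, and at methodologists studying how supervised function predictors
behave under annotation noise.

## Method

For every unordered gene pair (x, y) and every dataset d, the pipeline
computes the Pearson correlation ρ over the conditions observed for both
genes, Fisher-transforms it, f = ½·log((1+ρ)/(1−ρ)), and standardizes it
with moments (μ_f, σ_f) estimated from up to 200,000 random pairs of the same
dataset:

    z_xy^(d) = (f_xy^(d) − μ_f) / σ_f

Stacking z across the D datasets gives the pair's feature vector. Genes
annotated to ≥ 1 predicted term (each term needs ≥ 10 annotated genes) form
the gold standard; a pair is **related** if co-annotated to a predicted term
and **unrelated** if both genes have known, different functions (their
smallest shared term covers ≥ 10% of the genome, or they share none). Gold
genes are split into 4 folds; pairs never straddle a fold's train/test
boundary, so no gene leaks between training and testing.

Each fold trains a ReLU multilayer perceptron (default 500–200–100 hidden
units, logistic outputs, one output per term) with classical SGD (learning
rate 0.01, momentum 0.9), class-balanced minibatches of 25 related + 25
unrelated pairs, binary cross-entropy averaged over terms, and weights drawn
from U[−k, k], k = 1/fan-in. A pair's final score averages exactly the folds
that held out at least one of its genes. Per term, these scores form a
complete weighted **functional relationship graph**, and each genome gene is
ranked by its mean edge weight to the term's annotated genes ("guilt by
association"). Evaluation covers pairwise and single-gene ROC AUC,
convex-hulled precision–recall, per-term overfitting (train − test AUC),
the KL divergence D_KL(T‖B) between a term's average-z distribution T and
the training background B, and a contaminated-negative analysis comparing
two annotation snapshots.

A synthetic-data module generates compendia with planted, strength-graded
co-regulated modules and an annotation-drift operator, so the whole pipeline
is testable end to end without external data.

## Worked example

```bash
coexfp init-config --profile demo -o demo.yaml --output-dir demo_out --seed 1
coexfp run all -c demo.yaml
```

This simulates a 150-gene compendium (6 datasets, 8 terms with planted
co-regulation strengths 0.1–0.9), trains the 4 folds, builds the per-term
graphs and rankings, and writes `demo_out/performance.csv`:

```
term  train_auc  test_auc  overfitting  single_gene_auc  kl_divergence
 T00      0.622     0.506        0.117            0.689          0.515
 T04      0.965     0.882        0.083            1.000          2.562
 T07      0.985     0.981        0.004            1.000          2.802
```

(excerpt). Reading it: the term planted at strength 0.9 (`T07`) is recovered
almost perfectly — held-out pairwise AUC 0.98 and a single-gene ranking that
places every annotated gene above every negative (AUC 1.0) — while the
near-noise term `T00` stays at chance. `kl_divergence` quantifies how far a
term's co-expression departs from the background; across the eight terms it
correlates strongly with held-out AUC (r ≈ 0.92, p ≈ 0.001), i.e., terms
whose genes are co-regulated are the predictable ones. With
`flip_rate > 0` the training snapshot is drifted and
`demo_out/contamination.csv` shows that genes whose true annotation was
withheld still rank near the top (median relative rank ≈ 0.95 vs ≈ 0.45 for
genuine negatives) — the model sees through the mis-annotation.

`coexfp compare` evaluates external ranking tables (gene, per-model scores,
old/new labels coded 1/−1/0) under both label sets and runs right-tailed
Kolmogorov–Smirnov tests between models' contaminated-negative ranks.

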