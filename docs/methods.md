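# Methods

This note documents the models and procedures implemented in `coexfp`, the
choices made where the design was open, and what the synthetic study
conditions do and do not demonstrate.

## Pairwise co-expression features

For a gene pair within one dataset, the Pearson correlation is computed over
the conditions observed for *both* genes (pairwise-complete). A correlation
is flagged uncomputable when fewer than `min_overlap = 3` shared conditions
remain (the minimum for a non-degenerate correlation) or either restricted
vector has zero variance. Correlations are Fisher-transformed with |ρ|
clamped to 1 − 10⁻⁶ so identical profiles (which occur in noise-free
synthetic data) stay finite.

Per dataset, the transform's mean μ_f and standard deviation σ_f are
estimated from up to 200,000 random unordered pairs (`calibration_pairs`);
when the pair universe is smaller, every pair is used, making the fit
exhaustive and seed-independent. Calibration uses its own seeded generator
(`seeds.calib`), separate from training randomness, so normalizers are
reproducible in isolation. The resulting z-scores are approximately standard
normal within each dataset, which is what makes values comparable across
datasets of very different condition counts.

Uncomputable pair–dataset entries (gene absent, low overlap, zero variance)
contribute the fill value z = 0 — the normalized mean, i.e. "no evidence" —
keeping feature vectors fixed-length without imputation machinery. Feature
matrices are computed per dataset; a `low_memory` mode recomputes batches on
demand so the all-pairs table is never required in memory at genome scale.

## Gold standard and cross-validation

Predicted terms are the slim terms with at least `min_annotations = 10`
annotated genes, in lexicographic order persisted to disk (output-neuron
order must be stable across folds and runs). Pair labeling: *related* =
co-annotated to ≥ 1 predicted term; *unrelated* = both genes annotated
(functions known) and functions different — either no shared term at all, or
a smallest shared term covering ≥ `genome_fraction = 10%` of the genome;
everything else is *excluded*. Two open choices here are configurable: the
reference collection for the smallest-shared-term test defaults to the full
annotation vocabulary (falling back to the slim when that is all there is),
and two gold genes sharing no term at all are classed unrelated, on the
reasoning that both functions are known and differ.

Gold genes are partitioned into `k_folds = 4` near-equal folds by seeded
shuffle and round-robin. A fold's training pairs draw both genes from the
other folds and its testing pairs both genes from the held-out fold, so the
train and test gene sets are disjoint by construction — the leakage control
that the test suite asserts directly.

## Network and training

The network is a plain ReLU multilayer perceptron, default hidden sizes
(500, 200, 100) at full scale, logistic output per term. Implementation is
pure numpy with hand-written backpropagation; this keeps training exactly
reproducible from the seeds and removes any GPU/toolkit dependency.

- **Initialization.** Every weight *and bias* of a layer is drawn i.i.d.
  from U[−k, k] with k = 1/fan-in. This linear (not √) scaling is the
  method's stated convention and is implemented as such; it is noticeably
  smaller than the common 1/√fan-in initialization for wide layers, which
  mainly slows early training.
- **Loss.** Binary cross-entropy, treated as one independent binary task
  per term, computed in the stable logits form and reduced by the mean over
  terms and over the batch, so the loss scale is independent of term count.
- **Minibatches.** 50 pairs: 25 sampled uniformly *with replacement* from
  the related pool and 25 from the unrelated pool. Replacement keeps the
  25/25 balance well defined even for very small pools, and the unrelated
  pool typically dwarfs the related one.
- **Optimizer.** Classical (non-Nesterov) SGD with momentum 0.9 and
  learning rate 0.01: v ← 0.9·v + g, w ← w − 0.01·v.
- **Stopping.** A fixed iteration budget (default 600,000) rather than a
  convergence criterion; the loss trace is logged every `log_every`
  iterations so convergence can be inspected after the fact.

Feature vectors are not standardized further — they are already z-scores.

## Aggregation, graphs, rankings

A pair's final per-term score is the unweighted mean over the folds that
held out at least one of its genes (one fold when both genes share it).
Pairs with an uncharacterized gene were in no fold's training data and
average all folds — including mixed gold/uncharacterized pairs, by the
method's literal rule, even though the gold gene trained three of the four
folds. Per term, scores become edge weights of a complete graph; edge lists
are written as per-term TSV shards with a manifest, with optional
storage-pruning of near-zero edges (off by default; rankings use all edges).

A gene's score for a term is the mean weight of its edges to the term's
annotated genes, excluding itself when annotated; the annotated set comes
from the *training-time* snapshot — newer snapshots only ever re-label an
existing ranking for evaluation. Ties break by gene identifier. Relative
rank maps position to (0, 1] with 1.0 at the top, so "relative rank in
[0.8, 1.0]" reads as "top 20% of predictions".

## Evaluation statistics

Pairwise per-term AUC samples up to `max_pos = 10,000` co-annotated pairs
and `neg_factor = 10` times as many pairs where *neither* gene is annotated
to the term, from within the fold's train or test gene set respectively, and
averages the per-fold AUCs (unweighted). AUC is the tie-corrected
Mann–Whitney probability (scikit-learn's implementation; the tests pin it to
brute-force concordant-pair counting). Overfitting per term is train AUC −
test AUC.

D_KL(T‖B) uses average z-scores (across datasets, fills included) of
`kl_samples` pairs sampled with replacement from the term's co-annotated
pairs (T) and from all classified training pairs (B). Both histograms share
100 equal-width bins spanning the pooled range with one pseudo-count per bin
before normalization; bins, smoothing, and sample count are configurable
since the estimator is not otherwise pinned down. Smoothing makes the
estimate biased but finite and stable; with both samples drawn from one pool
it stays below 0.01.

Contaminated negatives are genes labeled negative at training time (gold
but not annotated to the term) that the newer snapshot annotates to the
term. Their relative ranks are compared with a right-tailed two-sample
Kolmogorov–Smirnov test, by default restricted to the high-confidence window
[0.8, 1.0] (a parameter, not a constant). Cross-term correlations are plain
Pearson r with two-sided t-distribution p-values; model-vs-model AUC
comparisons use a right-tailed paired t-test.

## Synthetic study conditions

The generator emulates the *structure* of a curated microarray compendium:
several datasets with differing condition counts, independently missing
entries, and a flat ontology of terms (each ≥ 10 genes, overlaps allowed).
Per dataset, each term draws an independent standard-normal latent profile
over conditions; a member gene's expression sums `signal_strength ×
profile` over its terms plus N(0, `noise_sd`) noise, the simplest model
producing term-specific co-expression blocks whose within-term correlation
rises monotonically with strength (≈ s²/(s² + σ²) for a single-term gene).
Genes in no term are pure noise and exercise the all-folds aggregation path
for uncharacterized genes.

The drift operator derives the historical training snapshot from the
generative truth: per term, a fraction `flip_rate` of truly annotated genes
is removed (they remain co-regulated, becoming contaminated negatives of any
model trained on the old labels) and an equal number of other gold genes is
added (spurious positives). Whole genes move, matching how curated
annotations change between releases.

The demo profile — the configuration the tests and `scripts/acceptance.py`
run — uses 150 genes, 6 datasets of 20–30 conditions, eight 14-gene terms at
strengths 0.1–0.9, noise 0.3, 5% missingness, a (32, 16)-hidden network and
4,000 training iterations, sized so a full pipeline run takes a few seconds
on one CPU while leaving the strongest term recoverable nearly perfectly and
the weakest near chance.

Deliberately not modeled: dye bias, batch effects, or any realistic
microarray noise covariance; the GO DAG hierarchy (terms are flat slim
terms); probe-to-gene mapping and within-dataset intensity normalization
(assumed done upstream); dataset quality filtering. Passing tests on these
conditions show the pipeline's machinery is correct and that its statistics
behave as designed when co-regulation truly drives annotation — they do not
show that real expression compendia carry equally clean signal, nor that
the absolute AUC values transfer to real genomes.

## Known limitations

- The cached feature mode holds one gene×gene matrix per dataset; at full
  genome scale use `low_memory` feature access (slower, constant memory) or
  restrict the gene universe.
- The unrelated-pair definition assumes two genes with different known
  functions are functionally unrelated — multifunctional proteins violate
  this, which is exactly the mis-annotation phenomenon the drift analysis
  measures.
- Iteration budgets are fixed, not adaptive; at full scale the 600,000
  default follows the method's convention and has no early-stopping rule.
- Checkpoints are npz archives (config, seeds, weights); all other
  artifacts are plain text with a version/config-hash header.
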