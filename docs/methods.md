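# Methods

This note documents the statistical model behind `ifxmps`, the choices made
where the procedure was genuinely open, and what the synthetic-data results
do and do not demonstrate.

## Problem and data model

The task is binary prediction — responder vs. primary non-responder to
infliximab induction — from baseline (pre-treatment) mucosal expression in
ulcerative colitis. Inputs are log2-scale gene × sample matrices (microarray
intensities normalised upstream; the package neither detects nor converts
units) plus a phenotype table with a response label and a batch id per
sample. The batch id identifies the source dataset: pooled cohorts from
different experiments carry additive dataset-level shifts that must be
removed before any between-class testing.

## Pipeline stages

### Probe collapsing

Multiple probes mapping to one symbol are collapsed by keeping the probe with
the highest mean expression across samples — the conventional
maximum-intensity rule. Collapsing is an explicit step on probe-level input;
the expression readers reject duplicated symbols rather than collapsing
silently.

### Batch-effect removal

Per gene, an ordinary least-squares model with intercept, response indicator
and batch indicators is fit, and the fitted batch terms are subtracted after
centring them to zero mean across samples (preserving each gene's grand
mean). Including the response term in the design protects class signal from
being absorbed into the batch coefficients. This targets exactly the additive,
gene-constant shifts the generator plants; it does not model multiplicative
or gene-specific batch interactions. A single batch is a no-op; a batch
containing only one class makes batch and response partially confounded, and
is recorded as a warning in the result's metadata rather than an error.

### DEG screening

log2FC = responder mean − non-responder mean, so "down" genes — the bulk of
the signature — are lower in responders. Significance is a two-sided Welch
t-test per gene with Benjamini–Hochberg adjustment, and the screen keeps
`fdr < 0.05` and `|log2FC| > 1`, both strict. The Welch test was chosen over
an empirical-Bayes moderated t deliberately: it is fully specified by a
textbook formula (and therefore testable against one), and at the cohort
sizes involved (≥ 20 per class) variance moderation changes little. BH is the
standard reading of an otherwise unnamed "false discovery rate" control.
Degenerate zero-variance genes get p = 1 when the class means are equal and
p = 0 otherwise, the limiting behaviour that avoids NaN propagation.

### Random-forest ranking

The DEGs are features of a bagging ensemble of CART trees (500 trees,
⌊√p⌋ candidate features per split — classical classification defaults).
Importance is the out-of-bag permutation importance: for each tree, the
accuracy on its out-of-bag samples minus the accuracy after permuting one
feature among those samples, averaged over trees — the *mean decrease of
accuracy*, unscaled by default (a variant scaled by its standard error over
trees is available). The bagging loop is implemented in the package, with
trees from scikit-learn, because the forest implementations available expose
either Gini importance or non-OOB permutation importance, neither of which is
this statistic. Ranking ties are broken lexicographically by gene id so the
top-30 selection is reproducible; the random seed is a required, logged
parameter.

### Gene Score

Each signature gene is binarised against its median over all samples of the
cohort being scored (classes pooled). Genes higher in responders ("up"):
score 1 strictly above the median — a value equal to the median scores 0.
Genes lower in responders ("down") use the exact complement (1 at or below
the median). The two rules always sum to one, and the scoring is rank-based:
any strictly monotone transform of a gene's values leaves its scores
unchanged. "Up/down" is interpreted relative to responders, matching the
fold-change orientation; this is the only orientation under which score = 1
co-varies with response = 1 for every signature gene, which in turn is what
makes uniformly positive weights yield high mPS for responders. Validation
cohorts are always scored against their own medians, never the training
cohort's — the scoring rule, not the thresholds, is what transfers.

### Network and Gene Weight

The classifier on the Gene Score table is a single-hidden-layer network:
30 binary inputs → 10 ReLU units → 2 softmax outputs, mean categorical
cross-entropy loss, full-batch Adam (learning rate 1e-3, β₁ = 0.9,
β₂ = 0.999, ε = 1e-8), He-uniform initialisation, zero biases, no
regularisation or early stopping. Gradients and the Adam update are written
out from their definitions so the implementation can be certified against
central finite differences (relative error < 1e-5 in the tests). The default
is 2000 epochs: with ~46 samples a full-batch step is microseconds, and on a
perfectly separable toy problem 2000 Adam steps at this learning rate drive
the loss below 0.05 where a few hundred leave it an order of magnitude
higher; the budget is exposed as a hyperparameter.

The Gene Weight of gene *i* is the signed maximum over the 10 hidden units of
its input-layer weights `W_in[i, ·]`. Two readings of "maximum weight in the
hidden layer" are defensible; the signed input→hidden maximum is the default
because short training from a symmetric initialisation leaves such maxima
small and positive — consistent with a published all-positive weight column —
and an `abs_max` flag exposes the largest-magnitude alternative.

### mPS and evaluation

mPS(sample) = Σ score × weight over the signature. With non-negative weights
it is bounded by [0, Σ weights], attained at all-zero and all-one score rows.
No decision threshold is defined; evaluation is threshold-free via the ROC
curve (all thresholds kept, anchored at (0,0) and (1,1)) and the
tie-corrected Mann–Whitney AUC. The AUC is computed from mid-ranks and
asserted, at every evaluation, to agree with the trapezoidal ROC area to
1e-12 — two independent routes to the same quantity acting as an internal
oracle. External validation applies the same preprocessing (collapsing, batch
removal within the validation cohort), rescans nothing: signature,
directions and weights come from training unchanged. Re-running the forest on
the validation cohort is a diagnostic, not part of scoring.

## Synthetic cohorts

The generator draws
`value(g,s) = baseline(g) + class_effect(g,s) + batch_offset(batch(s)) + N(0, σ²)`
with per-gene baselines uniform on [4, 12] log2 units (a typical microarray
intensity range), class effects ±δ/2 so the planted responder-minus-non-responder
log2FC is exactly ±δ, and gene-constant additive batch offsets. Gaussian
log-scale noise is the faithful desk-scale analog of microarray log
intensities (not negative-binomial counts, which model sequencing). The
default configuration mirrors the pooled training cohorts: 46 samples
(20 responders / 26 non-responders) in batches of 24 (8+16) and 22 (12+10),
offset 0.8 log2 units apart, 1000 genes, 30 planted signature genes
(28 down / 2 up in responders), δ = 1.5 — above the |log2FC| > 1 screening
threshold — and σ = 0.5. The acceptance experiments use the balanced variant
(23/23, δ = 2) for signature recovery and external validation, and δ = 0 or
permuted labels for null controls.

What the generator does **not** emulate: probe-level structure, correlated
co-expression blocks, gene-specific batch interactions, heavy-tailed or
intensity-dependent noise, and class imbalance beyond the configured counts.
Consequently, passing tests demonstrate that the pipeline's machinery is
correct and recovers planted structure under its stated assumptions — not
that real cohorts of this size yield similarly high AUCs. In the strong-signal
synthetic regime AUCs saturate near 1.0; observed values on real data depend
on effect sizes and cohort composition that the simulation deliberately
idealises.

## Numerical choices and scaling

- Expression TSV round-trips are exact: values are parsed with a
  correctly-rounded string→double conversion (the default pandas fast parser
  can be off by one ulp).
- The BH implementation is the vectorised step-up rule; tests compare it to a
  literal enumeration of the definition and to statsmodels.
- Test and acceptance problem sizes (1000–2000 genes, 20–25 seed replicates,
  100–500 trees, null-validation cohorts of 100 per class) were chosen so
  per-seed sampling noise is small relative to the asserted bands — e.g. a
  null AUC on 100/100 samples has standard deviation ≈ 0.04, so the
  0.5 ± 0.15 control band sits at ~3.7 standard deviations — while a full
  pipeline run stays in the seconds range.
- Reproducibility is bit-exact: every stochastic component (generator,
  bootstrap, permutations, initialisation) derives from an explicit seed, and
  re-running training with the same inputs reproduces the model exactly.

## Known limitations

- The exact published signature and AUCs (0.93 training / 0.81 validation)
  arise from specific GEO cohorts and unrecorded forest/network seeds; they
  are not reproducible from the method description alone and are not claimed.
  The packaged published weight table supports worked-example scoring, not
  re-derivation.
- The Welch test deviates from the variance-moderated test of the limma
  family; on very small classes the moderated test would be more powerful.
- The network is intentionally minimal (no minibatching, GPU, architecture
  search); it exists to produce weights, not to maximise classification
  accuracy.
- With fewer than 30 genes passing the DEG screen the pipeline refuses to
  train rather than silently selecting fewer; relax the thresholds or lower
  `k` explicitly.
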