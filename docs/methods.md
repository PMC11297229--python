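# Methods

This note records the model, its assumptions, the parameter choices that
matter, and the places where the design was genuinely open.

## Model and assumptions

A visible network is a composition of masked affine layers
`h = act(x · (M ∘ W) + b)` whose binary masks come from genomic annotation,
so that each hidden unit is a gene or a pathway rather than an anonymous
neuron. The assumptions this encodes:

- **A CpG informs exactly one gene**, the one with the nearest transcription
  start site on the same chromosome (distance in base pairs). Ties go to the
  smaller TSS, then the lexicographically smaller gene id, which makes the
  assignment deterministic. No maximum-distance cutoff is applied by default
  (configurable), and CpGs on chromosomes without genes are dropped with a
  count. This deliberately simplifies regulatory reality (enhancers act at a
  distance, a CpG can regulate several genes); tissue-specific or functional
  annotation would slot in by swapping the mask builder.
- **Omics merge at the gene level.** Each gene's combined node receives two
  scalar edges — its methylation gene node and its raw expression input —
  tagged `me`/`ge`. The tags are what make omic-specific penalties and
  per-gene omic decompositions possible. Only genes present in both omics
  (the sorted intersection list, which fixes the gene-node ordering for all
  masks, weights and reports) are used.
- **Pathway structure is a three-level forest** (local → mid → global).
  Genes without any pathway annotation keep a skip edge straight to the
  output, so the pathway-annotated and skip genes partition the gene set and
  every gene retains a path to the prediction.

Dense and locally connected layers are represented as masked layers with
complete-bipartite and windowed masks; one engine then serves every
architecture, and the contribution scorer never needs special cases.

## Activations and their numerics

Classification networks use arctanh hidden activations with pre-activations
clipped to (−1+ε, 1−ε), ε = 1e−5 (configurable), and a sigmoid output;
regression networks use ReLU for hidden and output layers, so regression
targets must be nonnegative (the generator maps its phenotype to an age-like
mean-50/sd-10 scale for this reason). The clip keeps arctanh finite; its
cost is a zero gradient in the saturated region. Two consequences shaped
defaults:

- **Initialization gain.** Weights are Glorot-uniform restricted to mask
  edges, with fans computed from the *masked* degrees, scaled by a gain of
  0.05. At gain 1 most arctanh units start saturated (|z| > 1) and training
  stalls; the small gain keeps initial pre-activations inside the live
  region. The gain is an argument of `init_state`.
- **tanh alternative.** tanh (bounded, never saturating to a hard zero
  gradient) is available as a config alternative for every hidden layer;
  arctanh is the primary implementation.

The output bias is initialized to the training-set phenotype mean, which
starts regression networks at the right scale and classification networks at
the prevalence.

## Input scaling

Methylation beta values are used raw (they already live in [0, 1]).
Expression is log1p-transformed and z-scored per gene using training-set
statistics only — unscaled log-normal expression otherwise dominates the
clipped arctanh, and training-set-only statistics avoid leakage into
validation/test. Both behaviours are switches on `InputPipeline`
(`scale_expression`, `log_expression`).

A known asymmetry follows from these choices: the expression branch offers
the optimizer one clean unit-variance input per gene, while the methylation
branch spreads its signal over several raw-beta CpGs behind an extra weight
layer, so trained networks tend to lean on expression when both omics carry
signal. This is a property of the representation, not a bug; it is visible
in the omic shares and discussed below under the omic-specific L1.

## Training

Minibatch Adam (β₁ = 0.9, β₂ = 0.999) on the task loss plus L1. Defaults:
100 epochs, batch 64, early stopping on validation data loss with patience
10; all configurable and recorded in every artifact. Classification uses
class-weighted BCE with w_c = n/(2·n_c), so the weights average to one and
the loss scale is comparable across imbalance levels; single-class training
labels are a configuration error. The learning-rate grid is
{0.01, 0.001, 0.005, 0.0001} and the L1 grid {0.01, 0.001, 0.0001}.

The L1 penalty applies by default to the combined-gene and output layers
(`HyperParams.l1_layers`). Penalizing the CpG→gene layer as well is
supported but not default: on the synthetic study it suppresses the
methylation branch outright (methylation-only-signal AUC drops from ~0.85 to
~0.57), because CpG weights then pay the penalty before their multiplicative
path to the output has grown enough to earn it.

Omic-specific L1 runs use a fixed-epoch schedule (no early stopping) so the
penalty can finish pruning: early stopping on the data loss freezes the run
at the epoch before the penalized omic has been traded away.

**Cross-validation protocol.** Leave-one-cohort-out: for each fold the
held-out cohort is the test set; the pooled remainder is split 75/25 into
train/validation by a fold-seeded RNG (one fixed split per fold, shared by
all grid points); the grid is searched on validation AUC (classification) or
RMSE (regression); the winner is retrained with seeds base+0..base+9 and
each replicate evaluated on the test cohort. Aggregates are reported as the
mean over fold means with a normal-approximation 95% CI
(mean ± 1.96·sd/√k). Seeds appear in every artifact; the same seed
reproduces metrics bit-for-bit on fixed hardware/thread settings.

## Interpretation

Input scores: sum over all input→output paths of the product of absolute
edge weights, normalized over inputs; computed by one backward sweep
(dynamic programming), which is algebraically identical to path enumeration
on the acyclic layer graph. Hidden-node scores push the input proportions
forward along the same absolute-weight paths and normalize within the layer.
Absolute weights are used throughout — signed weights would allow
cancellation and negative "proportions". Biases are ignored: importance is a
property of connections. Skip edges participate in gene and output scores
but belong to no pathway node, so pathway-layer normalization excludes them.
Per-gene omic fractions partition the path mass arriving at each combined
gene node by the tag of the incoming edge (upstream CpG mass included);
`omic_shares` aggregates these fractions weighted by the gene node's
contribution. Activation PCA takes the post-activation values of the
combined-gene layer per sample, centers them, and returns the top principal
components with gene loadings.

## The synthetic generator

`SimulationConfig` defaults describe the study the tests run: 4 cohorts ×
250 samples, 500 genes, Poisson(5) CpGs per gene, 5 causal genes, equal
per-omic effects, cohort shift 0.5 sd between neighbouring cohorts, noise sd
0.5. Per causal gene a latent per-sample factor drives both its CpG betas
(loading 1.2 on the logit scale, per-CpG noise 0.3) and its log expression
(loading 0.8, noise 0.4); the phenotype is built from the *observable*
summaries (standardized mean beta and log expression), so a perfect model
can in principle reach the generator's ceiling. The binary phenotype is
drawn through a logistic link with the intercept solved for a target
prevalence (default 0.25); the generator reports its own ceiling as the AUC
of the true latent score against the sampled labels (≈0.96 under defaults).
Gene TSSs sit on a 100 kb grid with CpGs within ±20 kb, so nearest-TSS
annotation recovers the intended map exactly — the annotation code is tested
against the manifest, not trusted.

Two purpose-built configurations serve specific analyses:

- **Redundant views** (view noises 0.1/0.1, loadings 1.5/1.0) for the
  omic-specific-L1 analysis, whose premise is that the signal exists in both
  omics so either suffices. Under the *defaults* each omic carries
  independent noise and both are necessary; dropping one there costs real
  AUC by construction. With redundant views, penalizing the methylation omic
  at λ = 0.01 drives its share below 5% at an AUC cost under 0.05, while in
  an omic-exclusive configuration the penalized-but-necessary omic retains a
  large share (tens of percent). The penalty directions differ (methylation
  penalized in the redundant experiment, expression in the exclusive one)
  because of the expression-accessibility asymmetry described above: an
  expression penalty reaches a gradient/penalty equilibrium near a 50–70%
  share rather than full eviction.
- **Group block on predictive genes** (`sex_block_overlap_causal`) for the
  activation-PCA analysis: a binary covariate shifts the inputs of the
  causal genes (plus extras). Only genes whose weights survive the L1 carry
  group structure into their activations, so the block must overlap genes
  the network uses; with it, PC1 of the combined-gene activations separates
  the groups (silhouette ≈ 0.54–0.59).

What the generator does **not** emulate: array probe chemistry, batch
effects, cell-type composition, linkage between neighbouring genes, and
realistic pathway topology (its hierarchy is random with balanced parents).
Passing tests therefore demonstrate that the machinery recovers planted
signal under the stated noise model across cohort shifts — not that it will
rank genes correctly under confounding it has never seen.

## Problem sizes and runtime choices

The test suite and the acceptance script run the full study conditions
(1000 samples, 500 genes, ~2500 CpGs) but search a 2-point hyperparameter
grid (learning rates 0.005/0.01 at L1 0.001) with epochs 150 / patience 20,
rather than the full 12-point grid; the full grid is `default_grid()` and is
exercised at small scale in unit tests. Penalized-omic runs use 300 fixed
epochs. With these sizes the complete cross-validation (2 grid points + 10
seed replicates × 4 folds) takes on the order of a minute or two on one CPU.

## Known limitations

- Clipped arctanh has zero gradient outside (−1, 1); badly scaled inputs can
  silently freeze units. The small initialization gain mitigates but does
  not remove this.
- The L1 subgradient under Adam leaves small nonzero weights rather than
  exact zeros; sparsity counts use a 1e−3 threshold.
- Contribution scores quantify what the trained network uses, which is
  neither a causal statement nor accompanied by a significance measure.
- Single-threaded dense/sparse numpy: adequate at tens of thousands of
  CpGs; genome-wide 450k-scale inputs would want a chunked HDF5 path (the
  readers accept it) and more careful memory layout.
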