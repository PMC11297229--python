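# visomix

Biologically masked ("visible") neural networks for multi-omics phenotype
prediction, with built-in interpretation.

## The problem

Predicting a phenotype (smoking status, age, a lipid level) from genome-wide
DNA methylation and gene expression is easy to do with a black box and hard
to do with a model a biologist can read. `visomix` builds neural networks
whose connectivity *is* the biology: CpG methylation inputs connect only to
the gene whose transcription start site is nearest, each gene's methylation
node merges with that gene's expression value into one combined gene node,
and (optionally) gene nodes feed a three-level pathway hierarchy. Every
neuron therefore corresponds to a gene or a pathway, and the trained weights
can be read off as importance scores.

The package is aimed at epigenomics / regulatory-genomics groups with
multi-cohort methylation + RNA-seq data who want generalization estimates
that survive a cohort change, which is why evaluation is leave-one-cohort-out
cross-validation: train and validate on all cohorts but one, test on the
held-out cohort, repeat for every cohort, and replicate every fit across ten
random seeds.

## The model

A network is an ordered list of masked affine layers over *named units*.
For input vector `x` and a binary mask `M` from prior annotation,

    h = act( x · (M ∘ W) + b )

with `W` trainable only on the nonzeros of `M`. Architectures:

| name | structure |
|---|---|
| `ge` | expression → output (LASSO-like single layer) |
| `me` | CpGs → gene nodes → output |
| `me_ge` | CpGs → methylation gene nodes; per gene, {methylation node, expression input} → combined gene node → output |
| `me_ge_pathway` | `me_ge` + local/mid/global pathway layers (e.g. 321/44/6 nodes); unannotated genes keep a skip edge to the output |
| `me_ge_dense` | `me_ge` + dense layers of the same widths (no-prior-knowledge comparison) |
| `baseline_lc` | locally connected 1D layer + two dense layers on the concatenated omics |

Classification uses clipped-arctanh hidden activations and a sigmoid output
trained with class-weighted binary cross-entropy; regression uses ReLU
throughout with mean-squared-error loss. An L1 penalty on the gene-level
weights enforces sparsity; an *omic-specific* L1 penalizes only the edges of
one omic, probing whether that omic carries unique information.

**Interpretation.** The contribution of input *i* is

    score(i) = Σ_paths(i → output)  Π_edges |w|,  normalized over inputs,

computed exactly by one backward sweep over the layer DAG. Hidden-node
scores redistribute these proportions forward and are normalized within a
layer; per-gene pie-chart-style omic fractions split the mass arriving at
each combined gene node by the omic tag of the incoming edge.

Because there is no public multi-cohort dataset bundled here, the package
ships a first-class generator (`visomix.synthdata`) that emulates such a
study — cohort-shifted phenotypes, beta values in [0, 1], log-normal
expression passing a ≥1 counts-per-million filter, planted causal genes with
known per-omic effects, and a sex-linked gene block — so every claim the
package makes is testable against known ground truth.

## Worked example

```python
import visomix as v
from visomix.interpret import compute_report, omic_shares

# 1. simulate a 4-cohort methylation+expression study with 5 causal genes
cfg = v.SimulationConfig(n_cohorts=4, samples_per_cohort=150, n_genes=100,
                         n_causal_genes=5, seed=42)
data, annotations, truth = v.simulate_classification(cfg)

# 2. annotate CpGs to nearest-TSS genes and build the masks
cpg_map = v.map_cpgs_to_genes(annotations.cpgs, annotations.genes)
genes = v.intersect_gene_sets(cpg_map.genes(), set(data.expression.columns))
gene_mask = v.build_gene_mask(cpg_map, genes, list(data.methylation.columns))

# 3. assemble the multi-omic network and run cohort-wise CV
spec = v.build_me_ge_network(gene_mask, genes, "classification")
grid = [v.HyperParams(learning_rate=0.005, l1_lambda=0.001, epochs=150, patience=20)]
results = v.cohort_cv(spec, data, grid=grid, n_seeds=3, base_seed=0)
agg = results.aggregate()
print(f"mean held-out AUC: {agg['mean']:.3f} "
      f"(95% CI {agg['ci_low']:.3f}-{agg['ci_high']:.3f})")

# 4. interpret: mean gene contributions over all folds and seeds
reports = [compute_report(st, spec) for f in results.folds for st in f.states]
top = v.aggregate_over_seeds(reports, layer="gene")["mean"].nlargest(5)
print("top genes by contribution:", ", ".join(f"{g} ({s:.1%})" for g, s in top.items()))
print("planted causal genes:     ", ", ".join(sorted(truth.causal_genes)))
shares = omic_shares(results.folds[0].states[0], spec)
print(f"omic share (fold 1, seed 0): methylation {shares['me']:.1%}, "
      f"expression {shares['ge']:.1%}")
```

Output:

```
mean held-out AUC: 0.869 (95% CI 0.841-0.896)
top genes by contribution: G0033 (19.9%), G0071 (16.5%), G0016 (12.6%), G0079 (12.4%), G0002 (11.1%)
planted causal genes:      G0002, G0016, G0033, G0071, G0079
omic share (fold 1, seed 0): methylation 12.9%, expression 87.1%
```

The network generalizes across cohorts (AUC 0.87 against a generator ceiling
near 0.96), and the five planted causal genes are exactly the five largest
mean contributions. The omic share says how much of the decision mass flows
through methylation versus expression edges.

The same pipeline is available from a shell via the `visomix` command
(`simulate`, `build-masks`, `train`, `crossval`, `interpret`); each
subcommand writes a config snapshot, metrics JSON and contribution tables to
its output directory.

## Layout

```
src/visomix/annot_masks.py  annotations -> sparse connectivity masks
src/visomix/vnn_core.py     layer/network specs, builders, forward/backward engine
src/visomix/training.py     losses, Adam, grid search, cohort-wise CV
src/visomix/interpret.py    contribution scores, omic splits, activation PCA
src/visomix/synthdata.py    multi-cohort generator with planted ground truth
src/visomix/io.py, cli.py   file formats and the command-line surface
docs/methods.md             model, assumptions, parameter choices, limitations
```
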