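# mtann

Multiple-reference ensemble cell-type annotation for single-cell RNA-seq,
with automatic detection of cell types the references have never seen.

## The problem

Reference-based annotation transfers cell-type labels from a well-annotated
scRNA-seq atlas to a new query dataset. Two things routinely go wrong:
the choice of a single reference (and of the genes fed to the classifier)
strongly affects results, and the query may contain **unseen cell types** —
types absent from every reference — which a closed-set classifier will
silently mislabel. `mtann` addresses both by ensembling many small
classifiers across multiple references and gene-selection views, and by
scoring each query cell's prediction uncertainty to call unseen cells
"unassigned".

## The method

Given M labeled references and one query sharing a gene namespace:

1. **Gene selection.** Eight per-gene scores per reference — five
   supervised one-vs-rest statistics (moderated t, Bartlett,
   Kolmogorov–Smirnov, detection chi-squared, bimodality index) and three
   unsupervised highly-variable-gene scores (Gini, normalized dispersion,
   variance-stabilized variance). The top genes of each view, intersected
   with the query's genes, define 8M reference subsets.
2. **Base classifiers.** One autoencoder-regularized network per subset:
   encoder E, linear softmax head C over the *global* type vocabulary K,
   and mirrored decoder D, trained to minimize
   `L_ce + λ·L_re`, where the reconstruction term covers both reference
   and query cells (the query contributes no labels).
3. **Normalized majority vote.** Each model votes with its argmax label;
   cell c receives label `argmax_k Σ_ij 1[Ŷ_c^ij = k] / L_k`, where
   `L_k` counts the subsets whose reference contains type k — so a type
   carried by a single reference needs proportionally fewer votes.
4. **Uncertainty.** Three entropy metrics per cell: the mean per-model
   prediction entropy (m¹), the entropy of the L_k-normalized average
   probability (m²), and the entropy of the L_k-normalized vote
   distribution (m³). Each is min-max scaled over the query; their mean
   m ∈ [0,1] is the unseen-type score.
5. **Adaptive threshold.** A 1-D Gaussian mixture (1–5 components,
   AIC-selected) is fit to m. One component ⇒ nothing is flagged;
   otherwise groups with mean m ≥ 0.6, plus the largest-mean group, are
   called "unassigned".

## Worked example

```python
from mtann import AnnotateConfig, annotate
from mtann.evaluation import annotation_accuracy, auprc
from mtann.simulate import SimulationConfig, simulate_collection

# 3 references x 5 types, 2000 genes; "type4" held out of every
# reference and present in the query at 20%
cfg = SimulationConfig(unseen_type="type4", seed=2)
references, query, truth = simulate_collection(cfg)

result = annotate(references, query, config=AnnotateConfig(epochs=30), seed=2)
print("AUPRC (unseen vs shared):",
      round(auprc(result.scores.m, truth.unseen_mask), 3))
print("annotation accuracy:",
      round(annotation_accuracy(result.labels, truth.labels, truth.unseen_mask), 3))
print("unassigned fraction:", round(result.unassigned.mean(), 3))
print("mixture components:", result.diagnostics.chosen_k)
```

prints

```
AUPRC (unseen vs shared): 0.971
annotation accuracy: 0.972
unassigned fraction: 0.204
mixture components: 2
```

i.e. the uncertainty score ranks the 50 held-out-type cells essentially
above all shared cells, 97% of cells end up correctly annotated (unseen
cells counting as correct only when called "unassigned"), and the
adaptive threshold flags 20.4% of cells against a true unseen proportion
of 20%.

The same pipeline is available from the shell:

```bash
mtann simulate --preset easy --out sim/ --seed 2
mtann run --ref sim/ref0.csv,sim/ref1.csv,sim/ref2.csv \
          --ref-labels sim/ref0_labels.tsv,sim/ref1_labels.tsv,sim/ref2_labels.tsv \
          --query sim/query.csv --out results/ --skip-filter
```

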