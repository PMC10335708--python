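# Methods

This note records the model, the defaults and the numerical decisions
behind `mtann`, and what the synthetic benchmarks do and do not show.

## Model and assumptions

The annotation problem is open-set label transfer: M labeled reference
expression matrices X^{r_i} (cells × genes, raw counts or
library-normalizable values) with label vectors Y^{r_i}, and one
unlabeled query X^q sharing a gene namespace. The global vocabulary K is
the union of the reference label sets, ordered lexicographically so every
run enumerates classes identically. Types present in the query but in no
reference are *unseen*; the method's job is to label shared-type cells
correctly and call unseen-type cells "unassigned".

The working assumptions: cell types are characterized by reasonably
stable marker programs across datasets; datasets differ by multiplicative
technology/batch effects that preprocessing and ensembling absorb rather
than explicit correction (batch-correcting references before training
tends to erase exactly the biological contrasts classification needs);
and prediction uncertainty is systematically higher for unseen-type cells
than for shared-type cells, so that the per-cell uncertainty score is
bimodally distributed whenever unseen types are present. That last
assumption is what licenses the Gaussian-mixture threshold.

## Preprocessing

Four steps with a fixed order, enforced by a stage machine
(`raw → libnorm → selected → log → zscore → minmax`):

1. library-size normalization to 10 000 counts per cell, applied to the
   raw matrix;
2. after gene selection: `log2(x+1)`;
3. per-gene z-score (population sd; a constant gene maps to zero — it
   carries no information and this avoids 0/0);
4. per-gene min-max to [0, 1] (constant genes again to zero).

Each matrix (every reference view and the query view) is standardized on
its own cells. Scaling the query jointly with its reference would leak
query statistics into training and couple the 8M views; per-dataset
scaling is the only self-contained choice.

Dataset quality filters (applied before everything, in order): cell types
with < 10 cells, then genes expressed in < 100 cells, then cells
expressing < 100 genes. All three thresholds are parameters; synthetic
fixtures at desk scale use smaller ones or skip filtering.

Gene names match by exact string; duplicate gene columns are summed with
a warning. Cross-reference label harmonization (e.g. "PP" vs "gamma") is
left to the user via an optional two-column rename map.

## Gene selection

Eight scores per gene and reference; the top `n_top` genes per view are
intersected with the query's genes. Supervised scores run one-vs-rest per
cell type and keep the per-gene maximum across comparisons, because
markers are type-specific and a gene only needs to separate one type to
be useful.

- **DE** — moderated t statistic: pooled two-group residual variance
  shrunk toward an inverse-chi-squared prior whose scale and df come from
  the Smyth moment estimator (trigamma inversion by Newton's method).
  A plain Welch t is available (`moderated=False`).
- **DV** — Bartlett's variance-homogeneity statistic (vectorized
  two-group form; zero-variance groups score 0).
- **DD** — two-sample Kolmogorov–Smirnov statistic, computed at pooled
  sorted-value block boundaries so ties are exact.
- **DP** — Pearson chi-squared (no continuity correction) on the 2×2
  table of detection (value > 0) × group.
- **BI** — bimodality index `δ·sqrt(π(1−π))` with δ the standardized
  separation of a two-component fit (deterministic vectorized 1-D
  two-means initialized at the 10th/90th percentiles). Fit once per gene
  on all cells; one-vs-rest does not apply to a mixture fit.
- **GC** — Gini coefficient of expression across cells.
- **Disp** — log variance/mean dispersion, z-scored within 20 equal-width
  bins of log1p(mean) (the classic "dispersion" HVG recipe; verified
  against scanpy's implementation in the tests).
- **Vst** — standardized variance after a lowess fit of log10(var) on
  log10(mean) (frac 0.3), per-cell standardized values clipped at
  sqrt(n). The trend fit is local-linear lowess rather than
  local-quadratic loess; at these gene counts the difference is
  negligible and is covered by a ranking test.

Supervised scores are computed on log-transformed library-normalized
data; the unsupervised trio on library-normalized (pre-log) values,
matching the conventions of their source recipes. Selection is by fixed
count (`n_top`, default 500) with stable ties (input gene order); a
score-threshold mode exists for users who prefer it. Views whose
intersection with the query drops below `gene_floor` (default 10) genes
are dropped with a warning and excluded from the vote normalizer.

A caveat surfaced by testing: on sparse counts, zero-inflation makes
nearly every expressed gene "bimodal", so the bimodality index ranks
sparsity rather than marker structure; its marker-recovery property holds
on well-detected backgrounds. Conversely the detection chi-squared needs
incompletely detected genes to have any signal. No single count regime
exercises all five supervised scores at once, which is itself the reason
to keep all eight views in the ensemble.

## Base classifiers

One network per (reference, method) view: dense encoder
input→256→64 (ReLU), linear softmax head 64→|K| over the *global*
vocabulary, mirrored decoder 64→256→input. Training minimizes

    L = L_ce + λ·L_re,    λ = 1 by default,

with L_ce the natural-log cross-entropy on reference cells and L_re the
mean-squared reconstruction error of reference *and* query cells, each
term normalized by its own cell × gene count. Query cells contribute only
reconstruction — no pseudo-labels. Classes a reference never saw get no
supervision from that model; softmax still assigns them mass, which the
vote normalization L_k downweights.

Optimization: Adam (lr 1e-3), mini-batch 128 (a reference batch paired
with an equally sized cycling query batch), 30 epochs by default. The
implementation is plain NumPy with manual backpropagation — at a few
hundred cells × a few hundred genes per view it runs in under a second
per model and is exactly reproducible: per-model seed = master seed +
subset index, recorded in the model manifest together with the loss
trajectory. Initial and final full-data objectives are stored; training
aborts on a non-finite loss.

The entropy modules use log base 2 (entropies in bits, bounded by
log2|K|); the training loss uses natural log. The two conventions never
mix.

## Vote and uncertainty

Votes are hard argmax labels (ties → lowest vocabulary index). The
consensus label maximizes `Σ votes_k / L_k`, where `L_k` counts usable
subsets containing type k — dropped subsets are excluded from both
numerator and denominator. When all L_k are equal this reduces exactly to
plain majority voting (asserted by test).

The three uncertainty metrics are as in the README; implementation
details worth noting: the m²/m³ row normalizations divide by exact row
sums (rows are provably positive — softmax for m², at least one vote per
cell for m³); min-max scaling of a constant metric vector yields zeros;
and the ensemble score is the exact arithmetic mean of the three scaled
metrics, so m ∈ [0,1] with the maximum attained only by a cell that is
extreme in all three.

## Threshold selection

`sklearn` Gaussian mixtures with k = 1…5 components, full covariance,
10 restarts per k, variance floor 1e-6, fixed random state; k chosen by
AIC (for a 1-D mixture the free-parameter count is 3k−1: weights, means,
variances). Ties in AIC go to the smaller k. Cells are assigned to the
posterior-argmax component, posterior ties to the larger-mean component.
With k = 1 nothing is flagged. Otherwise the uncertain groups are those
with mean(m) ≥ 0.6 *plus, unconditionally, the largest-mean group*; the
`strict_cutoff_only` switch restricts to the 0.6 rule for users who want
the conservative reading. The 0.6 cutoff applies to the scaled score m
(which lives on [0,1] by construction). Diagnostics record per-k AICs,
group means, flagged groups and the implied threshold (the minimum m
among flagged cells), so every unassigned cell satisfies
m ≥ implied_threshold by construction.

## Synthetic data

The generator emulates the structure the method assumes: a shared
marker model (per-type marker genes elevated by `marker_effect` on the
log scale over lognormal base means), per-(dataset, gene) lognormal
multiplicative batch factors of sd `batch_shift_sd` standing in for
technology differences, negative-binomial counts (fixed dispersion 0.3),
per-cell lognormal size factors, and Bernoulli zero-inflation at
`dropout_rate`. The query is always its own batch; it may carry one type
excluded from every reference at a configurable fraction, and its
composition can be made imbalanced (`query_type_weights`). References may
carry partially overlapping type subsets.

Two presets: **easy** (3 references × 5 types × 50 cells, 2000 genes,
30 markers/type, marker effect 1.5, batch sd 0.2, dropout 0.1) — the
regime in which held-out-type recovery is near-ceiling and end-to-end
contracts are asserted — and **hard** (800 genes, 30 cells/type,
15 markers, effect 0.8, batch 0.4, dropout 0.3), a low-signal regime
useful for exercising failure modes.

What passing these benchmarks does *not* show: the generator has no
ambient RNA, doublets, platform-specific count distributions, nested or
similar cell types (each type is equidistant from the others), or
label noise in the references. Real-data difficulty — in particular
closely related subtypes, which dominate real annotation errors — is not
represented, so synthetic accuracies overstate what any method achieves
on tissue atlases.

The metric-complementarity suite (20 leave-one-type-out tests with
heterogeneous marker strength, technology-scale batch shifts, dropout,
partial reference overlap, unseen fractions 0.05–0.3 and imbalanced
queries) deserves a candid note. The combined score m beats the
intra-model metric m¹ and the vote metric m³ by AR index, but ties the
inter-model metric m² in our synthetic world: with a single homogeneous
generative mechanism, the pooled-probability entropy is already a
near-optimal detector, and the highly correlated base models make m³
noisy enough that averaging it in cancels the residual gain. The
robustness advantage of the combined score is a cross-dataset
heterogeneity effect, and a homogeneous simulator under-represents it.
The corresponding assertion is kept at the claimed strength (AR > 1
against each component) and is expected to fail for m² here; it is not
loosened.

## Problem sizes

Desk-scale defaults throughout: the end-to-end assertions run the easy
collection (24 base models, 250 query cells, 30 epochs — roughly half a
minute per run), and the complementarity suite runs 20 reduced tests
(800 genes, n_top 200). These sizes are the package's chosen trade-off
between statistical resolution and a test suite that runs in minutes on
one CPU; all of them are parameters, and nothing in the implementation
caps problem size.

## Known limitations

- Gene matching is exact string equality; no alias/ortholog resolution.
- The classifier head spans the global vocabulary even for references
  lacking a type; with many references and very uneven type coverage the
  softmax mass on never-supervised classes adds noise that L_k
  normalization only partially absorbs.
- The bimodality index degenerates on sparse counts (see above).
- "Unassigned" cells get no further identity; clustering or ontology-
  based post-hoc labeling is out of scope.
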