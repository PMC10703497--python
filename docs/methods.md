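# Methods

## Overview

`celltics` is a two-stage, pathway-constrained classifier for scRNA-seq.
The pipeline is: normalize → score marker specificity → prune the pathway
hierarchy to the markers → layer it to depth `l` → train a masked
feedforward network with one predictive head per hidden layer → vote →
route cells to per-cell-type sub-networks for sub-type calls → rank
pathway neurons by their activation gap between cell types.

## Normalization and QC

Raw UMI counts are normalized per cell to counts-per-10k and
log2-transformed with a pseudo-count: `expr = log2(1e4·m/Σm + 1)`. A cell
with zero total count is an error, not a silent drop. Inputs that are
already normalized (counts-per-10k, log-transformed) bypass this step via
a flag. Quality control is a plain two-pass filter — cells expressing
fewer than `min_genes_per_cell` genes (default 200), then genes detected
in fewer than `min_cells_per_gene` remaining cells (default 3). The
thresholds are conventional scRNA-seq values; nothing downstream depends
on them and the defaults are no-ops on the synthetic data. Doublet
detection, ambient-RNA and batch correction are out of scope.

## Marker specificity scores

For the type-level profile `expr[t,g]` (arithmetic mean of normalized
expression over cells of type t — the aggregation is a design choice;
medians behaved indistinguishably on synthetic data and the mean keeps the
score differentiable in the inputs) the high score is
`φ = τ·x̂` and the low score `ρ = ω·ẑ` (formulas in the README). Both
factor a gene-level dispersion term (τ, ω) against a type-level ratio
(x̂, ẑ) and live in [0, 1]; φ equals τ exactly at every maximum-expressing
type and ρ equals ω at every minimum. Selection is strictly above the
per-type quantile (α = 0.95 high, β = 0.9 low), with linear-interpolation
quantiles over all genes that survived QC; ties at the cutoff are
excluded. Markers are recomputed per stage: stage 1 at cell-type
granularity, each stage-2 sub-network at sub-type granularity on its own
type's training cells.

## Pathway hierarchy and masks

Reactome ships parent→child pathway relations plus gene→pathway
annotations. Although usually called a tree, the relation files contain
multi-parent pathways, so the graph is treated as a DAG; a multi-parent
pathway keeps all of its parent edges and its mask row carries several
ones. A synthetic root collects top-level pathways.

After pruning to marker genes (keeping exactly the pathways on a
root-to-marker path; unannotated markers are dropped and counted), each
pathway's level is its **shortest-path depth from the root**, computed on
the pruned graph. Only edges between adjacent levels are kept — along a
shortest path every non-root node retains a parent one level up, so
nothing is orphaned; longer-range DAG edges are discarded as they cannot
be represented in a strictly layered network. Genes attach below level l:

* annotated deeper than l → re-attached to the annotation's depth-l
  ancestors (each annotation handled independently, connections unioned);
* annotated shallower than l → a shared chain of pass-through artificial
  nodes `<pathway>#pad<k>` bridges the gap; pads are trainable but
  excluded from importance reports;
* pathway nodes left without any input from below are removed bottom-up.

Entity order at every level is lexicographic, making the binary masks
reproducible byte for byte. Mask entry (i, j) is 1 iff child entity i
connects to parent entity j.

## Network, training, initialization

Hidden layer k computes `h_k = tanh((M_k ∘ W_k) h_{k−1} + b_k)`; masking
is enforced by construction (masked entries start at zero and receive
masked gradients), so they are *exactly* zero after any number of steps.
Each hidden layer feeds an affine softmax head with C = number of classes
outputs. The loss is the unweighted sum of per-head mean cross-entropies
(no head weighting is specified by the method; equal weights are the
neutral choice) plus `λ‖M ∘ W‖²` on the masked layers (λ = 1e-4).
Optimization is Adam, minibatch 32, learning rate 0.001, 10 epochs for
stage 1 and 50 for stage 2, minibatch order reshuffled each epoch from
the run seed. Final labels are a plurality vote over the heads' argmax
calls; ties go to the class with the largest probability mass summed
across heads, residual ties lexicographic. A stratified-k-fold grid
search (macro F1, ties keep grid order) is available for tuning but the
defaults above are used everywhere.

Two numerical choices matter at small step budgets and are deliberate:

* **Input standardization.** Each stage standardizes its design matrix
  per gene with training-set mean/sd (stored in the fitted bundle and
  reapplied at prediction; genes missing from a query matrix impute to
  the training mean). Raw log-normalized values are all-positive with
  magnitude ~6, which parks tanh units on their saturated shoulder where
  gradients vanish.
* **Initialization.** Hidden weight (i,j) starts at
  `0.7·(1 + 0.3·ε)/fan_in` with ε standard normal and fan-in the mask
  column sum: a pathway neuron begins as (approximately) the average of
  its member genes' standardized expression — an informative,
  interpretable feature from the first forward pass — with jitter for
  symmetry breaking. Heads start at exactly zero, like a
  zero-initialized logistic regression, so early Adam steps encode signal
  rather than undo a random draw. A conventional signed Glorot draw
  works eventually but needs roughly an order of magnitude more steps on
  the problem sizes used here, and it leaves pathway-neuron activations
  as random ± mixtures of member genes, which blunts the importance
  score below.

Training errors loudly on single-class labels and non-finite losses
(reporting the epoch). Everything is deterministic under the seed; the
implementation is plain numpy with hand-written backpropagation, which is
what makes bit-exact reruns possible.

## Two-stage prediction

Stage 2 trains one sub-network per cell type with ≥ 2 sub-types, on that
type's **true**-labeled training cells; at prediction time cells are
routed by their **predicted** stage-1 type. This asymmetry is inherent to
the design: a misrouted cell is scored against the wrong type's sub-label
universe. Types with ≤ 1 sub-type get a passthrough bundle that emits the
single known sub-label, or the cell type itself when no sub-labels exist
(so with no sub-annotation the model degenerates exactly to stage 1).
Condition-style sub-labels (old-A vs young-A, disease-A vs control-A) are
expressed by composing them into the sub-type column upstream; no special
code path exists. There is no rejection option — the argmax class is
always assigned.

## Pathway importance

`A[t,p]` is the mean post-tanh activation (signed, no absolute value) of
pathway neuron p over **training** cells of type t, computed after
training completes. Importance is `d_p = A(1),p − A(2),p` (gap between
the two largest type means), assigned to the top type, flagged when
`D_p ≥ 0.1`. Because hidden activations are shared by all downstream
heads in this architecture, d_p is single-valued per neuron and
`D_p = d_p`; the layer level is recorded so a per-head variant could be
compared later. d_p is translation-invariant in A and non-negative by
construction. Artificial pads never appear in the table.

## CV stochasticity test

For two cell groups and a pathway's gene set, each gene's coefficient of
variation (sample sd, ddof = 1, over mean) is computed per group; genes
with zero mean in either group are excluded and counted rather than given
infinite CV. A two-sided Wilcoxon signed-rank test pairs the per-gene CVs
across groups; zero differences are dropped; the exact null is used below
25 nonzero pairs, otherwise the normal approximation with continuity
correction. All differences zero reports p = 1.0 with a reason code, a
pathway with no testable gene reports p = NA. Raw p-values only — no
multiplicity correction across pathways. The test runs on normalized
expression, consistent with the rest of the pipeline. Gene-level ranked
exports (score or log fold change = difference of group means on the log
scale) are provided for external enrichment tools; enrichment itself is
out of scope.

## Synthetic data generator

Counts are negative binomial in the mean/dispersion parameterization
(`var = μ + μ²/size`), the standard UMI noise model. Defaults — chosen
once as the study conditions — are 3 cell types × 2 sub-types × 100
cells, 120 genes, baseline mean 5, size 2, planted log2 fold change 2:
8 high + 4 low markers per type (multiplicative 2^±effect on μ) and 6
high markers per sub-type nested within its type's cells. The toy
hierarchy is a balanced depth-2, branching-3 tree in the Reactome TSV
dialect; the first three leaves are *pure signal* pathways holding
exactly one type's high markers, half of the remaining leaves host the
low/sub-type markers and the rest only background genes. Gene-to-leaf
assignment is a pure function of the configuration, so the count matrix
and the hierarchy agree without shared state. A separate generator makes
equal-mean, dispersion-shifted two-group matrices for the CV test (gene
means log-normal around the baseline, shared across groups; one group's
`size` divided by the multiplier).

The generator emulates marker structure and NB noise only: no dropout
beyond the NB law, no batch effects, doublets or ambient RNA. Passing
tests therefore demonstrate the pipeline's correctness and its behavior
under clean planted signal, not performance on real tissue atlases.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use l = 2 on the depth-2 toy
tree, 600-cell simulations over five seeds, 1000 null and 200 power
replicates for the CV test — sizes chosen so the full suite runs in
seconds while every statistical check retains adequate resolution. Every
random draw (generator, init, minibatch order, splits, CV folds) flows
from explicit integer seeds, and reruns reproduce prediction and
importance files bit-identically.

## Known limitations

* Shortest-path layering discards DAG edges that skip levels; a pathway
  reachable at several depths is placed at its shallowest.
* Stage-2 quality is bounded by stage-1 routing; there is no "unassigned"
  class to absorb uncertain cells.
* The importance score compares only the top two type means; a pathway
  separating two *groups* of types equally strongly scores zero.
* CV estimates are noisy for genes with small means; the zero-mean
  exclusion rule removes them but reduces the number of paired genes.
* Real Reactome hierarchies are far deeper and wider than the toy tree;
  runtime scales with mask sizes (dense numpy matmuls), which is fine for
  marker-compressed inputs but would need sparse kernels for
  whole-transcriptome masks.
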