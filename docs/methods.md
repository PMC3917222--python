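# Methods

This note documents the statistical procedures, the synthetic study design,
the numerical choices, and the limitations of `nitronet`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Differential expression: rank products with permutation PFP

Each experiment is a log2 expression matrix with a treatment/control design.
Fold changes are taken over **all treatment × control sample pairs**
(k = n_t · n_c columns), the unpaired rank-products convention; the method
is rank-based, so it is invariant to any monotone per-comparison transform
and robust at 2–3 replicates. Within each comparison genes are ranked by
descending ratio for up-regulation (ascending for down), ties averaged; the
statistic is the geometric mean of a gene's k ranks, computed on the
sum-of-log scale.

The null is built by shuffling the observed rank vector independently
within every comparison, `n_perm` times (default 1000; every run receives a
spawned sub-seed). Pooling all null values,

```
evalue_g = #{null RP <= RP_g} / n_perm
pfp_g    = evalue_g / ascending-RP rank of g
```

Two numerical guards: e-values of exactly zero are floored at `1/n_perm`
(finite sampling must not produce a perfect call, and a threshold of 0 then
provably calls nothing), and PFP is made monotone non-decreasing along
ascending RP by a running maximum — the step-up convention that makes
"sorted by RP" and "sorted by PFP" agree. PFP is clipped at 1 for calling;
the default call threshold is 0.05.

Because the k comparisons share samples, observed ranks are positively
correlated across comparisons while the shuffle null treats them as
independent; the procedure is therefore somewhat anti-conservative on
3-vs-3 designs. The test suite measures the realized null call rate
(fraction of genes at PFP ≤ 0.05 on pure-noise experiments, either
direction, 20 seeds) and bounds it at 7%. A gene significant in both
directions of one experiment keeps the direction with the smaller PFP.

## GO handling and enrichment

The ontology is an is_a-style DAG (child → parent edge list, one root).
A term's level is the shortest-path edge count to the root (BFS); cycles or
multiple roots are rejected. Annotations are propagated to ancestors
(true-path rule) by default — standard GO practice; the flag is switchable
for sensitivity analysis.

Enrichment of a gene set against a universe is the one-sided
over-representation Fisher test, i.e. the hypergeometric upper tail,
computed per term over all terms with at least one annotated universe gene.
The universe is the full expression platform (all genes in the matrices) —
the natural reference for array-derived DE sets. Multiplicity is controlled
with Benjamini–Yekutieli (step-up with the harmonic factor c(m) = Σ 1/i),
chosen over Benjamini–Hochberg because GO terms are strongly dependent
through the DAG; discovery threshold 0.05 on the adjusted value. For
function-specific summaries only terms at levels 7–8 are kept; the filter is
a pure restriction applied after testing. REVIGO-style redundancy collapse
is not implemented (out of scope); the level filter stands alone.

## Consistency statistics

*Overlap metric.* "Shared percentage" of m sets is defined as
100·|∩|/|∪| (Jaccard); an intersection-over-mean-size variant is available
behind a flag since either normalization is defensible. The overlap curves
evaluate, for every tuple size m, the mean shared percentage of DE genes
and of enriched terms over all C(E, m) experiment combinations, or over
10,000 uniformly sampled combinations when the exhaustive count exceeds
that cap (flagged in the output). Gene and term curves use identical
combinations.

*Controls.* (1) Level distributions of all vs. pairwise-shared enriched
terms, summarized by total-variation distance — closeness rules out the
"shared terms are just shallow terms" artifact. (2) Distinct-annotation
counts of random gene lists matched in size to the DE union (1000 draws
without replacement), with the observed list's empirical quantile — rules
out "DE genes are simply annotation-rich". (3) Gene overlap inside shared
terms: for every pair and shared term, the Jaccard percentage of the two
experiments' DE genes annotated to that term; a low grand mean means shared
functions are realized by different genes.

*Protein-similarity test.* For a term shared by ≥ 2 experiments, the
observed statistic is the mean similarity over all distinct cross-experiment
gene pairs (pairs absent from the similarity table score 0 — they failed
the alignment E-value filter; self-pairs are excluded). The null draws the
same number of pairs uniformly without replacement from all distinct pairs
of genes annotated to the term, `n_perm` times; a term is significant when
the observed statistic exceeds the empirical (1 − α) null quantile. Terms
with < 2 annotated genes or < 2 cross pairs are skipped with a reason. The
null resamples *pairs* rather than permuting gene labels — with similarity
assigned independently of contributor status this makes the observed
statistic exchangeable with the null draws, which is what the type-I
calibration in the test suite verifies (within α ± 2 percentage points over
600 simulated terms). A count-above-threshold statistic is available behind
a flag. Pipeline-level contributors are aggregated per term across all
experiment pairs sharing it, and one test is run per term.

## Coexpression network

Profiles for the network are each union-DE gene's expression across **all
samples of all experiments**, median-centered per experiment to remove
batch location. Adjacency is unsigned, |r|^β. The soft-power search
evaluates, per candidate power, the scale-free fit: connectivities are
discretized into 10 equal-width bins, log10 frequency is regressed on log10
mean connectivity, and R² is negated when the slope is positive; the chosen
power is the smallest reaching R² ≥ 0.8, else the argmax. The pipeline
default is the study convention β = 7 (the fit table is always written for
inspection; `beta: auto` switches to the data-driven choice, which is
unstable on matrices this small).

Topological overlap is computed in matrix form,
`TO = (A·A − a_ii·a_ij − a_ij·a_jj + A) / (min(k_i,k_j) + 1 − A)` with
k excluding the diagonal and unit TO diagonal; the suite verifies exact
agreement with a naive double loop of the pairwise formula.

Module detection clusters 1 − TO by average linkage and applies a
tree-variant dynamic cut: a static seed cut at the 0.99 quantile of merge
heights, then per branch — a cut producing ≥ 2 children of size ≥
`min_module_size` is a real split and recursion continues; a cut producing
one big child plus undersized offcuts is treated as noise chaining, the
offcuts are peeled (label 0) and the big branch is re-cut. Branches that
cannot split further become modules, renumbered by size. The PAM-like
"hybrid" refinement stage of the reference algorithm is not implemented.
`min_module_size` defaults to 30 (the reference convention); the pipeline
configuration uses 15 because its DE network holds ~600–800 genes rather
than the thousands of a full platform.

Hubs are per-module genes ranked by degree on the TO ≥ 0.10 graph, ties
broken by summed incident TO then gene id (fully deterministic). The
TF → target stage takes each TF's TO ≥ threshold neighborhood, tests each
of the TF's motifs for over-representation among neighbors vs.
non-neighbors (one-sided Fisher, BH across the TF's motifs — a small
per-TF family, so the harmonic BY penalty is unnecessary), and keeps edges
to neighbors carrying a significant motif.

## Synthetic study design

The generator emulates a desk-scale version of a multi-laboratory nitrate
root transcriptome compendium. Defaults (the reference study conditions):
2000 genes, 300 families (sizes 1 + Poisson(3); singletons beyond), 300 GO
terms in a depth-9 DAG, 10 experiments of 3 treatment + 3 control
replicates, baseline ~ Normal(8, 1.5) log2 units, residual sd 0.5, planted
log2 effect 2.0 with 10% of responsive genes down-regulated, 5 responsive
terms × 20 families each, redundancy 0.2, 5 planted modules × 40 genes at
within-module correlation 0.64, 4 TFs with motif planting rate 0.8 over a
2% background, and direct-signal flags at 0.8 in four "hot" modules vs. 2%
elsewhere. One master seed drives independent per-stage RNG streams, so
outputs are bit-reproducible.

Choices that required design judgment:

* **Responsive terms are deep leaves.** Interior terms inherit their whole
  subtree's genes under propagation, so planting a function on an interior
  term buries it in background annotation; leaf terms at levels 7–8 keep
  the annotated set compact (≈ 20 families × 3–4 members + random extras).
* **Term size vs. family size.** Each responsive family contributes exactly
  one member per experiment, so a term's expected DE count equals its family
  count. Twenty families of size 3–4 give enrichment comfortable power
  against the DE list (~100 planted + ~70 permutation false calls out of
  2000) under the heavy BY penalty, while keeping the per-family member
  pool large enough for degeneracy. These sizes were fixed from this power
  analysis, before calibration runs.
* **Degeneracy mechanism.** Per (term, family) a canonical member is drawn
  once; each experiment keeps it with probability `redundancy`, otherwise
  resamples uniformly from the family. Redundancy 1 forces identical gene
  sets; low redundancy yields low gene overlap with unchanged function
  overlap.
* **Modules are condition-balanced and family-aware.** The module latent is
  zero-meaned (variance restored) within every condition group so planted
  coexpression is orthogonal to the planted treatment effect — module genes
  are not pseudo-DE and the null type-I measurement stays clean. Module
  genes are drawn from responsive-family members (so the DE-driven network
  contains them), round-robin across the families of a single responsive
  term — spreading members over many families keeps the mild within-family
  anti-correlation (one member responds per experiment) from dominating any
  module, and the one-term-per-module layout gives detected modules a
  coherent planted function. Module genes carry a larger
  residual scale (`module_scale` = 2 × noise sd) so the latent remains
  visible beside the treatment shifts; within-module correlation in the
  pure-module benchmark is analytically `module_cor` (gene =
  √c·latent + √(1−c)·noise).
* **Similarity table.** Within-family pairs get Beta(8, 2) scores (mean
  0.8), between-family pairs are absent — emulating an already-filtered,
  length-normalized alignment table. Promoters are not sequences; motif
  presence is a Boolean gene × motif table.
* **Calibration terms.** The similarity-test benchmarks simulate shared
  terms directly: the planted mode draws distinct members per experiment
  (the degenerate alternative); the null mode assigns similarity i.i.d.
  across pairs and contributors uniformly, which makes the observed
  statistic exchangeable with null draws by construction.

What the generator does **not** emulate: probe-level microarray noise and
normalization artifacts, heavy-tailed expression, correlated annotation
biases, realistic GO topology, promoter sequence context, or
batch-by-treatment interactions. Passing tests therefore demonstrate
correctness and calibration of the procedures under a clean generative
model, not performance on raw array data.

## Problem sizes and runtime

The reference conditions (2000 genes × 10 experiments, 1000 permutations
for DE and for the similarity test, 1000 random lists) run end to end in
well under a minute on one CPU; benchmarks in the test suite use the same
conditions, with the null-calibration checks at 20 seeds (DE) and 600
simulated terms (similarity). The exhaustive rank-product oracle runs at
G = 3, k = 2, where the null has exactly 36 equiprobable rank matrices.

## Known limitations

* The all-pairs comparison design plus independent per-comparison shuffling
  makes PFP mildly anti-conservative (measured ≈ 6–7% calls at the 5%
  threshold under the null); a paired-comparison or sample-label
  permutation scheme would be calibrated but is a different estimator.
* The scale-free fit is noisy for networks of a few hundred genes; the
  pipeline therefore pins β = 7 by default and treats the fit table as
  diagnostic output.
* Dynamic tree cut is implemented in its tree variant only; borderline
  genes that the hybrid variant's assignment stage would rescue are left
  unlabeled (module 0).
* GMT/edge-list inputs assume is_a-style parentage; relationship types,
  obsolete terms and full OBO parsing are out of scope.
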