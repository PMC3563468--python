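# Methods

## Model

A regulatory module is a set of genes whose expression across experimental
conditions is explained by one *regulatory decision tree*: a binary tree
whose internal nodes query the discretized expression level of a candidate
transcription factor (TF) and whose leaves are condition subgroups. The
working assumption is that TFs act through changes in their own transcript
level — post-translational regulation (e.g. phosphorylation) is outside
the model — and that, conditional on the leaf a condition falls in, a
member gene's expression values are independent Gaussians.

Within leaf *S_k* the parameters (μ_k, σ_k) are the sample mean and the
population (1/n) standard deviation of the member genes' values in those
conditions, pooled over genes. The per-gene log-likelihood is

    l(g_i) = Σ_k Σ_{j ∈ S_k} [ −(x_ij − μ_k)² / (2 σ_k²) − ln σ_k ]

with the constant −½·ln(2π) dropped everywhere: every tree covers the same
condition set, so the constant contributes identically to every comparison
(split selection, reassignment) and cancels. The module likelihood is the
sum of member-gene likelihoods.

## Fitting procedure

1. **DEG selection.** A gene is differentially expressed when some
   condition value satisfies x > t or x < −t (strict; default t = 3, on the
   normalized log scale). Raising t can only shrink the selection.
2. **TF discretization.** Each TF profile is clustered into k = 2 or 3
   level groups; k is the number of expression situations (> t, < −t,
   between) present in the profile. The 1-D k-means is solved *exactly* by
   exhaustive search over contiguous partitions of the sorted values
   (optimal 1-D clusters are contiguous), with cuts restricted to
   boundaries between distinct values so equal values always share a
   level. Clusters map to levels by ascending centroid; with two clusters
   the label pair follows the centroid signs ({0,+1} both non-negative,
   {−1,0} both non-positive, {−1,+1} mixed). Near-constant profiles are
   excluded from candidacy with a warning.
3. **Initial clustering.** K-means (Euclidean, best of `n_restarts` by SSE)
   on DEG profiles. When k is not supplied it is chosen from a grid
   (default 10–150 by 10) at the knee of the (mean cluster size, mean
   within-cluster pairwise correlation) curve, operationalized as the point
   of maximum perpendicular distance to the chord joining the curve's
   endpoints. Both axes are rescaled to [0, 1] before the distance is
   computed — the axes carry incommensurate units and without rescaling
   the size axis dominates. Ties break to the smallest k.
4. **Tree construction.** Greedy recursion: at each node every (TF, level)
   query with two non-empty condition sides is scored by the summed
   Gaussian log-likelihood of the cluster genes under the two fitted
   subgroups, and the best is taken. Recursion stops at `max_depth`
   (default 5 TF levels), when the condition set has at most
   `min_leaf_conditions` members (default 2), when no candidate exists, or
   when the best split's gain over the unsplit leaf is below `min_gain`
   (default 0) — the gain rule quantifies the otherwise qualitative
   "similar enough" stopping criterion. Score ties break by TF id then
   queried level (+1 first) so fits are reproducible.
5. **Reassignment and iteration.** Genes move to the argmax-likelihood
   tree (leaf parameters frozen during the pass; ties to the lowest tree
   index); trees are then rebuilt from the new members. Clusters emptied
   by reassignment are dropped, so the module count can shrink below the
   initial k. The loop ends when an assignment pass changes nothing or
   after `max_iterations`.

**Monotone ascent.** Reassignment is an argmax under fixed trees, and
refitting leaf parameters is a constrained maximum-likelihood update, so
both steps are non-decreasing in the total log-likelihood. A *greedy*
structural rebuild, however, carries no such guarantee. The fit therefore
keeps the incumbent tree structure (leaves refit to the current members)
whenever the greedy rebuild scores lower. This makes the per-iteration
likelihood trace provably non-decreasing and guarantees termination, while
`build_tree` itself remains the plain greedy construction.

**Self-regulation.** A cluster containing a TF's own gene may query that
TF (TFs are themselves differentially expressed, clusterable targets);
`exclude_self=True` disables this.

## Numerical choices

- **Variance floor.** σ is clamped below at 1e−4. Zero-variance leaves
  (single conditions, perfectly coherent genes) would otherwise produce
  infinite densities; the floor keeps likelihoods finite and comparable.
- Population (1/n) standard deviation so single-condition leaves are
  well-defined.
- Condition and gene indices are 0-based internally; external identifiers
  are opaque strings. GFF3 coordinates (1-based inclusive) are converted
  to 0-based half-open on input.
- Mathematically tied splits (distinct TFs inducing the same condition
  partition) can order differently under different floating-point
  summation schemes; all equivalence checks in the test suite compare
  scores, not labels, for this reason.

## Validation statistics

Module **coherence** is the mean Pearson r over all unordered member
pairs; pairs involving a zero-variance profile contribute 0 (logged).
**Enrichment** per function term is the upper-tail hypergeometric
probability P(X ≥ a) of the module's a hits given the background
(N genes, K annotated) and module size n, reported both raw — the scale on
which per-module results are usually tabulated — and Benjamini–Hochberg
adjusted across the terms tested within the module (the annotation input
carries no GO-namespace column, so the adjustment pools namespaces). Terms
with fewer than `min_hits` (default 3) module hits are not tested. A probe
mapping to several genes is expanded to one annotation row per gene before
counting.

## Promoter extraction

Upstream windows (default 500 bp) are taken 5′ of the translation start:
the 5′-most CDS boundary when CDS features exist, else the gene feature's
5′ end — an approximation where UTR annotation is incomplete. Windows are
truncated at contig edges rather than skipped, minus-strand windows are
reverse-complemented, and the export writes plain FASTA plus a sidecar
note with the intended external MEME settings (motif width 6–18 nt, site
p < 0.001). Motif discovery and motif-motif comparison run externally;
their summary tables are parsed back and flagged at the p < 0.001 cutoff.

## Synthetic data

The generator inverts the likelihood model into a sampler: random
three-level TF vectors per condition, a random decision tree per module
(default depth 2, giving up to 4 leaves over 30 conditions — within the
1–5 TF levels trees exhibit in practice), leaf means drawn from a grid
with spacing `leaf_mean_separation` (default 3), and gene values drawn
Normal(leaf mean, `noise_sigma`, default 1). Module condition-mean
profiles are rejection-sampled to be mutually distinct (Euclidean
separation of at least sep·√n_cond/2), since indistinguishable modules are
unidentifiable under the model. TF rows are planted at level·(t+1) plus
±0.25 jitter so DEG selection keeps them and discretization recovers the
planted levels exactly. Annotations plant one enriched term per module at
a stated coverage fraction plus Bernoulli background noise.

The default generator conditions (5 modules × 40 genes, 30 conditions,
10 TFs, separation 3, σ = 1) are the problem sizes used throughout the
recovery experiments and by `scripts/acceptance.py`; the monotone-ascent
sweep uses 100 smaller replicates (3 modules × 6 genes, 12 conditions,
5 TFs) so that many independent fits are exercised.

What passing recovery tests shows — and does not. The generator draws
data exactly from the model family the fit assumes (independent Gaussian
leaves, TFs acting through transcript level, modules distinct by
construction). Recovery at ARI ≥ 0.9 under these conditions demonstrates
correctness of the machinery, not robustness to the violations real
microarray data exhibit: correlated residuals across conditions,
replicate structure, probe cross-hybridization, TFs regulated only
post-translationally, and modules of very unequal size.

## Known limitations

- Tree construction is greedy and unpenalized; there is no averaging over
  tree structures and no cross-validation of tree size.
- A node can query only the +1 or −1 state of a TF; "normally expressed"
  (level 0) cannot be queried directly and such conditions fall to the
  *no* branch.
- The fit converges to a local optimum of the likelihood; different
  initial clusterings can yield different module sets.
- Enrichment treats annotation terms as independent; the term hierarchy
  (parent/child GO relations) is not modeled.
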