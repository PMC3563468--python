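# gnet — gene regulatory module inference from expression data

`gnet` infers **gene regulatory modules** — sets of co-expressed genes
together with the transcription factors (TFs) that putatively regulate
them — from a normalized log-scale expression matrix (genes × experimental
conditions) and a list of candidate TF genes. It is aimed at systems
biologists working on organisms with little prior regulatory knowledge
(e.g. crop plants under stress treatments), where networks must be learned
from expression data alone.

## The model

Starting from the differentially expressed genes (DEGs: |x| > 3 in at least
one condition), each candidate TF's profile is discretized per condition
into expression levels {−1: lowly, 0: normally, +1: highly expressed} by
exact 1-D k-means. DEGs are initially clustered by k-means (the cluster
count chosen at the knee of the mean-cluster-size vs mean-within-cluster
correlation curve), then two steps alternate until gene assignments
stabilize:

1. **Regulatory decision tree construction.** For each cluster, a binary
   tree is grown greedily over the conditions: each internal node queries
   one TF's level (is it +1? is it −1?), sending matching conditions to the
   *yes* branch. Within each leaf's condition subgroup *S<sub>k</sub>*, the
   cluster genes' values are modeled as Gaussian with parameters
   (μ<sub>k</sub>, σ<sub>k</sub>); the split maximizing the summed log-likelihood

   ℓ(g<sub>i</sub>) = Σ<sub>k</sub> Σ<sub>j∈S<sub>k</sub></sub> [ −(x<sub>ij</sub> − μ<sub>k</sub>)² / (2σ<sub>k</sub>²) − ln σ<sub>k</sub> ]

   over the cluster's genes is chosen at each node (trees have up to five
   TF levels).
2. **Maximum-likelihood reassignment.** Every gene is moved to the tree
   under which ℓ(g<sub>i</sub>) is maximal (leaf parameters frozen); the
   module likelihood is ℓ(M) = Σ<sub>i</sub> ℓ(g<sub>i</sub>).

Fitted modules are validated by their **coherence** (mean pairwise Pearson
*r* of member profiles) and by **hypergeometric enrichment** of function
terms (upper-tail *p* with Benjamini–Hochberg adjustment), and each
module's 500 bp upstream promoter windows can be exported as FASTA for
external motif discovery (MEME/TomTom).

## Worked example

```python
from gnet import GeneModuleNetworkModel, synthetic
from gnet.preprocess import discretize_tf_matrix

matrix, tf_ids, truth = synthetic.generate(seed=1)   # 5 planted modules
profiles = discretize_tf_matrix(matrix, tf_ids, threshold=3.0)
model = GeneModuleNetworkModel(matrix, profiles, max_depth=5)
result = model.fit(k=5, seed=0)
print(result.summary())
```

```
Gene regulatory module fit
==============================================================
genes:    210    conditions:   30    candidate TFs:   10
modules:    5    iterations:   1    converged: True
total log-likelihood: -4123.1567
--------------------------------------------------------------
module  genes  TFs  depth  coherence       loglik
     0     40    8      5     0.9517      -578.71
     1     50    8      5     0.5590     -1799.72
     2     40    9      5     0.9276      -553.29
     3     40    9      5     0.9688      -569.29
     4     40    8      5     0.8502      -622.15
==============================================================
```

Each row is one recovered module: its gene count (module 1 additionally
absorbed the 10 TF genes, which are themselves differentially expressed),
the number of distinct TFs queried in its regulatory tree, the tree depth,
the module coherence (mean pairwise Pearson *r*; high values mean tightly
co-expressed members), and the summed member log-likelihood. Here the five
planted modules are recovered exactly (adjusted Rand index 1.0 against the
ground truth in `truth`).

The same workflow is available from the shell:

```bash
gnet simulate --seed 1 --out-dir sim
gnet fit --matrix sim/expression.tsv --tf-list sim/tf_list.tsv --k 5 --out-dir fit
gnet report --modules fit/modules.json --matrix sim/expression.tsv
```

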