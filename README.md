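# autophy

Automated, threshold-free partitioning of a phylogenetic tree into
monophyletic clusters (protein subfamilies), with per-cluster divergence
scores and an annotation-concordance test.

## Who this is for

Phylogenetic analysis resolves functional subfamilies inside broad
protein families (porins, hydrolases, receptors, …) as clades, but
delineating those clades is usually manual, or depends on an ad hoc
distance threshold whose choice changes the answer. This package makes
the partition a model-selection problem instead: the user supplies only
a rooted tree with branch lengths.

## Method

Given a rooted tree with n leaves:

1. **Patristic distance matrix.** δ(i, j) = sum of branch lengths on the
   i–j path, for all leaf pairs.
2. **Embedding.** UMAP reduces the n×n matrix (consumed as a precomputed
   metric) to n×d points, d = 2 by default.
3. **Mixture sweep.** Gaussian mixtures with k = 1..min(n−1, 50)
   full-covariance components are fit by EM and scored with
   BIC = p·ln(n) − 2·ln L̂; the lowest-BIC model assigns each leaf an
   integer cluster label.
4. **Monophyletic cluster maximization.** Clusters that are not clades
   are decomposed into the maximal clades of the tree they contain
   (unique, since tree clades form a laminar family); parts of cluster B
   are relabeled B.0, B.1, … Every final cluster is monophyletic by
   construction.
5. **Divergence scores.** Per cluster: MPD = Σ_{i<j} δ(i, j) / C(n, 2),
   the subtending branch length (MRCA's parent edge), and
   log_ratio = ln(MPD / subtending). Strongly negative scores mark tight
   subfamilies on long stems.
6. **Validation (optional).** With a leaf→annotation table, the Fitch
   parsimony score of the annotation keys (first 3 characters by
   default) is compared against uniformly permuted assignments;
   p = (1 + #{null ≤ obs}) / (n_perm + 1).

See `docs/methods.md` for assumptions, parameter defaults, and
limitations.

## Worked example

`examples/cluster_planted_tree.py` simulates a 40-leaf tree with four
planted subfamilies (tight clades on 100×-longer stems) and runs the
whole pipeline:

```
leaves: 40
selected k (lowest BIC): 4
final monophyletic clusters: 4
adjusted Rand index vs planted truth: 1.00
  cluster 0: 10 tips, MPD=0.1342, stem=5.595, log ratio=-3.73
  cluster 1: 10 tips, MPD=0.1094, stem=5.950, log ratio=-4.00
  cluster 2: 10 tips, MPD=0.1175, stem=4.630, log ratio=-3.67
  cluster 3: 10 tips, MPD=0.1164, stem=4.631, log ratio=-3.68
```

The BIC sweep chose k = 4 with no threshold; the adjusted Rand index of
1.00 means the planted subfamilies were recovered exactly; each
cluster's log ratio ≈ −3.7 says its internal divergence is e^3.7 ≈ 40×
smaller than the stem isolating it. The other examples print divergence
scores on a toy tree (`examples/divergence_scores.py`) and run the
annotation-concordance test (`examples/annotation_concordance.py`,
observed score 2 vs permutation null 12–22, p = 0.001).

The same pipeline is available from the shell:

```sh
autophy simulate --clades 4 --seed 1 --tree-out family.nwk --truth-out truth.tsv
autophy cluster --tree family.nwk --seed 1 --out results/
```

`results/` then holds `clusters.tsv` (leaf, cluster label, provenance),
`divergence.tsv`, `bic_curve.tsv`, the cluster-annotated tree in newick
and FigTree-colored nexus, and `metadata.json` (effective config, stage
timings, cluster counts).

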