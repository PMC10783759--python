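# Methods

## The problem

Protein families catalogued at the family level (profile-HMM databases,
keyword searches) hide substantial functional diversity: subfamilies with
distinct substrates or roles appear as clades of the family's phylogeny.
Partitioning a tree into such subfamilies is usually done by hand, or by
tools that require an ad hoc distance threshold or minimum cluster size.
This package partitions a rooted phylogenetic tree with branch lengths
into monophyletic clusters without any user-supplied threshold, then
scores each cluster's relative divergence and, when annotations are
available, the concordance between the clustering and the annotations.

## Pipeline

1. **Patristic distance matrix (PDM).** For leaves i, j, δ(i, j) is the
   sum of branch lengths on the unique path between them. Rows are
   ordered by a stable postorder traversal of the input tree.
2. **Embedding.** The n×n PDM is reduced to n×d points (d = 2 by
   default, up to 10) with UMAP consuming the matrix as a *precomputed*
   metric — distances are never re-derived from matrix rows. UMAP
   preserves neighborhood structure, so tight subtrees separated by long
   stems become compact, well-separated point clouds.
3. **Mixture sweep.** Gaussian mixtures with k = 1..k_max full-covariance
   components are fit by expectation–maximization and scored by
   BIC = p·ln(n) − 2·ln L̂, with p = (k−1) + k·d + k·d(d+1)/2. The
   lowest-BIC model wins; ties go to smaller k. Hard maximum-posterior
   labels (consecutive integers from 0) are the putative clusters.
4. **Monophyletic cluster maximization.** Each mixture cluster is mapped
   back to the tree. A cluster whose members are exactly the descendant
   leaves of their MRCA keeps its integer label. Any other cluster is
   decomposed into the maximal clades of the tree contained in it; the
   clades of a rooted tree form a laminar family, so this decomposition
   is unique, disjoint, and covers the cluster. Parts are labeled
   B.0, B.1, … in extraction order (size descending; equal sizes broken
   toward the part containing the lexicographically smallest leaf label).
5. **Divergence scores.** Per final cluster: MPD (mean patristic distance
   over unordered leaf pairs, i.e. Σ_{i<j} δ(i,j) / C(n,2)), the
   subtending branch (edge from the cluster's MRCA to the previous
   split), and log_ratio = ln(MPD / subtending). Strongly negative values
   flag tight clusters on long stems — candidates for strong purifying
   constraint. Singletons (MPD = 0), root clusters (no subtending
   branch) and zero-length stems are reported as undefined with a reason
   code, never as ±infinity.
6. **Annotation concordance (optional).** Each leaf's annotation is
   reduced to a categorical key (its first 3 characters by default); the
   minimum number of key changes on the tree (small parsimony) is
   compared with the scores of uniformly permuted leaf→key assignments.
   p = (1 + #{null ≤ observed}) / (n_perm + 1), so p is never exactly 0.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `dims` | 2 | embedding dimensionality (2–10) |
| UMAP `n_neighbors` | min(15, n−1) | neighborhood size |
| UMAP `min_dist` | 0.1 | minimum embedded distance |
| `k_max` | min(n−1, 50) | largest mixture size swept |
| EM restarts | 5 | best log-likelihood kept |
| EM tolerance | 1e-4 | mean log-likelihood change |
| `reg_covar` | `"auto"` | covariance floor, 1e-2 × mean per-dimension variance |
| `log_base` | e | log ratio base (10 available) |
| `key_length` | 3 | annotation prefix used as parsimony state |
| `n_perm` | 999 | label permutations for the null |
| `seed` | 42 | master seed; derives one seed per stochastic stage |

Branch lengths are in whatever units the tree carries (typically
substitutions/site); MPD and subtending lengths inherit those units and
the log ratio is dimensionless and invariant under rescaling all branch
lengths.

### Why the covariance floor is relative

With an absolute covariance regularization (say 1e-6), a component that
collapses onto one or two embedded points reaches the floor and its
likelihood grows without meaningful bound; on small inputs this
degenerate reward outruns BIC's p·ln(n) penalty and the sweep drifts
toward k ≈ n−1 even when the embedding shows perfectly separated blobs.
Scaling the floor to the data (1e-2 of the mean per-dimension variance)
bounds the reward a collapsed component can earn while leaving genuinely
separated structure untouched. An absolute floor can still be supplied
as a float.

## Rooting and degenerate inputs

Monophyly and subtending branches are meaningless without a root, so a
basal trifurcation (the usual signature of an unrooted newick) is a hard
error unless midpoint rooting is explicitly requested; applied rooting is
recorded in the run metadata. Zero-length branches are accepted (they
occur in MCC summary trees); negative or missing branch lengths are hard
errors, as are duplicate or empty leaf labels. Clustering requires ≥ 4
leaves (distance computation alone requires 2). Trees with fewer than 8
leaves bypass UMAP — whose neighborhood graph is unreliable at tiny n —
in favor of classical metric scaling (principal coordinates) of the PDM;
the bypass is recorded in the metadata.

Parsimony handles polytomies exactly: the score is computed by a
unit-cost dynamic program over observed states, which reduces to the
classic intersection/union recurrence on bifurcating trees and remains
exactly minimal at multifurcations (the plain pairwise rule can
undercount there).

## The synthetic generator

`generate_planted_tree` emulates the geometry of trees that cluster
cleanly: c clades hanging off a backbone (caterpillar or balanced), with
within-clade patristic diameters of about 2×`within_height` and stems of
about `stem_length`. Within a clade the topology is a random merge;
internal edges are short (exponential, mean 0.1 × height by default —
the "radiation" shape) and terminal branches are near the clade height.
The "star" shape sets internal edges to zero: a hard-polytomy radiation
with no substructure at all, which is the structureless negative
control. Defaults (`within_height` = 0.05, `stem_length` = 5.0, i.e. a
100× separation ratio; clade sizes drawn from 8–15) describe strongly
separated subfamilies.

A deliberate caveat: a clade whose internal edges carry non-trivial
random length is *not* structureless — it contains genuine nested
clades, and the pipeline resolves them. Only the star shape is a fair
"no subfamilies" control.

What the generator does not emulate: rate heterogeneity across sites or
lineages, alignment and tree-inference error, overlapping or weakly
separated subfamilies, and annotation noise. Passing the recovery tests
therefore demonstrates correctness of the machinery under unambiguous
geometry, not performance on hard real data, where over-splitting of
long-branch clades is the known failure mode.

## Problem sizes used in tests and the acceptance script

Recovery experiments use c ∈ {2, 3, 4, 6} clades of 8–15 leaves over 10
seeds each; the negative control uses 40-leaf star clades over 10 seeds;
oracle comparisons use 100–200 random trees (n ≤ 20 for distances,
n ≤ 12 for clade decomposition, n ≤ 8 for exhaustive parsimony);
mixture-recovery uses k ∈ {1..5} components of 100 points at 20σ
separation. These sizes keep each experiment's combinatorial oracle
exact and the full run comfortably reproducible on a laptop CPU.

## Numerical choices

* BIC ties break toward smaller k (parsimony).
* Clade-decomposition ties (equal-size maximal clades) break toward the
  part containing the lexicographically smallest leaf label; the set of
  parts itself is order-independent.
* Patristic matrices are validated for symmetry, zero diagonal and
  finiteness; generated trees additionally satisfy the four-point
  condition to 1e-6 of the matrix scale in tests.
* One master seed derives independent per-stage seeds (embedding,
  mixture, permutations) via seed sequences, so a single integer
  reproduces a run byte-for-byte.

## Known limitations

* UMAP can fabricate apparent clusters from weak continuous structure;
  the BIC sweep inherits that tendency (over-splitting), consistent with
  the method's behavior on long-branch families.
* Final clusters are never re-merged across different mixture clusters,
  and the mixture is not re-run on split remnants; many small clusters
  on sparse data are expected.
* Hard labels only; no soft memberships are propagated downstream.
* The permutation test permutes annotations uniformly over all leaves;
  no stratification is offered.
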