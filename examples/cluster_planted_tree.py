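"""Cluster a simulated protein-family tree and recover its subfamilies.

Builds a planted-partition tree (4 tight clades on long stems), runs the
full pipeline (patristic distances -> UMAP -> GMM/BIC sweep -> monophyly
maximization) and compares the result with the planted truth.
"""

from sklearn.metrics import adjusted_rand_score

from autophy import PlantedTreeSpec, RunConfig, generate_planted_tree, run_on_tree

spec = PlantedTreeSpec(n_clades=4, leaves_per_clade=10, seed=1)
tree, truth = generate_planted_tree(spec)
result = run_on_tree(tree, RunConfig(seed=1))

pred = [str(result.partition.assignments[leaf]) for leaf in tree.leaf_labels]
ari = adjusted_rand_score([truth[leaf] for leaf in tree.leaf_labels], pred)

print(f"leaves: {tree.n_leaves}")
print(f"selected k (lowest BIC): {result.sweep.selected_k}")
print(f"final monophyletic clusters: {result.partition.n_clusters}")
print(f"adjusted Rand index vs planted truth: {ari:.2f}")
for record in result.records:
    print(
        f"  cluster {record.cluster_label}: {record.n_tips} tips, "
        f"MPD={record.mpd:.4f}, stem={record.subtending_length:.3f}, "
        f"log ratio={record.log_ratio:.2f}"
    )
# The BIC sweep picks the number of clusters without any threshold; an
# ARI of 1.00 means the planted subfamilies were recovered exactly, and
# the strongly negative log ratios say each cluster is far tighter than
# the stem separating it from the rest of the tree.
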