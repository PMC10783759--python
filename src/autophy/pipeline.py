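"""End-to-end orchestration: tree → distances → embedding → mixture →
monophyly maximization → divergence scores (→ optional annotation
validation), with reproducible seeded stages and atomic file outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
import shutil
import sys
import tempfile
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import __version__
from .divergence import DivergenceRecord, divergence_report, report_frame
from .embed import MIN_LEAVES_FOR_UMAP, embed_distances
from .mcim import ClusterPartition, is_monophyletic, maximize_monophyly
from .mixture import GmmSweepResult, bic_curve, sweep_gmm
from .tree import (
    PatristicDistanceMatrix,
    RootedTree,
    patristic_matrix,
    read_tree,
    write_clustered_tree,
)
from .validate import AnnotationTable, PermutationTestResult, parsimony_randomization

__all__ = ["RunConfig", "RunMetadata", "PipelineResult", "run_pipeline", "run_on_tree"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a pipeline run; every knob is recorded in the run
    metadata so results are reproducible from the metadata alone."""

    tree_path: Optional[str] = None
    format: str = "auto"
    seed: int = 42
    dims: int = 2
    k_max: Optional[int] = None  # default min(n-1, 50), resolved at run time
    log_base: str = "e"  # "e" or "10"
    midpoint_root: bool = False
    embed_method: str = "auto"  # auto | umap | mds
    annotations_path: Optional[str] = None
    key_length: int = 3
    drop_unannotated: bool = False
    n_perm: int = 999
    out_dir: Optional[str] = None

    def resolved_log_base(self) -> float:
        if self.log_base in ("e", "ln"):
            return math.e
        if self.log_base == "10":
            return 10.0
        raise ValueError(f"log base must be 'e' or '10', got {self.log_base!r}")


@dataclass
class RunMetadata:
    config: dict
    version: str
    n_leaves: int
    selected_k: int
    n_mixture_clusters: int
    n_nonmonophyletic_flagged: int
    n_final_clusters: int
    undefined_reasons: dict[str, int]
    embed_method: str
    stage_seconds: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    tree: RootedTree
    pdm: PatristicDistanceMatrix
    sweep: GmmSweepResult
    partition: ClusterPartition
    records: list[DivergenceRecord]
    metadata: RunMetadata
    permutation: Optional[PermutationTestResult] = None


def _derive_seeds(seed: int, n: int = 3) -> list[int]:
    """Per-stage seeds from one master seed (embed, mixture, permutation)."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def _log(stage: str, msg: str) -> None:
    print(f"[autophy] {stage}: {msg}", file=sys.stderr)


def run_on_tree(
    tree: RootedTree,
    config: RunConfig = RunConfig(),
    annotations: Optional[AnnotationTable] = None,
) -> PipelineResult:
    """Run the clustering pipeline on an in-memory tree.

    Stages: patristic matrix → embedding → GMM/BIC sweep → monophyly
    maximization → divergence report → optional parsimony validation.
    Deterministic for a fixed (tree, config): the master seed derives one
    seed per stochastic stage.
    """
    if tree.n_leaves < 4:
        raise ValueError("the clustering pipeline requires at least 4 leaves")
    embed_seed, gmm_seed, perm_seed = _derive_seeds(config.seed)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    pdm = patristic_matrix(tree)
    timings["patristic_matrix"] = time.perf_counter() - t0
    _log("pdm", f"{pdm.n} leaves")

    method = config.embed_method
    if method == "auto":
        method = "umap" if tree.n_leaves >= MIN_LEAVES_FOR_UMAP else "mds"
    t0 = time.perf_counter()
    emb = embed_distances(pdm, d=config.dims, seed=embed_seed, method=method)
    timings["embedding"] = time.perf_counter() - t0
    _log("embed", f"method={method} d={config.dims}")

    k_max = config.k_max if config.k_max is not None else min(tree.n_leaves - 1, 50)
    t0 = time.perf_counter()
    sweep = sweep_gmm(emb, k_max=k_max, seed=gmm_seed)
    timings["mixture"] = time.perf_counter() - t0
    _log("mixture", f"swept k=1..{k_max}, selected k={sweep.selected_k}")

    mixture_labels = dict(zip(tree.leaf_labels, (int(x) for x in sweep.labels)))
    n_mix = len(set(mixture_labels.values()))
    by_cluster: dict[int, set[str]] = {}
    for lf, lb in mixture_labels.items():
        by_cluster.setdefault(lb, set()).add(lf)
    n_flagged = sum(
        0 if is_monophyletic(tree, m) else 1 for m in by_cluster.values()
    )
    t0 = time.perf_counter()
    partition = maximize_monophyly(tree, mixture_labels)
    timings["mcim"] = time.perf_counter() - t0
    clusters = partition.clusters()
    for members in clusters.values():  # hard guarantee of the whole method
        assert is_monophyletic(tree, members)
    _log("mcim", f"{n_mix} mixture clusters, {n_flagged} flagged, "
                 f"{len(clusters)} final clusters")

    t0 = time.perf_counter()
    records = divergence_report(
        tree, pdm, partition, base=config.resolved_log_base()
    )
    timings["divergence"] = time.perf_counter() - t0

    permutation = None
    if annotations is not None:
        t0 = time.perf_counter()
        states = annotations.keys_for(
            tree, drop_unannotated=config.drop_unannotated
        )
        permutation = parsimony_randomization(
            tree, states, n_perm=config.n_perm, seed=perm_seed,
            drop_unannotated=config.drop_unannotated,
        )
        timings["validation"] = time.perf_counter() - t0
        _log("validate", f"observed={permutation.observed} "
                         f"p={permutation.p_value:.4g}")

    reasons: dict[str, int] = {}
    for r in records:
        if r.reason:
            reasons[r.reason] = reasons.get(r.reason, 0) + 1
    metadata = RunMetadata(
        config=dataclasses.asdict(config),
        version=__version__,
        n_leaves=tree.n_leaves,
        selected_k=sweep.selected_k,
        n_mixture_clusters=n_mix,
        n_nonmonophyletic_flagged=n_flagged,
        n_final_clusters=len(clusters),
        undefined_reasons=reasons,
        embed_method=method,
        stage_seconds={k: round(v, 4) for k, v in timings.items()},
    )
    return PipelineResult(
        tree=tree, pdm=pdm, sweep=sweep, partition=partition,
        records=records, metadata=metadata, permutation=permutation,
    )


def _write_outputs(result: PipelineResult, out_dir: str) -> None:
    """Write all artifacts atomically: stage into a temp dir, then move."""
    os.makedirs(out_dir, exist_ok=True)
    stage_dir = tempfile.mkdtemp(prefix=".autophy-", dir=out_dir)
    try:
        leaf_order = result.tree.leaf_labels
        result.partition.to_frame(leaf_order).to_csv(
            os.path.join(stage_dir, "clusters.tsv"), sep="\t", index=False
        )
        report_frame(result.records).to_csv(
            os.path.join(stage_dir, "divergence.tsv"), sep="\t", index=False
        )
        bic_curve(result.sweep).to_csv(
            os.path.join(stage_dir, "bic_curve.tsv"), sep="\t", index=False
        )
        str_partition = {
            lf: str(lb) for lf, lb in result.partition.assignments.items()
        }
        write_clustered_tree(
            result.tree, str_partition,
            os.path.join(stage_dir, "clustered.nwk"), format="newick",
        )
        write_clustered_tree(
            result.tree, str_partition,
            os.path.join(stage_dir, "clustered.nex"), format="nexus",
        )
        if result.permutation is not None:
            result.permutation.to_frame().to_csv(
                os.path.join(stage_dir, "permutation_null.tsv"),
                sep="\t", index=False,
            )
            with open(os.path.join(stage_dir, "validation.json"), "w") as fh:
                json.dump(
                    {
                        "observed": result.permutation.observed,
                        "n_perm": result.permutation.n_perm,
                        "p_value": result.permutation.p_value,
                        "seed": result.permutation.seed,
                    },
                    fh, indent=2, sort_keys=True,
                )
        with open(os.path.join(stage_dir, "metadata.json"), "w") as fh:
            json.dump(result.metadata.to_dict(), fh, indent=2, sort_keys=True)
        for name in os.listdir(stage_dir):
            os.replace(
                os.path.join(stage_dir, name), os.path.join(out_dir, name)
            )
    finally:
        shutil.rmtree(stage_dir, ignore_errors=True)


def run_pipeline(
    config: RunConfig, annotations: Optional[AnnotationTable] = None
) -> PipelineResult:
    """File-level entry point: read the tree, run, write outputs.

    Outputs (in ``config.out_dir`` when set): clusters.tsv,
    divergence.tsv, bic_curve.tsv, clustered.nwk, clustered.nex,
    metadata.json, and permutation_null.tsv/validation.json when an
    annotation table is supplied.  Identical config+seed yields
    byte-identical clusters.tsv and divergence.tsv.
    """
    if config.tree_path is None:
        raise ValueError("config.tree_path is required")
    tree = read_tree(
        config.tree_path, config.format, midpoint_root=config.midpoint_root,
        min_leaves=4,
    )
    if annotations is None and config.annotations_path is not None:
        from .validate import read_annotations

        annotations = read_annotations(
            config.annotations_path, key_length=config.key_length
        )
    result = run_on_tree(tree, config, annotations)
    if config.out_dir is not None:
        _write_outputs(result, config.out_dir)
    return result
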