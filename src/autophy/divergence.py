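"""Per-cluster divergence scoring.

For each final (monophyletic) cluster the pipeline reports its mean
pairwise patristic distance (MPD), the length of its subtending branch —
the edge from the cluster's MRCA to the previous split — and the log
ratio

    log_ratio = ln(MPD / subtending branch length)

A strongly negative score marks a tight cluster hanging from a long stem:
little divergence within the subfamily relative to the divergence that
separates it, the signature of interest for candidate subfamilies under
strong constraint.  Singletons (MPD = 0), clusters whose MRCA is the root
(no subtending branch) and zero-length stems have no finite score and are
reported as undefined with a reason code rather than ±infinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .mcim import ClusterPartition, is_monophyletic
from .tree import PatristicDistanceMatrix, RootedTree

__all__ = [
    "DivergenceRecord",
    "mean_pairwise_distance",
    "subtending_branch_length",
    "log_ratio",
    "divergence_report",
]


@dataclass(frozen=True)
class DivergenceRecord:
    cluster_label: str
    n_tips: int
    mpd: float
    subtending_length: float | None  # None when MRCA is the root
    log_ratio: float | None
    defined: bool
    reason: str | None  # singleton | root-cluster | zero-subtending | zero-mpd


def mean_pairwise_distance(
    pdm: PatristicDistanceMatrix, leafset: Iterable[str]
) -> float:
    """MPD: sum of δ(i, j) over unordered pairs, divided by n·(n−1)/2.

    A singleton has no pairs and returns 0 by convention (flagged as an
    undefined score downstream).
    """
    idx = pdm.indices(leafset)
    if idx.size == 0:
        raise ValueError("empty leaf set")
    if idx.size == 1:
        return 0.0
    sub = pdm.values[np.ix_(idx, idx)]
    n = idx.size
    return float(sub.sum() / 2.0 / (n * (n - 1) / 2.0))


def subtending_branch_length(
    tree: RootedTree, leafset: Iterable[str]
) -> float | None:
    """Length of the edge from the leafset's MRCA to its parent.

    Only monophyletic sets may be scored.  Returns None when the MRCA is
    the root (there is no previous split).
    """
    ls = tree.check_leaves(leafset)
    if not is_monophyletic(tree, ls):
        raise ValueError(
            "subtending branch is defined only for monophyletic clusters"
        )
    mrca = tree.mrca_node(ls)
    if mrca.parent_node is None:
        return None
    return float(mrca.edge.length)


def log_ratio(
    mpd: float, subtending: float | None, *, base: float = math.e
) -> tuple[float | None, str | None]:
    """log(MPD / subtending) in the given base, or (None, reason).

    Reasons: ``root-cluster`` (no subtending branch), ``singleton``
    (MPD = 0 from a one-tip cluster, indistinguishable here from any
    zero MPD, reported as ``zero-mpd`` when n is unknown),
    ``zero-subtending``.
    """
    if mpd < 0 or (subtending is not None and subtending < 0):
        raise ValueError("distances must be non-negative")
    if subtending is None:
        return None, "root-cluster"
    if subtending == 0.0:
        return None, "zero-subtending"
    if mpd == 0.0:
        return None, "zero-mpd"
    return math.log(mpd / subtending) / math.log(base), None


def divergence_report(
    tree: RootedTree,
    pdm: PatristicDistanceMatrix,
    partition: ClusterPartition,
    *,
    base: float = math.e,
) -> list[DivergenceRecord]:
    """One DivergenceRecord per final cluster, ordered by cluster label.

    Undefined scores are carried with reason codes, never dropped.
    """
    records: list[DivergenceRecord] = []
    for lb, members in partition.clusters().items():
        n = len(members)
        mpd = mean_pairwise_distance(pdm, members)
        sub = subtending_branch_length(tree, members)
        lr, reason = log_ratio(mpd, sub, base=base)
        if reason == "zero-mpd" and n == 1:
            reason = "singleton"
        records.append(
            DivergenceRecord(
                cluster_label=str(lb),
                n_tips=n,
                mpd=mpd,
                subtending_length=sub,
                log_ratio=lr,
                defined=lr is not None,
                reason=reason,
            )
        )
    return records


def report_frame(records: list[DivergenceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cluster_label": [r.cluster_label for r in records],
            "n_tips": [r.n_tips for r in records],
            "mpd": [r.mpd for r in records],
            "subtending_length": [r.subtending_length for r in records],
            "log_ratio": [r.log_ratio for r in records],
            "defined": [r.defined for r in records],
            "reason": [r.reason if r.reason is not None else "" for r in records],
        }
    )
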