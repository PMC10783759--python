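"""Low-dimensional embedding of the patristic distance matrix.

The mixture stage clusters points, not distances, so the n×n patristic
matrix is first reduced to an n×d point cloud (d = 2 by default, up to 10).
The default embedder is UMAP consuming the matrix as a precomputed metric;
for very small trees, where a neighborhood graph is unreliable, classical
metric scaling (principal coordinates) of the same matrix can be used
instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .tree import PatristicDistanceMatrix

__all__ = ["Embedding", "embed_distances", "MIN_LEAVES_FOR_UMAP"]

#: below this many leaves the pipeline falls back to classical metric scaling
MIN_LEAVES_FOR_UMAP = 8


@dataclass(frozen=True)
class Embedding:
    """An n×d coordinate matrix over the same leaves, in the same order,
    as the distance matrix it was derived from."""

    labels: tuple[str, ...]
    coords: np.ndarray = field(repr=False)
    d: int
    seed: int
    method: str = "umap"

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (len(self.labels), self.d):
            raise ValueError("coordinate shape does not match labels/d")
        if not np.all(np.isfinite(c)):
            raise ValueError("non-finite embedding coordinates")
        if not 2 <= self.d <= 10:
            raise ValueError("embedding dimension must be in [2, 10]")
        object.__setattr__(self, "coords", c)

    @property
    def n(self) -> int:
        return len(self.labels)


def _umap_embed(values: np.ndarray, d: int, seed: int,
                n_neighbors: int | None, min_dist: float) -> np.ndarray:
    import umap  # deferred: numba compilation makes this import heavy

    n = values.shape[0]
    k = min(15, n - 1) if n_neighbors is None else min(n_neighbors, n - 1)
    if k < 2:
        raise ValueError(f"{n} points is too small for a UMAP neighborhood")
    with warnings.catch_warnings():
        # umap warns that a precomputed metric disables transform(); expected
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=d,
            metric="precomputed",
            n_neighbors=k,
            min_dist=min_dist,
            random_state=seed,
        )
        return np.asarray(reducer.fit_transform(values), dtype=float)


def _pcoa_embed(values: np.ndarray, labels: tuple[str, ...], d: int) -> np.ndarray:
    from skbio import DistanceMatrix
    from skbio.stats.ordination import pcoa

    res = pcoa(DistanceMatrix(values, ids=list(labels)), number_of_dimensions=d)
    coords = np.asarray(res.samples.values, dtype=float)
    if coords.shape[1] < d:  # degenerate matrices can yield fewer axes
        pad = np.zeros((coords.shape[0], d - coords.shape[1]))
        coords = np.hstack([coords, pad])
    return coords[:, :d]


def embed_distances(
    pdm: PatristicDistanceMatrix,
    d: int = 2,
    seed: int = 42,
    *,
    method: str = "umap",
    n_neighbors: int | None = None,
    min_dist: float = 0.1,
) -> Embedding:
    """Embed a patristic distance matrix into ``d`` dimensions.

    Parameters
    ----------
    pdm:
        the precomputed distance matrix; it is consumed as a metric, never
        re-derived from matrix rows.
    d:
        target dimensionality, 2–10 (2 by default).
    seed:
        random seed; the same seed gives identical coordinates.
    method:
        ``"umap"`` (default) or ``"mds"`` for classical metric scaling of
        the distance matrix (deterministic; intended for tiny trees).

    The contract for block-structured inputs (within-block distances much
    smaller than between-block) is that embedded within-block pairs end up
    closer than between-block pairs.
    """
    n = pdm.n
    if n < 4:
        raise ValueError("embedding requires at least 4 leaves")
    if not 2 <= d <= 10:
        raise ValueError("embedding dimension must be in [2, 10]")
    if d >= n:
        raise ValueError(f"embedding dimension {d} must be < number of points {n}")
    if method == "umap":
        coords = _umap_embed(pdm.values, d, seed, n_neighbors, min_dist)
    elif method == "mds":
        coords = _pcoa_embed(pdm.values, pdm.labels, d)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return Embedding(labels=pdm.labels, coords=coords, d=d, seed=seed, method=method)
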