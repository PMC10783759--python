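"""Gaussian-mixture model sweep with BIC model selection.

Mixtures of k = 1..k_max full-covariance Gaussians are fit to the embedded
points by expectation–maximization; each fit is scored by the Bayesian
Information Criterion, BIC = p·ln(n) − 2·lnL̂ with
p = (k−1) + k·d + k·d(d+1)/2, and the model with the lowest BIC wins
(ties broken toward smaller k).  Hard maximum-posterior labels of the
winning model — consecutive integers from 0 — seed the tree-side
monophyly step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .embed import Embedding

__all__ = ["GmmSweepEntry", "GmmSweepResult", "sweep_gmm", "bic_curve"]


@dataclass(frozen=True)
class GmmSweepEntry:
    k: int
    bic: float
    log_likelihood: float
    converged: bool


@dataclass(frozen=True)
class GmmSweepResult:
    entries: tuple[GmmSweepEntry, ...]
    selected_k: int
    labels: np.ndarray = field(repr=False)  # hard labels, 0..selected_k-1

    def entry(self, k: int) -> GmmSweepEntry:
        for e in self.entries:
            if e.k == k:
                return e
        raise KeyError(k)


def _as_points(embedding) -> np.ndarray:
    if isinstance(embedding, Embedding):
        return embedding.coords
    X = np.asarray(embedding, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected an Embedding or an n×d array")
    return X


#: default covariance floor, as a fraction of the mean per-dimension variance
REL_REG_COVAR = 1e-2


def sweep_gmm(
    embedding: Embedding | np.ndarray,
    k_max: int,
    seed: int = 42,
    *,
    n_init: int = 5,
    tol: float = 1e-4,
    reg_covar: float | str = "auto",
    max_iter: int = 500,
) -> GmmSweepResult:
    """Fit GMMs for k = 1..k_max and select the lowest-BIC model.

    Each k is fit with ``n_init`` EM restarts (best log-likelihood kept)
    and full per-component covariances.  Deterministic for a fixed seed.

    ``reg_covar`` is the diagonal floor added to component covariances.
    The default ``"auto"`` scales it to the data,
    ``REL_REG_COVAR × mean per-dimension variance``: an absolute floor
    lets near-singleton components collapse onto it, and the resulting
    degenerate likelihood outruns the BIC penalty, driving the selected k
    toward n−1 on small inputs.  A variance-relative floor bounds that
    reward while leaving well-separated structure untouched.  Pass a float
    for an absolute floor.
    """
    X = _as_points(embedding)
    n = X.shape[0]
    if not 1 <= k_max <= n - 1:
        raise ValueError(f"k_max must be in [1, n-1] = [1, {n - 1}], got {k_max}")
    if reg_covar == "auto":
        reg_covar = max(REL_REG_COVAR * float(np.mean(np.var(X, axis=0))), 1e-10)
    elif not isinstance(reg_covar, (int, float)):
        raise ValueError("reg_covar must be 'auto' or a number")
    entries: list[GmmSweepEntry] = []
    best: tuple[float, int, np.ndarray] | None = None
    for k in range(1, k_max + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_init,
            tol=tol,
            reg_covar=reg_covar,
            max_iter=max_iter,
            random_state=seed,
        )
        gm.fit(X)
        bic = float(gm.bic(X))
        ll = float(gm.score(X) * n)
        converged = bool(gm.converged_)
        entries.append(GmmSweepEntry(k=k, bic=bic, log_likelihood=ll,
                                     converged=converged))
        if converged and np.isfinite(bic):
            if best is None or bic < best[0]:  # strict: ties keep smaller k
                best = (bic, k, gm.predict(X))
    if best is None:
        diag = ", ".join(f"k={e.k}: converged={e.converged}" for e in entries)
        raise RuntimeError(f"no mixture fit converged ({diag})")
    _, selected_k, labels = best
    labels = _relabel_consecutive(labels)
    return GmmSweepResult(entries=tuple(entries), selected_k=selected_k,
                          labels=labels)


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    """Map labels to consecutive integers from 0, in order of first use.

    EM can leave a component empty; hard labels must still be 0..k'-1.
    """
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for i, lb in enumerate(labels):
        if lb not in mapping:
            mapping[lb] = len(mapping)
        out[i] = mapping[lb]
    return out


def bic_curve(result: GmmSweepResult) -> pd.DataFrame:
    """The (k, BIC) diagnostic table, one row per swept k in k order."""
    return pd.DataFrame(
        {
            "k": [e.k for e in result.entries],
            "bic": [e.bic for e in result.entries],
            "log_likelihood": [e.log_likelihood for e in result.entries],
            "converged": [e.converged for e in result.entries],
        }
    )
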