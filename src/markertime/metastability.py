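"""Metastable-state detection from posterior ordering consistency.

The posterior over pseudotimes induces, for every cell pair (i, j), an
empirical probability that cell i precedes cell j.  The resulting N x N
consistency matrix is near rank-one: its first principal component recovers
the cell ordering, and discrete "metastable" states — stretches of the
trajectory where cells are nearly exchangeable — appear as clusters in that
one-dimensional representation.  States are found with a 1-D Gaussian
mixture whose number of components maximizes the BIC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .inference import PosteriorSamples

logger = logging.getLogger(__name__)

__all__ = ["ConsistencyMatrix", "MetastableAssignment", "consistency_matrix",
           "cluster_metastable_states"]


@dataclass(frozen=True)
class ConsistencyMatrix:
    """P[i, j] = empirical posterior probability that cell i precedes cell j.

    Ties in stored draws contribute half to each direction, so
    P + P.T == 1 holds exactly off-diagonal; the diagonal is fixed at 0.5.
    """

    P: np.ndarray
    cell_ids: tuple


@dataclass(frozen=True)
class MetastableAssignment:
    """Cluster labels along the trajectory and the model-selection trace."""

    labels: np.ndarray          # values in {1..k}, increasing with pseudotime
    k: int
    bic_by_k: pd.DataFrame      # columns: k, bic (higher is better)
    pc1: np.ndarray             # rank-one representation of cell-cell ordering


def consistency_matrix(samples: PosteriorSamples, chunk=200) -> ConsistencyMatrix:
    """Empirical cell-precedence probabilities over all posterior draws."""
    T = samples.flat("t")              # (S, N)
    S, N = T.shape
    P = np.zeros((N, N))
    for start in range(0, S, chunk):
        block = T[start:start + chunk]
        less = block[:, :, None] < block[:, None, :]
        equal = block[:, :, None] == block[:, None, :]
        P += less.sum(axis=0) + 0.5 * equal.sum(axis=0)
    P /= S
    np.fill_diagonal(P, 0.5)
    return ConsistencyMatrix(P=P, cell_ids=tuple(samples.cell_ids))


def cluster_metastable_states(P: ConsistencyMatrix, k_candidates=range(1, 10),
                              *, mean_pseudotime=None, n_init=10,
                              seed=0) -> MetastableAssignment:
    """PCA rank-one reduction of the consistency matrix + BIC-selected GMM.

    PC1 of the column-centred matrix is clustered with one-dimensional
    Gaussian mixtures (per-component variances, ``n_init`` seeded restarts
    per candidate k); the k maximizing the BIC — on the higher-is-better
    sign convention — is selected.  Labels are renumbered so that state
    index increases along the trajectory: against ``mean_pseudotime`` when
    given, otherwise against the matrix's own ordering information (the
    column means of P, which grow with a cell's position in pseudotime).
    """
    M = np.asarray(P.P, float)
    N = M.shape[0]
    k_candidates = sorted(set(int(k) for k in k_candidates))
    if min(k_candidates) < 1:
        raise ValueError("candidate k must be >= 1")
    if N < max(k_candidates) + 1:
        raise ValueError(
            f"{N} cells cannot support up to {max(k_candidates)} states"
        )
    X = M - M.mean(axis=0, keepdims=True)   # column-centred
    _, svals, vt = np.linalg.svd(X, full_matrices=False)
    pc1 = X @ vt[0]
    # orientation: increase along the trajectory
    order_proxy = (np.asarray(mean_pseudotime, float)
                   if mean_pseudotime is not None else M.mean(axis=0))
    if np.std(pc1) > 0 and np.std(order_proxy) > 0:
        if np.corrcoef(pc1, order_proxy)[0, 1] < 0:
            pc1 = -pc1

    if np.std(pc1) < 1e-10:
        msg = "degenerate consistency matrix (no ordering information); k = 1"
        logger.warning(msg)
        warnings.warn(msg, UserWarning, stacklevel=2)
        return MetastableAssignment(
            labels=np.ones(N, dtype=int), k=1,
            bic_by_k=pd.DataFrame({"k": [1], "bic": [np.nan]}), pc1=pc1,
        )

    Xf = pc1[:, None]
    fits, bics = {}, {}
    for k in k_candidates:
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             n_init=n_init, random_state=seed)
        gm.fit(Xf)
        fits[k] = gm
        bics[k] = -gm.bic(Xf)   # sklearn's BIC is lower-is-better; flip sign
    best_k = max(k_candidates, key=lambda k: bics[k])
    raw = fits[best_k].predict(Xf)
    # renumber states by increasing mean position along the trajectory
    centers = [order_proxy[raw == c].mean() for c in range(best_k)]
    rank = {c: r + 1 for r, c in enumerate(np.argsort(centers))}
    labels = np.array([rank[c] for c in raw], dtype=int)
    bic_by_k = pd.DataFrame({"k": k_candidates,
                             "bic": [bics[k] for k in k_candidates]})
    return MetastableAssignment(labels=labels, k=int(best_k),
                                bic_by_k=bic_by_k, pc1=pc1)
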