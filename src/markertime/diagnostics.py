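"""Pre-fit corroboration of declared gene behaviours.

Along a shared trajectory, switch-like genes are strongly correlated with
each other (up to sign) but only weakly with transient genes, whose
rise-and-fall profile is nearly orthogonal to any monotone curve.
Hierarchically clustering genes on 1 - |Pearson r| and cutting the tree into
two groups therefore tends to separate the two behaviour classes; comparing
that split against the user's declarations flags likely misdeclarations
*before* any model fitting.  This is a corroboration aid only — it never
overrides the declarations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .model import resolve_behaviours
from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["BehaviourDiagnostic", "behaviour_correlation_check"]


@dataclass(frozen=True)
class BehaviourDiagnostic:
    """Absolute gene-gene correlations and the two-group behaviour split."""

    abs_corr: np.ndarray        # (G, G), symmetric, unit diagonal
    dendrogram: np.ndarray      # scipy linkage matrix
    two_group_labels: np.ndarray
    agreement: float            # fraction of genes matching their group majority
    gene_ids: tuple


def behaviour_correlation_check(Y, behaviours, *, method="average",
                                mask_zeros=False,
                                warn_below=0.8) -> BehaviourDiagnostic:
    """Cluster genes by absolute correlation and compare with declarations.

    Dropout zeros are included in the correlations by default; with
    ``mask_zeros=True`` each pairwise correlation uses only cells where both
    genes are nonzero.  A warning is logged when the agreement between the
    declared behaviours and the two-group cut falls below ``warn_below``.
    """
    if isinstance(Y, ExpressionMatrix):
        values, gene_ids = Y.values, Y.gene_ids
    else:
        values = np.asarray(Y, float)
        gene_ids = tuple(f"gene_{j}" for j in range(values.shape[1]))
    n, g = values.shape
    if g < 3:
        raise ValueError("need at least 3 genes for the behaviour diagnostic")
    beh = resolve_behaviours(gene_ids, behaviours)
    var = values.var(axis=0)
    if np.any(var == 0):
        names = [gene_ids[j] for j in np.flatnonzero(var == 0)]
        raise ValueError(f"zero-variance gene(s): {names}")
    if mask_zeros:
        corr = np.eye(g)
        for i in range(g):
            for j in range(i + 1, g):
                keep = (values[:, i] > 0) & (values[:, j] > 0)
                if keep.sum() < 3 or values[keep, i].std() == 0 or values[keep, j].std() == 0:
                    corr[i, j] = corr[j, i] = 0.0
                else:
                    corr[i, j] = corr[j, i] = np.corrcoef(
                        values[keep, i], values[keep, j]
                    )[0, 1]
    else:
        corr = np.corrcoef(values, rowvar=False)
    abs_corr = np.clip(np.abs(corr), 0.0, 1.0)
    np.fill_diagonal(abs_corr, 1.0)

    dist = 1.0 - abs_corr
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method=method)
    labels = fcluster(Z, t=2, criterion="maxclust")

    agree = 0
    for grp in np.unique(labels):
        members = labels == grp
        grp_beh = beh[members]
        counts = {b: int((grp_beh == b).sum()) for b in set(grp_beh)}
        majority = max(counts.values())
        agree += majority
    agreement = agree / g
    if agreement < warn_below:
        msg = (
            f"behaviour declarations agree with the correlation structure for "
            f"only {agreement:.0%} of genes; declared behaviours may be "
            "misspecified"
        )
        logger.warning(msg)
        warnings.warn(msg, UserWarning, stacklevel=2)
    return BehaviourDiagnostic(
        abs_corr=abs_corr, dendrogram=Z, two_group_labels=labels,
        agreement=float(agreement), gene_ids=tuple(gene_ids),
    )
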