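"""Input validation and gene-wise size-factor normalization.

The model downstream assumes a non-negative, log-scale cell-by-gene
expression matrix in which each gene's approximate half-peak expression is
1.  That scale is achieved by dividing each gene by its size factor

    s_g = mean of the strictly positive observations of gene g,

so exact zeros (dropouts) are excluded from the mean and stay exactly zero
after normalization.  The normalization makes activation-strength parameters
comparable across genes of very different absolute expression.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SizeFactors",
    "validate_expression",
    "compute_size_factors",
    "normalize_expression",
]


class ValidationError(ValueError):
    """Raised when input expression data violates the model's preconditions."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Non-negative log-scale expression, cells in rows, genes in columns.

    Attributes
    ----------
    values : (N, G) float array, all entries >= 0, no NaN/inf.
    cell_ids : N unique cell labels.
    gene_ids : G unique gene labels.
    """

    values: np.ndarray
    cell_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.values, index=list(self.cell_ids), columns=list(self.gene_ids)
        )


@dataclass(frozen=True)
class SizeFactors:
    """Per-gene positive scale factors, aligned with an ExpressionMatrix."""

    s: np.ndarray
    gene_ids: tuple[str, ...] = field(default=())


def validate_expression(values, cell_ids, gene_ids, *, log_transform=None,
                        drop_empty=False) -> ExpressionMatrix:
    """Validate raw input and return an :class:`ExpressionMatrix`.

    Parameters
    ----------
    values : array-like, shape (n_cells, n_genes)
        Non-negative log-scale expression.  The function never applies a log
        itself unless ``log_transform="log1p"`` is requested explicitly.
    cell_ids, gene_ids : sequences of labels
        Must be unique and match the matrix dimensions.
    log_transform : {None, "log1p"}
        Optional transform for raw counts; off by default because the model
        assumes the input is already log-scale.
    drop_empty : bool
        If True, genes with no positive observation are dropped with a
        warning instead of raising.  Off by default: an all-zero gene has no
        defined size factor and silently dropping it changes the panel.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValidationError(f"expression matrix must be 2-D, got shape {values.shape}")
    cell_ids = tuple(str(c) for c in cell_ids)
    gene_ids = tuple(str(g) for g in gene_ids)
    n, g = values.shape
    if n != len(cell_ids):
        raise ValidationError(
            f"matrix has {n} rows but {len(cell_ids)} cell ids; "
            "use transpose=True if the file is gene-by-cell"
        )
    if g != len(gene_ids):
        raise ValidationError(f"matrix has {g} columns but {len(gene_ids)} gene ids")
    if n < 2 or g < 2:
        raise ValidationError(f"need at least 2 cells and 2 genes, got {n}x{g}")
    if len(set(cell_ids)) != n:
        raise ValidationError("duplicate cell ids")
    if len(set(gene_ids)) != g:
        raise ValidationError("duplicate gene ids")
    if not np.all(np.isfinite(values)):
        raise ValidationError("expression matrix contains missing or non-finite entries")
    if log_transform == "log1p":
        values = np.log1p(values)
    elif log_transform is not None:
        raise ValidationError(f"unknown log_transform {log_transform!r}")
    if np.any(values < 0):
        bad = np.argwhere(values < 0)[0]
        raise ValidationError(
            "negative expression at cell "
            f"{cell_ids[bad[0]]!r}, gene {gene_ids[bad[1]]!r}: input must be "
            "non-negative log-scale values"
        )
    empty = ~np.any(values > 0, axis=0)
    if np.any(empty):
        names = [gene_ids[i] for i in np.flatnonzero(empty)]
        if drop_empty:
            msg = f"dropping {len(names)} gene(s) with no positive observation: {names}"
            logger.warning(msg)
            warnings.warn(msg, UserWarning, stacklevel=2)
            keep = ~empty
            values = values[:, keep]
            gene_ids = tuple(gid for gid, k in zip(gene_ids, keep) if k)
            if values.shape[1] < 2:
                raise ValidationError("fewer than 2 genes remain after dropping empty genes")
        else:
            raise ValidationError(
                f"gene(s) with all-zero expression: {names}; the size factor is "
                "undefined for them (pass drop_empty=True to remove)"
            )
    values = values.copy()
    values.setflags(write=False)
    return ExpressionMatrix(values=values, cell_ids=cell_ids, gene_ids=gene_ids)


def compute_size_factors(X: ExpressionMatrix) -> SizeFactors:
    """Per-gene mean of the strictly positive entries."""
    vals = X.values
    pos = vals > 0
    npos = pos.sum(axis=0)
    if np.any(npos == 0):
        names = [X.gene_ids[i] for i in np.flatnonzero(npos == 0)]
        raise ValidationError(f"gene(s) with no positive entries: {names}")
    s = np.where(pos, vals, 0.0).sum(axis=0) / npos
    return SizeFactors(s=s, gene_ids=X.gene_ids)


def normalize_expression(X: ExpressionMatrix, s: SizeFactors | None = None) -> ExpressionMatrix:
    """Divide each gene by its size factor; zeros stay exactly zero.

    After normalization the mean of each gene's positive entries is 1, so
    the half-peak expression of a switch-like gene is approximately 1.
    """
    if s is None:
        s = compute_size_factors(X)
    sf = np.asarray(s.s, dtype=float)
    if sf.shape != (X.n_genes,):
        raise ValidationError(
            f"size factors have shape {sf.shape}, expected ({X.n_genes},)"
        )
    if np.any(sf <= 0):
        raise ValidationError("size factors must be strictly positive")
    out = X.values / sf
    out.setflags(write=False)
    return ExpressionMatrix(values=out, cell_ids=X.cell_ids, gene_ids=X.gene_ids)
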