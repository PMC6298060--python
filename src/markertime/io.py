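"""Readers and writers for the text formats the workflow exchanges.

Expression comes in either as a delimited matrix (header row of gene ids,
first column of cell ids; comma or tab, sniffed from the first line) or as a
MatrixMarket triplet with two sidecar line files of gene and cell ids
(densified on load — marker panels are small).  Behaviour declarations are a
two-column delimited file ``gene_id,behaviour``.  Priors and run settings
are flat YAML with optional per-gene override sections.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import PriorSettings
from .preprocess import ExpressionMatrix, validate_expression

__all__ = [
    "read_expression",
    "read_expression_mtx",
    "read_behaviours",
    "read_priors",
    "write_expression",
    "write_run_manifest",
]


def _sniff_sep(path):
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") > first.count(",") else ","


def read_expression(path, *, transpose=False, log_transform=None,
                    drop_empty=False) -> ExpressionMatrix:
    """Delimited matrix with cell ids in the first column, gene ids in the header.

    ``transpose=True`` for gene-by-cell exports.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if transpose:
        df = df.T
    return validate_expression(
        df.to_numpy(dtype=float), df.index, df.columns,
        log_transform=log_transform, drop_empty=drop_empty,
    )


def _read_lines(path):
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def read_expression_mtx(mtx_path, gene_path, cell_path, *,
                        log_transform=None, drop_empty=False) -> ExpressionMatrix:
    """MatrixMarket triplet plus gene-id and cell-id sidecar line files.

    The orientation is inferred from the sidecar lengths (single-cell MTX
    exports are usually gene-by-cell); a square matrix whose sidecars have
    equal length is ambiguous and rejected.
    """
    from scipy.io import mmread

    M = mmread(mtx_path)
    if hasattr(M, "toarray"):
        M = M.toarray()
    M = np.asarray(M, dtype=float)
    genes = _read_lines(gene_path)
    cells = _read_lines(cell_path)
    if len(genes) == len(cells) and M.shape[0] == M.shape[1]:
        raise ValueError(
            "square matrix with equally long sidecars is ambiguous; use the "
            "delimited reader or unequal panel sizes"
        )
    if M.shape == (len(cells), len(genes)):
        values = M
    elif M.shape == (len(genes), len(cells)):
        values = M.T
    else:
        raise ValueError(
            f"matrix shape {M.shape} matches neither (cells={len(cells)}, "
            f"genes={len(genes)}) nor its transpose"
        )
    return validate_expression(values, cells, genes,
                               log_transform=log_transform, drop_empty=drop_empty)


def read_behaviours(path) -> dict:
    """Two-column file gene_id,behaviour with behaviour in {switch, transient}."""
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError("behaviours file needs two columns: gene_id,behaviour")
    first = str(df.iloc[0, 1]).lower()
    if first not in ("switch", "transient"):  # header row present
        df = df.iloc[1:]
    return {str(g): str(b).lower() for g, b in zip(df.iloc[:, 0], df.iloc[:, 1])}


def read_priors(path) -> PriorSettings:
    """YAML prior settings; top-level keys are global hyperparameters and an
    optional ``per_gene`` mapping of gene id -> overrides."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    per_gene = raw.pop("per_gene", {}) or {}
    allowed = set(PriorSettings.__dataclass_fields__) - {"per_gene"}
    bad = set(raw) - allowed
    if bad:
        raise ValueError(f"unknown prior setting(s): {sorted(bad)}")
    return PriorSettings(**raw, per_gene=per_gene)


def write_expression(X: ExpressionMatrix, path):
    X.to_frame().to_csv(path, index_label="cell_id")


def _digest(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_manifest(outdir, subcommand, config, seed, inputs=()):
    """Reproducibility manifest: version, resolved config, seed, input digests."""
    from datetime import datetime, timezone

    from . import __version__

    manifest = dict(
        package="markertime",
        version=__version__,
        subcommand=subcommand,
        config=config,
        seed=seed,
        inputs={str(p): _digest(p) for p in inputs if Path(p).exists()},
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    path = Path(outdir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
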