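"""Cell-level QC filtering and log-normalization.

Cells are retained when they express at least ``min_genes`` genes (default
1,400) with a mitochondrial count fraction strictly below ``max_mito_frac``
(default 15%), both computed on raw counts. Normalization is the standard
LogNormalize transform: counts per cell scaled to a fixed total (10,000) and
mapped through ln(1 + x).
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd

from .errors import EmptyResultError


def _dense(X) -> np.ndarray:
    return X.toarray() if hasattr(X, "toarray") else np.asarray(X)


def qc_metrics(counts: ad.AnnData) -> pd.DataFrame:
    """Per-cell QC table: detected genes, mito fraction (raw counts)."""
    X = _dense(counts.X)
    mito = counts.var["mito"].to_numpy(dtype=bool)
    n_genes = (X > 0).sum(axis=1)
    total = X.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, X[:, mito].sum(axis=1) / total, 0.0)
    return pd.DataFrame(
        {"n_genes": n_genes, "mito_frac": mito_frac, "total_counts": total},
        index=counts.obs_names,
    )


def qc_filter(counts: ad.AnnData, min_genes: int = 1400,
              max_mito_frac: float = 0.15) -> ad.AnnData:
    """Drop cells with < ``min_genes`` detected genes or mito fraction >= cutoff.

    Boundary semantics: a cell with exactly ``min_genes`` detected genes is
    kept (>=); a cell with mito fraction exactly ``max_mito_frac`` is removed
    (strict <). The gene set and the order of surviving cells are unchanged.

    Raises
    ------
    EmptyResultError
        If no cell survives.
    """
    m = qc_metrics(counts)
    keep = (m["n_genes"].to_numpy() >= min_genes) & \
           (m["mito_frac"].to_numpy() < max_mito_frac)
    if not keep.any():
        raise EmptyResultError(
            f"qc_filter removed all {counts.n_obs} cells "
            f"(min_genes={min_genes}, max_mito_frac={max_mito_frac})")
    return counts[keep].copy()


def lognormalize(counts: ad.AnnData, scale: float = 10_000) -> ad.AnnData:
    """LogNormalize: value(g, i) = ln(1 + count(g, i) / total(i) * scale)."""
    X = _dense(counts.X).astype(float)
    total = X.sum(axis=1)
    if np.any(total <= 0):
        bad = counts.obs_names[np.flatnonzero(total <= 0)[0]]
        raise ValueError(f"cell {bad!r} has zero total counts; run qc_filter first")
    out = counts.copy()
    out.X = np.log1p(X / total[:, None] * scale)
    return out
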