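"""Reference-centered, genome-smoothed relative copy-number profiles.

The profile construction mirrors the smoothing-and-denoising stage of
expression-CNV tools: genes are placed in genomic order, each gene is centered
on its mean over the reference (presumed euploid) cells, extreme centered
values are clipped, a boxcar moving average along the chromosome (window
truncated at chromosome boundaries) smooths gene-level noise, and observation
values inside a band of +/- ``sd_multiplier`` reference SDs around baseline
are zeroed (denoising). One output segment per retained gene; values stay on
the centered log scale, so 0 is the euploid baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import anndata as ad
import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyResultError
from .preprocess import _dense
from .simulate import REFERENCE


@dataclass(frozen=True)
class CopyNumberProfile:
    """Cells x genomic segments of relative copy signal (0 = baseline).

    Segments follow genomic coordinate order and are grouped contiguously by
    chromosome; ``segment_chromosome`` maps each segment to its chromosome.
    """

    values: np.ndarray                 # cells x segments, float
    cell_ids: pd.Index
    cell_group: np.ndarray             # per-cell {reference, observation}
    segment_ids: pd.Index              # gene ids, genomic order
    segment_chromosome: np.ndarray     # per-segment chromosome label
    segment_start: np.ndarray          # per-segment coordinate (bp)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_segments(self) -> int:
        return self.values.shape[1]

    @property
    def chromosomes(self) -> list[str]:
        return list(pd.unique(self.segment_chromosome))

    def is_reference(self) -> np.ndarray:
        return self.cell_group == REFERENCE


def order_genes(norm: ad.AnnData, positions: pd.DataFrame,
                min_cells_expressing: int = 3) -> ad.AnnData:
    """Restrict to positioned, sufficiently expressed genes in genomic order.

    Genes absent from ``positions`` or expressed (value > 0) in fewer than
    ``min_cells_expressing`` cells are dropped; survivors are sorted by
    (chromosome, start), with chromosomes in their order of appearance in the
    position table.
    """
    pos = positions.set_index("gene_id") if "gene_id" in positions.columns \
        else positions
    X = _dense(norm.X)
    expressed = (X > 0).sum(axis=0)
    keep = norm.var_names.isin(pos.index) & (expressed >= min_cells_expressing)
    if not keep.any():
        raise EmptyResultError("no genes left after position/expression filter")
    sub = norm[:, keep].copy()
    chrom = pos.loc[sub.var_names, "chromosome"].astype(str)
    start = pos.loc[sub.var_names, "start"].astype(int)
    chrom_order = {c: i for i, c in enumerate(pd.unique(pos["chromosome"].astype(str)))}
    order = np.lexsort((start.to_numpy(), chrom.map(chrom_order).to_numpy()))
    sub = sub[:, order].copy()
    sub.var["chromosome"] = chrom.to_numpy()[order]
    sub.var["start"] = start.to_numpy()[order]
    return sub


def center_on_reference(norm: ad.AnnData) -> ad.AnnData:
    """Subtract each gene's mean over reference cells; reference means become 0."""
    ref = norm.obs["group"].to_numpy() == REFERENCE
    if ref.sum() < 2:
        raise ValueError("center_on_reference requires >= 2 reference cells")
    X = _dense(norm.X).astype(float)
    out = norm.copy()
    out.X = X - X[ref].mean(axis=0, keepdims=True)
    return out


def _truncated_moving_mean(block: np.ndarray, window: int) -> np.ndarray:
    """Boxcar mean along axis 1, window truncated at the block edges."""
    n = block.shape[1]
    h = window // 2
    cs = np.concatenate(
        [np.zeros((block.shape[0], 1)), np.cumsum(block, axis=1)], axis=1)
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h + 1, n)
    return (cs[:, hi] - cs[:, lo]) / (hi - lo)


def smooth_genomic(centered: ad.AnnData, window: int = 101,
                   clip: float | None = 3.0) -> CopyNumberProfile:
    """Smooth centered expression along each chromosome into a copy profile.

    Parameters
    ----------
    window
        Odd number of genes in the uniform moving-average window; the window
        never crosses a chromosome boundary (it is truncated at the ends).
    clip
        Bound on centered values (+/- clip) applied before smoothing to
        stabilize the downstream deviation statistic; ``None`` disables.
    """
    if window < 1 or window % 2 == 0:
        raise ConfigurationError("window must be a positive odd integer")
    X = _dense(centered.X).astype(float)
    if clip is not None:
        X = np.clip(X, -clip, clip)
    chrom = centered.var["chromosome"].to_numpy().astype(str)
    smoothed = np.empty_like(X)
    for c in pd.unique(chrom):
        cols = np.flatnonzero(chrom == c)
        smoothed[:, cols] = _truncated_moving_mean(X[:, cols], window)
    return CopyNumberProfile(
        values=smoothed,
        cell_ids=centered.obs_names.copy(),
        cell_group=centered.obs["group"].to_numpy().astype(str),
        segment_ids=centered.var_names.copy(),
        segment_chromosome=chrom,
        segment_start=centered.var["start"].to_numpy().astype(int),
    )


def denoise(profile: CopyNumberProfile,
            sd_multiplier: float = 1.5) -> CopyNumberProfile:
    """Zero observation values within +/- ``sd_multiplier`` reference SDs of 0.

    Per segment, the band half-width is ``sd_multiplier`` times the sample SD
    of the reference cells at that segment; observation values inside the band
    (inclusive) are set to 0, values outside pass through, and reference cells
    are unchanged.
    """
    ref = profile.is_reference()
    if ref.sum() < 2:
        raise ValueError("denoise requires >= 2 reference cells in the profile")
    sigma = profile.values[ref].std(axis=0, ddof=1)
    band = sd_multiplier * sigma
    values = profile.values.copy()
    obs = ~ref
    inside = np.abs(values[obs]) <= band[None, :]
    values[np.ix_(obs, np.arange(profile.n_segments))] = \
        np.where(inside, 0.0, values[obs])
    return replace(profile, values=values)
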