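"""End-to-end convenience: counts -> QC -> normalize -> profile -> calls."""

from __future__ import annotations

import anndata as ad
import pandas as pd

from .cnv import center_on_reference, denoise, order_genes, smooth_genomic
from .preprocess import lognormalize, qc_filter
from .scoring import AneuploidyCall, DeviationTable, score_profile
from .simulate import OBSERVATION


def run_pipeline(counts: ad.AnnData, positions: pd.DataFrame,
                 min_genes: int = 1400, max_mito_frac: float = 0.15,
                 scale: float = 10_000, min_cells_expressing: int = 3,
                 window: int = 101, clip: float | None = 3.0,
                 denoise_sd: float = 1.5, multiplier: float = 2.5,
                 mean_over: str = "all", sd: str = "sample",
                 group: str = OBSERVATION
                 ) -> tuple[DeviationTable, AneuploidyCall]:
    """Run the full aneuploidy-calling pipeline on a labeled count matrix."""
    filtered = qc_filter(counts, min_genes=min_genes,
                         max_mito_frac=max_mito_frac)
    norm = lognormalize(filtered, scale=scale)
    ordered = order_genes(norm, positions,
                          min_cells_expressing=min_cells_expressing)
    centered = center_on_reference(ordered)
    profile = smooth_genomic(centered, window=window, clip=clip)
    profile = denoise(profile, sd_multiplier=denoise_sd)
    return score_profile(profile, multiplier=multiplier, mean_over=mean_over,
                         sd=sd, group=group)
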