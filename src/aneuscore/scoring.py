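"""Per-chromosome summed-deviation statistic and 2.5-SD outlier calls.

For each segment the deviation of a cell from the overall mean across cells is
computed; deviations are summed (signed) across each chromosome, giving one
statistic D per cell and chromosome. The distribution of D across cells is
summarized by its peak (a Gaussian-KDE mode estimate) and its sample SD; cells
whose absolute deviation from the peak exceeds ``multiplier`` (default 2.5)
times the SD are outliers on that chromosome, and a cell is called aneuploid
when it is an outlier on at least one chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cnv import CopyNumberProfile
from .simulate import OBSERVATION

KDE_GRID_POINTS = 512
MIN_KDE_N = 10


@dataclass(frozen=True)
class DeviationTable:
    """Summed deviations D (cells x chromosomes) with peak/SD/outlier flags."""

    D: pd.DataFrame            # cells x chromosomes
    peak: pd.Series            # per-chromosome distribution peak
    sd: pd.Series              # per-chromosome sample SD of D
    outlier: pd.DataFrame      # cells x chromosomes, boolean
    cell_group: pd.Series      # per-cell group label


@dataclass(frozen=True)
class AneuploidyCall:
    """Per-cell aneuploidy verdicts and the group-level aneuploid fraction."""

    aneuploid: pd.Series              # per-cell boolean
    flagged_chromosomes: pd.Series    # per-cell list of chromosome labels
    aneuploid_fraction: float         # among cells of ``group``
    group: str


def segment_deviation(profile: CopyNumberProfile,
                      mean_over: str = "all") -> np.ndarray:
    """Deviation of each cell from the per-segment mean across cells.

    ``mean_over`` selects the cells defining the per-segment mean: ``"all"``
    (reference + observation, the default) or ``"observation"`` only.
    """
    if profile.n_cells < 2:
        raise ValueError("segment_deviation requires >= 2 cells")
    if mean_over == "all":
        mean = profile.values.mean(axis=0, keepdims=True)
    elif mean_over == "observation":
        obs = profile.cell_group == OBSERVATION
        if obs.sum() < 2:
            raise ValueError("mean_over='observation' requires >= 2 observation cells")
        mean = profile.values[obs].mean(axis=0, keepdims=True)
    else:
        raise ValueError(f"unknown mean_over: {mean_over!r}")
    return profile.values - mean


def chromosome_deviation_sum(dev: np.ndarray,
                             segment_chromosome: np.ndarray) -> np.ndarray:
    """Signed sum of segment deviations within each chromosome.

    Returns a cells x chromosomes array, chromosomes in order of first
    appearance along the genome. Signed summation preserves the direction of
    whole-chromosome gains vs losses.
    """
    seg_chrom = np.asarray(segment_chromosome, dtype=object)
    bad = pd.isna(seg_chrom)
    if bad.any():
        raise ValueError(f"segment {np.flatnonzero(bad)[0]} has no chromosome")
    if len(seg_chrom) != dev.shape[1]:
        raise ValueError("segment_chromosome length does not match deviations")
    chroms = list(pd.unique(seg_chrom))
    D = np.empty((dev.shape[0], len(chroms)))
    for j, c in enumerate(chroms):
        D[:, j] = dev[:, seg_chrom == c].sum(axis=1)
    return D


def find_peak(values) -> float:
    """Mode estimate of a 1-d sample: argmax of a Gaussian KDE on a 512-point
    grid over [min, max] with Silverman bandwidth; median for n < 10 or a
    degenerate (constant) sample."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("find_peak requires at least one value")
    if not np.all(np.isfinite(v)):
        raise ValueError("find_peak requires finite values")
    if v.size < MIN_KDE_N or np.ptp(v) == 0:
        return float(np.median(v))
    try:
        kde = stats.gaussian_kde(v, bw_method="silverman")
    except np.linalg.LinAlgError:
        return float(np.median(v))
    grid = np.linspace(v.min(), v.max(), KDE_GRID_POINTS)
    return float(grid[np.argmax(kde(grid))])


def call_outliers(D_column, peak: float, multiplier: float = 2.5) -> np.ndarray:
    """Flag values with |D - peak| strictly greater than multiplier * sample SD.

    The SD is the ordinary sample SD (denominator n-1) of the column; a zero
    SD yields no flags, and ties at the threshold are not flagged.
    """
    d = np.asarray(D_column, dtype=float)
    if d.size < 2:
        raise ValueError("call_outliers requires >= 2 values")
    if not np.all(np.isfinite(d)) or not np.isfinite(peak):
        raise ValueError("call_outliers requires finite values")
    s = d.std(ddof=1)
    if s == 0:
        return np.zeros(d.size, dtype=bool)
    return np.abs(d - peak) > multiplier * s


def _mad_sd(values: np.ndarray) -> float:
    return float(stats.median_abs_deviation(values, scale="normal"))


def build_deviation_table(profile: CopyNumberProfile,
                          multiplier: float = 2.5,
                          mean_over: str = "all",
                          sd: str = "sample") -> DeviationTable:
    """Run the scoring chain on a profile and assemble the deviation table.

    ``sd`` chooses the spread estimate for the outlier rule: ``"sample"``
    (ordinary sample SD, the default) or ``"mad"`` (normal-consistent median
    absolute deviation, a robust alternative).
    """
    if sd not in ("sample", "mad"):
        raise ValueError(f"unknown sd estimator: {sd!r}")
    dev = segment_deviation(profile, mean_over=mean_over)
    D = chromosome_deviation_sum(dev, profile.segment_chromosome)
    chroms = list(pd.unique(profile.segment_chromosome))
    peaks, sds, flags = [], [], []
    for j in range(D.shape[1]):
        col = D[:, j]
        pk = find_peak(col)
        if sd == "sample":
            flag = call_outliers(col, pk, multiplier)
            s = col.std(ddof=1)
        else:
            s = _mad_sd(col)
            flag = np.zeros(col.size, bool) if s == 0 \
                else np.abs(col - pk) > multiplier * s
        peaks.append(pk)
        sds.append(s)
        flags.append(flag)
    idx = profile.cell_ids
    return DeviationTable(
        D=pd.DataFrame(D, index=idx, columns=chroms),
        peak=pd.Series(peaks, index=chroms),
        sd=pd.Series(sds, index=chroms),
        outlier=pd.DataFrame(np.column_stack(flags), index=idx, columns=chroms),
        cell_group=pd.Series(profile.cell_group, index=idx),
    )


def aneuploid_call(table: DeviationTable,
                   group: str = OBSERVATION) -> AneuploidyCall:
    """Call cells aneuploid (outlier on >= 1 chromosome) and report the
    aneuploid fraction within ``group``."""
    in_group = table.cell_group == group
    if not in_group.any():
        raise ValueError(f"no cells in group {group!r}")
    aneuploid = table.outlier.any(axis=1)
    flagged = table.outlier.apply(
        lambda row: list(table.outlier.columns[row.to_numpy()]), axis=1)
    frac = float(aneuploid[in_group].mean())
    return AneuploidyCall(
        aneuploid=aneuploid,
        flagged_chromosomes=flagged,
        aneuploid_fraction=frac,
        group=group,
    )


def score_profile(profile: CopyNumberProfile, multiplier: float = 2.5,
                  mean_over: str = "all", sd: str = "sample",
                  group: str = OBSERVATION
                  ) -> tuple[DeviationTable, AneuploidyCall]:
    """Deviation table plus aneuploidy calls in one step."""
    table = build_deviation_table(profile, multiplier=multiplier,
                                  mean_over=mean_over, sd=sd)
    return table, aneuploid_call(table, group=group)
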