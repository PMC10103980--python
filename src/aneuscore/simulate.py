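"""Synthetic scRNA-seq data with planted whole-chromosome copy-number changes.

The generator emulates a two-group design: reference cells that are euploid by
construction and observation cells of which a configurable fraction carry one
or more whole-chromosome copy-ratio changes. A copy ratio r multiplies the
expected expression of every gene on the affected chromosome (r = 1.5 is
roughly one extra copy of a diploid chromosome; r = 0.5 a loss). Counts are
drawn gamma-Poisson (negative binomial), the standard overdispersion model for
droplet scRNA-seq, with log-normal per-gene baseline means and log-normal
per-cell library-size factors. A small set of highly expressed mitochondrial
genes on a pseudo-contig "MT" exists only to exercise the QC filter; they
carry no copy-number changes and no genomic positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .errors import ConfigurationError

MITO_CONTIG = "MT"
REFERENCE = "reference"
OBSERVATION = "observation"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic two-group scRNA-seq experiment.

    Attributes
    ----------
    n_ref, n_obs
        Numbers of reference (euploid baseline) and observation cells.
    n_chromosomes, genes_per_chromosome
        Genome layout used for the planted events.
    aneuploid_fraction
        Probability that an observation cell carries at least one
        whole-chromosome copy-number alteration.
    copy_ratios
        Allowed per-chromosome copy ratios for altered chromosomes
        (1.0 is permitted and plants a no-op event).
    max_altered_chromosomes
        Each aneuploid cell alters between 1 and this many chromosomes.
    mean_counts_per_gene
        Expected baseline counts per gene at library factor 1. The default (5)
        yields ~10k counts and ~1,700 detected genes per typical cell with the
        default genome of 2,000 genes, comfortably above the 1,400-gene QC
        floor applied downstream.
    baseline_mean_log_sd
        SD of the per-gene log baseline means (log-normal heterogeneity).
    nb_dispersion
        Gamma-Poisson overdispersion; 0 gives pure Poisson counts.
    library_size_cv
        Coefficient of variation of the per-cell depth factors (mean 1).
    mito_gene_count
        Number of mitochondrial genes appended on pseudo-contig "MT".
    seed
        Seed for all randomness; identical seed gives identical output.
    """

    n_ref: int = 200
    n_obs: int = 400
    n_chromosomes: int = 8
    genes_per_chromosome: int = 250
    aneuploid_fraction: float = 0.2
    copy_ratios: tuple[float, ...] = (0.5, 1.5)
    max_altered_chromosomes: int = 3
    mean_counts_per_gene: float = 5.0
    baseline_mean_log_sd: float = 1.0
    nb_dispersion: float = 0.1
    library_size_cv: float = 0.3
    mito_gene_count: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_ref", "n_obs", "n_chromosomes", "genes_per_chromosome",
                     "max_altered_chromosomes"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.mito_gene_count < 0:
            raise ConfigurationError("mito_gene_count must be >= 0")
        if not 0.0 <= self.aneuploid_fraction <= 1.0:
            raise ConfigurationError("aneuploid_fraction must be in [0, 1]")
        if self.aneuploid_fraction > 0 and len(self.copy_ratios) == 0:
            raise ConfigurationError(
                "copy_ratios must be non-empty when aneuploid_fraction > 0")
        if any(r <= 0 for r in self.copy_ratios):
            raise ConfigurationError("copy_ratios must all be > 0")
        if self.nb_dispersion < 0 or self.library_size_cv < 0:
            raise ConfigurationError("dispersion and CV must be >= 0")
        if self.mean_counts_per_gene <= 0:
            raise ConfigurationError("mean_counts_per_gene must be > 0")
        # normalize copy_ratios to a sorted tuple for determinism
        object.__setattr__(self, "copy_ratios", tuple(sorted(self.copy_ratios)))


def make_gene_positions(n_chromosomes: int, genes_per_chromosome: int,
                        chromosome_length: int = 100_000_000,
                        seed: int = 0) -> pd.DataFrame:
    """Generate a gene-position table (gene_id, chromosome, start, end).

    Coordinates are 1-based inclusive, the convention of the position files
    consumed by expression-CNV tools. Per chromosome, intervals are
    non-overlapping and sorted by start. Deterministic given ``seed``.
    """
    if n_chromosomes < 1 or genes_per_chromosome < 1:
        raise ConfigurationError("chromosome and gene counts must be >= 1")
    if chromosome_length < 2 * genes_per_chromosome:
        raise ConfigurationError("chromosome_length too small for gene count")
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(1, n_chromosomes + 1):
        # 2g distinct sorted coordinates; consecutive pairs become intervals,
        # which guarantees non-overlap and start <= end
        cuts = np.sort(rng.choice(
            np.arange(1, chromosome_length + 1),
            size=2 * genes_per_chromosome, replace=False))
        starts = cuts[0::2]
        ends = cuts[1::2]
        for j, (s, e) in enumerate(zip(starts, ends)):
            rows.append((f"gene-{c}-{j + 1:04d}", str(c), int(s), int(e)))
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end"])


def _draw_karyotype(cfg: SimulationConfig, chromosomes: list[str],
                    rng: np.random.Generator) -> pd.DataFrame:
    """Copy-ratio truth matrix, cells x chromosomes; reference cells all 1."""
    n_cells = cfg.n_ref + cfg.n_obs
    truth = np.ones((n_cells, len(chromosomes)))
    ratios = np.asarray(cfg.copy_ratios, dtype=float)
    for i in range(cfg.n_ref, n_cells):
        if rng.random() < cfg.aneuploid_fraction:
            n_alt = int(rng.integers(1, cfg.max_altered_chromosomes + 1))
            n_alt = min(n_alt, len(chromosomes))
            which = rng.choice(len(chromosomes), size=n_alt, replace=False)
            truth[i, which] = rng.choice(ratios, size=n_alt, replace=True)
    return truth


def simulate_counts(config: SimulationConfig,
                    positions: pd.DataFrame) -> tuple[ad.AnnData, pd.DataFrame]:
    """Draw a gene x cell count matrix with planted CNAs.

    The expected count of gene g in cell i is
    ``baseline_mean(g) * library_factor(i) * copy_ratio(i, chrom(g))``,
    realized gamma-Poisson with the configured dispersion.

    Returns
    -------
    adata
        AnnData (cells x genes); ``obs['group']`` holds reference/observation
        labels, ``var`` carries chromosome/start/end and a ``mito`` flag.
        Mitochondrial genes sit on contig "MT" with no planted events.
    truth
        DataFrame (cells x chromosomes) of copy ratios; 1.0 = euploid.
    """
    chroms = list(pd.unique(positions["chromosome"]))
    if len(chroms) < config.n_chromosomes:
        raise ConfigurationError(
            f"positions covers {len(chroms)} chromosomes, "
            f"config requires {config.n_chromosomes}")
    chroms = chroms[: config.n_chromosomes]
    pos = positions[positions["chromosome"].isin(chroms)].copy()
    pos = pos.sort_values(["chromosome", "start"],
                          key=lambda s: s.map({c: i for i, c in enumerate(chroms)})
                          if s.name == "chromosome" else s)

    rng = np.random.default_rng(config.seed)
    n_cells = config.n_ref + config.n_obs
    n_genes = len(pos)
    n_mito = config.mito_gene_count

    sd = config.baseline_mean_log_sd
    mu = np.log(config.mean_counts_per_gene) - sd ** 2 / 2
    base = rng.lognormal(mu, sd, n_genes)
    # mitochondrial genes: few, highly expressed (~5% of counts for the
    # default genome), so the QC mito fraction has a realistic scale
    base_mito = rng.lognormal(mu + np.log(10.0), sd, n_mito)

    cv = config.library_size_cv
    if cv > 0:
        sig = np.sqrt(np.log1p(cv ** 2))
        lib = rng.lognormal(-sig ** 2 / 2, sig, n_cells)
    else:
        lib = np.ones(n_cells)

    truth = _draw_karyotype(config, chroms, rng)
    chrom_index = pd.Series(range(len(chroms)), index=chroms)
    gene_chrom_idx = chrom_index[pos["chromosome"]].to_numpy()

    mean = (base[None, :] * lib[:, None]) * truth[:, gene_chrom_idx]
    if n_mito:
        mean = np.concatenate([mean, base_mito[None, :] * lib[:, None]], axis=1)

    if config.nb_dispersion > 0:
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape, mean * config.nb_dispersion)
    else:
        lam = mean
    counts = rng.poisson(lam).astype(np.int32)

    gene_ids = list(pos["gene_id"]) + [f"mt-{j + 1}" for j in range(n_mito)]
    var = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    var["chromosome"] = list(pos["chromosome"]) + [MITO_CONTIG] * n_mito
    var["start"] = list(pos["start"]) + [0] * n_mito
    var["end"] = list(pos["end"]) + [0] * n_mito
    var["mito"] = [False] * n_genes + [True] * n_mito

    cell_ids = [f"cell-{i + 1:05d}" for i in range(n_cells)]
    obs = pd.DataFrame(index=pd.Index(cell_ids, name="cell_id"))
    obs["group"] = [REFERENCE] * config.n_ref + [OBSERVATION] * config.n_obs

    adata = ad.AnnData(X=counts, obs=obs, var=var)
    truth_df = pd.DataFrame(truth, index=obs.index, columns=chroms)
    return adata, truth_df


def simulate_growth_series(A0: float, k: float, days,
                           noise_cv: float = 0.0, seed: int = 0,
                           subject_id: str = "subject-1"):
    """Exponential growth series area(t) = A0*e^(k*t) with multiplicative noise.

    Noise factors are log-normal with mean 1 and coefficient of variation
    ``noise_cv``; ``noise_cv = 0`` returns the exact exponential.
    """
    from .growth import GrowthSeries

    if A0 <= 0:
        raise ConfigurationError("A0 must be > 0")
    if noise_cv < 0:
        raise ConfigurationError("noise_cv must be >= 0")
    t = np.asarray(list(days), dtype=float)
    if t.size == 0 or np.any(np.diff(t) <= 0):
        raise ConfigurationError("days must be non-empty and strictly increasing")
    area = A0 * np.exp(k * t)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sig = np.sqrt(np.log1p(noise_cv ** 2))
        area = area * rng.lognormal(-sig ** 2 / 2, sig, t.size)
    return GrowthSeries(subject_id=subject_id, time=t, area=area)
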