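import numpy as np
import pandas as pd
import pytest

from aneuscore import SimulationConfig, make_gene_positions, simulate_counts
from aneuscore.cnv import CopyNumberProfile


@pytest.fixture(scope="session")
def positions_small():
    """3 chromosomes x 40 genes — enough for smoothing/scoring unit tests."""
    return make_gene_positions(3, 40, chromosome_length=10**6, seed=11)


@pytest.fixture(scope="session")
def sim_small(positions_small):
    """Cheap simulated dataset: 30 ref + 60 obs cells, 30% aneuploid."""
    cfg = SimulationConfig(n_ref=30, n_obs=60, n_chromosomes=3,
                           genes_per_chromosome=40, aneuploid_fraction=0.3,
                           mito_gene_count=4, seed=5)
    adata, truth = simulate_counts(cfg, positions_small)
    return cfg, adata, truth


def random_profile(rng, n_cells=None, n_chrom=3, seg_per_chrom=4):
    """Random CopyNumberProfile for scoring tests."""
    if n_cells is None:
        n_cells = int(rng.integers(5, 21))
    n_seg = n_chrom * seg_per_chrom
    values = rng.normal(0, 1, (n_cells, n_seg))
    n_ref = max(2, n_cells // 3)
    group = np.array(["reference"] * n_ref +
                     ["observation"] * (n_cells - n_ref))
    return CopyNumberProfile(
        values=values,
        cell_ids=pd.Index([f"c{i}" for i in range(n_cells)]),
        cell_group=group,
        segment_ids=pd.Index([f"s{j}" for j in range(n_seg)]),
        segment_chromosome=np.repeat(
            [str(c + 1) for c in range(n_chrom)], seg_per_chrom),
        segment_start=np.arange(n_seg) * 1000 + 1,
    )
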