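import anndata as ad
import numpy as np
import pandas as pd
import pytest

from aneuscore import (
    ConfigurationError,
    EmptyResultError,
    SimulationConfig,
    center_on_reference,
    denoise,
    lognormalize,
    order_genes,
    simulate_counts,
    smooth_genomic,
)
from aneuscore.cnv import _truncated_moving_mean


def make_norm(X, gene_ids, groups, chromosome=None, start=None):
    X = np.asarray(X, float)
    var = pd.DataFrame(index=pd.Index(gene_ids))
    if chromosome is not None:
        var["chromosome"] = chromosome
        var["start"] = start
    obs = pd.DataFrame(
        {"group": groups},
        index=pd.Index([f"c{i}" for i in range(X.shape[0])]))
    return ad.AnnData(X=X, obs=obs, var=var)


def positions_df(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end"])


class TestOrderGenes:
    POS = positions_df([("gA", "1", 100, 200), ("gB", "1", 500, 600),
                        ("gC", "2", 50, 80)])

    def test_pure_reordering_when_nothing_drops(self):
        norm = make_norm([[1, 2, 3]] * 4, ["gB", "gC", "gA"],
                         ["reference"] * 2 + ["observation"] * 2)
        out = order_genes(norm, self.POS, min_cells_expressing=1)
        assert list(out.var_names) == ["gA", "gB", "gC"]
        assert out.n_obs == 4

    def test_low_expression_gene_dropped(self):
        X = np.ones((4, 3))
        X[2:, 0] = 0  # gB expressed in only 2 cells
        norm = make_norm(X, ["gB", "gC", "gA"], ["observation"] * 4)
        out = order_genes(norm, self.POS, min_cells_expressing=3)
        assert list(out.var_names) == ["gA", "gC"]

    def test_unpositioned_gene_dropped(self):
        norm = make_norm([[1, 1]] * 3, ["gA", "gX"], ["observation"] * 3)
        out = order_genes(norm, self.POS, min_cells_expressing=1)
        assert list(out.var_names) == ["gA"]

    def test_shuffled_input_matches_brute_force_sort(self):
        rng = np.random.default_rng(2)
        pos = positions_df(
            [(f"g{j}", str(1 + j % 3), int(rng.integers(1, 10**6)), 10**6 + j)
             for j in range(30)])
        perm = rng.permutation(30)
        norm = make_norm(rng.poisson(3, (5, 30)) + 1.0,
                         [f"g{j}" for j in perm], ["observation"] * 5)
        out = order_genes(norm, pos, min_cells_expressing=1)
        chrom_order = {c: i for i, c in enumerate(pd.unique(pos["chromosome"]))}
        expected = sorted(
            pos["gene_id"],
            key=lambda g: (chrom_order[pos.set_index("gene_id").loc[g, "chromosome"]],
                           pos.set_index("gene_id").loc[g, "start"]))
        assert list(out.var_names) == expected

    def test_all_genes_dropped_raises(self):
        norm = make_norm([[1]] * 3, ["unknown"], ["observation"] * 3)
        with pytest.raises(EmptyResultError):
            order_genes(norm, self.POS)


class TestCenterOnReference:
    def test_hand_arithmetic(self):
        norm = make_norm([[1.0], [3.0], [5.0]], ["g0"],
                         ["reference", "reference", "observation"])
        out = center_on_reference(norm)
        np.testing.assert_allclose(out.X.ravel(), [-1.0, 1.0, 3.0])

    def test_observation_equal_to_reference_zeroes_out(self):
        norm = make_norm(np.full((4, 3), 2.5), [f"g{j}" for j in range(3)],
                         ["reference"] * 2 + ["observation"] * 2)
        out = center_on_reference(norm)
        np.testing.assert_allclose(out.X, 0.0, atol=1e-15)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        norm = make_norm(rng.normal(5, 1, (6, 4)), [f"g{j}" for j in range(4)],
                         ["reference"] * 3 + ["observation"] * 3)
        once = center_on_reference(norm)
        twice = center_on_reference(once)
        np.testing.assert_allclose(once.X, twice.X, atol=1e-12)

    def test_requires_reference_cells(self):
        norm = make_norm([[1.0], [2.0]], ["g0"], ["observation"] * 2)
        with pytest.raises(ValueError):
            center_on_reference(norm)

    def test_reference_gene_means_exactly_zero(self):
        rng = np.random.default_rng(4)
        norm = make_norm(rng.normal(3, 1, (10, 7)), [f"g{j}" for j in range(7)],
                         ["reference"] * 5 + ["observation"] * 5)
        out = center_on_reference(norm)
        ref_means = out.X[:5].mean(axis=0)
        np.testing.assert_allclose(ref_means, 0.0, atol=1e-12)


class TestSmoothing:
    def _centered(self, X, chrom, start=None):
        n_genes = np.asarray(X).shape[1]
        return make_norm(X, [f"g{j}" for j in range(n_genes)],
                         ["reference", "observation"][: np.asarray(X).shape[0]]
                         if np.asarray(X).shape[0] <= 2
                         else ["reference"] * 2 + ["observation"] * (np.asarray(X).shape[0] - 2),
                         chromosome=chrom,
                         start=start if start is not None else np.arange(n_genes))

    def test_hand_computed_truncated_moving_average(self):
        X = np.array([[0.0, 1.0, 2.0, 3.0, 4.0]])
        np.testing.assert_allclose(
            _truncated_moving_mean(X, 3).ravel(), [0.5, 1, 2, 3, 3.5])

    def test_window_one_is_identity(self):
        rng = np.random.default_rng(5)
        adata = self._centered(rng.normal(0, 1, (3, 8)), ["1"] * 8)
        prof = smooth_genomic(adata, window=1, clip=None)
        np.testing.assert_allclose(prof.values, adata.X)

    def test_constant_input_unchanged(self):
        adata = self._centered(np.full((2, 10), 0.7), ["1"] * 5 + ["2"] * 5)
        prof = smooth_genomic(adata, window=5, clip=None)
        np.testing.assert_allclose(prof.values, 0.7)

    def test_window_never_crosses_chromosomes(self):
        """A spike on chromosome 1 leaves chromosome 2 untouched."""
        X = np.zeros((2, 10))
        X[:, 4] = 10.0  # last gene of chromosome 1
        adata = self._centered(X, ["1"] * 5 + ["2"] * 5, start=list(range(5)) * 2)
        prof = smooth_genomic(adata, window=3, clip=None)
        assert (prof.values[:, 5:] == 0).all()
        assert prof.values[0, 4] > 0

    def test_even_window_rejected(self):
        adata = self._centered(np.zeros((2, 4)), ["1"] * 4)
        with pytest.raises(ConfigurationError):
            smooth_genomic(adata, window=4)

    def test_reference_segment_means_stay_zero(self):
        """Smoothing is linear, so centered reference means remain ~0."""
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (8, 12))
        X[:4] -= X[:4].mean(axis=0, keepdims=True)  # centered on reference
        adata = make_norm(X, [f"g{j}" for j in range(12)],
                          ["reference"] * 4 + ["observation"] * 4,
                          chromosome=["1"] * 6 + ["2"] * 6,
                          start=list(range(6)) * 2)
        prof = smooth_genomic(adata, window=3, clip=None)
        np.testing.assert_allclose(prof.values[:4].mean(axis=0), 0.0, atol=1e-10)


class TestDenoise:
    def _profile(self, values, n_ref=2):
        values = np.asarray(values, float)
        n = values.shape[0]
        adata = make_norm(values, [f"g{j}" for j in range(values.shape[1])],
                          ["reference"] * n_ref + ["observation"] * (n - n_ref),
                          chromosome=["1"] * values.shape[1],
                          start=np.arange(values.shape[1]))
        return smooth_genomic(adata, window=1, clip=None)

    def test_band_rule_hand_example(self):
        """sigma_ref = 1 on the segment; band +/-1.5 zeroes only 0.5."""
        col = np.array([[2 ** -0.5], [-(2 ** -0.5)],  # ref values, SD = 1
                        [0.5], [-2.0], [1.6]])
        prof = self._profile(col)
        out = denoise(prof, sd_multiplier=1.5)
        np.testing.assert_allclose(out.values[2:, 0], [0.0, -2.0, 1.6])
        np.testing.assert_allclose(out.values[:2, 0], col[:2, 0])

    def test_zero_multiplier_keeps_nonzero_values(self):
        rng = np.random.default_rng(8)
        prof = self._profile(rng.normal(0, 1, (6, 5)))
        out = denoise(prof, sd_multiplier=0.0)
        np.testing.assert_allclose(out.values, prof.values)

    def test_all_zero_observations_unchanged(self):
        vals = np.vstack([np.random.default_rng(9).normal(0, 1, (2, 5)),
                          np.zeros((3, 5))])
        prof = self._profile(vals)
        out = denoise(prof, sd_multiplier=1.5)
        assert (out.values[2:] == 0).all()


class TestEndToEndProfile:
    def test_gained_chromosome_separates_carriers(self, positions_small):
        """Carriers of a 1.5x chromosome have higher smoothed values there."""
        cfg = SimulationConfig(n_ref=50, n_obs=200, n_chromosomes=3,
                               genes_per_chromosome=40, aneuploid_fraction=0.5,
                               copy_ratios=(1.5,), max_altered_chromosomes=1,
                               seed=12)
        adata, truth = simulate_counts(cfg, positions_small)
        norm = lognormalize(adata)
        ordered = order_genes(norm, positions_small, min_cells_expressing=3)
        centered = center_on_reference(ordered)
        prof = smooth_genomic(centered, window=11)
        obs = prof.cell_group == "observation"
        for chrom in truth.columns:
            carriers = (truth[chrom] == 1.5).to_numpy() & obs
            euploid = (truth.to_numpy() == 1.0).all(axis=1) & obs
            if carriers.sum() < 10:
                continue
            seg = prof.segment_chromosome == chrom
            assert prof.values[np.ix_(carriers, np.flatnonzero(seg))].mean() > \
                prof.values[np.ix_(euploid, np.flatnonzero(seg))].mean()
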