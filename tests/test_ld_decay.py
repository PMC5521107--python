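"""r² estimators, pair sampling, decay fitting, chromosome combination."""

import numpy as np
import pytest

from ldne import (LdGrid, combine_chromosomes, default_grid,
                  em_haplotype_r2, fit_decay, haplotype_r2,
                  inverse_variance_combine, pair_r2, pairwise_r2,
                  replicate_grid, sample_pairs)


class TestR2Estimators:
    def test_identical_vectors_give_one(self):
        d = np.array([0, 1, 2, 1, 0, 2], dtype=float)
        assert pairwise_r2(d, d) == pytest.approx(1.0)

    def test_haplotype_formula_hand_example(self):
        # 4x AB, 1x Ab, 2x aB, 3x ab over 10 haplotypes:
        # f(AB)=0.4, f(A)=0.5, f(B)=0.6, D=0.1, r2=0.01/0.036=0.1667
        a = np.array([1] * 4 + [1] * 1 + [0] * 2 + [0] * 3, dtype=float)
        b = np.array([1] * 4 + [0] * 1 + [1] * 2 + [0] * 3, dtype=float)
        expected = 0.01 / (0.5 * 0.5 * 0.6 * 0.4)
        assert haplotype_r2(a, b) == pytest.approx(expected)
        # brute-force Pearson over the allele indicators agrees
        r = np.corrcoef(a, b)[0, 1]
        assert haplotype_r2(a, b) == pytest.approx(r * r)

    def test_composite_equals_haplotype_r2_on_phased_pairs(self):
        # random-mating collapse: genotype = sum of two random haplotypes
        rng = np.random.default_rng(0)
        n = 2000
        # correlated loci via shared latent haplotype state
        h1 = (rng.random(2 * n) < 0.5).astype(float)
        keep = rng.random(2 * n) < 0.8
        h2 = np.where(keep, h1, (rng.random(2 * n) < 0.5))
        true = haplotype_r2(h1, h2)
        g1 = h1[0::2] + h1[1::2]
        g2 = h2[0::2] + h2[1::2]
        assert pairwise_r2(g1, g2) == pytest.approx(true, abs=0.02)

    def test_em_recovers_haplotype_r2_from_unphased(self):
        rng = np.random.default_rng(1)
        n = 3000
        h1 = (rng.random(2 * n) < 0.4).astype(float)
        keep = rng.random(2 * n) < 0.7
        h2 = np.where(keep, h1, (rng.random(2 * n) < 0.6))
        true = haplotype_r2(h1, h2)
        g1 = h1[0::2] + h1[1::2]
        g2 = h2[0::2] + h2[1::2]
        assert em_haplotype_r2(g1, g2) == pytest.approx(true, abs=0.02)

    def test_allele_swap_invariance(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 3, 200).astype(float)
        b = rng.integers(0, 3, 200).astype(float)
        base = pairwise_r2(a, b)
        assert pairwise_r2(2 - a, b) == pytest.approx(base)
        assert pairwise_r2(a, 2 - b) == pytest.approx(base)
        assert pairwise_r2(b, a) == pytest.approx(base)

    def test_independent_loci_r2_near_reciprocal_n(self):
        rng = np.random.default_rng(3)
        n = 10000
        g1 = rng.binomial(2, 0.5, n).astype(float)
        g2 = rng.binomial(2, 0.5, n).astype(float)
        assert pairwise_r2(g1, g2) < 0.01

    def test_monomorphic_pair_is_nan(self):
        assert np.isnan(pairwise_r2(np.zeros(10), np.arange(10) % 3))


class TestSamplePairs:
    def test_exhaustion_returns_all_pairs(self):
        i, j = sample_pairs(3, 10, 0)
        assert sorted(zip(i.tolist(), j.tolist())) == [(0, 1), (0, 2), (1, 2)]

    def test_deterministic_under_seed(self):
        i1, j1 = sample_pairs(500, 1000, 42)
        i2, j2 = sample_pairs(500, 1000, 42)
        np.testing.assert_array_equal(i1, i2)
        np.testing.assert_array_equal(j1, j2)
        i3, _ = sample_pairs(500, 1000, 43)
        assert not np.array_equal(i1, i3)

    def test_twenty_thousand_distinct_pairs_from_675_snps(self):
        i, j = sample_pairs(675, 20000, 7)
        assert i.size == 20000
        assert (i < j).all()
        codes = i * 675 + j
        assert np.unique(codes).size == 20000

    def test_vectorised_r2_matches_scalar(self, tiny_population):
        _, matrix, _ = tiny_population
        d = matrix.dosages[:, :50]
        i, j = sample_pairs(50, 100, 0)
        fast = pair_r2(d, i, j)
        slow = np.array([pairwise_r2(d[:, a], d[:, b])
                         for a, b in zip(i, j)])
        np.testing.assert_allclose(
            np.nan_to_num(fast, nan=-1), np.nan_to_num(slow, nan=-1),
            atol=1e-10)


class TestFitDecay:
    def test_constant_r2_reproduced(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 60, 5000)
        y = np.full(5000, 0.3)
        grid = default_grid(100)
        np.testing.assert_allclose(fit_decay(x, y, grid), 0.3, atol=1e-6)

    def test_known_curve_recovered_within_noise(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 60, 30000)
        true = 1.0 / (1.0 + 0.5 * x)
        y = true + rng.normal(0, 0.05, x.size)
        grid = default_grid(200)
        fitted = fit_decay(x, y, grid)
        true_grid = 1.0 / (1.0 + 0.5 * grid)
        interior = (grid > 2) & (grid < 45)
        assert np.abs(fitted[interior] - true_grid[interior]).max() < 0.02

    def test_predictions_clamped_non_negative(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 60, 2000)
        y = rng.normal(0.0, 0.01, 2000)          # noise around zero
        assert (fit_decay(x, y, default_grid(100)) >= 0).all()

    def test_insufficient_pairs_raises(self):
        with pytest.raises(ValueError, match="informative pairs"):
            fit_decay(np.array([1.0, 2.0]), np.array([0.1, 0.2]),
                      default_grid(10))


class TestReplicateGrid:
    def test_identical_seeds_give_zero_variance(self, tiny_population):
        _, matrix, _ = tiny_population
        d = matrix.dosages[:, :300]
        pos = np.linspace(0, 50, 300)
        grid = default_grid(50)
        m1, v1, reps = replicate_grid(d, pos, grid, n_pairs=2000, n_reps=2,
                                      rng_seed=0, min_pairs=20)
        assert reps.shape == (2, 50)
        # force identical replicates by fitting the same sample twice
        m2a, _, _ = replicate_grid(d, pos, grid, n_pairs=2000, n_reps=1,
                                   rng_seed=5, min_pairs=20)
        m2b, _, _ = replicate_grid(d, pos, grid, n_pairs=2000, n_reps=1,
                                   rng_seed=5, min_pairs=20)
        np.testing.assert_allclose(m2a, m2b)

    def test_single_replicate_variance_missing(self, tiny_population):
        _, matrix, _ = tiny_population
        poly = matrix.dosages.std(axis=0) > 0
        d = matrix.dosages[:, poly][:, :200]
        _, v, _ = replicate_grid(d, np.linspace(0, 50, d.shape[1]),
                                 default_grid(20), n_pairs=3000, n_reps=1,
                                 min_pairs=20)
        assert np.isnan(v).all()

    def test_map_method_changes_distances_not_r2(self, tiny_population):
        # the same pair sample under two maps: r² values identical
        _, matrix, _ = tiny_population
        d = matrix.dosages[:, :100]
        i, j = sample_pairs(100, 300, 1)
        r2 = pair_r2(d, i, j)
        # distances under M1 vs a rescaled map differ...
        pos1 = np.linspace(0, 50, 100)
        pos2 = pos1 * 1.7
        assert not np.allclose(np.abs(pos1[i] - pos1[j]),
                               np.abs(pos2[i] - pos2[j]))
        # ...but r² is a function of genotypes only
        np.testing.assert_array_equal(r2, pair_r2(d, i, j))


class TestCombine:
    def test_weighted_mean_oracle(self):
        mean, se = inverse_variance_combine(
            np.array([[0.3], [0.6]]), np.array([[0.01], [0.04]]))
        assert mean[0] == pytest.approx(0.36)
        assert se[0] == pytest.approx(np.sqrt(1 / 125))

    def test_equal_variances_reduce_to_plain_mean(self):
        rng = np.random.default_rng(7)
        m = rng.random((5, 20))
        v = np.full((5, 20), 0.02)
        mean, _ = inverse_variance_combine(m, v)
        np.testing.assert_allclose(mean, m.mean(axis=0))

    def test_single_chromosome_passthrough(self):
        mean, se = inverse_variance_combine(np.array([[0.4]]),
                                            np.array([[0.09]]))
        assert mean[0] == pytest.approx(0.4)
        assert se[0] == pytest.approx(0.3)

    def test_zero_variance_weight_is_capped(self):
        mean, se = inverse_variance_combine(
            np.array([[0.2], [0.8]]), np.array([[0.0], [0.01]]))
        assert np.isfinite(mean[0]) and np.isfinite(se[0])
        assert mean[0] == pytest.approx(0.5)       # capped to equal weights

    def test_combine_chromosomes_ci_ordering(self):
        grid = default_grid(10)
        g = LdGrid("M1", grid)
        rng = np.random.default_rng(8)
        for c in ("1", "2", "3"):
            g.mean_r2[c] = rng.uniform(0.1, 0.3, 10)
            g.var_r2[c] = rng.uniform(0.001, 0.01, 10)
        curve = combine_chromosomes(g)
        assert (curve.ci95_low <= curve.weighted_mean_r2 + 1e-12).all()
        assert (curve.weighted_mean_r2 <= curve.ci95_high + 1e-12).all()


class TestDecayShape:
    def test_equilibrium_population_decay_non_increasing(self, tiny_population):
        # broad monotone trend up to CI noise: check via coarse bins
        _, matrix, _ = tiny_population
        from ldne import ld_snp_filter, m1_positions, ld_grid_for_matrix
        m = ld_snp_filter(matrix, 0.05)
        dense = m1_positions(m.snp_table())
        grid = ld_grid_for_matrix(m, dense, default_grid(100, 0.5, 40),
                                  n_pairs=4000, n_reps=5, rng_seed=3,
                                  min_pairs=20)
        curve = combine_chromosomes(grid)
        from scipy import stats
        rho, p = stats.spearmanr(curve.grid_cm, curve.weighted_mean_r2)
        assert rho < 0 and p < 0.01
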