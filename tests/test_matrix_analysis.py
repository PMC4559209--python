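import numpy as np
import pytest
from scipy import optimize, stats

from hicdesk import (
    ComparisonResult,
    FragmentCovariates,
    GenomeIndex,
    HicdeskError,
    InteractionMatrix,
    bin_genome,
    correlated_difference,
    normalize_distance_coverage,
    normalize_iterative,
    normalize_poisson,
    relative_difference,
    render_heatmap,
    sample_correlation,
    signed_difference,
)
from hicdesk.matrix_analysis import ConvergenceError, expected_by_distance


def square_matrix(frags, dense):
    dense = np.asarray(dense, float)
    return InteractionMatrix(frags, np.triu(dense))


@pytest.fixture
def frags10():
    return bin_genome(GenomeIndex(["c"], [10_000]), 1_000)


@pytest.fixture
def two_chrom_frags():
    return bin_genome(GenomeIndex(["chr1", "chr2"], [8_000, 6_000]), 1_000)


def decay_matrix(n, c=100.0, alpha=1.0):
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    return c * np.maximum(d, 0.5) ** (-alpha)


class TestDistanceCoverage:
    def test_constant_per_diagonal_becomes_one(self, frags10):
        m = square_matrix(frags10, decay_matrix(10))
        norm = normalize_distance_coverage(m)
        assert np.allclose(norm.matrix, 1.0)

    def test_scale_invariance(self, frags10, rng):
        d = rng.poisson(20, (10, 10)).astype(float)
        d = (d + d.T) / 2
        n1 = normalize_distance_coverage(square_matrix(frags10, d))
        n2 = normalize_distance_coverage(square_matrix(frags10, 2 * d))
        assert np.allclose(n1.matrix, n2.matrix, equal_nan=True)

    def test_diagonal_class_means_are_one(self, two_chrom_frags, rng):
        d = rng.poisson(15, (14, 14)).astype(float) + 1
        d = (d + d.T) / 2
        norm = normalize_distance_coverage(square_matrix(two_chrom_frags, d))
        exp = expected_by_distance(norm.matrix, two_chrom_frags)
        assert np.allclose(exp[np.isfinite(exp)], 1.0)

    def test_inter_chromosomal_coverage_normalization(self, two_chrom_frags, rng):
        d = rng.poisson(15, (14, 14)).astype(float) + 1
        d = (d + d.T) / 2
        norm = normalize_distance_coverage(square_matrix(two_chrom_frags, d))
        codes = two_chrom_frags.chrom_codes
        inter = codes[:, None] != codes[None, :]
        assert np.nanmean(norm.matrix[inter]) == pytest.approx(1.0, abs=0.2)

    def test_empty_matrix_error(self, frags10):
        with pytest.raises(HicdeskError):
            normalize_distance_coverage(InteractionMatrix.empty(frags10))


def balancing_oracle(M):
    """Independent bias solution: solve row-sum equations with least_squares."""
    n = M.shape[0]

    def resid(logb):
        b = np.exp(logb)
        W = M / np.outer(b, b)
        s = W.sum(axis=1)
        return s - s.mean()

    sol = optimize.least_squares(resid, np.zeros(n), xtol=1e-15, ftol=1e-15)
    b = np.exp(sol.x)
    return b / b.mean()


class TestIterative:
    def test_balanced_matrix_unchanged(self):
        frags = bin_genome(GenomeIndex(["c"], [2_000]), 1_000)
        m = square_matrix(frags, [[0, 2], [2, 0]])
        norm = normalize_iterative(m, mask_percentile=0)
        assert norm.matrix[0, 1] == pytest.approx(norm.matrix[1, 0])
        assert norm.matrix[0, 0] == 0 and norm.matrix[1, 1] == 0
        sums = norm.matrix.sum(axis=1)
        assert np.allclose(sums, sums[0])

    def test_matches_least_squares_oracle(self, rng):
        n = 5
        frags = bin_genome(GenomeIndex(["c"], [n * 1000]), 1_000)
        M = rng.uniform(1, 10, (n, n))
        M = (M + M.T) / 2
        norm = normalize_iterative(square_matrix(frags, M),
                                   tolerance=1e-12, mask_percentile=0)
        b_hat = norm.meta["bias"]
        b_ref = balancing_oracle(M)
        assert np.allclose(b_hat / b_hat.mean(), b_ref, atol=1e-6)

    def test_planted_bias_recovery(self, rng):
        # circulant (wrap-around) decay has equal row sums, so the ICE bias
        # vector is exactly the planted one up to scale
        n = 60
        frags = bin_genome(GenomeIndex(["c"], [n * 1000]), 1_000)
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        d = np.minimum(d, n - d)
        T = np.maximum(d, 0.5) ** -1.0
        b = rng.uniform(0.5, 2.0, n)
        O = np.outer(b, b) * T
        norm = normalize_iterative(square_matrix(frags, O), mask_percentile=0)
        bias = norm.meta["bias"]
        assert np.corrcoef(bias, b)[0, 1] > 0.99

    def test_permutation_invariance(self, rng):
        n = 8
        frags = bin_genome(GenomeIndex(["c"], [n * 1000]), 1_000)
        M = rng.uniform(1, 5, (n, n))
        M = (M + M.T) / 2
        perm = rng.permutation(n)
        n1 = normalize_iterative(square_matrix(frags, M), mask_percentile=0)
        n2 = normalize_iterative(square_matrix(frags, M[np.ix_(perm, perm)]),
                                 mask_percentile=0)
        assert np.allclose(n2.matrix, n1.matrix[np.ix_(perm, perm)], atol=1e-8)

    def test_row_sums_equal_within_tolerance(self, rng):
        n = 40
        frags = bin_genome(GenomeIndex(["c"], [n * 1000]), 1_000)
        M = rng.poisson(10, (n, n)).astype(float)
        M = (M + M.T) / 2
        norm = normalize_iterative(square_matrix(frags, M), tolerance=1e-6)
        keep = ~norm.mask
        sums = np.nansum(norm.matrix[keep][:, keep], axis=1)
        assert np.ptp(sums) / sums.mean() < 1e-5

    def test_non_convergence_raises_with_residual(self, rng):
        n = 10
        frags = bin_genome(GenomeIndex(["c"], [n * 1000]), 1_000)
        M = rng.uniform(1, 20, (n, n))
        M = (M + M.T) / 2
        with pytest.raises(ConvergenceError) as exc:
            normalize_iterative(square_matrix(frags, M), tolerance=1e-12,
                                max_iterations=1)
        assert exc.value.residual > 0


class TestPoisson:
    def test_identical_covariates_output_proportional(self, frags10, rng):
        d = rng.poisson(10, (10, 10)).astype(float)
        d = (d + d.T) / 2
        cov = FragmentCovariates(np.full(10, 1000.0), np.full(10, 0.5))
        with pytest.warns(UserWarning, match="zero variance"):
            norm = normalize_poisson(square_matrix(frags10, d), cov)
        iu, ju = np.triu_indices(10, k=1)
        ratio = norm.matrix[iu, ju] / d[iu, ju]
        ok = np.isfinite(ratio)
        assert np.allclose(ratio[ok], ratio[ok][0])

    def test_coefficient_recovery_within_two_se(self, rng):
        n = 80
        frags = bin_genome(GenomeIndex(["c"], [n * 1000]), 1_000)
        length = rng.uniform(500, 2000, n)
        gc = rng.uniform(0.3, 0.7, n)
        iu, ju = np.triu_indices(n, k=1)
        true_len, true_gc = 0.5, 0.8
        eta = (true_len * np.log(length[iu] * length[ju])
               + true_gc * np.log(gc[iu] * gc[ju]))
        mu = np.exp(eta - eta.mean() + 2.5)
        y = rng.poisson(mu).astype(float)
        M = np.zeros((n, n))
        M[iu, ju] = y
        norm = normalize_poisson(InteractionMatrix(frags, M),
                                 FragmentCovariates(length, gc))
        fit = norm.meta["coefficients"]["c"]
        for key, truth in (("log_len", true_len), ("log_gc", true_gc)):
            assert abs(fit["params"][key] - truth) < 2 * fit["bse"][key]
        # decorrelation from the length covariate
        out = norm.matrix[iu, ju]
        ok = np.isfinite(out)
        rho = stats.spearmanr(out[ok], np.log(length[iu] * length[ju])[ok]).statistic
        assert abs(rho) < 0.05


class TestSampleCorrelation:
    def test_identical_and_scaled(self, frags10, rng):
        d = rng.poisson(10, (10, 10)).astype(float)
        d = (d + d.T) / 2
        m = square_matrix(frags10, d)
        m2 = square_matrix(frags10, 2 * d)
        corr = sample_correlation([m, m, m2])
        assert np.allclose(corr, 1.0)

    def test_independent_matrices_near_zero(self, rng):
        n = 500
        frags = bin_genome(GenomeIndex(["c"], [n * 1000]), 1_000)
        a = rng.normal(10, 1, (n, n))
        b = rng.normal(10, 1, (n, n))
        corr = sample_correlation(
            [square_matrix(frags, (a + a.T) / 2), square_matrix(frags, (b + b.T) / 2)]
        )
        assert abs(corr[0, 1]) < 0.05

    def test_median_statistic_and_errors(self, frags10, rng):
        d = rng.poisson(10, (10, 10)).astype(float)
        m = square_matrix(frags10, (d + d.T) / 2)
        assert sample_correlation([m, m], "median")[0, 1] == pytest.approx(1.0)
        with pytest.raises(HicdeskError):
            sample_correlation([m, m], "mode")


class TestRelativeDifference:
    def test_formula_and_antisymmetry(self, frags10, rng):
        a = np.full((10, 10), 3.0)
        b = np.full((10, 10), 1.0)
        res = relative_difference(square_matrix(frags10, a), square_matrix(frags10, b))
        assert np.allclose(res.matrix, 1.0)
        res_ba = relative_difference(square_matrix(frags10, b), square_matrix(frags10, a))
        assert np.allclose(res.matrix, -res_ba.matrix)

    def test_identical_and_both_zero(self, frags10, rng):
        d = rng.poisson(3, (10, 10)).astype(float)
        d = (d + d.T) / 2
        m = square_matrix(frags10, d)
        assert np.allclose(relative_difference(m, m).matrix, 0.0)

    def test_bounded_by_two(self, frags10, rng):
        a = rng.poisson(2, (10, 10)).astype(float)
        b = rng.poisson(2, (10, 10)).astype(float)
        res = relative_difference(square_matrix(frags10, (a + a.T) / 2),
                                  square_matrix(frags10, (b + b.T) / 2))
        assert np.nanmax(np.abs(res.matrix)) <= 2.0
        # bound attained when one entry is zero and the other positive
        a0 = np.zeros((10, 10)); a0[0, 1] = a0[1, 0] = 4.0
        res2 = relative_difference(square_matrix(frags10, a0),
                                   square_matrix(frags10, np.zeros((10, 10))))
        assert res2.matrix[0, 1] == 2.0


class TestCorrelatedDifference:
    def test_identical_and_negated_rows(self, frags10):
        m = np.zeros((10, 10))
        m[0] = m[1] = np.arange(10)
        m[2] = -np.arange(10)
        res = correlated_difference(ComparisonResult(m, "relative_difference"))
        assert res.matrix[0, 1] == pytest.approx(1.0)
        assert res.matrix[0, 2] == pytest.approx(-1.0)

    def test_kind_check(self, frags10):
        with pytest.raises(HicdeskError):
            correlated_difference(ComparisonResult(np.eye(3), "signed_difference"))

    def test_block_structure_recovered(self, frags10, rng):
        base1, base2 = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
        m = np.array([base1 + rng.normal(0, .1, 10) for _ in range(5)]
                     + [base2 + rng.normal(0, .1, 10) for _ in range(5)])
        res = correlated_difference(ComparisonResult(m, "relative_difference"))
        within = np.concatenate([res.matrix[:5, :5][np.triu_indices(5, 1)],
                                 res.matrix[5:, 5:][np.triu_indices(5, 1)]])
        between = res.matrix[:5, 5:].ravel()
        assert np.nanmean(within) > np.nanmean(between)


class TestSignedDifference:
    def test_offset_region_all_positive(self, frags10, rng):
        d = rng.poisson(10, (10, 10)).astype(float)
        d = (d + d.T) / 2
        a = d + 5.0
        res = signed_difference(square_matrix(frags10, a), square_matrix(frags10, d),
                                permutations=19, seed=1)
        assert res.statistic == pytest.approx(1.0)
        assert np.all(res.matrix[np.triu_indices(10, 1)] == 1)

    def test_sign_antisymmetry(self, frags10, rng):
        a = rng.poisson(10, (10, 10)).astype(float)
        b = rng.poisson(10, (10, 10)).astype(float)
        a, b = (a + a.T) / 2, (b + b.T) / 2
        r1 = signed_difference(square_matrix(frags10, a), square_matrix(frags10, b),
                               permutations=9, seed=0)
        r2 = signed_difference(square_matrix(frags10, b), square_matrix(frags10, a),
                               permutations=9, seed=0)
        assert np.array_equal(r1.matrix, -r2.matrix)

    def test_null_not_significant(self, rng):
        n = 30
        frags = bin_genome(GenomeIndex(["c"], [n * 1000]), 1_000)
        ps, ss = [], []
        for rep in range(30):
            a = rng.poisson(20, (n, n)).astype(float)
            b = rng.poisson(20, (n, n)).astype(float)
            res = signed_difference(square_matrix(frags, (a + a.T) / 2),
                                    square_matrix(frags, (b + b.T) / 2),
                                    permutations=99, seed=rep)
            ps.append(res.p_value)
            ss.append(res.statistic)
        assert np.mean(np.array(ps) > 0.05) >= 0.9
        assert np.mean(ss) < 0.1

    def test_pvalue_uniform_under_null(self, rng):
        n = 20
        frags = bin_genome(GenomeIndex(["c"], [n * 1000]), 1_000)
        ps = []
        for rep in range(200):
            a = rng.normal(20, 2, (n, n))
            b = rng.normal(20, 2, (n, n))
            res = signed_difference(square_matrix(frags, (a + a.T) / 2),
                                    square_matrix(frags, (b + b.T) / 2),
                                    permutations=49, seed=1000 + rep)
            ps.append(res.p_value)
        assert stats.kstest(ps, "uniform").statistic < 0.1

    def test_replicate_permutation_mode(self, frags10, rng):
        reps_a = [square_matrix(frags10, (lambda x: (x + x.T) / 2)(
            rng.poisson(10, (10, 10)).astype(float))) for _ in range(3)]
        reps_b = [square_matrix(frags10, (lambda x: (x + x.T) / 2)(
            rng.poisson(10, (10, 10)).astype(float))) for _ in range(3)]
        a = square_matrix(frags10, np.mean([m.dense() for m in reps_a], axis=0))
        b = square_matrix(frags10, np.mean([m.dense() for m in reps_b], axis=0))
        res = signed_difference(a, b, replicates_a=reps_a, replicates_b=reps_b,
                                permutations=49, seed=3)
        assert res.meta["mode"] == "replicate_permutation"
        assert res.p_value > 0.05

    def test_permutations_validation(self, frags10):
        m = square_matrix(frags10, np.ones((10, 10)))
        with pytest.raises(HicdeskError):
            signed_difference(m, m, permutations=0)


class TestHeatmap:
    def test_writes_images(self, tmp_path, frags10, rng):
        d = rng.poisson(5, (10, 10)).astype(float)
        d[0, 3] = np.nan
        m = square_matrix(frags10, np.nan_to_num((d + d.T) / 2))
        p1 = tmp_path / "map.png"
        render_heatmap(m, str(p1))
        assert p1.stat().st_size > 0
        comp = relative_difference(m, square_matrix(frags10, np.ones((10, 10))))
        p2 = tmp_path / "cmp.png"
        render_heatmap(comp, str(p2), title="relative difference")
        assert p2.stat().st_size > 0
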