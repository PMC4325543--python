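import numpy as np
import pytest
from scipy import stats

from jackstraw import (
    AssociationSpec,
    ExpressionMatrix,
    JackstrawConfig,
    center_rows,
    empirical_pvalues,
    exhaustive_jackstraw,
    jackstraw_iteration,
    permute_rows,
    run_jackstraw,
    simulate_study,
    SimulationScenario,
)
from jackstraw.engine import default_B, default_s


def naive_empirical_pvalues(observed, pool, pseudo_count=False):
    """O(m * sB) double-loop oracle for the empirical p-value formula."""
    out = np.empty(len(observed))
    for i, f in enumerate(observed):
        count = sum(1 for f0 in pool if f0 >= f)
        out[i] = (count + 1) / (len(pool) + 1) if pseudo_count else count / len(pool)
    return out


class TestPermuteRows:
    def test_multiset_preserved_and_others_untouched(self, rng):
        M = ExpressionMatrix.from_array(rng.standard_normal((6, 8)))
        out = permute_rows(M, [1, 4], rng)
        for i in range(6):
            if i in (1, 4):
                np.testing.assert_array_equal(
                    np.sort(out.values[i]), np.sort(M.values[i])
                )
            else:
                assert np.array_equal(out.values[i], M.values[i])

    def test_constant_row_is_fixed_point(self, rng):
        A = np.vstack([np.zeros(5), np.arange(5.0)])
        out = permute_rows(ExpressionMatrix.from_array(A), [0], rng)
        np.testing.assert_array_equal(out.values[0], np.zeros(5))

    def test_row_means_preserved(self, rng):
        M = ExpressionMatrix.from_array(rng.standard_normal((5, 7)))
        out = permute_rows(M, [0, 1, 2, 3, 4], rng)
        np.testing.assert_allclose(
            out.values.mean(axis=1), M.values.mean(axis=1), atol=1e-15
        )

    @pytest.mark.parametrize("rows", [[], [2, 2]])
    def test_bad_row_sets(self, rows, rng):
        M = ExpressionMatrix.from_array(np.arange(12.0).reshape(3, 4))
        with pytest.raises(ValueError):
            permute_rows(M, rows, rng)


class TestJackstrawIteration:
    def test_shape_and_determinism(self, rng):
        study = simulate_study(SimulationScenario(m=100, n=12, seed=3))
        Yc = center_rows(study.Y)
        spec = AssociationSpec(r=1)
        f1 = jackstraw_iteration(Yc, spec, 10, np.random.default_rng(42))
        f2 = jackstraw_iteration(Yc, spec, 10, np.random.default_rng(42))
        assert f1.shape == (10,) and np.all(f1 >= 0)
        np.testing.assert_array_equal(f1, f2)

    def test_requires_centered_input(self, rng):
        M = ExpressionMatrix.from_array(rng.standard_normal((20, 8)) + 5.0)
        with pytest.raises(ValueError, match="centered"):
            jackstraw_iteration(M, AssociationSpec(r=1), 3, rng)

    def test_s_larger_than_m_rejected(self, rng):
        M = center_rows(ExpressionMatrix.from_array(rng.standard_normal((10, 8))))
        with pytest.raises(ValueError, match="exceeds"):
            jackstraw_iteration(M, AssociationSpec(r=1), 11, rng)

    def test_null_statistics_match_observed_on_pure_noise(self, rng):
        """On pure noise every row is null, so the synthetic null statistics and
        the observed statistics of the same rows are draws from one distribution."""
        from jackstraw import fstats_all, svd_decompose, top_pcs

        m, n, s = 500, 20, 50
        Y = center_rows(ExpressionMatrix.from_array(rng.standard_normal((m, n))))
        spec = AssociationSpec(r=1)
        observed = fstats_all(Y, top_pcs(svd_decompose(Y, center=False), 1), spec)
        rng2 = np.random.default_rng(7)
        null_pool = [
            jackstraw_iteration(Y, spec, s, rng2) for _ in range(200)
        ]
        ks = stats.ks_2samp(np.concatenate(null_pool), observed)
        assert ks.pvalue > 0.01


class TestEmpiricalPvalues:
    def test_counting_examples(self):
        pool = np.array([1.0, 2.0, 3.0, 4.0])
        assert empirical_pvalues(np.array([2.5]), pool)[0] == 0.5
        assert empirical_pvalues(np.array([5.0]), pool)[0] == 0.0
        assert empirical_pvalues(np.array([5.0]), pool, pseudo_count=True)[0] == 0.2
        assert empirical_pvalues(np.array([0.5]), pool)[0] == 1.0
        # exact ties count toward the numerator
        assert empirical_pvalues(np.array([2.0]), pool)[0] == 0.75

    @pytest.mark.parametrize("pseudo", [False, True])
    def test_sorted_implementation_equals_double_loop(self, pseudo, rng):
        observed = np.concatenate([rng.exponential(size=40), [np.inf, 0.0]])
        pool = np.concatenate([rng.exponential(size=97), observed[:3]])
        fast = empirical_pvalues(observed, pool, pseudo_count=pseudo)
        slow = naive_empirical_pvalues(observed, pool, pseudo_count=pseudo)
        np.testing.assert_array_equal(fast, slow)

    def test_granularity_and_monotonicity(self, rng):
        observed = rng.exponential(size=50)
        pool = rng.exponential(size=200)
        p = empirical_pvalues(observed, pool)
        np.testing.assert_allclose(p * 200, np.round(p * 200), atol=1e-9)
        order = np.argsort(observed)
        assert np.all(np.diff(p[order]) <= 0)

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            empirical_pvalues(np.array([1.0]), np.array([]))
        with pytest.raises(ValueError, match="NaN"):
            empirical_pvalues(np.array([np.nan]), np.array([1.0]))


class TestRunJackstraw:
    def test_same_seed_reproduces_everything(self):
        study = simulate_study(SimulationScenario(m=120, n=16, seed=9))
        spec = AssociationSpec(r=1)
        cfg = JackstrawConfig(s=12, B=100, seed=5)
        a = run_jackstraw(study.Y, spec, cfg)
        b = run_jackstraw(study.Y, spec, cfg)
        assert np.array_equal(a.observed_f, b.observed_f)
        assert np.array_equal(a.null_f, b.null_f)
        assert np.array_equal(a.pvalues, b.pvalues)

    def test_pvalues_monotone_in_observed_f(self):
        study = simulate_study(SimulationScenario(m=120, n=16, seed=9))
        res = run_jackstraw(study.Y, AssociationSpec(r=1), JackstrawConfig(s=12, B=100, seed=5))
        order = np.argsort(res.observed_f)
        assert np.all(np.diff(res.pvalues[order]) <= 0)
        grid = np.round(res.pvalues * res.null_f.size)
        np.testing.assert_allclose(res.pvalues * res.null_f.size, grid, atol=1e-9)

    def test_pure_noise_calibration(self):
        rng = np.random.default_rng(2024)
        Y = ExpressionMatrix.from_array(rng.standard_normal((500, 20)))
        res = run_jackstraw(Y, AssociationSpec(r=1), JackstrawConfig(s=50, B=100, seed=1))
        assert 0.45 <= res.pvalues.mean() <= 0.55
        ks = stats.ks_1samp(res.pvalues, stats.uniform.cdf, alternative="greater")
        assert ks.pvalue > 0.01

    def test_signal_rows_get_smaller_pvalues(self):
        study = simulate_study(
            SimulationScenario(m=1000, n=20, pi0=0.95, seed=31)
        )
        res = run_jackstraw(
            study.Y, AssociationSpec(r=1), JackstrawConfig(s=50, B=200, seed=8)
        )
        mw = stats.mannwhitneyu(
            res.pvalues[~study.null_mask],
            res.pvalues[study.null_mask],
            alternative="less",
        )
        assert mw.pvalue < 1e-6

    def test_parameter_validation(self):
        study = simulate_study(SimulationScenario(m=50, n=10, seed=0))
        with pytest.raises(ValueError, match="n >= r"):
            run_jackstraw(study.Y, AssociationSpec(r=9), JackstrawConfig(s=5, B=200))
        with pytest.raises(ValueError, match="exceeds"):
            run_jackstraw(study.Y, AssociationSpec(r=1), JackstrawConfig(s=51, B=100))

    def test_defaults(self):
        assert default_s(1000) == 100
        assert default_B(1000, 100) == 100
        cfg = JackstrawConfig.for_matrix(1000, seed=3)
        assert cfg.s == 100 and cfg.B == 100
        with pytest.warns(UserWarning, match="coarse"):
            JackstrawConfig(s=3, B=10)


class TestExhaustiveJackstraw:
    def test_granularity(self):
        study = simulate_study(SimulationScenario(m=30, n=12, seed=4))
        p = exhaustive_jackstraw(study.Y, AssociationSpec(r=1), B=20, seed=6)
        assert p.shape == (30,)
        np.testing.assert_array_equal(p * 20, np.round(p * 20))

    def test_deterministic(self):
        study = simulate_study(SimulationScenario(m=20, n=12, seed=4))
        a = exhaustive_jackstraw(study.Y, AssociationSpec(r=1), B=15, seed=6)
        b = exhaustive_jackstraw(study.Y, AssociationSpec(r=1), B=15, seed=6)
        np.testing.assert_array_equal(a, b)

    def test_agrees_with_pooled_on_null_data(self):
        """Within-variable and pooled p-values estimate the same quantity; on a
        small null dataset they should correlate strongly."""
        rng = np.random.default_rng(77)
        Y = ExpressionMatrix.from_array(rng.standard_normal((60, 12)))
        spec = AssociationSpec(r=1)
        pooled = run_jackstraw(Y, spec, JackstrawConfig(s=6, B=200, seed=1)).pvalues
        exhaustive = exhaustive_jackstraw(Y, spec, B=200, seed=2)
        rho = stats.spearmanr(pooled, exhaustive).statistic
        assert rho > 0.9
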