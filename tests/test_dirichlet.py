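import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cultnet.dirichlet_stats import (
    clip_to_simplex_interior,
    dirichlet_loglik,
    fit_dirichlet,
    normalized_fst,
    outlier_test,
    region_test,
    _moment_init,
)


class TestFitDirichlet:
    def test_mle_consistency(self):
        P = np.random.default_rng(1).dirichlet([2, 5], size=2000)
        fit = fit_dirichlet(P)
        assert np.all(np.abs(fit.concentration - [2, 5]) / np.array([2, 5]) < 0.1)

    def test_boundary_rows_clipped(self):
        P = np.array([[1.0, 0.0], [0.6, 0.4], [0.3, 0.7], [0.0, 1.0], [0.5, 0.5]])
        fit = fit_dirichlet(P)
        assert np.all(np.isfinite(fit.concentration)) and (fit.concentration > 0).all()

    def test_degenerate_repeated_row_rejected(self):
        P = np.tile([0.4, 0.6], (8, 1))
        with pytest.raises((ValueError, RuntimeError)):
            fit_dirichlet(P)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            fit_dirichlet(np.array([[0.3, 0.7]]))

    def test_fitted_loglik_beats_moment_init(self):
        for seed in range(5):
            P = np.random.default_rng(seed).dirichlet([1, 3, 6], size=80)
            Pc = clip_to_simplex_interior(P)
            fit = fit_dirichlet(P)
            ll_init = dirichlet_loglik(Pc, _moment_init(Pc))
            assert fit.loglik >= ll_init - 1e-8


class TestRegionTest:
    def test_identical_samples_not_distinct(self):
        A = np.random.default_rng(2).dirichlet([3, 3, 3], size=40)
        res = region_test(A, A.copy())
        assert res.statistic == pytest.approx(0.0, abs=1e-6)
        assert res.p_value > 0.99
        assert res.df == 3

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(3)
        A = rng.dirichlet([4, 2], size=30)
        B = rng.dirichlet([2, 4], size=25)
        r1, r2 = region_test(A, B), region_test(B, A)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-9)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-9)

    def test_power_under_strong_separation(self):
        rej = 0
        for s in range(40):
            rng = np.random.default_rng(s)
            a = rng.dirichlet([10, 2], size=30)
            b = rng.dirichlet([2, 10], size=30)
            rej += region_test(a, b).p_value < 0.001
        assert rej >= 38

    def test_type_one_error_near_nominal(self):
        rej = 0
        N = 400
        for s in range(N):
            rng = np.random.default_rng(20_000 + s)
            a = rng.dirichlet([3, 3, 3], size=50)
            b = rng.dirichlet([3, 3, 3], size=50)
            rej += region_test(a, b).p_value < 0.05
        assert 0.02 <= rej / N <= 0.09

    def test_mismatched_k_rejected(self):
        with pytest.raises(ValueError):
            region_test(np.ones((5, 2)) / 2, np.ones((5, 3)) / 3)


def _membership_samples(seed, focal_from_ref, N=40, n_per=30, home_c=(1, 1, 20), ref_c=(20, 1, 1)):
    rng = np.random.default_rng(seed)
    ids = [f"h{i}" for i in range(n_per)] + [f"r{i}" for i in range(n_per)]
    region_of = {f"h{i}": "home" for i in range(n_per)}
    region_of.update({f"r{i}": "ref" for i in range(n_per)})
    samples = np.empty((N, 2 * n_per, 3))
    for s in range(N):
        samples[s, :n_per] = rng.dirichlet(home_c, n_per)
        samples[s, n_per:] = rng.dirichlet(ref_c, n_per)
        samples[s, 0] = rng.dirichlet(ref_c if focal_from_ref else home_c)
    return samples, ids, region_of


class TestOutlierTest:
    def test_identical_loglik_sets_not_flagged(self):
        # degenerate: home and reference identically distributed and the focal
        # society drawn from its home -> one-sided p should not be small
        samples, ids, region_of = _membership_samples(
            0, focal_from_ref=False, home_c=(3, 3, 3), ref_c=(3, 3, 3)
        )
        res = outlier_test(samples, ids, "h0", "home", "ref", region_of)
        assert res.p_value >= 0.2

    def test_power_on_injected_outlier(self):
        flags = 0
        for s in range(20):
            samples, ids, region_of = _membership_samples(s, focal_from_ref=True)
            flags += outlier_test(samples, ids, "h0", "home", "ref", region_of).significant
        assert flags >= 18

    def test_false_positive_rate_low(self):
        flags = 0
        for s in range(20):
            samples, ids, region_of = _membership_samples(500 + s, focal_from_ref=False)
            flags += outlier_test(samples, ids, "h0", "home", "ref", region_of).significant
        assert flags <= 2

    def test_row_order_within_regions_irrelevant(self):
        samples, ids, region_of = _membership_samples(9, True)
        res1 = outlier_test(samples, ids, "h0", "home", "ref", region_of)
        # shuffle the non-focal rows consistently across samples
        perm = np.concatenate([[0], np.random.default_rng(0).permutation(np.arange(1, 60))])
        ids2 = [ids[i] for i in perm]
        res2 = outlier_test(samples[:, perm], ids2, "h0", "home", "ref", region_of)
        assert res1.p_value == pytest.approx(res2.p_value, rel=1e-9)

    def test_small_region_rejected(self):
        samples, ids, region_of = _membership_samples(1, True, n_per=3)
        with pytest.raises(ValueError, match="k\\+1|fewer"):
            outlier_test(samples, ids, "h0", "home", "ref", region_of)


class TestNormalizedFst:
    def test_identical_rows_zero(self):
        assert normalized_fst(np.tile([0.2, 0.3, 0.5], (10, 1))) == pytest.approx(0.0, abs=1e-12)

    def test_one_hot_rows_one(self):
        P = np.eye(3)[np.arange(12) % 3]
        assert normalized_fst(P) == pytest.approx(1.0)

    def test_decreasing_in_concentration(self):
        vals = [
            normalized_fst(np.random.default_rng(5).dirichlet([c] * 3, size=300))
            for c in (1, 5, 25)
        ]
        assert vals[0] > vals[1] > vals[2]

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_column_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.dirichlet([2, 1, 3], size=20)
        perm = rng.permutation(3)
        assert normalized_fst(P) == pytest.approx(normalized_fst(P[:, perm]), rel=1e-9)
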