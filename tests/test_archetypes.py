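import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cultnet.archetypes import (
    fit_archetypes,
    scan_candidates,
    select_from_metrics,
    select_num_kmeans_clusters,
    simplex_project_rows,
)


class TestSimplexProjection:
    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=6),
            min_size=1,
            max_size=8,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1)
    )
    def test_projects_onto_simplex(self, rows):
        M = np.array(rows, dtype=float)
        P = simplex_project_rows(M)
        assert (P >= 0).all()
        assert np.abs(P.sum(axis=1) - 1).max() < 1e-9
        # projection is idempotent
        assert np.abs(simplex_project_rows(P) - P).max() < 1e-9


class TestFitArchetypes:
    def test_vertices_are_their_own_archetypes(self):
        rng = np.random.default_rng(3)
        P = rng.normal(size=(3, 8))
        X = P[rng.integers(0, 3, 30)]
        am = fit_archetypes(X, 3, n_restarts=3, seed=1)
        assert am.sse < 1e-10
        assert np.allclose(am.alpha.max(axis=1), 1.0, atol=1e-5)
        # constraints
        assert np.abs(am.alpha.sum(axis=1) - 1).max() < 1e-8
        assert np.abs(am.beta.sum(axis=0) - 1).max() < 1e-8
        assert (am.alpha >= -1e-12).all() and (am.beta >= -1e-12).all()
        assert np.abs(am.S - X.T @ am.beta).max() < 1e-8

    def test_k1_matches_grid_search_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(5, 3))
        am = fit_archetypes(X, 1, n_restarts=2, seed=3, max_iter=5000)
        assert np.allclose(am.alpha, 1.0)
        best = np.inf
        g = np.linspace(0, 1, 21)
        for b in itertools.product(g, repeat=4):
            if sum(b) > 1 + 1e-12:
                continue
            bb = np.array(list(b) + [1 - sum(b)])
            z = bb @ X
            best = min(best, float(np.sum((X - np.outer(np.ones(5), z)) ** 2)))
        assert am.sse <= best + 1e-6

    def test_k_equals_n_reaches_zero_sse(self):
        X = np.random.default_rng(1).normal(size=(5, 4))
        am = fit_archetypes(X, 5, n_restarts=3, seed=2, max_iter=4000)
        assert am.sse < 1e-6

    def test_sse_history_monotone_and_explained_variance_bounds(self):
        X = np.random.default_rng(2).normal(size=(30, 6))
        am = fit_archetypes(X, 3, n_restarts=1, seed=4)
        h = np.array(am.sse_history)
        assert (np.diff(h) <= 1e-12).all()
        assert 0.0 <= am.explained_variance <= 1.0
        assert am.explained_variance == pytest.approx(1 - am.sse / np.sum(X**2))

    def test_row_permutation_equivariance(self):
        X = np.random.default_rng(3).normal(size=(25, 5))
        perm = np.random.default_rng(0).permutation(25)
        am = fit_archetypes(X, 3, n_restarts=2, seed=9)
        amp = fit_archetypes(X[perm], 3, n_restarts=2, seed=9)
        assert amp.sse == pytest.approx(am.sse, rel=1e-4)

    def test_recovers_generator_profiles(self, clean_low_noise_X):
        X, tm, truth, _ = clean_low_noise_X
        am = fit_archetypes(X, 3, n_restarts=5, seed=0)
        true_S = truth.true_profiles * truth.col_scale[:, None] + truth.col_offset[:, None]
        col_means = np.nanmean(np.where(tm.mask, tm.values, np.nan), axis=0)
        true_S_c = true_S - col_means[:, None]
        best = -1.0
        for perm in itertools.permutations(range(3)):
            rs = min(
                np.corrcoef(am.S[:, i], true_S_c[:, perm[i]])[0, 1] for i in range(3)
            )
            best = max(best, rs)
        assert best > 0.95

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            fit_archetypes(np.ones((3, 2)), 4, seed=0)

    def test_incomplete_matrix_rejected(self):
        X = np.ones((4, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            fit_archetypes(X, 2, seed=0)


class TestClusterSelection:
    def test_scan_ranges(self):
        assert scan_candidates(2) == [2, 3, 4]
        assert scan_candidates(3) == [2, 3, 4, 5]
        assert scan_candidates(5) == [3, 4, 5, 6, 7]

    def _metrics(self, sil, vrc, dbi):
        return pd.DataFrame(
            {"silhouette": sil, "variance_ratio": vrc, "davies_bouldin": dbi},
            index=pd.Index([2, 3, 4], name="n_clusters"),
        )

    def test_two_metric_majority_wins(self):
        m = self._metrics([0.1, 0.9, 0.2], [10, 90, 20], [0.5, 0.9, 0.1])
        selected, _ = select_from_metrics(m, k=2)
        assert selected == 3

    def test_three_way_disagreement_falls_back_to_k(self):
        m = self._metrics([0.9, 0.1, 0.2], [10, 90, 20], [0.9, 0.5, 0.1])
        selected, _ = select_from_metrics(m, k=2)
        assert selected == 2

    def test_selection_on_separated_clusters(self):
        rng = np.random.default_rng(0)
        centers = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        alpha = np.vstack([c + 0.03 * rng.normal(size=(20, 3)) for c in centers])
        alpha = np.abs(alpha)
        alpha /= alpha.sum(axis=1, keepdims=True)
        am = fit_archetypes(alpha, 3, n_restarts=2, seed=1)
        sel = select_num_kmeans_clusters(am, seed=2)
        assert sel.n_clusters == 3
        assert set(np.unique(sel.labels)) == set(range(3))
        assert list(sel.metrics.columns) == ["silhouette", "variance_ratio", "davies_bouldin"]
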