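"""Connectivity estimators against independent oracles and their invariants."""

import numpy as np
import pytest

from neurofcn.fcn import (DirectedCausality, RoiTimeSeries,
                          SrConfig, build_pattern_graphs, canonicalize,
                          granger_fcn, pearson_fcn, sparse_representation_fcn,
                          sr_objective, symmetrize_gcm)
from conftest import random_time_series


def _ts(values, subject_id="s"):
    values = np.asarray(values, dtype=float)
    return RoiTimeSeries(values=values,
                         roi_labels=[f"R{i}" for i in range(values.shape[1])],
                         subject_id=subject_id)


def brute_force_correlation(x):
    """Textbook centered dot-product correlation, coded independently."""
    t, n = x.shape
    w = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            a = x[:, i] - x[:, i].mean()
            b = x[:, j] - x[:, j].mean()
            w[i, j] = (a @ b) / np.sqrt((a @ a) * (b @ b))
    return w


class TestPearson:
    def test_perfect_linear_dependence(self, rng):
        base = rng.standard_normal(40)
        x = np.column_stack([base, 2 * base + 3, 5 * base - 1])
        w = pearson_fcn(_ts(x)).weights
        assert np.allclose(w, 1.0)

    def test_anticorrelation(self, rng):
        base = rng.standard_normal(40)
        w = pearson_fcn(_ts(np.column_stack([base, -base]))).weights
        assert w[0, 1] == pytest.approx(-1.0)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_textbook_formula(self, rng, trial):
        x = rng.standard_normal((50, 8))
        w = pearson_fcn(_ts(x)).weights
        assert np.max(np.abs(w - brute_force_correlation(x))) < 1e-10

    def test_zero_variance_roi_zeroed_with_warning(self, rng):
        x = rng.standard_normal((30, 4))
        x[:, 2] = 7.0
        with pytest.warns(UserWarning, match="R2"):
            w = pearson_fcn(_ts(x)).weights
        assert np.all(w[2, [0, 1, 3]] == 0) and np.all(w[[0, 1, 3], 2] == 0)
        assert w[2, 2] == 1.0

    def test_symmetric_unit_diagonal(self, rng):
        w = pearson_fcn(random_time_series(rng)).weights
        assert np.allclose(w, w.T)
        assert np.allclose(np.diag(w), 1.0)
        assert np.all(np.abs(w) <= 1.0)


class TestSparseRepresentation:
    def test_huge_lambda_gives_zero_matrix(self, rng):
        ts = random_time_series(rng, t=60, n=5)
        scale = 1e6 * np.abs(ts.values.T @ ts.values).max()
        cm = sparse_representation_fcn(ts, SrConfig(lam=scale))
        assert np.all(cm.weights == 0)

    def test_lambda_zero_matches_least_squares(self, rng):
        ts = random_time_series(rng, t=80, n=6)
        cm = sparse_representation_fcn(ts, SrConfig(lam=0.0, max_iterations=3000,
                                                    tolerance=1e-12))
        x = ts.values
        for i in range(6):
            others = [j for j in range(6) if j != i]
            design = x[:, others]
            # normal-equations oracle
            w_ols = np.linalg.solve(design.T @ design, design.T @ x[:, i])
            assert np.max(np.abs(cm.weights[i, others] - w_ols)) < 1e-6

    def test_objective_beats_random_search(self, rng):
        ts = random_time_series(rng, t=40, n=3)
        lam = 0.5
        cm = sparse_representation_fcn(ts, SrConfig(lam=lam))
        x = ts.values
        for i in range(3):
            others = [j for j in range(3) if j != i]
            design = x[:, others]
            best = sr_objective(x[:, i], design, cm.weights[i, others], lam)
            cands = rng.uniform(-2, 2, size=(10_000, 2))
            vals = ((x[:, i][None, :] - cands @ design.T) ** 2).sum(axis=1) \
                + lam * np.abs(cands).sum(axis=1)
            assert best <= vals.min() + 1e-9

    def test_matches_sklearn_lasso(self, rng):
        # independent solver route: sklearn minimizes (1/2t)||r||^2 + a||w||_1
        from sklearn.linear_model import Lasso
        ts = random_time_series(rng, t=60, n=6)
        lam = 2.0
        cm = sparse_representation_fcn(ts, SrConfig(lam=lam, max_iterations=5000,
                                                    tolerance=1e-12))
        x = ts.values
        t = x.shape[0]
        for i in range(6):
            others = [j for j in range(6) if j != i]
            ref = Lasso(alpha=lam / (2 * t), fit_intercept=False,
                        max_iter=50_000, tol=1e-12).fit(x[:, others], x[:, i])
            assert np.max(np.abs(cm.weights[i, others] - ref.coef_)) < 1e-5

    def test_l1_mass_non_increasing_in_lambda(self, rng):
        ts = random_time_series(rng, t=60, n=6)
        masses = []
        for lam in [0.0, 0.5, 2.0, 10.0, 50.0]:
            cm = sparse_representation_fcn(ts, SrConfig(lam=lam))
            masses.append(np.abs(cm.weights).sum())
        assert all(b <= a + 1e-9 for a, b in zip(masses, masses[1:]))

    def test_self_weight_zero_and_t_less_than_n(self, rng):
        ts = random_time_series(rng, t=8, n=12)  # underdetermined regime
        cm = sparse_representation_fcn(ts, SrConfig(lam=1.0))
        assert np.all(np.diag(cm.weights) == 0)
        assert np.all(np.isfinite(cm.weights))

    def test_nonconvergence_flag_not_exception(self, rng):
        ts = random_time_series(rng, t=60, n=6)
        with pytest.warns(UserWarning, match="did not converge"):
            cm = sparse_representation_fcn(
                ts, SrConfig(lam=0.0, max_iterations=1, tolerance=1e-15))
        assert cm.converged is False


class TestGranger:
    def test_white_noise_below_permutation_null(self, rng):
        t = 500
        x = rng.standard_normal(t)
        y = rng.standard_normal(t)
        dc = granger_fcn(_ts(np.column_stack([x, y])), lag_order=1)
        observed = dc.strengths[0, 1]
        null = []
        for k in range(200):
            shift = int(rng.integers(1, t))
            xs = np.roll(x, shift)
            null.append(granger_fcn(_ts(np.column_stack([xs, y])),
                                    lag_order=1).strengths[0, 1])
        assert observed < np.quantile(null, 0.99)

    def test_constant_target_degenerate(self, rng):
        x = rng.standard_normal(50)
        y = np.full(50, 3.0)
        with pytest.warns(UserWarning, match="constant target"):
            dc = granger_fcn(_ts(np.column_stack([x, y])), lag_order=1)
        assert dc.strengths[0, 1] == 0.0

    def test_matches_statsmodels_ols_rss_ratio(self, rng):
        """Independent route: both regressions fitted with statsmodels OLS."""
        import statsmodels.api as sm
        t, lag = 120, 2
        x = rng.standard_normal((t, 2))
        x[2:, 1] += 0.4 * x[1:-1, 0]
        dc = granger_fcn(_ts(x), lag_order=lag)
        y = x[lag:, 1]
        own = np.column_stack([x[lag - k - 1:t - k - 1, 1] for k in range(lag)])
        other = np.column_stack([x[lag - k - 1:t - k - 1, 0] for k in range(lag)])
        rss_r = sm.OLS(y, sm.add_constant(own)).fit().ssr
        rss_u = sm.OLS(y, sm.add_constant(np.column_stack([own, other]))).fit().ssr
        assert dc.strengths[0, 1] == pytest.approx(np.log(rss_r / rss_u),
                                                   rel=1e-5)

    def test_non_negative_and_zero_diagonal(self, rng):
        dc = granger_fcn(random_time_series(rng, t=120, n=5), lag_order=2)
        assert np.all(dc.strengths >= 0)
        assert np.all(np.diag(dc.strengths) == 0)

    def test_too_short_series_rejected(self, rng):
        with pytest.raises(ValueError, match="lag_order"):
            granger_fcn(random_time_series(rng, t=6, n=3), lag_order=2)


class TestSymmetrizeGcm:
    def test_direct_formula(self):
        g = np.zeros((2, 2))
        g[0, 1], g[1, 0] = 0.3, 0.1
        a = symmetrize_gcm(DirectedCausality(strengths=g, lag_order=1)).weights
        assert a[0, 1] == pytest.approx(0.4)
        assert a[1, 0] == pytest.approx(0.4)

    def test_zero_strengths_give_zero_matrix(self):
        a = symmetrize_gcm(DirectedCausality(strengths=np.zeros((4, 4)),
                                             lag_order=1)).weights
        assert np.all(a == 0)

    def test_elementwise_oracle(self, rng):
        g = np.abs(rng.standard_normal((6, 6)))
        np.fill_diagonal(g, 0.0)
        a = symmetrize_gcm(DirectedCausality(strengths=g, lag_order=1)).weights
        for i in range(6):
            for j in range(6):
                expect = 0.0 if i == j else abs(g[i, j] + g[j, i])
                assert a[i, j] == pytest.approx(expect)
        assert np.allclose(a, a.T)


class TestCanonicalize:
    def test_absolute_value_and_rescale(self, rng):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = -0.8
        w[1, 2] = w[2, 1] = 0.4
        np.fill_diagonal(w, 1.0)
        cm = pearson_fcn(random_time_series(rng, n=3))
        cm.weights = w
        canon = canonicalize(cm, threshold=0.1)
        assert canon.weights[0, 1] == pytest.approx(1.0)  # 0.8 / max(0.8)
        assert canon.weights[1, 2] == pytest.approx(0.5)

    def test_threshold_zero_keeps_all_edges(self, rng):
        cm = pearson_fcn(random_time_series(rng, n=6))
        canon = canonicalize(cm, threshold=0.0)
        off = ~np.eye(6, dtype=bool)
        assert np.count_nonzero(canon.weights[off]) == np.count_nonzero(cm.weights[off])

    def test_edge_count_matches_counting_oracle(self, rng):
        cm = pearson_fcn(random_time_series(rng, n=8))
        theta = 0.2
        canon = canonicalize(cm, threshold=theta)
        w = np.abs((cm.weights + cm.weights.T) / 2)
        np.fill_diagonal(w, 0)
        w = w / w.max()
        assert np.count_nonzero(canon.weights) == np.count_nonzero(w >= theta)

    def test_idempotent(self, rng):
        cm = pearson_fcn(random_time_series(rng, n=7))
        once = canonicalize(cm, threshold=0.2)
        twice = canonicalize(once, threshold=0.2)
        assert np.array_equal(once.weights, twice.weights)

    def test_threshold_one_rejected(self, rng):
        with pytest.raises(ValueError, match="threshold"):
            canonicalize(pearson_fcn(random_time_series(rng)), threshold=1.0)

    def test_emptying_threshold_warns(self):
        from neurofcn.fcn import ConnectivityMatrix
        cm = ConnectivityMatrix(weights=np.zeros((4, 4)), pattern="GCM",
                                roi_labels=list("abcd"))
        with pytest.warns(UserWarning, match="empty"):
            canon = canonicalize(cm, threshold=0.5)
        assert canon.weights.max() == 0


class TestPermutationConsistency:
    """estimator(P·ts) = P·estimator(ts)·Pᵀ for all three patterns."""

    @pytest.mark.parametrize("pattern", ["PC", "SR", "GCM"])
    def test_roi_permutation(self, rng, pattern):
        ts = random_time_series(rng, t=80, n=6)
        perm = rng.permutation(6)
        permuted = RoiTimeSeries(values=ts.values[:, perm],
                                 roi_labels=[ts.roi_labels[p] for p in perm])
        kw = dict(sr_config=SrConfig(lam=0.5, max_iterations=3000,
                                     tolerance=1e-12), lag_order=1,
                  thresholds={p: 0.0 for p in ("PC", "SR", "GCM")})
        g0 = build_pattern_graphs(ts, (pattern,), **kw)[0].adjacency.weights
        g1 = build_pattern_graphs(permuted, (pattern,), **kw)[0].adjacency.weights
        assert np.max(np.abs(g1 - g0[np.ix_(perm, perm)])) < 1e-6


class TestBuildPatternGraphs:
    def test_single_pattern_shape(self, small_cohort):
        graphs = build_pattern_graphs(small_cohort.subjects[0], ("PC",))
        assert len(graphs) == 1
        assert graphs[0].node_features.shape == (10, 10)

    def test_three_patterns_pairwise_distinct(self, small_cohort):
        graphs = build_pattern_graphs(small_cohort.subjects[0])
        assert [g.pattern for g in graphs] == ["PC", "SR", "GCM"]
        for i in range(3):
            for j in range(i + 1, 3):
                d = np.linalg.norm(graphs[i].adjacency.weights
                                   - graphs[j].adjacency.weights)
                assert d > 0

    def test_empty_pattern_set_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            build_pattern_graphs(small_cohort.subjects[0], ())
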