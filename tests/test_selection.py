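"""Group-LASSO solver, baseline selectors and network statistics."""

import numpy as np
import pytest
from scipy import stats
from sklearn.linear_model import Lasso

from modselect import (
    GroupLasso,
    ModulePartition,
    SelectionResult,
    build_design,
    global_clustering,
    group_lasso_fit,
    lasso_select,
    node_statistics,
    select_edges,
    signed_degree,
    ttest_select,
)
from conftest import random_signed_network


def planted_design(rng, n=80, m=10, K=2, signal_group=0, shift=1.0):
    """Grouped design from random networks with a mean shift on one module's
    within edges for the positive class."""
    labels = np.arange(m) % K
    P = ModulePartition(labels, K)
    y = np.repeat([1.0, -1.0], n // 2)
    Ws = []
    members = P.members(signal_group)
    for yi in y:
        W = random_signed_network(rng, m) * 0.3
        if yi > 0:
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    i, j = members[a], members[b]
                    W[i, j] += shift
                    W[j, i] += shift
        Ws.append(W)
    return build_design(Ws, P), y


class TestGroupLassoSolver:
    def test_vanishing_penalty_recovers_least_squares(self, rng):
        X = rng.standard_normal((60, 10))
        y = np.sign(rng.standard_normal(60))
        model = GroupLasso(y, X, groups=np.array([0] * 5 + [1] * 5))
        res = model.fit(1e-8, tol=1e-16, max_iter=50000)
        w_ls = np.linalg.lstsq(X, y - y.mean(), rcond=None)[0]
        assert np.linalg.norm(res.params - w_ls) < 1e-4

    def test_zero_solution_at_lambda_max(self, rng):
        X = rng.standard_normal((40, 30))
        y = np.sign(rng.standard_normal(40))
        model = GroupLasso(y, X, groups=np.arange(30) // 3)
        res = model.fit(model.lambda_max)
        assert np.all(res.params == 0)
        res2 = model.fit(0.95 * model.lambda_max)
        assert np.any(res2.params != 0)

    def test_kkt_and_monotone_objective(self, rng):
        D, y = planted_design(rng)
        sel = group_lasso_fit(D, y, lam=0.3 * GroupLasso(y, D).lambda_max)
        r = sel.results
        assert np.all(np.diff(r.objective_trace) <= 1e-12)
        scale = np.abs(D.X.T @ (y - y.mean())).max()
        assert r.kkt_residual < 1e-4 * scale

    def test_group_sparsity_all_or_none(self, rng):
        D, y = planted_design(rng)
        model = GroupLasso(y, D)
        res = model.fit(0.5 * model.lambda_max)
        for g in range(D.n_groups):
            block = res.params[D.group_index == g]
            norm = np.linalg.norm(block)
            assert norm <= 1e-8 or np.all(np.abs(block) > 0)

    def test_selected_groups_nonincreasing_along_path(self, rng):
        D, y = planted_design(rng)
        model = GroupLasso(y, D)
        lmax = model.lambda_max
        counts = [
            len(model.fit(f * lmax).selected_groups)
            for f in (0.01, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
        ]
        assert np.all(np.diff(counts) <= 0)

    def test_singleton_groups_match_coordinate_descent_oracle(self, rng):
        for _ in range(5):
            X = rng.standard_normal((50, 100))
            y = np.sign(rng.standard_normal(50))
            model = GroupLasso(y, X)
            lam = 0.3 * model.lambda_max
            res = model.fit(lam, tol=1e-14, max_iter=50000)
            oracle = Lasso(alpha=lam / 50, fit_intercept=False, tol=1e-14,
                           max_iter=500000).fit(X, y - y.mean())
            assert np.abs(res.params - oracle.coef_).max() < 1e-5

    def test_planted_groups_recovered(self, rng):
        D, y = planted_design(rng, n=120, m=12, K=3, shift=1.2)
        model = GroupLasso(y, D)
        res = model.fit(0.5 * model.lambda_max)
        assert list(res.selected_groups) == [0]

    def test_nan_rejected_and_summary_prints(self, rng):
        X = rng.standard_normal((10, 4))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            GroupLasso(np.ones(10), X)
        D, y = planted_design(rng)
        model = GroupLasso(y, D)
        text = model.fit(0.5 * model.lambda_max).summary()
        assert "lambda" in text and "selected" in text


class TestSelectEdges:
    def test_zero_empty_and_consistency(self, rng):
        D, y = planted_design(rng)
        model = GroupLasso(y, D)
        empty = SelectionResult(model.fit(model.lambda_max), D)
        assert select_edges(empty) == set()
        sel = SelectionResult(model.fit(0.4 * model.lambda_max), D)
        edges = select_edges(sel)
        assert len(edges) == len(sel.selected)


class TestTTestSelect:
    def test_type_one_calibration(self, rng):
        # with exchangeable classes the selected fraction tracks alpha
        alpha, reps, p = 0.1, 400, 40
        hits = 0
        for _ in range(reps):
            F = rng.standard_normal((40, p))
            y = np.repeat([1.0, -1.0], 20)
            hits += len(ttest_select(F, y, alpha))
        frac = hits / (reps * p)
        se = np.sqrt(alpha * (1 - alpha) / (reps * p))
        assert abs(frac - alpha) < 4 * se

    def test_power_on_large_shift(self, rng):
        F = rng.standard_normal((100, 5))
        y = np.repeat([1.0, -1.0], 50)
        F[y > 0, 2] += 3.0  # 3-SD mean shift: power ~ 1
        assert 2 in ttest_select(F, y, alpha=0.01)

    def test_alpha_one_selects_all_valid(self, rng):
        F = rng.standard_normal((20, 6))
        y = np.repeat([1.0, -1.0], 10)
        assert len(ttest_select(F, y, alpha=1.0)) == 6

    def test_rejects_single_class(self, rng):
        with pytest.raises(ValueError):
            ttest_select(rng.standard_normal((10, 3)), np.ones(10), 0.05)


class TestLassoSelect:
    def test_zero_bound_and_planted_signal(self, rng):
        X = rng.standard_normal((60, 40))
        y = np.repeat([1.0, -1.0], 30)
        X[y > 0, 7] += 2.0
        yc = y - y.mean()
        lam_max = np.abs(X.T @ yc).max()
        assert len(lasso_select(X, y, lam_max * 1.001)) == 0
        sel = lasso_select(X, y, 0.5 * lam_max)
        assert 7 in sel


class TestNodeStatistics:
    def test_positive_triangle_lcc(self):
        W = np.ones((3, 3)) - np.eye(3)
        assert np.allclose(node_statistics(W, "LCC"), 1.0)
        assert global_clustering(W) == pytest.approx(1.0)

    def test_star_betweenness(self):
        W = np.zeros((5, 5))
        W[0, 1:] = W[1:, 0] = 0.7
        bc = node_statistics(W, "BC")
        assert bc[0] == max(bc)
        assert np.allclose(bc[1:], 0.0)

    def test_dc_equals_signed_degree(self, rng):
        W = random_signed_network(rng, 8)
        assert np.allclose(node_statistics(W, "DC"), signed_degree(W))

    def test_ec_matches_power_iteration(self, rng):
        W = random_signed_network(rng, 8)
        A = np.abs(W)
        v = np.ones(8)
        for _ in range(500):
            v = A @ v
            v /= np.linalg.norm(v)
        ec = node_statistics(W, "EC")
        ec = ec / np.linalg.norm(ec)
        assert np.allclose(np.abs(ec), np.abs(v), atol=1e-6)

    def test_unknown_tag_rejected(self, rng):
        with pytest.raises(ValueError):
            node_statistics(random_signed_network(rng, 4), "XX")
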