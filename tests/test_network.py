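"""Graphical lasso, EBIC selection, strength centrality, layout.

The in-house block-coordinate glasso is checked two independent ways:
against a brute-force penalized-likelihood optimizer (direct numerical
maximization over positive-definite matrices via a split-variable
parameterization) and against scikit-learn's implementation.
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from trailmetrics.errors import ValidationError
from trailmetrics.network import (
    NetworkConfig,
    build_prevalence_matrix,
    correlation,
    ebic_score,
    fr_layout,
    graphical_lasso,
    lambda_path,
    select_network,
    strength,
)
from trailmetrics.synthetic import chain_precision, synth_indicator_data
from trailmetrics.travel_time import Duration


def random_correlation(p, seed, n=50):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    return np.corrcoef(X, rowvar=False)


def brute_force_glasso_3x3(S, lam):
    """Direct maximization of log det Θ − tr(SΘ) − λ·Σ_{i≠j}|θ_ij|.

    Off-diagonals are split θ = a − b with a, b ≥ 0 so the L1 term is
    smooth in the optimization variables; positive definiteness is
    enforced by an infinite barrier.
    """

    def unpack(x):
        d = x[:3]
        off = x[3:9:2] - x[4:9:2]
        theta = np.diag(d).astype(float)
        theta[0, 1] = theta[1, 0] = off[0]
        theta[0, 2] = theta[2, 0] = off[1]
        theta[1, 2] = theta[2, 1] = off[2]
        return theta

    def neg_objective(x):
        theta = unpack(x)
        sign, logdet = np.linalg.slogdet(theta)
        if sign <= 0:
            return 1e10
        penalty = lam * 2 * np.sum(x[3:9:2] + x[4:9:2])
        return -(logdet - float(np.sum(S * theta))) + penalty

    theta0 = np.linalg.inv(S + 0.05 * np.eye(3))
    x0 = np.array(
        [
            theta0[0, 0], theta0[1, 1], theta0[2, 2],
            max(theta0[0, 1], 0), max(-theta0[0, 1], 0),
            max(theta0[0, 2], 0), max(-theta0[0, 2], 0),
            max(theta0[1, 2], 0), max(-theta0[1, 2], 0),
        ]
    )
    bounds = [(1e-6, None)] * 3 + [(0, None)] * 6
    res = minimize(neg_objective, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
    return unpack(res.x)


class TestGraphicalLasso:
    def test_identity_input_gives_empty_network(self):
        for lam in (0.0, 0.1, 1.0):
            theta, w = graphical_lasso(np.eye(4), lam)
            assert np.allclose(theta, np.eye(4))
            assert np.all(w == 0)

    def test_full_shrinkage_at_large_lambda(self):
        S = random_correlation(5, seed=1)
        lam = np.abs(S - np.diag(np.diag(S))).max()
        _, w = graphical_lasso(S, lam * 1.0001)
        assert np.all(w == 0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle_3x3(self, seed):
        S = random_correlation(3, seed=seed)
        theta, _ = graphical_lasso(S, 0.1)
        oracle = brute_force_glasso_3x3(S, 0.1)
        assert np.allclose(theta, oracle, atol=1e-4)

    @pytest.mark.parametrize("seed,lam", [(7, 0.05), (8, 0.2), (9, 0.1)])
    def test_matches_sklearn(self, seed, lam):
        from sklearn.covariance import graphical_lasso as sk_glasso

        S = random_correlation(5, seed=seed)
        theta, _ = graphical_lasso(S, lam)
        _, sk_theta = sk_glasso(S, alpha=lam, tol=1e-8, max_iter=500)
        assert np.allclose(theta, sk_theta, atol=1e-3)

    def test_partial_correlation_properties(self):
        S = random_correlation(6, seed=5)
        theta, w = graphical_lasso(S, 0.05)
        assert np.allclose(w, w.T)
        assert np.all(np.diag(w) == 0)
        assert np.all(np.abs(w) < 1)
        # theta positive definite
        assert np.linalg.eigvalsh(theta).min() > 0

    def test_edge_count_non_increasing_in_lambda(self):
        for seed in range(3):
            S = random_correlation(6, seed=100 + seed)
            counts = []
            for lam in lambda_path(S, NetworkConfig(n_lambda=20)):
                _, w = graphical_lasso(S, float(lam))
                counts.append(int(np.count_nonzero(np.triu(w, k=1))))
            assert counts == sorted(counts)  # path runs from large to small lambda

    def test_asymmetric_input_rejected(self):
        S = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValidationError):
            graphical_lasso(S, 0.1)


class TestEbic:
    def test_empty_network_reduces_to_likelihood_term(self):
        S = np.eye(3)
        theta = np.eye(3)
        n = 40
        score = ebic_score(theta, S, n=n, n_edges=0, gamma=0.5, p=3)
        sign, logdet = np.linalg.slogdet(theta)
        assert score == pytest.approx(-n * (logdet - np.trace(S @ theta)))

    def test_gamma_zero_is_plain_bic_penalty(self):
        S = random_correlation(4, seed=2)
        theta = np.linalg.inv(S + 0.1 * np.eye(4))
        base = ebic_score(theta, S, n=30, n_edges=0, gamma=0.0, p=4)
        with_edges = ebic_score(theta, S, n=30, n_edges=3, gamma=0.0, p=4)
        assert with_edges - base == pytest.approx(3 * math.log(30))

    def test_hand_computed_2x2(self):
        S = np.array([[1.0, 0.4], [0.4, 1.0]])
        theta = np.array([[1.2, -0.3], [-0.3, 1.1]])
        n, gamma, p, E = 50, 0.5, 2, 1
        expected = (
            -n * (math.log(1.2 * 1.1 - 0.09) - (1.2 + 1.1 + 2 * 0.4 * -0.3))
            + E * math.log(n)
            + 4 * E * gamma * math.log(p)
        )
        assert ebic_score(theta, S, n, E, gamma, p) == pytest.approx(expected)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValidationError):
            ebic_score(np.eye(2), np.eye(2), n=0, n_edges=0, gamma=0.5, p=2)


class TestSelectNetwork:
    def test_identity_selects_empty_network(self):
        model = select_network(np.eye(7), n=100)
        assert model.n_edges == 0

    def test_small_sample_warns_but_runs(self):
        S = random_correlation(7, seed=3, n=3)
        with pytest.warns(UserWarning):
            model = select_network(S, n=3)
        assert np.isfinite(model.ebic)

    def test_recovery_degrades_with_sample_size(self):
        theta = chain_precision(7, 0.3)
        true_edges = {(i, i + 1) for i in range(6)}

        def mean_tp(n, seeds=5):
            tp = 0
            for seed in range(seeds):
                X = synth_indicator_data(theta, n=n, seed=500 + seed)
                S = correlation(X)
                if n < 7:
                    with pytest.warns(UserWarning):
                        m = select_network(S, n=n)
                else:
                    m = select_network(S, n=n)
                sel = {
                    (i, j)
                    for i in range(7)
                    for j in range(i + 1, 7)
                    if m.weights[i, j] != 0
                }
                tp += len(sel & true_edges)
            return tp / seeds

        assert mean_tp(200) >= mean_tp(20) >= mean_tp(5)


class TestStrength:
    def test_direct_sum(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[0, 2] = W[2, 0] = -0.2
        r = strength(W, standardize=False)
        assert r.raw == pytest.approx([0.7, 0.5, 0.2])

    def test_empty_network_zero_strength(self):
        r = strength(np.zeros((4, 4)), standardize=True)
        assert np.all(r.raw == 0)
        assert np.all(r.standardized == 0)

    def test_standardized_sums_to_zero(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(6, 6))
        W = (A + A.T) / 2
        np.fill_diagonal(W, 0)
        r = strength(W)
        assert abs(r.standardized.sum()) < 1e-12

    def test_single_node_standardization_undefined(self):
        with pytest.raises(ValidationError):
            strength(np.zeros((1, 1)), standardize=True)


class TestLayout:
    def test_single_node_at_origin(self):
        assert fr_layout(np.zeros((1, 1)))["V1"] == (0.0, 0.0)

    def test_deterministic_for_fixed_seed(self):
        S = random_correlation(5, seed=4)
        _, w = graphical_lasso(S, 0.05)
        assert fr_layout(w, seed=3) == fr_layout(w, seed=3)

    def test_connected_nodes_end_closer(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.9  # strongly tied pair; nodes 2,3 isolated
        pos = fr_layout(W, seed=0, iterations=100)

        def dist(a, b):
            (x1, y1), (x2, y2) = pos[a], pos[b]
            return math.hypot(x1 - x2, y1 - y2)

        assert dist("V1", "V2") < dist("V3", "V4")


class TestCorrelationAndMatrix:
    def test_identical_and_opposite_columns(self):
        X = pd.DataFrame({"a": [1.0, 2, 3], "b": [1.0, 2, 3], "c": [-1.0, -2, -3]})
        C = correlation(X)
        assert C.loc["a", "b"] == pytest.approx(1.0)
        assert C.loc["a", "c"] == pytest.approx(-1.0)

    def test_constant_columns_dropped_with_warning(self):
        X = pd.DataFrame({"a": [1.0, 2, 3], "k": [5.0, 5, 5]})
        with pytest.warns(UserWarning, match="constant"):
            C = correlation(X)
        assert list(C.columns) == ["a"]

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValidationError):
            correlation(pd.DataFrame({"a": [1.0]}))

    def test_empirical_correlation_close_to_truth(self):
        theta = chain_precision(4, 0.4)
        X = synth_indicator_data(theta, n=500, seed=9)
        truth = np.linalg.inv(theta)
        d = np.sqrt(np.diag(truth))
        truth_corr = truth / np.outer(d, d)
        emp = correlation(X).to_numpy()
        assert np.max(np.abs(emp - truth_corr)) < 0.1

    def test_prevalence_rows(self):
        results = {
            "SF": dict(es=11, cg=2, sg=3, td_km=1.7, bok_km=2.320,
                       tt=Duration.parse("58 min 40 s"), att_pct=29.9),
            "MVW": dict(es=7, cg=1, sg=2, td_km=4.0, bok_km=5.1,
                        tt=Duration.parse("1 h 35 min 30 s"),
                        att=Duration.parse("21 min 34 s")),
        }
        M = build_prevalence_matrix(results)
        sf = M.loc["SF"]
        assert sf["ES"] == pytest.approx(42.3, abs=0.05)
        assert sf["CG"] == pytest.approx(40.0)
        assert sf["SG"] == pytest.approx(50.0)
        assert (sf["TD"], sf["TT"]) == (100.0, 100.0)
        assert sf["BOK"] == pytest.approx(36.5, abs=0.05)
        assert sf["ATT"] == pytest.approx(29.9)
        # ATT computed from durations when no explicit percent is given
        assert M.loc["MVW", "ATT"] == pytest.approx(100 * (21 * 60 + 34) / (95 * 60 + 30))

    def test_missing_indicator_names_trail_and_variable(self):
        with pytest.raises(ValidationError, match="'SF'.*'td_km'"):
            build_prevalence_matrix({"SF": dict(es=1, cg=1, sg=1)})

    def test_all_zero_rubrics(self):
        results = {
            "A": dict(es=0, cg=0, sg=0, td_km=1.0, bok_km=1.0,
                      tt=Duration.parse("10 min"), att_pct=0.0),
            "B": dict(es=0, cg=0, sg=0, td_km=2.0, bok_km=2.0,
                      tt=Duration.parse("20 min"), att_pct=0.0),
        }
        M = build_prevalence_matrix(results)
        assert np.all(M[["ES", "CG", "SG", "BOK", "ATT"]].to_numpy() == 0)
        assert np.all(M[["TD", "TT"]].to_numpy() == 100.0)
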