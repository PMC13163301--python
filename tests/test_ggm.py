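"""Network estimation: EBIC criterion, graphical-lasso path (cross-checked
against the sklearn solver as an independent oracle), partial correlations,
and the residual/extended variants."""

import numpy as np
import pandas as pd
import pytest
from sklearn.covariance import graphical_lasso as sklearn_glasso

from distressnet.ggm import (
    ebic,
    extended_network,
    fit_ebicglasso,
    network_from_data,
    partial_correlations,
    residual_network,
)
from distressnet._glasso import glasso_path
from distressnet.synthetic import sample_latent_gaussian



class TestEbic:
    def test_gamma_zero_reduces_to_bic(self):
        assert ebic(-50.0, 7, 200, 10, 0.0) == pytest.approx(
            100.0 + 7 * np.log(200)
        )

    def test_zero_edges_is_twice_negative_loglik(self):
        assert ebic(-123.4, 0, 415, 16, 0.5) == pytest.approx(246.8)

    def test_closed_form(self):
        expected = 200.0 + 5 * np.log(415) + 10 * np.log(16)
        assert ebic(-100.0, 5, 415, 16, 0.5) == pytest.approx(expected)

    def test_negative_edge_count_raises(self):
        with pytest.raises(ValueError):
            ebic(-1.0, -1, 100, 5, 0.5)


class TestPartialCorrelations:
    def test_identity_precision_gives_zero_matrix(self):
        assert np.allclose(partial_correlations(np.eye(4)), 0.0)

    def test_two_by_two_closed_form(self):
        prec = np.array([[1.0, -0.5], [-0.5, 1.0]])
        assert partial_correlations(prec)[0, 1] == pytest.approx(0.5)

    def test_chain_conditional_independence(self, chain_correlation):
        # 1-3 are linked only through 2: their partial correlation vanishes
        omega = partial_correlations(np.linalg.inv(chain_correlation))
        assert omega[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_chain_matches_recursive_formula_oracle(self, chain_correlation):
        # independent oracle: first-order partial correlation formula
        r = chain_correlation
        expected_12 = (r[0, 1] - r[0, 2] * r[1, 2]) / np.sqrt(
            (1 - r[0, 2] ** 2) * (1 - r[1, 2] ** 2)
        )
        omega = partial_correlations(np.linalg.inv(r))
        assert omega[0, 1] == pytest.approx(expected_12, abs=1e-9)

    def test_nonpositive_diagonal_raises(self):
        with pytest.raises(ValueError):
            partial_correlations(np.array([[0.0, 0.1], [0.1, 1.0]]))


class TestGlassoSolver:
    @pytest.mark.parametrize("p,n,seed", [(6, 500, 0), (12, 800, 1)])
    def test_matches_sklearn_solver(self, p, n, seed):
        rng = np.random.default_rng(seed)
        target = 0.35 * np.ones((p, p)) + 0.65 * np.eye(p)
        A = rng.standard_normal((n, p)) @ np.linalg.cholesky(target).T
        S = np.corrcoef(A.T)
        lam_max = np.max(np.abs(S - np.eye(p)))
        alphas = np.geomspace(lam_max, 0.05 * lam_max, 15)
        ours, flags = glasso_path(S, alphas, 1e-7, 1000)
        assert flags.all()
        for i, a in enumerate(alphas):
            _, prec = sklearn_glasso(S, alpha=float(a), tol=1e-8, max_iter=3000)
            # compare on the partial-correlation scale
            diff = partial_correlations(ours[i]) - partial_correlations(prec)
            assert np.abs(diff).max() < 5e-3

    def test_edge_count_monotone_along_path(self, sixteen_node_truth):
        X = sample_latent_gaussian(sixteen_node_truth, 415, seed=2)
        S = np.corrcoef(X.to_numpy().T)
        lam_max = np.max(np.abs(S - np.eye(16)))
        alphas = np.geomspace(lam_max, 0.01 * lam_max, 50)
        Ks, _ = glasso_path(S, alphas)
        iu = np.triu_indices(16, 1)
        counts = [int(np.count_nonzero(K[iu])) for K in Ks]
        assert counts[0] == 0
        assert all(a <= b for a, b in zip(counts, counts[1:]))


class TestFitEbicglasso:
    def test_identity_correlation_gives_empty_network(self):
        net = fit_ebicglasso(np.eye(8), n=400)
        assert np.count_nonzero(net.weights) == 0

    def test_two_node_strong_edge_survives(self):
        corr = np.array([[1.0, 0.8], [0.8, 1.0]])
        net = fit_ebicglasso(corr, n=1000)
        assert net.weights[0, 1] > 0.5

    def test_unregularized_limit_matches_inversion_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((5000, 6)) @ np.linalg.cholesky(
            0.3 * np.ones((6, 6)) + 0.7 * np.eye(6)
        )
        S = np.corrcoef(X.T)
        net = fit_ebicglasso(S, n=5000, gamma=0.0, lambda_min_ratio=1e-4)
        oracle = partial_correlations(np.linalg.inv(S))
        # compare at the smallest penalty on the grid, not the selected one
        from distressnet._glasso import glasso_path

        lam_max = np.max(np.abs(S - np.eye(6)))
        Ks, _ = glasso_path(S, np.geomspace(lam_max, 1e-4 * lam_max, 100))
        assert np.abs(partial_correlations(Ks[-1]) - oracle).max() < 0.01

    def test_selected_lambda_is_on_grid(self, sixteen_node_truth):
        X = sample_latent_gaussian(sixteen_node_truth, 415, seed=4)
        net = network_from_data(X, gamma=0.5)
        assert net.lambda_selected in net.lambda_grid

    def test_invariants_of_weight_matrix(self, sixteen_node_truth):
        X = sample_latent_gaussian(sixteen_node_truth, 415, seed=5)
        net = network_from_data(X, gamma=0.5)
        w = net.weights
        assert np.allclose(w, w.T)
        assert np.all(np.diag(w) == 0)
        assert np.abs(w).max() <= 1

    def test_non_pd_input_raises(self):
        bad = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, -0.9], [0.9, -0.9, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            fit_ebicglasso(bad, n=100)


class TestRecovery:
    def test_sparse_truth_recovered_at_study_size(self, sixteen_node_truth):
        truth = sixteen_node_truth != 0
        iu = np.triu_indices(16, 1)
        sens, spec = [], []
        for seed in range(10):
            X = sample_latent_gaussian(sixteen_node_truth, 415, seed=seed)
            net = network_from_data(X, gamma=0.5)
            est = net.weights[iu] != 0
            sens.append((est & truth[iu]).sum() / truth[iu].sum())
            spec.append((~est & ~truth[iu]).sum() / (~truth[iu]).sum())
        assert np.mean(sens) >= 0.8
        assert np.mean(spec) >= 0.6

    def test_independent_data_selects_empty_graph(self):
        empties = 0
        for seed in range(10):
            X = pd.DataFrame(np.random.default_rng(seed).standard_normal((415, 16)))
            net = network_from_data(X, gamma=0.5)
            empties += int(np.count_nonzero(net.weights) == 0)
        assert empties >= 9


class TestResidualNetwork:
    def test_independent_covariates_change_little(self, sixteen_node_truth):
        X = sample_latent_gaussian(sixteen_node_truth, 2000, seed=6)
        rng = np.random.default_rng(7)
        cov = pd.DataFrame(
            {"D1": rng.integers(0, 4, 2000), "D2": rng.integers(0, 2, 2000)},
            index=X.index,
        )
        plain = network_from_data(X, gamma=0.5)
        resid = residual_network(X, cov, gamma=0.5)
        mad = np.abs(plain.weights - resid.weights).mean()
        assert mad < 0.05

    def test_constant_covariate_raises_collinearity(self, sixteen_node_truth):
        X = sample_latent_gaussian(sixteen_node_truth, 100, seed=8)
        cov = pd.DataFrame({"D1": np.zeros(100, dtype=int)}, index=X.index)
        # a constant covariate contributes no dummy column; identical to
        # intercept-only adjustment (centering)
        resid = residual_network(X, cov, gamma=0.5)
        plain = network_from_data(X, gamma=0.5)
        assert np.abs(resid.weights - plain.weights).max() < 1e-6

    def test_aliased_covariates_raise(self, sixteen_node_truth):
        X = sample_latent_gaussian(sixteen_node_truth, 100, seed=9)
        d = np.random.default_rng(0).integers(0, 2, 100)
        cov = pd.DataFrame({"D1": d, "D2": d}, index=X.index)
        with pytest.raises(ValueError, match="collinear"):
            residual_network(X, cov)


class TestExtendedNetwork:
    @pytest.mark.parametrize("n_ext,expected_nodes,expected_possible",
                             [(5, 21, 210), (12, 28, 378), (11, 27, 351)])
    def test_node_and_possible_edge_counts(self, sixteen_node_truth, n_ext,
                                           expected_nodes, expected_possible):
        from distressnet.netstats import count_edges

        X = sample_latent_gaussian(sixteen_node_truth, 200, seed=10)
        rng = np.random.default_rng(11)
        ext = pd.DataFrame(
            rng.normal(size=(200, n_ext)),
            columns=[f"E{k}" for k in range(n_ext)],
            index=X.index,
        )
        net = extended_network(X, ext, gamma=0.5)
        assert net.p == expected_nodes
        assert count_edges(net)[1] == expected_possible
        assert sum(v == "external" for v in net.node_classes.values()) == n_ext

    def test_null_externals_rarely_link_to_symptoms(self, sixteen_node_truth):
        false_links = []
        for seed in range(10):
            X = sample_latent_gaussian(sixteen_node_truth, 2000, seed=20 + seed)
            rng = np.random.default_rng(40 + seed)
            ext = pd.DataFrame(
                rng.normal(size=(2000, 5)),
                columns=[f"Z{k}" for k in range(5)],
                index=X.index,
            )
            net = extended_network(X, ext, gamma=0.5)
            w = net.as_frame()
            cross = w.loc[X.columns, ext.columns].to_numpy()
            false_links.append(np.count_nonzero(cross))
        assert np.mean(false_links) <= 2.0

    def test_duplicate_names_raise(self, sixteen_node_truth):
        X = sample_latent_gaussian(sixteen_node_truth, 50, seed=12)
        with pytest.raises(ValueError, match="duplicated"):
            extended_network(X, X.iloc[:, :2])
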