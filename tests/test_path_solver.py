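"""Tests for the penalized path solver and the modified cross-validation."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import logit

from adap.gradient_exchange import build_surrogate, make_packet, surrogate_value
from adap.model_core import SiteDataset, logistic_gradient
from adap.path_solver import (
    PenaltySpec,
    cv_fit,
    fit_path,
    fit_penalized,
    lambda_grid,
    local_objective,
    modified_cv,
    stratified_folds,
)
from conftest import random_site


def brute_force_lasso(objective, lam, alpha=1.0, p=None):
    """Independent penalized solve: split beta = b+ - b- and run L-BFGS-B,
    then soft-threshold-aware coordinate polish via 1-d numeric minimization."""
    p = p or objective.lead.p

    def obj(v):
        b = v[:p] - v[p:]
        pen = lam * (alpha * np.abs(b[1:]).sum()
                     + (1 - alpha) * (b[1:] ** 2).sum())
        return surrogate_value(objective, b) + lam * alpha * 0.0 + pen

    best, bv = None, np.inf
    for start in (np.zeros(2 * p), 0.01 * np.ones(2 * p)):
        res = minimize(obj, start, method="L-BFGS-B",
                       bounds=[(0, None)] * (2 * p),
                       options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-10})
        if res.fun < bv:
            bv, best = res.fun, res.x
    beta = best[:p] - best[p:]
    # polish each coordinate by golden-section on the exact 1-d restriction
    from scipy.optimize import minimize_scalar

    def coord_obj(t, j, b):
        b2 = b.copy()
        b2[j] = t
        pen = lam * (alpha * np.abs(b2[1:]).sum()
                     + (1 - alpha) * (b2[1:] ** 2).sum())
        return surrogate_value(objective, b2) + pen

    for _ in range(3):
        for j in range(p):
            r = minimize_scalar(coord_obj, args=(j, beta),
                                bracket=(beta[j] - 0.5, beta[j] + 0.5),
                                method="brent", options={"xtol": 1e-12})
            cand = beta.copy()
            cand[j] = 0.0 if j > 0 else r.x
            if j > 0 and coord_obj(0.0, j, beta) <= r.fun:
                beta[j] = 0.0
            else:
                beta[j] = r.x
            del cand
    return beta


class TestLambdaGrid:
    def test_grid_geometry(self, rng):
        ds = random_site(rng, n=80, p=5)
        grid = lambda_grid(local_objective(ds), n_lambda=40,
                           lambda_min_ratio=1e-2)
        assert grid.size == 40
        ratios = grid[1:] / grid[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-10)
        assert grid[-1] == pytest.approx(grid[0] * 1e-2)

    def test_all_null_at_lambda_max(self, rng):
        ds = random_site(rng, n=80, p=5)
        obj = local_objective(ds)
        grid = lambda_grid(obj, n_lambda=5)
        b = fit_penalized(obj, PenaltySpec(lam=grid[0]))
        assert np.all(b.beta[1:] == 0.0)

    def test_kkt_bracketing_around_lambda_max(self, rng):
        """Slightly above lambda_max stays null; slightly below activates."""
        ds = random_site(rng, n=120, p=5)
        obj = local_objective(ds)
        lam_max = lambda_grid(obj, n_lambda=2)[0]
        above = fit_penalized(obj, PenaltySpec(lam=lam_max * 1.01))
        below = fit_penalized(obj, PenaltySpec(lam=lam_max * 0.95))
        assert np.all(above.beta[1:] == 0.0)
        assert np.any(below.beta[1:] != 0.0)

    def test_error_when_nothing_penalized(self):
        ds = SiteDataset(np.ones((6, 1)), np.array([0, 1, 0, 1, 0, 1.0]))
        with pytest.raises(ValueError, match="penalized"):
            lambda_grid(local_objective(ds), n_lambda=5)


class TestFitPenalized:
    def test_null_model_intercept_is_logit_prevalence(self, rng):
        ds = random_site(rng, n=200, p=4)
        b = fit_penalized(local_objective(ds), PenaltySpec(lam=10.0), tol=1e-12)
        assert b.beta[0] == pytest.approx(logit(ds.y.mean()), abs=1e-6)
        assert np.all(b.beta[1:] == 0.0)

    @pytest.mark.parametrize("alpha", [1.0, 0.5])
    def test_matches_brute_force_on_local_objective(self, rng, alpha):
        ds = random_site(rng, n=200, p=5)
        obj = local_objective(ds)
        pen = PenaltySpec("lasso" if alpha == 1 else "elastic_net",
                          alpha=alpha, lam=0.01)
        ours = fit_penalized(obj, pen, tol=1e-12).beta
        ref = brute_force_lasso(obj, 0.01, alpha)
        np.testing.assert_allclose(ours, ref, atol=1e-4)

    def test_matches_brute_force_on_second_order_surrogate(self, rng):
        sites = [random_site(rng, n=150, p=5, site_id=f"s{i}", rho=0.3)
                 for i in range(3)]
        bbar = 0.1 * rng.standard_normal(5)
        pks = [make_packet(d, bbar, 2) for d in sites[1:]]
        obj = build_surrogate(sites[0], pks, bbar, order=2)
        ours = fit_penalized(obj, PenaltySpec(lam=0.02), tol=1e-12).beta
        ref = brute_force_lasso(obj, 0.02)
        np.testing.assert_allclose(ours, ref, atol=1e-4)

    def test_zero_correction_surrogate_equals_local_fit(self, rng):
        ds = random_site(rng, n=100, p=4)
        s = build_surrogate(ds, [], np.zeros(4), order=2)
        pen = PenaltySpec(lam=0.02)
        np.testing.assert_allclose(fit_penalized(s, pen, tol=1e-10).beta,
                                   fit_penalized(local_objective(ds), pen,
                                                 tol=1e-10).beta, atol=1e-10)

    def test_kkt_conditions_at_solution(self, rng):
        """Returned solutions satisfy penalized stationarity within tol."""
        ds = random_site(rng, n=150, p=6, rho=0.4)
        lam = 0.015
        b = fit_penalized(local_objective(ds), PenaltySpec(lam=lam),
                          tol=1e-12).beta
        g = logistic_gradient(ds, b)
        assert abs(g[0]) < 1e-5
        for j in range(1, 6):
            if b[j] == 0.0:
                assert abs(g[j]) <= lam + 1e-5
            else:
                assert g[j] + lam * np.sign(b[j]) == pytest.approx(0, abs=1e-5)

    def test_rejects_single_class_data(self):
        ds = SiteDataset(np.hstack([np.ones((10, 1)),
                                    np.arange(10.0).reshape(-1, 1)]),
                         np.ones(10))
        with pytest.raises(ValueError, match="classes"):
            fit_penalized(local_objective(ds), PenaltySpec(lam=0.1))


class TestFitPath:
    def test_support_grows_from_empty(self, rng):
        ds = random_site(rng, n=150, p=6)
        path = fit_path(local_objective(ds), n_lambda=30)
        assert path.df[0] == 0
        assert set(np.flatnonzero(path.betas[0][1:])) <= \
            set(np.flatnonzero(path.betas[-1][1:]))

    def test_cold_restart_reproduces_warm_solution(self, rng):
        ds = random_site(rng, n=120, p=5)
        obj = local_objective(ds)
        path = fit_path(obj, n_lambda=20, tol=1e-13)
        for i in (5, 12, 19):
            cold = fit_penalized(obj, PenaltySpec(lam=path.lambdas[i]),
                                 tol=1e-13).beta
            np.testing.assert_allclose(path.betas[i], cold, atol=1e-6)

    def test_orthogonal_design_soft_threshold_form(self, rng):
        """On an orthogonal balanced design the lasso coordinates obey the
        textbook soft-threshold formula of the curvature-0.25 quadratic
        model around the null (exact to third order in the coefficients)."""
        n, p = 400, 5
        z = rng.standard_normal((n, p - 1))
        q, _ = np.linalg.qr(z - z.mean(0))
        X = np.hstack([np.ones((n, 1)), q * np.sqrt(n)])  # columns: x'x = n
        y = (rng.uniform(size=n) < 0.5).astype(float)
        ds = SiteDataset(X, y)
        lam = 0.03
        b = fit_penalized(local_objective(ds), PenaltySpec(lam=lam),
                          tol=1e-13).beta
        g0 = logistic_gradient(ds, np.zeros(p))
        for j in range(1, p):
            expected = np.sign(-g0[j]) * max(abs(g0[j]) - lam, 0.0) / 0.25
            assert b[j] == pytest.approx(expected, abs=5e-3)


class TestModifiedCV:
    def test_folds_partition_and_stratify(self):
        y = np.r_[np.ones(40), np.zeros(160)]
        assign = stratified_folds(y, 5, seed=3)
        assert np.bincount(assign).tolist() == [40] * 5
        for f in range(5):
            assert (y[assign == f] == 1).sum() == 8

    def test_deterministic_under_seed(self, rng):
        ds = random_site(rng, n=200, p=5)
        a = cv_fit(ds, seed=11, n_lambda=30)
        b = cv_fit(ds, seed=11, n_lambda=30)
        assert a.lambda_selected == b.lambda_selected
        np.testing.assert_array_equal(a.beta_selected.beta, b.beta_selected.beta)

    def test_collapses_to_standard_cv_against_sklearn(self, rng):
        """With no remote packets the modified CV is plain 5-fold lasso CV;
        cross-check selected lambda and coefficients against scikit-learn
        on the identical folds and grid."""
        sklearn = pytest.importorskip("sklearn.linear_model")
        ds = random_site(rng, n=300, p=8, rho=0.2)
        path = cv_fit(ds, seed=5, n_lambda=30, lambda_min_ratio=1e-2,
                      tol=1e-10, patience=None)
        assign = stratified_folds(ds.y, 5, seed=5)
        splits = [(np.flatnonzero(assign != f), np.flatnonzero(assign == f))
                  for f in range(5)]
        n = ds.n_k
        Cs = 1.0 / (n * path.lambdas)
        clf = sklearn.LogisticRegressionCV(
            Cs=Cs, cv=splits, penalty="l1", solver="saga",
            scoring="neg_log_loss", tol=1e-8, max_iter=20000, refit=True)
        clf.fit(ds.X[:, 1:], ds.y)
        lam_sk = 1.0 / (n * clf.C_[0])
        grid_step = path.lambdas[0] / path.lambdas[1]
        assert abs(np.log(lam_sk / path.lambda_selected)) \
            <= np.log(grid_step) * 1.5 + 1e-9
        ours = fit_penalized(local_objective(ds), PenaltySpec(lam=lam_sk),
                             tol=1e-12).beta
        np.testing.assert_allclose(ours[1:], clf.coef_.ravel(), atol=2e-3)
        assert ours[0] == pytest.approx(clf.intercept_[0], abs=2e-3)

    def test_remote_information_changes_selection(self, rng):
        """Packets from collaborating sites shift the tuned fit toward the
        pooled solution."""
        beta_true = np.r_[-1.0, 0.8, 0.8, np.zeros(17)]
        sites = [random_site(rng, n=250, p=20, beta=beta_true,
                             site_id=f"s{i}") for i in range(4)]
        bbar = fit_penalized(local_objective(sites[0]), PenaltySpec(lam=0.05)).beta
        pks = [make_packet(d, bbar, 1) for d in sites[1:]]
        path = modified_cv(sites[0], pks, bbar, order=1, seed=2, n_lambda=40)
        local = cv_fit(sites[0], seed=2, n_lambda=40)
        pooled_ds = SiteDataset(np.vstack([d.X for d in sites]),
                                np.concatenate([d.y for d in sites]))
        pooled = cv_fit(pooled_ds, seed=2, n_lambda=40)
        err_adap = np.linalg.norm(path.beta_selected.beta - pooled.beta_selected.beta)
        err_local = np.linalg.norm(local.beta_selected.beta - pooled.beta_selected.beta)
        assert err_adap < err_local

    def test_requires_enough_per_class(self):
        X = np.hstack([np.ones((8, 1)), np.arange(8.0).reshape(-1, 1)])
        ds = SiteDataset(X, np.r_[np.ones(3), np.zeros(5)])
        with pytest.raises(ValueError, match="per class"):
            cv_fit(ds, folds=5)

    def test_path_export_frame(self, rng):
        ds = random_site(rng, n=150, p=4)
        path = cv_fit(ds, seed=1, n_lambda=20)
        frame = path.to_frame()
        assert {"lambda", "df", "cv_deviance", "beta0"} <= set(frame.columns)
        assert len(frame) == path.betas.shape[0]
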