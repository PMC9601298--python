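"""Unit tests for BLUPs, Newton scoring, dispersion updates and the fit."""

import numpy as np
import pytest
import statsmodels.api as sm

from poispair import (
    ModelParams,
    PanelData,
    SimConfig,
    SubjectData,
    fit,
    initialize,
    marginal_mean,
    newton_step,
    predict_random_effects,
    score_gamma,
    sensitivity_matrix,
    simulate_panel,
    stacked_design,
    subject_moments,
    update_rho,
    update_sigma2,
    update_tau2,
    wald_table,
)
from poispair.estimation import FitResult, _workspaces

from helpers import dense_blups, dense_corrections, dense_mu, dense_cov_v, dense_var_y


def _glm_oracle(data):
    """Independent Poisson-GLM fit (IRLS in statsmodels) on the stacked design."""
    X = np.vstack([stacked_design(s.Z, s.X) for s in data.subjects])
    y = np.concatenate([s.y for s in data.subjects])
    return sm.GLM(y, X, family=sm.families.Poisson()).fit().params


def _unit_panel():
    """2-subject panel with all counts equal to 1 (zero residual at mu = 1)."""
    mk = lambda sid: SubjectData(
        subject=sid, times=[1, 2], y1=[1, 1], y2=[1, 1],
        Z=np.ones((2, 1)), X=np.ones((2, 1)),
    )
    return PanelData(subjects=[mk("a"), mk("b")])


class TestPredictRandomEffects:
    def test_zero_variance_components_give_ones(self, tiny_panel):
        params = ModelParams(alpha=np.array([0.1, -0.2]), beta=np.array([0.3, 0.15]))
        pred = predict_random_effects(params, tiny_panel)
        np.testing.assert_array_equal(pred.u_hat, 1.0)
        for v in pred.v_hat:
            np.testing.assert_array_equal(v, 1.0)

    def test_zero_residual_gives_ones(self):
        panel = _unit_panel()
        params = ModelParams(
            alpha=np.zeros(1), beta=np.zeros(1),
            sigma2=0.2, tau2=np.array([0.3, 0.1]), rho=np.array([0.4, 0.0]),
        )
        pred = predict_random_effects(params, panel)
        np.testing.assert_allclose(pred.u_hat, 1.0, atol=1e-14)
        for v in pred.v_hat:
            np.testing.assert_allclose(v, 1.0, atol=1e-14)

    def test_matches_dense_oracle(self, tiny_panel, tiny_params):
        pred = predict_random_effects(tiny_params, tiny_panel)
        for i, s in enumerate(tiny_panel.subjects):
            u, v = dense_blups(
                tiny_params.alpha, tiny_params.beta, tiny_params.sigma2,
                tiny_params.tau2, tiny_params.rho, s.Z, s.X, s.y,
            )
            np.testing.assert_allclose(pred.u_hat[i], u, atol=1e-10)
            np.testing.assert_allclose(pred.v_hat[i], v, atol=1e-10)

    def test_linear_in_response(self, tiny_panel, tiny_params):
        # Uhat(y + y') - 1 = (Uhat(y) - 1) + (Uhat(y') - 1) around mu.
        s = tiny_panel.subjects[0]
        base = predict_random_effects(tiny_params, tiny_panel)
        bumped = PanelData(
            subjects=[
                SubjectData(
                    subject=s.subject, times=s.times,
                    y1=s.y1 + np.array([2, 0]), y2=s.y2, Z=s.Z, X=s.X,
                ),
                tiny_panel.subjects[1],
            ]
        )
        pred2 = predict_random_effects(tiny_params, bumped)
        sm_ = subject_moments(tiny_params, s.Z, s.X)
        w = np.linalg.solve(sm_.VarY, np.array([2.0, 0.0, 0.0, 0.0]))
        np.testing.assert_allclose(
            pred2.u_hat[0] - base.u_hat[0], sm_.CovUY @ w, atol=1e-10
        )


class TestScoreGamma:
    def test_zero_residual_is_fixed_point(self):
        panel = _unit_panel()
        params = ModelParams(
            alpha=np.zeros(1), beta=np.zeros(1),
            sigma2=0.2, tau2=np.array([0.3, 0.1]), rho=np.array([0.4, 0.0]),
        )
        pred = predict_random_effects(params, panel)
        np.testing.assert_allclose(score_gamma(params, panel, pred), 0.0, atol=1e-12)

    def test_reduces_to_poisson_score_without_random_effects(self, tiny_panel):
        params = ModelParams(alpha=np.array([0.1, -0.2]), beta=np.array([0.3, 0.15]))
        pred = predict_random_effects(params, tiny_panel)
        psi = score_gamma(params, tiny_panel, pred)
        expected = np.zeros(4)
        for s in tiny_panel.subjects:
            Xi = stacked_design(s.Z, s.X)
            expected += Xi.T @ (s.y - marginal_mean(params, s.Z, s.X))
        np.testing.assert_allclose(psi, expected, atol=1e-12)


class TestSensitivityMatrix:
    def test_reduces_to_fisher_information(self, tiny_panel):
        params = ModelParams(alpha=np.array([0.1, -0.2]), beta=np.array([0.3, 0.15]))
        S = sensitivity_matrix(params, tiny_panel)
        expected = np.zeros((4, 4))
        for s in tiny_panel.subjects:
            Xi = stacked_design(s.Z, s.X)
            mu = marginal_mean(params, s.Z, s.X)
            expected -= Xi.T @ np.diag(mu) @ Xi
        np.testing.assert_allclose(S, expected, atol=1e-12)

    def test_symmetric_negative_definite(self, tiny_panel, tiny_params):
        S = sensitivity_matrix(tiny_params, tiny_panel)
        np.testing.assert_allclose(S, S.T, atol=1e-10)
        assert np.all(np.linalg.eigvalsh(S) < 0)

    def test_matches_dense_oracle(self, tiny_panel, tiny_params):
        S = sensitivity_matrix(tiny_params, tiny_panel)
        expected = np.zeros((4, 4))
        for s in tiny_panel.subjects:
            mu = dense_mu(tiny_params.alpha, tiny_params.beta, s.Z, s.X)
            CovV = dense_cov_v(tiny_params.sigma2, tiny_params.tau2, tiny_params.rho, s.T)
            Vinv = np.linalg.inv(dense_var_y(mu, CovV))
            Xi = stacked_design(s.Z, s.X)
            expected -= Xi.T @ np.diag(mu) @ Vinv @ np.diag(mu) @ Xi
        np.testing.assert_allclose(S, expected, atol=1e-10)


class TestNewtonStep:
    def test_fixed_point_at_zero_score(self):
        panel = _unit_panel()
        params = ModelParams(
            alpha=np.zeros(1), beta=np.zeros(1),
            sigma2=0.2, tau2=np.array([0.3, 0.1]), rho=np.array([0.4, 0.0]),
        )
        np.testing.assert_allclose(newton_step(params, panel), params.gamma, atol=1e-12)

    def test_iterated_step_matches_glm_oracle(self, small_panel):
        params = ModelParams(alpha=np.zeros(2), beta=np.zeros(2))
        gamma = params.gamma
        for _ in range(50):
            new = newton_step(params.with_gamma(gamma), small_panel)
            if np.sum(np.abs(new - gamma)) < 1e-12:
                break
            gamma = new
        np.testing.assert_allclose(gamma, _glm_oracle(small_panel), atol=1e-6)

    def test_step_reduces_score_norm(self, true_params):
        panel = simulate_panel(SimConfig(m=80, T=8, params=true_params, seed=11))
        start = true_params.with_gamma(true_params.gamma + 0.15)
        pred0 = predict_random_effects(start, panel)
        norm0 = np.linalg.norm(score_gamma(start, panel, pred0))
        stepped = start.with_gamma(newton_step(start, panel))
        pred1 = predict_random_effects(stepped, panel)
        norm1 = np.linalg.norm(score_gamma(stepped, panel, pred1))
        assert norm1 < norm0


class TestDispersionUpdates:
    def test_degenerate_zero_fixed_point(self):
        panel = _unit_panel()
        params = ModelParams(alpha=np.zeros(1), beta=np.zeros(1))
        pred = predict_random_effects(params, panel)
        assert update_sigma2(params, panel, pred) == 0.0
        assert update_tau2(params, panel, pred, 0) == 0.0
        assert update_rho(params, panel, pred, 0) == 0.0

    def test_sigma2_correction_matches_dense_oracle(self, tiny_panel, tiny_params):
        work = _workspaces(tiny_params, tiny_panel)
        pred = predict_random_effects(tiny_params, tiny_panel, _work=work)
        total = 0.0
        for i, s in enumerate(tiny_panel.subjects):
            c, _, _ = dense_corrections(
                tiny_params.alpha, tiny_params.beta, tiny_params.sigma2,
                tiny_params.tau2, tiny_params.rho, s.Z, s.X,
            )
            total += (pred.u_hat[i] - 1.0) ** 2 + c
        expected = max(total / tiny_panel.m, 0.0)
        np.testing.assert_allclose(
            update_sigma2(tiny_params, tiny_panel, pred, _work=work),
            expected,
            atol=1e-10,
        )

    @pytest.mark.parametrize("j", [0, 1])
    def test_tau2_correction_matches_moment_identity_oracle(self, tiny_panel, tiny_params, j):
        work = _workspaces(tiny_params, tiny_panel)
        pred = predict_random_effects(tiny_params, tiny_panel, _work=work)
        total, n = 0.0, 0
        for i, s in enumerate(tiny_panel.subjects):
            _, d, _ = dense_corrections(
                tiny_params.alpha, tiny_params.beta, tiny_params.sigma2,
                tiny_params.tau2, tiny_params.rho, s.Z, s.X,
            )
            dev = pred.v_hat[i][j * s.T : (j + 1) * s.T] - pred.u_hat[i]
            total += np.sum(dev**2 + d[j])
            n += s.T
        expected = max(total / n, 0.0)
        np.testing.assert_allclose(
            update_tau2(tiny_params, tiny_panel, pred, j, _work=work),
            expected,
            atol=1e-8,
        )

    @pytest.mark.parametrize("j", [0, 1])
    def test_rho_correction_matches_dense_oracle(self, tiny_params, j):
        # m=2, T=3 instance; b assembled from its five covariance terms
        # through the moment identity, with dense inverses.
        rng = np.random.default_rng(17)
        subjects = [
            SubjectData(
                subject=i, times=[1, 2, 3],
                y1=rng.poisson(1.5, size=3), y2=rng.poisson(1.0, size=3),
                Z=rng.normal(size=(3, 2)) * 0.3, X=rng.normal(size=(3, 2)) * 0.3,
            )
            for i in range(2)
        ]
        panel = PanelData(subjects=subjects)
        work = _workspaces(tiny_params, panel)
        pred = predict_random_effects(tiny_params, panel, _work=work)
        num, dl, dr = 0.0, 0.0, 0.0
        for i, s in enumerate(panel.subjects):
            _, d, b = dense_corrections(
                tiny_params.alpha, tiny_params.beta, tiny_params.sigma2,
                tiny_params.tau2, tiny_params.rho, s.Z, s.X,
            )
            dev = pred.v_hat[i][j * s.T : (j + 1) * s.T] - pred.u_hat[i]
            for t in range(s.T - 1):
                num += dev[t] * dev[t + 1] + b[j][(t, t + 1)]
                dl += dev[t] ** 2 + d[j, t]
                dr += dev[t + 1] ** 2 + d[j, t + 1]
        expected = np.clip(num / np.sqrt(dl * dr), -0.99, 0.99)
        np.testing.assert_allclose(
            update_rho(tiny_params, panel, pred, j, _work=work), expected, atol=1e-8
        )

    def test_rho_unidentifiable_with_single_time(self, tiny_params):
        subjects = [
            SubjectData(subject=i, times=[1], y1=[2], y2=[1],
                        Z=np.ones((1, 2)), X=np.ones((1, 2)))
            for i in range(3)
        ]
        panel = PanelData(subjects=subjects)
        pred = predict_random_effects(tiny_params, panel)
        with pytest.raises(ValueError):
            update_rho(tiny_params, panel, pred, 0)

    def test_unstructured_update_returns_correlation_matrix(self, true_params):
        panel = simulate_panel(SimConfig(m=60, T=4, params=true_params, seed=5))
        params = true_params.replace(
            corr_structure="unstructured",
            R1=np.eye(4), R2=np.eye(4),
        )
        pred = predict_random_effects(params, panel)
        R = update_rho(params, panel, pred, 0)
        assert R.shape == (4, 4)
        np.testing.assert_allclose(R, R.T)
        np.testing.assert_allclose(np.diag(R), 1.0)
        assert np.all(np.abs(R) <= 1.0)

    def test_subject_order_invariance(self, small_panel, true_params):
        pred = predict_random_effects(true_params, small_panel)
        s2 = update_sigma2(true_params, small_panel, pred)
        rev = PanelData(subjects=list(reversed(small_panel.subjects)))
        pred_r = predict_random_effects(true_params, rev)
        s2_r = update_sigma2(true_params, rev, pred_r)
        np.testing.assert_allclose(s2, s2_r, rtol=1e-12)
        np.testing.assert_allclose(
            update_tau2(true_params, small_panel, pred, 0),
            update_tau2(true_params, rev, pred_r, 0),
            rtol=1e-12,
        )


class TestInitialize:
    def test_constant_counts_give_zero_dispersion(self):
        panel = _unit_panel()
        params = initialize(panel)
        assert params.sigma2 == 0.0
        np.testing.assert_array_equal(params.tau2, 0.0)

    def test_sigma2_formula_from_subject_means(self):
        # subject means 0.5 and 1.5 -> sigma2_0 = ((0.5-1)^2 + (1.5-1)^2)/2
        subjects = [
            SubjectData(subject="a", times=[1, 2], y1=[1, 0], y2=[1, 0],
                        Z=np.zeros((2, 1)), X=np.zeros((2, 1))),
            SubjectData(subject="b", times=[1, 2], y1=[2, 1], y2=[2, 1],
                        Z=np.zeros((2, 1)), X=np.zeros((2, 1))),
        ]
        params = initialize(PanelData(subjects=subjects))
        np.testing.assert_allclose(params.sigma2, 0.25)

    def test_gamma0_matches_glm_oracle(self, small_panel):
        params = initialize(small_panel)
        np.testing.assert_allclose(params.gamma, _glm_oracle(small_panel), atol=1e-6)

    def test_all_zero_series_falls_back(self, caplog):
        subjects = [
            SubjectData(subject=i, times=[1, 2], y1=[1, 2], y2=[0, 0],
                        Z=np.ones((2, 1)), X=np.ones((2, 1)))
            for i in range(3)
        ]
        with caplog.at_level("WARNING", logger="poispair"):
            params = initialize(PanelData(subjects=subjects))
        assert params.alpha[0] < 0
        assert any("zero" in r.message for r in caplog.records)


class TestFit:
    def test_fixed_zero_variance_reduces_to_glm(self, small_panel):
        res = fit(small_panel, fix_variance_components=0.0, tolerance=1e-10)
        assert res.converged
        np.testing.assert_allclose(res.params.gamma, _glm_oracle(small_panel), atol=1e-6)
        assert res.params.sigma2 == 0.0

    def test_non_convergence_warns_not_raises(self, small_panel):
        with pytest.warns(RuntimeWarning):
            res = fit(small_panel, tolerance=1e-12, max_iter=2)
        assert not res.converged
        assert res.n_iter == 2
        assert len(res.trace) == 2

    def test_full_fit_smoke(self, true_params):
        panel = simulate_panel(SimConfig(m=60, T=12, params=true_params, seed=3))
        res = fit(panel, tolerance=1e-4, max_iter=300)
        assert res.converged
        assert np.all(res.se > 0)
        assert np.all((res.pvalues >= 0) & (res.pvalues <= 1))
        assert res.params.sigma2 >= 0
        assert np.all(np.abs(res.params.rho) <= 0.99)
        assert len(res.predictions.u_hat) == panel.m

    def test_blup_beats_naive_predictors(self, true_params):
        # Mean squared prediction error of the BLUP must beat both the
        # constant predictor 1 and the naive per-subject mean of y/mu.
        mse = {"blup": 0.0, "naive": 0.0, "const": 0.0}
        for seed in range(25):
            panel, eff = simulate_panel(
                SimConfig(m=40, T=10, params=true_params, seed=600 + seed),
                return_effects=True,
            )
            pred = predict_random_effects(true_params, panel)
            for i, s in enumerate(panel.subjects):
                mu = marginal_mean(true_params, s.Z, s.X)
                u = eff["u"][i]
                mse["blup"] += (pred.u_hat[i] - u) ** 2
                mse["naive"] += (np.mean(s.y / mu) - u) ** 2
                mse["const"] += (1.0 - u) ** 2
        assert mse["blup"] < mse["naive"]
        assert mse["blup"] < mse["const"]

    def test_label_swap_symmetry(self, true_params):
        # With z and x spanning the same covariates, swapping the two series
        # is an exact reparametrization (alpha' = alpha + beta, beta' = -beta,
        # series parameters exchanged), so fitted means must swap exactly.
        rng = np.random.default_rng(21)
        W = 0.1 * rng.standard_normal((50, 8, 2))
        panel = simulate_panel(
            SimConfig(m=50, T=8, params=true_params, seed=21, Z=W, X=W)
        )
        swapped = PanelData(
            subjects=[
                SubjectData(subject=s.subject, times=s.times, y1=s.y2, y2=s.y1,
                            Z=s.Z, X=s.X)
                for s in panel.subjects
            ]
        )
        r1 = fit(panel, tolerance=1e-8, max_iter=500)
        r2 = fit(swapped, tolerance=1e-8, max_iter=500)
        for s in panel.subjects[:5]:
            mu1 = marginal_mean(r1.params, s.Z, s.X)
            mu2 = marginal_mean(r2.params, s.Z, s.X)
            T = s.T
            np.testing.assert_allclose(mu2[T:], mu1[:T], rtol=1e-5)
            np.testing.assert_allclose(mu2[:T], mu1[T:], rtol=1e-5)
        np.testing.assert_allclose(
            r2.params.tau2, r1.params.tau2[::-1], rtol=1e-4
        )


class TestWaldTable:
    def test_zero_estimate_gives_p_one(self, small_panel):
        res = fit(small_panel, fix_variance_components=0.0, tolerance=1e-8)
        res_zero = FitResult(
            params=res.params.with_gamma(np.zeros_like(res.params.gamma)),
            se=res.se,
            pvalues=np.ones_like(res.se),
            predictions=res.predictions,
            n_iter=res.n_iter,
            converged=True,
            trace=res.trace,
            tolerance=res.tolerance,
            gamma_names=res.gamma_names,
        )
        table = wald_table(res_zero)
        assert np.all(table["p_value"].iloc[: len(res.se)].to_numpy() == 1.0)

    def test_normal_quantile(self):
        from scipy.stats import norm

        assert 2 * (1 - norm.cdf(1.96)) == pytest.approx(0.05, abs=1e-3)

    def test_se_matches_dense_information_oracle(self, tiny_panel, tiny_params):
        res = fit(tiny_panel, init=tiny_params, tolerance=1e-8, max_iter=1)
        info = np.zeros((4, 4))
        for s in tiny_panel.subjects:
            mu = dense_mu(res.params.alpha, res.params.beta, s.Z, s.X)
            CovV = dense_cov_v(
                res.params.sigma2, res.params.tau2, res.params.rho, s.T
            )
            Vinv = np.linalg.inv(dense_var_y(mu, CovV))
            Xi = stacked_design(s.Z, s.X)
            info += Xi.T @ np.diag(mu) @ Vinv @ np.diag(mu) @ Xi
        np.testing.assert_allclose(
            res.se, np.sqrt(np.diag(np.linalg.inv(info))), atol=1e-10
        )

    def test_dispersion_rows_have_no_se(self, small_panel):
        res = fit(small_panel, fix_variance_components=0.0, tolerance=1e-8)
        table = wald_table(res)
        disp = table[table["parameter"].isin(["sigma2", "tau2_1", "tau2_2"])]
        assert disp["se"].isna().all()
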