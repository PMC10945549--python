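"""Elastic-net KiR machinery against independent oracles: closed-form
ridge, per-lambda cold-start LOOCV refits, sklearn's coordinate descent,
and analytic special cases of the penalized objective."""

import numpy as np
import pandas as pd
import pytest

import kirscreen.kir_core as kc
from kirscreen.kir_core import (
    DEFAULT_ALPHA_GRID, DegenerateResponseError, ElasticNetSolution,
    InsufficientDataError, KiRModel, call_informative_kinases, evaluate_model,
    fit_elastic_net, fit_kir_model, lambda_max, loocv_path_mse, loocv_select,
    make_lambda_grid, penalized_objective, predict_out_of_panel,
)

from conftest import random_problem


def ridge_closed_form(X, y, lam):
    """Independent ridge oracle: direct solve of the standardized normal
    equations (Xs'Xs + n*lam*I) b = Xs'yc, back-transformed."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    mean, sd = X.mean(0), X.std(0)
    Xs = (X - mean) / sd
    yc = y - y.mean()
    b_std = np.linalg.solve(Xs.T @ Xs + n * lam * np.eye(p), Xs.T @ yc)
    b = b_std / sd
    return y.mean() - b @ mean, b


class TestFitElasticNet:
    def test_lambda_max_gives_null_model(self):
        rng = np.random.default_rng(0)
        X, y = random_problem(rng, n=20, p=10)
        lmax = lambda_max(X, y, 1.0)
        sols = fit_elastic_net(X, y, 1.0, [2 * lmax, 1.001 * lmax])
        for s in sols:
            assert (s.coefficients == 0).all()
            assert s.intercept == pytest.approx(y.mean())

    def test_ridge_matches_closed_form(self):
        rng = np.random.default_rng(42)
        X, y = random_problem(rng, n=10, p=5)
        grid = make_lambda_grid(X, y, 0.0, n_lambdas=10)
        sols = fit_elastic_net(X, y, 0.0, grid)
        for s in sols:
            b0, b = ridge_closed_form(X, y, s.lam)
            assert np.abs(s.coefficients.to_numpy() - b).max() < 1e-6
            assert s.intercept == pytest.approx(b0, abs=1e-6)

    def test_matches_sklearn_coordinate_descent(self):
        # independent solver route for alpha > 0
        from sklearn.linear_model import enet_path
        rng = np.random.default_rng(3)
        X, y = random_problem(rng, n=25, p=15)
        for alpha in (0.3, 1.0):
            grid = make_lambda_grid(X, y, alpha, n_lambdas=30)
            sols = fit_elastic_net(X, y, alpha, grid, tol=1e-10)
            mean, sd = X.mean(0), X.std(0)
            Xs = (X - mean) / sd
            _, coefs_ref, _ = enet_path(Xs, y - y.mean(), l1_ratio=alpha,
                                        alphas=grid, tol=1e-13,
                                        max_iter=1_000_000)
            mine = np.column_stack(
                [s.coefficients.to_numpy() * sd for s in sols])
            assert np.abs(mine - coefs_ref).max() < 1e-6

    def test_planted_signal_carries_largest_coefficients(self):
        rng = np.random.default_rng(1)
        n, p = 30, 8
        X = rng.uniform(0, 100, (n, p))
        beta = np.zeros(p)
        beta[[2, 5]] = [0.3, 0.25]
        y = 0.5 + (X / 100) @ beta  # exact linear, no noise
        grid = make_lambda_grid(X, y, 0.5)
        sol = fit_elastic_net(X, y, 0.5, grid)[-1]  # smallest penalty
        top2 = set(np.argsort(np.abs(sol.coefficients.to_numpy()))[-2:])
        assert top2 == {2, 5}

    def test_constant_column_dropped_with_zero_coefficient(self):
        rng = np.random.default_rng(2)
        X, y = random_problem(rng, n=15, p=6)
        X[:, 3] = 42.0
        sol = fit_elastic_net(X, y, 0.5, make_lambda_grid(X, y, 0.5))[-1]
        assert sol.coefficients.iloc[3] == 0.0

    def test_invalid_arguments_rejected(self):
        rng = np.random.default_rng(0)
        X, y = random_problem(rng, n=10, p=4)
        with pytest.raises(ValueError, match="alpha"):
            fit_elastic_net(X, y, 1.5, [1.0, 0.5])
        with pytest.raises(ValueError, match="decreasing"):
            fit_elastic_net(X, y, 0.5, [0.5, 1.0])
        with pytest.raises(InsufficientDataError):
            fit_elastic_net(X[:2], y[:2], 0.5, [1.0, 0.5])

    def test_objective_optimality_under_perturbation(self):
        # no +-1e-4 coordinate-wise nudge may lower the penalized objective
        rng = np.random.default_rng(5)
        X, y = random_problem(rng, n=20, p=8)
        for alpha in (0.2, 1.0):
            grid = make_lambda_grid(X, y, alpha, n_lambdas=20)
            for s in fit_elastic_net(X, y, alpha, grid, tol=1e-12)[::5]:
                base = penalized_objective(X, y, alpha, s.lam, s.intercept,
                                           s.coefficients.to_numpy())
                for j in range(X.shape[1]):
                    for d in (1e-4, -1e-4):
                        pert = s.coefficients.to_numpy().copy()
                        pert[j] += d
                        obj = penalized_objective(X, y, alpha, s.lam,
                                                  s.intercept, pert)
                        assert obj >= base - 1e-10

    def test_support_essentially_monotone_along_path(self):
        # as lambda decreases the support grows, except that a variable may
        # leave by shrinking continuously through zero; assert no materially
        # active variable (>1% of the largest coefficient) is ever expelled
        rng = np.random.default_rng(7)
        X, y = random_problem(rng, n=25, p=12)
        for alpha in (0.3, 0.7, 1.0):
            grid = make_lambda_grid(X, y, alpha, n_lambdas=50)
            sols = fit_elastic_net(X, y, alpha, grid)
            for a, b in zip(sols, sols[1:]):
                ca, cb = a.coefficients.abs(), b.coefficients.abs()
                leavers = ca[(ca > 0) & (cb == 0)]
                if len(leavers):
                    assert leavers.max() <= 0.01 * ca.max()


class TestLoocv:
    def test_matches_brute_force_refits(self):
        # oracle: cold-start refit per (fold, lambda), no path warm starts
        rng = np.random.default_rng(11)
        X, y = random_problem(rng, n=10, p=6)
        grid = make_lambda_grid(X, y, 0.5, n_lambdas=12)
        mse, preds = loocv_path_mse(X, y, 0.5, grid, tol=1e-12)
        for li, lam in enumerate(grid):
            errs = []
            for i in range(len(y)):
                mask = np.arange(len(y)) != i
                sol = fit_elastic_net(X[mask], y[mask], 0.5,
                                      [lam], tol=1e-12)[0]
                pred = sol.intercept + X[i] @ sol.coefficients.to_numpy()
                errs.append((y[i] - pred) ** 2)
                assert preds[i, li] == pytest.approx(pred, abs=1e-8)
            assert mse[li] == pytest.approx(np.mean(errs), abs=1e-8)

    def test_noiseless_linear_response_is_recovered(self):
        rng = np.random.default_rng(4)
        n, p = 20, 5
        X = rng.uniform(0, 100, (n, p))
        y = 0.3 + (X / 100) @ np.array([0.2, 0, 0.1, 0, 0])
        sol = loocv_select(X, y, 0.5)
        assert sol.loocv_mse < 1e-6
        assert np.corrcoef(y, sol.loocv_predictions)[0, 1] > 0.999

    def test_pure_noise_prefers_null_model(self):
        # uninformative X: the selected lambda sits at or near lambda_max
        # (an empty or near-empty model) for the majority of 50 seeds
        near_null, nnzs = 0, []
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            X = rng.uniform(0, 100, (15, 10))
            y = rng.normal(1.0, 0.05, 15)
            grid = make_lambda_grid(X, y, 1.0, n_lambdas=50)
            sol = loocv_select(X, y, 1.0, lambda_grid=grid)
            idx = int(np.argmin(np.abs(grid - sol.lam)))
            nnz = int((sol.coefficients != 0).sum())
            nnzs.append(nnz)
            near_null += (idx < 5) or nnz == 0  # top decile of the grid
        assert near_null > n_seeds // 2
        assert np.median(nnzs) <= 2

    def test_tie_break_prefers_larger_lambda(self):
        # constant response after centering -> all lambdas give identical
        # null fits; the largest lambda must win
        X = np.arange(12, dtype=float).reshape(4, 3) * 10
        y = np.full(4, 2.0)
        grid = np.geomspace(1.0, 0.001, 10)
        sol = loocv_select(X, y, 1.0, lambda_grid=grid)
        assert sol.lam == pytest.approx(1.0)

    def test_too_few_drugs_rejected(self):
        with pytest.raises(InsufficientDataError):
            loocv_path_mse(np.ones((2, 3)), np.ones(2), 0.5, [1.0])


class TestKiRModel:
    def test_eleven_alpha_solutions_on_default_grid(self, sim, fitted_models):
        model = next(iter(fitted_models.values()))
        assert len(model.solutions) == 11
        assert model.alpha_grid == tuple(np.round(np.linspace(0, 1, 11), 10))

    def test_ridge_member_is_dense(self, sim, fitted_models):
        # alpha=0 always carries a nonzero coefficient for every kinase
        for model in fitted_models.values():
            ridge = [s for s in model.solutions if s.alpha == 0.0][0]
            assert (ridge.coefficients != 0).all()

    def test_hit_rule_excludes_ridge_only_positives(self):
        kinases = ["KIN001", "KIN002", "KIN003"]

        def sol(alpha, coefs):
            return ElasticNetSolution(
                alpha=alpha, lam=0.1, intercept=1.0,
                coefficients=pd.Series(coefs, index=kinases),
                loocv_mse=0.1, loocv_predictions=np.empty(0))

        model = KiRModel(cytokine_id="c", solutions=[
            sol(0.0, [0.5, 0.5, 0.5]),     # ridge: never counted
            sol(0.5, [0.2, 0.0, -0.3]),    # negative never counted
            sol(1.0, [0.0, 0.1, 0.0]),
        ])
        assert call_informative_kinases(model) == {"KIN001", "KIN002"}

    def test_all_null_solutions_give_empty_hit_set(self):
        kinases = ["KIN001", "KIN002"]
        model = KiRModel(cytokine_id="c", solutions=[
            ElasticNetSolution(alpha=a, lam=1.0, intercept=1.0,
                               coefficients=pd.Series(0.0, index=kinases),
                               loocv_mse=0.1, loocv_predictions=np.empty(0))
            for a in (0.0, 0.5, 1.0)])
        assert call_informative_kinases(model) == set()

    def test_constant_response_is_skipped(self):
        X = np.random.default_rng(0).uniform(0, 100, (10, 4))
        with pytest.raises(DegenerateResponseError):
            fit_kir_model(X, np.full(10, 1.0))

    def test_planted_kinases_recovered(self, sim, fitted_models):
        gt = sim["ground_truth"]
        recalls = [
            len(m.informative_kinases & gt.support[c]) / len(gt.support[c])
            for c, m in fitted_models.items()
        ]
        assert np.mean(recalls) >= 0.8


class TestEvaluateModel:
    def test_perfect_prediction_accepted(self):
        y = np.array([1.0, 0.5, 0.8, 0.2])
        q = evaluate_model(y, y)
        assert q.nrmse == 0 and q.pearson_r == pytest.approx(1.0)
        assert q.accepted

    def test_null_prediction_rejected(self):
        y = np.array([1.0, 0.5, 0.8, 0.2])
        q = evaluate_model(y, np.full_like(y, y.mean()))
        assert not q.accepted and q.reason == "constant predictions"

    def test_constant_response_rejected_with_flag(self):
        q = evaluate_model(np.ones(5), np.ones(5))
        assert not q.accepted and q.reason == "constant response"

    def test_gate_is_strict_on_both_thresholds(self):
        # nRMSE exactly at 0.1 or r exactly at 0.85 must not pass
        y = np.array([0.0, 1.0, 0.0, 1.0])
        q = evaluate_model(y, y)
        assert q.accepted
        assert not evaluate_model(y, y, nrmse_threshold=0.0).accepted
        assert not evaluate_model(y, y, pearson_threshold=1.0).accepted

    def test_quality_gate_calibration(self, sim, fitted_models):
        # planted low-noise screen: most models accepted; pure-noise
        # response: rejected
        accepted = [m.quality.accepted for m in fitted_models.values()]
        assert np.mean(accepted) >= 0.5
        rng = np.random.default_rng(123)
        X = sim["X_screen"]
        y = rng.normal(1.0, 0.05, len(X))
        m = fit_kir_model(X, y, "noise")
        assert not m.quality.accepted


class TestPrediction:
    def test_training_panel_reproduces_fitted_values(self, sim, fitted_models):
        X = sim["X_screen"]
        pred = predict_out_of_panel(fitted_models, X, include_rejected=True)
        for c, m in fitted_models.items():
            s = m.best_solution
            fitted = s.intercept + X.to_numpy() @ s.coefficients.to_numpy()
            assert np.allclose(pred[c].to_numpy(), fitted)

    def test_uninhibiting_pseudo_drug_predicts_control_fit(self, sim,
                                                           fitted_models):
        X = sim["X_screen"]
        pseudo = pd.DataFrame(100.0, index=["lps_only"], columns=X.columns)
        pred = predict_out_of_panel(fitted_models, pseudo,
                                    include_rejected=True)
        for c, m in fitted_models.items():
            s = m.best_solution
            want = s.intercept + 100.0 * s.coefficients.sum()
            assert pred.loc["lps_only", c] == pytest.approx(want)

    def test_missing_required_kinase_named_in_error(self, sim, fitted_models):
        X = sim["X_screen"]
        model = next(m for m in fitted_models.values()
                     if m.best_solution.nonzero_kinases)
        kin = sorted(model.best_solution.nonzero_kinases)[0]
        with pytest.raises(KeyError, match=kin):
            predict_out_of_panel({model.cytokine_id: model},
                                 X.drop(columns=[kin]),
                                 include_rejected=True)

    def test_rejected_models_excluded_by_default(self, sim, fitted_models):
        X = sim["X_screen"]
        pred = predict_out_of_panel(fitted_models, X)
        accepted = {c for c, m in fitted_models.items() if m.quality.accepted}
        assert set(pred.columns) == accepted

    def test_held_out_panel_tracks_generative_truth(self, sim, fitted_models):
        pred = predict_out_of_panel(fitted_models, sim["X_panel"])
        truth = sim["Y_panel_true"]
        for c in pred.columns:
            r = np.corrcoef(pred[c], truth[c])[0, 1]
            assert r >= 0.9, f"{c}: r={r:.3f}"
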