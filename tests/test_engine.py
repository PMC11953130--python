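import numpy as np
import pandas as pd
import pytest

from penfactreg.baselines import fit_additive
from penfactreg.design import build_design
from penfactreg.engine import (
    CVScheme,
    FRFit,
    PenaltySpec,
    cv_select_lambda,
    elnet_path,
    fit_gne,
    kkt_residual,
    lambda_max,
    make_folds,
    resolve_lambda_grid,
)
from penfactreg.exceptions import ValidationError
from penfactreg.predict_eval import predict_goen
from penfactreg.simulate import SimConfig, simulate_met

from conftest import make_dataset


def _sim(seed=0, **kw):
    cfg = SimConfig(
        n_g=kw.pop("n_g", 12),
        n_e_train=kw.pop("n_e_train", 20),
        n_e_test=kw.pop("n_e_test", 5),
        n_c=kw.pop("n_c", 3),
        n_active=kw.pop("n_active", 2),
        seed=seed,
        **kw,
    )
    return simulate_met(cfg)


class TestPenaltySpec:
    def test_kind_alpha_consistency(self):
        assert PenaltySpec(kind="ridge").alpha == 0.0
        assert PenaltySpec(kind="lasso").alpha == 1.0
        assert PenaltySpec(kind="elnet").alpha == 0.5  # equal-weights default
        with pytest.raises(ValidationError):
            PenaltySpec(kind="ridge", alpha=0.3)
        with pytest.raises(ValidationError):
            PenaltySpec(kind="elnet", lambda_grid=[1.0, 2.0])  # not decreasing


class TestPathSolvers:
    def test_lambda_zero_equals_ols(self):
        data, _, _ = _sim(seed=1)
        d = build_design(data)
        coefs = elnet_path(d, PenaltySpec(kind="ridge", lambda_grid=[0.0]))
        oracle = np.linalg.lstsq(np.asarray(d.X.todense()), d.y, rcond=None)[0]
        assert np.abs(coefs[0] - oracle).max() < 1e-6

    def test_lasso_at_lambda_max_is_additive(self):
        data, _, _ = _sim(seed=2)
        d = build_design(data)
        lmax = lambda_max(d, 1.0)
        theta = elnet_path(d, PenaltySpec(kind="lasso", lambda_grid=[lmax * (1 + 1e-9)]))[0]
        assert np.count_nonzero(theta[d.n_unpenalized :]) == 0
        add = fit_additive(data)
        assert theta[0] == pytest.approx(add.mu, abs=1e-6)
        g_hat = dict(zip(d.genotypes[1:], theta[1 : len(d.genotypes)]))
        for gid, val in g_hat.items():
            assert val == pytest.approx(add.g[gid], abs=1e-6)

    @pytest.mark.parametrize("kind,alpha", [("lasso", 1.0), ("elnet", 0.5), ("ridge", 0.0)])
    def test_kkt_conditions_along_path(self, kind, alpha):
        data, _, _ = _sim(seed=3)
        d = build_design(data)
        spec = PenaltySpec(kind=kind, n_lambda=12)
        grid = resolve_lambda_grid(d, spec)
        coefs = elnet_path(d, spec)
        for theta, lam in zip(coefs, grid):
            assert kkt_residual(d, theta, lam, alpha) < 1e-5

    def test_ridge_norm_monotone_in_lambda(self):
        data, _, _ = _sim(seed=4)
        d = build_design(data)
        grid = np.logspace(2, -4, 25)
        coefs = elnet_path(d, PenaltySpec(kind="ridge", lambda_grid=grid))
        norms = [np.linalg.norm(c[d.n_unpenalized :]) for c in coefs]
        # grid is decreasing, so |B| must strictly increase
        assert np.all(np.diff(norms) > 0)

    def test_training_mse_non_decreasing_in_lambda(self):
        data, _, _ = _sim(seed=5)
        d = build_design(data)
        spec = PenaltySpec(kind="elnet", n_lambda=15)
        grid = resolve_lambda_grid(d, spec)
        coefs = elnet_path(d, spec)
        mse = [np.mean((d.y - d.X @ c) ** 2) for c in coefs]
        # grid decreasing -> MSE must be non-increasing down the path
        assert np.all(np.diff(mse) <= 1e-10)

    def test_ec_rescaling_invariance_with_standardization(self):
        data, _, _ = _sim(seed=6)
        fit1 = fit_gne(data, PenaltySpec(kind="elnet", lambda_grid=[0.05]), standardize=True)
        from penfactreg.data_model import align_and_validate

        data2, _, _ = _sim(seed=6)
        data2.ecs.values.iloc[:, 0] *= 10.0
        data2 = align_and_validate(data2.phenotypes, data2.ecs, test_envs=data2.test_envs)
        fit2 = fit_gne(data2, PenaltySpec(kind="elnet", lambda_grid=[0.05]), standardize=True)
        p1 = predict_goen(fit1, data.ecs, fit1.genotypes, data.test_envs)
        p2 = predict_goen(fit2, data2.ecs, fit2.genotypes, data2.test_envs)
        assert np.abs(p1.df["y_hat"].to_numpy() - p2.df["y_hat"].to_numpy()).max() < 1e-6
        # back-transformed slopes on the original scale differ by the rescaling
        assert np.allclose(
            fit1.B.iloc[:, 0].to_numpy(), fit2.B.iloc[:, 0].to_numpy() * 10.0, atol=1e-6
        )
        assert np.allclose(fit1.B.iloc[:, 1:].to_numpy(), fit2.B.iloc[:, 1:].to_numpy(), atol=1e-6)


class TestFolds:
    def test_stratified_whole_environments(self):
        data, _, _ = _sim(seed=7, n_e_train=25)
        folds = make_folds(data, CVScheme(mode="stratified", k=5, seed=1))
        envs = data.train_records["env"].to_numpy()
        env_fold = {}
        for e, f in zip(envs, folds):
            env_fold.setdefault(e, set()).add(f)
        assert all(len(s) == 1 for s in env_fold.values())
        sizes = pd.Series({e: next(iter(s)) for e, s in env_fold.items()}).value_counts()
        assert sorted(sizes) == [5, 5, 5, 5, 5]

    def test_random_leave_one_out(self):
        data, _, _ = _sim(seed=8, n_g=4, n_e_train=5, n_e_test=2)
        n = len(data.train_records)
        folds = make_folds(data, CVScheme(mode="random", k=n, seed=1))
        assert sorted(folds) == list(range(n))

    def test_same_seed_identical_folds(self):
        data, _, _ = _sim(seed=9)
        s = CVScheme(mode="random", k=7, seed=99)
        assert np.array_equal(make_folds(data, s), make_folds(data, s))

    def test_stratified_k_bound(self):
        data, _, _ = _sim(seed=10, n_e_train=5)
        with pytest.raises(ValidationError):
            make_folds(data, CVScheme(mode="stratified", k=6, seed=0))


class TestCVSelect:
    def test_single_lambda_grid_returned(self):
        data, _, _ = _sim(seed=11)
        d = build_design(data)
        lam, _ = cv_select_lambda(d, PenaltySpec(kind="ridge", lambda_grid=[0.3]), CVScheme(k=3, seed=0))
        assert lam == 0.3

    def test_large_lambda_cv_error_matches_additive_model(self):
        """At the all-zero-B end of the path the CV error is the additive model's."""
        data, _, _ = _sim(seed=12)
        d = build_design(data)
        lmax = lambda_max(d, 1.0)
        scheme = CVScheme(mode="random", k=4, seed=5)
        grid = np.array([lmax * 10.0, lmax * 1e-2])
        _, trace = cv_select_lambda(d, PenaltySpec(kind="lasso", lambda_grid=grid), scheme)
        # oracle: per-fold additive (main effects only) fit
        from penfactreg.engine import _fold_core, _main_effect_residuals

        folds = _fold_core([e for _, e in d.row_keys], d.environments, scheme)
        errs = []
        X = d.X.tocsr()
        p0 = d.n_unpenalized
        for f in range(4):
            tr = folds != f
            U = X[tr][:, :p0]
            theta_U = np.linalg.pinv(np.asarray((U.T @ U).todense())) @ (U.T @ d.y[tr])
            pred = X[~tr][:, :p0] @ theta_U
            errs.append(np.mean((d.y[~tr] - pred) ** 2))
        assert trace["cv_mean"].iloc[0] == pytest.approx(np.mean(errs), abs=1e-8)

    def test_pure_noise_selects_strong_penalty(self):
        """With no true sensitivities the CV choice should lean on the penalty."""
        hits_upper, hits_better = 0, 0
        for seed in range(10):
            cfg = SimConfig(
                n_g=40, n_e_train=40, n_e_test=10, n_c=15, n_active=0, seed=100 + seed
            )
            data, _, truth = simulate_met(cfg)
            d = build_design(data)
            spec = PenaltySpec(kind="ridge", n_lambda=30)
            grid = resolve_lambda_grid(d, spec)
            lam, _ = cv_select_lambda(d, spec, CVScheme(mode="stratified", k=5, seed=seed))
            if lam >= grid[len(grid) // 2]:
                hits_upper += 1
            # held-out test error: penalized vs unpenalized
            fit_pen = fit_gne(data, PenaltySpec(kind="ridge", lambda_grid=[lam]))
            fit_un = fit_gne(data, PenaltySpec(kind="ridge", lambda_grid=[1e-10]))
            gv = truth.genetic_values
            err = {}
            for name, f in (("pen", fit_pen), ("un", fit_un)):
                preds = predict_goen(f, data.ecs, f.genotypes, data.test_envs)
                merged = preds.df.assign(
                    truth=[
                        gv.loc[g, e] - truth.e[e]  # environment-centred truth
                        for g, e in zip(preds.df["genotype"], preds.df["env"])
                    ]
                )
                err[name] = np.mean((merged["y_hat"] - merged["truth"]) ** 2)
            if err["pen"] <= err["un"]:
                hits_better += 1
        assert hits_upper >= 9
        assert hits_better >= 9


class TestFitGnE:
    def test_default_penalty_is_equal_weight_elnet(self):
        data, _, _ = _sim(seed=13)
        fit = fit_gne(data, scheme=CVScheme(k=3, seed=0))
        assert fit.penalty.kind == "elnet"
        assert fit.penalty.alpha == 0.5

    def test_noise_free_ridge_recovers_sensitivities(self):
        cfg = SimConfig(
            n_g=10, n_e_train=60, n_e_test=5, n_c=4, n_active=4, h2=1.0, seed=14
        )
        data, _, truth = simulate_met(cfg)
        fit = fit_gne(data, PenaltySpec(kind="ridge", lambda_grid=[1e-8]))
        err = fit.B.to_numpy() - truth.B.to_numpy()
        assert np.sqrt(np.mean(err**2)) < 1e-3

    def test_genotype_relabeling_equivariance(self):
        data, _, _ = _sim(seed=15)
        fit1 = fit_gne(data, PenaltySpec(kind="elnet", lambda_grid=[0.02]))
        # rename genotypes (order preserved)
        ren = {g: f"X_{g}" for g in data.phenotypes.genotypes}
        pheno2 = data.phenotypes.df.assign(genotype=data.phenotypes.df["genotype"].map(ren))
        from penfactreg.data_model import ECTable, PhenotypeTable, align_and_validate

        p2 = PhenotypeTable.from_frame(pheno2)
        ecs2 = data.ecs.copy()
        ecs2.values = ecs2.values.rename(index=ren, level="genotype")
        data2 = align_and_validate(p2, ecs2, test_envs=data.test_envs)
        fit2 = fit_gne(data2, PenaltySpec(kind="elnet", lambda_grid=[0.02]))
        for g in data.phenotypes.genotypes:
            assert fit2.g[ren[g]] == pytest.approx(fit1.g[g], abs=1e-8)
        assert np.allclose(fit1.B.to_numpy(), fit2.B.to_numpy(), atol=1e-8)

    def test_deterministic_given_seed(self):
        data, _, _ = _sim(seed=16)
        f1 = fit_gne(data, PenaltySpec(kind="elnet", n_lambda=10), CVScheme(k=3, seed=4))
        f2 = fit_gne(data, PenaltySpec(kind="elnet", n_lambda=10), CVScheme(k=3, seed=4))
        assert f1.lambda_selected == f2.lambda_selected
        assert np.array_equal(f1.B.to_numpy(), f2.B.to_numpy())

    def test_save_load_round_trip(self, tmp_path):
        data, _, _ = _sim(seed=17)
        fit = fit_gne(data, PenaltySpec(kind="elnet", lambda_grid=[0.05]))
        fit.save(tmp_path / "fit")
        back = FRFit.load(tmp_path / "fit")
        assert back.mu == pytest.approx(fit.mu)
        assert back.g == pytest.approx(fit.g)
        pd.testing.assert_frame_equal(back.B, fit.B)
        preds1 = predict_goen(fit, data.ecs, fit.genotypes, data.test_envs)
        preds2 = predict_goen(back, data.ecs, back.genotypes, data.test_envs)
        assert np.allclose(preds1.df["y_hat"], preds2.df["y_hat"])
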