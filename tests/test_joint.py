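import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal, norm

from cogjoint import default_config
from cogjoint.cohort import assemble_cohort
from cogjoint.lmm import LMMSpec, build_design, fit_lmm_ml
from cogjoint.survival import define_dropout, fit_ph_baseline
from cogjoint.joint import (
    JointSpec,
    MCMCConfig,
    ParamSet,
    complete_loglik,
    dementia_only_outcomes,
    dic,
    fit_dementia_only,
    fit_joint_mcmc,
    marginal_loglik_quadrature,
    posterior_summary,
    predict_trajectory,
    prepare_joint_data,
    split_rhat,
)


def _prepared(seed=3, n=30, regime="MAR", spec=None, **cfg_kw):
    cfg = default_config(seed=seed, n_subjects=n, regime=regime, **cfg_kw)
    c = assemble_cohort(cfg)
    out = define_dropout(c.events, admin_end=cfg.admin_censor_time)
    spec = spec or JointSpec()
    data = prepare_joint_data(c.visits, c.baselines, c.exposures, out, spec)
    return c, out, data, spec


def _params(data, alpha=(0.0, 0.0, 0.0), gamma_val=0.0, sigma2=0.09):
    q = data.long.Z.shape[1]
    G = np.array([[0.5, -0.01, 0.0], [-0.01, 0.006, 0.0], [0.0, 0.0, 0.004]])[:q, :q]
    return ParamSet(
        beta=np.zeros(data.long.X.shape[1]),
        sigma2=sigma2,
        G=G,
        gamma=np.full(data.Xs.shape[1], gamma_val),
        rates=np.full(len(data.knots), 0.03),
        alpha=np.asarray(alpha, dtype=float)[:q],
    )


def _naive_subject_loglik(params, data, i, b):
    """Deliberately naive term-by-term re-implementation with scipy pdfs."""
    rows = data.long.groups == i
    Xi, Zi, yi = data.long.X[rows], data.long.Z[rows], data.long.y[rows]
    q = len(b)
    ll = norm.logpdf(yi, Xi @ params.beta + Zi @ b, np.sqrt(params.sigma2)).sum()
    eta = data.Xs[i] @ params.gamma + params.alpha[:q] @ b
    H0 = data.Epc[i] @ params.rates
    piece = min(np.searchsorted(data.knots, data.T[i], side="right") - 1,
                len(params.rates) - 1)
    if data.delta[i]:
        ll += np.log(params.rates[piece]) + eta
    ll -= np.exp(eta) * H0
    ll += multivariate_normal.logpdf(b, np.zeros(q), params.G[:q, :q])
    return ll


class TestCompleteLoglik:
    def test_matches_naive_reimplementation(self, rng):
        _, _, data, _ = _prepared()
        params = _params(data, alpha=(-0.3, -6.0, -3.0), gamma_val=0.2)
        for i in (0, 5, 11):
            b = rng.normal(0, 0.2, 3)
            assert complete_loglik(params, data, i, b) == pytest.approx(
                _naive_subject_loglik(params, data, i, b), abs=1e-10
            )

    def test_alpha_zero_factorizes_into_lmm_plus_survival(self, rng):
        _, _, data, _ = _prepared()
        p0 = _params(data, alpha=(0.0, 0.0, 0.0), gamma_val=0.1)
        b = rng.normal(0, 0.2, 3)
        i = 2
        total = complete_loglik(p0, data, i, b)
        rows = data.long.groups == i
        Xi, Zi, yi = data.long.X[rows], data.long.Z[rows], data.long.y[rows]
        lmm_term = norm.logpdf(yi, Xi @ p0.beta + Zi @ b, np.sqrt(p0.sigma2)).sum()
        lmm_term += multivariate_normal.logpdf(b, np.zeros(3), p0.G)
        surv = total - lmm_term
        # survival part does not depend on b when alpha is zero
        b2 = rng.normal(0, 0.2, 3)
        total2 = complete_loglik(p0, data, i, b2)
        lmm2 = norm.logpdf(yi, Xi @ p0.beta + Zi @ b2, np.sqrt(p0.sigma2)).sum()
        lmm2 += multivariate_normal.logpdf(b2, np.zeros(3), p0.G)
        assert total2 - lmm2 == pytest.approx(surv, abs=1e-10)

    def test_indefinite_G_rejected(self):
        _, _, data, _ = _prepared()
        params = _params(data)
        params.G = np.diag([1.0, -1.0, 1.0])
        with pytest.raises(ValueError):
            complete_loglik(params, data, 0, np.zeros(3))


class TestQuadrature:
    def test_gaussian_case_matches_closed_form(self):
        _, _, data, _ = _prepared()
        params = _params(data)
        ll = 0.0
        for i in range(data.n_subjects):
            rows = data.long.groups == i
            Xi, Zi, yi = data.long.X[rows], data.long.Z[rows], data.long.y[rows]
            V = Zi @ params.G @ Zi.T + params.sigma2 * np.eye(len(yi))
            ll += multivariate_normal.logpdf(yi, Xi @ params.beta, V)
            H0 = data.Epc[i] @ params.rates
            piece = min(np.searchsorted(data.knots, data.T[i], side="right") - 1,
                        len(params.rates) - 1)
            if data.delta[i]:
                ll += np.log(params.rates[piece])
            ll -= H0
        assert marginal_loglik_quadrature(params, data, 7) == pytest.approx(ll, abs=1e-8)

    def test_one_dimensional_toy_matches_trapezoid(self):
        spec = JointSpec(lmm=LMMSpec(random=("intercept",)), association="intercept")
        _, _, data, _ = _prepared(n=10, spec=spec)
        params = _params(data, alpha=(-1.5,), gamma_val=0.3)
        grid = np.linspace(-6, 6, 20001)
        brute = 0.0
        for i in range(data.n_subjects):
            f = np.array([
                complete_loglik(params, data, i, np.array([bb])) for bb in grid
            ])
            m = f.max()
            brute += m + np.log(np.trapezoid(np.exp(f - m), grid))
        agh = marginal_loglik_quadrature(params, data, 15)
        assert agh == pytest.approx(brute, abs=1e-6)

    def test_node_count_convergence(self):
        _, _, data, _ = _prepared(n=25, regime="MNAR")
        params = _params(data, alpha=(-0.5, -2.0, -1.0), gamma_val=0.2)
        v5 = marginal_loglik_quadrature(params, data, 5)
        v15 = marginal_loglik_quadrature(params, data, 15)
        assert abs(v5 - v15) < 1e-6

    def test_rejects_too_few_nodes(self):
        _, _, data, _ = _prepared(n=5)
        with pytest.raises(ValueError):
            marginal_loglik_quadrature(_params(data), data, 2)


class TestSampler:
    def test_same_seed_gives_identical_draws(self):
        _, _, data, spec = _prepared(n=60, regime="MNAR")
        mc = MCMCConfig(n_iter=300, n_burnin=150, seed=5)
        f1 = fit_joint_mcmc(data, spec, mc)
        f2 = fit_joint_mcmc(data, spec, mc)
        for k in f1.draws:
            np.testing.assert_array_equal(f1.draws[k], f2.draws[k])

    def test_refuses_post_dementia_records(self):
        cfg = default_config(seed=41, n_subjects=300, post_dementia_retention=0.9)
        c = assemble_cohort(cfg)
        out = define_dropout(c.events, admin_end=cfg.admin_censor_time)
        with pytest.raises(ValueError, match="exclude_post_dementia"):
            prepare_joint_data(c.visits, c.baselines, c.exposures, out, JointSpec())

    def test_association_none_matches_ml_lmm(self):
        cfg = default_config(seed=43, n_subjects=250, regime="MAR")
        c = assemble_cohort(cfg)
        out = define_dropout(c.events, admin_end=cfg.admin_censor_time)
        spec = JointSpec(association="none")
        data = prepare_joint_data(c.visits, c.baselines, c.exposures, out, spec)
        lfit = fit_lmm_ml(build_design(c.visits, c.baselines, c.exposures, spec.lmm),
                          spec.lmm)
        mc = MCMCConfig(n_iter=1500, n_burnin=750, seed=2)
        init = dict(beta=lfit.beta.to_numpy(), sigma2=lfit.sigma**2, G=lfit.G)
        fit = fit_joint_mcmc(data, spec, mc, init=init)
        est, lo, hi, _ = posterior_summary(fit, "time_since_exposure")
        sd = (hi - lo) / (2 * 1.96)
        ml = lfit.beta["time_since_exposure"]
        assert abs(est - ml) < 2 * sd
        # alpha stays fixed at zero under the factorized model
        assert np.all(fit.pooled("alpha") == 0.0)

    def test_sign_recovery_of_slope_association(self):
        """With strongly negative slope association in the generator, the
        posterior mass of alpha1 is predominantly negative."""
        cfg = default_config(seed=44, n_subjects=400)
        c = assemble_cohort(cfg)
        out = define_dropout(c.events, admin_end=cfg.admin_censor_time)
        spec = JointSpec()
        data = prepare_joint_data(c.visits, c.baselines, c.exposures, out, spec)
        ph = fit_ph_baseline(out, c.baselines, data.knots, spec.hazard_covariates)
        fit = fit_joint_mcmc(
            data, spec, MCMCConfig(n_iter=2000, n_burnin=1000, seed=4),
            init=dict(gamma=ph.gamma.to_numpy(), rates=ph.rates),
        )
        a1 = fit.pooled("alpha")[:, 1]
        assert (a1 < 0).mean() > 0.8


class TestOracleEquivalence:
    def test_quadrature_map_matches_mcmc_posterior_mean(self):
        """Maximizing the quadrature marginal likelihood (the independent
        oracle) reproduces the long-run MCMC posterior location on a small
        random-intercept cohort."""
        from scipy import optimize

        spec = JointSpec(lmm=LMMSpec(covariates=("mci",), interactions=(),
                                     random=("intercept",)),
                         hazard_covariates=("mci",),
                         n_hazard_pieces=2, association="intercept")
        cfg = default_config(seed=45, n_subjects=80,
                             alpha=(-1.0, 0.0, 0.0),
                             hazard_knots=[0.0], hazard_rates=[0.06])
        c = assemble_cohort(cfg)
        out = define_dropout(c.events, admin_end=cfg.admin_censor_time)
        data = prepare_joint_data(c.visits, c.baselines, c.exposures, out, spec)
        K = len(data.knots)
        p = data.long.X.shape[1]

        def unpack(th):
            return ParamSet(
                beta=th[:p], sigma2=np.exp(th[p]),
                G=np.array([[np.exp(th[p + 1])]]),
                gamma=th[p + 2: p + 3],
                rates=np.exp(th[p + 3: p + 3 + K]),
                alpha=th[p + 3 + K: p + 4 + K],
            )

        def neg(th):
            try:
                return -marginal_loglik_quadrature(unpack(th), data, 9)
            except np.linalg.LinAlgError:
                return 1e10

        th0 = np.concatenate([np.zeros(p), [np.log(0.09)], [np.log(0.5)], [0.0],
                              np.log(np.full(K, 0.05)), [0.0]])
        res = optimize.minimize(neg, th0, method="Nelder-Mead",
                                options={"maxiter": 6000, "xatol": 1e-6,
                                         "fatol": 1e-8})
        map_params = unpack(res.x)

        fit = fit_joint_mcmc(data, spec, MCMCConfig(n_iter=4000, n_burnin=2000,
                                                    seed=11))
        post = fit.posterior_mean_params()
        # posterior mean vs penalized mode differ at O(1/n) on an 80-subject
        # cohort; agreement is asserted at that small-sample tolerance
        np.testing.assert_allclose(post.beta, map_params.beta, atol=0.12)
        assert post.sigma2 == pytest.approx(map_params.sigma2, rel=0.15)
        assert post.G[0, 0] == pytest.approx(map_params.G[0, 0], rel=0.3)
        assert post.alpha[0] == pytest.approx(map_params.alpha[0], abs=0.5)


class TestPosteriorSummary:
    def test_constant_draws(self):
        x = np.full(100, 3.2)
        from cogjoint.joint import _summarize_draws

        est, lo, hi, p = _summarize_draws(x)
        assert est == pytest.approx(3.2, rel=1e-12)
        assert (lo, hi) == (3.2, 3.2)
        assert p == 0.0

    def test_symmetric_draws_give_p_near_one(self, rng):
        x = np.concatenate([rng.normal(0, 1, 5000), -rng.normal(0, 1, 5000)])
        from cogjoint.joint import _summarize_draws

        *_, p = _summarize_draws(x)
        assert p == pytest.approx(1.0, abs=0.05)

    def test_standard_normal_interval(self, rng):
        from cogjoint.joint import _summarize_draws

        x = rng.standard_normal(1_000_000)
        _, lo, hi, _ = _summarize_draws(x)
        assert lo == pytest.approx(-1.959964, abs=0.01)
        assert hi == pytest.approx(1.959964, abs=0.01)

    def test_unknown_parameter_raises(self):
        _, _, data, spec = _prepared(n=40)
        fit = fit_joint_mcmc(data, spec, MCMCConfig(n_iter=120, n_burnin=60, seed=1))
        with pytest.raises(KeyError):
            posterior_summary(fit, "nonexistent")


class TestSplitRhat:
    def test_well_mixed_chains_near_one(self, rng):
        x = rng.standard_normal((4, 2000))
        assert split_rhat(x) == pytest.approx(1.0, abs=0.02)

    def test_matches_arviz(self, rng):
        import arviz as az

        x = rng.standard_normal((2, 1000)).cumsum(axis=1) * 0.01 + rng.standard_normal((2, 1000))
        ours = split_rhat(x)
        ref = float(az.rhat(az.convert_to_dataset(x[None].transpose(1, 2, 0)))["x"].values) \
            if False else float(az.rhat(az.convert_to_dataset(x))["x"].values)
        assert ours == pytest.approx(ref, rel=0.02)


class TestTrajectories:
    def _beta(self):
        spec = LMMSpec(covariates=("mci",), interactions=("mci",))
        beta = pd.Series(
            {"intercept": 0.4, "mci": -1.0, "time": -0.05, "mci:time": -0.02,
             "time_since_exposure": -0.08}
        )
        return beta, spec

    def test_straight_line_without_exposure(self, toy_baselines):
        beta, spec = self._beta()
        grid = np.linspace(0, 8, 33)
        tr = predict_trajectory(beta, spec, toy_baselines.iloc[[0]], None, grid)
        slopes = np.diff(tr["z"]) / np.diff(tr["t"])
        np.testing.assert_allclose(slopes, -0.05, atol=1e-12)

    def test_kink_at_exposure_equals_coefficient(self, toy_baselines):
        beta, spec = self._beta()
        grid = np.linspace(0, 8, 81)  # step 0.1, kink at index 20
        tr = predict_trajectory(beta, spec, toy_baselines.iloc[[2]], 2.0, grid)
        z = tr["z"].to_numpy()
        pre = (z[20] - z[19]) / 0.1
        post = (z[22] - z[21]) / 0.1
        assert post - pre == pytest.approx(-0.08, abs=1e-9)

    def test_scenarios_coincide_before_exposure(self, toy_baselines):
        beta, spec = self._beta()
        grid = np.linspace(0, 8, 41)
        none = predict_trajectory(beta, spec, toy_baselines.iloc[[1]], None, grid)
        at2 = predict_trajectory(beta, spec, toy_baselines.iloc[[1]], 2.0, grid)
        pre = grid <= 2.0
        np.testing.assert_allclose(none["z"][pre], at2["z"][pre], atol=1e-12)
        assert (none["z"][~pre].to_numpy() > at2["z"][~pre].to_numpy()).all()

    def test_grid_beyond_horizon_rejected(self, toy_baselines):
        beta, spec = self._beta()
        with pytest.raises(ValueError, match="extrapolation"):
            predict_trajectory(beta, spec, toy_baselines.iloc[[0]], None,
                               np.linspace(0, 12, 5))

    def test_unknown_covariate_level_rejected(self, toy_baselines):
        beta = pd.Series({"intercept": 0.0, "educ_ge16": 0.1, "time": -0.05,
                          "time_since_exposure": -0.08})
        spec = LMMSpec(covariates=("educ_ge16",), interactions=())
        bad = toy_baselines.iloc[[0]].copy()
        bad["education_level"] = "phd"
        with pytest.raises(ValueError, match="level"):
            predict_trajectory(beta, spec, bad, None, np.linspace(0, 5, 3))


class TestDementiaOnly:
    def test_event_count_matches_brute_force(self):
        cfg = default_config(seed=46, n_subjects=500, p_dementia=0.4)
        c = assemble_cohort(cfg)
        out = define_dropout(c.events, admin_end=cfg.admin_censor_time)
        dem = dementia_only_outcomes(out)
        brute = int((out["cause"] == "dementia").sum())
        assert int((dem["status"] == "event").sum()) == brute
        # death dropouts are censored at their event time
        died = out["cause"] == "death"
        assert (dem.loc[died, "status"] == "censored").all()
        assert np.allclose(dem.loc[died, "time"], out.loc[died, "time"])

    def test_no_death_events_equals_composite_fit(self):
        cfg = default_config(seed=47, n_subjects=120, p_dementia=1.0)
        c = assemble_cohort(cfg)
        out = define_dropout(c.events, admin_end=cfg.admin_censor_time)
        spec = JointSpec()
        mc = MCMCConfig(n_iter=300, n_burnin=150, seed=9)
        data = prepare_joint_data(c.visits, c.baselines, c.exposures, out, spec)
        composite = fit_joint_mcmc(data, spec, mc)
        demfit = fit_dementia_only(c.visits, c.baselines, c.exposures, out, spec, mc)
        for k in composite.draws:
            np.testing.assert_array_equal(composite.draws[k], demfit.draws[k])

    def test_zero_dementia_events_rejected(self):
        cfg = default_config(seed=48, n_subjects=150, p_dementia=0.0)
        c = assemble_cohort(cfg)
        out = define_dropout(c.events, admin_end=cfg.admin_censor_time)
        with pytest.raises(ValueError, match="dementia"):
            dementia_only_outcomes(out)


class TestDIC:
    def test_pd_nonnegative_and_association_selection(self):
        cfg = default_config(seed=49, n_subjects=250)
        c = assemble_cohort(cfg)
        out = define_dropout(c.events, admin_end=cfg.admin_censor_time)
        mc = MCMCConfig(n_iter=1500, n_burnin=750, seed=6)
        results = {}
        for assoc in ("none", "full"):
            spec = JointSpec(association=assoc)
            data = prepare_joint_data(c.visits, c.baselines, c.exposures, out, spec)
            ph = fit_ph_baseline(out, c.baselines, data.knots, spec.hazard_covariates)
            fit = fit_joint_mcmc(data, spec, mc,
                                 init=dict(gamma=ph.gamma.to_numpy(), rates=ph.rates))
            results[assoc] = dic(fit, data, n_draws=25, n_nodes=5)
        assert results["full"]["pD"] >= 0
        assert np.isfinite(results["none"]["dic"])
        # data generated with all three associations active prefer the full model
        assert results["full"]["dic"] < results["none"]["dic"]
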