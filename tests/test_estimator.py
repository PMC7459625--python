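"""Maximum-likelihood fitting, inference conventions and model selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from locomix import (
    ActivityNLMM,
    FULL_NLMM,
    OPTIMAL_NLMM,
    ModelSpec,
    SimulationDesign,
    VarianceComponents,
    fit,
    one_sided_p,
    select_model,
    simulate_panel,
    wald_interval,
)
from locomix.estimator import FitResult, observed_information
from locomix.model import log_likelihood

from conftest import REF_DELTA, REF_THETA


class TestFit:
    def test_near_noiseless_recovery(self):
        design = SimulationDesign(
            delta=VarianceComponents(0.0, 0.0, 1e-8), seed=4
        )
        truth = simulate_panel(design)
        result = fit(truth.panel, OPTIMAL_NLMM, compute_se=False)
        assert result.converged
        assert result.theta.xi0 == pytest.approx(REF_THETA.xi0, abs=1e-3)
        assert result.theta.beta1 == pytest.approx(REF_THETA.beta1, abs=1e-3)
        assert result.theta.beta2 == pytest.approx(REF_THETA.beta2, abs=1e-3)

    def test_nlrm_loglik_never_exceeds_nlmm(self, default_panel, optimal_fit):
        nlrm = fit(default_panel,
                   ModelSpec(free_xi1=False, free_xi2=False,
                             free_omega2=False, mixed=False),
                   compute_se=False)
        assert nlrm.loglik <= optimal_fit.loglik

    def test_information_criterion_identities(self, optimal_fit):
        assert optimal_fit.aic == pytest.approx(
            -2 * optimal_fit.loglik + 2 * optimal_fit.k_params
        )
        assert optimal_fit.bic == pytest.approx(
            -2 * optimal_fit.loglik
            + optimal_fit.k_params * np.log(optimal_fit.n_obs)
        )
        assert optimal_fit.k_params == 7

    def test_row_order_invariance(self, default_panel, optimal_fit):
        shuffled = default_panel.sample(frac=1, random_state=3)
        refit = fit(shuffled, OPTIMAL_NLMM, compute_se=False)
        assert refit.loglik == pytest.approx(optimal_fit.loglik, abs=1e-6)
        assert refit.theta.beta1 == pytest.approx(
            optimal_fit.theta.beta1, abs=1e-6
        )

    def test_warm_start_is_a_fixed_point(self, default_panel, optimal_fit):
        init = {n: optimal_fit.estimate(n)
                for n in optimal_fit.param_names}
        warm = fit(default_panel, OPTIMAL_NLMM, init=init, compute_se=False)
        assert abs(-2 * warm.loglik - (-2 * optimal_fit.loglik)) < 1e-6

    def test_profile_refit_of_theta_reproduces_theta_hat(
        self, default_panel, optimal_fit
    ):
        # fix the variance components at their estimates and re-optimize
        # the fixed effects only: theta_hat must be reproduced
        delta = optimal_fit.delta
        names = optimal_fit.spec.free_fixed

        def nll(x):
            values = dict(zip(names, x))
            values["omega1"] = np.exp(values["omega1"])
            theta = optimal_fit.theta.replace(
                **{n: values[n] for n in names}
            )
            return -log_likelihood(default_panel, theta, delta)

        x0 = np.array(
            [np.log(optimal_fit.estimate(n)) if n == "omega1"
             else optimal_fit.estimate(n) for n in names]
        )
        res = optimize.minimize(nll, x0, method="L-BFGS-B")
        assert res.fun == pytest.approx(-optimal_fit.loglik, abs=1e-6)
        refit = dict(zip(names, res.x))
        assert refit["xi0"] == pytest.approx(optimal_fit.theta.xi0, abs=1e-5)
        assert refit["beta1"] == pytest.approx(
            optimal_fit.theta.beta1, abs=1e-5
        )

    def test_single_dose_group_is_singular(self):
        truth = simulate_panel(SimulationDesign(seed=1))
        panel = truth.panel.assign(dose_gy=2.0)
        with pytest.raises(ValueError, match="singular design"):
            fit(panel, FULL_NLMM)

    def test_sklearn_estimator_interface(self, default_panel):
        est = ActivityNLMM(free_xi1=False, free_xi2=False,
                           free_omega2=False, compute_se=False)
        params = est.get_params()
        assert params["mixed"] is True and params["d0"] == 2.75
        X = default_panel[["animal_id", "day", "dose_gy"]]
        est.fit(X, default_panel["log_activity"])
        assert hasattr(est, "theta_") and est.converged_
        pred = est.predict(X)
        assert pred.shape == (len(default_panel),)
        # predictions are the fitted mean, so R^2 against data is positive
        assert est.score(X, default_panel["log_activity"]) > 0

    def test_array_design_matches_dataframe(self, default_panel, optimal_fit):
        codes = pd.factorize(default_panel["animal_id"], sort=True)[0]
        X = np.column_stack(
            [codes, default_panel["day"], default_panel["dose_gy"]]
        )
        est = ActivityNLMM(free_xi1=False, free_xi2=False,
                           free_omega2=False, compute_se=False)
        est.fit(X, default_panel["log_activity"].to_numpy())
        assert est.loglik_ == pytest.approx(optimal_fit.loglik, abs=1e-6)


class TestInference:
    @pytest.mark.parametrize(
        "est,se,lo,hi",
        [
            (9.063, 2.949, 3.283, 14.843),
            (0.0, 1.0, -1.960, 1.960),
            (0.066, 0.016, 0.035, 0.097),
        ],
    )
    def test_wald_interval(self, est, se, lo, hi):
        got = wald_interval(est, se)
        assert round(got[0], 3) == pytest.approx(lo, abs=5e-4)
        assert round(got[1], 3) == pytest.approx(hi, abs=5e-4)

    @pytest.mark.parametrize(
        "est,se,p",
        [
            (0.082, 0.166, 0.311),
            (0.0, 1.0, 0.5),
            (-0.008, 0.022, 0.358),
        ],
    )
    def test_one_sided_p(self, est, se, p):
        assert one_sided_p(est, se) == pytest.approx(p, abs=1e-3)

    def test_one_sided_p_is_symmetric_in_sign(self):
        assert one_sided_p(0.5, 0.2) == one_sided_p(-0.5, 0.2)

    def test_invalid_se_rejected(self):
        with pytest.raises(ValueError):
            wald_interval(1.0, 0.0)
        with pytest.raises(ValueError):
            one_sided_p(1.0, -1.0)

    def test_quadratic_toy_loglik_se_is_inverse_root_curvature(self):
        # loglik = -0.5 * c * x^2 -> information c -> SE = c^{-1/2}
        c = 4.0
        info = observed_information(lambda x: -0.5 * c * x[0] ** 2,
                                    np.array([0.0]))
        assert 1.0 / np.sqrt(info[0, 0]) == pytest.approx(0.5, rel=1e-6)

    def test_se_calibration_against_replicates(self):
        # empirical SD of beta1 across replicates within 25% of the mean
        # reported SE
        from locomix import recovery_experiment

        rr = recovery_experiment(SimulationDesign(), 40, seed=11)
        # re-derive mean reported SE from a couple of fits
        ses = []
        for s in (101, 202, 303):
            truth = simulate_panel(SimulationDesign(seed=s))
            ses.append(fit(truth.panel, OPTIMAL_NLMM).se["beta1"])
        mean_se = float(np.mean(ses))
        emp_sd = float(rr.summary.loc["beta1", "sd"])
        assert abs(emp_sd - mean_se) / mean_se < 0.25


class TestModelSelection:
    def test_table_identities_and_nesting(self, default_panel):
        sel = select_model(default_panel, mixed=True)
        t = sel.table
        assert len(t) == 16
        np.testing.assert_allclose(
            t["aic"], -2 * t["loglik"] + 2 * t["k"], rtol=1e-12
        )
        assert (t["aic"].diff().dropna() >= -1e-9).all()  # sorted by AIC
        full_ll = t.loc[t["spec"] == "NLMM:xi1+xi2+beta2+omega2",
                        "loglik"].iloc[0]
        assert (full_ll >= t["loglik"] - 1e-6).all()

    def test_tie_break_prefers_fewer_parameters(self):
        a = FitResult(
            spec=ModelSpec(free_xi1=False, free_xi2=False, free_beta2=False,
                           free_omega2=False),
            theta=REF_THETA, delta=REF_DELTA, loglik=10.0, aic=-8.0,
            bic=-8.0, n_obs=10, k_params=6, converged=True,
        )
        b = FitResult(
            spec=ModelSpec(free_xi1=True, free_xi2=False, free_beta2=False,
                           free_omega2=False),
            theta=REF_THETA, delta=REF_DELTA, loglik=11.0, aic=-8.0,
            bic=-8.0, n_obs=10, k_params=7, converged=True,
        )
        best = min([b, a], key=lambda f: (f.aic, f.k_params, f.spec.label))
        assert best is a


class TestFitResultSerialisation:
    def test_json_round_trip(self, optimal_fit):
        d = optimal_fit.to_json_dict()
        back = FitResult.from_json_dict(d)
        assert back.spec == optimal_fit.spec
        assert back.loglik == pytest.approx(optimal_fit.loglik)
        assert back.theta == optimal_fit.theta
        pd.testing.assert_frame_equal(back.cov_params,
                                      optimal_fit.cov_params)

    def test_table_layout(self, optimal_fit):
        t = optimal_fit.table()
        assert list(t["parameter"]) == [
            "xi0", "beta1", "beta2", "omega1", "psi2", "phi2", "sigma2"
        ]
        assert {"estimate", "se", "ci_lower", "ci_upper",
                "p_value"} <= set(t.columns)
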