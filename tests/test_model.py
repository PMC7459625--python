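"""Mean function, crossed covariance and likelihood against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from locomix import (
    FixedEffects,
    VarianceComponents,
    ModelSpec,
    covariance_matrix,
    heaviside,
    log_likelihood,
    mean_activity,
    q_objective,
)
from locomix.model import OPTIMAL_NLMM, FULL_NLMM, params_from_dict, params_to_dict

from conftest import REF_DELTA, REF_THETA, small_panel


class TestMeanFunction:
    @pytest.mark.parametrize("t,expected", [(-1, 0.0), (0, 1.0), (20, 1.0)])
    def test_heaviside_step(self, t, expected):
        assert heaviside(t) == expected

    def test_pre_irradiation_is_pure_polynomial(self):
        theta = FixedEffects(xi0=4.0, xi1=0.1, xi2=-0.01, beta1=1.0,
                             beta2=1.0, omega1=2.0)
        assert mean_activity(-2, 5.0, theta) == pytest.approx(
            4.0 + 0.1 * (-2) + (-0.01) * 4
        )

    def test_controls_unaffected_by_decrease_term(self):
        theta = FixedEffects(xi0=4.0, xi1=0.1, xi2=-0.01, beta1=1.0,
                             beta2=1.0, omega1=2.0)
        assert mean_activity(5, 0.0, theta) == pytest.approx(
            4.0 + 0.5 - 0.25
        )

    def test_reference_value_at_day_zero_dose_five(self):
        # hand evaluation: 4.319 - (0.066*5 - 0.006*25) = 4.139
        assert mean_activity(0, 5.0, REF_THETA) == pytest.approx(4.139)

    def test_jump_at_irradiation_equals_initial_decrease(self):
        theta = REF_THETA
        d = 3.5
        jump = mean_activity(-1e-9, d, theta) - mean_activity(0.0, d, theta)
        assert jump == pytest.approx(0.066 * d - 0.006 * d * d, abs=1e-6)
        # controls: single polynomial, no jump
        assert mean_activity(-1e-9, 0.0, theta) == pytest.approx(
            mean_activity(0.0, 0.0, theta)
        )

    def test_dose_independent_recovery_when_omega2_zero(self):
        theta = REF_THETA  # omega2 = 0
        from locomix.model import recovery_rate

        assert recovery_rate(0.0, theta) == recovery_rate(5.0, theta) == 9.063


class TestCovariance:
    def test_single_cell(self):
        delta = VarianceComponents(1.0, 2.0, 4.0)
        omega = covariance_matrix([0], [0], delta)
        assert omega.shape == (1, 1)
        assert omega[0, 0] == 7.0

    def test_two_by_two_entry_classes(self):
        # brute-force from the decomposition y - f = delta_i + eta_t + eps
        delta = VarianceComponents(1.0, 2.0, 4.0)
        a = np.array([0, 0, 1, 1])
        d = np.array([0, 1, 0, 1])
        omega = covariance_matrix(a, d, delta)
        assert np.all(np.diag(omega) == 7.0)
        assert omega[0, 1] == 1.0  # same animal, different day
        assert omega[0, 2] == 2.0  # same day, different animal
        assert omega[0, 3] == 0.0  # different both

    def test_full_design_matches_kronecker_form(self):
        # entrywise rule vs I_a (x) (psi2 J_d + sigma2 I_d) + phi2 (J_a (x) I_d)
        na, nd = 16, 24
        a = np.repeat(np.arange(na), nd)
        d = np.tile(np.arange(nd), na)
        omega = covariance_matrix(a, d, REF_DELTA)
        kron = (
            np.kron(np.eye(na),
                    REF_DELTA.psi2 * np.ones((nd, nd))
                    + REF_DELTA.sigma2 * np.eye(nd))
            + REF_DELTA.phi2 * np.kron(np.ones((na, na)), np.eye(nd))
        )
        np.testing.assert_allclose(omega, kron, rtol=0, atol=0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        psi2=st.floats(0, 5),
        phi2=st.floats(0, 5),
        sigma2=st.floats(1e-3, 5),
    )
    def test_positive_definite_whenever_sigma2_positive(self, psi2, phi2,
                                                        sigma2):
        delta = VarianceComponents(psi2, phi2, sigma2)
        a = np.repeat(np.arange(3), 4)
        d = np.tile(np.arange(4), 3)
        omega = covariance_matrix(a, d, delta)
        np.linalg.cholesky(omega)  # raises if not PD

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError, match="psi2"):
            VarianceComponents(-1.0, 0.0, 1.0)


class TestLikelihood:
    def test_matches_dense_gaussian_oracle_on_random_panels(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            panel = small_panel(seed=rng.integers(1 << 30))
            theta = FixedEffects(
                xi0=4.3 + rng.normal(0, 0.1),
                xi1=rng.normal(0, 0.02),
                beta1=abs(rng.normal(0.05, 0.02)),
                omega1=abs(rng.normal(1, 0.5)) + 0.1,
            )
            delta = VarianceComponents(*np.abs(rng.normal(0.1, 0.05, 3)) + 1e-3)
            ours = log_likelihood(panel, theta, delta)
            mu = mean_activity(panel["day"].to_numpy(),
                               panel["dose_gy"].to_numpy(), theta)
            a = pd.factorize(panel["animal_id"], sort=True)[0]
            d = pd.factorize(panel["day"], sort=True)[0]
            ref = stats.multivariate_normal.logpdf(
                panel["log_activity"], mean=mu,
                cov=covariance_matrix(a, d, delta),
            )
            assert ours == pytest.approx(ref, rel=1e-12)

    def test_nlrm_limit_is_sum_of_univariate_densities(self):
        panel = small_panel(seed=11)
        theta = FixedEffects(xi0=4.3, beta1=0.05, omega1=1.0)
        delta = VarianceComponents(0.0, 0.0, 0.04)
        mu = mean_activity(panel["day"].to_numpy(),
                           panel["dose_gy"].to_numpy(), theta)
        ref = stats.norm.logpdf(panel["log_activity"], mu, 0.2).sum()
        assert log_likelihood(panel, theta, delta) == pytest.approx(
            ref, rel=1e-12
        )

    def test_loglik_at_exact_mean_is_normalisation_only(self):
        panel = small_panel(seed=3)
        theta = FixedEffects(xi0=4.3, beta1=0.05, omega1=1.0)
        delta = VarianceComponents(0.5, 0.25, 1.0)
        mu = mean_activity(panel["day"].to_numpy(),
                           panel["dose_gy"].to_numpy(), theta)
        panel = panel.assign(log_activity=mu)
        a = pd.factorize(panel["animal_id"], sort=True)[0]
        d = pd.factorize(panel["day"], sort=True)[0]
        omega = covariance_matrix(a, d, delta)
        expected = -0.5 * (np.linalg.slogdet(omega)[1]
                           + len(panel) * np.log(2 * np.pi))
        assert log_likelihood(panel, theta, delta) == pytest.approx(expected)

    def test_balanced_fast_path_equals_dense(self, default_panel):
        ll_auto = log_likelihood(default_panel, REF_THETA, REF_DELTA)
        ll_dense = log_likelihood(default_panel, REF_THETA, REF_DELTA,
                                  method="dense")
        assert ll_auto == pytest.approx(ll_dense, rel=1e-12)

    def test_singular_covariance_names_component(self):
        panel = small_panel()
        with pytest.raises(ValueError, match="sigma2"):
            log_likelihood(panel, REF_THETA,
                           VarianceComponents(0.1, 0.1, 0.0))


class TestQObjective:
    def test_q_is_minus_two_loglik(self):
        panel = small_panel(seed=4)
        q = q_objective(panel, REF_THETA, REF_DELTA)
        ll = log_likelihood(panel, REF_THETA, REF_DELTA)
        assert q + 2 * ll == pytest.approx(0.0, abs=1e-9)

    def test_diagonal_closed_form(self):
        panel = small_panel(seed=9)
        theta = FixedEffects(xi0=4.3, beta1=0.05, omega1=1.0)
        sigma2 = 0.02
        mu = mean_activity(panel["day"].to_numpy(),
                           panel["dose_gy"].to_numpy(), theta)
        rss = float(((panel["log_activity"] - mu) ** 2).sum())
        n = len(panel)
        expected = n * np.log(2 * np.pi) + n * np.log(sigma2) + rss / sigma2
        q = q_objective(panel, theta, VarianceComponents(0, 0, sigma2))
        assert q == pytest.approx(expected, rel=1e-12)

    def test_perturbing_data_away_from_mean_increases_q(self):
        panel = small_panel(seed=2)
        theta = FixedEffects(xi0=4.3, beta1=0.05, omega1=1.0)
        mu = mean_activity(panel["day"].to_numpy(),
                           panel["dose_gy"].to_numpy(), theta)
        exact = panel.assign(log_activity=mu)
        shifted = panel.assign(log_activity=mu + 0.1)
        assert q_objective(shifted, theta, REF_DELTA) > q_objective(
            exact, theta, REF_DELTA
        )


class TestModelSpec:
    def test_parameter_counts(self):
        assert FULL_NLMM.k_params == 10
        assert OPTIMAL_NLMM.k_params == 7
        assert ModelSpec(mixed=False).k_params == 8
        assert OPTIMAL_NLMM.free_fixed == ("xi0", "beta1", "beta2", "omega1")

    def test_sixteen_candidates_per_mixed_flag(self):
        cands = ModelSpec.all_candidates(mixed=True)
        assert len(cands) == 16
        assert len({c.label for c in cands}) == 16

    def test_params_roundtrip_serialisation(self):
        d = params_to_dict(REF_THETA, REF_DELTA)
        assert d["D0"] == 2.75 and d["beta1"] == 0.066
        theta, delta = params_from_dict(d)
        assert theta == REF_THETA and delta == REF_DELTA
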