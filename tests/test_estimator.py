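"""Time-resolved MR estimator: exact identities and quadrature/variance oracles."""

import numpy as np
import pytest
from scipy import stats

import chronomr as cm
from chronomr.aalen import YearlyIncrements
from chronomr.estimator import WeakInstrumentError, effect_series
from chronomr.instrument import InstrumentEffectFunction
from chronomr.presets import validation_config


def make_incr(H, s2=None, events=None):
    H = np.asarray(H, dtype=float)
    K = H.size
    return YearlyIncrements(
        years=np.arange(1, K + 1),
        H_hat=H,
        sigma2=np.zeros(K) if s2 is None else np.asarray(s2, dtype=float),
        events_in_bin=np.ones(K, dtype=int) if events is None else events,
        covariate="instrument",
    )


def const_beta(value, kind="constant"):
    coeffs = {"constant": [value], "linear": [value, 0.0], "quartic": [value, 0.0, 0.0]}
    k = len(coeffs[kind])
    return InstrumentEffectFunction(
        model_kind=kind,
        coefficients=np.array(coeffs[kind]),
        covariance=np.zeros((k, k)),
        n=1,
        age_domain=(0.0, 100.0),
    )


def quartic_beta(a, b, c):
    return InstrumentEffectFunction(
        model_kind="quartic",
        coefficients=np.array([a, b, c]),
        covariance=np.zeros((3, 3)),
        n=1,
        age_domain=(0.0, 100.0),
    )


class TestMomentaneous:
    def test_zero_increments_give_zero_gamma(self):
        g, v = cm.momentaneous_effects(make_incr(np.zeros(30)), const_beta(0.2))
        assert np.all(g == 0) and np.all(v == 0)

    def test_constant_beta_is_elementwise_division(self, rng):
        H = rng.normal(size=40)
        g, _ = cm.momentaneous_effects(make_incr(H), const_beta(0.25))
        dH = np.diff(np.concatenate([[0.0], H]))
        assert np.allclose(g, dH / 0.25, rtol=1e-14)

    def test_analytic_hazard_series_recovers_power_law(self):
        # exact H(t_k) = sum_{j<=k} gamma(j-1/2) beta_G(j-1/2) with the
        # validation-scenario quartic; the Wald-ratio gradient returns
        # gamma at midpoints exactly, so Gamma_mid matches c T^5/5 up to
        # the O(dt^2) midpoint-rule error
        cfg = validation_config()
        K = 80
        mids = np.arange(1, K + 1) - 0.5
        gam = cfg.gamma(mids)
        bet = cfg.beta_g(mids)
        H = np.cumsum(gam * bet)
        beta_fit = quartic_beta(*cfg.beta_g_coeffs)
        g, _ = cm.momentaneous_effects(make_incr(H), beta_fit)
        assert np.allclose(g, gam, rtol=1e-12)
        G = cm.cumulative_midpoint(g)
        T = np.arange(1, K + 1, dtype=float)
        truth = cfg.gamma_scale * T**5 / 5.0
        assert np.allclose(G, truth, rtol=2e-3)

    def test_weak_instrument_floor_names_ages(self):
        beta = quartic_beta(0.3, -9e-4, -5.8e-9)  # crosses zero near age 80
        with pytest.raises(WeakInstrumentError, match="ages"):
            cm.momentaneous_effects(make_incr(np.zeros(80)), beta)

    def test_variance_per_yearly_sigmas(self):
        s2 = np.array([1.0, 2.0, 3.0])
        _, v = cm.momentaneous_effects(make_incr(np.zeros(3), s2), const_beta(0.5))
        assert np.allclose(v, np.array([1.0, 3.0, 5.0]) / 0.25)


class TestCumulativeRules:
    def test_midpoint_is_running_sum(self):
        g = np.array([1.0, -1.0, 1.0, -1.0])
        assert np.allclose(cm.cumulative_midpoint(g), [1.0, 0.0, 1.0, 0.0])

    def test_constant_gamma_midpoint_linear(self):
        G = cm.cumulative_midpoint(np.full(10, 0.5))
        assert np.allclose(G, 0.5 * np.arange(1, 11))

    def test_trapezoid_matches_literal_formula(self, rng):
        # literal transcription: 1/4 g1 + 1/2 g1 + sum_{i=2}^{k-1} g_i + 1/2 g_k
        g = rng.normal(size=25)
        got = cm.cumulative_trapezoid(g)
        for k in range(1, 26):
            if k == 1:
                want = g[0] / 4.0
            else:
                want = 0.25 * g[0] + 0.5 * g[0] + g[1 : k - 1].sum() + 0.5 * g[k - 1]
            assert got[k - 1] == pytest.approx(want, rel=1e-12, abs=1e-15)

    def test_trapezoid_constant_gamma_closed_form(self):
        g = cm.cumulative_trapezoid(np.full(30, 2.0))
        k = np.arange(1, 31)
        assert np.allclose(g[1:], 2.0 * (k[1:] - 0.75))

    def test_zero_gamma_gives_zero(self):
        assert np.all(cm.cumulative_trapezoid(np.zeros(12)) == 0)

    def test_trapezoid_quadrature_error_second_order(self):
        # smooth gamma: trapezoid evaluated at midpoints approximates the
        # integral to O(dt^2)
        t = np.arange(1, 81) - 0.5
        g = (t / 40.0) ** 3
        got = cm.cumulative_trapezoid(g)
        exact = (t / 40.0) ** 4 * 40.0 / 4.0  # integral from 0 to t_{k-1/2}
        assert np.max(np.abs(got - exact)) < 0.02 * exact.max()

    def test_constant_beta_exact_telescoping_reduction(self, rng):
        # when beta_G is constant, Gamma_mid(t_k) = H_hat(t_k)/beta exactly
        H = np.cumsum(rng.normal(size=60))
        incr = make_incr(H)
        beta = const_beta(0.31, kind="quartic")
        g, _ = cm.momentaneous_effects(incr, beta)
        G = cm.cumulative_midpoint(g)
        assert np.allclose(G, H / 0.31, rtol=1e-12)
        # and the two naive comparators coincide with it
        assert np.allclose(cm.naive_wald_constant(incr, 0.31), G, rtol=1e-12)
        assert np.allclose(cm.naive_wald_timevarying(incr, beta), G, rtol=1e-12)


class TestVariances:
    def test_midpoint_variance_elementwise(self):
        s2 = np.full(10, 4.0)
        v = cm.variance_midpoint(make_incr(np.zeros(10), s2), const_beta(0.5))
        assert np.allclose(v, 16.0)

    def test_zero_sigma_gives_zero(self):
        v = cm.variance_midpoint(make_incr(np.zeros(5)), const_beta(0.4))
        assert np.all(v == 0)

    def test_trapezoid_first_point_is_sigma1_over_16(self):
        s2 = np.array([3.0, 1.0, 1.0, 1.0])
        v = cm.variance_trapezoid(make_incr(np.zeros(4), s2), const_beta(0.5))
        assert v[0] == pytest.approx(3.0 / (16.0 * 0.25), rel=1e-14)
        assert v[1] == pytest.approx(3.0 / (16 * 0.25) + 1.0 / (4 * 0.25), rel=1e-14)

    def test_trapezoid_half_of_midpoint_in_stated_limit(self):
        # sigma_1 -> 0, sigma_{k-1} = sigma_k, constant beta: the trapezoid
        # variance is half the midpoint-rule variance
        s2 = np.concatenate([[1e-30], np.full(29, 2.0)])
        incr = make_incr(np.zeros(30), s2)
        beta = const_beta(0.5)
        ratio = cm.variance_trapezoid(incr, beta)[5:] / cm.variance_midpoint(incr, beta)[5:]
        assert np.allclose(ratio, 0.5, rtol=1e-6)

    def test_full_and_simplified_forms_agree_within_eighth(self):
        s2 = np.full(40, 1.5)
        incr = make_incr(np.zeros(40), s2)
        beta = const_beta(0.3)
        full = cm.variance_trapezoid(incr, beta)
        simp = cm.variance_trapezoid(incr, beta, simplified=True)
        rel = np.abs(full[3:] - simp[3:]) / simp[3:]
        assert np.all(rel <= 0.125 + 1e-9)

    def test_montecarlo_variance_of_cumulative_effect(self):
        # empirical replicate variance of Gamma_hat(t70) against the
        # sigma_k^2/beta^2 formula
        R = 220
        vals, formula = [], []
        for r in range(R):
            cfg = validation_config(25_000, seed=90_000 + r)
            coh = cm.simulate_cohort(cfg)
            beta = cm.fit_beta_quartic(coh, covariates=["covar"])
            afit = cm.fit_aalen(coh, ["instrument", "covar"], max_follow_age=80, seed=r)
            incr = cm.yearly_increments(afit, "instrument")
            # small-n replicates: relax the weak-instrument floor so noisy
            # beta fits at the oldest ages do not abort the study
            es = effect_series(incr, beta, floor=1e-4)
            vals.append(es.Gamma_mid[69])
            formula.append(es.var_Gamma_mid[69])
        emp = np.var(vals, ddof=1)
        assert emp == pytest.approx(np.mean(formula), rel=0.25)


class TestPointwiseCI:
    def test_zero_variance_zero_width(self):
        lo, hi = cm.pointwise_ci(np.ones(5), np.zeros(5))
        assert np.allclose(lo, 1.0) and np.allclose(hi, 1.0)

    @pytest.mark.parametrize(
        "alpha,mult", [(0.05, 1.959964), (0.32, stats.norm.ppf(0.84))]
    )
    def test_normal_multiplier(self, alpha, mult):
        lo, hi = cm.pointwise_ci(np.zeros(1), np.ones(1), alpha=alpha)
        assert hi[0] == pytest.approx(mult, rel=1e-6)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            cm.pointwise_ci(np.zeros(2), np.array([1.0, -1.0]))


class TestNaiveComparators:
    def test_zero_hazard_series(self):
        incr = make_incr(np.zeros(10))
        assert np.all(cm.naive_wald_constant(incr, 0.2) == 0)

    def test_zero_divisor_rejected(self):
        with pytest.raises(ZeroDivisionError):
            cm.naive_wald_constant(make_incr(np.ones(3)), 0.0)

    def test_single_bin_equals_time_resolved(self):
        incr = make_incr(np.array([0.5]))
        beta = quartic_beta(0.2, 1e-4, 0.0)
        g, _ = cm.momentaneous_effects(incr, beta)
        tr = cm.cumulative_midpoint(g)
        naive = cm.naive_wald_timevarying(incr, beta)
        # one-term integral: the only difference is midpoint (0.5) versus
        # endpoint (1.0) evaluation of beta_G
        assert naive[0] == pytest.approx(0.5 / beta(1.0))
        assert tr[0] == pytest.approx(0.5 / beta(0.5))
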