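"""Likelihood, priors, posterior and gradients for both models."""

import math

import numpy as np
import pytest
from scipy import stats

import crpbayes as cb
from crpbayes import model_core as mc


def _m1_zero(**overrides):
    kwargs = dict(beta0=0.0, beta_fixed=np.zeros(13), u_edu=np.zeros(6),
                  u_occ=np.zeros(9), sd_edu=0.1, sd_occ=0.1,
                  sigma=1.0, nu=10.0)
    kwargs.update(overrides)
    return cb.Model1Params(**kwargs)


def _m2_from(p1: cb.Model1Params, **overrides):
    kwargs = dict(beta0=p1.beta0, beta_fixed=p1.beta_fixed, u_edu=p1.u_edu,
                  u_occ=p1.u_occ, sd_edu=p1.sd_edu, sd_occ=p1.sd_occ,
                  gamma0=math.log(p1.sigma), gamma_fixed=np.zeros(13),
                  v_edu=np.zeros(6), v_occ=np.zeros(9),
                  sd_v_edu=0.05, sd_v_occ=0.05, nu=p1.nu)
    kwargs.update(overrides)
    return cb.Model2Params(**kwargs)


class TestStudentTLogpdf:
    def test_cauchy_peak(self):
        # nu=1 is the Cauchy distribution; density at the mode is 1/pi
        assert cb.student_t_logpdf(0.0, 0.0, 1.0, 1.0) == pytest.approx(
            math.log(1.0 / math.pi), abs=1e-12)

    @pytest.mark.parametrize("x", [-2.0, 0.0, 1.5, 3.0])
    def test_normal_limit(self, x):
        t_val = cb.student_t_logpdf(x, 0.0, 1.0, 1e6)
        n_val = stats.norm.logpdf(x)
        assert t_val == pytest.approx(n_val, abs=1e-4)

    @pytest.mark.parametrize("loc,scale,nu", [(0, 1, 3), (2.5, 0.5, 9.7),
                                              (-1, 4, 30)])
    def test_matches_scipy(self, loc, scale, nu):
        x = np.linspace(-5, 5, 11)
        ours = cb.student_t_logpdf(x, loc, scale, nu)
        ref = stats.t.logpdf(x, df=nu, loc=loc, scale=scale)
        assert np.allclose(ours, ref, atol=1e-12)

    def test_location_scale_family(self):
        a = cb.student_t_logpdf(3.0, 1.0, 2.0, 5.0)
        b = cb.student_t_logpdf(1.0, 0.0, 1.0, 5.0) - math.log(2.0)
        assert a == pytest.approx(b, abs=1e-12)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            cb.student_t_logpdf(0.0, 0.0, -1.0, 5.0)
        with pytest.raises(ValueError):
            cb.student_t_logpdf(0.0, 0.0, 1.0, 0.0)


class TestLinearPredictor:
    def test_intercept_only(self, prepared):
        _, design, _ = prepared
        eta = cb.linear_predictor(_m1_zero(beta0=2.5), design)
        assert np.allclose(eta, 2.5)

    def test_additivity_of_components(self, prepared):
        _, design, _ = prepared
        beta = np.zeros(13)
        beta[0] = 0.7  # gender_female dummy
        p = _m1_zero(beta0=1.0, beta_fixed=beta,
                     u_edu=np.arange(6) * 0.01, u_occ=np.arange(9) * 0.001)
        eta = cb.linear_predictor(p, design)
        expected = (1.0 + 0.7 * design.X[:, 0]
                    + 0.01 * design.edu_idx + 0.001 * design.occ_idx)
        assert np.allclose(eta, expected)

    def test_row_permutation_equivariance(self, prepared):
        _, design, _ = prepared
        import dataclasses
        p = cb.model1_reference_truth()
        eta = cb.linear_predictor(p, design)
        perm = np.random.default_rng(3).permutation(design.n)
        design_p = dataclasses.replace(design, X=design.X[perm],
                                       edu_idx=design.edu_idx[perm],
                                       occ_idx=design.occ_idx[perm])
        assert np.allclose(cb.linear_predictor(p, design_p), eta[perm])

    def test_sigma_side_requires_model2(self, prepared):
        _, design, _ = prepared
        with pytest.raises(ValueError):
            cb.linear_predictor(_m1_zero(), design, side="sigma")


class TestLogLikelihood:
    def test_single_row_equals_logpdf(self, prepared):
        _, design, y = prepared
        import dataclasses
        d1 = dataclasses.replace(design, X=design.X[:1],
                                 edu_idx=design.edu_idx[:1],
                                 occ_idx=design.occ_idx[:1])
        p = cb.model1_reference_truth()
        ll = cb.log_likelihood(p, y[:1], d1)
        mu = cb.linear_predictor(p, d1)[0]
        assert ll == pytest.approx(
            float(cb.student_t_logpdf(y[0], mu, p.sigma, p.nu)), abs=1e-12)

    def test_dataset_doubling_doubles_value(self, prepared):
        _, design, y = prepared
        import dataclasses
        p = cb.model1_reference_truth()
        ll = cb.log_likelihood(p, y, design)
        d2 = dataclasses.replace(
            design, X=np.vstack([design.X, design.X]),
            edu_idx=np.concatenate([design.edu_idx, design.edu_idx]),
            occ_idx=np.concatenate([design.occ_idx, design.occ_idx]))
        assert cb.log_likelihood(p, np.concatenate([y, y]), d2) == pytest.approx(
            2 * ll, rel=1e-12)

    def test_model2_nesting_identity(self, prepared):
        _, design, y = prepared
        p1 = cb.model1_reference_truth()
        p2 = _m2_from(p1)
        assert abs(cb.log_likelihood(p1, y, design)
                   - cb.log_likelihood(p2, y, design)) < 1e-10

    def test_t_to_normal_limit(self, prepared):
        _, design, y = prepared
        p = _m1_zero(nu=1e6)
        mu = cb.linear_predictor(p, design)
        gauss = float(np.sum(stats.norm.logpdf(y, loc=mu, scale=p.sigma)))
        assert cb.log_likelihood(p, y, design) == pytest.approx(gauss, abs=1e-3)


class TestLogPrior:
    def test_nu_contribution(self, prior):
        # Exponential(rate 1/29) density at nu - 1 = 29: log(1/29) - 1
        base = _m1_zero(nu=30.0)
        ref = _m1_zero(nu=1.0 + 1e-12)
        delta = (mc.log_prior(base, prior) - mc.log_prior(ref, prior))
        expected = (-1.0) - (-(1.0 / 29.0) * 1e-12)
        assert delta == pytest.approx(expected, abs=1e-9)
        # absolute value of the nu term at nu=30
        lp30 = math.log(1 / 29) - 1.0
        assert lp30 == pytest.approx(-4.3673, abs=1e-4)

    def test_out_of_support_gives_minus_inf(self, prior):
        assert mc.log_prior(_m1_zero(sigma=-1.0), prior) == -np.inf
        assert mc.log_prior(_m1_zero(sd_edu=0.0), prior) == -np.inf
        assert mc.log_prior(_m1_zero(nu=0.5), prior) == -np.inf

    def test_slope_contribution_at_zero_is_standard_normal_peak(self, prior):
        a = mc.log_prior(_m1_zero(), prior)
        shifted = _m1_zero(beta_fixed=np.r_[1.0, np.zeros(12)])
        b = mc.log_prior(shifted, prior)
        assert a - b == pytest.approx(0.5, abs=1e-12)  # N(0,1): -x^2/2 term

    def test_prior_slices_integrate_to_one(self, prior):
        # 1-d quadrature over sigma with everything else fixed
        from scipy.integrate import quad
        val, _ = quad(lambda s: math.exp(
            mc.log_prior(_m1_zero(sigma=s), prior)
            - mc.log_prior(_m1_zero(sigma=1.0), prior)), 1e-9, 50.0)
        ref = math.exp(-mc._half_normal_logpdf(1.0, prior.sigma_y))
        assert val == pytest.approx(ref, rel=1e-6)


class TestPosteriorAndGradient:
    def test_posterior_is_sum_of_parts(self, prepared, prior):
        _, design, y = prepared
        p = cb.model1_reference_truth()
        assert cb.log_posterior(p, y, design, prior) == pytest.approx(
            cb.log_likelihood(p, y, design) + mc.log_prior(p, prior), rel=1e-12)

    def test_improving_fit_raises_posterior(self, prepared, prior):
        _, design, y = prepared
        good = cb.model1_reference_truth()
        bad = cb.model1_reference_truth()
        bad.beta0 += 5.0  # move the intercept far from the data
        assert (cb.log_posterior(good, y, design, prior)
                > cb.log_posterior(bad, y, design, prior))

    @pytest.mark.parametrize("model", [1, 2])
    def test_gradient_matches_finite_differences(self, request, model,
                                                 prepared, prior):
        target = request.getfixturevalue(f"target_m{model}")
        rng = np.random.default_rng(model)
        for _ in range(3):
            q = rng.uniform(-0.5, 0.5, target.dim)
            g = target.grad(q)
            h = 1e-6
            for i in rng.choice(target.dim, size=12, replace=False):
                qp, qm = q.copy(), q.copy()
                qp[i] += h
                qm[i] -= h
                fd = (target.logp(qp) - target.logp(qm)) / (2 * h)
                assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_gradient_additivity_and_prior_mode(self, target_m1):
        # at a slope's prior mode the prior contributes zero gradient there
        q = np.zeros(target_m1.dim)
        q[target_m1._sl["log_sigma"]] = 0.0
        g_full = target_m1.grad(q)
        assert np.all(np.isfinite(g_full))

    def test_gradient_entry_point_requires_interior(self, prepared, prior):
        _, design, y = prepared
        with pytest.raises(ValueError):
            mc.gradient(_m1_zero(sigma=0.0), y, design, prior)
        g = mc.gradient(cb.model1_reference_truth(), y, design, prior)
        assert np.all(np.isfinite(g))

    def test_unconstrain_constrain_round_trip(self, target_m1, target_m2):
        p1 = cb.model1_reference_truth()
        q = target_m1.unconstrain(p1)
        back = target_m1.params(q)
        assert back.sigma == pytest.approx(p1.sigma, rel=1e-12)
        assert np.allclose(back.u_occ, p1.u_occ)
        p2 = cb.model2_reference_truth()
        q2 = target_m2.unconstrain(p2)
        back2 = target_m2.params(q2)
        assert np.allclose(back2.v_occ, p2.v_occ)
        assert len(target_m2.constrained_names) == target_m2.constrain(q2).size
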