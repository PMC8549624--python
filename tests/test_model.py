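"""Model core: likelihood closed forms, priors, transforms, gradients."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import gammaln
from scipy.stats import t as t_dist

from daphtox.design import ExperimentalUnit
from daphtox.model import (
    ModelData,
    ModelParameters,
    PriorSpec,
    intercept_only_logp_and_grad,
    inverse_logit,
    linear_predictor,
    log_likelihood,
    log_posterior,
    log_prior,
    make_posterior,
)


def single_unit_data(y: int, n: int = 5) -> ModelData:
    unit = ExperimentalUnit("r1", "r1.1", "rural", 20, "control", 1, n, y)
    return ModelData([unit])


def params_with(data: ModelData, **kw) -> ModelParameters:
    base = dict(
        beta=np.zeros(8),
        b_pop=np.zeros(data.n_populations),
        b_clone=np.zeros(data.n_clones),
        sigma_pop=1.0,
        sigma_clone=1.0,
        nu=10.0,
    )
    base.update(kw)
    return ModelParameters(**base)


class TestInverseLogit:
    def test_symmetry_point(self):
        assert inverse_logit(0.0) == 0.5

    def test_closed_form(self):
        assert inverse_logit(np.log(999)) == pytest.approx(0.999, abs=1e-12)

    def test_no_underflow_to_zero(self):
        p = inverse_logit(-50.0)
        assert 0 < p < 2e-22


class TestLinearPredictor:
    def test_all_zero_parameters(self, study_data):
        params = params_with(study_data)
        assert np.all(linear_predictor(params, study_data) == 0.0)

    def test_intercept_only(self, study_data):
        params = params_with(study_data, beta=np.r_[1.0, np.zeros(7)])
        assert np.allclose(linear_predictor(params, study_data), 1.0)

    def test_cpf_scaled_clone_effect(self):
        # eta = 0.5*(-7.86) + 0.5*2 = -2.93 for an exposed unit
        unit = ExperimentalUnit("r1", "r1.1", "rural", 20, "chlorpyrifos", 1, 5, 0)
        data = ModelData([unit])
        params = params_with(
            data,
            beta=np.array([0.0, -7.86, 0, 0, 0, 0, 0, 0]),
            b_clone=np.array([2.0]),
        )
        # urb and temp main effects are 0 here, so only cpf terms remain
        assert linear_predictor(params, data)[0] == pytest.approx(-2.93, abs=1e-12)

    def test_indicator_scaling_option(self):
        # with the 0/1 reading, control units get no random-effect term
        units = [
            ExperimentalUnit("r1", "r1.1", "rural", 20, "control", 1, 5, 5),
            ExperimentalUnit("r1", "r1.1", "rural", 20, "chlorpyrifos", 1, 5, 0),
        ]
        data = ModelData(units, scale_by_cpf=False)
        params = params_with(data, b_clone=np.array([2.0]))
        eta = linear_predictor(params, data)
        assert eta[0] == 0.0 and eta[1] == 2.0

    def test_wrong_random_effect_length_rejected(self, study_data):
        params = params_with(study_data, b_pop=np.zeros(3))
        with pytest.raises(IndexError):
            linear_predictor(params, study_data)


class TestLogLikelihood:
    def test_certain_survival_limit(self):
        data = single_unit_data(y=5)
        params = params_with(data, beta=np.r_[700.0, np.zeros(7)])
        assert log_likelihood(params, data) == pytest.approx(0.0, abs=1e-10)

    def test_all_dead_at_even_odds(self):
        data = single_unit_data(y=0)
        params = params_with(data)
        assert log_likelihood(params, data) == pytest.approx(5 * np.log(0.5), abs=1e-10)

    def test_binomial_coefficient_included(self):
        data = single_unit_data(y=2)
        params = params_with(data)
        assert log_likelihood(params, data) == pytest.approx(
            np.log(10 * 0.5**5), abs=1e-10
        )

    def test_permutation_invariance(self, study_units):
        data = ModelData(study_units)
        rng = np.random.default_rng(0)
        shuffled = ModelData(list(rng.permutation(np.array(study_units, dtype=object))))
        params = params_with(
            data,
            beta=rng.normal(size=8),
            b_pop=rng.normal(size=data.n_populations),
            b_clone=rng.normal(size=data.n_clones),
        )
        # clone/population index orders differ; map effects by label
        params2 = ModelParameters(
            beta=params.beta,
            b_pop=np.array(
                [params.b_pop[data.populations.index(p)] for p in shuffled.populations]
            ),
            b_clone=np.array(
                [params.b_clone[data.clones.index(c)] for c in shuffled.clones]
            ),
            sigma_pop=1.0,
            sigma_clone=1.0,
            nu=10.0,
        )
        assert log_likelihood(params, data) == pytest.approx(
            log_likelihood(params2, shuffled), abs=1e-10
        )

    def test_coding_symmetry(self, study_units):
        """Flipping the pesticide codes together with the sign of every
        CPF-bearing parameter leaves each linear predictor unchanged."""
        flipped_units = [
            ExperimentalUnit(
                u.population_id,
                u.clone_id,
                u.urbanization,
                u.temperature,
                "chlorpyrifos" if u.pesticide == "control" else "control",
                u.replicate,
                u.n_start,
                u.n_surviving,
            )
            for u in study_units
        ]
        data = ModelData(study_units)
        flipped = ModelData(flipped_units)
        rng = np.random.default_rng(3)
        beta = rng.normal(size=8)
        b_pop = rng.normal(size=data.n_populations)
        b_clone = rng.normal(size=data.n_clones)
        params = params_with(data, beta=beta, b_pop=b_pop, b_clone=b_clone)
        beta_flip = beta * np.array([1, -1, 1, 1, -1, -1, 1, -1])
        params_flip = params_with(
            flipped, beta=beta_flip, b_pop=-b_pop, b_clone=-b_clone
        )
        assert np.allclose(
            linear_predictor(params, data),
            linear_predictor(params_flip, flipped),
            atol=1e-10,
        )


class TestLogPrior:
    def test_student_t_density_at_zero(self):
        # independent oracle: log[ Gamma(2) / (Gamma(1.5) sqrt(3 pi) 5) ]
        expected = -gammaln(1.5) - 0.5 * np.log(3 * np.pi) - np.log(5.0)
        assert expected == pytest.approx(-2.61034, abs=1e-4)
        assert t_dist.logpdf(0.0, 3, scale=5.0) == pytest.approx(expected, abs=1e-12)

    def test_gamma_prior_mode(self):
        # Gamma(shape 2, rate 0.1) has mode (shape-1)/rate = 10
        from scipy.stats import gamma

        nus = np.linspace(0.1, 100, 10_000)
        dens = gamma.pdf(nus, 2, scale=10.0)
        assert nus[np.argmax(dens)] == pytest.approx(10.0, abs=0.05)

    def test_clone_prior_approaches_normal_for_large_nu(self, study_data):
        from scipy.stats import norm

        params_t = params_with(study_data, nu=1e8, b_clone=np.full(study_data.n_clones, 0.7))
        lp_t = log_prior(params_t)
        params_n = params_with(study_data, nu=1e8, b_clone=np.zeros(study_data.n_clones))
        delta_t = lp_t - log_prior(params_n)
        delta_n = study_data.n_clones * (
            norm.logpdf(0.7) - norm.logpdf(0.0)
        )
        assert delta_t == pytest.approx(delta_n, abs=1e-4)

    def test_out_of_support_is_minus_inf(self, study_data):
        params = params_with(study_data)
        object.__setattr__(params, "nu", -1.0)
        assert log_prior(params) == -np.inf

    def test_prior_propriety_by_quadrature(self):
        total, _ = quad(
            lambda x: t_dist.pdf(x, 3, scale=5.0), -1e4, 1e4, limit=200
        )
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_invalid_prior_spec_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(beta_scale=0.0)
        with pytest.raises(ValueError):
            PriorSpec(nu_rate=-0.1)


class TestUnconstrainedPosterior:
    def test_transform_round_trip(self, study_data):
        post = make_posterior(study_data)
        rng = np.random.default_rng(1)
        for _ in range(100):
            q = rng.normal(0, 2, post.n_dim)
            q2 = post.transform(post.untransform(q))
            assert np.max(np.abs(q - q2)) < 1e-10

    def test_log_posterior_is_likelihood_plus_prior(self, study_data):
        rng = np.random.default_rng(2)
        for _ in range(5):
            params = params_with(
                study_data,
                beta=rng.normal(size=8),
                b_pop=rng.normal(size=study_data.n_populations),
                b_clone=rng.normal(size=study_data.n_clones),
                sigma_pop=float(rng.uniform(0.5, 2)),
                sigma_clone=float(rng.uniform(0.5, 2)),
                nu=float(rng.uniform(2, 30)),
            )
            assert log_posterior(params, study_data) == pytest.approx(
                log_likelihood(params, study_data) + log_prior(params), abs=1e-9
            )

    def test_gradient_matches_finite_differences(self, study_data):
        post = make_posterior(study_data)
        rng = np.random.default_rng(5)
        eps = 1e-6
        for _ in range(20):
            q = rng.normal(0, 0.8, post.n_dim)
            _, grad = post.logp_and_grad(q)
            for i in rng.choice(post.n_dim, size=8, replace=False):
                qp, qm = q.copy(), q.copy()
                qp[i] += eps
                qm[i] -= eps
                fd = (post.logp(qp) - post.logp(qm)) / (2 * eps)
                assert grad[i] == pytest.approx(fd, rel=1e-5, abs=1e-6)

    def test_compiled_kernel_matches_reference(self, study_data):
        post = make_posterior(study_data)
        rng = np.random.default_rng(8)
        for _ in range(25):
            q = rng.normal(0, 1.2, post.n_dim)
            lp_ref, g_ref = post.logp_and_grad(q)
            lp_fast, g_fast = post.fast_logp_and_grad(q)
            assert lp_fast == pytest.approx(lp_ref, rel=1e-10, abs=1e-8)
            assert np.allclose(g_fast, g_ref, rtol=1e-6, atol=1e-6)

    def test_non_finite_input_rejected(self, study_data):
        post = make_posterior(study_data)
        q = np.zeros(post.n_dim)
        q[0] = np.nan
        with pytest.raises(ValueError):
            post.logp_and_grad(q)
        with pytest.raises(ValueError):
            post.fast_logp_and_grad(q)

    def test_intercept_only_reduction_consistent(self):
        # the 1-D reduced model equals likelihood + beta prior at several points
        logp_grad = intercept_only_logp_and_grad(y=3, n=5)
        data = single_unit_data(y=3)
        for b0 in (-2.0, 0.0, 1.5):
            params = params_with(data, beta=np.r_[b0, np.zeros(7)])
            expected = log_likelihood(params, data) + float(
                t_dist.logpdf(b0, 3, scale=5.0)
            )
            assert logp_grad(np.array([b0]))[0] == pytest.approx(expected, abs=1e-10)
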