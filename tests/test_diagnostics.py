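"""Convergence diagnostics and posterior predictive checks."""

import numpy as np
import pytest

from conftest import make_fake_draws
from daphtox.diagnostics import (
    NOT_APPLICABLE,
    DegenerateParameterError,
    divergence_count,
    effective_sample_size,
    posterior_predictive,
    split_rhat,
)
from daphtox.model import ModelData
from daphtox.simulate import (
    SimulationTruth,
    draw_random_effects,
    simulate_outcomes,
)


class TestSplitRhat:
    def test_iid_chains_below_threshold(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4, 5000))
        assert split_rhat(x) < 1.01

    def test_non_mixing_chains_flagged(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 1000)) + np.array([[-10.0], [10.0]])
        assert split_rhat(x) > 1.1

    def test_degenerate_parameter_is_an_error(self):
        x = np.ones((2, 100))
        with pytest.raises(DegenerateParameterError):
            split_rhat(x)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((4, 2000)) * np.array([[1.0], [1.1], [0.9], [1.05]])
        # rank-normalization: invariant to increasing affine maps (up to
        # floating-point noise in the folded component's rank ties)
        assert split_rhat(3.7 * x - 12.0) == pytest.approx(split_rhat(x), abs=1e-4)

    def test_too_few_chains_rejected(self):
        with pytest.raises(ValueError):
            split_rhat(np.random.default_rng(0).standard_normal((1, 100)))


class TestEffectiveSampleSize:
    def test_iid_draws_near_total(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((4, 5000))
        assert effective_sample_size(x) == pytest.approx(20_000, rel=0.10)

    def test_ar1_closed_form(self):
        # AR(1) with rho=0.9: ESS/N = (1-rho)/(1+rho) = 1/19
        rho, n = 0.9, 20_000
        rng = np.random.default_rng(4)
        chains = []
        for _ in range(4):
            e = rng.standard_normal(n)
            x = np.empty(n)
            x[0] = e[0] / np.sqrt(1 - rho**2)
            for t in range(1, n):
                x[t] = rho * x[t - 1] + e[t]
            chains.append(x)
        x = np.stack(chains)
        expected = x.size * (1 - rho) / (1 + rho)
        assert effective_sample_size(x) == pytest.approx(expected, rel=0.25)

    def test_antithetic_chain_superefficient(self):
        rng = np.random.default_rng(5)
        base = np.abs(rng.standard_normal((2, 4000))) + 0.1
        x = base * (-1.0) ** np.arange(4000)  # perfectly alternating signs
        ess = effective_sample_size(x)
        assert ess > x.size  # super-efficiency, no crash

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((4, 2000))
        assert effective_sample_size(-2.0 * x + 5.0) == pytest.approx(
            effective_sample_size(x), rel=1e-9
        )


class TestDivergenceCount:
    def test_absent_flags_not_applicable(self, zero_draws):
        zero_draws.divergent = None
        assert divergence_count(zero_draws) == NOT_APPLICABLE

    def test_all_false_flags_zero_per_chain(self, zero_draws):
        zero_draws.divergent = np.zeros((2, 50), dtype=bool)
        assert divergence_count(zero_draws) == (0, 0)

    def test_injected_flags_bookkeeping(self, zero_draws):
        flags = np.zeros((4, 50), dtype=bool)
        flags[1, [3, 10, 40]] = True
        draws = make_fake_draws(
            {"x": np.zeros((4, 50))}, divergent=flags
        )
        assert divergence_count(draws) == (0, 3, 0, 0)


def _model_draws(
    data: ModelData,
    beta: np.ndarray,
    spread: float,
    seed: int,
    b_pop: dict | None = None,
    b_clone: dict | None = None,
):
    """Fake posterior draws centered at `beta` (and optional effects)."""
    from daphtox.summaries import sample_fixed_effect_names

    rng = np.random.default_rng(seed)
    shape = (4, 250)
    vals = {
        name: beta[j] + spread * rng.standard_normal(shape)
        for j, name in enumerate(sample_fixed_effect_names())
    }
    for p in data.populations:
        center = b_pop.get(p, 0.0) if b_pop else 0.0
        vals[f"b_pop[{p}]"] = center + spread * rng.standard_normal(shape)
    for c in data.clones:
        center = b_clone.get(c, 0.0) if b_clone else 0.0
        vals[f"b_clone[{c}]"] = center + spread * rng.standard_normal(shape)
    vals["sigma_pop"] = np.full(shape, 1.0)
    vals["sigma_clone"] = np.full(shape, 1.0)
    vals["nu"] = np.full(shape, 15.0)
    return make_fake_draws(vals)


class TestPosteriorPredictive:
    def test_replicates_respect_binomial_bounds(self, study_data):
        draws = _model_draws(study_data, np.zeros(8), spread=0.5, seed=0)
        result = posterior_predictive(draws, study_data, n_replicates=50, seed=1)
        assert result.replicated.shape == (50, study_data.n_units)
        assert np.all(result.replicated >= 0)
        assert np.all(result.replicated <= study_data.N)

    def test_self_consistency_tail_probabilities(self, study_design):
        # observed data generated from the same parameters the draws center
        # on: no discrepancy statistic should be in the extreme tails
        truth = SimulationTruth(
            beta=(2.0, -3.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
            sigma_pop=0.3,
            sigma_clone=0.3,
            nu=15.0,
            seed=21,
        )
        from daphtox.design import build_design

        units = build_design(study_design)
        b_pop, b_clone = draw_random_effects(truth, study_design)
        data = ModelData(simulate_outcomes(units, truth, b_pop, b_clone))
        # random-effect draws centered on the generator's own effects
        draws = _model_draws(
            data, truth.beta_array, spread=0.3, seed=2, b_pop=b_pop, b_clone=b_clone
        )
        result = posterior_predictive(draws, data, n_replicates=400, seed=3)
        assert np.all(result.summary.tail_probability > 0.05)
        assert np.all(result.summary.tail_probability < 0.95)

    def test_gross_misfit_detected(self, study_design):
        from daphtox.design import build_design

        units = [
            u.with_outcome(u.n_start) for u in build_design(study_design)
        ]  # full survival everywhere
        data = ModelData(units)
        draws = _model_draws(data, np.zeros(8), spread=0.2, seed=4)  # p ~ 0.5
        result = posterior_predictive(draws, data, n_replicates=200, seed=5)
        mean_rows = result.summary[
            result.summary.statistic.str.startswith("mean_survival")
        ]
        assert np.all(mean_rows.tail_probability < 0.01)

    def test_zero_replicates_empty_summary(self, study_data):
        draws = _model_draws(study_data, np.zeros(8), spread=0.2, seed=6)
        result = posterior_predictive(draws, study_data, n_replicates=0)
        assert result.summary.empty
        assert result.replicated.shape == (0, study_data.n_units)

    def test_more_replicates_than_draws_rejected(self, study_data):
        draws = _model_draws(study_data, np.zeros(8), spread=0.2, seed=7)
        with pytest.raises(ValueError, match="exceeds"):
            posterior_predictive(draws, study_data, n_replicates=10_000)

    def test_count_table_covers_observed_range(self, study_data):
        draws = _model_draws(study_data, np.zeros(8), spread=0.2, seed=8)
        result = posterior_predictive(draws, study_data, n_replicates=20, seed=9)
        assert list(result.count_table.survivors) == list(range(7))  # 0..6
        assert result.count_table.observed.sum() == study_data.n_units
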