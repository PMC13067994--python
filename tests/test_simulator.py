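import numpy as np
import pytest
from scipy.stats import chisquare

from cierstates.measurement_models import QuadratureGrid, grm_category_logprobs
from cierstates.simulator import (
    ConditionSpec,
    apply_heterogeneity,
    apply_loading_decay,
    apply_two_factor,
    default_attentive_grm,
    default_cier_grm,
    generate_condition,
    noisy_assignments,
    simulate_attentive,
    simulate_cier,
    simulate_markov_dataset,
)
from cierstates.ct_latent_markov import TransitionModel


class TestSurrogates:
    def test_attentive_surrogate_structure(self):
        grm = default_attentive_grm()
        assert grm.n_items == 10 and grm.n_thresholds == 6
        assert np.all(np.diff(grm.thresholds, axis=1) < 0)
        assert (grm.loadings < 0).sum() == 2    # two negatively worded items

    def test_attentive_marginal_nondegenerate(self):
        """Every category keeps visible marginal mass under theta ~ N(0,1)."""
        grm = default_attentive_grm()
        grid = QuadratureGrid.normal(61)
        logp = grm_category_logprobs(grm.loadings, grm.thresholds, grid.nodes)
        marginal = np.einsum("q,qjg->jg", grid.weights, np.exp(logp))
        assert marginal.min() > 0.01
        assert np.allclose(marginal.sum(axis=1), 1.0, atol=1e-10)

    def test_cier_surrogate_extreme_peaked(self):
        m = default_cier_grm()
        grid = QuadratureGrid.normal(61)
        logp = grm_category_logprobs(
            np.array([np.sqrt(m.pref_var)]), m.thresholds[None, :],
            grid.nodes)
        marginal = np.einsum("q,qjg->g", grid.weights, np.exp(logp[:, :, :]))
        assert marginal[0] > 0.2 and marginal[-1] > 0.2
        assert marginal[[0, -1]].sum() > marginal[1:-1].sum()


class TestCierPatterns:
    def test_midpoint_probability_vector(self):
        from cierstates.simulator import _midpoint_probs
        p = _midpoint_probs(7)
        assert p.sum() == pytest.approx(1.0)
        assert np.allclose(p, [0.025, 0.025, 0.05, 0.80, 0.05, 0.025, 0.025])

    def test_straightlining_rows_constant(self):
        Y = simulate_cier("straightlining", 500, seed=1)
        assert np.all(Y.std(axis=1) == 0)
        # category choices vary across observations
        assert len(np.unique(Y[:, 0])) == 7

    def test_uniform_frequencies(self):
        Y = simulate_cier("uniform", 10_000, seed=2)
        freq = np.bincount(Y.ravel(), minlength=7) / Y.size
        se = np.sqrt((1 / 7) * (6 / 7) / Y.size)
        assert np.all(np.abs(freq - 1 / 7) < 3 * se)

    def test_unknown_pattern_rejected(self):
        with pytest.raises(ValueError):
            simulate_cier("zigzag", 10)

    def test_determinism(self):
        a = simulate_cier("grm_preference", 50, seed=9)
        b = simulate_cier("grm_preference", 50, seed=9)
        assert np.array_equal(a, b)


class TestAttentiveGeneration:
    def test_zero_loading_matches_threshold_probs(self):
        grm = default_attentive_grm()
        from cierstates.measurement_models import AttentiveGRM
        flat = AttentiveGRM(loadings=np.zeros(10), thresholds=grm.thresholds)
        Y = simulate_attentive(flat, 10_000, seed=3)
        grid = QuadratureGrid.normal(31)
        logp = grm_category_logprobs(flat.loadings, flat.thresholds,
                                     np.array([0.0]))
        probs = np.exp(logp[0])
        for j in (0, 4, 9):
            freq = np.bincount(Y[:, j], minlength=7) / len(Y)
            assert np.all(np.abs(freq - probs[j]) <
                          3 * np.sqrt(probs[j] * (1 - probs[j]) / len(Y))
                          + 1e-3)

    def test_single_item_marginal_gof(self):
        grm = default_attentive_grm()
        Y = simulate_attentive(grm, 10_000, seed=4)
        grid = QuadratureGrid.normal(61)
        logp = grm_category_logprobs(grm.loadings, grm.thresholds, grid.nodes)
        marginal = np.einsum("q,qjg->jg", grid.weights, np.exp(logp))
        j = 5
        observed = np.bincount(Y[:, j], minlength=7)
        result = chisquare(observed, marginal[j] * len(Y))
        assert result.pvalue > 0.01


class TestManipulations:
    def test_heterogeneity_low_all_positive(self):
        grm, rec = apply_heterogeneity(default_attentive_grm(), "low", 0,
                                       seed=1)
        assert np.all(grm.loadings > 0)
        assert np.array_equal(grm.thresholds,
                              default_attentive_grm().thresholds)

    def test_heterogeneity_high_scales_triples(self):
        base = default_attentive_grm()
        grm, rec = apply_heterogeneity(base, "high", 2, seed=2)
        assert len(rec["halved_items"]) == 3
        assert len(rec["doubled_items"]) == 3
        assert len(rec["negative_items"]) == 2
        for j in rec["halved_items"]:
            assert np.allclose(grm.thresholds[j], base.thresholds[j] * 0.5)
        for j in rec["doubled_items"]:
            assert np.allclose(grm.thresholds[j], base.thresholds[j] * 2.0)
        assert np.all(np.diff(grm.thresholds, axis=1) < 0)

    def test_loading_decay_values(self):
        from cierstates.measurement_models import AttentiveGRM
        grm = AttentiveGRM(loadings=np.full(10, 2.0),
                           thresholds=default_attentive_grm().thresholds)
        load_t, affected = apply_loading_decay(grm, 0.99, 10, 60, seed=3)
        assert load_t[59, 0] == pytest.approx(2 * 0.99**59, abs=1e-9)
        assert load_t[59, 0] == pytest.approx(1.106, abs=2e-3)
        load_t95, _ = apply_loading_decay(grm, 0.95, 10, 60, seed=3)
        assert np.all(load_t95[59] < 0.1 * 2.0)
        const, _ = apply_loading_decay(grm, 1.0, 5, 60, seed=3)
        assert np.allclose(const, 2.0)

    def test_two_factor_correlation(self):
        flags, traits = apply_two_factor(default_attentive_grm(), 1.0, 0.6,
                                         10_000, seed=4)
        assert flags.all()
        r = np.corrcoef(traits.T)[0, 1]
        assert abs(r - 0.6) < 3 / np.sqrt(len(traits))

    def test_two_factor_degenerate_limit(self):
        flags, traits = apply_two_factor(default_attentive_grm(), 1.0, 1.0,
                                         500, seed=5)
        assert np.allclose(traits[:, 0], traits[:, 1], atol=1e-6)


class TestGenerateCondition:
    def test_shapes_and_planted_rate(self):
        data, truth = generate_condition(ConditionSpec(seed=10))
        assert data.n_observations == 75 * 60
        n_cier = truth.states.sum()
        sd = np.sqrt(4500 * 0.1 * 0.9)
        assert abs(n_cier - 450) < 3 * sd
        assert len(truth.states) == len(truth.patterns) == 4500
        # pattern labels partition the C/IER set
        assert np.all((truth.patterns != "") == (truth.states == 1))

    def test_pure_function_of_spec(self):
        a, ta = generate_condition(ConditionSpec(seed=11))
        b, tb = generate_condition(ConditionSpec(seed=11))
        assert np.array_equal(a.responses, b.responses)
        assert np.array_equal(ta.states, tb.states)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ConditionSpec(pattern_mix={"uniform": 0.7})
        with pytest.raises(ValueError):
            ConditionSpec(decay_d=0.0)


class TestMarkovSimulation:
    def test_zero_intensity_freezes_states(self):
        model = TransitionModel(beta0=0.5, gamma0=np.array([-40.0, -40.0]))
        data, truth = simulate_markov_dataset(model, 20, 10, seed=6,
                                              responses=False)
        states = truth.states.reshape(20, 10)
        assert np.all(states == states[:, [0]])

    def test_longrun_frequencies_match_stationary(self):
        model = TransitionModel(beta0=0.0, gamma0=np.log([0.2, 0.6]))
        data, truth = simulate_markov_dataset(model, 2, 2000, seed=7,
                                              responses=False)
        freq = truth.states.mean()
        stationary = 0.2 / 0.8
        assert abs(freq - stationary) < 0.05

    def test_covariate_slope_direction(self):
        model = TransitionModel(beta0=-1.0, gamma0=np.log([0.1, 0.4]),
                                gamma=np.array([[1.0], [0.0]]),
                                covariate_names=["z"])
        sampler = lambda rng, N, T: rng.choice([-1.0, 1.0], size=(N, T, 1))
        data, truth = simulate_markov_dataset(model, 200, 20, seed=8,
                                              covariate_sampler=sampler,
                                              responses=False)
        states = truth.states.reshape(200, 20)
        z = data.covariates.reshape(200, 20)
        from_att = states[:, :-1] == 0
        trans = states[:, 1:][from_att]
        zt = z[:, 1:][from_att]
        rate_high = trans[zt > 0].mean()
        rate_low = trans[zt < 0].mean()
        assert rate_high > rate_low

    def test_noisy_assignment_error_rates(self):
        states = np.zeros((100, 50), dtype=int)
        D = np.array([[0.9, 0.1], [0.3, 0.7]])
        w = noisy_assignments(states, D, seed=9)
        assert abs(w.mean() - 0.1) < 0.02
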