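import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from cierstates.ct_latent_markov import (
    TransitionModel,
    backward_select,
    fit_transition_model,
    forward_loglik,
    initial_state_probs,
    intensity_matrix,
    predict_transition_probs,
    transition_prob_matrix,
    wald_test,
)
from cierstates.simulator import noisy_assignments, simulate_markov_dataset

from conftest import make_dataset

D_TEST = np.array([[0.95, 0.05], [0.20, 0.80]])


def intercept_model(q12, q21, beta0=0.0):
    return TransitionModel(beta0=beta0, gamma0=np.log([q12, q21]))


class TestTransitionProbMatrix:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_general_matrix_exponential(self, seed):
        rng = np.random.default_rng(seed)
        q12, q21 = rng.uniform(0.01, 5.0, 2)
        delta = rng.uniform(0.0, 10.0)
        Q = np.array([[-q12, q12], [q21, -q21]])
        assert np.allclose(transition_prob_matrix(Q, delta),
                           expm(Q * delta), atol=1e-12)

    def test_closed_form_example(self):
        Q = np.array([[-1.0, 1.0], [2.0, -2.0]])
        P = transition_prob_matrix(Q, 0.5)
        assert np.allclose(P, [[0.7410, 0.2590], [0.5179, 0.4821]],
                           atol=5e-5)

    def test_zero_interval_identity_and_negative_rejected(self):
        Q = np.array([[-1.0, 1.0], [2.0, -2.0]])
        assert np.allclose(transition_prob_matrix(Q, 0.0), np.eye(2))
        with pytest.raises(ValueError):
            transition_prob_matrix(Q, -0.1)

    def test_long_interval_reaches_stationarity(self):
        Q = np.array([[-1.0, 1.0], [2.0, -2.0]])
        P = transition_prob_matrix(Q, 1e3)
        assert np.allclose(P, [[2 / 3, 1 / 3], [2 / 3, 1 / 3]], atol=1e-12)

    def test_chapman_kolmogorov(self):
        Q = np.array([[-0.7, 0.7], [0.4, -0.4]])
        P = transition_prob_matrix
        assert np.allclose(P(Q, 1.3) @ P(Q, 0.9), P(Q, 2.2), atol=1e-12)

    def test_monotone_in_intensity(self):
        deltas = [0.2, 1.0, 4.0]
        for d in deltas:
            probs = [transition_prob_matrix(
                np.array([[-q, q], [0.5, -0.5]]), d)[0, 1]
                for q in (0.2, 0.5, 1.0, 2.0)]
            assert np.all(np.diff(probs) > 0)


class TestCovariateModels:
    def test_initial_state_logit(self):
        assert np.allclose(initial_state_probs(intercept_model(1, 1)),
                           [0.5, 0.5])
        m = intercept_model(1, 1, beta0=-2.1972)
        assert initial_state_probs(m)[1] == pytest.approx(0.10, abs=1e-4)
        m2 = TransitionModel(beta0=0.7, beta=np.zeros(2),
                             gamma0=np.zeros(2), covariate_names=["a", "b"],
                             init_covariates=True)
        assert np.allclose(initial_state_probs(m2, [5.0, -3.0]),
                           initial_state_probs(m2, [0.0, 0.0]))

    def test_intensity_matrix_structure(self):
        Q = intensity_matrix(intercept_model(1.0, 1.0))
        assert np.allclose(Q, [[-1, 1], [1, -1]])
        assert np.allclose(Q.sum(axis=1), 0.0)
        m = TransitionModel(beta0=0.0, gamma0=np.log([1.0, 1.0]),
                            gamma=np.array([[0.5], [0.0]]),
                            covariate_names=["z"])
        Q2 = intensity_matrix(m, [2.0])
        assert Q2[0, 1] == pytest.approx(np.e, rel=1e-12)
        assert Q2[1, 0] == pytest.approx(1.0, rel=1e-12)


class TestForwardLoglik:
    def test_single_occasion_no_transition(self):
        model = intercept_model(0.3, 0.6, beta0=-1.0)
        data = make_dataset(np.zeros((1, 2)), n_categories=7)
        ll = forward_loglik(np.array([1]), D_TEST, data, model)
        pi = initial_state_probs(model)
        assert ll == pytest.approx(np.log(pi @ D_TEST[:, 1]), rel=1e-12)

    def test_identity_error_reduces_to_chain_probability(self):
        model = intercept_model(0.5, 0.8, beta0=0.2)
        data = make_dataset(np.zeros((3, 2)),
                            times=[1.0, 2.0, 3.5], n_categories=7)
        w = np.array([0, 1, 1])
        ll = forward_loglik(w, np.eye(2), data, model)
        pi = initial_state_probs(model)
        Q = intensity_matrix(model)
        P1 = transition_prob_matrix(Q, 1.0)
        P2 = transition_prob_matrix(Q, 1.5)
        assert ll == pytest.approx(
            np.log(pi[0] * P1[0, 1] * P2[1, 1]), rel=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        model = TransitionModel(
            beta0=rng.normal(), gamma0=rng.normal(size=2),
            gamma=rng.normal(scale=0.3, size=(2, 1)),
            covariate_names=["z"])
        T = 4
        z = rng.normal(size=(T, 1))
        times = np.cumsum(rng.uniform(0.5, 2.0, T)) + 1
        w = rng.integers(0, 2, T)
        data = make_dataset(np.zeros((T, 2)), times=times, n_categories=7,
                            covariates=z, covariate_names=["z"])
        ll = forward_loglik(w, D_TEST, data, model)
        delta = np.diff(times)
        total = 0.0
        for path in itertools.product([0, 1], repeat=T):
            p = initial_state_probs(model, z[0])[path[0]] * D_TEST[path[0],
                                                                   w[0]]
            for t in range(1, T):
                P = transition_prob_matrix(intensity_matrix(model, z[t]),
                                           delta[t - 1])
                p *= P[path[t - 1], path[t]] * D_TEST[path[t], w[t]]
            total += p
        assert ll == pytest.approx(np.log(total), abs=1e-10)

    def test_missing_covariate_rejected(self):
        model = TransitionModel(beta0=0.0, gamma0=np.zeros(2),
                                gamma=np.zeros((2, 1)),
                                covariate_names=["z"])
        data = make_dataset(np.zeros((2, 2)), n_categories=7,
                            covariates=np.array([[1.0], [np.nan]]),
                            covariate_names=["z"])
        with pytest.raises(ValueError):
            forward_loglik(np.array([0, 1]), D_TEST, data, model)


class TestFitting:
    def test_recovers_staying_probabilities(self):
        truth = intercept_model(0.05, 0.30, beta0=-2.0)
        data, gt = simulate_markov_dataset(truth, 150, 25, seed=3,
                                           responses=False)
        w = noisy_assignments(gt.states.reshape(150, 25), D_TEST, seed=4)
        model = fit_transition_model(w.ravel(), D_TEST, data)
        P_true = predict_transition_probs(truth, delta=1.0)
        P_fit = predict_transition_probs(model, delta=1.0)
        assert np.allclose(np.diag(P_fit), np.diag(P_true), atol=0.05)

    def test_wald_zero_slopes(self):
        model = TransitionModel(
            beta0=0.0, gamma0=np.zeros(2), gamma=np.zeros((2, 1)),
            covariate_names=["z"])
        model.covariance = np.eye(model.pack().size)
        stat, df, p = wald_test(model, "z")
        assert (stat, df, p) == (0.0, 2, 1.0)

    def test_wald_unknown_covariate(self):
        model = intercept_model(1, 1)
        with pytest.raises(KeyError):
            wald_test(model, "nope")

    def test_backward_select_alpha_one_keeps_all(self):
        truth = intercept_model(0.1, 0.4)
        truth.covariate_names = ["z"]
        truth.gamma = np.zeros((2, 1))
        sampler = lambda rng, N, T: rng.normal(size=(N, T, 1))
        data, gt = simulate_markov_dataset(truth, 40, 8, seed=6,
                                           covariate_sampler=sampler,
                                           responses=False)
        w = noisy_assignments(gt.states.reshape(40, 8), D_TEST, seed=7)
        model, trail = backward_select(w.ravel(), D_TEST, data, ["z"],
                                       alpha=1.0)
        assert model.covariate_names == ["z"]
        assert trail == []

    def test_predict_transition_rows_sum_to_one(self):
        m = TransitionModel(beta0=0.0, gamma0=np.log([0.2, 0.9]),
                            gamma=np.array([[0.3], [-0.2]]),
                            covariate_names=["z"])
        for z in ([-2.0], [0.0], [3.0]):
            P = predict_transition_probs(m, z, delta=1.0)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(P >= 0)
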