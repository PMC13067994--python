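"""Synthetic EMA data with planted attentive / C/IER structure.

The generator mirrors an intensive-longitudinal design: N respondents
answering J 7-point Likert items at T occasions, with each
respondent-by-occasion observation generated independently. A configurable
share of observations is careless (C/IER) and drawn from one of four
planted patterns: uniform random responding, strong midpoint preference,
straightlining, or the constrained category-preference GRM. Attentive
observations come from a unidimensional GRM whose measurement structure can
be perturbed: item heterogeneity and negative wording (questionnaire
properties), exponential loading decay over occasions (measurement-model
drift), or a partially two-factor trait structure (factor-structure
heterogeneity).

Default generating parameters are a documented SURROGATE set shaped like an
empirical momentary-satisfaction application (10 items, two negatively
worded, homogeneous thresholds, bimodal-extreme careless preferences);
they reproduce distributional behaviour, not any particular dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .ct_latent_markov import TransitionModel, initial_state_probs, \
    intensity_matrix, transition_prob_matrix
from .data_io import EMADataset
from .measurement_models import AttentiveGRM, CIERGRM

PATTERNS = ("uniform", "midpoint", "straightlining", "grm_preference")


@dataclass
class ConditionSpec:
    """Full description of one simulation condition.

    ``pattern_mix`` maps pattern names to proportions summing to one.
    ``decay_d`` in (0, 1] and ``decay_items`` control exponential loading
    decay alpha_jt = alpha_j1 * d**(t-1) for a random item subset;
    ``twofactor_prop`` flags a share of attentive observations as generated
    from a 5+5 two-factor model with factor correlation ``twofactor_rho``.
    """

    n_respondents: int = 75
    n_occasions: int = 60
    n_items: int = 10
    n_categories: int = 7
    cier_rate: float = 0.10
    pattern_mix: dict = field(
        default_factory=lambda: {"uniform": 0.5, "grm_preference": 0.5})
    heterogeneity: str = "low"
    n_negative: int = 2
    decay_d: float = 1.0
    decay_items: int = 0
    twofactor_prop: float = 0.0
    twofactor_rho: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.pattern_mix.values()), 1.0):
            raise ValueError("pattern_mix proportions must sum to 1")
        for name in self.pattern_mix:
            if name not in PATTERNS:
                raise ValueError(f"unknown C/IER pattern {name!r}")
        if not 0 < self.decay_d <= 1:
            raise ValueError("decay_d must be in (0, 1]")
        if not -1 < self.twofactor_rho < 1 and self.twofactor_rho != 1.0:
            raise ValueError("twofactor_rho must be in (-1, 1) (1 allowed "
                             "as a degenerate test limit)")
        if not 0 <= self.cier_rate <= 1 or not 0 <= self.twofactor_prop <= 1:
            raise ValueError("rates must be proportions")


@dataclass
class GroundTruth:
    """One truth record per generated observation."""

    states: np.ndarray                     # 0 attentive, 1 C/IER
    patterns: np.ndarray                   # pattern label, "" for attentive
    attentive: AttentiveGRM
    cier: CIERGRM
    manipulations: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# surrogate generating parameters
# ---------------------------------------------------------------------------

def default_attentive_grm() -> AttentiveGRM:
    """SURROGATE attentive GRM: 10 homogeneous 7-point items, 2 negative.

    The emulated momentary-satisfaction scale is highly reliable
    (split-half correlations above .9), which a GRM expresses through
    strong discriminations combined with thresholds spread widely enough
    that, at any given trait value, an item concentrates on few adjacent
    categories. Loading magnitudes lie in [2.0, 3.6]; items 3 and 8 (the
    negatively worded positions of the emulated questionnaire) load
    negatively. Thresholds decrease over roughly [-5, 5] with mild item
    shifts.
    """
    loadings = np.array([3.3, 2.9, -2.4, 3.0, 3.6, 3.2, 2.3, -2.0, 2.6, 3.4])
    base = np.array([5.0, 3.0, 1.0, -1.0, -3.0, -5.0])
    shifts = np.array([0.0, 0.15, -0.2, 0.1, -0.1, 0.2, -0.15, 0.05, -0.05, 0.12])
    thresholds = base[None, :] + shifts[:, None]
    return AttentiveGRM(loadings=loadings, thresholds=thresholds)


def default_cier_grm() -> CIERGRM:
    """SURROGATE C/IER GRM: unit preference variance and narrowly spaced
    thresholds, giving a marginal careless-response distribution peaked on
    the extreme categories (each roughly 0.3) with light middle-category
    mass, shifted towards one end by the preference trait."""
    return CIERGRM(
        thresholds=np.array([0.75, 0.40, 0.13, -0.13, -0.40, -0.75]),
        pref_var=1.0,
    )


# ---------------------------------------------------------------------------
# attentive response generation
# ---------------------------------------------------------------------------

def _draw_grm(loadings_nj: np.ndarray, thresholds: np.ndarray,
              traits_nj: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draw from GRM category probabilities, row-wise.

    Cumulative P(Y >= g) = expit(a * theta + kappa_g); a uniform u maps to
    the count of cumulative probabilities exceeding it.
    """
    eta = loadings_nj[..., None] * traits_nj[..., None] + thresholds[None, :, :]
    cum = expit(eta)                               # (n, J, G)
    u = rng.uniform(size=loadings_nj.shape)
    return (u[..., None] < cum).sum(axis=-1)


def simulate_attentive(grm: AttentiveGRM, n_observations: int,
                       seed: int = 0) -> np.ndarray:
    """Attentive responses: one trait draw per observation, items independent
    given the trait. Multi-trait models draw from a standard multivariate
    normal with the model's trait correlation; items map to traits through
    the loading matrix columns (one nonzero loading per item)."""
    rng = np.random.default_rng(seed)
    J = grm.n_items
    if grm.n_traits == 1:
        theta = rng.standard_normal(n_observations)
        theta_nj = np.broadcast_to(theta[:, None], (n_observations, J))
        load_nj = np.broadcast_to(grm.loadings, (n_observations, J))
    else:
        L = np.linalg.cholesky(grm.trait_corr)
        theta = rng.standard_normal((n_observations, grm.n_traits)) @ L.T
        lmat = grm.loading_matrix()
        factor_of_item = np.argmax(np.abs(lmat), axis=1)
        theta_nj = theta[:, factor_of_item]
        load_nj = lmat[np.arange(J), factor_of_item][None, :]
        load_nj = np.broadcast_to(load_nj, (n_observations, J))
    return _draw_grm(np.ascontiguousarray(load_nj), grm.thresholds,
                     np.ascontiguousarray(theta_nj), rng)


def _midpoint_probs(n_categories: int) -> np.ndarray:
    p = np.full(n_categories, 0.025)
    mid = n_categories // 2
    p[mid] = 0.80
    p[mid - 1] = p[mid + 1] = 0.05
    return p / p.sum()


def simulate_cier(pattern: str, n_observations: int, seed: int = 0,
                  n_items: int = 10, n_categories: int = 7,
                  cier_model: CIERGRM | None = None) -> np.ndarray:
    """C/IER responses for one planted pattern.

    uniform: iid uniform over categories per item; midpoint: 0.80 on the
    scale midpoint, 0.05 adjacent, 0.025 elsewhere; straightlining: one
    uniform category per observation copied to every item; grm_preference:
    a preference trait draw followed by the constrained GRM.
    """
    rng = np.random.default_rng(seed)
    n, J, K = n_observations, n_items, n_categories
    if pattern == "uniform":
        return rng.integers(0, K, size=(n, J))
    if pattern == "midpoint":
        return rng.choice(K, size=(n, J), p=_midpoint_probs(K))
    if pattern == "straightlining":
        return np.repeat(rng.integers(0, K, size=(n, 1)), J, axis=1)
    if pattern == "grm_preference":
        model = cier_model or default_cier_grm()
        xi = rng.standard_normal(n) * np.sqrt(model.pref_var)
        load = np.ones((n, J))
        thr = np.tile(model.thresholds, (J, 1))
        return _draw_grm(load, thr, np.broadcast_to(xi[:, None], (n, J)), rng)
    raise ValueError(f"unknown C/IER pattern {pattern!r}")


# ---------------------------------------------------------------------------
# measurement-model manipulations
# ---------------------------------------------------------------------------

def apply_heterogeneity(grm: AttentiveGRM, level: str, n_negative: int,
                        seed: int = 0) -> tuple[AttentiveGRM, dict]:
    """Questionnaire-property manipulation.

    ``level='high'`` multiplies the thresholds of one random item triple by
    0.50 and another by 2.00 (proportionally for J != 10), leaving the rest
    unaltered; ``'low'`` leaves thresholds as they are. ``n_negative = 0``
    takes absolute values of all loadings; otherwise that many randomly
    selected items get negative loadings.
    """
    rng = np.random.default_rng(seed)
    J = grm.n_items
    if n_negative > J:
        raise ValueError("more negative items than items")
    load = np.abs(np.asarray(grm.loadings, dtype=float))
    neg_items = np.array([], dtype=int)
    if n_negative > 0:
        neg_items = rng.choice(J, size=n_negative, replace=False)
        load[neg_items] *= -1.0
    thr = np.array(grm.thresholds, dtype=float)
    halved = doubled = np.array([], dtype=int)
    if level == "high":
        k = max(1, round(3 * J / 10))
        chosen = rng.choice(J, size=2 * k, replace=False)
        halved, doubled = chosen[:k], chosen[k:]
        thr[halved] *= 0.50
        thr[doubled] *= 2.00
    elif level != "low":
        raise ValueError("heterogeneity level must be 'low' or 'high'")
    record = {"negative_items": np.sort(neg_items),
              "halved_items": np.sort(halved),
              "doubled_items": np.sort(doubled)}
    return AttentiveGRM(loadings=load, thresholds=thr), record


def apply_loading_decay(grm: AttentiveGRM, d: float, n_affected: int,
                        n_occasions: int, seed: int = 0):
    """Occasion-indexed loadings alpha_jt = alpha_j1 * d**(t-1) for a random
    item subset; unaffected items stay constant. Returns the (T, J) loading
    array and the affected item indices."""
    if not 0 < d <= 1:
        raise ValueError("decay factor d must be in (0, 1]")
    if n_affected > grm.n_items:
        raise ValueError("more affected items than items")
    rng = np.random.default_rng(seed)
    affected = np.sort(rng.choice(grm.n_items, size=n_affected, replace=False))
    T = n_occasions
    load_t = np.tile(np.asarray(grm.loadings, dtype=float), (T, 1))
    decay = d ** np.arange(T)
    load_t[:, affected] = load_t[:, affected] * decay[:, None]
    return load_t, affected


def apply_two_factor(grm: AttentiveGRM, proportion: float, rho: float,
                     n_observations: int, seed: int = 0):
    """Flag a share of observations for two-factor generation.

    Flagged observations draw correlated trait pairs (theta_1, theta_2); the
    first half of the items measures factor 1 and the rest factor 2, with
    unchanged loading magnitudes and thresholds. Returns the flag vector and
    the (n_flagged, 2) trait draws.
    """
    rng = np.random.default_rng(seed)
    flags = rng.uniform(size=n_observations) < proportion
    cov = np.array([[1.0, rho], [rho, 1.0]])
    # svd factorisation tolerates the degenerate rho = 1 test limit
    traits = rng.multivariate_normal(np.zeros(2), cov, size=int(flags.sum()),
                                     method="svd")
    return flags, traits


# ---------------------------------------------------------------------------
# full condition generator
# ---------------------------------------------------------------------------

def generate_condition(spec: ConditionSpec) -> tuple[EMADataset, GroundTruth]:
    """Generate one dataset under a condition, with truth labels attached.

    Occasions are time-stamped at equal 1-hour spacing (the mixture step
    ignores the time axis; transition-model tests draw their own intervals).
    All randomness is a pure function of the spec, including its seed.
    """
    root = np.random.default_rng(spec.seed)
    seeds = root.integers(0, 2**31 - 1, size=8)
    pattern_seeds = dict(zip(PATTERNS,
                             root.integers(0, 2**31 - 1, size=len(PATTERNS))))
    N, T, J, K = (spec.n_respondents, spec.n_occasions, spec.n_items,
                  spec.n_categories)
    n = N * T
    grm, record = apply_heterogeneity(default_attentive_grm(),
                                      spec.heterogeneity, spec.n_negative,
                                      seed=seeds[0])
    cier_model = default_cier_grm()

    rng_state = np.random.default_rng(seeds[1])
    states = (rng_state.uniform(size=n) < spec.cier_rate).astype(int)
    patterns = np.full(n, "", dtype=object)
    cier_idx = np.flatnonzero(states == 1)
    names = list(spec.pattern_mix)
    probs = np.array([spec.pattern_mix[k] for k in names])
    patterns[cier_idx] = rng_state.choice(names, size=cier_idx.size, p=probs)

    Y = np.zeros((n, J), dtype=float)

    # attentive observations, with optional decay / two-factor structure
    att_idx = np.flatnonzero(states == 0)
    occasions = np.tile(np.arange(1, T + 1), N)
    rng_att = np.random.default_rng(seeds[2])
    if spec.decay_items > 0 and spec.decay_d < 1:
        load_t, decayed = apply_loading_decay(grm, spec.decay_d,
                                              spec.decay_items, T,
                                              seed=seeds[3])
        record["decayed_items"] = decayed
        load_nj = load_t[occasions[att_idx] - 1]
    else:
        load_nj = np.broadcast_to(grm.loadings, (att_idx.size, J)).copy()

    flags2f = np.zeros(n, dtype=bool)
    if spec.twofactor_prop > 0:
        sub_flags, traits2 = apply_two_factor(grm, spec.twofactor_prop,
                                              spec.twofactor_rho,
                                              att_idx.size, seed=seeds[4])
        flags2f[att_idx] = sub_flags
        theta = rng_att.standard_normal(att_idx.size)
        theta_nj = np.repeat(theta[:, None], J, axis=1)
        half = J // 2
        theta_nj[sub_flags, :half] = traits2[:, [0]]
        theta_nj[sub_flags, half:] = traits2[:, [1]]
    else:
        theta = rng_att.standard_normal(att_idx.size)
        theta_nj = np.repeat(theta[:, None], J, axis=1)
    Y[att_idx] = _draw_grm(load_nj, grm.thresholds, theta_nj, rng_att)

    for p in PATTERNS:
        idx = np.flatnonzero(patterns == p)
        if idx.size:
            Y[idx] = simulate_cier(p, idx.size, seed=int(pattern_seeds[p]),
                                   n_items=J, n_categories=K,
                                   cier_model=cier_model)

    record["twofactor_flags"] = flags2f
    dataset = EMADataset(
        respondent_id=np.repeat(np.arange(1, N + 1), T),
        occasion_index=occasions,
        time_hours=occasions.astype(float),
        responses=Y,
        n_categories=K,
    )
    truth = GroundTruth(states=states, patterns=patterns, attentive=grm,
                        cier=cier_model, manipulations=record)
    return dataset, truth


# ---------------------------------------------------------------------------
# Markov-driven sequences for transition-model testing
# ---------------------------------------------------------------------------

def simulate_markov_states(model: TransitionModel, covariates: np.ndarray,
                           intervals: np.ndarray,
                           rng: np.random.Generator) -> np.ndarray:
    """(N, T) latent state paths under the CT chain with given covariates."""
    N, T, _ = covariates.shape
    states = np.empty((N, T), dtype=int)
    for i in range(N):
        pi = initial_state_probs(model, covariates[i, 0])
        states[i, 0] = rng.choice(2, p=pi)
        for t in range(1, T):
            Q = intensity_matrix(model, covariates[i, t])
            P = transition_prob_matrix(Q, intervals[i, t])
            states[i, t] = rng.choice(2, p=P[states[i, t - 1]])
    return states


def noisy_assignments(states: np.ndarray, D: np.ndarray,
                      seed: int = 0) -> np.ndarray:
    """Sample error-prone modal-style indicators w ~ D[true state]."""
    rng = np.random.default_rng(seed)
    D = np.asarray(D, dtype=float)
    u = rng.uniform(size=states.shape)
    return (u < D[states, 1]).astype(int)


def simulate_markov_dataset(model: TransitionModel, n_respondents: int,
                            n_occasions: int, seed: int = 0,
                            covariate_sampler=None,
                            intervals: str = "equal",
                            attentive: AttentiveGRM | None = None,
                            cier: CIERGRM | None = None,
                            responses: bool = True):
    """Generate respondent sequences from the latent-Markov data model.

    Initial states follow the logit model, later states the CT chain with
    piecewise-constant intensities evaluated at the destination occasion's
    covariates; each observation's responses come from its state's
    measurement model. ``intervals`` is ``'equal'`` (1 h) or ``'uniform'``
    (1-3 h, exercising the continuous-time machinery).
    ``covariate_sampler(rng, n_respondents, n_occasions)`` must return an
    (N, T, U) array. With ``responses=False`` item responses are zeros
    (placeholders for assignment-only analyses).
    """
    rng = np.random.default_rng(seed)
    N, T = n_respondents, n_occasions
    U = len(model.covariate_names)
    Z = (covariate_sampler(rng, N, T) if covariate_sampler is not None
         else np.zeros((N, T, U)))
    if intervals == "equal":
        delta = np.ones((N, T))
    elif intervals == "uniform":
        delta = rng.uniform(1.0, 3.0, size=(N, T))
    else:
        raise ValueError("intervals must be 'equal' or 'uniform'")
    delta[:, 0] = 0.0
    times = np.cumsum(delta, axis=1) + 1.0
    states = simulate_markov_states(model, Z, delta, rng)

    attentive = attentive or default_attentive_grm()
    cier = cier or default_cier_grm()
    J, K = attentive.n_items, attentive.n_thresholds + 1
    flat_states = states.ravel()
    Y = np.zeros((N * T, J), dtype=float)
    if responses:
        att_idx = np.flatnonzero(flat_states == 0)
        cier_idx = np.flatnonzero(flat_states == 1)
        Y[att_idx] = simulate_attentive(attentive, att_idx.size,
                                        seed=int(rng.integers(2**31 - 1)))
        if cier_idx.size:
            Y[cier_idx] = simulate_cier(
                "grm_preference", cier_idx.size,
                seed=int(rng.integers(2**31 - 1)), n_items=J,
                n_categories=K, cier_model=cier)

    dataset = EMADataset(
        respondent_id=np.repeat(np.arange(1, N + 1), T),
        occasion_index=np.tile(np.arange(1, T + 1), N),
        time_hours=times.ravel(),
        responses=Y,
        n_categories=K,
        covariates=Z.reshape(N * T, U),
        covariate_names=list(model.covariate_names),
    )
    truth = GroundTruth(states=flat_states,
                        patterns=np.where(flat_states == 1,
                                          "grm_preference", ""),
                        attentive=attentive, cier=cier)
    return dataset, truth


__all__ = [
    "ConditionSpec",
    "GroundTruth",
    "PATTERNS",
    "default_attentive_grm",
    "default_cier_grm",
    "simulate_attentive",
    "simulate_cier",
    "apply_heterogeneity",
    "apply_loading_decay",
    "apply_two_factor",
    "generate_condition",
    "simulate_markov_states",
    "simulate_markov_dataset",
    "noisy_assignments",
]
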