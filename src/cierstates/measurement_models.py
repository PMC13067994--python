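"""Measurement models for attentive and careless/insufficient-effort (C/IER) responding.

Two component models share the graded-response-model (GRM) form on cumulative
logits. The *attentive* model has item-specific loadings and thresholds on a
substantive trait theta (mean 0, variance 1 for identification). The *C/IER*
model replaces the substantive trait with a single category-preference trait
xi: all loadings are fixed to 1 and one set of thresholds is shared across
items, so the model is blind to item content by construction. As the variance
of xi shrinks to zero the C/IER model collapses to a single multinomial over
categories determined by the shared thresholds (pure random responding).

Thresholds enter the cumulative logit with a positive sign: the probability of
responding in category g or above is logistic(loading * trait + kappa_g).
Ordered categories therefore require kappa strictly *decreasing* in g.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, log_expit, logsumexp


class ModelValidityError(ValueError):
    """Raised when model parameters violate GRM constraints."""


def _check_decreasing(thresholds: np.ndarray, name: str = "thresholds") -> None:
    t = np.asarray(thresholds, dtype=float)
    if t.ndim == 1:
        t = t[None, :]
    if t.shape[-1] > 1 and not np.all(np.diff(t, axis=-1) < 0):
        raise ModelValidityError(
            f"{name} must be strictly decreasing across categories "
            "(kappa_1 > kappa_2 > ... > kappa_G)"
        )


@dataclass
class AttentiveGRM:
    """Graded response model for attentive observations.

    Parameters
    ----------
    loadings : (J,) or (J, M) array
        Item discriminations. Negative values are legitimate: raw responses
        to negatively worded items are modelled without recoding.
    thresholds : (J, G) array
        Category thresholds kappa_jg, strictly decreasing in g per item.
    trait_corr : (M, M) array, optional
        Latent trait correlation matrix (used by the simulator for M = 2;
        estimation is unidimensional). Defaults to the identity.
    """

    loadings: np.ndarray
    thresholds: np.ndarray
    trait_corr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.loadings = np.atleast_1d(np.asarray(self.loadings, dtype=float))
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.thresholds.ndim != 2:
            raise ModelValidityError("thresholds must be a J x G matrix")
        _check_decreasing(self.thresholds)
        if self.loadings.shape[0] != self.thresholds.shape[0]:
            raise ModelValidityError("loadings and thresholds disagree on J")
        if self.trait_corr is None:
            self.trait_corr = np.eye(self.n_traits)
        else:
            self.trait_corr = np.asarray(self.trait_corr, dtype=float)

    @property
    def n_items(self) -> int:
        return self.thresholds.shape[0]

    @property
    def n_thresholds(self) -> int:
        return self.thresholds.shape[1]

    @property
    def n_traits(self) -> int:
        return 1 if self.loadings.ndim == 1 else self.loadings.shape[1]

    def loading_matrix(self) -> np.ndarray:
        """Loadings as a J x M matrix regardless of storage shape."""
        a = self.loadings
        return a[:, None] if a.ndim == 1 else a


@dataclass
class CIERGRM:
    """Constrained GRM for C/IER observations.

    All loadings are fixed to 1 and one decreasing threshold vector is shared
    across items; the latent category-preference trait xi has mean 0 and free
    variance ``pref_var``. A large ``pref_var`` accommodates straightlining-like
    behaviour; the estimation routine caps it (see ``PREF_VAR_MAX``) and flags
    solutions at the cap.
    """

    thresholds: np.ndarray
    pref_var: float = 1.0

    PREF_VAR_MAX = 100.0

    def __post_init__(self) -> None:
        self.thresholds = np.atleast_1d(np.asarray(self.thresholds, dtype=float))
        _check_decreasing(self.thresholds)
        if self.pref_var < 0:
            raise ModelValidityError("pref_var must be nonnegative")

    @property
    def n_thresholds(self) -> int:
        return self.thresholds.shape[0]


@dataclass
class QuadratureGrid:
    """Fixed rectangular quadrature for the standard-normal latent trait.

    Equally spaced nodes on [-bound, bound] with weights proportional to the
    standard normal density, normalised to sum to one. The same standard grid
    serves the C/IER trait after rescaling nodes by sqrt(pref_var).
    """

    nodes: np.ndarray
    weights: np.ndarray

    @classmethod
    def normal(cls, n_nodes: int = 61, bound: float = 6.0) -> "QuadratureGrid":
        nodes = np.linspace(-bound, bound, n_nodes)
        w = np.exp(-0.5 * nodes**2)
        return cls(nodes=nodes, weights=w / w.sum())

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("quadrature weights must sum to 1")

    @property
    def log_weights(self) -> np.ndarray:
        return np.log(self.weights)


# ---------------------------------------------------------------------------
# probability kernels
# ---------------------------------------------------------------------------

def attentive_cumulative_prob(model: AttentiveGRM, trait, item: int, g: int) -> float:
    """P(Y_j >= g | attentive, theta): 1 at g=0, 0 at g=G+1, logistic between."""
    G = model.n_thresholds
    if g == 0:
        return 1.0
    if g == G + 1:
        return 0.0
    if not 1 <= g <= G:
        raise IndexError(f"category index g={g} outside 0..{G + 1}")
    theta = np.atleast_1d(np.asarray(trait, dtype=float))
    logit = float(model.loading_matrix()[item] @ theta + model.thresholds[item, g - 1])
    return float(expit(logit))


def cier_cumulative_prob(model: CIERGRM, preference: float, g: int) -> float:
    """P(Y_j >= g | C/IER, xi): identical for every item by construction."""
    G = model.n_thresholds
    if g == 0:
        return 1.0
    if g == G + 1:
        return 0.0
    if not 1 <= g <= G:
        raise IndexError(f"category index g={g} outside 0..{G + 1}")
    return float(expit(preference + model.thresholds[g - 1]))


def category_probs(cumulative) -> np.ndarray:
    """Adjacent differences of a cumulative probability vector (1, ..., 0)."""
    c = np.asarray(cumulative, dtype=float)
    if c[0] != 1.0 or c[-1] != 0.0:
        raise ValueError("cumulative vector must start at 1 and end at 0")
    if np.any(np.diff(c) > 0):
        raise ValueError("cumulative probabilities must be nonincreasing")
    return -np.diff(c)


def random_responding_probs(model: CIERGRM) -> np.ndarray:
    """Category probabilities of pure random responding (the pref_var -> 0 limit)."""
    cum = np.concatenate(([1.0], expit(model.thresholds), [0.0]))
    return -np.diff(cum)


def grm_category_logprobs(loadings: np.ndarray, thresholds: np.ndarray,
                          theta: np.ndarray) -> np.ndarray:
    """Log category probabilities on a trait grid, vectorised.

    Parameters are a (J,) loading vector, (J, G) threshold matrix, and (Q,)
    grid; the result has shape (Q, J, G + 1). Adjacent logistic differences
    are floored at 1e-300 before the log so extreme logits stay finite.
    """
    eta = (np.asarray(loadings)[None, :, None] * np.asarray(theta)[:, None, None]
           + np.asarray(thresholds)[None, :, :])          # (Q, J, G)
    c = expit(eta)
    Q, J, G = eta.shape
    p = np.empty((Q, J, G + 1))
    p[..., 0] = expit(-eta[..., 0])
    p[..., G] = c[..., G - 1]
    if G > 1:
        p[..., 1:G] = c[..., :-1] - c[..., 1:]
    return np.log(np.maximum(p, 1e-300))


def _logprob_grid(model: AttentiveGRM | CIERGRM, theta: np.ndarray,
                  n_items: int | None = None) -> np.ndarray:
    """(Q, J, G+1) log category probabilities for either component model."""
    if isinstance(model, AttentiveGRM):
        if model.n_traits != 1:
            raise ModelValidityError("grid evaluation is unidimensional; "
                                     "multi-trait models are simulation-only")
        return grm_category_logprobs(model.loadings, model.thresholds, theta)
    J = n_items if n_items is not None else 1
    load = np.ones(J)
    thr = np.tile(model.thresholds, (J, 1))
    return grm_category_logprobs(load, thr, theta)


def pattern_loglik_given_trait(model: AttentiveGRM | CIERGRM, responses,
                               trait: float) -> float:
    """Log-likelihood of one response pattern at a fixed trait value.

    Missing responses (masked or NaN) are skipped: by local independence a
    masked item integrates out of the pattern probability. An all-missing
    pattern has no likelihood contribution and is rejected.
    """
    y = np.ma.masked_invalid(np.asarray(responses, dtype=float))
    if y.mask is np.ma.nomask:
        y.mask = np.zeros(y.shape, dtype=bool)
    observed = ~y.mask
    if not observed.any():
        raise ValueError("pattern has no observed responses; drop the row upstream")
    logp = _logprob_grid(model, np.atleast_1d(float(trait)), n_items=y.size)[0]
    items = np.flatnonzero(observed)
    cats = y.data[observed].astype(int)
    return float(logp[items, cats].sum())


def marginal_pattern_loglik(model: AttentiveGRM | CIERGRM, responses,
                            grid: QuadratureGrid) -> float:
    """Pattern log-likelihood marginalised over the latent trait.

    For the C/IER model the standard-normal grid is rescaled by
    sqrt(pref_var) so the same grid integrates any preference variance.
    """
    y = np.ma.masked_invalid(np.asarray(responses, dtype=float))
    if y.mask is np.ma.nomask:
        y.mask = np.zeros(y.shape, dtype=bool)
    observed = ~y.mask
    if not observed.any():
        raise ValueError("pattern has no observed responses")
    theta = grid.nodes
    if isinstance(model, CIERGRM):
        theta = theta * np.sqrt(model.pref_var)
    logp = _logprob_grid(model, theta, n_items=y.size)     # (Q, J, G+1)
    items = np.flatnonzero(observed)
    cats = y.data[observed].astype(int)
    per_node = logp[:, items, cats].sum(axis=1)            # (Q,)
    return float(logsumexp(per_node + grid.log_weights))


__all__ = [
    "AttentiveGRM",
    "CIERGRM",
    "QuadratureGrid",
    "ModelValidityError",
    "attentive_cumulative_prob",
    "cier_cumulative_prob",
    "category_probs",
    "random_responding_probs",
    "grm_category_logprobs",
    "pattern_loglik_given_trait",
    "marginal_pattern_loglik",
]
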