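"""Step 2: modal state assignment and the classification-error matrix.

Modal assignment maps each observation to its highest-posterior state.
Because that assignment is imperfect, the step-3 transition model treats it
as an error-prone indicator of the true latent state; the error is
quantified by the 2 x 2 matrix D with entries

    D[k, l] = P(assigned state l | true state k),

estimated by total-posterior weighting: the posterior mass of state k among
observations assigned to l, divided by the total posterior mass of state k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ATTENTIVE, CIER = 0, 1
_D_FLOOR = 1e-10


@dataclass
class ClassificationResult:
    """Modal assignments plus the classification-error matrix.

    ``assignments`` holds 0 for attentive and 1 for C/IER per observation;
    ``error_matrix`` is row-stochastic with rows indexed by the true state;
    ``error_probs[k] = 1 - D[k, k]`` is the per-state misclassification
    probability.
    """

    assignments: np.ndarray
    error_matrix: np.ndarray

    @property
    def error_probs(self) -> np.ndarray:
        return 1.0 - np.diag(self.error_matrix)

    @property
    def cier_rate(self) -> float:
        return float(np.mean(self.assignments == CIER))


def modal_assign(posteriors: np.ndarray) -> np.ndarray:
    """Assign each observation to its most probable state.

    Ties (posterior exactly 0.5) go to the attentive state, so an
    uninformative observation is not flagged as careless.
    """
    post = np.asarray(posteriors, dtype=float)
    return (post[:, CIER] > 0.5).astype(int)


def classification_error_matrix(posteriors: np.ndarray,
                                assignments: np.ndarray) -> np.ndarray:
    """Posterior-weighted misclassification rates of the modal assignment."""
    post = np.asarray(posteriors, dtype=float)
    w = np.asarray(assignments)
    mass = post.sum(axis=0)
    if np.any(mass <= 0):
        raise ValueError(
            "a state has zero total posterior mass; the mixture is degenerate")
    D = np.empty((2, 2))
    for ell in (ATTENTIVE, CIER):
        D[:, ell] = post[w == ell].sum(axis=0) / mass
    return np.clip(D, _D_FLOOR, None)


def classify(posteriors: np.ndarray) -> ClassificationResult:
    """Run modal assignment and error quantification in one step."""
    w = modal_assign(posteriors)
    return ClassificationResult(
        assignments=w,
        error_matrix=classification_error_matrix(posteriors, w),
    )


__all__ = [
    "ATTENTIVE",
    "CIER",
    "ClassificationResult",
    "modal_assign",
    "classification_error_matrix",
    "classify",
]
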