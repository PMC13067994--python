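"""Step 3: continuous-time latent Markov model on error-prone state assignments.

The modal assignments from step 2 are treated as manifest indicators of the
true attentive / C/IER states, with the fixed classification-error matrix D
from step 2 as their (error-containing) response model. The latent chain is
a two-state continuous-time Markov process: covariates act on the initial
state through a logit model and on the transition intensities through a
log-linear model,

    logit P(s_1 = cier | z_1) = beta_0 + beta' z_1,
    log q_lk = gamma_0lk + gamma_lk' z_t        (l != k),

and the transition probability matrix over an interval delta is the matrix
exponential of Q * delta, available in closed form for two states. The
likelihood is a scaled forward recursion per respondent; covariance of the
estimates comes from the inverse observed information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.optimize import minimize
from scipy.stats import chi2

from .data_io import EMADataset

_LOG_Q_CAP = 50.0   # caps exp() in the intensity model


@dataclass
class TransitionModel:
    """Fitted (or specified) two-state CT latent Markov transition model.

    ``gamma0`` and ``gamma`` hold the log-intensity intercepts and slopes in
    the order (attentive->cier, cier->attentive). State 1 (attentive) is the
    reference category of the initial-state logit.
    """

    beta0: float
    gamma0: np.ndarray                      # (2,)
    beta: np.ndarray = field(default_factory=lambda: np.zeros(0))
    gamma: np.ndarray | None = None         # (2, U)
    covariate_names: list[str] = field(default_factory=list)
    init_covariates: bool = False
    error_matrix: np.ndarray = field(
        default_factory=lambda: np.eye(2))
    covariance: np.ndarray | None = None
    loglik: float | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gamma0 = np.asarray(self.gamma0, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        U = len(self.covariate_names)
        if self.gamma is None:
            self.gamma = np.zeros((2, U))
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.error_matrix = np.asarray(self.error_matrix, dtype=float)

    # -- parameter vector layout -------------------------------------------
    # [beta0, beta (if init_covariates), gamma0_12, gamma0_21,
    #  gamma_12 (U), gamma_21 (U)]
    def pack(self) -> np.ndarray:
        parts = [[self.beta0]]
        if self.init_covariates:
            parts.append(self.beta)
        parts.append(self.gamma0)
        parts.extend(self.gamma)
        return np.concatenate(parts)

    def unpack(self, x: np.ndarray) -> "TransitionModel":
        U = len(self.covariate_names)
        i = 1
        beta = np.zeros(U)
        if self.init_covariates:
            beta = x[i:i + U]
            i += U
        gamma0 = x[i:i + 2]
        gamma = x[i + 2:i + 2 + 2 * U].reshape(2, U)
        return TransitionModel(
            beta0=float(x[0]), beta=beta, gamma0=gamma0, gamma=gamma,
            covariate_names=list(self.covariate_names),
            init_covariates=self.init_covariates,
            error_matrix=self.error_matrix,
        )

    def param_names(self) -> list[str]:
        names = ["beta0"]
        if self.init_covariates:
            names += [f"beta[{c}]" for c in self.covariate_names]
        names += ["gamma0[att->cier]", "gamma0[cier->att]"]
        names += [f"gamma[att->cier,{c}]" for c in self.covariate_names]
        names += [f"gamma[cier->att,{c}]" for c in self.covariate_names]
        return names


def initial_state_probs(model: TransitionModel, z1=None) -> np.ndarray:
    """(attentive, C/IER) probabilities at the first occasion."""
    z1 = np.zeros(len(model.covariate_names)) if z1 is None else np.asarray(z1)
    eta = model.beta0 + (model.beta @ z1 if model.init_covariates else 0.0)
    p2 = 1.0 / (1.0 + np.exp(-eta))
    return np.array([1.0 - p2, p2])


def intensity_matrix(model: TransitionModel, z=None) -> np.ndarray:
    """2 x 2 transition intensity matrix at covariate vector z."""
    z = np.zeros(len(model.covariate_names)) if z is None else np.asarray(z)
    q12 = np.exp(min(model.gamma0[0] + model.gamma[0] @ z, _LOG_Q_CAP))
    q21 = np.exp(min(model.gamma0[1] + model.gamma[1] @ z, _LOG_Q_CAP))
    return np.array([[-q12, q12], [q21, -q21]])


def transition_prob_matrix(Q: np.ndarray, delta: float) -> np.ndarray:
    """Matrix exponential of Q * delta via the 2 x 2 closed form.

    With s = q12 + q21 the spectral decomposition gives
    expm(Q d) = Pi + exp(-s d) (I - Pi), where Pi has the stationary
    distribution (q21, q12)/s in both rows; s = 0 returns the identity.
    """
    if delta < 0:
        raise ValueError("interval must be nonnegative")
    q12, q21 = Q[0, 1], Q[1, 0]
    s = q12 + q21
    if s <= 0:
        return np.eye(2)
    pi_row = np.array([q21, q12]) / s
    stat = np.tile(pi_row, (2, 1))
    return stat + np.exp(-s * delta) * (np.eye(2) - stat)


def predict_transition_probs(model: TransitionModel, z=None,
                             delta: float = 1.0) -> np.ndarray:
    """Transition probability matrix over an interval at a covariate profile."""
    return transition_prob_matrix(intensity_matrix(model, z), delta)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _stack_sequences(assignments, data: EMADataset, covariates: list[str]):
    """Pad per-respondent sequences into (N, Tmax) arrays for the recursion."""
    w = np.asarray(assignments)
    cov_idx = [data.covariate_names.index(c) for c in covariates]
    Z_all = data.covariates[:, cov_idx] if cov_idx else np.zeros((len(w), 0))
    if np.any(np.isnan(Z_all)):
        raise ValueError("missing covariate values in the transition model")
    slices = data.respondent_slices()
    N, Tmax, U = len(slices), max(len(s) for s in slices), len(cov_idx)
    W = np.full((N, Tmax), -1)
    Z = np.zeros((N, Tmax, U))
    delta = np.zeros((N, Tmax))
    mask = np.zeros((N, Tmax), dtype=bool)
    for i, idx in enumerate(slices):
        T = len(idx)
        W[i, :T] = w[idx]
        Z[i, :T] = Z_all[idx]
        delta[i, 1:T] = data.intervals[idx[1:]]
        mask[i, :T] = True
    return W, Z, delta, mask


def _forward_loglik_arrays(model: TransitionModel, W, Z, delta, mask) -> float:
    D = model.error_matrix
    N, Tmax, _ = Z.shape
    eta_init = model.beta0 + (Z[:, 0] @ model.beta if model.init_covariates
                              else 0.0)
    p2 = 1.0 / (1.0 + np.exp(-eta_init))
    f = np.column_stack([1.0 - p2, p2]) * D[:, W[:, 0]].T
    scale = f.sum(axis=1)
    ll = np.log(np.maximum(scale, 1e-300))
    f /= np.maximum(scale, 1e-300)[:, None]
    for t in range(1, Tmax):
        live = mask[:, t]
        if not live.any():
            break
        lq12 = np.minimum(model.gamma0[0] + Z[:, t] @ model.gamma[0], _LOG_Q_CAP)
        lq21 = np.minimum(model.gamma0[1] + Z[:, t] @ model.gamma[1], _LOG_Q_CAP)
        q12, q21 = np.exp(lq12), np.exp(lq21)
        s = q12 + q21
        e = np.exp(-s * delta[:, t])
        with np.errstate(invalid="ignore", divide="ignore"):
            p1 = np.where(s > 0, q21 / np.maximum(s, 1e-300), 1.0)  # stat P(att)
        P = np.empty((N, 2, 2))
        P[:, 0, 0] = p1 + e * (1.0 - p1)
        P[:, 0, 1] = 1.0 - P[:, 0, 0]
        P[:, 1, 0] = p1 * (1.0 - e)
        P[:, 1, 1] = 1.0 - P[:, 1, 0]
        f_new = np.einsum("nl,nlk->nk", f, P) * D[:, W[:, t]].T
        scale = f_new.sum(axis=1)
        ll = ll + np.where(live, np.log(np.maximum(scale, 1e-300)), 0.0)
        f = np.where(live[:, None],
                     f_new / np.maximum(scale, 1e-300)[:, None], f)
    return float(ll.sum())


def forward_loglik(assignments, D, data: EMADataset,
                   model: TransitionModel) -> float:
    """Log-likelihood of the assignment sequences under the CT latent chain."""
    model = TransitionModel(
        beta0=model.beta0, beta=model.beta, gamma0=model.gamma0,
        gamma=model.gamma, covariate_names=model.covariate_names,
        init_covariates=model.init_covariates, error_matrix=np.asarray(D))
    W, Z, delta, mask = _stack_sequences(assignments, data,
                                         model.covariate_names)
    return _forward_loglik_arrays(model, W, Z, delta, mask)


# ---------------------------------------------------------------------------
# fitting and inference
# ---------------------------------------------------------------------------

def _numerical_hessian(fun, x, step=1e-4):
    p = len(x)
    H = np.empty((p, p))
    hs = step * np.maximum(1.0, np.abs(x))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = hs[i]
            ej = np.zeros(p); ej[j] = hs[j]
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej)
                - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4.0 * hs[i] * hs[j])
    return H


def fit_transition_model(assignments, D, data: EMADataset,
                         covariates: list[str] | None = None,
                         init_covariates: bool = False,
                         n_starts: int = 1, seed: int = 0) -> TransitionModel:
    """Maximise the forward log-likelihood over (beta, gamma).

    The measurement part (D) stays fixed. The default start is the
    deterministic near-identity chain (log-intensities log 0.1, zero slopes,
    initial-state intercept from the observed first-occasion assignment
    share); additional starts jitter it reproducibly. Person-level
    covariates that are constant within every respondent inflate the
    effective sample size, so a warning is emitted for them.
    """
    covariates = list(covariates or [])
    for name in covariates:
        u = data.covariate_names.index(name)
        col = data.covariates[:, u]
        if all(np.unique(col[idx]).size == 1
               for idx in data.respondent_slices()):
            warnings.warn(
                f"covariate {name!r} is constant within persons; repeated "
                "person-level scores inflate the effective sample size",
                stacklevel=2)
    W, Z, delta, mask = _stack_sequences(assignments, data, covariates)
    template = TransitionModel(
        beta0=0.0, gamma0=np.log([0.1, 0.1]),
        gamma=np.zeros((2, len(covariates))),
        covariate_names=covariates, init_covariates=init_covariates,
        error_matrix=np.asarray(D, dtype=float),
    )
    first_share = np.clip(np.mean(W[:, 0]), 0.02, 0.98)
    template.beta0 = float(np.log(first_share / (1 - first_share)))
    x0 = template.pack()

    def negloglik(x):
        return -_forward_loglik_arrays(template.unpack(x), W, Z, delta, mask)

    rng = np.random.default_rng(seed)
    best = None
    for s in range(max(1, n_starts)):
        xs = x0 if s == 0 else x0 + rng.normal(0, 0.5, size=x0.size)
        if not np.isfinite(negloglik(xs)):
            xs = 0.5 * xs          # dampened restart
        res = minimize(negloglik, xs, method="BFGS",
                       options={"gtol": 1e-6, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res

    fitted = template.unpack(best.x)
    fitted.loglik = float(-best.fun)
    H = _numerical_hessian(negloglik, best.x)
    try:
        cov = linalg.inv(H)
        if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
            raise linalg.LinAlgError("non-positive variance")
    except linalg.LinAlgError:
        cov = linalg.pinvh(H)
        fitted.flags.append("singular_information")
        warnings.warn("observed information is singular; covariance is a "
                      "pseudo-inverse", stacklevel=2)
    fitted.covariance = cov
    if np.any(best.x[len(best.x) - 2 * len(covariates) - 2:
                     len(best.x) - 2 * len(covariates)] < -15):
        fitted.flags.append("intensity_boundary")
    return fitted


def wald_test(model: TransitionModel, covariate: str):
    """Joint Wald test of a covariate's two transition slopes (df = 2)."""
    if covariate not in model.covariate_names:
        raise KeyError(f"covariate {covariate!r} not in model")
    if model.covariance is None:
        raise ValueError("model has no covariance matrix; fit it first")
    names = model.param_names()
    idx = [names.index(f"gamma[att->cier,{covariate}]"),
           names.index(f"gamma[cier->att,{covariate}]")]
    u = model.covariate_names.index(covariate)
    b = np.array([model.gamma[0, u], model.gamma[1, u]])
    V = model.covariance[np.ix_(idx, idx)]
    if np.allclose(b, 0.0):
        return 0.0, 2, 1.0
    try:
        stat = float(b @ linalg.solve(V, b, assume_a="sym"))
    except linalg.LinAlgError as err:
        raise linalg.LinAlgError(
            f"singular covariance block for {covariate!r}") from err
    if stat < 0:
        raise linalg.LinAlgError(
            f"covariance block for {covariate!r} is not positive definite")
    return stat, 2, float(chi2.sf(stat, 2))


def backward_select(assignments, D, data: EMADataset,
                    candidates: list[str], alpha: float = 0.05,
                    init_covariates: bool = False, seed: int = 0):
    """Backward covariate selection with Wald tests.

    Starting from the model with every candidate, repeatedly drops the
    covariate with the largest non-significant p-value and refits, until
    all remaining covariates are significant at ``alpha``. Returns the
    final model and the removal trail (name, statistic, p-value).
    """
    if not candidates:
        raise ValueError("candidate list must be nonempty")
    current = list(candidates)
    trail = []
    while True:
        model = fit_transition_model(assignments, D, data, current,
                                     init_covariates=init_covariates,
                                     seed=seed)
        if not current:
            return model, trail
        tests = {c: wald_test(model, c) for c in current}
        worst = max(current, key=lambda c: tests[c][2])
        stat, _, p = tests[worst]
        if p > alpha:
            trail.append((worst, stat, p))
            current.remove(worst)
        else:
            return model, trail


__all__ = [
    "TransitionModel",
    "initial_state_probs",
    "intensity_matrix",
    "transition_prob_matrix",
    "predict_transition_probs",
    "forward_loglik",
    "fit_transition_model",
    "wald_test",
    "backward_select",
]
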