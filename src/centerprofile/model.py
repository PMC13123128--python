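"""Hierarchical logistic regression with center-level random intercepts.

The model for a binary outcome :math:`y_{j[i]}` (patient *i* nested in
center *j*) is

.. math::

    \\operatorname{logit} P(y_{j[i]} = 1)
        = \\eta_i = \\alpha + x_i^\\top \\beta + u_{j[i]},
    \\qquad u_j \\sim \\mathcal N(0, \\sigma_u^2),

with independent Gaussian priors :math:`\\alpha \\sim N(0, \\sigma_\\alpha^2)`,
:math:`\\beta_k \\sim N(0, \\Sigma_{\\beta,kk})` and an Inverse-Gamma prior
:math:`\\sigma_u^2 \\sim \\mathrm{IG}(a_0, b_0)` on the between-center
variance.  The logistic likelihood is non-conjugate with the Gaussian
priors, so the posterior has no closed form; this module supplies the log
full-conditional densities and their gradients for each parameter block
(used by Metropolis-Hastings updates) together with the exact conjugate
Inverse-Gamma full conditional for :math:`\\sigma_u^2`.

Conventions
-----------
* ``IG(a, b)`` uses the *rate* parameterisation: density proportional to
  :math:`x^{-(a+1)} e^{-b/x}`.
* Center indices are 0-based internally; labels travel alongside.
* All log densities are reported up to state-independent additive
  constants, which is sufficient for MH acceptance ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

__all__ = [
    "CohortData",
    "Hyperparameters",
    "ParameterState",
    "logistic",
    "linear_predictor",
    "bernoulli_loglik",
    "log_conditional_alpha",
    "grad_alpha",
    "log_conditional_beta",
    "grad_beta",
    "log_conditional_u",
    "grad_u",
    "ig_full_conditional_params",
    "log_joint_posterior",
]


@dataclass(frozen=True)
class CohortData:
    """Patient-level cohort: outcomes, design matrix and center assignment.

    Parameters
    ----------
    y : array of 0/1, shape (n,)
        Binary outcome per patient.
    X : array, shape (n, p)
        Design matrix of encoded predictors (reference-level dummy coding,
        no intercept column).
    center_index : int array, shape (n,)
        0-based center assignment, values in ``[0, J)``.
    center_labels : tuple of str, length J
        Ordered center names.
    column_names : tuple of str, length p, optional
        Names of the design-matrix columns.
    """

    y: np.ndarray
    X: np.ndarray
    center_index: np.ndarray
    center_labels: tuple
    column_names: tuple = ()

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float)
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        ci = np.asarray(self.center_index, dtype=np.int64)
        if X.size == 0:
            X = X.reshape(y.shape[0], X.shape[1] if X.ndim == 2 else 0)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "center_index", ci)
        object.__setattr__(self, "center_labels", tuple(self.center_labels))
        if not self.column_names:
            object.__setattr__(
                self, "column_names", tuple(f"x{k}" for k in range(X.shape[1]))
            )
        else:
            object.__setattr__(self, "column_names", tuple(self.column_names))
        if y.ndim != 1:
            raise ValueError("y must be one-dimensional")
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("outcome values must all be 0 or 1")
        if X.shape[0] != y.shape[0] or ci.shape[0] != y.shape[0]:
            raise ValueError("y, X and center_index must have equal length")
        if len(self.column_names) != X.shape[1]:
            raise ValueError("column_names length must match X columns")
        J = len(self.center_labels)
        if y.shape[0] and (ci.min() < 0 or ci.max() >= J):
            raise ValueError("center_index out of range [0, J)")
        counts = np.bincount(ci, minlength=J)
        if J and (counts == 0).any():
            empty = [self.center_labels[j] for j in np.flatnonzero(counts == 0)]
            raise ValueError(f"centers with no patients: {empty}")

    @property
    def n_patients(self) -> int:
        return self.y.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]

    @property
    def n_centers(self) -> int:
        return len(self.center_labels)

    def center_counts(self) -> np.ndarray:
        """Number of patients per center (length J)."""
        return np.bincount(self.center_index, minlength=self.n_centers)

    def observed_counts(self) -> np.ndarray:
        """Observed event count O_j per center (length J)."""
        return np.bincount(
            self.center_index, weights=self.y, minlength=self.n_centers
        ).astype(int)


@dataclass(frozen=True)
class Hyperparameters:
    """Prior hyperparameters.

    ``sigma2_alpha`` and the diagonal of ``Sigma_beta`` default to 100
    (weakly informative on the log-odds scale); ``a0 = b0 = 1`` for the
    Inverse-Gamma prior on the between-center variance.
    """

    sigma2_alpha: float = 100.0
    sigma2_beta: object = 100.0  # scalar or length-p vector (diagonal of Sigma_beta)
    a0: float = 1.0
    b0: float = 1.0

    def __post_init__(self):
        if self.sigma2_alpha <= 0 or self.a0 <= 0 or self.b0 <= 0:
            raise ValueError("hyperparameters must be strictly positive")
        if np.any(np.asarray(self.sigma2_beta, dtype=float) <= 0):
            raise ValueError("sigma2_beta entries must be strictly positive")

    def sigma2_beta_vec(self, p: int) -> np.ndarray:
        """Diagonal of the beta prior covariance as a length-p vector."""
        v = np.asarray(self.sigma2_beta, dtype=float)
        if v.ndim == 0:
            return np.full(p, float(v))
        if v.shape[0] != p:
            raise ValueError("sigma2_beta length does not match p")
        return v


@dataclass(frozen=True)
class ParameterState:
    """One point (alpha, beta, u, sigma2_u) in parameter space."""

    alpha: float
    beta: np.ndarray
    u: np.ndarray
    sigma2_u: float

    def __post_init__(self):
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "u", np.asarray(self.u, dtype=float))
        if self.sigma2_u <= 0:
            raise ValueError("sigma2_u must be positive")

    def with_(self, **kwargs) -> "ParameterState":
        return replace(self, **kwargs)


def logistic(eta):
    """Logistic CDF sigma(eta) = 1/(1+exp(-eta)), overflow-safe.

    Raises ``ValueError`` on non-finite input (an invalid linear predictor).
    """
    eta = np.asarray(eta, dtype=float)
    if not np.isfinite(eta).all():
        raise ValueError("non-finite linear predictor")
    out = expit(eta)
    return float(out) if out.ndim == 0 else out


def linear_predictor(state: ParameterState, data: CohortData) -> np.ndarray:
    """eta_i = alpha + x_i' beta + u_{j[i]} for every patient."""
    if state.beta.shape[0] != data.n_covariates:
        raise ValueError("beta length does not match number of covariates")
    if state.u.shape[0] != data.n_centers:
        raise ValueError("u length does not match number of centers")
    eta = np.full(data.n_patients, state.alpha)
    if data.n_covariates:
        eta += data.X @ state.beta
    if data.n_patients:
        eta += state.u[data.center_index]
    return eta


def bernoulli_loglik(y, eta) -> float:
    """Bernoulli log-likelihood sum_i [y_i eta_i - log(1 + e^{eta_i})].

    Uses ``logaddexp`` so it is finite for eta anywhere in [-700, 700].
    """
    y = np.asarray(y, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if y.shape != eta.shape:
        raise ValueError("y and eta must have equal length")
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def log_conditional_alpha(
    alpha: float, state: ParameterState, data: CohortData, hyper: Hyperparameters
) -> float:
    """Log full conditional of the intercept, up to an additive constant."""
    eta = linear_predictor(state.with_(alpha=alpha), data)
    return bernoulli_loglik(data.y, eta) - alpha**2 / (2.0 * hyper.sigma2_alpha)


def grad_alpha(
    state: ParameterState, data: CohortData, hyper: Hyperparameters
) -> float:
    """d/d alpha of ``log_conditional_alpha`` at the current state."""
    eta = linear_predictor(state, data)
    return float(np.sum(data.y - expit(eta)) - state.alpha / hyper.sigma2_alpha)


def log_conditional_beta(
    beta, state: ParameterState, data: CohortData, hyper: Hyperparameters
) -> float:
    """Log full conditional of the fixed-effect vector, up to a constant.

    The data term is sum_i [y_i x_i' beta - log(1 + e^{eta_i})]; it differs
    from the Bernoulli log-likelihood only by a beta-independent constant.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape[0] != data.n_covariates:
        raise ValueError("beta length does not match number of covariates")
    eta = linear_predictor(state.with_(beta=beta), data)
    xb = data.X @ beta if data.n_covariates else np.zeros(data.n_patients)
    data_term = float(np.sum(data.y * xb - np.logaddexp(0.0, eta)))
    s2 = hyper.sigma2_beta_vec(beta.shape[0])
    return data_term - 0.5 * float(np.sum(beta**2 / s2))


def grad_beta(
    state: ParameterState, data: CohortData, hyper: Hyperparameters
) -> np.ndarray:
    """Gradient of ``log_conditional_beta`` at the current state."""
    eta = linear_predictor(state, data)
    resid = data.y - expit(eta)
    s2 = hyper.sigma2_beta_vec(data.n_covariates)
    return data.X.T @ resid - state.beta / s2


def log_conditional_u(
    j: int, u_j: float, state: ParameterState, data: CohortData, hyper: Hyperparameters
) -> float:
    """Log full conditional of center j's random intercept.

    Only patients of center j contribute to the likelihood term; the prior
    is N(0, sigma2_u) at the current variance.
    """
    if not 0 <= j < data.n_centers:
        raise ValueError(f"invalid center index {j}")
    mask = data.center_index == j
    u = state.u.copy()
    u[j] = u_j
    eta = linear_predictor(state.with_(u=u), data)[mask]
    return bernoulli_loglik(data.y[mask], eta) - u_j**2 / (2.0 * state.sigma2_u)


def grad_u(
    j: int, state: ParameterState, data: CohortData, hyper: Hyperparameters
) -> float:
    """d/d u_j of ``log_conditional_u`` at the current state."""
    if not 0 <= j < data.n_centers:
        raise ValueError(f"invalid center index {j}")
    mask = data.center_index == j
    eta = linear_predictor(state, data)[mask]
    return float(np.sum(data.y[mask] - expit(eta)) - state.u[j] / state.sigma2_u)


def ig_full_conditional_params(u, a0: float, b0: float):
    """Exact Inverse-Gamma full conditional for the between-center variance.

    Given u_j ~ N(0, sigma2_u) and sigma2_u ~ IG(a0, b0),

        sigma2_u | u ~ IG(a0 + J/2, b0 + 0.5 * sum_j u_j^2)

    (rate parameterisation).  Returns ``(shape, rate)``.
    """
    u = np.asarray(u, dtype=float)
    if u.size == 0:
        raise ValueError("u must be non-empty")
    if a0 <= 0 or b0 <= 0:
        raise ValueError("a0 and b0 must be positive")
    return a0 + u.size / 2.0, b0 + 0.5 * float(np.sum(u**2))


def log_joint_posterior(
    state: ParameterState, data: CohortData, hyper: Hyperparameters
) -> float:
    """Log of the joint posterior density, up to a constant.

    Includes the likelihood, the Gaussian priors for alpha and beta, the
    N(0, sigma2_u) prior for u *with* its -(J/2) log(sigma2_u) normaliser
    (needed for the conjugate sigma2_u update to be consistent), and the
    IG(a0, b0) prior for sigma2_u.  Serves as the oracle against which all
    block conditionals are checked.
    """
    if state.sigma2_u <= 0:
        raise ValueError("sigma2_u must be positive")
    eta = linear_predictor(state, data)
    ll = bernoulli_loglik(data.y, eta)
    lp = -state.alpha**2 / (2.0 * hyper.sigma2_alpha)
    if state.beta.size:
        s2 = hyper.sigma2_beta_vec(state.beta.shape[0])
        lp -= 0.5 * float(np.sum(state.beta**2 / s2))
    J = state.u.shape[0]
    s2u = state.sigma2_u
    lp -= 0.5 * J * np.log(s2u) + float(np.sum(state.u**2)) / (2.0 * s2u)
    lp -= (hyper.a0 + 1.0) * np.log(s2u) + hyper.b0 / s2u
    return ll + lp
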