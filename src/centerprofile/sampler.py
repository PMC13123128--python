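"""Metropolis-Hastings-within-Gibbs sampler.

Each iteration cycles through the parameter blocks in a fixed order:

1. random-walk MH update of the intercept ``alpha``;
2. componentwise random-walk MH sweep over the fixed effects ``beta_k``
   (ascending k);
3. per-center random-walk MH sweep over the random intercepts ``u_j``,
   whose acceptance ratio touches only that center's patients;
4. an exact Gibbs draw of ``sigma2_u`` from its conjugate Inverse-Gamma
   full conditional.

Proposal standard deviations are adapted multiplicatively during burn-in
only (targeting 20-40% acceptance per block) and frozen afterwards, so the
retained draws come from a fixed-kernel chain with the correct invariant
distribution.  Chains are fully reproducible from ``(seed, chain_id)``.

The public ``update_*`` functions are straightforward reference
implementations built on the log full conditionals in
:mod:`centerprofile.model`; :func:`run_chain` uses an equivalent
incremental-eta fast path (the two are cross-checked in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    CohortData,
    Hyperparameters,
    ParameterState,
    ig_full_conditional_params,
    log_conditional_alpha,
    log_conditional_beta,
    log_conditional_u,
    log_joint_posterior,
)

__all__ = [
    "SamplerConfig",
    "PosteriorDraws",
    "mh_accept",
    "update_alpha",
    "update_beta",
    "update_u",
    "update_sigma2_u",
    "adapt_proposals",
    "initial_state",
    "run_chain",
    "run_chains",
]


@dataclass(frozen=True)
class SamplerConfig:
    """Sampler settings; defaults follow the reference run configuration
    (3 chains x 20,000 iterations, burn-in 2,000, thin 1)."""

    n_iter: int = 20_000
    burn_in: int = 2_000
    thin: int = 1
    n_chains: int = 3
    seed: int = 0
    # None = scale each block's initial proposal SD from the curvature of
    # its conditional (2.4 / sqrt(Fisher information at the event rate));
    # a scalar or per-block vector overrides
    proposal_sd_alpha: object = None
    proposal_sd_beta: object = None
    proposal_sd_u: object = None
    adapt: bool = True
    target_accept_window: tuple = (0.20, 0.40)
    adapt_interval: int = 100
    sample_u: bool = True
    sample_sigma2: bool = True

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @property
    def n_retained(self) -> int:
        """Retained draws per chain: floor((n_iter - burn_in) / thin)."""
        return (self.n_iter - self.burn_in) // self.thin

    @property
    def n_retained_total(self) -> int:
        """Pooled retained draws across all chains."""
        return self.n_retained * self.n_chains


@dataclass
class PosteriorDraws:
    """Retained multi-chain samples with acceptance bookkeeping.

    Arrays are indexed ``[chain, draw]`` (plus a trailing parameter axis
    for ``beta`` and ``u``).
    """

    alpha: np.ndarray  # (m, S)
    beta: np.ndarray  # (m, S, p)
    u: np.ndarray  # (m, S, J)
    sigma2_u: np.ndarray  # (m, S)
    beta_names: tuple
    center_labels: tuple
    acceptance: dict  # block name -> (m,) or (m, p)/(m, J) post-burn-in rates
    config: SamplerConfig
    proposal_sd_final: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_retained(self) -> int:
        return self.alpha.shape[1]

    @property
    def n_retained_total(self) -> int:
        return self.alpha.size

    def pooled(self, name: str) -> np.ndarray:
        """Draws for one block pooled across chains (draws axis first)."""
        arr = getattr(self, name)
        return arr.reshape(arr.shape[0] * arr.shape[1], *arr.shape[2:])

    def parameter_names(self) -> list:
        names = ["alpha"]
        names += [f"beta.{n}" for n in self.beta_names]
        names += [f"u.{c}" for c in self.center_labels]
        names.append("sigma2_u")
        return names

    def chain_matrix(self, name: str) -> np.ndarray:
        """Per-chain draws (m, S) for a single named parameter."""
        if name == "alpha":
            return self.alpha
        if name == "sigma2_u":
            return self.sigma2_u
        if name.startswith("beta."):
            k = self.beta_names.index(name[5:])
            return self.beta[:, :, k]
        if name.startswith("u."):
            j = self.center_labels.index(name[2:])
            return self.u[:, :, j]
        raise KeyError(name)


def mh_accept(log_target_proposed: float, log_target_current: float, rng) -> bool:
    """Metropolis accept-reject for a symmetric proposal.

    Accepts with probability min(1, exp(proposed - current)).  A uniform
    variate is always consumed so the RNG stream advances identically on
    accept and reject paths (determinism contract).
    """
    delta = log_target_proposed - log_target_current
    if np.isnan(delta):  # -inf - -inf: current impossible -> always move
        delta = np.inf
    return bool(np.log(rng.uniform()) < delta)


def update_alpha(state, data, hyper, tau_alpha, rng):
    """One random-walk MH update of alpha.  Returns (state, accepted)."""
    prop = state.alpha + tau_alpha * rng.standard_normal()
    lp = log_conditional_alpha(prop, state, data, hyper)
    lc = log_conditional_alpha(state.alpha, state, data, hyper)
    if mh_accept(lp, lc, rng):
        return state.with_(alpha=prop), True
    return state, False


def update_beta(state, data, hyper, tau_beta, rng):
    """Componentwise MH sweep over beta (ascending k).

    Each coordinate is proposed and accepted separately with the full
    conditional evaluated at the current values of all other coordinates.
    Returns (state, accepted flags per k).
    """
    p = data.n_covariates
    tau = np.broadcast_to(np.asarray(tau_beta, dtype=float), (p,))
    beta = state.beta.copy()
    accepted = np.zeros(p, dtype=bool)
    for k in range(p):
        prop = beta.copy()
        prop[k] = beta[k] + tau[k] * rng.standard_normal()
        cur_state = state.with_(beta=beta)
        lp = log_conditional_beta(prop, cur_state, data, hyper)
        lc = log_conditional_beta(beta, cur_state, data, hyper)
        if mh_accept(lp, lc, rng):
            beta = prop
            accepted[k] = True
    return state.with_(beta=beta), accepted


def update_u(state, data, hyper, tau_u, rng):
    """Per-center MH sweep over the random intercepts u_j.

    The acceptance ratio for center j uses only center-j patients plus the
    N(0, sigma2_u) prior term.  Returns (state, accepted flags per j).
    """
    J = data.n_centers
    tau = np.broadcast_to(np.asarray(tau_u, dtype=float), (J,))
    u = state.u.copy()
    accepted = np.zeros(J, dtype=bool)
    for j in range(J):
        prop = u[j] + tau[j] * rng.standard_normal()
        cur_state = state.with_(u=u)
        lp = log_conditional_u(j, prop, cur_state, data, hyper)
        lc = log_conditional_u(j, u[j], cur_state, data, hyper)
        if mh_accept(lp, lc, rng):
            u[j] = prop
            accepted[j] = True
    return state.with_(u=u), accepted


def update_sigma2_u(state, hyper, rng):
    """Exact Gibbs draw of sigma2_u from IG(a0 + J/2, b0 + 0.5 sum u_j^2)."""
    shape, rate = ig_full_conditional_params(state.u, hyper.a0, hyper.b0)
    precision = rng.gamma(shape, 1.0 / rate)
    return state.with_(sigma2_u=1.0 / precision)


def adapt_proposals(acceptance_rates, proposal_sd, config: SamplerConfig,
                    in_burn_in: bool = True):
    """Multiplicative proposal-scale adaptation over the last window.

    Scales each block's proposal SD by 1.1 when its windowed acceptance
    exceeds the upper target, by 1/1.1 when below the lower target.  May
    only be called during burn-in; adaptation is frozen afterwards so
    retained draws come from a fixed kernel.
    """
    if not in_burn_in:
        raise RuntimeError("adapt_proposals must not be called after burn-in")
    lo, hi = config.target_accept_window
    rates = np.asarray(acceptance_rates, dtype=float)
    sd = np.asarray(proposal_sd, dtype=float).copy()
    sd[rates > hi] *= 1.1
    sd[rates < lo] /= 1.1
    return sd


def initial_state(data: CohortData, chain_id: int, rng) -> ParameterState:
    """Default initial state; chains beyond the first are overdispersed.

    Chain 0 starts at alpha = logit(pooled event rate), beta = 0, u = 0,
    sigma2_u = 1; later chains jitter alpha and beta by N(0, 0.5^2).
    """
    rate = float(np.mean(data.y)) if data.n_patients else 0.5
    rate = min(max(rate, 1e-3), 1 - 1e-3)
    alpha = float(np.log(rate / (1 - rate)))
    beta = np.zeros(data.n_covariates)
    if chain_id > 0:
        alpha += 0.5 * rng.standard_normal()
        beta = beta + 0.5 * rng.standard_normal(data.n_covariates)
    return ParameterState(
        alpha=alpha, beta=beta, u=np.zeros(data.n_centers), sigma2_u=1.0
    )


def _chain_rng(seed: int, chain_id: int):
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(chain_id,))
    )


def run_chain(
    data: CohortData,
    hyper: Hyperparameters,
    config: SamplerConfig,
    chain_id: int = 0,
    init: ParameterState | None = None,
):
    """Run one chain; returns a dict of retained arrays and bookkeeping.

    The update cycle per iteration is alpha -> beta sweep -> u sweep ->
    sigma2_u, with incremental updates of the linear predictor.  Fully
    reproducible from ``(config.seed, chain_id)``.
    """
    rng = _chain_rng(config.seed, chain_id)
    if init is None:
        init = initial_state(data, chain_id, rng)

    n, p, J = data.n_patients, data.n_covariates, data.n_centers
    y = data.y
    X = data.X
    # sparse-column bookkeeping: only rows where x_ik != 0 feel a beta_k move
    col_rows = [np.flatnonzero(X[:, k]) for k in range(p)]
    col_vals = [X[col_rows[k], k] for k in range(p)]
    col_ydot = [float(y[col_rows[k]] @ col_vals[k]) for k in range(p)]
    ctr_rows = [np.flatnonzero(data.center_index == j) for j in range(J)]
    ctr_ysum = [float(y[ctr_rows[j]].sum()) for j in range(J)]
    y_sum = float(y.sum())

    alpha = float(init.alpha)
    beta = np.asarray(init.beta, dtype=float).copy()
    u = np.asarray(init.u, dtype=float).copy()
    sigma2_u = float(init.sigma2_u)
    from .model import linear_predictor

    eta = linear_predictor(init, data)
    log_l = np.logaddexp(0.0, eta)  # per-patient log(1 + e^eta), kept in sync
    if not np.isfinite(log_joint_posterior(init, data, hyper)):
        raise ValueError(
            f"non-finite log posterior at initial state of chain {chain_id}"
        )

    s2a = hyper.sigma2_alpha
    s2b = hyper.sigma2_beta_vec(p)
    # initial proposal scales: 2.4 / sqrt(block Fisher information), using
    # the pooled event rate as the working probability; adaptation during
    # burn-in refines these toward the 20-40% acceptance target
    w = max(float(np.mean(y) * (1.0 - np.mean(y))), 1e-3) if n else 0.25
    if config.proposal_sd_alpha is None:
        tau_a = 2.4 / np.sqrt(n * w + 1.0 / s2a)
    else:
        tau_a = float(config.proposal_sd_alpha)
    if config.proposal_sd_beta is None:
        info_b = np.array(
            [float(col_vals[k] @ col_vals[k]) * w for k in range(p)]
        ) + 1.0 / s2b
        tau_b = 2.4 / np.sqrt(info_b)
    else:
        tau_b = np.broadcast_to(
            np.asarray(config.proposal_sd_beta, dtype=float), (p,)
        ).copy()
    if config.proposal_sd_u is None:
        n_j = np.array([len(r) for r in ctr_rows], dtype=float)
        tau_u = 2.4 / np.sqrt(n_j * w + 1.0 / max(sigma2_u, 1e-3))
    else:
        tau_u = np.broadcast_to(
            np.asarray(config.proposal_sd_u, dtype=float), (J,)
        ).copy()

    S = config.n_retained
    out_alpha = np.empty(S)
    out_beta = np.empty((S, p))
    out_u = np.empty((S, J))
    out_s2 = np.empty(S)
    acc_a = 0
    acc_b = np.zeros(p)
    acc_u = np.zeros(J)
    win_a = 0
    win_b = np.zeros(p)
    win_u = np.zeros(J)
    s = 0

    for it in range(config.n_iter):
        # --- alpha: global shift of eta
        delta = tau_a * rng.standard_normal()
        prop_l = np.logaddexp(0.0, eta + delta)
        d_log = (
            y_sum * delta
            - (prop_l.sum() - log_l.sum())
            - ((alpha + delta) ** 2 - alpha**2) / (2.0 * s2a)
        )
        if np.log(rng.uniform()) < d_log:
            alpha += delta
            eta += delta
            log_l = prop_l
            win_a += 1
            if it >= config.burn_in:
                acc_a += 1

        # --- beta sweep, ascending k
        for k in range(p):
            delta = tau_b[k] * rng.standard_normal()
            rows = col_rows[k]
            eta_s = eta[rows] + col_vals[k] * delta
            prop_l_s = np.logaddexp(0.0, eta_s)
            bk = beta[k]
            d_log = (
                col_ydot[k] * delta
                - (prop_l_s.sum() - log_l[rows].sum())
                - ((bk + delta) ** 2 - bk**2) / (2.0 * s2b[k])
            )
            if np.log(rng.uniform()) < d_log:
                beta[k] = bk + delta
                eta[rows] = eta_s
                log_l[rows] = prop_l_s
                win_b[k] += 1
                if it >= config.burn_in:
                    acc_b[k] += 1

        # --- u sweep (center-j patients only)
        if config.sample_u:
            for j in range(J):
                delta = tau_u[j] * rng.standard_normal()
                rows = ctr_rows[j]
                eta_s = eta[rows] + delta
                prop_l_s = np.logaddexp(0.0, eta_s)
                uj = u[j]
                d_log = (
                    ctr_ysum[j] * delta
                    - (prop_l_s.sum() - log_l[rows].sum())
                    - ((uj + delta) ** 2 - uj**2) / (2.0 * sigma2_u)
                )
                if np.log(rng.uniform()) < d_log:
                    u[j] = uj + delta
                    eta[rows] = eta_s
                    log_l[rows] = prop_l_s
                    win_u[j] += 1
                    if it >= config.burn_in:
                        acc_u[j] += 1

        # --- sigma2_u: exact conjugate draw
        if config.sample_sigma2 and J:
            shape, rate = ig_full_conditional_params(u, hyper.a0, hyper.b0)
            sigma2_u = 1.0 / rng.gamma(shape, 1.0 / rate)

        # --- burn-in-only proposal adaptation
        if (
            config.adapt
            and it < config.burn_in
            and (it + 1) % config.adapt_interval == 0
        ):
            aw = config.adapt_interval
            tau_a = float(
                adapt_proposals(np.array([win_a / aw]), np.array([tau_a]), config)[0]
            )
            tau_b = adapt_proposals(win_b / aw, tau_b, config)
            tau_u = adapt_proposals(win_u / aw, tau_u, config)
            win_a = 0
            win_b[:] = 0.0
            win_u[:] = 0.0

        # retained count is exactly floor((n_iter - burn_in) / thin)
        if it >= config.burn_in and (it - config.burn_in + 1) % config.thin == 0:
            out_alpha[s] = alpha
            out_beta[s] = beta
            out_u[s] = u
            out_s2[s] = sigma2_u
            s += 1

    n_post = config.n_iter - config.burn_in
    return {
        "alpha": out_alpha[:s],
        "beta": out_beta[:s],
        "u": out_u[:s],
        "sigma2_u": out_s2[:s],
        "accept_alpha": acc_a / n_post,
        "accept_beta": acc_b / n_post,
        "accept_u": acc_u / n_post,
        "proposal_sd": {"alpha": tau_a, "beta": tau_b.copy(), "u": tau_u.copy()},
    }


def run_chains(
    data: CohortData, hyper: Hyperparameters, config: SamplerConfig
) -> PosteriorDraws:
    """Run ``config.n_chains`` independent chains with disjoint RNG streams
    and overdispersed initial states; returns pooled :class:`PosteriorDraws`."""
    results = [
        run_chain(data, hyper, config, chain_id=c) for c in range(config.n_chains)
    ]
    m = config.n_chains
    S = config.n_retained
    p, J = data.n_covariates, data.n_centers
    draws = PosteriorDraws(
        alpha=np.stack([r["alpha"] for r in results]),
        beta=np.stack([r["beta"] for r in results]).reshape(m, S, p),
        u=np.stack([r["u"] for r in results]).reshape(m, S, J),
        sigma2_u=np.stack([r["sigma2_u"] for r in results]),
        beta_names=data.column_names,
        center_labels=data.center_labels,
        acceptance={
            "alpha": np.array([r["accept_alpha"] for r in results]),
            "beta": np.stack([r["accept_beta"] for r in results]).reshape(m, p),
            "u": np.stack([r["accept_u"] for r in results]).reshape(m, J),
        },
        config=config,
        proposal_sd_final={c: results[c]["proposal_sd"] for c in range(m)},
    )
    return draws
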