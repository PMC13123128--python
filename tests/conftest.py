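import numpy as np
import pytest

from centerprofile.model import CohortData, Hyperparameters, ParameterState
from centerprofile.sampler import PosteriorDraws, SamplerConfig


def random_cohort(rng, n=80, J=4, p=3):
    """Small random cohort with every center populated."""
    ci = rng.integers(0, J, n)
    ci[:J] = np.arange(J)  # guarantee occupancy
    X = rng.integers(0, 2, (n, p)).astype(float)
    y = rng.integers(0, 2, n)
    labels = tuple(chr(ord("A") + j) for j in range(J))
    return CohortData(y=y, X=X, center_index=ci, center_labels=labels)


def random_state(rng, p=3, J=4):
    return ParameterState(
        alpha=float(rng.normal(0, 1)),
        beta=rng.normal(0, 1, p),
        u=rng.normal(0, 1, J),
        sigma2_u=float(rng.uniform(0.2, 2.0)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def small_cohort(rng):
    return random_cohort(rng)


@pytest.fixture
def hyper():
    return Hyperparameters()


def constant_draws(alpha, beta, u, sigma2_u, beta_names, center_labels,
                   n_chains=1, S=4):
    """PosteriorDraws in which every retained draw is the same point."""
    p, J = len(beta_names), len(center_labels)
    cfg = SamplerConfig(n_iter=S + 1, burn_in=1, thin=1, n_chains=n_chains)
    return PosteriorDraws(
        alpha=np.full((n_chains, S), float(alpha)),
        beta=np.tile(np.asarray(beta, dtype=float), (n_chains, S, 1)).reshape(
            n_chains, S, p
        ),
        u=np.tile(np.asarray(u, dtype=float), (n_chains, S, 1)).reshape(
            n_chains, S, J
        ),
        sigma2_u=np.full((n_chains, S), float(sigma2_u)),
        beta_names=tuple(beta_names),
        center_labels=tuple(center_labels),
        acceptance={
            "alpha": np.zeros(n_chains),
            "beta": np.zeros((n_chains, p)),
            "u": np.zeros((n_chains, J)),
        },
        config=cfg,
    )
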