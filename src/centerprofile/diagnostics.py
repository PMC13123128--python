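"""Convergence diagnostics, posterior summary tables, and the posterior
predictive ROC/AUC check.

* ``psrf`` is the classic (unsplit) Gelman-Rubin potential scale reduction
  factor; a split-chain variant is available via ``split=True``.
* ``ess`` estimates effective sample size from the empirical
  autocorrelations, truncated by Geyer's initial-positive-sequence rule.
* ``summarize`` produces the mean / SD / quantile tables with the
  exponentiated (odds-ratio or SIR) columns computed from unrounded draws.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .model import CohortData
from .sampler import PosteriorDraws

__all__ = [
    "psrf",
    "ess",
    "diagnostics_table",
    "summarize",
    "summarize_matrix",
    "posterior_predictive_auc",
]

_QUANTS = (0.025, 0.25, 0.5, 0.75, 0.975)


def psrf(chains, split: bool = False) -> float:
    """Gelman-Rubin potential scale reduction factor.

    Parameters
    ----------
    chains : array (m, n)
        Draws for one parameter, one row per chain (m >= 2, n >= 10).
    split : bool
        If True, each chain is first split in half (split-Rhat).

    With W the mean within-chain variance and B/n the variance of the
    chain means, PSRF = sqrt(((n-1)/n W + B/n) / W).
    """
    c = np.asarray(chains, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2:
        raise ValueError("psrf needs >= 2 chains of equal length")
    if split:
        half = c.shape[1] // 2
        c = np.concatenate([c[:, :half], c[:, half : 2 * half]], axis=0)
    m, n = c.shape
    if n < 10:
        raise ValueError("chains too short for PSRF")
    W = float(np.mean(np.var(c, axis=1, ddof=1)))
    if W == 0.0:
        raise ValueError("PSRF undefined: zero within-chain variance")
    B_over_n = float(np.var(np.mean(c, axis=1), ddof=1))
    V = (n - 1) / n * W + B_over_n
    return float(np.sqrt(V / W))


def ess(draws) -> float:
    """Effective sample size of a single chain of draws.

    ESS = S / (1 + 2 sum_t rho_t) where the autocorrelation sum is
    truncated by the initial-positive-sequence rule on the pair sums
    Gamma_m = rho_{2m} + rho_{2m+1}; the result is clipped to (0, S].
    """
    x = np.asarray(draws, dtype=float)
    if x.ndim != 1 or x.size < 10:
        raise ValueError("ess needs a vector of length >= 10")
    S = x.size
    x = x - x.mean()
    var = float(x @ x) / S
    if var == 0.0:
        raise ValueError("ESS undefined: zero variance")
    # autocovariance by FFT
    nfft = int(2 ** np.ceil(np.log2(2 * S)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:S].real / S
    rho = acov / acov[0]
    # Geyer initial positive sequence on pair sums
    tau = 0.0
    m = 0
    while 2 * m + 1 < S:
        gamma = rho[2 * m] + rho[2 * m + 1]
        if gamma <= 0.0:
            break
        tau += gamma
        m += 1
    tau = max(2.0 * tau - 1.0, 1e-12)  # = 1 + 2 sum rho over the kept window
    return float(min(S / tau, S))


def diagnostics_table(draws: PosteriorDraws, split: bool = False) -> pd.DataFrame:
    """PSRF and ESS for every parameter; ESS is summed across chains."""
    rows = []
    for name in draws.parameter_names():
        c = draws.chain_matrix(name)
        try:
            r = psrf(c, split=split) if c.shape[0] >= 2 else np.nan
        except ValueError:
            r = np.nan
        try:
            e = float(sum(ess(chain) for chain in c))
        except ValueError:
            e = np.nan
        rows.append({"parameter": name, "psrf": r, "ess": e})
    return pd.DataFrame(rows)


def summarize_matrix(samples: np.ndarray, names, exponentiate: bool = True,
                     exp_label: str = "exp") -> pd.DataFrame:
    """Summary table for pooled draws (S, k): mean, SD, quantiles and,
    optionally, the exponentiated scale with exponentiated 2.5/97.5% bounds
    (computed from unrounded draws)."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] < 1:
        raise ValueError("need at least one retained draw")
    q = np.quantile(samples, _QUANTS, axis=0)
    out = pd.DataFrame(
        {
            "parameter": list(names),
            "mean": samples.mean(axis=0),
            "sd": samples.std(axis=0, ddof=1) if samples.shape[0] > 1 else 0.0,
            "q2.5": q[0],
            "q25": q[1],
            "q50": q[2],
            "q75": q[3],
            "q97.5": q[4],
        }
    )
    if exponentiate:
        out[exp_label] = np.exp(out["mean"])
        out[f"{exp_label}_lower"] = np.exp(out["q2.5"])
        out[f"{exp_label}_upper"] = np.exp(out["q97.5"])
    return out


def summarize(draws: PosteriorDraws, params: str = "beta",
              exponentiate: bool = True) -> pd.DataFrame:
    """Posterior summary table for one block of a fitted model.

    ``params`` is one of ``"alpha"``, ``"beta"``, ``"u"`` or
    ``"sigma2_u"``; exponentiated columns are labelled ``OR`` (odds
    ratio).
    """
    if params == "beta":
        samples, names = draws.pooled("beta"), draws.beta_names
    elif params == "u":
        samples, names = draws.pooled("u"), draws.center_labels
    elif params == "alpha":
        samples, names = draws.pooled("alpha")[:, None], ("alpha",)
    elif params == "sigma2_u":
        samples, names = draws.pooled("sigma2_u")[:, None], ("sigma2_u",)
        exponentiate = False
    else:
        raise KeyError(params)
    return summarize_matrix(samples, names, exponentiate=exponentiate,
                            exp_label="OR")


def posterior_predictive_auc(
    draws: PosteriorDraws, data: CohortData, rng, max_draws: int = 500
) -> dict:
    """Posterior predictive discrimination check (ROC AUC).

    For a random subsample of posterior draws, computes each draw's
    fitted probabilities and their ROC AUC against the observed outcomes
    (Mann-Whitney formulation; ties get midranks).  Returns the 2.5/50/
    97.5% quantiles of the per-draw AUCs plus the AUC of the draw-averaged
    probabilities, all on the [0, 1] scale.
    """
    y = data.y
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: outcome has a single class")
    from .profiling import predict_probs

    S = draws.n_retained_total
    n_use = min(max_draws, S)
    idx = rng.choice(S, size=n_use, replace=False) if n_use < S else np.arange(S)
    probs = predict_probs(draws, data, draw_indices=idx)
    aucs = np.array([roc_auc_score(y, probs[s]) for s in range(n_use)])
    q = np.quantile(aucs, (0.025, 0.5, 0.975))
    return {
        "q2.5": float(q[0]),
        "q50": float(q[1]),
        "q97.5": float(q[2]),
        "auc_mean_prob": float(roc_auc_score(y, probs.mean(axis=0))),
        "n_draws": int(n_use),
    }
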