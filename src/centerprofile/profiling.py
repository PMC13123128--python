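"""Center profiling: posterior predictive probabilities, expected counts,
standardized incidence ratios (SIR), funnel-plot control limits, and
FDR-adjusted limits.

For every retained posterior draw *s*, each patient's event probability is

    p_i^(s) = sigma(alpha^(s) + x_i' beta^(s) + u_{j[i]}^(s))

and the per-draw expected count for center *j* is
E_j^(s) = sum over that center's patients of p_i^(s); E_j is the mean over
draws.  The center's performance measure is SIR_j = O_j / E_j with the
zero-count guard (O_j + eps)/(E_j + eps), eps = 1e-6 applied to numerator
and denominator always, and its log.  Funnel-plot control limits on the
log-SIR scale are mu +/- z * sigma_j with sigma_j the posterior SD of the
per-draw log ratios; FDR-adjusted limits replace z by the Benjamini-
Hochberg step-up critical value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .model import CohortData
from .sampler import PosteriorDraws

__all__ = [
    "DEFAULT_EPS",
    "predict_probs",
    "expected_counts",
    "expected_counts_by_center",
    "sir",
    "sir_credible_interval",
    "var_log_sir",
    "funnel_limits",
    "FunnelLimits",
    "fdr_adjusted_limits",
    "center_profiles",
    "classify_centers",
    "funnel_plot_data",
    "plot_funnel",
]

DEFAULT_EPS = 1e-6


def _draw_arrays(draws: PosteriorDraws, draw_indices=None):
    alpha = draws.pooled("alpha")
    beta = draws.pooled("beta")
    u = draws.pooled("u")
    if draw_indices is not None:
        idx = np.asarray(draw_indices)
        alpha, beta, u = alpha[idx], beta[idx], u[idx]
    return alpha, beta, u


def predict_probs(draws: PosteriorDraws, data: CohortData,
                  draw_indices=None) -> np.ndarray:
    """Per-draw per-patient probabilities p_i^(s), shape (S, n)."""
    if tuple(draws.center_labels) != tuple(data.center_labels):
        raise ValueError("draws and cohort disagree on the set of centers")
    alpha, beta, u = _draw_arrays(draws, draw_indices)
    eta = alpha[:, None] + u[:, data.center_index]
    if data.n_covariates:
        eta += beta @ data.X.T
    return expit(eta)


def expected_counts(prob_draws: np.ndarray, center_index: np.ndarray):
    """Per-draw and posterior-mean expected counts per center.

    Returns ``(E_j_draws, E_j)`` with shapes (S, J) and (J,), where
    E_j^(s) sums p_i^(s) over center-j patients and E_j averages over s.
    """
    prob_draws = np.atleast_2d(np.asarray(prob_draws, dtype=float))
    ci = np.asarray(center_index)
    J = int(ci.max()) + 1 if ci.size else 0
    order = np.argsort(ci, kind="stable")
    starts = np.searchsorted(ci[order], np.arange(J))
    E_draws = np.add.reduceat(prob_draws[:, order], starts, axis=1)
    return E_draws, E_draws.mean(axis=0)


def expected_counts_by_center(draws: PosteriorDraws, data: CohortData,
                              chunk: int = 512):
    """(E_j_draws, E_j) over *all* retained draws, computed in chunks so the
    (S, n) probability matrix is never fully materialised."""
    S = draws.n_retained_total
    J = data.n_centers
    E_draws = np.empty((S, J))
    for start in range(0, S, chunk):
        idx = np.arange(start, min(start + chunk, S))
        probs = predict_probs(draws, data, draw_indices=idx)
        E_draws[idx], _ = expected_counts(probs, data.center_index)
    return E_draws, E_draws.mean(axis=0)


def sir(O_j, E_j, eps: float = DEFAULT_EPS):
    """SIR and log-SIR with the additive-eps zero-count guard.

    SIR = (O_j + eps) / (E_j + eps); the guard is applied to numerator and
    denominator always, so positive-count centers shift only at O(eps).
    """
    if O_j < 0 or E_j < 0:
        raise ValueError("counts must be non-negative")
    s = (O_j + eps) / (E_j + eps)
    return float(s), float(np.log(s))


def sir_credible_interval(O_j, E_j_draws, eps: float = DEFAULT_EPS,
                          levels=(0.025, 0.975)):
    """Equal-tail credible bounds for SIR_j from the per-draw ratios
    r^(s) = (O_j + eps)/(E_j^(s) + eps); log-scale bounds are the logs of
    the same quantiles (log is monotone).  Returns (sir_bounds, log_bounds)."""
    E = np.asarray(E_j_draws, dtype=float)
    if E.size < 2:
        raise ValueError("need >= 2 draws")
    r = (O_j + eps) / (E + eps)
    b = np.quantile(r, levels)
    return b, np.log(b)


def var_log_sir(O_j, E_j_draws, eps: float = DEFAULT_EPS,
                method: str = "mcmc") -> float:
    """Variance of log SIR_j.

    ``method="mcmc"`` (default): sample variance of the per-draw log
    ratios log((O_j + eps)/(E_j^(s) + eps)).  O_j is a fixed observed
    count here, so its variance and covariance contributions are zero
    under this estimator.

    ``method="delta"``: descriptive delta-method alternative treating O_j
    as Poisson, 1/max(O_j, eps) + Var[log(E_j^(s) + eps)].
    """
    E = np.asarray(E_j_draws, dtype=float)
    if E.size < 2:
        raise ValueError("need >= 2 draws")
    log_E = np.log(E + eps)
    if method == "mcmc":
        return float(np.var(np.log(O_j + eps) - log_E, ddof=1))
    if method == "delta":
        return float(1.0 / max(O_j, eps) + np.var(log_E, ddof=1))
    raise ValueError(f"unknown method {method!r}")


def funnel_limits(sigma_j: float, alpha_level: float = 0.05, mu: float = 0.0):
    """Conventional funnel control limits mu +/- z_{1-alpha/2} sigma_j."""
    if sigma_j <= 0:
        raise ValueError("sigma_j must be positive")
    if not 0 < alpha_level < 1:
        raise ValueError("alpha_level must be in (0, 1)")
    z = norm.ppf(1.0 - alpha_level / 2.0)
    return mu - z * sigma_j, mu + z * sigma_j


@dataclass
class FunnelLimits:
    """Per-center control limits, conventional and FDR-adjusted."""

    sigmas: np.ndarray
    alpha_level: float
    q: float
    z_conventional: float
    z_fdr: float
    p_values: np.ndarray
    k_star: int  # number of BH rejections (0 = none)
    no_signals: bool
    mu: float = 0.0

    @property
    def conventional(self) -> np.ndarray:
        """(m, 2) lower/upper conventional limits."""
        z = self.z_conventional
        return np.column_stack(
            [self.mu - z * self.sigmas, self.mu + z * self.sigmas]
        )

    @property
    def fdr(self) -> np.ndarray:
        """(m, 2) lower/upper FDR-adjusted limits."""
        z = self.z_fdr
        return np.column_stack(
            [self.mu - z * self.sigmas, self.mu + z * self.sigmas]
        )


def fdr_adjusted_limits(log_sirs, sigmas, q: float = 0.05,
                        alpha_level: float = 0.05, mu: float = 0.0
                        ) -> FunnelLimits:
    """Benjamini-Hochberg FDR-adjusted funnel limits.

    Two-sided p-values p_j = 2 Phi(-|log SIR_j - mu| / sigma_j) are sorted
    ascending; the step-up picks the largest k with p_(k) <= (k/m) q and
    sets z_FDR = Phi^{-1}(1 - p_(k)/2).  When nothing is rejected the
    conventional z_{1-alpha/2} is reported and ``no_signals`` is set.
    """
    log_sirs = np.asarray(log_sirs, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    if log_sirs.shape != sigmas.shape or log_sirs.size < 1:
        raise ValueError("log_sirs and sigmas must be equal-length, m >= 1")
    if np.any(sigmas <= 0):
        raise ValueError("sigmas must be positive")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    m = log_sirs.size
    p = 2.0 * norm.cdf(-np.abs(log_sirs - mu) / sigmas)
    p_sorted = np.sort(p)
    ks = np.flatnonzero(p_sorted <= (np.arange(1, m + 1) / m) * q)
    z_conv = float(norm.ppf(1.0 - alpha_level / 2.0))
    if ks.size:
        k_star = int(ks[-1]) + 1
        # isf(p/2) = Phi^{-1}(1 - p/2), stable for p near 0
        z_fdr = float(norm.isf(p_sorted[k_star - 1] / 2.0))
        no_signals = False
    else:
        k_star = 0
        z_fdr = z_conv
        no_signals = True
    return FunnelLimits(
        sigmas=sigmas, alpha_level=alpha_level, q=q, z_conventional=z_conv,
        z_fdr=z_fdr, p_values=p, k_star=k_star, no_signals=no_signals, mu=mu,
    )


def center_profiles(draws: PosteriorDraws, data: CohortData,
                    eps: float = DEFAULT_EPS, levels=(0.025, 0.975),
                    chunk: int = 512) -> pd.DataFrame:
    """Full per-center profile table.

    Columns: center, N (patients), O (observed events), E (posterior-mean
    expected events), sir, log_sir, log-scale and ratio-scale credible
    bounds, sd_log_sir, and precision 1/sqrt(E).
    """
    E_draws, E = expected_counts_by_center(draws, data, chunk=chunk)
    O = data.observed_counts()
    N = data.center_counts()
    rows = []
    for j, label in enumerate(data.center_labels):
        s, ls = sir(O[j], E[j], eps)
        sb, lb = sir_credible_interval(O[j], E_draws[:, j], eps, levels)
        v = var_log_sir(O[j], E_draws[:, j], eps)
        rows.append(
            {
                "center": label,
                "N": int(N[j]),
                "O": int(O[j]),
                "E": E[j],
                "sir": s,
                "log_sir": ls,
                "sd_log_sir": np.sqrt(v),
                "log_sir_lower": lb[0],
                "log_sir_upper": lb[1],
                "sir_lower": sb[0],
                "sir_upper": sb[1],
                "precision": 1.0 / np.sqrt(E[j]) if E[j] > 0 else np.inf,
            }
        )
    return pd.DataFrame(rows)


def classify_centers(profiles: pd.DataFrame,
                     limits: FunnelLimits | None = None) -> pd.DataFrame:
    """Add CrI-based and (optionally) FDR-based classifications.

    CrI rule: "above" if the 2.5% log-SIR bound exceeds 0, "below" if the
    97.5% bound is under 0, else "consistent".  FDR rule: outside the
    +/- z_FDR sigma_j band; a point exactly on a limit counts as within.
    """
    out = profiles.copy()
    out["class_cri"] = np.where(
        out["log_sir_lower"] > 0, "above",
        np.where(out["log_sir_upper"] < 0, "below", "consistent"),
    )
    if limits is not None:
        lo, hi = limits.fdr[:, 0], limits.fdr[:, 1]
        out["class_fdr"] = np.where(
            out["log_sir"].to_numpy() > hi, "above",
            np.where(out["log_sir"].to_numpy() < lo, "below", "consistent"),
        )
    return out


def funnel_plot_data(profiles: pd.DataFrame, limits: FunnelLimits,
                     n_grid: int = 200) -> dict:
    """Plot-ready tables for a funnel plot of log-SIR vs precision.

    Returns ``{"centers": ..., "limits": ...}``: the per-center points
    (precision = 1/sqrt(E_j), log-SIR, in/out flags; input order
    preserved) and the conventional and FDR limit curves evaluated on a
    precision grid.  The limits are +/- z sigma_j per center; to draw them
    as curves, sigma is interpolated across centers as a function of
    precision.
    """
    pts = classify_centers(profiles, limits)
    sig = np.asarray(limits.sigmas, dtype=float)
    prec = pts["precision"].to_numpy(dtype=float)
    order = np.argsort(prec)
    grid = np.linspace(prec.min(), prec.max(), n_grid)
    sig_on_grid = np.interp(grid, prec[order], sig[order])
    curves = pd.DataFrame(
        {
            "precision": grid,
            "sigma": sig_on_grid,
            "conv_lower": limits.mu - limits.z_conventional * sig_on_grid,
            "conv_upper": limits.mu + limits.z_conventional * sig_on_grid,
            "fdr_lower": limits.mu - limits.z_fdr * sig_on_grid,
            "fdr_upper": limits.mu + limits.z_fdr * sig_on_grid,
        }
    )
    return {"centers": pts, "limits": curves}


def plot_funnel(profiles: pd.DataFrame, limits: FunnelLimits, path=None):
    """Render the funnel plot (log-SIR against sigma_j) to ``path`` or
    return the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = funnel_plot_data(profiles, limits)
    fig, ax = plt.subplots(figsize=(7, 5))
    curves = d["limits"]
    ax.plot(curves["precision"], curves["conv_lower"], "k--", lw=0.8,
            label=f"{(1 - limits.alpha_level) * 100:.0f}% limits")
    ax.plot(curves["precision"], curves["conv_upper"], "k--", lw=0.8)
    ax.plot(curves["precision"], curves["fdr_lower"], "r-.", lw=0.8,
            label=f"FDR limits (q={limits.q})")
    ax.plot(curves["precision"], curves["fdr_upper"], "r-.", lw=0.8)
    ax.axhline(limits.mu, color="k", lw=1)
    pts = d["centers"]
    ax.scatter(pts["precision"], pts["log_sir"], s=18, c="tab:blue")
    ax.set_xlabel(r"precision $1/\sqrt{E_j}$")
    ax.set_ylabel("log SIR")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
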