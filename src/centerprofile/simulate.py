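"""Synthetic cohort generator with known ground truth.

Emulates the structure of an Australian kidney-replacement-therapy
registry extract: ~34 centers labelled alphabetically and split into
Indigenous/non-Indigenous sub-centers ("AI", "AN", ...), heavily varying
center sizes (log-normal, roughly 20 to 2,500 patients, ~17,000 total at
the defaults), categorical patient covariates with realistic and partly
sparse prevalences (CVD well under 1%), an overall two-year transplant
prevalence around 12%, and a couple of small centers forced to have
(essentially) zero events.

Outcomes are drawn from the same hierarchical logistic model the sampler
fits: u_j ~ N(0, sigma_u^2), y_i ~ Bernoulli(sigma(alpha + x_i'beta +
u_{j[i]})).  The generating parameters default to posterior point
estimates reported for the real registry analysis, so synthetic fits land
in a realistic regime; every value is overridable.  Generation is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .model import CohortData, ParameterState

__all__ = [
    "Covariate",
    "SimulationConfig",
    "SyntheticTruth",
    "default_covariates",
    "generate_cohort",
    "generate_cohort_table",
    "inject_zero_event_center",
]

_LETTERS = "ABCDEFGHIJOPQRSTU"  # 17 letters x {I, N} = 34 centers


@dataclass(frozen=True)
class Covariate:
    """One categorical covariate: level names, prevalences, true effects.

    The first level is the reference; ``betas`` gives the true log-odds
    for the remaining levels, in order.  Design columns are named
    ``{name}.{level}``.
    """

    name: str
    levels: tuple
    probs: tuple
    betas: tuple  # length len(levels) - 1

    def __post_init__(self):
        if len(self.probs) != len(self.levels):
            raise ValueError(f"{self.name}: probs/levels length mismatch")
        if len(self.betas) != len(self.levels) - 1:
            raise ValueError(f"{self.name}: need one beta per non-reference level")
        if not np.isclose(sum(self.probs), 1.0):
            raise ValueError(f"{self.name}: prevalences must sum to 1")
        if min(self.probs) < 0:
            raise ValueError(f"{self.name}: prevalences must be in [0, 1]")

    @property
    def column_names(self):
        return tuple(f"{self.name}.{lv}" for lv in self.levels[1:])


def default_covariates() -> tuple:
    """Default covariate mix: prevalences chosen to mimic the registry's
    marginal structure, true effects set to estimates from a real registry analysis of this outcome."""
    return (
        Covariate("sex", ("Female", "Male"), (0.40, 0.60), (0.14,)),
        Covariate(
            "age_group",
            ("<26", "26-36", "36-46", "46-56", "56-66", "66-76", "76+"),
            (0.12, 0.16, 0.20, 0.22, 0.16, 0.10, 0.04),
            (-0.14, -0.31, -0.82, -1.14, -2.35, -5.25),
        ),
        Covariate(
            "indigenous", ("Indigenous", "Non_Indigenous"), (0.04, 0.96), (1.73,)
        ),
        Covariate("lung_disease", ("No", "Yes"), (0.90, 0.10), (-0.81,)),
        Covariate("diabetes", ("No", "Yes"), (0.55, 0.45), (-1.08,)),
        Covariate("cvd", ("No", "Yes"), (0.996, 0.004), (1.04,)),
        Covariate("late_referral", ("No", "Yes"), (0.75, 0.25), (-0.93,)),
        Covariate("obesity", ("No", "Yes"), (0.70, 0.30), (-0.52,)),
        Covariate(
            "mmm",
            ("1", "2", "3", "4", "5", "6", "7"),
            (0.45, 0.15, 0.10, 0.08, 0.08, 0.07, 0.07),
            (0.20, -0.02, -0.02, 0.08, -0.31, 0.11),
        ),
        # two-year follow-up is required for the outcome, so the latest
        # era is under-represented relative to registry growth
        Covariate(
            "period",
            ("2006-2009", "2010-2014", "2015-2018", "2019-2023"),
            (0.30, 0.28, 0.24, 0.18),
            (-0.23, -0.29, -1.27),
        ),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Synthetic cohort settings.

    Center sizes are log-normal (``size_meanlog``, ``size_sdlog``, clipped
    below at ``size_min``); the defaults give N_j from a few dozen to a
    couple of thousand and ~17,000 patients in total over J = 34 centers.
    ``zero_event_centers`` of the smallest centers get their random
    intercept forced to -6, which drives their event probability to ~0
    while keeping the generating model coherent.
    """

    J: int = 34
    center_labels: tuple = ()
    size_meanlog: float = float(np.log(280.0))
    size_sdlog: float = 1.1
    size_min: int = 15
    covariates: tuple = field(default_factory=default_covariates)
    true_alpha: float = -2.38
    true_sigma_u: float = 0.4
    zero_event_centers: int = 2
    zero_event_u: float = -6.0
    seed: int = 0

    def __post_init__(self):
        if self.J < 2:
            raise ValueError("J must be >= 2")
        if self.zero_event_centers > self.J:
            raise ValueError("zero_event_centers cannot exceed J")
        if not self.center_labels:
            labels = [f"{c}{g}" for c in _LETTERS for g in ("I", "N")]
            if self.J > len(labels):
                labels += [f"Z{i}" for i in range(self.J - len(labels))]
            object.__setattr__(self, "center_labels", tuple(labels[: self.J]))
        if len(self.center_labels) != self.J:
            raise ValueError("center_labels length must equal J")

    def scaled_to(self, total_patients: int) -> "SimulationConfig":
        """Config with the size law rescaled toward a target total n."""
        expected = self.J * np.exp(self.size_meanlog + self.size_sdlog**2 / 2)
        shift = float(np.log(total_patients / expected))
        return replace(
            self,
            size_meanlog=self.size_meanlog + shift,
            size_min=max(3, int(self.size_min * total_patients / expected)),
        )

    @property
    def beta_names(self) -> tuple:
        return tuple(n for c in self.covariates for n in c.column_names)

    @property
    def true_beta(self) -> np.ndarray:
        return np.array([b for c in self.covariates for b in c.betas])


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating parameters and per-center true event rates."""

    alpha: float
    beta: np.ndarray
    beta_names: tuple
    u: np.ndarray
    sigma2_u: float
    center_labels: tuple
    center_rates: np.ndarray
    seed: int

    @property
    def state(self) -> ParameterState:
        return ParameterState(
            alpha=self.alpha, beta=self.beta, u=self.u, sigma2_u=self.sigma2_u
        )


def _generate(config: SimulationConfig):
    rng = np.random.default_rng(config.seed)
    J = config.J
    sizes = np.maximum(
        np.round(
            rng.lognormal(config.size_meanlog, config.size_sdlog, size=J)
        ).astype(int),
        config.size_min,
    )
    u = rng.normal(0.0, np.sqrt(config.true_sigma_u**2), size=J)
    # force near-zero event probability at the smallest centers
    if config.zero_event_centers:
        smallest = np.argsort(sizes, kind="stable")[: config.zero_event_centers]
        u[smallest] = config.zero_event_u

    n = int(sizes.sum())
    center_index = np.repeat(np.arange(J), sizes)
    frame = {"center": np.repeat(np.asarray(config.center_labels), sizes)}
    cols = []
    names = []
    for cov in config.covariates:
        codes = rng.choice(len(cov.levels), size=n, p=cov.probs)
        frame[cov.name] = np.asarray(cov.levels, dtype=object)[codes]
        for lv in range(1, len(cov.levels)):
            cols.append((codes == lv).astype(float))
        names.extend(cov.column_names)
    X = np.column_stack(cols) if cols else np.empty((n, 0))
    beta = config.true_beta
    eta = config.true_alpha + X @ beta + u[center_index]
    p = expit(eta)
    y = (rng.uniform(size=n) < p).astype(int)
    frame["transplanted"] = y

    cohort = CohortData(
        y=y, X=X, center_index=center_index,
        center_labels=config.center_labels, column_names=tuple(names),
    )
    rates = np.bincount(center_index, weights=p, minlength=J) / sizes
    truth = SyntheticTruth(
        alpha=config.true_alpha, beta=beta, beta_names=tuple(names), u=u,
        sigma2_u=config.true_sigma_u**2, center_labels=config.center_labels,
        center_rates=rates, seed=config.seed,
    )
    df = pd.DataFrame(frame)[
        ["center"] + [c.name for c in config.covariates] + ["transplanted"]
    ]
    return cohort, truth, df


def generate_cohort(config: SimulationConfig):
    """Draw a synthetic cohort; returns ``(CohortData, SyntheticTruth)``."""
    cohort, truth, _ = _generate(config)
    return cohort, truth


def generate_cohort_table(config: SimulationConfig):
    """As :func:`generate_cohort` but also returns the raw categorical
    patient table (one row per patient) for writing to delimited text."""
    cohort, truth, df = _generate(config)
    return df, cohort, truth


def inject_zero_event_center(cohort: CohortData, j: int, size: int,
                             rng=None) -> CohortData:
    """Replace center ``j`` with ``size`` all-negative patients.

    Covariate rows are resampled from the existing cohort; the outcome is
    forced to 0, exercising the eps rule and FDR edge cases downstream.
    """
    if not 0 <= j < cohort.n_centers:
        raise ValueError(f"invalid center index {j}")
    if rng is None:
        rng = np.random.default_rng(0)
    keep = cohort.center_index != j
    src = rng.choice(cohort.n_patients, size=size, replace=True)
    X = np.vstack([cohort.X[keep], cohort.X[src]])
    y = np.concatenate([cohort.y[keep], np.zeros(size)])
    ci = np.concatenate([cohort.center_index[keep], np.full(size, j)])
    return CohortData(
        y=y, X=X, center_index=ci, center_labels=cohort.center_labels,
        column_names=cohort.column_names,
    )
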