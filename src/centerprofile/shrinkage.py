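"""Partial-pooling (shrinkage) descriptives.

A hierarchical model pulls each center's raw event rate toward the group
mean, most strongly for small centers.  This module quantifies that pull
on the logit scale:

* ``empirical_logit`` — the raw center rate with a Haldane-Anscombe 0.5
  continuity correction so zero- and full-event centers stay finite;
* ``shrunken_logit`` — logit(E_j / N_j), the model-implied center rate
  from the posterior-mean expected count;
* ``shrinkage_table`` — per-center distance moved, percent moved toward
  the group mean, and a low/medium/high volume category (tertiles of N_j).

These are this package's operationalizations of the named descriptive
metrics; the formulas are documented here and in the methods note.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import CohortData
from .sampler import PosteriorDraws

__all__ = [
    "empirical_logit",
    "shrunken_logit",
    "shrinkage_metrics",
    "shrinkage_table",
]


def empirical_logit(O_j, N_j, correction: float = 0.5) -> float:
    """log((O_j + c) / (N_j - O_j + c)) with Haldane-Anscombe c = 0.5."""
    if N_j <= 0:
        raise ValueError("N_j must be positive")
    if not 0 <= O_j <= N_j:
        raise ValueError("require 0 <= O_j <= N_j")
    return float(np.log((O_j + correction) / (N_j - O_j + correction)))


def shrunken_logit(draws: PosteriorDraws, data: CohortData, j: int) -> float:
    """Model-implied center rate on the logit scale: logit(E_j / N_j)."""
    from .profiling import expected_counts_by_center

    _, E = expected_counts_by_center(draws, data)
    N = data.center_counts()
    r = E[j] / N[j]
    return float(np.log(r / (1.0 - r)))


def _volume_categories(N: np.ndarray, labels) -> np.ndarray:
    """Tertiles of N_j; ties broken by center label order."""
    order = np.lexsort((np.arange(len(N)), N))  # stable in input order
    thirds = np.array_split(order, 3)
    cats = np.empty(len(N), dtype=object)
    for name, idx in zip(("low", "medium", "high"), thirds):
        cats[idx] = name
    return cats


def shrinkage_metrics(center_labels, N, O, empirical, shrunken,
                      weighted_group_mean: bool = False) -> pd.DataFrame:
    """Pull-to-mean metrics from precomputed empirical/shrunken logits.

    distance_moved = |empirical - shrunken|;
    pct_moved = 100 (|empirical - gm| - |shrunken - gm|) / |empirical - gm|
    with gm the group mean of the empirical logits (unweighted by default,
    N_j-weighted behind ``weighted_group_mean``); pct_moved is NaN for a
    center sitting exactly at the group mean.  Negative pct_moved means
    the model estimate sits farther from the mean than the raw one; 100
    means complete pooling onto the group mean.
    """
    N = np.asarray(N)
    emp = np.asarray(empirical, dtype=float)
    shr = np.asarray(shrunken, dtype=float)
    gm = float(np.average(emp, weights=N if weighted_group_mean else None))
    d_emp = np.abs(emp - gm)
    d_shr = np.abs(shr - gm)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(d_emp > 0, 100.0 * (d_emp - d_shr) / d_emp, np.nan)
    return pd.DataFrame(
        {
            "center": list(center_labels),
            "N": N,
            "O": np.asarray(O),
            "empirical_logit": emp,
            "shrunken_logit": shr,
            "group_mean_logit": gm,
            "distance_moved": np.abs(emp - shr),
            "pct_moved": pct,
            "volume_category": _volume_categories(N, center_labels),
        }
    )


def shrinkage_table(draws: PosteriorDraws, data: CohortData,
                    correction: float = 0.5,
                    weighted_group_mean: bool = False) -> pd.DataFrame:
    """Per-center shrinkage record for a fitted model (see
    :func:`shrinkage_metrics` for the metric definitions)."""
    from .profiling import expected_counts_by_center

    O = data.observed_counts()
    N = data.center_counts()
    emp = np.array(
        [empirical_logit(O[j], N[j], correction) for j in range(data.n_centers)]
    )
    _, E = expected_counts_by_center(draws, data)
    rate = E / N
    shr = np.log(rate / (1.0 - rate))
    return shrinkage_metrics(
        data.center_labels, N, O, emp, shr,
        weighted_group_mean=weighted_group_mean,
    )
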