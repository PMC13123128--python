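"""Cohort and draws I/O.

All artifacts are delimited text (CSV, or TSV by extension) so runs are
transparent and diffable: the patient table, the design-matrix encoding
map, one draws file per chain, and a JSON run manifest carrying the
configuration echo, seeds and per-block acceptance rates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import CohortData
from .sampler import PosteriorDraws, SamplerConfig

__all__ = [
    "ColumnRoles",
    "load_cohort",
    "save_cohort",
    "encoding_map",
    "save_draws",
    "load_draws",
    "write_manifest",
]


@dataclass(frozen=True)
class ColumnRoles:
    """Column-role declarations for a patient table.

    ``covariates`` maps covariate column name to its ordered levels,
    reference level first; design columns are ``{name}.{level}`` for the
    non-reference levels in the declared order.
    """

    outcome: str = "transplanted"
    center: str = "center"
    covariates: dict = field(default_factory=dict)

    def design_columns(self):
        return [
            f"{name}.{lv}"
            for name, levels in self.covariates.items()
            for lv in levels[1:]
        ]


def _read_delimited(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                     na_values=[""])
    if df.empty:
        raise ValueError(f"{path}: file contains no data rows")
    return df


def load_cohort(path, roles: ColumnRoles) -> CohortData:
    """Read and validate a delimited patient table into a CohortData.

    Missing values in required columns are rejected with row numbers (the
    model has no imputation step); unknown covariate levels and non-binary
    outcomes are rejected likewise.  A center with a single patient is
    accepted with a low-volume warning.
    """
    df = _read_delimited(path)
    required = [roles.outcome, roles.center, *roles.covariates]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    na_rows = df[required].isna().any(axis=1)
    if na_rows.any():
        rows = (np.flatnonzero(na_rows) + 2).tolist()  # 1-based incl. header
        raise ValueError(f"{path}: missing values in required fields at "
                         f"file row(s) {rows[:20]}")
    y_raw = df[roles.outcome]
    bad = ~y_raw.isin(["0", "1"])
    if bad.any():
        r = int(np.flatnonzero(bad)[0]) + 2
        raise ValueError(
            f"{path}: outcome {y_raw[bad].iloc[0]!r} at file row {r} is not 0/1"
        )
    y = y_raw.astype(int).to_numpy()

    labels = tuple(pd.unique(df[roles.center]))
    label_to_idx = {c: j for j, c in enumerate(labels)}
    center_index = df[roles.center].map(label_to_idx).to_numpy()
    counts = np.bincount(center_index, minlength=len(labels))
    for j in np.flatnonzero(counts == 1):
        warnings.warn(f"center {labels[j]!r} has a single patient "
                      "(low-volume estimate will be prior-dominated)")

    cols, names = [], []
    for name, levels in roles.covariates.items():
        known = set(levels)
        unknown = ~df[name].isin(known)
        if unknown.any():
            r = int(np.flatnonzero(unknown)[0]) + 2
            raise ValueError(
                f"{path}: unknown level {df[name][unknown].iloc[0]!r} for "
                f"covariate {name!r} at file row {r}"
            )
        for lv in levels[1:]:
            cols.append((df[name] == lv).to_numpy(dtype=float))
            names.append(f"{name}.{lv}")
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return CohortData(
        y=y, X=X, center_index=center_index, center_labels=labels,
        column_names=tuple(names),
    )


def save_cohort(df: pd.DataFrame, path):
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, index=False)


def encoding_map(roles: ColumnRoles) -> pd.DataFrame:
    """Design-matrix column -> covariate / level / reference map."""
    rows = []
    for name, levels in roles.covariates.items():
        for lv in levels[1:]:
            rows.append(
                {
                    "design_column": f"{name}.{lv}",
                    "covariate": name,
                    "level": lv,
                    "reference": levels[0],
                }
            )
    return pd.DataFrame(rows)


def save_draws(draws: PosteriorDraws, out_dir):
    """One delimited file per chain plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for c in range(draws.n_chains):
        df = pd.DataFrame({"iteration": np.arange(draws.n_retained)})
        df["alpha"] = draws.alpha[c]
        for k, name in enumerate(draws.beta_names):
            df[f"beta.{name}"] = draws.beta[c, :, k]
        for j, lab in enumerate(draws.center_labels):
            df[f"u.{lab}"] = draws.u[c, :, j]
        df["sigma2_u"] = draws.sigma2_u[c]
        df.to_csv(out / f"chain_{c}.csv", index=False)
    write_manifest(draws, out / "manifest.json")


def write_manifest(draws: PosteriorDraws, path):
    cfg = draws.config
    manifest = {
        "config": {
            "n_iter": cfg.n_iter,
            "burn_in": cfg.burn_in,
            "thin": cfg.thin,
            "n_chains": cfg.n_chains,
            "seed": cfg.seed,
            "adapt": cfg.adapt,
            "target_accept_window": list(cfg.target_accept_window),
        },
        "n_retained_per_chain": draws.n_retained,
        "n_retained_total": draws.n_retained_total,
        "beta_names": list(draws.beta_names),
        "center_labels": list(draws.center_labels),
        "acceptance": {
            "alpha": draws.acceptance["alpha"].tolist(),
            "beta": draws.acceptance["beta"].tolist(),
            "u": draws.acceptance["u"].tolist(),
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2))


def load_draws(out_dir) -> PosteriorDraws:
    """Rebuild a PosteriorDraws from ``save_draws`` output."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    beta_names = tuple(manifest["beta_names"])
    labels = tuple(manifest["center_labels"])
    cfg_d = manifest["config"]
    config = SamplerConfig(
        n_iter=cfg_d["n_iter"], burn_in=cfg_d["burn_in"], thin=cfg_d["thin"],
        n_chains=cfg_d["n_chains"], seed=cfg_d["seed"], adapt=cfg_d["adapt"],
        target_accept_window=tuple(cfg_d["target_accept_window"]),
    )
    alpha, beta, u, s2 = [], [], [], []
    for c in range(config.n_chains):
        df = pd.read_csv(out / f"chain_{c}.csv")
        alpha.append(df["alpha"].to_numpy())
        beta.append(df[[f"beta.{n}" for n in beta_names]].to_numpy())
        u.append(df[[f"u.{lab}" for lab in labels]].to_numpy())
        s2.append(df["sigma2_u"].to_numpy())
    m = config.n_chains
    S = alpha[0].shape[0]
    return PosteriorDraws(
        alpha=np.stack(alpha),
        beta=np.stack(beta).reshape(m, S, len(beta_names)),
        u=np.stack(u).reshape(m, S, len(labels)),
        sigma2_u=np.stack(s2),
        beta_names=beta_names,
        center_labels=labels,
        acceptance={
            "alpha": np.asarray(manifest["acceptance"]["alpha"]),
            "beta": np.asarray(manifest["acceptance"]["beta"]),
            "u": np.asarray(manifest["acceptance"]["u"]),
        },
        config=config,
    )
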