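"""Adjusted yields from augmented complete block design field books.

Single-environment adjustment fits the fixed-effect augmented-design
model (mean + block + check-identifier + genotype) by least squares and
returns check-corrected, block-corrected line estimates (BLUEs).  Because
test entries are unreplicated, the genotype term saturates its plots and
the block effects are identified entirely by the replicated checks; the
BLUE of a test line is its plot yield minus the (recentred) block effect.

Across environments the genotype term is treated as random and its
variance component estimated by REML profiled over the variance ratio
(environment, nested-block and check-identifier terms fixed; interaction
terms folded into the residual), yielding shrunken line values (BLUPs)
and the (sigma_g^2, sigma_e^2) pair that feeds broad-sense heritability
H^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixedmodel import reml_fit, gls_blup

__all__ = [
    "AdjustedPhenotypes",
    "adjust_single_env",
    "adjust_multi_env",
    "variance_components_single_env",
    "estimate_h2",
]


@dataclass
class AdjustedPhenotypes:
    """Per-line adjusted yields plus the variance components behind H^2."""

    values: pd.Series                    # test lines only, t/ha
    mode: str                            # "BLUE" | "BLUP"
    environment_scope: str
    check_values: pd.Series | None = None
    variance_components: dict | None = None   # {"sigma_g2": ., "sigma_e2": .}

    def __post_init__(self):
        if self.values.isna().any():
            raise ValueError("NaN adjusted values")
        if self.variance_components is not None:
            vc = self.variance_components
            if vc["sigma_g2"] < 0 or vc["sigma_e2"] <= 0:
                raise ValueError("invalid variance components")

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({
            "line_id": self.values.index,
            "adjusted_value": self.values.to_numpy(),
        })
        df["mode"] = self.mode
        df["environment_scope"] = self.environment_scope
        df.to_csv(path, sep="\t", index=False)


def _drop_missing(fb: pd.DataFrame) -> pd.DataFrame:
    # augmented designs tolerate unbalanced blocks: listwise deletion
    return fb.dropna(subset=["yield_t_ha"]).reset_index(drop=True)


def _check_block_effects(checks: pd.DataFrame) -> pd.Series:
    """Least-squares block effects from the replicated check plots.

    Fits ``y ~ block + check_id`` on check plots only (the exact OLS
    solution for block effects in an augmented design, since unreplicated
    genotype terms saturate the test plots) and recentres the estimates to
    mean zero over blocks so check BLUEs average to the raw check mean.
    """
    blocks = pd.Categorical(checks["block"])
    ids = pd.Categorical(checks["line_id"])
    n = len(checks)
    Xb = pd.get_dummies(blocks, drop_first=True, dtype=float).to_numpy()
    Xi = pd.get_dummies(ids, drop_first=True, dtype=float).to_numpy()
    X = np.column_stack([np.ones(n), Xb, Xi])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("check/block design is collinear (disconnected checks)")
    coef, *_ = np.linalg.lstsq(X, checks["yield_t_ha"].to_numpy(), rcond=None)
    b = np.concatenate([[0.0], coef[1:1 + Xb.shape[1]]])
    b = b - b.mean()
    return pd.Series(b, index=list(blocks.categories))


def adjust_single_env(
    fieldbook: pd.DataFrame,
    environment: str,
    compute_vc: bool = False,
) -> AdjustedPhenotypes:
    """BLUEs for the test lines of one environment's augmented trial."""
    fb = _drop_missing(fieldbook[fieldbook["environment"] == environment])
    if fb.empty:
        raise ValueError(f"no plots for environment {environment!r}")
    blocks = fb["block"].unique()
    checks = fb[fb["is_check"]]
    tests = fb[~fb["is_check"]]
    if tests.duplicated(subset="line_id").any():
        raise ValueError("replicated test line within environment")

    if len(blocks) <= 1 or checks.empty:
        if len(blocks) > 1:
            raise ValueError("multi-block trial without checks is not adjustable")
        block_eff = pd.Series(0.0, index=blocks)
    else:
        counts = checks.groupby("block").size()
        missing = [b for b in blocks if counts.get(b, 0) == 0]
        if missing:
            raise ValueError(f"block(s) without any check plot: {missing}")
        block_eff = _check_block_effects(checks)

    adj = tests["yield_t_ha"].to_numpy() - block_eff.reindex(tests["block"]).to_numpy()
    values = pd.Series(adj, index=tests["line_id"].to_numpy()).sort_index()

    chk_adj = checks["yield_t_ha"].to_numpy() - block_eff.reindex(checks["block"]).to_numpy()
    check_values = (
        pd.Series(chk_adj, index=checks["line_id"].to_numpy())
        .groupby(level=0).mean().sort_index()
        if not checks.empty else None
    )

    vc = None
    if compute_vc:
        fit = variance_components_single_env(fieldbook, environment)
        vc = {"sigma_g2": fit.sigma_g2, "sigma_e2": fit.sigma_e2}
    return AdjustedPhenotypes(values, "BLUE", environment, check_values, vc)


def _fixed_design(fb: pd.DataFrame, with_env: bool) -> np.ndarray:
    """Intercept + (env) + block-within-env + check-identifier dummies.

    The check identifier is a factor with one level per named check plus a
    single pooled level for all unreplicated test genotypes.
    """
    n = len(fb)
    cols = [np.ones(n)]
    if with_env:
        env = pd.Categorical(fb["environment"])
        cols.append(pd.get_dummies(env, drop_first=True, dtype=float).to_numpy())
    # drop one block per environment to avoid collinearity with env dummies
    for env_name, sub in fb.groupby("environment", sort=True):
        blocks = sorted(sub["block"].unique())
        for b in blocks[1:]:
            cols.append(((fb["environment"] == env_name) & (fb["block"] == b))
                        .to_numpy(dtype=float)[:, None])
    check_id = np.where(fb["is_check"], fb["line_id"], "__TEST__")
    cols.append(pd.get_dummies(pd.Categorical(check_id), drop_first=True,
                               dtype=float).to_numpy())
    X = np.column_stack([np.atleast_2d(c.T).T if c.ndim == 1 else c for c in cols])
    # prune exactly collinear columns (e.g. a check present in every plot of a block)
    keep, rank = [], 0
    for j in range(X.shape[1]):
        r = np.linalg.matrix_rank(X[:, keep + [j]])
        if r > rank:
            keep.append(j)
            rank = r
    return X[:, keep]


def variance_components_single_env(fieldbook: pd.DataFrame, environment: str):
    """REML (sigma_g2, sigma_e2) from one environment's augmented trial.

    Genotype random; residual variance is identified by the replicated
    checks, genetic variance by the between-line spread of the
    unreplicated test plots.
    """
    fb = _drop_missing(fieldbook[fieldbook["environment"] == environment])
    if fb[fb["is_check"]].empty:
        raise ValueError("variance components need replicated check plots")
    X = _fixed_design(fb, with_env=False)
    Z = pd.get_dummies(
        pd.Categorical(np.where(fb["is_check"], "__CHK__", fb["line_id"])),
        dtype=float,
    )
    Z = Z.drop(columns="__CHK__", errors="ignore").to_numpy()
    A = Z @ Z.T
    return reml_fit(fb["yield_t_ha"].to_numpy(), X, A)


def adjust_multi_env(fieldbook: pd.DataFrame) -> AdjustedPhenotypes:
    """Genotype BLUPs and variance components across >= 2 environments."""
    fb = _drop_missing(fieldbook)
    envs = sorted(fb["environment"].unique())
    if len(envs) < 2:
        raise ValueError("multi-environment adjustment needs >= 2 environments")
    X = _fixed_design(fb, with_env=True)
    test_mask = ~fb["is_check"].to_numpy()
    lines = pd.Categorical(np.where(test_mask, fb["line_id"], "__CHK__"))
    Zdf = pd.get_dummies(lines, dtype=float).drop(columns="__CHK__", errors="ignore")
    line_order = list(Zdf.columns)
    Z = Zdf.to_numpy()
    A = Z @ Z.T

    y = fb["yield_t_ha"].to_numpy()
    fit = reml_fit(y, X, A)
    if fit.boundary:
        warnings.warn(f"REML variance ratio at search boundary: {fit.diagnostics}")
    beta, Vir, _ = gls_blup(y, X, A, fit.sigma_g2, fit.sigma_e2)
    u = fit.sigma_g2 * (Z.T @ Vir)           # per-line BLUPs (deviations)
    base = float((X @ beta)[test_mask].mean())
    values = pd.Series(base + u, index=line_order).sort_index()

    chk = fb[fb["is_check"]]
    fitted_fixed = X @ beta
    chk_vals = pd.Series(
        chk["yield_t_ha"].to_numpy() - (fitted_fixed[~test_mask] - base),
        index=chk["line_id"].to_numpy(),
    ).groupby(level=0).mean().sort_index()

    vc = {"sigma_g2": fit.sigma_g2, "sigma_e2": fit.sigma_e2}
    scope = "+".join(envs)
    return AdjustedPhenotypes(values, "BLUP", scope, chk_vals, vc)


def estimate_h2(variance_components: dict) -> float:
    """Broad-sense heritability sigma_g^2 / (sigma_g^2 + sigma_e^2), in [0, 1]."""
    sg2 = float(variance_components["sigma_g2"])
    se2 = float(variance_components["sigma_e2"])
    if sg2 < 0 or se2 < 0:
        raise ValueError("negative variance component")
    tot = sg2 + se2
    if tot == 0:
        raise ValueError("both variance components are zero")
    return float(np.clip(sg2 / tot, 0.0, 1.0))
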