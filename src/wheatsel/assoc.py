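"""Kinship-corrected single-marker association scan.

Each marker is tested as a fixed effect in y = mu + m g + u + e with
u ~ N(0, K sigma_u^2), using the P3D/EMMAX shortcut: the variance
components are estimated once on the null (no-marker) model and reused
for every marker, so the scan is one spectral decomposition plus a
vectorised weighted regression.  Significance is controlled by the
Benjamini-Hochberg step-up FDR; the top markers feed the marker-based
selection strategy and the GWAS-assisted prediction scenario.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .adjust import AdjustedPhenotypes
from .mixedmodel import reml_fit
from .relatedness import KinshipMatrix, compute_kinship
from .simulate import GenotypeMatrix

__all__ = [
    "GWASResult",
    "FavorableAlleleSet",
    "run_mlm_gwas",
    "bh_fdr",
    "select_top_snps",
    "snp_variance_explained",
]

ENGINE_NOTE = ("single-marker mixed linear model scan, kinship-corrected, "
               "null-model variance components reused per marker (P3D)")


@dataclass
class GWASResult:
    """Per-marker effects, p-values and BH-FDR q-values for one dataset."""

    table: pd.DataFrame        # marker, effect, se, pvalue, qvalue, maf, significant
    dataset: str
    q_threshold: float
    n_lines: int
    method_note: str = ENGINE_NOTE

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(1, "dataset", self.dataset)
        out.to_csv(path, sep="\t", index=False)


@dataclass
class FavorableAlleleSet:
    """Selected markers with the dosage a line must carry to pass MS.

    ``required_dosage`` is 2 when the counted (minor) allele raises yield
    and 0 when it lowers it — homozygous favourable, since the material is
    inbred; residual F5 heterozygotes fail the requirement.
    """

    table: pd.DataFrame        # marker, dataset, qvalue, effect, required_dosage

    @property
    def marker_ids(self) -> list[str]:
        return list(self.table["marker"])

    def required_dosages(self) -> pd.Series:
        return self.table.set_index("marker")["required_dosage"]

    def __len__(self) -> int:
        return len(self.table)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q(i) = min_{j >= i} (m * p(j) / j) over the sorted p-values, clipped
    at 1 and mapped back to the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def run_mlm_gwas(
    geno: GenotypeMatrix,
    pheno: AdjustedPhenotypes | pd.Series,
    kinship: KinshipMatrix | None = None,
    maf_min: float = 0.05,
    max_missing: float = 0.10,
    q_threshold: float = 0.05,
    dataset: str = "",
) -> GWASResult:
    """Kinship-corrected scan of every marker passing MAF/missingness filters."""
    values = pheno.values if isinstance(pheno, AdjustedPhenotypes) else pheno
    common = sorted(set(geno.line_ids) & set(values.index))
    if len(common) < 30:
        raise ValueError(f"only {len(common)} lines with genotype and phenotype (< 30)")
    sub = geno.subset_lines(common)
    y = values.loc[common].to_numpy(dtype=float)

    X = sub.data.to_numpy(dtype=float)
    miss = np.isnan(X).mean(axis=0)
    p_hat = np.nanmean(X, axis=0) / 2.0
    maf = np.minimum(p_hat, 1.0 - p_hat)
    keep = (maf > maf_min) & (miss <= max_missing)
    markers = [m for m, k in zip(sub.marker_ids, keep) if k]
    if not markers:
        raise ValueError("no markers pass the MAF/missingness filters")
    G = X[:, keep]
    if np.isnan(G).any():
        col_mean = np.nanmean(G, axis=0)
        idx = np.where(np.isnan(G))
        G[idx] = col_mean[idx[1]]

    if kinship is None:
        kinship = compute_kinship(sub)
    K = kinship.K.loc[common, common].to_numpy()
    ev_min = np.linalg.eigvalsh(K).min()
    if ev_min < -1e-6:
        raise ValueError(f"kinship matrix not PSD (min eigenvalue {ev_min:.3g})")

    n = len(common)
    ones = np.ones((n, 1))
    null = reml_fit(y, ones, K)

    d, U = linalg.eigh(K)
    w = 1.0 / np.sqrt(null.sigma_g2 * np.clip(d, 0.0, None) + null.sigma_e2)
    yt = w * (U.T @ y)
    Xt = w[:, None] * (U.T @ ones)
    Gt = w[:, None] * (U.T @ G)

    # Frisch-Waugh: residualise on the (transformed) intercept, then per-marker OLS
    q0 = Xt[:, 0] / np.linalg.norm(Xt[:, 0])
    ey = yt - q0 * (q0 @ yt)
    eG = Gt - np.outer(q0, q0 @ Gt)
    sgg = np.einsum("ij,ij->j", eG, eG)
    sgy = eG.T @ ey
    syy = float(ey @ ey)
    good = sgg > 1e-12
    beta = np.zeros(len(markers))
    beta[good] = sgy[good] / sgg[good]
    rss = syy - beta * sgy
    dfree = n - 2
    sigma2 = np.clip(rss, 0.0, None) / dfree
    se = np.full(len(markers), np.nan)
    se[good] = np.sqrt(sigma2[good] / sgg[good])
    tstat = np.zeros(len(markers))
    tstat[good] = beta[good] / se[good]
    pvals = np.ones(len(markers))
    pvals[good] = 2.0 * stats.t.sf(np.abs(tstat[good]), dfree)
    qvals = bh_fdr(pvals)

    table = pd.DataFrame({
        "marker": markers,
        "effect": beta,
        "se": se,
        "pvalue": pvals,
        "qvalue": qvals,
        "maf": maf[keep],
        "significant": qvals <= q_threshold,
    })
    return GWASResult(table, dataset, q_threshold, n)


def select_top_snps(
    gwas: GWASResult | list[GWASResult],
    k: int = 5,
    q_threshold: float | None = None,
) -> FavorableAlleleSet:
    """Top-k significant markers across one or more datasets.

    Markers are ranked by their best (minimum) q-value across datasets,
    requiring significance in at least one dataset; ties are broken by
    absolute effect (larger first) then marker ID.  The favourable allele
    is the dosage direction with a positive yield effect in the dataset
    achieving the best q.
    """
    results = gwas if isinstance(gwas, list) else [gwas]
    rows = []
    for res in results:
        thr = q_threshold if q_threshold is not None else res.q_threshold
        sig = res.table[res.table["qvalue"] <= thr]
        for _, r in sig.iterrows():
            rows.append((r["marker"], res.dataset, r["qvalue"], r["effect"]))
    if not rows:
        warnings.warn("no significant markers at the FDR threshold; empty allele set")
        return FavorableAlleleSet(pd.DataFrame(
            columns=["marker", "dataset", "qvalue", "effect", "required_dosage"]))

    df = pd.DataFrame(rows, columns=["marker", "dataset", "qvalue", "effect"])
    best = (
        df.sort_values(["qvalue", "marker"], kind="mergesort")
        .drop_duplicates("marker", keep="first")
    )
    best = best.assign(abs_effect=best["effect"].abs()).sort_values(
        ["qvalue", "abs_effect", "marker"],
        ascending=[True, False, True], kind="mergesort",
    ).head(k).drop(columns="abs_effect")
    best["required_dosage"] = np.where(best["effect"] > 0, 2, 0)
    return FavorableAlleleSet(best.reset_index(drop=True))


def snp_variance_explained(
    geno: GenotypeMatrix,
    pheno: AdjustedPhenotypes | pd.Series,
    significant_markers: list[str],
) -> pd.Series:
    """Drop-one R^2 per marker from the joint OLS fit of all significant SNPs.

    R^2 of the full model minus R^2 of the model without that marker;
    values can be tiny for markers shadowed by correlated partners.
    """
    values = pheno.values if isinstance(pheno, AdjustedPhenotypes) else pheno
    common = sorted(set(geno.line_ids) & set(values.index))
    y = values.loc[common].to_numpy(dtype=float)
    y = y - y.mean()

    # prune later-ordered collinear markers
    kept: list[str] = []
    Xcols = [np.ones(len(common))]
    rank = 1
    for m in significant_markers:
        col = geno.data.loc[common, m].to_numpy(dtype=float)
        trial = np.column_stack(Xcols + [col])
        r = np.linalg.matrix_rank(trial)
        if r > rank:
            kept.append(m)
            Xcols.append(col)
            rank = r
        else:
            warnings.warn(f"marker {m!r} collinear with earlier markers; pruned")
    if not kept:
        raise ValueError("no linearly independent significant markers")

    def r2(cols):
        Xm = np.column_stack([np.ones(len(common))] + cols)
        coef, *_ = np.linalg.lstsq(Xm, y, rcond=None)
        resid = y - Xm @ coef
        tss = float(y @ y)
        return 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0

    full_cols = Xcols[1:]
    r2_full = r2(full_cols)
    out = {}
    for i, m in enumerate(kept):
        rest = full_cols[:i] + full_cols[i + 1:]
        out[m] = r2_full - r2(rest)
    return pd.Series(out, name="r2_drop_one")
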