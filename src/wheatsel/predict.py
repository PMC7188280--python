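"""RRBLUP genomic prediction.

Fits y = X beta + Z u + e with u ~ N(0, K sigma_u^2), where K is the
marker-derived additive relationship matrix.  Variance components are
estimated by REML profiled over the variance ratio after one spectral
decomposition; fixed effects (intercept, plus optional GWAS-derived
marker dosages for the GWAS-assisted scenario) by GLS at the optimum.
Marker effects and genomic breeding values are two parameterisations of
the same fit: with K = W W' / c and matched ridge penalty, the
marker-effect solution (W'W + lambda I)^{-1} W'(y - X beta) reproduces
the K-model GEBVs exactly (RRBLUP-GBLUP equivalence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats

from .adjust import AdjustedPhenotypes
from .mixedmodel import reml_fit, gls_blup
from .relatedness import compute_kinship
from .simulate import GenotypeMatrix

__all__ = [
    "PredictionModel",
    "GEBVResult",
    "fit_rrblup",
    "predict_gebv",
    "predictive_ability",
    "cross_validate",
]

MIN_RECOMMENDED_TRAIN = 30


@dataclass
class PredictionModel:
    """Fitted RRBLUP state (marker-effect parameterisation retained)."""

    beta: pd.Series                  # intercept + one entry per fixed marker
    marker_effects: pd.Series        # random-marker BLUPs, t/ha per allele copy
    allele_freq: pd.Series           # training frequencies used for centring
    fixed_markers: list[str]
    sigma_u2: float                  # genomic variance on the K scale
    sigma_e2: float
    lambda_marker: float             # ridge penalty on the marker scale (= c * delta)
    scaling_c: float
    train_ids: list[str]
    train_gebv: pd.Series = dc_field(repr=False, default=None)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.marker_effects.index) + list(self.fixed_markers)


@dataclass
class GEBVResult:
    """Per-line GEBVs (deviation scale) and predicted yields (plus fixed part)."""

    table: pd.DataFrame              # line_id, gebv, predicted_yield
    scenario: str                    # "GS1" | "GS2"
    training_set: str = ""

    @property
    def gebv(self) -> pd.Series:
        return self.table.set_index("line_id")["gebv"]

    @property
    def predicted_yield(self) -> pd.Series:
        return self.table.set_index("line_id")["predicted_yield"]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["scenario"] = self.scenario
        out["training_set"] = self.training_set
        out.to_csv(path, sep="\t", index=False)


def fit_rrblup(
    train_geno: GenotypeMatrix,
    train_pheno: AdjustedPhenotypes | pd.Series,
    fixed_markers: list[str] | None = None,
    lambda_: float | None = None,
) -> PredictionModel:
    """Train an RRBLUP model on genotyped + phenotyped lines.

    Parameters
    ----------
    fixed_markers : marker IDs whose dosages enter the fixed-effect design
        (the GWAS-assisted GS scenario); they are removed from the random
        marker set.
    lambda_ : optional fixed ridge penalty on the *marker* scale; skips
        REML and reproduces the closed-form ridge solution
        ``(W'W + lambda I)^{-1} W' (y - X beta)``.
    """
    pheno = train_pheno.values if isinstance(train_pheno, AdjustedPhenotypes) else train_pheno
    common = sorted(set(train_geno.line_ids) & set(pheno.index))
    if len(common) < 2:
        raise ValueError("fewer than two lines with both genotype and phenotype")
    if len(common) < MIN_RECOMMENDED_TRAIN:
        warnings.warn(f"only {len(common)} training lines (< {MIN_RECOMMENDED_TRAIN})")
    geno = train_geno.subset_lines(common)
    y = pheno.loc[common].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("all-constant training phenotype")

    fixed_markers = list(fixed_markers or [])
    unknown = [m for m in fixed_markers if m not in geno.data.columns]
    if unknown:
        raise ValueError(f"fixed markers absent from genotype matrix: {unknown}")
    X = np.column_stack(
        [np.ones(len(common))] + [geno.data[m].to_numpy(dtype=float) for m in fixed_markers]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        for j, m in enumerate(fixed_markers, start=1):
            if np.linalg.matrix_rank(X[:, : j + 1]) < j + 1:
                raise ValueError(f"fixed-effect design rank deficient at marker {m!r} "
                                 "(monomorphic or collinear)")
        raise ValueError("fixed-effect design rank deficient")

    random_markers = [m for m in geno.marker_ids if m not in set(fixed_markers)]
    kin = compute_kinship(GenotypeMatrix(geno.data[random_markers], None))
    K = kin.to_numpy()
    c = kin.c
    W = geno.data[random_markers].to_numpy(dtype=float) - 2.0 * kin.allele_freq.to_numpy()

    if lambda_ is None:
        fit = reml_fit(y, X, K)
        sigma_u2 = fit.sigma_g2
        delta = fit.delta
    else:
        # fixed marker-scale ridge penalty: K-scale ratio is lambda / c
        delta = lambda_ / c
        sigma_u2 = 1.0

    beta, Vir, u = gls_blup(y, X, K, sigma_u2, sigma_u2 * delta)
    sigma_e2 = sigma_u2 * delta
    m_eff = (sigma_u2 / c) * (W.T @ Vir)     # sigma_m^2 W' V^{-1} (y - X beta)
    gebv = W @ m_eff

    names = ["intercept"] + fixed_markers
    return PredictionModel(
        beta=pd.Series(beta, index=names),
        marker_effects=pd.Series(m_eff, index=random_markers),
        allele_freq=kin.allele_freq,
        fixed_markers=fixed_markers,
        sigma_u2=float(sigma_u2),
        sigma_e2=float(sigma_e2),
        lambda_marker=float(delta * c),
        scaling_c=float(c),
        train_ids=common,
        train_gebv=pd.Series(gebv, index=common),
    )


def predict_gebv(model: PredictionModel, target_geno: GenotypeMatrix,
                 scenario: str = "GS1", training_set: str = "") -> GEBVResult:
    """GEBVs and predicted yields for target lines via marker effects."""
    random_markers = [m for m in model.marker_effects.index if m in target_geno.data.columns]
    if not random_markers:
        raise ValueError("no overlap between model markers and target genotype")
    n_lost = model.marker_effects.size - len(random_markers)
    if n_lost:
        warnings.warn(f"{n_lost} model markers absent from target; intersected")
    Wt = (target_geno.data[random_markers].to_numpy(dtype=float)
          - 2.0 * model.allele_freq[random_markers].to_numpy())
    gebv = Wt @ model.marker_effects[random_markers].to_numpy()

    fixed = np.full(target_geno.n_lines, model.beta.iloc[0])
    for m in model.fixed_markers:
        if m not in target_geno.data.columns:
            raise ValueError(f"fixed-effect marker {m!r} absent from target genotype")
        fixed = fixed + model.beta[m] * target_geno.data[m].to_numpy(dtype=float)

    table = pd.DataFrame({
        "line_id": target_geno.line_ids,
        "gebv": gebv,
        "predicted_yield": fixed + gebv,
    })
    return GEBVResult(table, scenario, training_set)


def predictive_ability(gebv: GEBVResult | pd.Series, observed: AdjustedPhenotypes | pd.Series):
    """Pearson correlation between GEBV and adjusted yield on the overlap."""
    g = gebv.gebv if isinstance(gebv, GEBVResult) else gebv
    o = observed.values if isinstance(observed, AdjustedPhenotypes) else observed
    common = sorted(set(g.index) & set(o.index))
    if len(common) < 3:
        raise ValueError("fewer than three overlapping lines")
    gv = g.loc[common].to_numpy(dtype=float)
    ov = o.loc[common].to_numpy(dtype=float)
    if np.std(gv) == 0 or np.std(ov) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.corrcoef(gv, ov)[0, 1])
    return r, len(common)


def cross_validate(
    geno: GenotypeMatrix,
    pheno: AdjustedPhenotypes | pd.Series,
    folds: int = 5,
    seed: int = 0,
    fixed_markers: list[str] | None = None,
):
    """K-fold cross-validated GEBVs and per-fold predictive abilities.

    Random disjoint folds from ``seed``; every line receives exactly one
    out-of-fold GEBV.  Returns ``(oof_gebv, fold_accuracies, mean_accuracy)``.
    """
    values = pheno.values if isinstance(pheno, AdjustedPhenotypes) else pheno
    common = sorted(set(geno.line_ids) & set(values.index))
    n = len(common)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds:
        raise ValueError("more folds than lines")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignments = np.array_split(perm, folds)

    oof = pd.Series(np.nan, index=common, dtype=float)
    accs = []
    for fold_idx in assignments:
        test_ids = [common[i] for i in fold_idx]
        train_ids = [l for l in common if l not in set(test_ids)]
        if len(train_ids) < 2:
            raise ValueError("fold leaves fewer than two training lines")
        model = fit_rrblup(geno.subset_lines(train_ids), values.loc[train_ids],
                           fixed_markers=fixed_markers)
        res = predict_gebv(model, geno.subset_lines(test_ids))
        oof.loc[test_ids] = res.gebv.reindex(test_ids).to_numpy()
        if len(test_ids) >= 3:
            try:
                r, _ = predictive_ability(res.gebv, values)
                accs.append(r)
            except ValueError:
                accs.append(np.nan)
    mean_acc = float(np.nanmean(accs)) if accs else np.nan
    return oof, accs, mean_acc
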