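"""Truncation-selection strategies and response to selection.

Implements the four strategies compared in the study design — phenotypic
(PS: top fraction on adjusted yield), marker-based (MS: lines homozygous
for every favourable allele at the top significant SNPs), genomic (GS:
top fraction on GEBV) and the PS+GS intersection — and scores each by
the response to selection

    R = H^2 * S,     S = mu_Selected - mu_Unselected,

with H^2 the broad-sense heritability of the evaluated trial.  Empty
selections (possible for MS and PS+GS) are reported as not-applicable
(NaN), never as zero, and dropped pairwise from strategy comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import FavorableAlleleSet
from .simulate import GenotypeMatrix

__all__ = [
    "select_top_fraction",
    "marker_select",
    "combine_ps_gs",
    "selection_differential",
    "response_to_selection",
    "response_vs_checks",
    "compare_strategies",
    "build_response_row",
]

DEFAULT_FRACTION = 0.20


def select_top_fraction(values: pd.Series, q: float = DEFAULT_FRACTION) -> list[str]:
    """IDs of the ``floor(q * N)`` highest-scoring lines (minimum one).

    Ties are broken by line ID (lexicographic) for determinism.
    """
    if values.empty:
        raise ValueError("empty population")
    if not 0.0 < q <= 1.0:
        raise ValueError("selection fraction must be in (0, 1]")
    n_sel = max(1, math.floor(q * len(values)))
    df = values.rename("score").rename_axis("line_id").reset_index()
    df = df.sort_values(["score", "line_id"], ascending=[False, True], kind="mergesort")
    return df["line_id"].head(n_sel).tolist()


def marker_select(geno: GenotypeMatrix, alleles: FavorableAlleleSet) -> list[str]:
    """Lines carrying the required favourable dosage at ALL listed markers.

    An empty allele set imposes no condition (all lines pass); an empty
    result is a valid outcome and is handled downstream as not-applicable.
    """
    if len(alleles) == 0:
        return list(geno.line_ids)
    req = alleles.required_dosages()
    missing = [m for m in req.index if m not in geno.data.columns]
    if missing:
        raise ValueError(f"markers absent from genotype matrix: {missing}")
    sub = geno.data[list(req.index)]
    mask = (sub == req).all(axis=1)
    return list(sub.index[mask])


def combine_ps_gs(ps_ids, gs_ids) -> list[str]:
    """Intersection of the phenotypic and genomic top sets (may be empty)."""
    return sorted(set(ps_ids) & set(gs_ids))


def selection_differential(selected_ids, evaluation_pheno: pd.Series) -> float:
    """S = mean(evaluation values of selected) - mean over the whole set.

    Returns NaN (not-applicable) for an empty selection.
    """
    if len(selected_ids) == 0:
        return float("nan")
    missing = [s for s in selected_ids if s not in evaluation_pheno.index]
    if missing:
        raise ValueError(f"selected lines without evaluation phenotype: {missing[:5]}")
    mu_sel = float(evaluation_pheno.loc[list(selected_ids)].mean())
    mu_all = float(evaluation_pheno.mean())
    return mu_sel - mu_all


def response_to_selection(h2: float, S: float) -> float:
    """R = H^2 * S (NaN propagates from a not-applicable S)."""
    if not 0.0 <= h2 <= 1.0:
        raise ValueError("H^2 outside [0, 1]")
    return h2 * S


def response_vs_checks(selected_ids, check_pheno: pd.Series,
                       evaluation_pheno: pd.Series, h2: float) -> dict:
    """Response with mu_Unselected replaced by the check mean."""
    if check_pheno is None or len(check_pheno) == 0:
        raise ValueError("no check phenotypes in the evaluation trial")
    if len(selected_ids) == 0:
        return {"S": float("nan"), "R": float("nan"), "check_mean": float(check_pheno.mean())}
    mu_sel = float(evaluation_pheno.loc[list(selected_ids)].mean())
    mu_chk = float(check_pheno.mean())
    S = mu_sel - mu_chk
    return {"S": S, "R": response_to_selection(h2, S), "check_mean": mu_chk}


def compare_strategies(r_matrix: pd.DataFrame) -> pd.DataFrame:
    """Paired t-tests between every pair of strategies.

    ``r_matrix``: rows = strategies, columns = (population x training
    dataset) cells of R values; NaN cells are dropped pairwise.  Degenerate
    pairs (zero-variance differences) follow the conventions: identical
    vectors give t = 0, p = 1; a constant non-zero shift gives |t| = inf,
    p = 0, flagged degenerate.
    """
    strategies = list(r_matrix.index)
    rows = []
    for i, a in enumerate(strategies):
        for b in strategies[i + 1:]:
            pair = r_matrix.loc[[a, b]].dropna(axis=1)
            n = pair.shape[1]
            if n < 2:
                raise ValueError(f"fewer than two complete pairs for {a} vs {b}")
            d = pair.loc[a].to_numpy() - pair.loc[b].to_numpy()
            if np.allclose(d.std(ddof=1), 0.0):
                if np.allclose(d, 0.0):
                    t, p, degenerate = 0.0, 1.0, True
                else:
                    t = math.inf if d.mean() > 0 else -math.inf
                    p, degenerate = 0.0, True
            else:
                t, p = stats.ttest_rel(pair.loc[a], pair.loc[b])
                t, p, degenerate = float(t), float(p), False
            rows.append({
                "strategy_a": a, "strategy_b": b, "n_pairs": n,
                "mean_diff": float(d.mean()), "t": t, "pvalue": p,
                "degenerate": degenerate,
            })
    return pd.DataFrame(rows)


def build_response_row(
    population: str,
    strategy: str,
    selected_ids,
    evaluation_pheno: pd.Series,
    h2: float,
    validation_population: str = "",
    training_dataset: str = "",
    check_pheno: pd.Series | None = None,
) -> dict:
    """One ledger row: mu without/with selection, S, H^2, R (+ vs-checks R)."""
    mu_all = float(evaluation_pheno.mean())
    if len(selected_ids) == 0:
        mu_sel = float("nan")
        S = float("nan")
    else:
        mu_sel = float(evaluation_pheno.loc[list(selected_ids)].mean())
        S = selection_differential(selected_ids, evaluation_pheno)
    row = {
        "population": population,
        "validation_population": validation_population,
        "strategy": strategy,
        "training_dataset": training_dataset,
        "n_selected": len(selected_ids),
        "mu_unselected": mu_all,
        "mu_selected": mu_sel,
        "S": S,
        "H2": h2,
        "R": response_to_selection(h2, S),
    }
    if check_pheno is not None and len(check_pheno) > 0:
        vs = response_vs_checks(selected_ids, check_pheno, evaluation_pheno, h2)
        row["check_mean"] = vs["check_mean"]
        row["R_vs_checks"] = vs["R"]
    return row
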