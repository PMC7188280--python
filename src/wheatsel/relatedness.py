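"""Marker-based relationship structures.

The additive genomic relationship matrix follows the VanRaden scaling
used by the rrBLUP ``A.mat`` convention: dosages are centred by twice the
allele frequency and the cross-product divided by ``2 * sum p (1 - p)``.
Rogers genetic distance between populations is the allele-frequency
Euclidean distance per marker divided by sqrt(2), averaged over markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix

__all__ = ["KinshipMatrix", "DistanceReport", "compute_kinship", "rogers_distance"]


@dataclass
class KinshipMatrix:
    """Symmetric line x line additive relationship matrix K = W W' / c."""

    K: pd.DataFrame
    c: float                       # VanRaden scaling constant 2 * sum p(1-p)
    allele_freq: pd.Series         # training allele frequencies used to centre

    @property
    def line_ids(self) -> list[str]:
        return list(self.K.index)

    def to_numpy(self) -> np.ndarray:
        return self.K.to_numpy()

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.K.to_numpy()).min())

    def to_tsv(self, path) -> None:
        self.K.to_csv(path, sep="\t", index_label="line_id")


@dataclass
class DistanceReport:
    """Rogers distance between two populations, overall and per chromosome."""

    overall: float
    per_chromosome: pd.Series
    n_markers: int

    def to_tsv(self, path) -> None:
        df = self.per_chromosome.rename("rogers_distance").to_frame()
        df.index.name = "chromosome"
        df.loc["ALL"] = self.overall
        df.to_csv(path, sep="\t")


def _imputed_dosages(geno: GenotypeMatrix) -> np.ndarray:
    """Dosages with per-marker mean imputation of missing entries."""
    X = geno.dosages()
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X = X.copy()
        X[idx] = col_mean[idx[1]]
    return X


def compute_kinship(geno: GenotypeMatrix) -> KinshipMatrix:
    """Additive relationship matrix from centred dosages (VanRaden)."""
    if geno.n_lines < 2:
        raise ValueError("kinship needs at least two lines")
    X = _imputed_dosages(geno)
    if np.isnan(X).all(axis=0).any():
        raise ValueError("all-missing marker in genotype matrix")
    p = X.mean(axis=0) / 2.0
    c = float(2.0 * np.sum(p * (1.0 - p)))
    if c == 0:
        raise ValueError("monomorphic-only panel: kinship scaling constant is zero")
    W = X - 2.0 * p
    K = (W @ W.T) / c
    Kdf = pd.DataFrame(K, index=geno.line_ids, columns=geno.line_ids)
    return KinshipMatrix(Kdf, c, pd.Series(p, index=geno.marker_ids))


def rogers_distance(
    popA: GenotypeMatrix,
    popB: GenotypeMatrix,
    scope: str = "overall",
) -> DistanceReport:
    """Rogers genetic distance between two populations' frequency profiles.

    Per biallelic marker the distance is
    ``sqrt((pA-pB)^2 + ((1-pA)-(1-pB))^2) / sqrt(2) = |pA - pB|``; the
    population-level value is the mean over the shared markers.  Markers
    monomorphic (and identical) in both populations contribute zero.
    """
    shared = [m for m in popA.marker_ids if m in set(popB.marker_ids)]
    if not shared:
        raise ValueError("no shared markers between populations")
    pA = popA.data[shared].mean(axis=0).to_numpy() / 2.0
    pB = popB.data[shared].mean(axis=0).to_numpy() / 2.0
    per_marker = np.sqrt((pA - pB) ** 2 + ((1 - pA) - (1 - pB)) ** 2) / np.sqrt(2.0)

    chrom = popA.chromosomes().reindex(shared)
    per_chrom = (
        pd.Series(per_marker, index=shared).groupby(chrom).mean().sort_index()
    )
    overall = float(np.mean(per_marker))
    if scope not in ("overall", "per_chromosome"):
        raise ValueError(f"unknown scope {scope!r}")
    return DistanceReport(overall, per_chrom, len(shared))
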