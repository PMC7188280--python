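"""Synthetic breeding populations and multi-environment yield trials.

Generates the data structures the rest of the package analyses: inbred
founder panels (a stand-in for a diverse association mapping panel),
biparental F5 / doubled-haploid progeny populations, and augmented
complete block design field books with replicated checks, unreplicated
test entries, and genotype-by-environment interaction, together with the
ground-truth genetic values needed for parameter-recovery tests.

Dosages are minor-allele counts on a {0, 1, 2} scale; founders and DH
lines are fully homozygous (every dosage 0 or 2).  Marker IDs follow the
``S<chrom>_<bp>`` convention used for wheat GBS SNPs, e.g.
``S1A_497083519``, with markers assigned round-robin to the 21 wheat
chromosomes 1A–7D.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CHROMOSOMES",
    "GenotypeMatrix",
    "SimConfig",
    "GeneticArchitecture",
    "SimulationTruth",
    "simulate_founders",
    "derive_biparental",
    "draw_architecture",
    "simulate_trial",
    "validate_fieldbook",
    "write_fieldbook",
    "read_fieldbook",
]

CHROMOSOMES = tuple(f"{i}{g}" for i in range(1, 8) for g in "ABD")
#: physical length used to spread marker positions (bp)
CHROM_BP = 800_000_000
_MARKER_RE = re.compile(r"^S([1-7][ABD]|UN)_(\d+)$")

FIELDBOOK_COLUMNS = ["line_id", "environment", "block", "is_check", "yield_t_ha"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Lines x markers dosage matrix with marker metadata.

    ``data`` holds minor-allele counts (rows = line IDs, columns = marker
    IDs).  ``marker_map`` (markers x [chrom, pos_bp, cM]) carries the
    genetic map used for meiosis simulation; it is optional for ingested
    panels, in which case chromosome and position are re-parsed from the
    marker IDs on demand.
    """

    data: pd.DataFrame
    marker_map: pd.DataFrame | None = None

    def __post_init__(self):
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate marker IDs in genotype matrix")
        if self.marker_map is not None:
            self.marker_map = self.marker_map.loc[self.data.columns]

    # -- basic views --------------------------------------------------------
    @property
    def line_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_lines(self) -> int:
        return self.data.shape[0]

    @property
    def n_markers(self) -> int:
        return self.data.shape[1]

    def dosages(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def allele_freq(self) -> pd.Series:
        """Frequency of the counted (minor-coded) allele per marker."""
        return self.data.mean(axis=0) / 2.0

    def maf(self) -> pd.Series:
        p = self.allele_freq()
        return pd.concat([p, 1.0 - p], axis=1).min(axis=1)

    def is_homozygous(self) -> bool:
        vals = self.data.to_numpy()
        return bool(np.isin(vals[~np.isnan(vals.astype(float))], (0, 2)).all())

    def subset_lines(self, ids) -> "GenotypeMatrix":
        return GenotypeMatrix(self.data.loc[list(ids)], self.marker_map)

    def chromosomes(self) -> pd.Series:
        """Chromosome per marker, parsed from the map or the marker IDs."""
        if self.marker_map is not None:
            return self.marker_map["chrom"]
        return pd.Series(
            [parse_marker_id(m)[0] for m in self.marker_ids],
            index=self.data.columns, name="chrom",
        )

    # -- I/O -----------------------------------------------------------------
    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="line_id")

    @classmethod
    def from_csv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, index_col="line_id")
        return cls(df)

    def to_vcf(self, path) -> None:
        """Minimal text VCF: inbred lines as 0/0 and 1/1 genotypes."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n##source=wheatsel\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.line_ids) + "\n")
            vals = self.data.to_numpy()
            for j, mid in enumerate(self.marker_ids):
                chrom, pos = parse_marker_id(mid)
                gts = "\t".join("1/1" if v >= 1.5 else ("0/1" if v >= 0.5 else "0/0")
                                for v in vals[:, j])
                fh.write(f"{chrom}\t{pos}\t{mid}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def parse_marker_id(marker_id: str) -> tuple[str, int]:
    """``"S1A_497083519" -> ("1A", 497083519)``; raises on malformed IDs."""
    m = _MARKER_RE.match(marker_id)
    if not m:
        raise ValueError(f"malformed marker ID: {marker_id!r}")
    return m.group(1), int(m.group(2))


@dataclass
class SimConfig:
    """Parameters of one simulated population / trial."""

    n_lines: int = 456
    n_markers: int = 2000
    n_chromosomes: int = 21
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtl: int = 20
    h2_target: float = 0.5
    environments: tuple[str, ...] = ("E1",)
    gxe_corr: float = 0.1
    block_size: int = 40
    n_checks: int = 5
    mu: float = 5.0          # grand-mean yield, t/ha
    genetic_sd: float = 1.0  # per-environment genetic SD, t/ha
    map_length_cM: float = 150.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"degenerate maf_range {self.maf_range}; need 0 < lo <= hi <= 0.5")
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl exceeds n_markers")
        if not 0.0 <= self.h2_target <= 1.0:
            raise ValueError("h2_target outside [0, 1]")
        if self.block_size < self.n_checks + 1:
            raise ValueError("block_size must fit all checks plus at least one test plot")
        if not -1.0 <= self.gxe_corr <= 1.0:
            raise ValueError("gxe_corr outside [-1, 1]")
        if self.n_markers < self.n_chromosomes:
            raise ValueError("need at least one marker per chromosome")
        if self.n_chromosomes > len(CHROMOSOMES):
            raise ValueError(f"at most {len(CHROMOSOMES)} wheat chromosomes")


@dataclass
class GeneticArchitecture:
    """Causal loci and their per-environment additive effects (t/ha per copy)."""

    qtl_ids: list[str]
    effects: pd.DataFrame      # qtl x environment


@dataclass
class SimulationTruth:
    """Ground truth behind one simulated trial."""

    qtl_ids: list[str]
    qtl_effects: pd.DataFrame            # qtl x environment
    true_genetic_values: pd.DataFrame    # test line x environment (t/ha, centered)
    check_values: pd.DataFrame           # check pseudo-line x environment
    realized_h2: pd.Series               # per environment
    residual_var: pd.Series              # per environment, (t/ha)^2
    mu: float


# ---------------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------------

def simulate_founders(config: SimConfig, id_prefix: str = "L") -> GenotypeMatrix:
    """Inbred founder panel with per-marker MAF inside ``config.maf_range``.

    Minor-allele carrier counts are fixed at ``round(p * n)`` (clamped into
    the admissible range) and carriers drawn at random, so the realised MAF
    is forced into the requested range by construction.
    """
    n, m = config.n_lines, config.n_markers
    if n < 2:
        raise ValueError("need at least two founder lines")
    rng = np.random.default_rng(config.seed)
    lo, hi = config.maf_range

    chroms = list(CHROMOSOMES[: config.n_chromosomes])
    marker_chrom = [chroms[j % len(chroms)] for j in range(m)]
    # unique, sorted physical positions within each chromosome
    pos = np.empty(m, dtype=np.int64)
    for c in chroms:
        jj = [j for j in range(m) if marker_chrom[j] == c]
        p = np.sort(rng.integers(1, CHROM_BP, size=len(jj)))
        p += np.arange(len(jj))          # break ties deterministically
        pos[jj] = p
    marker_ids = [f"S{c}_{p}" for c, p in zip(marker_chrom, pos)]
    cm = pos / CHROM_BP * config.map_length_cM

    target_p = rng.uniform(lo, hi, size=m)
    count_lo = min(max(1, math.ceil(lo * n)), n // 2)
    counts = np.clip(np.round(target_p * n).astype(int), count_lo, n // 2)
    dosage = np.zeros((n, m), dtype=np.int8)
    order = np.argsort(rng.random((m, n)), axis=1)
    for j in range(m):
        dosage[order[j, : counts[j]], j] = 2

    lines = [f"{id_prefix}{i:04d}" for i in range(n)]
    data = pd.DataFrame(dosage, index=lines, columns=marker_ids)
    mmap = pd.DataFrame(
        {"chrom": marker_chrom, "pos_bp": pos, "cM": cm}, index=marker_ids
    )
    return GenotypeMatrix(data, mmap)


# ---------------------------------------------------------------------------
# biparental progeny
# ---------------------------------------------------------------------------

def _meiosis(h1: np.ndarray, h2: np.ndarray, chrom_slices, interval_r, rng):
    """One gamete per row of (h1, h2) under Haldane interval recombination.

    ``interval_r[k]`` are the adjacent-marker recombination fractions of
    chromosome ``k`` — the marker-level marginal of Poisson crossovers
    with uniform positions (no interference).
    """
    out = np.empty_like(h1)
    n = h1.shape[0]
    for sl, r in zip(chrom_slices, interval_r):
        width = sl.stop - sl.start
        start = rng.integers(0, 2, size=(n, 1))
        if width > 1:
            switches = rng.random((n, width - 1)) < r
            phase = np.concatenate(
                [start, (start + np.cumsum(switches, axis=1)) % 2], axis=1
            )
        else:
            phase = start
        out[:, sl] = np.where(phase == 0, h1[:, sl], h2[:, sl])
    return out


def derive_biparental(
    parents: GenotypeMatrix,
    n_progeny: int,
    pop_type: str,
    map_length_cM_per_chrom: float | None = None,
    seed: int = 0,
    id_prefix: str | None = None,
) -> GenotypeMatrix:
    """Simulate an F5 or DH biparental population from two inbred parents.

    F5 lines carry residual heterozygosity at ~1/16 of segregating loci
    (four rounds of selfing from the F1); DH lines are one doubled gamete
    and fully homozygous.
    """
    if parents.n_lines != 2:
        raise ValueError("parents must be exactly two lines")
    if not parents.is_homozygous():
        raise ValueError("parents must be fully homozygous inbreds")
    if n_progeny < 1:
        raise ValueError("n_progeny must be >= 1")
    pop_type = pop_type.upper()
    if pop_type not in ("F5", "DH"):
        raise ValueError("pop_type must be 'F5' or 'DH'")

    rng = np.random.default_rng(seed)
    order = np.arange(parents.n_markers)
    if parents.marker_map is not None:
        mm = parents.marker_map
        chrom = mm["chrom"].to_numpy()
        cm = mm["cM"].to_numpy(dtype=float)
    else:
        chrom = np.array([parse_marker_id(m)[0] for m in parents.marker_ids])
        L = map_length_cM_per_chrom or 150.0
        cm = np.empty(parents.n_markers)
        for c in np.unique(chrom):
            jj = np.where(chrom == c)[0]
            cm[jj] = np.linspace(0, L, len(jj) + 2)[1:-1]
    if map_length_cM_per_chrom is not None and parents.marker_map is not None:
        # rescale the stored map to the requested chromosome length
        cm = np.empty(parents.n_markers)
        for c in np.unique(chrom):
            jj = np.where(chrom == c)[0]
            top = parents.marker_map["cM"].iloc[jj].max()
            scale = map_length_cM_per_chrom / top if top > 0 else 1.0
            cm[jj] = parents.marker_map["cM"].iloc[jj] * scale

    # sort markers by (chrom, cM) for the meiosis walk; restore order at the end
    sort_idx = np.lexsort((cm, chrom))
    inv = np.argsort(sort_idx)
    chrom_s, cm_s = chrom[sort_idx], cm[sort_idx]
    slices, rates = [], []
    start = 0
    for k in range(1, len(chrom_s) + 1):
        if k == len(chrom_s) or chrom_s[k] != chrom_s[start]:
            slices.append(slice(start, k))
            d = np.diff(cm_s[start:k])
            rates.append(0.5 * (1.0 - np.exp(-2.0 * d / 100.0)))
            start = k

    hapA = (parents.dosages()[0] / 2.0)[sort_idx]
    hapB = (parents.dosages()[1] / 2.0)[sort_idx]
    h1 = np.tile(hapA, (n_progeny, 1))
    h2 = np.tile(hapB, (n_progeny, 1))
    if pop_type == "DH":
        g = _meiosis(h1, h2, slices, rates, rng)
        dosage = (2 * g).astype(np.int8)
    else:  # F5: F1 selfed four times
        for _ in range(4):
            g1 = _meiosis(h1, h2, slices, rates, rng)
            g2 = _meiosis(h1, h2, slices, rates, rng)
            h1, h2 = g1, g2
        dosage = (h1 + h2).astype(np.int8)

    prefix = id_prefix or pop_type
    lines = [f"{prefix}_{i:04d}" for i in range(n_progeny)]
    data = pd.DataFrame(dosage[:, inv], index=lines, columns=parents.marker_ids)
    return GenotypeMatrix(data, parents.marker_map)


# ---------------------------------------------------------------------------
# trials
# ---------------------------------------------------------------------------

def draw_architecture(
    geno: GenotypeMatrix,
    environments,
    n_qtl: int,
    env_corr,
    rng,
) -> GeneticArchitecture:
    """Draw QTL and per-environment effects with a given env correlation.

    ``env_corr`` may be a scalar (equicorrelation) or a full correlation
    matrix over the environments.  Effects are sampled through the
    eigendecomposition of the correlation matrix, so degenerate (corr = 1)
    structures are handled exactly.
    """
    environments = list(environments)
    E = len(environments)
    poly = [m for m, v in geno.data.var(axis=0).items() if v > 0]
    if n_qtl > len(poly):
        raise ValueError("fewer polymorphic markers than requested QTL")
    qtl = sorted(rng.choice(poly, size=n_qtl, replace=False).tolist())

    if np.isscalar(env_corr):
        C = np.full((E, E), float(env_corr))
        np.fill_diagonal(C, 1.0)
    else:
        C = np.asarray(env_corr, dtype=float)
    w, U = np.linalg.eigh(C)
    if w.min() < -1e-8:
        raise ValueError("environment correlation matrix is not PSD")
    F = U * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((n_qtl, E))
    eff = z @ F.T
    return GeneticArchitecture(qtl, pd.DataFrame(eff, index=qtl, columns=environments))


def simulate_trial(
    geno: GenotypeMatrix,
    config: SimConfig,
    seed: int | None = None,
    architecture: GeneticArchitecture | None = None,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Augmented-design multi-environment trial for the lines in ``geno``.

    Every block carries all ``n_checks`` replicated check plots plus
    ``block_size - n_checks`` unreplicated test plots; every test line
    appears exactly once per environment.  The residual variance is set
    from the realised genetic variance so broad-sense heritability
    sigma_g^2 / (sigma_g^2 + sigma_e^2) meets ``h2_target`` per
    environment.  Block effects are N(0, (0.2 * sigma_e)^2).
    """
    if geno.n_lines == 0:
        raise ValueError("empty genotype matrix")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    envs = list(config.environments)
    h2 = config.h2_target

    if architecture is None:
        architecture = draw_architecture(geno, envs, config.n_qtl, config.gxe_corr, rng)
    eff = architecture.effects[envs]
    Wq = geno.data[architecture.qtl_ids].to_numpy(dtype=float)
    Wq = Wq - Wq.mean(axis=0)
    G = Wq @ eff.to_numpy()                      # lines x envs, centered
    if h2 == 0.0:
        G = np.zeros_like(G)
    gvar = G.var(axis=0)
    # rescale so each environment's genetic SD hits config.genetic_sd
    # (a column scaling: preserves env correlations and effect signs)
    if h2 > 0.0 and config.genetic_sd is not None and np.all(gvar > 0):
        factors = config.genetic_sd / np.sqrt(gvar)
        G = G * factors
        eff = eff * factors
        gvar = G.var(axis=0)

    if 0.0 < h2 < 1.0 and np.any(gvar <= 0):
        raise ValueError("no genetic variance in some environment but 0 < h2_target < 1")
    if h2 == 1.0:
        res_var = np.zeros(len(envs))
    elif h2 == 0.0:
        res_var = np.ones(len(envs))
    else:
        res_var = gvar * (1.0 - h2) / h2

    # check pseudo-lines: genetic values on the same scale / env correlation
    check_ids = [f"CHK{k + 1}" for k in range(config.n_checks)]
    Cg = np.corrcoef(G.T) if (len(envs) > 1 and gvar.min() > 0) else np.eye(len(envs))
    Cg = np.nan_to_num(0.5 * (Cg + Cg.T), nan=0.0)
    np.fill_diagonal(Cg, 1.0)
    w, U = np.linalg.eigh(Cg)
    F = U * np.sqrt(np.clip(w, 0.0, None))
    chk = (rng.standard_normal((config.n_checks, len(envs))) @ F.T) * np.sqrt(gvar)

    tests_per_block = config.block_size - config.n_checks
    line_ids = geno.line_ids
    n_blocks = math.ceil(len(line_ids) / tests_per_block)

    records = []
    realized, resvar_out = {}, {}
    for e_idx, env in enumerate(envs):
        sd_e = math.sqrt(res_var[e_idx])
        block_eff = rng.normal(0.0, 0.2 * sd_e, size=n_blocks)
        resid_test = rng.normal(0.0, sd_e, size=len(line_ids))
        for b in range(n_blocks):
            label = f"{env}:B{b + 1:02d}"
            for k, cid in enumerate(check_ids):
                y = config.mu + block_eff[b] + chk[k, e_idx] + rng.normal(0.0, sd_e)
                records.append((cid, env, label, True, y))
            for i in range(b * tests_per_block, min((b + 1) * tests_per_block, len(line_ids))):
                y = config.mu + block_eff[b] + G[i, e_idx] + resid_test[i]
                records.append((line_ids[i], env, label, False, y))
        ev = resid_test.var()
        realized[env] = 1.0 if sd_e == 0 else float(gvar[e_idx] / (gvar[e_idx] + ev))
        resvar_out[env] = float(res_var[e_idx])

    fieldbook = pd.DataFrame(records, columns=FIELDBOOK_COLUMNS)
    truth = SimulationTruth(
        qtl_ids=list(architecture.qtl_ids),
        qtl_effects=eff.copy(),
        true_genetic_values=pd.DataFrame(G, index=line_ids, columns=envs),
        check_values=pd.DataFrame(chk, index=check_ids, columns=envs),
        realized_h2=pd.Series(realized),
        residual_var=pd.Series(resvar_out),
        mu=config.mu,
    )
    return fieldbook, truth


# ---------------------------------------------------------------------------
# field-book plumbing
# ---------------------------------------------------------------------------

def validate_fieldbook(fieldbook: pd.DataFrame) -> None:
    """Check the structural invariants of an augmented-design field book."""
    missing = set(FIELDBOOK_COLUMNS) - set(fieldbook.columns)
    if missing:
        raise ValueError(f"field book missing columns: {sorted(missing)}")
    if not np.isfinite(fieldbook["yield_t_ha"]).all():
        raise ValueError("non-finite yields in field book")
    tests = fieldbook[~fieldbook["is_check"]]
    dup = tests.groupby(["line_id", "environment"]).size()
    if (dup > 1).any():
        bad = dup[dup > 1].index[0]
        raise ValueError(f"test line replicated within an environment: {bad}")
    per_block = fieldbook.groupby("block")["is_check"].any()
    if not per_block.all():
        raise ValueError(f"block without a check plot: {per_block[~per_block].index[0]}")


def write_fieldbook(fieldbook: pd.DataFrame, path) -> None:
    fieldbook.to_csv(path, index=False)


def read_fieldbook(path) -> pd.DataFrame:
    fb = pd.read_csv(path)
    fb["is_check"] = fb["is_check"].astype(bool)
    validate_fieldbook(fb)
    return fb
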