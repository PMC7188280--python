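"""End-to-end study orchestration on synthetic (or ingested) data.

Reproduces the study skeleton: simulate an association mapping panel
(AMP) and biparental F5/DH breeding populations sharing one genetic
architecture; run augmented-design adjustment per environment; scan the
AMP for marker-trait associations; train RRBLUP on each AMP dataset
(standard GS1 and GWAS-assisted GS2); apply the four selection
strategies to the breeding populations; and report the response to
selection R = H^2 * S within the selection environment and in a
next-season validation environment.

The synthetic world uses a two-tier environment correlation: the trial
environments (AMP site-years and each population's selection
environment) share a common genetic correlation, while next-season
validation environments correlate with everything at ``gxe_corr`` — the
axis of genotype-by-environment interaction the cross-environment
validation probes.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .adjust import AdjustedPhenotypes, adjust_single_env, estimate_h2
from .assoc import FavorableAlleleSet, GWASResult, run_mlm_gwas, select_top_snps
from .predict import GEBVResult, fit_rrblup, predict_gebv
from .relatedness import compute_kinship, rogers_distance
from .select import (build_response_row, combine_ps_gs, compare_strategies,
                     marker_select, select_top_fraction)
from .simulate import (GenotypeMatrix, SimConfig, draw_architecture,
                       parse_marker_id, simulate_founders, simulate_trial,
                       derive_biparental)

__all__ = ["StudyConfig", "StudyResult", "run_study", "ingest_supplementary"]

AMP_DATASETS = ("AMP_LND", "AMP_PUL")
STRATEGIES = ("PS", "MS", "GS1", "GS2", "PS+GS1", "PS+GS2")
CROSS_STRATEGIES = ("PS", "GS1", "GS2", "PS+GS1", "PS+GS2")


@dataclass
class StudyConfig:
    """Configuration of one synthetic study run."""

    seed: int = 0
    outdir: str | None = None
    n_markers: int = 2000
    amp_lines: int = 456
    f5_lines: int = 200
    dh_lines: int = 500
    amp_h2: float = 0.40
    f5_h2: float = 0.15
    dh_h2: float = 0.55
    n_qtl: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    gxe_corr: float = 0.1          # validation env vs everything
    env_corr_trials: float = 0.5   # among AMP + selection environments
    selection_fraction: float = 0.20
    fdr_threshold: float = 0.05
    top_k: int = 5
    folds: int = 5
    n_checks: int = 5
    block_size: int = 40
    mu: float = 5.0

    def __post_init__(self):
        if not 0 <= self.seed < 2 ** 31:
            raise ValueError("seed must be a non-negative 31-bit integer")
        if not 0 < self.selection_fraction <= 1:
            raise ValueError("selection_fraction outside (0, 1]")

    def scientific_config(self) -> dict:
        """Config fields that define the run (output location excluded)."""
        d = asdict(self)
        d.pop("outdir", None)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.scientific_config(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class StudyResult:
    """All tables and fitted objects from one study run."""

    config: StudyConfig
    response_within: pd.DataFrame
    response_cross: pd.DataFrame
    summary: pd.DataFrame
    strategy_tests: pd.DataFrame
    gwas_results: list
    allele_set: FavorableAlleleSet
    h2: dict
    amp_selected_n: int
    rogers: dict
    adjusted: dict
    gebv: dict
    truths: dict
    fieldbooks: dict
    genotypes: dict
    log: dict


def _env_correlation(trial_envs, val_envs, rho_trial, rho_val):
    envs = list(trial_envs) + list(val_envs)
    E = len(envs)
    C = np.full((E, E), rho_val)
    t = len(trial_envs)
    C[:t, :t] = rho_trial
    np.fill_diagonal(C, 1.0)
    return envs, C


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2 ** 31)) for s in state]


def run_study(config: StudyConfig) -> StudyResult:
    """Run the full selection-strategy comparison on one synthetic world."""
    seeds = _child_seeds(config.seed, 12)
    rng_arch = np.random.default_rng(seeds[0])

    trial_envs = list(AMP_DATASETS) + ["F5_SEL", "DH_SEL"]
    val_envs = ["F5_VAL", "DH_VAL"]
    all_envs, C = _env_correlation(trial_envs, val_envs,
                                   config.env_corr_trials, config.gxe_corr)

    # --- populations -------------------------------------------------------
    amp_cfg = SimConfig(
        n_lines=config.amp_lines, n_markers=config.n_markers,
        maf_range=config.maf_range, n_qtl=config.n_qtl,
        h2_target=config.amp_h2, environments=tuple(AMP_DATASETS),
        gxe_corr=config.env_corr_trials, block_size=config.block_size,
        n_checks=config.n_checks, mu=config.mu, seed=seeds[1],
    )
    amp_geno = simulate_founders(amp_cfg, id_prefix="AMP")
    architecture = draw_architecture(amp_geno, all_envs, config.n_qtl, C, rng_arch)

    rng_parents = np.random.default_rng(seeds[2])
    pops = {}
    for name, n_prog, pop_type, seed_i in (
        ("F5", config.f5_lines, "F5", seeds[3]),
        ("DH", config.dh_lines, "DH", seeds[4]),
    ):
        pid = rng_parents.choice(config.amp_lines, size=2, replace=False)
        parents = amp_geno.subset_lines([amp_geno.line_ids[i] for i in sorted(pid)])
        pops[name] = derive_biparental(parents, n_prog, pop_type,
                                       seed=seed_i, id_prefix=name)

    # --- trials and adjustment --------------------------------------------
    def trial_config(n_lines, h2, envs, seed_i):
        return SimConfig(
            n_lines=n_lines, n_markers=config.n_markers,
            maf_range=config.maf_range, n_qtl=config.n_qtl, h2_target=h2,
            environments=tuple(envs), gxe_corr=config.gxe_corr,
            block_size=config.block_size, n_checks=config.n_checks,
            mu=config.mu, seed=seed_i,
        )

    fb_amp, truth_amp = simulate_trial(
        amp_geno, trial_config(config.amp_lines, config.amp_h2, AMP_DATASETS, seeds[5]),
        architecture=architecture,
    )
    adjusted: dict[str, AdjustedPhenotypes] = {
        d: adjust_single_env(fb_amp, d) for d in AMP_DATASETS
    }

    fieldbooks = {"AMP": fb_amp}
    truths = {"AMP": truth_amp}
    h2_est = {}
    pop_envs = {"F5": ("F5_SEL", "F5_VAL"), "DH": ("DH_SEL", "DH_VAL")}
    pop_h2 = {"F5": config.f5_h2, "DH": config.dh_h2}
    for i, (name, geno) in enumerate(pops.items()):
        fb, truth = simulate_trial(
            geno, trial_config(geno.n_lines, pop_h2[name], pop_envs[name], seeds[6 + i]),
            architecture=architecture,
        )
        truths[name] = truth
        fieldbooks[name] = fb
        sel_env, val_env = pop_envs[name]
        adjusted[sel_env] = adjust_single_env(fb, sel_env, compute_vc=True)
        adjusted[val_env] = adjust_single_env(fb, val_env)
        h2_est[name] = estimate_h2(adjusted[sel_env].variance_components)

    # --- GWAS on the AMP ----------------------------------------------------
    kin_amp = compute_kinship(amp_geno)
    gwas_results = [
        run_mlm_gwas(amp_geno, adjusted[d], kinship=kin_amp,
                     q_threshold=config.fdr_threshold, dataset=d)
        for d in AMP_DATASETS
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        allele_set = select_top_snps(gwas_results, k=config.top_k,
                                     q_threshold=config.fdr_threshold)

    # --- genomic prediction -------------------------------------------------
    gebv: dict[tuple[str, str, str], GEBVResult] = {}
    for d in AMP_DATASETS:
        for scenario in ("GS1", "GS2"):
            fixed = allele_set.marker_ids if scenario == "GS2" else None
            if scenario == "GS2" and not fixed:
                continue     # no significant markers: GS2 not applicable
            model = fit_rrblup(amp_geno, adjusted[d], fixed_markers=fixed)
            for name, geno in pops.items():
                gebv[(name, d, scenario)] = predict_gebv(
                    model, geno, scenario=scenario, training_set=d)

    # --- selection and response --------------------------------------------
    q = config.selection_fraction
    rows_within, rows_cross = [], []
    r_cells: dict[str, dict[str, float]] = {s: {} for s in STRATEGIES}

    for name, geno in pops.items():
        sel_env, val_env = pop_envs[name]
        eval_within = adjusted[sel_env].values
        eval_cross = adjusted[val_env].values
        checks_within = adjusted[sel_env].check_values
        checks_cross = adjusted[val_env].check_values
        h2 = h2_est[name]

        ps_ids = select_top_fraction(eval_within, q)
        ms_ids = marker_select(geno, allele_set) if len(allele_set) else []

        selections: dict[tuple[str, str], list[str]] = {
            ("PS", "-"): ps_ids, ("MS", "-"): ms_ids,
        }
        for d in AMP_DATASETS:
            for scenario in ("GS1", "GS2"):
                key = (name, d, scenario)
                if key not in gebv:
                    continue
                gs_ids = select_top_fraction(gebv[key].predicted_yield, q)
                selections[(scenario, d)] = gs_ids
                selections[(f"PS+{scenario}", d)] = combine_ps_gs(ps_ids, gs_ids)

        for (strategy, d), ids in selections.items():
            row = build_response_row(name, strategy, ids, eval_within, h2,
                                     training_dataset=d, check_pheno=checks_within)
            rows_within.append(row)
            cells = [f"{name}|{dd}" for dd in AMP_DATASETS] if d == "-" else [f"{name}|{d}"]
            for cell in cells:
                r_cells[strategy][cell] = row["R"]
            if strategy in CROSS_STRATEGIES:
                rows_cross.append(build_response_row(
                    name, strategy, ids, eval_cross, h2,
                    validation_population=val_env, training_dataset=d,
                    check_pheno=checks_cross))

    response_within = pd.DataFrame(rows_within)
    response_cross = pd.DataFrame(rows_cross)

    r_matrix = pd.DataFrame(r_cells).T
    try:
        strategy_tests = compare_strategies(r_matrix)
    except ValueError:
        strategy_tests = pd.DataFrame()

    amp_selected_n = len(select_top_fraction(adjusted[AMP_DATASETS[0]].values, q))
    rogers = {name: rogers_distance(amp_geno, geno) for name, geno in pops.items()}

    mean_within = response_within.groupby("strategy")["R"].mean()
    mean_cross = response_cross.groupby("strategy")["R"].mean()
    summary = pd.DataFrame({
        "mean_R_within": mean_within,
        "mean_R_cross": mean_cross,
    }).rename_axis("strategy").reset_index()

    log = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.scientific_config(),
        "substitutions": [
            "GWAS engine: kinship-corrected single-marker MLM (P3D), not FarmCPU",
            "imputation: per-marker mean dosage, not LD-kNNi",
        ],
        "amp_selected_n": amp_selected_n,
        "h2_estimates": h2_est,
        "n_significant_markers": int(sum(len(g.significant()) for g in gwas_results)),
        "avg_rogers": float(np.mean([r.overall for r in rogers.values()])),
    }

    result = StudyResult(
        config=config, response_within=response_within,
        response_cross=response_cross, summary=summary,
        strategy_tests=strategy_tests, gwas_results=gwas_results,
        allele_set=allele_set, h2=h2_est, amp_selected_n=amp_selected_n,
        rogers=rogers, adjusted=adjusted, gebv=gebv, truths=truths,
        fieldbooks=fieldbooks, genotypes={"AMP": amp_geno, **pops}, log=log,
    )
    if config.outdir:
        _write_outputs(result, Path(config.outdir))
    return result


def _fmt(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if out[c].dtype.kind == "f":
            out[c] = out[c].map(lambda v: f"{v:.6g}" if pd.notna(v) else "NA")
    return out


def _write_outputs(result: StudyResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    _fmt(result.response_within).to_csv(outdir / "response_within.tsv", sep="\t", index=False)
    _fmt(result.response_cross).to_csv(outdir / "response_cross.tsv", sep="\t", index=False)
    _fmt(result.summary).to_csv(outdir / "summary.tsv", sep="\t", index=False)
    if not result.strategy_tests.empty:
        _fmt(result.strategy_tests).to_csv(outdir / "strategy_ttests.tsv", sep="\t", index=False)
    for g in result.gwas_results:
        g.to_tsv(outdir / f"gwas_{g.dataset}.tsv")
    if len(result.allele_set):
        result.allele_set.table.to_csv(outdir / "favorable_alleles.tsv", sep="\t", index=False)
    for (pop, d, scen), res in result.gebv.items():
        res.to_tsv(outdir / f"gebv_{pop}_{d}_{scen}.tsv")
    for scope, adj in result.adjusted.items():
        adj.to_tsv(outdir / f"adjusted_{scope}.tsv")
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(result.log, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# supplementary-style ingest
# ---------------------------------------------------------------------------

def ingest_supplementary(geno_csv, pheno_csv):
    """Read a genotype CSV (lines x markers) and adjusted-yield CSV.

    Marker IDs must follow the ``S<chrom>_<bp>`` convention; malformed
    columns are quarantined with a warning, duplicated marker columns
    deduplicated.  Returns ``(GenotypeMatrix, AdjustedPhenotypes, report)``
    where the report carries MAF/missingness and chromosome tallies.
    """
    df = pd.read_csv(geno_csv, index_col=0)
    # pandas mangles duplicated CSV headers to "NAME.1", "NAME.2", ...
    import re as _re
    seen = set(df.columns)
    mangled = [c for c in df.columns
               if (m := _re.fullmatch(r"(.+)\.\d+", str(c))) and m.group(1) in seen]
    dup_mask = df.columns.duplicated() | df.columns.isin(mangled)
    if dup_mask.any():
        warnings.warn(f"{int(dup_mask.sum())} duplicated marker columns removed")
        df = df.loc[:, ~dup_mask]
    good, bad = [], []
    for m in df.columns:
        try:
            parse_marker_id(str(m))
            good.append(m)
        except ValueError:
            bad.append(m)
    if bad:
        warnings.warn(f"{len(bad)} malformed marker IDs quarantined")
    df = df[good]
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric dosages in genotype file: {exc}") from exc
    geno = GenotypeMatrix(df)

    pheno_df = pd.read_csv(pheno_csv)
    if "line_id" not in pheno_df.columns or "adjusted_value" not in pheno_df.columns:
        raise ValueError("phenotype CSV needs line_id and adjusted_value columns")
    values = pheno_df.set_index("line_id")["adjusted_value"].astype(float)
    scope = str(pheno_df["environment"].iloc[0]) if "environment" in pheno_df else "ingested"
    pheno = AdjustedPhenotypes(values, "BLUE", scope)

    chrom = geno.chromosomes()
    genome = chrom.str.extract(r"([ABD])$", expand=False).fillna("UN")
    report = {
        "n_lines": geno.n_lines,
        "n_markers": geno.n_markers,
        "n_quarantined": len(bad),
        "maf_mean": float(geno.maf().mean()),
        "missing_fraction": float(np.isnan(geno.dosages()).mean()),
        "markers_per_chromosome": chrom.value_counts().sort_index().to_dict(),
        "markers_per_genome": genome.value_counts().sort_index().to_dict(),
    }
    return geno, pheno, report
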