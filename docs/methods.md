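# Methods

## Scope and data model

`wheatsel` compares truncation-selection strategies for grain yield in a
winter wheat breeding program on synthetic populations whose structure
mirrors a common program design: a diverse inbred association mapping
panel (AMP) used for training and association mapping, and biparental
F5 / doubled-haploid (DH) breeding populations evaluated in augmented
complete block design (ACBD) yield trials. All genotypes are biallelic
SNP dosages coded as minor-allele counts {0, 1, 2}; inbred founders and
DH lines are fully homozygous. Marker IDs follow the wheat GBS
convention `S<chrom>_<bp>` (e.g. `S1A_497083519`), chromosomes 1A–7D.

## Mixed-model core

Every variance-component problem in the package is the one-component
model

    y = Xβ + u + e,   u ~ N(0, σ²g A),   e ~ N(0, σ²e I)

solved by REML profiled over δ = σ²e/σ²g after one spectral
decomposition (the EMMA formulation: eigendecompose S(A+I)S with S the
projector orthogonal to X, keep the n−p informative eigenpairs). The
profile restricted likelihood is maximised by a 41-point grid on
log δ ∈ [−10, 10] followed by bounded Brent refinement to 1e−8.
Variance components that REML drives to the boundary are clamped at
1e−10 with a warning, keeping H² inside [0, 1]. The implementation is
cross-checked against `lme4::lmer` REML on the same design (agreement
to ~1e−7 on a 120-line two-environment trial).

## Field adjustment

**Single environment (BLUEs).** The ACBD fixed-effect model is mean +
block + check-identifier + genotype. Because test entries are
unreplicated, their genotype terms saturate their plots and the block
effects are identified entirely by the replicated checks; the exact
least-squares BLUE of a test line is therefore its plot yield minus the
check-estimated block effect. Block effects are recentred to mean zero
over blocks so check BLUEs average to the raw check mean. The
check-identifier term is a factor with one level per named check plus a
single pooled level for test genotypes, which keeps the design
estimable. A block with no check plots is a hard error naming the
block; a single-block, check-free trial degenerates to raw values.

**Variance components per environment.** H² for a single-environment
augmented trial comes from a companion fit of the same data with
genotype random: the replicated checks identify σ²e, the between-line
spread of the unreplicated test plots identifies σ²g + σ²e.

**Across environments (BLUPs).** The multi-environment model keeps
environment, block-within-environment and check-identifier fixed and
the genotype term random, profiling the single genotype variance ratio;
interaction terms (G×E, check×E) are deliberately folded into the
residual so that the REML problem stays one-dimensional. BLUPs are the
usual shrunken values σ²g Z'V⁻¹(y − Xβ̂) re-centred at the fitted mean
of the test plots; their variance is strictly smaller than the matching
BLUEs'. Missing plots are dropped listwise — augmented designs tolerate
unbalanced blocks.

**Heritability.** H² = σ²g/(σ²g + σ²e), clamped to [0, 1]; an error if
both components vanish. Reports state which trial's H² each response
row uses (each breeding population's own selection-environment fit).

## Relatedness

The additive relationship matrix uses VanRaden scaling: dosages centred
by 2p̂ per marker, K = WW′/c with c = 2Σ p̂(1−p̂); missing dosages are
mean-imputed per marker before centring (a deliberate simplification of
LD-based imputation — the synthetic data are generated missing-free).
Duplicating every marker leaves K unchanged (c doubles too), and K is
PSD up to ~1e−8. Rogers distance between two populations is the
per-marker allele-frequency Euclidean distance divided by √2 — for
biallelic markers simply |p_A − p_B| — averaged over shared markers,
reported overall and per chromosome.

## Genomic prediction

RRBLUP is fitted on the K-parameterisation (REML as above with A = K)
and converted to marker effects through
m̂ = (σ²u/c) W′V⁻¹(y − Xβ̂), which by the push-through identity equals
the ridge solution (W′W + λI)⁻¹W′(y − Xβ̂) at the matched marker-scale
penalty λ = c·σ²e/σ²u; marker-model GEBVs and K-model GEBVs agree to
machine precision, and a fixed λ can be supplied to bypass REML. GEBVs
for new lines are centred target dosages (training allele frequencies)
times the marker effects; "GEBV" is the deviation-scale u and
"predicted yield" adds the fixed part Xβ̂ — both are emitted because
reported GEBV means in the field often include the intercept. In the
GWAS-assisted scenario (GS2) the top significant SNP dosages enter the
fixed design and are removed from the random marker set; a monomorphic
or collinear fixed marker is an error naming the column. Cross-
validation uses an unstratified random permutation split; every line
receives exactly one out-of-fold GEBV.

## Association scan

The scan is a kinship-corrected single-marker mixed linear model with
the P3D/EMMAX shortcut: null-model variance components estimated once
and reused per marker, the data whitened by V^{−1/2} from one
eigendecomposition of K, then a vectorised Wald test per marker
(t distribution, n−2 df). Markers are pre-filtered at MAF > 0.05 and
≤10% missingness. This deliberately replaces the multi-locus FarmCPU
algorithm: downstream stages consume only a ranked significant-SNP
list, and the substitution is recorded in every result object.
Benjamini–Hochberg step-up q-values are computed in-house (cross-
checked against statsmodels) and thresholded at 0.05. The top-k
(default 5) set takes each marker's best q across datasets, requiring
significance in at least one; ties break by |effect| then marker ID.
The favourable allele is the dosage direction with positive yield
effect; because the material is inbred, marker selection requires the
homozygous favourable dosage (2 or 0), and residual F5 heterozygotes
fail. Per-SNP variance explained is the drop-one R² from the joint OLS
fit of all significant markers, with later-ordered collinear markers
pruned under a warning.

## Selection strategies and response

Top-fraction selection takes ⌊q·N⌋ lines (minimum one), ties broken by
line ID — this reproduces 91 of 456 at q = 0.20. PS ranks adjusted
yield; GS ranks predicted yield; MS keeps lines homozygous favourable
at every top SNP; PS+GS is the intersection of the PS and GS sets.
S = mean(selected) − mean(all) on the declared evaluation set (the
selection environment within-environment, a next-season validation
environment cross-environment); R = H²·S. Empty selections (possible
for MS and PS+GS) are reported as not-applicable, never zero, and are
dropped pairwise from the paired t-tests between strategies; a
zero-variance difference vector is flagged degenerate (t = 0, p = 1 if
identical; |t| = ∞, p = 0 for a constant shift). A check-relative mode
replaces μ_Unselected by the check mean.

## The synthetic world

Defaults state the emulated program: an AMP of 456 lines × 2,000
markers (a desk-scale stand-in for a ~16k GBS panel), MAF uniform on
[0.05, 0.5] and forced into range by construction; biparental F5 (200
lines) and DH (500 lines) populations within the observed 60–760 range,
derived from AMP parents by simulated meiosis; 21 chromosomes of 150 cM
with Haldane interval recombination (the marker-level marginal of
Poisson crossovers with uniform positions, no interference); F5 lines
carry the expected 1/16 residual heterozygosity. Trials use 40-plot
blocks containing 5 replicated checks, every test line once per
environment; block effects are N(0, (0.2σe)²) — plot counts come from
the emulated design, block-effect magnitude is a stand-in exposed in
`SimConfig`. Twenty QTL drawn from the marker panel carry
per-environment effects; each environment's genetic SD is standardised
to 1 t/ha around a grand mean of 5 t/ha, and the residual variance is
set from the realised genetic variance so broad-sense heritability hits
its target (AMP 0.40; F5 0.15 and DH 0.55, the extremes observed for
such populations).

**Environment correlation is two-tier.** Trial environments (the AMP
site-years and each population's selection environment) share genetic
correlation 0.5; next-season validation environments correlate with
everything at `gxe_corr` (default 0.1). A single equicorrelated
structure would make the within- vs cross-environment contrast for GS
a coin flip in expectation (a GEBV trained on the AMP would be equally
correlated with both evaluation environments); the two-tier structure
encodes the intended mechanism — selections travel poorly into a new
season — and is the axis the cross-environment validation probes.

**What a green test does not establish.** The generator has no linkage
disequilibrium decay beyond family structure, no dominance or
epistasis, no spatial field trend, no missing genotypes by default, and
i.i.d. founder markers; within-panel cross-validation accuracy on an
unstructured panel is therefore pessimistic, and tests of CV accuracy
use family-structured panels instead. Pure-GS contrasts (GS1) sit near
the Monte-Carlo noise floor at 20 seeds because AMP-to-biparental
predictive ability is genuinely low — the same behaviour reported for
real programs — so ordering claims about GS are made on pooled means.

## Reproducibility and numerics

All randomness flows from one integer seed through `SeedSequence`
spawning; identical configuration and seed give byte-identical output
bundles (the run log stores the seed and a hash of the scientific
configuration). REML tolerance 1e−8 on log δ; kinship PSD tolerance
1e−8; collinear design columns pruned by exact rank tests; selection
ties broken lexicographically. Known limitations: the Eq-2-style
multi-environment fit estimates a single genotype variance (interaction
variance is not separated); FarmCPU-style multi-locus mapping, spatial
adjustment and pedigree A-matrices are out of scope.
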