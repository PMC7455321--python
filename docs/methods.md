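# Methods

## The causal model

bpmr implements two-sample Mendelian randomization (MR): genetic variants
are used as instruments for an exposure (here blood pressure, or the
BP-lowering action of an antihypertensive drug target), with
variant–exposure and variant–outcome associations taken from separate GWAS
summary statistics. Under the instrumental-variable assumptions
(relevance, independence from confounders, and no effect on the outcome
except through the exposure), the ratio of a variant's outcome effect to
its exposure effect estimates the causal effect θ of one exposure unit
(1 mm Hg) on the outcome (log odds ratio for binary outcomes; outcome
units for continuous ones such as white-matter-hyperintensity volume).

The estimator battery deliberately spans a ladder of assumptions:

| estimator | consistent when | role |
|---|---|---|
| fixed-effects IVW | all instruments valid | primary, BP traits |
| correlation-adjusted IVW (GLS) | all valid, instruments correlated | primary, drug-target proxies |
| MR-Egger slope | InSIDE: pleiotropic effects independent of instrument strength | sensitivity |
| weighted median | ≥ half the weight from valid instruments | sensitivity |
| weighted mode | a plurality of instruments valid | sensitivity |

Pleiotropy diagnostics: Cochran Q with I² = max(0, (Q − df)/Q)
(flagged when I² > 50% **and** p < 0.05), the MR-Egger intercept
(two-sided p < 0.05), and MR-PRESSO (below).

## The two instrument arms

**BP traits.** Instruments are variants with exposure p < 5×10⁻⁸
(strict inequality), greedily clumped to pairwise r² < 0.001: variants are
visited by ascending p (ties broken lexicographically by variant ID, so
runs are deterministic) and kept iff their squared correlation with every
already-kept variant is below threshold. The kept set is maximal for that
greedy order. LD is consumed as a user- or generator-supplied signed
correlation matrix; no reference panel is computed or downloaded.

**Drug-target proxies.** Genome-wide-significant variants lying inside
user-supplied gene regions (1-based inclusive intervals: gene body,
promoter, enhancer), pruned at a lenient r² < 0.4 — a deliberate
power/validity trade-off for cis instruments, with a stricter r² < 0.1
re-selection analysed by fixed-effects IVW as sensitivity. Proxies are
re-oriented so the effect allele is the BP-lowering allele, and the LD
matrix rows of flipped variants change sign accordingly. The pooled
estimate is the GLS solution with Ω_ij = σ_Yi σ_Yj ρ_ij. A class that
yields a single proxy is flagged and restricted to Wald-only estimation
(it is excluded from pooled analysis for lack of power).

Instrument strength is reported per variant as F = (β̂/σ̂)² with the weak
threshold at F ≤ 10, and variance explained as
r² = 2·EAF·(1−EAF)·β̂²/SD²_trait, which assumes Hardy–Weinberg equilibrium
and a continuous trait; the documented trait SDs are 21.5 mm Hg (SBP) and
11.4 mm Hg (DBP).

## Harmonization

Outcome records are aligned onto the exposure's effect allele: identical
pairs kept, swapped pairs get a sign flip (EAF mirrored), strand
complements are relabelled first. Palindromic (A/T, C/G) SNPs cannot be
resolved from labels; they are resolved by allele-frequency concordance
and dropped when either EAF lies within 0.5 ± 0.08 (window configurable)
or is missing. Indels and multi-allelic records are rejected at read time:
the design targets biallelic SNPs. A consistency check rejects rows whose
reported p disagrees with the normal p implied by β̂/σ̂ by more than one
decade in log10 (tolerance configurable, and switchable off because public
GWAS files often truncate p-values). All dropped records carry an explicit
action tag and never enter estimation.

## Weights

The delta-method ratio variance is used at second order by default
(σ²_j = σ²_Yj/β̂²_Xj + β̂²_Yj σ²_Xj/β̂⁴_Xj), which propagates exposure-side
sampling error; first-order weights are retained as an option and are used
in two places on purpose:

- **Cochran Q** uses first-order weights: conditional on the exposure
  effects, Q is then exactly χ²_{k−1} under homogeneity. Second-order
  weights involve the observed outcome effects and measurably distort the
  null distribution of Q (the test suite checks the uniformity of the
  first-order Q p-values directly).
- **MR-PRESSO's leave-one-out slopes** use first-order weights inside the
  resampling loop for speed; the second-order variant is available by
  flag and is immaterial at the SE ratios simulated here.

MR-Egger regresses β̂_Y on β̂_X (instruments oriented to β̂_X ≥ 0, which the
intercept requires) with weights 1/(σ²_j β̂²_Xj) — i.e. σ_Y⁻² at first
order — so the weighting convention matches IVW's on the outcome scale.
Egger SEs use the fit's multiplicative dispersion (random-effects Egger).

## Bootstrap standard errors

Weighted-median and weighted-mode SEs come from a seeded parametric
bootstrap of the summary statistics: β*_Xj ~ N(β̂_Xj, σ²_Xj) and, by
default, β*_Yj ~ N(θ̂·β̂_Xj, σ²_Yj) — the outcome resamples are centred on
the estimator's own fitted causal model, the same construction MR-PRESSO
uses for its null datasets. Centring on the *observed* β̂_Yj (the
convention of the originally published weighted-median code) folds the
observed ratio scatter into the resampling a second time and produces
measurably conservative SEs for these non-linear estimators; both
centrings are available (`boot_center="fitted"|"observed"`), and the
fitted centring is the default because its CI coverage is calibrated in
the package's recovery study. Defaults: 1,000 replicates, seed recorded in
the estimate metadata. The acceptance harness uses 300 bootstrap
replicates per estimate (SE estimation noise ~4%, negligible against the
coverage bands it checks) to keep 1,000-replicate studies fast.

The weighted-mode bandwidth is h = φ·0.9·min(sd, 1.4826·MAD)·J^(−1/5)
(φ = 1 by default), with the density evaluated on a 512-point grid over
[min θ̂_j − 3h, max θ̂_j + 3h]; if all ratios coincide the common value is
returned directly. Grid resolution is a resolution/runtime trade-off and
is configurable.

## MR-PRESSO

For each instrument j, the leave-one-out IVW slope θ̂_(−j) yields a
residual r_j = β̂_Yj − θ̂_(−j)β̂_Xj weighted by σ_Yj⁻²; RSS_obs = Σ w_j r_j².
n_sim parametric datasets are simulated from the fitted null and RSS
recomputed identically; empirical p-values use the add-one rule, so they
are bounded below by 1/(n_sim+1) and never zero. Per-instrument p-values
are Bonferroni-compared to α/k. Consequence: outlier flagging is
**impossible** unless n_sim ≥ k/α (e.g. 1,200 at k = 60, α = 0.05); the
implementation warns in that regime, and the outlier studies here use
n_sim = 2,000 — the smallest round value that clears the threshold, which
also pins the per-instrument false-flag probability at its
discreteness-limited value (a flag requires *zero* simulated exceedances).
Flagged variants are excluded and IVW re-estimated ("outlier-corrected");
when nothing is flagged the reported outlier-corrected row equals the
primary estimate. The distortion test of the published MR-PRESSO procedure
is not implemented: only the global and outlier tests feed this analysis
design.

## The synthetic generator

The generator works at summary-statistic level — no individual-level
genotypes — which is sufficient for every estimator here and orders of
magnitude faster. Per SNP: MAF ~ U(0.05, 0.5); true exposure effect γ_j
with sd 0.35 mm Hg per allele (the magnitude regime of
genome-wide-significant BP loci; mean instrument F ≈ 75 at the default
exposure sample size); SEs from the standard single-SNP approximations
σ_Xj = SD_trait/√(2n·MAF(1−MAF)) and, for binary outcomes,
σ_Yj = √((1/n_case + 1/n_ctrl)/(2·MAF(1−MAF))). Outcome effects follow
β_Yj ~ N(θγ_j + α_j, σ²_Yj). Defaults mirror the study scale:
n_exposure = 757,601, SD 21.5 mm Hg, 10,000/50,000 cases/controls,
θ = 0.0405 log-OR per mm Hg (OR ≈ 1.5 per 10 mm Hg).

Because the analysis operates on *selected* instruments (every variant
genome-wide significant, F > 10), γ magnitudes are drawn by default from
the half-normal truncated below 6·σ_Xj — the effect distribution that
survives significance selection. `instrument_z_min=None` gives the
unconditional normal draw (used e.g. for null-p-value uniformity checks).

Pleiotropy regimes on a configurable invalid fraction: `balanced`
(α ~ N(0, σ²_α)); `directional` (α aligned with the exposure-increasing
allele, α = sign(γ)·N(μ_α, σ²_α) — without the sign-alignment the
ratio-scale bias of symmetric-γ panels would cancel and the scenario would
not be directional); `inside_violating` (α proportional to |γ|, breaking
InSIDE). The directional stress scenario uses μ_α = 0.08, σ_α = 0.02:
direct effects several times the mediated per-variant effect, so the
invalid ratios form a cluster displaced beyond the valid instruments'
sampling spread — the regime the robust estimators' consistency conditions
describe, and the only regime in which a per-replicate robustness
separation can hold. Gross outliers add α of ±10× the typical mediated
effect to a chosen number of otherwise-valid variants.

Within LD blocks (AR(1) correlation), the estimation errors of **both**
samples are drawn jointly multivariate normal with the block correlation —
the exposure side because that is how LD propagates into a GWAS, and the
outcome side because Ω_ij = σ_Yi σ_Yj ρ_ij is precisely the covariance the
correlation-adjusted IVW models. The emitted LD matrix is the exact block
correlation used, so GLS coverage is testable against truth.

The outcome panel's allele representation is scrambled per SNP (as-is /
swapped / strand-complement) so harmonization is exercised, and undone
exactly, in every pipeline run. Drug-target fixtures plant configurable
numbers of significant SNPs (exposure |z| drawn from 10–16, so the planted
sets are recovered deterministically) inside named regions with AR(1)
in-region LD, over a null background — emulating the 60-CCB / 8-BB /
1-ACE proxy asymmetry as fixture geometry.

**What the generator does not emulate:** real LD structure (haplotype
blocks, long-range LD), allele-frequency–effect-size coupling, ancestry
structure, sample overlap between exposure and outcome GWAS, shared
controls across outcome subtypes, binary-trait non-collapsibility, and
winner's-curse inflation of the selected exposure effects. Passing tests
therefore demonstrate internal statistical correctness of the estimators
and pipeline under the stated model, not robustness to those real-data
features.

## Numerical choices

- 95% CIs use the 1.96 normal quantile throughout; p-values are two-sided
  normal (χ² upper tail for Q).
- GLS: Ω is Cholesky-solved; if its condition number exceeds 10⁸ a ridge
  ε·diag(Ω) (ε = 10⁻⁶) is added with a warning pointing at stricter LD
  pruning; failure after jitter raises a numerical error rather than
  silently pseudo-inverting.
- β̂_X = 0 raises a degenerate-instrument error (the Wald ratio is
  undefined); estimator minima are enforced (1 Wald, 2 IVW/median/mode,
  3 Egger, 4 MR-PRESSO).
- Empirical p-values use the add-one rule (never zero).
- Clump ties break lexicographically; results tables sort
  (exposure, outcome, method) lexicographically; re-running a pipeline
  config with the same seed reproduces the bundle byte for byte (no
  timestamps in provenance).
- TSV readers parse floats in round-trip mode, so written estimates and
  harmonized instruments re-read value-exact.

## Analysis grid and reporting

`run_analysis` executes every exposure × outcome pair independently
(a degenerate cell — e.g. a single-proxy class — is logged and skipped
without aborting the grid), applies the arm-appropriate selection and
primary estimator, the full sensitivity battery and diagnostics, scales to
the clinical increments (+10 SBP / +5 DBP / −10 drug proxies), and
evaluates configured subtype contrasts with the log-OR z test. Statistical
significance is two-sided 0.05 with no cross-cell multiplicity adjustment,
matching the analysis design this package reproduces. The z test treats
the two subtype estimates as independent; outcome GWAS sharing controls
violate that assumption, which is logged as a warning and left to the
user's interpretation.

## Problem sizes in the verification studies

The recovery study runs 1,000 replicates of the 60-instrument study-scale
scenario for all five pooled estimators (bootstrap SEs at 300 replicates);
calibration uses 2,000 null replicates for IVW type-I error, 500 for
Q/Egger-intercept p-value uniformity, and 300 for the MR-PRESSO global
test at n_sim = 1,000; robustness uses 200 replicates each for the
directional-pleiotropy separation and the planted-outlier detection
(n_sim = 2,000). These sizes give Monte-Carlo error comfortably below the
property bands being checked.

## Known limitations

- No multivariable MR, Steiger directionality filtering, CAUSE or
  contamination-mixture estimators; no MR-PRESSO distortion test.
- LD must be supplied (or generated); there is no reference-panel LD
  computation, liftover, or VCF ingestion.
- The shared-controls correlation in subtype comparisons is ignored (see
  above).
- Mediation analysis between BP traits and drug-target effects is out of
  scope.
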