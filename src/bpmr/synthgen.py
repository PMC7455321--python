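"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator works at the summary-statistic level (no individual-level
genotypes): per-SNP true exposure effects gamma_j are drawn, sampling error
is added with the SE implied by sample size and allele frequency, and
outcome effects follow the causal model

    beta_y_j ~ N(theta * gamma_j + alpha_j, se_y_j^2)

where alpha_j is a per-variant pleiotropic direct effect.  Standard errors
use the usual single-SNP approximations

    se_x_j = sd_trait / sqrt(2 n_exposure maf_j (1 - maf_j))            (continuous)
    se_y_j = sqrt((1/n_case + 1/n_ctrl) / (2 maf_j (1 - maf_j)))        (binary log-OR)

so at the default blood-pressure scale (sd 21.5 mm Hg, n = 757,601) the
exposure SEs land at the ~0.04 mm Hg magnitude of a large BP GWAS.  Within
LD blocks the estimation errors of both samples are drawn jointly
multivariate normal with AR(1) correlation, matching the covariance model
used by the correlated-instrument IVW.

Pleiotropy regimes
------------------
``none``; ``balanced`` (alpha ~ N(0, sigma_alpha^2) on the invalid
fraction); ``directional`` (alpha = sign(gamma) * N(mu_alpha, sigma_alpha^2):
direct effects aligned with the exposure-increasing allele, so the Wald
ratios of invalid instruments are shifted in one direction); and
``inside_violating`` (alpha proportional to instrument strength |gamma|,
breaking the InSIDE assumption that MR-Egger needs).  ``n_outliers``
variants additionally receive a gross direct effect of ``outlier_scale``
times the typical outcome-effect magnitude.

Scenario factory functions (:func:`null_scenario` etc.) encode the canonical
study conditions used by the calibration and recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError
from .instruments import GeneRegion, LDMatrix, write_regions
from .sumstats import CANONICAL_COLUMNS, write_sumstats

_NONPALINDROMIC_PAIRS = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
                         ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic two-sample MR scenario.

    Defaults are the real-study scale: a BP exposure GWAS of 757,601
    individuals (SBP sd 21.5 mm Hg), a binary outcome GWAS of 10,000 cases /
    50,000 controls (a stroke-subtype-sized panel), 60 instruments with
    per-allele effects of sd 0.35 mm Hg (typical genome-wide-significant BP
    loci; mean instrument F ~ 75), and a causal effect theta of 0.0405
    log-OR per mm Hg (OR ~ 1.5 per 10 mm Hg, the magnitude regime of the
    BP-stroke associations).
    """

    n_snps: int = 60
    maf_range: tuple[float, float] = (0.05, 0.5)
    theta_true: float = 0.0405
    sigma_gamma: float = 0.35
    trait_sd: float = 21.5
    n_exposure: int = 757_601
    n_case: int = 10_000
    n_ctrl: int = 50_000
    outcome_kind: str = "binary"
    outcome_sd: float = 1.0       # continuous outcomes only
    n_outcome: int = 50_000       # continuous outcomes only
    pleiotropy: str = "none"      # none|balanced|directional|inside_violating
    mu_alpha: float = 0.0
    sigma_alpha: float = 0.0
    frac_invalid: float = 0.0
    ld_blocks: tuple[int, ...] | None = None  # None -> independent SNPs
    ld_rho: float = 0.0
    n_outliers: int = 0
    outlier_scale: float = 10.0
    instrument_z_min: float | None = 6.0
    scramble_outcome_alleles: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.frac_invalid <= 1):
            raise ConfigurationError("frac_invalid must lie in [0, 1]")
        if not (0 < self.maf_range[0] < self.maf_range[1] <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < lo < hi <= 0.5")
        if min(self.n_exposure, self.n_case, self.n_ctrl) < 2:
            raise ConfigurationError("sample sizes must be >= 2")
        if self.pleiotropy not in ("none", "balanced", "directional", "inside_violating"):
            raise ConfigurationError(f"unknown pleiotropy regime {self.pleiotropy!r}")
        if self.ld_blocks is not None and sum(self.ld_blocks) != self.n_snps:
            raise ConfigurationError(
                f"ld_blocks {self.ld_blocks} do not partition n_snps={self.n_snps}")
        if self.n_outliers > self.n_snps:
            raise ConfigurationError("more outliers than SNPs")

    def replace(self, **kw) -> "ScenarioConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class Truth:
    """Ground truth stored with every generated scenario."""

    theta: float
    variant_ids: tuple
    gamma: np.ndarray
    alpha: np.ndarray
    maf: np.ndarray
    invalid_ids: tuple
    outlier_ids: tuple
    seed: int


class GeneratedPair(NamedTuple):
    exposure: pd.DataFrame
    outcome: pd.DataFrame
    ld: LDMatrix
    truth: Truth


# canonical study conditions --------------------------------------------------

def null_scenario(seed: int = 0, n_snps: int = 60) -> ScenarioConfig:
    """No causal effect, no pleiotropy: type-I-error calibration conditions."""
    return ScenarioConfig(n_snps=n_snps, theta_true=0.0, seed=seed)


def recovery_scenario(seed: int = 0, n_snps: int = 60) -> ScenarioConfig:
    """theta = 0.0405 log-OR per mm Hg (OR ~ 1.5 per 10 mm Hg), valid instruments."""
    return ScenarioConfig(n_snps=n_snps, theta_true=0.0405, seed=seed)


def balanced_pleiotropy_scenario(seed: int = 0, n_snps: int = 100) -> ScenarioConfig:
    """Balanced pleiotropy on all instruments (Egger-null conditions)."""
    return ScenarioConfig(n_snps=n_snps, theta_true=0.0, pleiotropy="balanced",
                          sigma_alpha=0.02, frac_invalid=1.0, seed=seed)


def directional_pleiotropy_scenario(seed: int = 0, n_snps: int = 60) -> ScenarioConfig:
    """40% invalid instruments with strong directional pleiotropy.

    mu_alpha = 0.08 puts the invalid variants' direct effects several times
    above the mediated per-variant effect, so their Wald ratios form a
    cluster displaced beyond the valid instruments' sampling spread.  This
    is the regime the robust estimators' consistency conditions address: a
    displaced pleiotropic minority that IVW averages in but that median and
    mode estimators, anchored on the valid majority, exclude.
    """
    return ScenarioConfig(n_snps=n_snps, theta_true=0.0405, pleiotropy="directional",
                          mu_alpha=0.08, sigma_alpha=0.02, frac_invalid=0.4, seed=seed)


def outlier_scenario(seed: int = 0, n_snps: int = 60, n_outliers: int = 2) -> ScenarioConfig:
    """Two gross pleiotropic outliers among otherwise valid instruments."""
    return ScenarioConfig(n_snps=n_snps, theta_true=0.0405,
                          n_outliers=n_outliers, outlier_scale=10.0, seed=seed)


def correlated_scenario(seed: int = 0, n_snps: int = 60, block: int = 5,
                        rho: float = 0.6) -> ScenarioConfig:
    """AR(1) LD blocks, for the correlated-instrument IVW."""
    if n_snps % block:
        raise ConfigurationError("block must divide n_snps")
    return ScenarioConfig(n_snps=n_snps, theta_true=0.0405,
                          ld_blocks=tuple([block] * (n_snps // block)),
                          ld_rho=rho, seed=seed)


# -----------------------------------------------------------------------------

def _block_ar1(blocks: tuple[int, ...], rho: float) -> np.ndarray:
    mats = []
    for b in blocks:
        idx = np.arange(b)
        mats.append(rho ** np.abs(idx[:, None] - idx[None, :]))
    n = sum(blocks)
    out = np.zeros((n, n))
    pos = 0
    for m in mats:
        b = m.shape[0]
        out[pos:pos + b, pos:pos + b] = m
        pos += b
    return out


def _correlated_normals(chol: np.ndarray | None, n: int, rng) -> np.ndarray:
    z = rng.standard_normal(n)
    return z if chol is None else chol @ z


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(beta) / se)


def generate_pair(cfg: ScenarioConfig, seed: int | None = None) -> GeneratedPair:
    """Generate one exposure/outcome summary-statistic pair with ground truth.

    All randomness flows from ``seed`` (default ``cfg.seed``).  The outcome
    panel's allele representation is scrambled per SNP (same order, swapped
    order, or strand-complement labels) when ``cfg.scramble_outcome_alleles``
    — harmonization must undo the scrambling exactly, which the truth record
    makes testable.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    j = cfg.n_snps
    width = len(str(j))
    vids = tuple(f"rs{i + 1:0{width}d}" for i in range(j))
    maf = rng.uniform(*cfg.maf_range, size=j)
    het = 2.0 * maf * (1.0 - maf)
    se_x = cfg.trait_sd / np.sqrt(cfg.n_exposure * het)
    gamma = _draw_gamma(cfg, rng, se_x)
    if cfg.outcome_kind == "binary":
        se_y = np.sqrt((1.0 / cfg.n_case + 1.0 / cfg.n_ctrl) / het)
        n_y = cfg.n_case + cfg.n_ctrl
    else:
        se_y = cfg.outcome_sd / np.sqrt(cfg.n_outcome * het)
        n_y = cfg.n_outcome

    alpha, invalid_ids, outlier_ids = _pleiotropy_effects(cfg, rng, gamma, vids)

    chol = None
    if cfg.ld_blocks is not None and cfg.ld_rho != 0.0:
        corr = _block_ar1(cfg.ld_blocks, cfg.ld_rho)
        chol = np.linalg.cholesky(corr)
        rho = corr
    else:
        rho = np.eye(j)
    ld = LDMatrix(vids, rho, validate=False)

    beta_x = gamma + se_x * _correlated_normals(chol, j, rng)
    beta_y = (cfg.theta_true * gamma + alpha
              + se_y * _correlated_normals(chol, j, rng))

    pairs = [_NONPALINDROMIC_PAIRS[i] for i in rng.integers(0, 8, size=j)]
    ea = np.array([p[0] for p in pairs])
    oa = np.array([p[1] for p in pairs])
    pos = 1_000_000 + 5_000 * np.arange(j)

    exposure = pd.DataFrame({
        "variant_id": vids, "chrom": "1", "pos": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": maf,
        "beta": beta_x, "se": se_x, "pval": _two_sided_p(beta_x, se_x),
        "n": float(cfg.n_exposure),
    }, columns=CANONICAL_COLUMNS)

    outcome = pd.DataFrame({
        "variant_id": vids, "chrom": "1", "pos": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": maf,
        "beta": beta_y, "se": se_y, "pval": _two_sided_p(beta_y, se_y),
        "n": float(n_y),
    }, columns=CANONICAL_COLUMNS)
    if cfg.scramble_outcome_alleles:
        outcome = _scramble_alleles(outcome, rng)

    truth = Truth(cfg.theta_true, vids, gamma, alpha, maf,
                  invalid_ids, outlier_ids, seed)
    return GeneratedPair(exposure, outcome, ld, truth)


def _draw_gamma(cfg, rng, se_x: np.ndarray) -> np.ndarray:
    """True exposure effects gamma_j ~ N(0, sigma_gamma^2).

    When ``instrument_z_min`` is set, magnitudes are drawn from the same
    half-normal truncated below ``z_min * se_x_j`` — the distribution of
    effects surviving significance selection, so the emitted panel mimics a
    set of already-selected instruments (every F well above the
    weak-instrument threshold).  ``None`` gives the raw normal draw.
    """
    j = len(se_x)
    if cfg.instrument_z_min is None:
        return rng.normal(0.0, cfg.sigma_gamma, size=j)
    lo = stats.norm.cdf(cfg.instrument_z_min * se_x / cfg.sigma_gamma)
    u = rng.uniform(size=j)
    magnitude = cfg.sigma_gamma * stats.norm.ppf(lo + u * (1.0 - lo))
    return rng.choice([-1.0, 1.0], size=j) * magnitude


def _pleiotropy_effects(cfg, rng, gamma, vids):
    j = len(gamma)
    alpha = np.zeros(j)
    n_invalid = int(round(cfg.frac_invalid * j))
    invalid = rng.choice(j, size=n_invalid, replace=False) if n_invalid else np.array([], int)
    if cfg.pleiotropy == "balanced":
        alpha[invalid] = rng.normal(0.0, cfg.sigma_alpha, size=n_invalid)
    elif cfg.pleiotropy == "directional":
        alpha[invalid] = (np.sign(gamma[invalid])
                          * rng.normal(cfg.mu_alpha, cfg.sigma_alpha, size=n_invalid))
    elif cfg.pleiotropy == "inside_violating":
        mean_abs = np.mean(np.abs(gamma)) or 1.0
        alpha[invalid] = (np.sign(gamma[invalid]) * cfg.mu_alpha
                          * np.abs(gamma[invalid]) / mean_abs
                          + rng.normal(0.0, cfg.sigma_alpha, size=n_invalid))

    outliers = np.array([], int)
    if cfg.n_outliers:
        outliers = rng.choice(np.setdiff1d(np.arange(j), invalid),
                              size=cfg.n_outliers, replace=False)
        typical = max(abs(cfg.theta_true) * cfg.sigma_gamma, 1e-12)
        alpha[outliers] = (rng.choice([-1.0, 1.0], size=cfg.n_outliers)
                           * cfg.outlier_scale * typical)
    invalid_ids = tuple(vids[i] for i in sorted(invalid))
    outlier_ids = tuple(vids[i] for i in sorted(outliers))
    return alpha, invalid_ids, outlier_ids


def _scramble_alleles(records: pd.DataFrame, rng) -> pd.DataFrame:
    """Re-express records under random equivalent allele representations."""
    out = records.copy()
    choice = rng.integers(0, 3, size=len(out))  # 0 as-is, 1 swapped, 2 strand-flipped
    swap = choice == 1
    out.loc[swap, ["effect_allele", "other_allele"]] = (
        out.loc[swap, ["other_allele", "effect_allele"]].to_numpy())
    out.loc[swap, "beta"] = -out.loc[swap, "beta"]
    out.loc[swap, "eaf"] = 1.0 - out.loc[swap, "eaf"]
    strand = choice == 2
    out.loc[strand, "effect_allele"] = out.loc[strand, "effect_allele"].map(_COMPLEMENT)
    out.loc[strand, "other_allele"] = out.loc[strand, "other_allele"].map(_COMPLEMENT)
    return out


# -----------------------------------------------------------------------------
# drug-target fixtures

class DrugFixture(NamedTuple):
    exposure: pd.DataFrame
    outcome: pd.DataFrame
    regions: list
    ld: LDMatrix
    truth: Truth


def generate_drug_fixture(
    cfg: ScenarioConfig,
    region_spec: dict[str, int],
    n_background: int = 200,
    region_rho: float = 0.8,
    z_range: tuple[float, float] = (10.0, 16.0),
    seed: int | None = None,
) -> DrugFixture:
    """Gene-region fixture: planted significant cis SNPs plus null background.

    ``region_spec`` maps region names (e.g. drug classes "CCB", "BB", "ACE")
    to the number of genome-wide-significant SNPs planted inside each —
    emulating the 60-CCB / 8-BB / 1-ACE proxy asymmetry as configurable
    counts.  Planted SNPs get exposure z-scores drawn from ``z_range``
    (random sign), far above the 5e-8 threshold, so the planted sets are
    recovered deterministically; background SNPs are null.  Within-region LD
    is AR(1) with adjacent correlation ``region_rho``; background SNPs are
    independent.
    """
    seed = cfg.seed if seed is None else seed
    if any(n < 1 for n in region_spec.values()):
        raise ConfigurationError("each region needs at least one planted SNP")
    counts = list(region_spec.values())
    n_planted = sum(counts)
    blocks = tuple(counts + [1] * n_background)
    base = cfg.replace(n_snps=n_planted + n_background, ld_blocks=blocks,
                       ld_rho=region_rho, sigma_gamma=1e-9, n_outliers=0,
                       frac_invalid=0.0, pleiotropy="none",
                       instrument_z_min=None)
    rng = np.random.default_rng(seed)
    pair = generate_pair(base, seed=int(rng.integers(2 ** 31)))
    exposure, outcome = pair.exposure.copy(), pair.outcome.copy()
    ld = pair.ld

    # overwrite planted SNPs with strong effects (gamma on the exposure,
    # theta*gamma on the outcome) while keeping the drawn LD noise structure
    se_x = exposure["se"].to_numpy()
    gamma = np.array(pair.truth.gamma)
    idx = 0
    regions = []
    span_pad = 2_000  # below half the 5 kb SNP spacing: regions stay disjoint
    for name, count in region_spec.items():
        sl = slice(idx, idx + count)
        z = rng.uniform(*z_range, size=count) * rng.choice([-1.0, 1.0], size=count)
        gamma[sl] = z * se_x[sl]
        pos = exposure["pos"].to_numpy()[sl]
        regions.append(GeneRegion(name, "1", int(pos.min() - span_pad),
                                  int(pos.max() + span_pad), "gene_body"))
        idx += count
    _assert_nonoverlapping(regions)

    noise_x = exposure["beta"].to_numpy() - pair.truth.gamma
    beta_x = gamma + noise_x
    exposure["beta"] = beta_x
    exposure["pval"] = _two_sided_p(beta_x, se_x)

    # outcome refreshed on the same noise realisation, preserving scrambling:
    # swapped-order labels carry a flipped beta sign, strand-complement
    # labels keep it
    swapped = np.array([
        o_ea == x_oa and o_oa == x_ea
        for o_ea, o_oa, x_ea, x_oa in zip(
            outcome["effect_allele"], outcome["other_allele"],
            exposure["effect_allele"], exposure["other_allele"])])
    flip = np.where(swapped, -1.0, 1.0)
    noise_y = flip * outcome["beta"].to_numpy() - cfg.theta_true * pair.truth.gamma
    beta_y = flip * (cfg.theta_true * gamma + noise_y)
    outcome["beta"] = beta_y
    outcome["pval"] = _two_sided_p(beta_y, outcome["se"].to_numpy())

    truth = Truth(cfg.theta_true, pair.truth.variant_ids, gamma,
                  np.zeros_like(gamma), np.array(pair.truth.maf),
                  (), (), seed)
    return DrugFixture(exposure, outcome, regions, ld, truth)


def _assert_nonoverlapping(regions) -> None:
    by_chrom: dict[str, list] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for rs in by_chrom.values():
        rs = sorted(rs, key=lambda r: r.start)
        for a, b in zip(rs, rs[1:]):
            if b.start <= a.end:
                raise ConfigurationError(f"regions {a.name} and {b.name} overlap")


# -----------------------------------------------------------------------------
# scenario I/O

def write_scenario(pair, outdir, cfg: ScenarioConfig | None = None) -> None:
    """Write a generated scenario as plain-text files (seed recorded in each)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = pair.truth.seed
    write_sumstats(pair.exposure, outdir / "exposure.tsv", seed=seed)
    write_sumstats(pair.outcome, outdir / "outcome.tsv", seed=seed)
    pair.ld.to_tsv(outdir / "ld.tsv")
    truth = pair.truth
    with open(outdir / "truth.json", "w") as fh:
        json.dump({
            "theta": truth.theta, "seed": truth.seed,
            "variant_ids": list(truth.variant_ids),
            "gamma": list(truth.gamma), "alpha": list(truth.alpha),
            "maf": list(truth.maf),
            "invalid_ids": list(truth.invalid_ids),
            "outlier_ids": list(truth.outlier_ids),
        }, fh, indent=1)
    if hasattr(pair, "regions"):
        write_regions(pair.regions, outdir / "regions.tsv")
    if cfg is not None:
        with open(outdir / "scenario.cfg", "w") as fh:
            for f in dataclasses.fields(cfg):
                fh.write(f"{f.name} = {getattr(cfg, f.name)!r}\n")
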