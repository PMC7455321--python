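"""Orchestration of the full exposure x outcome analysis grid.

The study design has two arms:

* **BP traits** (SBP, DBP): genome-wide-significant instruments clumped to
  r^2 < 0.001, fixed-effects IVW as the primary estimator;
* **drug classes** (e.g. CCB, BB targets): cis proxies within gene regions
  at r^2 < 0.4, correlation-adjusted IVW as primary, with a sensitivity
  re-selection at r^2 < 0.1 analysed by fixed-effects IVW.

Every pair additionally runs the sensitivity battery (MR-Egger, weighted
median, weighted mode, MR-PRESSO-outlier-excluded IVW) and the pleiotropy
diagnostics, scales results to the clinical increments, and evaluates the
configured subtype contrasts.  One failing pair is logged and does not
abort the rest of the grid.  All randomness derives from the config seed,
so a re-run of the same config reproduces the bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimators import (
    MREstimate, estimates_frame, ivw_correlated, ivw_fixed, mr_egger,
    wald_estimate, wald_ratios, weighted_median, weighted_mode,
)
from .exceptions import BpmrError, ConfigurationError
from .instruments import (
    LDMatrix, ld_clump, read_regions, select_drug_proxies, select_gw_significant,
)
from .pleiotropy import cochran_q, mr_presso
from .reporting import ScaledEstimate, build_results_table, compare_or, scale_estimate
from .sumstats import harmonize, kept_instruments, read_sumstats
from .synthgen import ScenarioConfig, generate_pair

logger = logging.getLogger(__name__)

SENSITIVITY_METHODS = ("egger_slope", "weighted_median", "weighted_mode",
                       "ivw_outlier_corrected")


@dataclass
class ExposureSpec:
    label: str
    sumstats: object  # path or DataFrame
    kind: str         # bp_trait | drug_class
    scale_mmhg: float
    trait_sd: float = 21.5
    ld: object = None        # path or LDMatrix
    regions: object = None   # path or list[GeneRegion]; drug_class only

    def __post_init__(self):
        if self.kind not in ("bp_trait", "drug_class"):
            raise ConfigurationError(f"exposure kind {self.kind!r} unknown")
        if self.kind == "drug_class" and self.regions is None:
            raise ConfigurationError(f"drug_class exposure {self.label} needs regions")
        if self.ld is None:
            raise ConfigurationError(f"exposure {self.label} needs an LD matrix")


@dataclass
class OutcomeSpec:
    label: str
    sumstats: object
    kind: str  # binary | continuous

    def __post_init__(self):
        if self.kind not in ("binary", "continuous"):
            raise ConfigurationError(f"outcome kind {self.kind!r} unknown")


@dataclass
class AnalysisConfig:
    exposures: list
    outcomes: list
    contrasts: list = field(default_factory=list)  # (exposure, outcome_a, outcome_b)
    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    proxy_r2: float = 0.4
    proxy_r2_sensitivity: float = 0.1
    palindrome_eaf_window: float = 0.08
    n_boot: int = 1000
    presso_nsim: int = 1000
    alpha_outlier: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            exposures = [ExposureSpec(**e) for e in raw.pop("exposures")]
            outcomes = [OutcomeSpec(**o) for o in raw.pop("outcomes")]
            contrasts = [tuple(c) for c in raw.pop("contrasts", [])]
            return cls(exposures=exposures, outcomes=outcomes,
                       contrasts=contrasts, **raw)
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"invalid analysis config {path}: {exc}") from exc


@dataclass
class PairResult:
    exposure: str
    outcome: str
    estimates: list            # MREstimate
    scaled: list               # ScaledEstimate
    diagnostics: dict
    n_instruments: int
    seed: int
    single_instrument: bool = False


@dataclass
class ResultsBundle:
    results: pd.DataFrame
    diagnostics: pd.DataFrame
    contrasts: pd.DataFrame
    provenance: str
    pair_results: list
    errors: list


def _load_sumstats(src, trait_kind: str) -> pd.DataFrame:
    if isinstance(src, pd.DataFrame):
        return src
    return read_sumstats(src, trait_kind=trait_kind).records


def _load_ld(src) -> LDMatrix:
    return src if isinstance(src, LDMatrix) else LDMatrix.from_tsv(src)


def _load_regions(src):
    if src is None or isinstance(src, list):
        return src
    return read_regions(src)


def _pair_seed(cfg_seed: int, i_exp: int, i_out: int) -> int:
    ss = np.random.SeedSequence([cfg_seed, i_exp, i_out])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def analyze_pair(
    exposure: ExposureSpec,
    outcome: OutcomeSpec,
    cfg: AnalysisConfig,
    seed: int,
) -> PairResult:
    """Run the full estimator and diagnostic battery for one exposure-outcome pair."""
    exp_records = _load_sumstats(exposure.sumstats, "continuous")
    out_records = _load_sumstats(
        outcome.sumstats, "binary" if outcome.kind == "binary" else "continuous")
    ld = _load_ld(exposure.ld)

    if exposure.kind == "bp_trait":
        selected = ld_clump(
            select_gw_significant(exp_records, cfg.p_threshold), ld, cfg.clump_r2)
        ld_primary = ld.subset(list(selected["variant_id"]))
        primary_fn = lambda insts, ratios: ivw_fixed(ratios)  # noqa: E731
        strict = None
    else:
        selected = select_drug_proxies(exp_records, _load_regions(exposure.regions),
                                       ld, cfg.p_threshold, cfg.proxy_r2)
        flipped = selected.loc[selected["orientation_flipped"], "variant_id"]
        ld_primary = ld.subset(list(selected["variant_id"])).reorient(flipped)
        primary_fn = lambda insts, ratios: ivw_correlated(insts, ld_primary)  # noqa: E731
        strict = select_drug_proxies(exp_records, _load_regions(exposure.regions),
                                     ld, cfg.p_threshold, cfg.proxy_r2_sensitivity)

    harmonized = harmonize(selected, out_records, cfg.palindrome_eaf_window)
    insts = kept_instruments(harmonized)
    if insts.empty:
        raise BpmrError(f"no instruments survive harmonization for "
                        f"{exposure.label} -> {outcome.label}")

    estimates: list[MREstimate] = []
    diagnostics: dict = {}
    single = len(insts) == 1
    if single:
        # mirrors the study's single-proxy ACE class: Wald only, flagged,
        # excluded from pooled estimation for lack of power
        logger.warning("%s -> %s: single-instrument class; Wald-only estimation",
                       exposure.label, outcome.label)
        estimates.append(wald_estimate(insts.iloc[0]))
    else:
        ratios = wald_ratios(insts, "second")
        primary = dataclasses.replace(
            primary_fn(insts, ratios),
            method="ivw_correlated" if exposure.kind == "drug_class" else "ivw_fixed")
        estimates.append(primary)

        if len(insts) >= 3:
            egger = mr_egger(insts, "second")
            estimates.append(egger.slope)
            diagnostics.update(egger_intercept=egger.intercept.value,
                               egger_intercept_se=egger.intercept.se,
                               egger_intercept_p=egger.intercept.pval)
        estimates.append(weighted_median(ratios, cfg.n_boot, seed))
        estimates.append(weighted_mode(ratios, n_boot=cfg.n_boot, seed=seed + 1))

        het = cochran_q(wald_ratios(insts, "first"))
        diagnostics.update(q=het.q, q_df=het.df, p_q=het.p_q, i2=het.i2,
                           heterogeneity_significant=het.significant)
        if len(insts) >= 4:
            presso = mr_presso(insts, cfg.presso_nsim, seed + 2, cfg.alpha_outlier)
            diagnostics.update(presso_rss=presso.rss_obs,
                               presso_p_global=presso.p_global,
                               presso_outliers=",".join(presso.outlier_ids),
                               presso_n_outliers=len(presso.outlier_ids))
            corrected = presso.theta_outlier_corrected or primary
            estimates.append(dataclasses.replace(
                corrected, method="ivw_outlier_corrected"))

        if strict is not None and len(strict) >= 2:
            sh = kept_instruments(harmonize(strict, out_records,
                                            cfg.palindrome_eaf_window))
            if len(sh) >= 2:
                strict_est = ivw_fixed(wald_ratios(sh, "second"))
                estimates.append(dataclasses.replace(
                    strict_est, method="ivw_fixed_strict_ld"))

    scaled = [scale_estimate(est, exposure.scale_mmhg, outcome.kind,
                             exposure.label, outcome.label)
              for est in estimates]
    return PairResult(exposure.label, outcome.label, estimates, scaled,
                      diagnostics, len(insts), seed, single)


def run_analysis(cfg: AnalysisConfig, out_dir=None) -> ResultsBundle:
    """Run every exposure-outcome pair, the contrasts, and write the bundle.

    Per-pair failures are recorded in ``bundle.errors`` and do not abort the
    remaining pairs.  With ``out_dir`` set, writes ``results.tsv``,
    ``diagnostics.tsv``, ``contrasts.tsv``, ``estimates.tsv`` and
    ``provenance.txt`` (no timestamps: identical config and seed give
    byte-identical files).
    """
    pair_results, errors, scaled_all, diag_rows = [], [], [], []
    scaled_lookup = {}
    for i_exp, exposure in enumerate(cfg.exposures):
        for i_out, outcome in enumerate(cfg.outcomes):
            seed = _pair_seed(cfg.seed, i_exp, i_out)
            try:
                pr = analyze_pair(exposure, outcome, cfg, seed)
            except BpmrError as exc:
                logger.error("pair %s -> %s failed: %s",
                             exposure.label, outcome.label, exc)
                errors.append((exposure.label, outcome.label, str(exc)))
                continue
            pair_results.append(pr)
            scaled_all.extend(pr.scaled)
            diag_rows.append({"exposure": pr.exposure, "outcome": pr.outcome,
                              "n_instruments": pr.n_instruments,
                              "single_instrument": pr.single_instrument,
                              **pr.diagnostics})
            for s in pr.scaled:
                scaled_lookup[(pr.exposure, pr.outcome, s.method)] = s

    results = build_results_table(scaled_all)
    diagnostics = pd.DataFrame(diag_rows).sort_values(
        ["exposure", "outcome"], kind="mergesort").reset_index(drop=True) \
        if diag_rows else pd.DataFrame()

    contrast_rows = []
    for exp_label, out_a, out_b in cfg.contrasts:
        prim = [m for (e, o, m) in scaled_lookup if e == exp_label and o == out_a
                and m in ("ivw_fixed", "ivw_correlated")]
        if not prim or (exp_label, out_b, prim[0]) not in scaled_lookup:
            errors.append((exp_label, f"{out_a} vs {out_b}",
                           "contrast skipped: missing primary estimates"))
            continue
        comp = compare_or(scaled_lookup[(exp_label, out_a, prim[0])],
                          scaled_lookup[(exp_label, out_b, prim[0])],
                          warn_shared_controls=False)
        contrast_rows.append({"exposure": exp_label, "outcome_a": out_a,
                              "outcome_b": out_b, "method": prim[0],
                              "z": comp.z, "p": comp.p})
    contrasts = pd.DataFrame(
        contrast_rows, columns=["exposure", "outcome_a", "outcome_b", "method", "z", "p"])

    provenance = _provenance(cfg, pair_results, errors)
    bundle = ResultsBundle(results, diagnostics, contrasts, provenance,
                           pair_results, errors)
    if out_dir is not None:
        _write_bundle(bundle, out_dir)
    return bundle


def _provenance(cfg: AnalysisConfig, pair_results, errors) -> str:
    lines = [f"bpmr {__version__}", "settings:"]
    for name in ("p_threshold", "clump_r2", "proxy_r2", "proxy_r2_sensitivity",
                 "palindrome_eaf_window", "n_boot", "presso_nsim",
                 "alpha_outlier", "seed"):
        lines.append(f"  {name} = {getattr(cfg, name)!r}")
    lines.append("pairs:")
    for pr in pair_results:
        lines.append(f"  {pr.exposure} -> {pr.outcome}: "
                     f"n_instruments={pr.n_instruments} seed={pr.seed} "
                     f"single_instrument={pr.single_instrument}")
    for exp, out, msg in errors:
        lines.append(f"  FAILED {exp} -> {out}: {msg}")
    return "\n".join(lines) + "\n"


def _write_bundle(bundle: ResultsBundle, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle.results.to_csv(out_dir / "results.tsv", sep="\t", index=False)
    bundle.diagnostics.to_csv(out_dir / "diagnostics.tsv", sep="\t", index=False)
    bundle.contrasts.to_csv(out_dir / "contrasts.tsv", sep="\t", index=False)
    ests = pd.concat(
        [estimates_frame(pr.estimates).assign(exposure=pr.exposure, outcome=pr.outcome)
         for pr in bundle.pair_results],
        ignore_index=True) if bundle.pair_results else pd.DataFrame()
    ests.to_csv(out_dir / "estimates.tsv", sep="\t", index=False)
    (out_dir / "provenance.txt").write_text(bundle.provenance)


# ---------------------------------------------------------------------------
# parameter recovery

RECOVERY_ESTIMATORS = ("ivw_fixed", "ivw_correlated", "egger_slope",
                       "weighted_median", "weighted_mode")


def recover_parameters(
    scenario: ScenarioConfig,
    n_reps: int,
    estimators=RECOVERY_ESTIMATORS,
    n_boot: int = 300,
    seed: int | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parameter-recovery study: bias, coverage and rejection per estimator.

    Each replicate generates a fresh summary-statistic pair from
    ``scenario``, harmonizes it, and runs the requested estimators; the
    replicate seeds derive from ``seed``.  Returns ``(summary, per_rep)``:
    the summary has one row per estimator with mean bias, empirical SE,
    mean model SE, 95% CI coverage of the true theta and two-sided
    rejection rate at ``alpha``; ``per_rep`` holds every individual
    estimate for finer-grained comparisons.
    """
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    rep_seeds = np.random.SeedSequence(seed).generate_state(2 * n_reps, dtype=np.uint64)
    rep_seeds = (rep_seeds % (2 ** 31)).astype(np.int64)
    theta_true = scenario.theta_true
    rows = []
    for rep in range(n_reps):
        s = int(rep_seeds[rep])
        pair = generate_pair(scenario, seed=s)
        insts = kept_instruments(harmonize(pair.exposure, pair.outcome))
        ratios = wald_ratios(insts, "second")
        boot_seed = int(rep_seeds[n_reps + rep])
        for name in estimators:
            est = _run_estimator(name, insts, ratios, pair.ld, n_boot, boot_seed)
            rows.append({
                "rep": rep, "estimator": name, "theta": est.theta, "se": est.se,
                "error": est.theta - theta_true,
                "covered": est.ci_low <= theta_true <= est.ci_high,
                "rejected": est.pval < alpha,
            })
    per_rep = pd.DataFrame(rows)
    summary = per_rep.groupby("estimator", sort=False).agg(
        mean_bias=("error", "mean"),
        empirical_se=("theta", lambda x: x.std(ddof=1)),
        mean_model_se=("se", "mean"),
        coverage=("covered", "mean"),
        rejection_rate=("rejected", "mean"),
    ).reset_index()
    summary["theta_true"] = theta_true
    summary["n_reps"] = n_reps
    return summary, per_rep


def _run_estimator(name, insts, ratios, ld, n_boot, seed) -> MREstimate:
    if name == "ivw_fixed":
        return ivw_fixed(ratios)
    if name == "ivw_correlated":
        return ivw_correlated(insts, ld)
    if name == "egger_slope":
        return mr_egger(insts, "second").slope
    if name == "weighted_median":
        return weighted_median(ratios, n_boot, seed)
    if name == "weighted_mode":
        return weighted_mode(ratios, n_boot=n_boot, seed=seed)
    raise ConfigurationError(f"unknown estimator {name!r}")
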