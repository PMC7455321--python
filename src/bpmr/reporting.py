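"""Scaling of MR estimates to clinical units and subtype comparison.

Causal estimates are computed per 1 mm Hg of blood pressure; for reporting
they are scaled to the study's clinical increments — +10 mm Hg SBP,
+5 mm Hg DBP, and -10 mm Hg (a lowering) for antihypertensive drug-target
proxies — and exponentiated to odds ratios for binary outcomes.  Scaled
log-ORs for two outcomes (e.g. stroke subtypes) are compared with a z test
on the difference of their natural logarithms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, Z95
from .exceptions import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScaledEstimate:
    """An MR estimate on a clinical BP increment.

    ``theta_scaled`` is scale_mmhg * theta (a log-OR for binary outcomes, an
    outcome-unit difference for continuous ones) and ``se_scaled`` =
    |scale_mmhg| * se.  For binary outcomes ``or_point`` = exp(theta_scaled)
    with CI bounds transformed identically and ordered.
    """

    exposure: str
    outcome: str
    method: str
    scale_mmhg: float
    outcome_kind: str  # binary | continuous
    theta_scaled: float
    se_scaled: float
    pval: float
    n_instruments: int
    or_point: float | None = None
    or_low: float | None = None
    or_high: float | None = None
    beta_scaled: float | None = None
    beta_low: float | None = None
    beta_high: float | None = None


def scale_estimate(
    est: MREstimate,
    scale_mmhg: float,
    outcome_kind: str,
    exposure: str = "",
    outcome: str = "",
) -> ScaledEstimate:
    """Scale a per-mm Hg estimate to a signed BP increment.

    Binary outcomes: OR = exp(scale * theta), CI = exp(scale * (theta -+
    1.96 se)) with bounds ordered (a negative scale, e.g. -10 mm Hg for a
    drug-target proxy, reverses them).  Continuous outcomes report
    beta_scaled = scale * theta with the analogous CI.  The p-value is
    scale-invariant and carried through unchanged.
    """
    if scale_mmhg == 0:
        raise ConfigurationError("scale_mmhg must be non-zero")
    if outcome_kind not in ("binary", "continuous"):
        raise ConfigurationError(f"unknown outcome_kind {outcome_kind!r}")
    theta_s = scale_mmhg * est.theta
    se_s = abs(scale_mmhg) * est.se
    lo, hi = sorted((scale_mmhg * est.ci_low, scale_mmhg * est.ci_high))
    common = dict(
        exposure=exposure, outcome=outcome, method=est.method,
        scale_mmhg=scale_mmhg, outcome_kind=outcome_kind,
        theta_scaled=theta_s, se_scaled=se_s, pval=est.pval,
        n_instruments=est.n_instruments,
    )
    if outcome_kind == "binary":
        return ScaledEstimate(**common, or_point=float(np.exp(theta_s)),
                              or_low=float(np.exp(lo)), or_high=float(np.exp(hi)))
    return ScaledEstimate(**common, beta_scaled=theta_s, beta_low=lo, beta_high=hi)


@dataclass(frozen=True)
class ORComparison:
    label_a: str
    label_b: str
    z: float
    p: float


def compare_or(a: ScaledEstimate, b: ScaledEstimate,
               warn_shared_controls: bool = True) -> ORComparison:
    """z test for the difference of two scaled log-ORs.

    z = (ln OR_a - ln OR_b) / sqrt(se_a^2 + se_b^2), two-sided normal p.
    The two estimates are treated as independent; outcome GWAS from the same
    consortium typically share controls, which this test ignores (a warning
    is logged when the labels suggest it).
    """
    if abs(a.scale_mmhg) != abs(b.scale_mmhg):
        raise ConfigurationError(
            f"cannot compare estimates on different scales "
            f"({a.scale_mmhg} vs {b.scale_mmhg} mm Hg)")
    if a.method != b.method:
        raise ConfigurationError(f"cannot compare methods {a.method} vs {b.method}")
    if warn_shared_controls:
        logger.warning(
            "compare_or assumes independent estimates; subtype GWAS sharing "
            "controls makes this conservative assumption inexact")
    z = (a.theta_scaled - b.theta_scaled) / np.hypot(a.se_scaled, b.se_scaled)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return ORComparison(f"{a.exposure}:{a.outcome}", f"{b.exposure}:{b.outcome}",
                        float(z), p)


RESULTS_COLUMNS = [
    "exposure", "outcome", "method", "scale_mmhg", "outcome_kind",
    "n_instruments", "or_point", "or_low", "or_high",
    "beta_scaled", "beta_low", "beta_high", "pval",
]


def build_results_table(scaled_estimates, diagnostics: pd.DataFrame | None = None
                        ) -> pd.DataFrame:
    """Assemble the exposures x outcomes x methods results grid.

    One row per (exposure, outcome, method) triple, sorted lexicographically
    for deterministic output; empty input yields a header-only table.
    Heterogeneity/pleiotropy diagnostics, when given as a DataFrame keyed by
    (exposure, outcome), are merged in.
    """
    rows = [{
        "exposure": e.exposure, "outcome": e.outcome, "method": e.method,
        "scale_mmhg": e.scale_mmhg, "outcome_kind": e.outcome_kind,
        "n_instruments": e.n_instruments,
        "or_point": e.or_point, "or_low": e.or_low, "or_high": e.or_high,
        "beta_scaled": e.beta_scaled, "beta_low": e.beta_low, "beta_high": e.beta_high,
        "pval": e.pval,
    } for e in scaled_estimates]
    table = pd.DataFrame(rows, columns=RESULTS_COLUMNS)
    table = table.sort_values(["exposure", "outcome", "method"],
                              kind="mergesort").reset_index(drop=True)
    if diagnostics is not None and not table.empty:
        table = table.merge(diagnostics, on=["exposure", "outcome"], how="left")
    return table


def write_forest_long(table: pd.DataFrame, path) -> None:
    """Long-format forest-plot export: one (label, point, lo, hi) row per estimate."""
    binary = table["or_point"].notna()
    out = pd.DataFrame({
        "label": table["exposure"] + " -> " + table["outcome"] + " [" + table["method"] + "]",
        "point": table["or_point"].where(binary, table["beta_scaled"]),
        "lo": table["or_low"].where(binary, table["beta_low"]),
        "hi": table["or_high"].where(binary, table["beta_high"]),
        "measure": np.where(binary, "odds_ratio", "beta"),
        "pval": table["pval"],
    })
    out.to_csv(path, sep="\t", index=False)
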