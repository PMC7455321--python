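"""Heterogeneity and pleiotropy diagnostics.

Valid instruments should all estimate the same causal effect, so excess
scatter of the per-variant Wald ratios is evidence of pleiotropy.  Three
complementary diagnostics are provided:

* :func:`cochran_q` — Cochran's Q against the IVW pooled estimate, with the
  I^2 fraction of beyond-chance variability; the study convention flags
  heterogeneity when I^2 > 50% AND p < 0.05.
* :func:`egger_intercept` — the MR-Egger intercept test for *directional*
  pleiotropy (re-exported from the estimators module).
* :func:`mr_presso` — the MR-PRESSO resampling test: compares the observed
  leave-one-out weighted residual sum of squares against its parametric
  null distribution (global test) and flags individual outlier variants by
  Bonferroni-corrected empirical p-values, then re-estimates IVW without
  them.  The distortion test of the published procedure is not implemented
  (see docs/methods.md).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import EggerIntercept, MREstimate, ivw_fixed, mr_egger, wald_ratios
from .exceptions import InsufficientInstrumentsError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HeterogeneityReport:
    q: float
    df: int
    p_q: float
    i2: float

    @property
    def significant(self) -> bool:
        """Study rule: heterogeneity when I^2 > 50% and Q-test p < 0.05."""
        return self.i2 > 0.5 and self.p_q < 0.05


def cochran_q(ratios: pd.DataFrame) -> HeterogeneityReport:
    """Cochran's Q over the Wald ratios against their IVW pooled value.

    Q = sum_j w_j (theta_j - theta_IVW)^2, chi-square with k-1 df under
    homogeneity; I^2 = max(0, (Q - df)/Q).

    Pass first-order-weight ratios for the exactly calibrated test:
    conditional on the exposure effects, Q is then chi-square under the
    null, whereas second-order weights involve the observed outcome effects
    and skew the null distribution.
    """
    if len(ratios) < 2:
        raise InsufficientInstrumentsError("cochran_q needs >= 2 instruments")
    w = ratios["weight"].to_numpy(dtype=float)
    th = ratios["theta"].to_numpy(dtype=float)
    theta_ivw = float(np.sum(w * th) / w.sum())
    q = float(np.sum(w * (th - theta_ivw) ** 2))
    df = len(th) - 1
    p_q = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return HeterogeneityReport(q, df, p_q, i2)


def egger_intercept(insts: pd.DataFrame, weight_order: str = "second") -> EggerIntercept:
    """MR-Egger intercept test for directional pleiotropy."""
    return mr_egger(insts, weight_order).intercept


# ---------------------------------------------------------------------------
# MR-PRESSO

@dataclass(frozen=True, eq=False)
class PressoResult:
    rss_obs: float
    p_global: float
    outlier_pvals: pd.Series  # indexed by variant_id
    outlier_ids: tuple
    theta_outlier_corrected: MREstimate | None
    n_sim: int
    seed: int | None


def _loo_slopes(bx: np.ndarray, by: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes of by on bx (weights v), vectorized over j.

    Accepts 1-D arrays (one dataset) or 2-D (n_sim, J) batches.
    """
    sxy = np.sum(v * bx * by, axis=-1, keepdims=True)
    sxx = np.sum(v * bx ** 2, axis=-1, keepdims=True)
    return (sxy - v * bx * by) / (sxx - v * bx ** 2)


def mr_presso(
    insts: pd.DataFrame,
    n_sim: int = 1000,
    seed: int | None = None,
    alpha_outlier: float = 0.05,
    weight_order: str = "first",
) -> PressoResult:
    """MR-PRESSO global pleiotropy test and outlier detection.

    For each instrument j the leave-one-out IVW slope theta_(-j) gives a
    residual r_j = beta_y_j - theta_(-j) beta_x_j, weighted by 1/se_y_j^2;
    RSS_obs = sum_j w_j r_j^2.  ``n_sim`` parametric datasets are simulated
    (beta_x* ~ N(beta_x, se_x^2); beta_y* ~ N(theta_(-j) beta_x_j, se_y^2))
    and the RSS recomputed identically, yielding the add-one empirical
    global p.  Per-instrument empirical p-values are Bonferroni-compared to
    ``alpha_outlier / k``; flagged variants are excluded and IVW re-estimated.

    Empirical p-values are bounded below by 1/(n_sim+1), so outlier flagging
    is impossible unless n_sim >= k/alpha_outlier; a warning is issued in
    that regime.

    ``weight_order`` controls the leave-one-out slope weights inside the
    resampling loop ("first", the default, uses 1/se_y^2 and is the cheap
    standard choice; "second" divides by se_y^2 + theta_j^2 se_x^2).
    """
    k = len(insts)
    if k < 4:
        raise InsufficientInstrumentsError(f"mr_presso needs >= 4 instruments, got {k}")
    if n_sim < 500:
        raise InsufficientInstrumentsError("n_sim must be >= 500")
    threshold = alpha_outlier / k
    if 1.0 / (n_sim + 1) >= threshold:
        logger.warning(
            "n_sim=%d cannot reach the Bonferroni threshold %.2g with %d "
            "instruments; no outlier can be flagged — increase n_sim above k/alpha",
            n_sim, threshold, k)

    bx = insts["beta_x"].to_numpy(dtype=float)
    sx = insts["se_x"].to_numpy(dtype=float)
    by = insts["beta_y"].to_numpy(dtype=float)
    sy = insts["se_y"].to_numpy(dtype=float)
    w = 1.0 / sy ** 2

    def slope_weights(bx_, by_):
        if weight_order == "first":
            return np.broadcast_to(1.0 / sy ** 2, bx_.shape)
        return 1.0 / (sy ** 2 + (by_ / bx_) ** 2 * sx ** 2)

    loo = _loo_slopes(bx, by, slope_weights(bx, by))
    resid = by - loo * bx
    contrib = w * resid ** 2
    rss_obs = float(contrib.sum())

    rng = np.random.default_rng(seed)
    bx_s = rng.normal(bx, sx, size=(n_sim, k))
    by_s = rng.normal(loo * bx, sy, size=(n_sim, k))
    loo_s = _loo_slopes(bx_s, by_s, slope_weights(bx_s, by_s))
    contrib_s = w * (by_s - loo_s * bx_s) ** 2
    rss_s = contrib_s.sum(axis=1)

    p_global = float((1 + np.sum(rss_s >= rss_obs)) / (n_sim + 1))
    p_out = (1 + np.sum(contrib_s >= contrib, axis=0)) / (n_sim + 1)
    outlier_pvals = pd.Series(p_out, index=insts["variant_id"].to_numpy())
    outlier_ids = tuple(outlier_pvals.index[p_out < threshold])

    theta_corrected = None
    if outlier_ids:
        keep = ~insts["variant_id"].isin(outlier_ids)
        if keep.sum() >= 2:
            theta_corrected = ivw_fixed(wald_ratios(insts.loc[keep], "second"))
    return PressoResult(rss_obs, p_global, outlier_pvals, outlier_ids,
                        theta_corrected, n_sim, seed)
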