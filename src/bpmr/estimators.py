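"""Causal-effect estimators for two-sample Mendelian randomization.

Given J harmonized instruments with variant-exposure effects beta_x (SE
se_x) and variant-outcome effects beta_y (SE se_y), each per copy of a
shared effect allele, the per-variant Wald ratio

    theta_j = beta_y_j / beta_x_j

estimates the causal effect of the exposure on the outcome.  Its
delta-method variance is used at first order, se_y^2 / beta_x^2, or at
second order (the default here),

    sigma2_j = se_y_j^2 / beta_x_j^2 + beta_y_j^2 * se_x_j^2 / beta_x_j^4,

which additionally propagates the sampling error of the exposure effect.

Estimators
----------
* :func:`ivw_fixed` — fixed-effects inverse-variance-weighted mean of the
  ratios; unbiased when all instruments are valid.
* :func:`ivw_correlated` — generalized weighted least squares through the
  origin with covariance Omega_ij = se_y_i * se_y_j * rho_ij, for
  drug-target proxy sets retained at lenient LD thresholds.
* :func:`mr_egger` — weighted regression of beta_y on beta_x with an
  intercept absorbing directional pleiotropy (InSIDE assumption).
* :func:`weighted_median` — consistent when >= 50% of the weight comes from
  valid instruments.
* :func:`weighted_mode` — consistent when a plurality of instruments is
  valid; kernel-density mode of the ratios.

Bootstrap SEs (median, mode) resample beta_x and beta_y from normal
distributions with their reported SEs, i.e. a parametric bootstrap of the
summary statistics themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats, linalg

from .exceptions import (
    ConfigurationError,
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    NumericalError,
)
from .instruments import LDMatrix

logger = logging.getLogger(__name__)

#: Normal 95% CI multiplier used throughout (the study's CI convention).
Z95 = 1.96

MODE_GRID_POINTS = 512


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate: theta per 1 exposure unit (e.g. log-OR per mm Hg)."""

    method: str
    theta: float
    se: float
    pval: float
    n_instruments: int
    weight_order: str = "second"
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "ci_low", self.theta - Z95 * self.se)
        object.__setattr__(self, "ci_high", self.theta + Z95 * self.se)


@dataclass(frozen=True)
class EggerIntercept:
    """MR-Egger intercept: average directional pleiotropy per instrument."""

    value: float
    se: float
    pval: float


@dataclass(frozen=True)
class EggerResult:
    slope: MREstimate
    intercept: EggerIntercept


def _normal_p(theta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(theta) / se))


# ---------------------------------------------------------------------------
# Wald ratios

def wald_ratios(insts: pd.DataFrame, weight_order: str = "second") -> pd.DataFrame:
    """Per-variant Wald ratios with delta-method variances.

    Returns a DataFrame with columns ``variant_id, theta, sigma2, weight``
    plus the underlying ``beta_x, se_x, beta_y, se_y`` (needed by the
    parametric bootstrap of the median/mode estimators).
    """
    if weight_order not in ("first", "second"):
        raise ConfigurationError(f"unknown weight_order {weight_order!r}")
    bx = insts["beta_x"].to_numpy(dtype=float)
    if np.any(bx == 0):
        bad = insts.loc[insts["beta_x"] == 0, "variant_id"].tolist()
        raise DegenerateInstrumentError(f"zero exposure effect for {bad}")
    sx = insts["se_x"].to_numpy(dtype=float)
    by = insts["beta_y"].to_numpy(dtype=float)
    sy = insts["se_y"].to_numpy(dtype=float)
    theta = by / bx
    sigma2 = _ratio_sigma2(bx, sx, by, sy, weight_order)
    return pd.DataFrame({
        "variant_id": insts["variant_id"].to_numpy(),
        "theta": theta,
        "sigma2": sigma2,
        "weight": 1.0 / sigma2,
        "beta_x": bx, "se_x": sx, "beta_y": by, "se_y": sy,
    })


def _ratio_sigma2(bx, sx, by, sy, weight_order: str):
    sigma2 = sy ** 2 / bx ** 2
    if weight_order == "second":
        sigma2 = sigma2 + by ** 2 * sx ** 2 / bx ** 4
    return sigma2


def wald_ratio(inst, weight_order: str = "second") -> pd.Series:
    """Single-instrument Wald ratio (a one-row convenience over :func:`wald_ratios`)."""
    df = pd.DataFrame([dict(inst)]) if not isinstance(inst, pd.DataFrame) else inst
    return wald_ratios(df, weight_order).iloc[0]


def wald_estimate(inst, weight_order: str = "second") -> MREstimate:
    """Wald ratio packaged as an MREstimate (single-instrument classes)."""
    r = wald_ratio(inst, weight_order)
    se = float(np.sqrt(r["sigma2"]))
    return MREstimate("wald", float(r["theta"]), se, _normal_p(r["theta"], se),
                      1, weight_order)


# ---------------------------------------------------------------------------
# IVW

def _require(ratios: pd.DataFrame, k_min: int, method: str) -> None:
    if len(ratios) < k_min:
        raise InsufficientInstrumentsError(
            f"{method} needs >= {k_min} instruments, got {len(ratios)}")


def ivw_fixed(ratios: pd.DataFrame, random_effects: bool = False) -> MREstimate:
    """Fixed-effects inverse-variance-weighted pooling of Wald ratios.

    ``random_effects=True`` applies the multiplicative heterogeneity
    correction, inflating the SE by max(1, sqrt(Q/(k-1))); off by default,
    matching the fixed-effects primary analysis.
    """
    _require(ratios, 2, "ivw_fixed")
    w = ratios["weight"].to_numpy(dtype=float)
    th = ratios["theta"].to_numpy(dtype=float)
    sw = w.sum()
    theta = float(np.sum(w * th) / sw)
    se = float(sw ** -0.5)
    meta = {}
    if random_effects:
        q = float(np.sum(w * (th - theta) ** 2))
        infl = max(1.0, np.sqrt(q / (len(th) - 1)))
        se *= infl
        meta["re_inflation"] = infl
    wo = _infer_weight_order(ratios)
    return MREstimate("ivw_fixed", theta, se, _normal_p(theta, se), len(th), wo,
                      metadata=meta)


def _infer_weight_order(ratios: pd.DataFrame) -> str:
    # ratios built by wald_ratios: first-order iff sigma2 == se_y^2/beta_x^2
    first = np.allclose(ratios["sigma2"],
                        ratios["se_y"] ** 2 / ratios["beta_x"] ** 2, rtol=1e-12)
    return "first" if first else "second"


def ivw_correlated(
    insts: pd.DataFrame,
    ld: LDMatrix,
    cond_bound: float = 1e8,
    ridge_eps: float = 1e-6,
) -> MREstimate:
    """IVW generalized for correlated instruments (GLS through the origin).

    The outcome-effect covariance is modelled as
    Omega_ij = se_y_i * se_y_j * rho_ij; the estimate is

        theta = (bx' Omega^-1 bx)^-1 bx' Omega^-1 by,
        se    = sqrt((bx' Omega^-1 bx)^-1).

    With identity LD this reduces exactly to first-order-weight fixed-effects
    IVW.  When Omega's condition number exceeds ``cond_bound`` a ridge term
    ``ridge_eps * diag(Omega)`` is added (with a warning) — a hint that the
    proxy set should be pruned at a stricter r^2.
    """
    _require(insts, 2, "ivw_correlated")
    sub = ld.subset(list(insts["variant_id"]))
    sy = insts["se_y"].to_numpy(dtype=float)
    bx = insts["beta_x"].to_numpy(dtype=float)
    by = insts["beta_y"].to_numpy(dtype=float)
    omega = np.outer(sy, sy) * sub.rho
    if np.linalg.cond(omega) > cond_bound:
        logger.warning(
            "ill-conditioned instrument covariance (cond > %g); applying ridge "
            "jitter eps=%g — consider pruning at a stricter r2", cond_bound, ridge_eps)
        omega = omega + ridge_eps * np.diag(np.diag(omega))
    try:
        cho = linalg.cho_factor(omega)
    except linalg.LinAlgError as exc:
        raise NumericalError(
            "instrument covariance not positive definite even after ridge "
            "jitter; prune proxies at a stricter r2 threshold") from exc
    oi_bx = linalg.cho_solve(cho, bx)
    denom = float(bx @ oi_bx)
    theta = float(oi_bx @ by) / denom
    se = denom ** -0.5
    return MREstimate("ivw_correlated", theta, se, _normal_p(theta, se),
                      len(insts), "first")


# ---------------------------------------------------------------------------
# MR-Egger

def mr_egger(insts: pd.DataFrame, weight_order: str = "second") -> EggerResult:
    """MR-Egger regression: beta_y = alpha + theta * beta_x, weighted.

    Instruments are first oriented so beta_x >= 0 (the intercept is only
    identified on a fixed orientation).  Regression weights are the ratio
    weights mapped to the outcome scale, 1/(sigma2_j * beta_x_j^2): se_y^-2
    at first order, (se_y^2 + theta_j^2 se_x^2)^-1 at second order.  SEs use
    the fit's multiplicative dispersion (random-effects Egger).  A non-zero
    intercept alpha indicates directional pleiotropy.
    """
    _require(insts, 3, "mr_egger")
    ratios = wald_ratios(insts, weight_order)
    sgn = np.sign(ratios["beta_x"].to_numpy())
    bx = ratios["beta_x"].to_numpy() * sgn
    by = ratios["beta_y"].to_numpy() * sgn
    w = 1.0 / (ratios["sigma2"].to_numpy() * bx ** 2)
    fit = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
    alpha, theta = (float(v) for v in fit.params)
    se_alpha, se_theta = (float(v) for v in fit.bse)
    slope = MREstimate("egger_slope", theta, se_theta, _normal_p(theta, se_theta),
                       len(insts), weight_order)
    intercept = EggerIntercept(alpha, se_alpha, _normal_p(alpha, se_alpha))
    return EggerResult(slope, intercept)


# ---------------------------------------------------------------------------
# weighted median

def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta, kind="mergesort")
    th, wt = theta[order], w[order]
    cum = np.cumsum(wt)
    p = (cum - 0.5 * wt) / cum[-1]
    return float(np.interp(0.5, p, th))


def _bootstrap_draws(ratios: pd.DataFrame, n_boot: int, rng,
                     center: str, theta_hat: float) -> tuple[np.ndarray, np.ndarray]:
    """Parametric bootstrap of the summary statistics.

    ``center="fitted"`` draws outcome effects around the fitted causal model
    theta_hat * beta_x (the default): the bootstrap dispersion of the ratios
    then matches their sampling dispersion and the resulting SE is
    calibrated.  ``center="observed"`` draws around the observed beta_y (the
    convention of the published weighted-median code); it folds the observed
    ratio scatter into the resampling a second time and is mildly
    conservative.
    """
    if center not in ("fitted", "observed"):
        raise ConfigurationError(f"unknown bootstrap center {center!r}")
    bx_obs = ratios["beta_x"].to_numpy()
    by_center = theta_hat * bx_obs if center == "fitted" else ratios["beta_y"].to_numpy()
    bx = rng.normal(bx_obs, ratios["se_x"].to_numpy(), size=(n_boot, len(ratios)))
    by = rng.normal(by_center, ratios["se_y"].to_numpy(), size=(n_boot, len(ratios)))
    return bx, by


def weighted_median(
    ratios: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
    boot_center: str = "fitted",
) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    The point estimate interpolates the inverse-variance-weighted empirical
    quantile function of the ratios at probability 0.5; it is consistent as
    long as at least half the weight comes from valid instruments.  SEs come
    from the parametric bootstrap (see :func:`_bootstrap_draws` for the two
    centering conventions).
    """
    _require(ratios, 2, "weighted_median")
    if n_boot < 100:
        raise ConfigurationError("n_boot must be >= 100")
    wo = _infer_weight_order(ratios)
    theta = _weighted_median_point(ratios["theta"].to_numpy(),
                                   ratios["weight"].to_numpy())
    rng = np.random.default_rng(seed)
    bx, by = _bootstrap_draws(ratios, n_boot, rng, boot_center, theta)
    sx = ratios["se_x"].to_numpy()
    sy = ratios["se_y"].to_numpy()
    th_b = by / bx
    w_b = 1.0 / _ratio_sigma2(bx, sx, by, sy, wo)
    ests = np.array([_weighted_median_point(th_b[i], w_b[i]) for i in range(n_boot)])
    se = float(ests.std(ddof=1))
    return MREstimate("weighted_median", theta, se, _normal_p(theta, se),
                      len(ratios), wo, metadata={"n_boot": n_boot, "seed": seed})


# ---------------------------------------------------------------------------
# weighted mode

def _mode_bandwidth(theta: np.ndarray, phi: float) -> float:
    sd = theta.std(ddof=1)
    mad = np.median(np.abs(theta - np.median(theta))) * 1.4826
    return float(phi * 0.9 * min(sd, mad) * len(theta) ** (-1 / 5))


def _weighted_mode_point(theta: np.ndarray, w: np.ndarray, phi: float) -> float:
    h = _mode_bandwidth(theta, phi)
    if h == 0.0 or not np.isfinite(h):
        return float(theta[0])  # all ratios identical
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, MODE_GRID_POINTS)
    dens = np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / h) ** 2) @ w
    return float(grid[int(np.argmax(dens))])


def _weighted_mode_batch(th_b: np.ndarray, w_b: np.ndarray, phi: float) -> np.ndarray:
    """Vectorized mode over bootstrap rows (one bandwidth and grid per row)."""
    n_boot, j = th_b.shape
    sd = th_b.std(axis=1, ddof=1)
    med = np.median(th_b, axis=1, keepdims=True)
    mad = np.median(np.abs(th_b - med), axis=1) * 1.4826
    h = phi * 0.9 * np.minimum(sd, mad) * j ** (-1 / 5)
    out = np.empty(n_boot)
    degenerate = (h == 0) | ~np.isfinite(h)
    out[degenerate] = th_b[degenerate, 0]
    live = np.flatnonzero(~degenerate)
    step = 128  # chunk rows to bound the (rows, grid, J) workspace
    u = np.linspace(0.0, 1.0, MODE_GRID_POINTS)
    for start in range(0, len(live), step):
        idx = live[start:start + step]
        lo = th_b[idx].min(axis=1) - 3 * h[idx]
        hi = th_b[idx].max(axis=1) + 3 * h[idx]
        grid = lo[:, None] + (hi - lo)[:, None] * u[None, :]
        z = (grid[:, :, None] - th_b[idx][:, None, :]) / h[idx][:, None, None]
        dens = np.einsum("bgj,bj->bg", np.exp(-0.5 * z ** 2), w_b[idx])
        out[idx] = grid[np.arange(len(idx)), np.argmax(dens, axis=1)]
    return out


def weighted_mode(
    ratios: pd.DataFrame,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
    boot_center: str = "fitted",
) -> MREstimate:
    """Mode-based estimator: argmax of a weighted normal-kernel density of the ratios.

    Bandwidth h = phi * 0.9 * min(sd, 1.4826*MAD) * J^(-1/5), density evaluated
    on a 512-point grid spanning [min-3h, max+3h].  Consistent when a
    plurality of instruments is valid.  SE by parametric bootstrap.
    """
    _require(ratios, 2, "weighted_mode")
    if phi <= 0:
        raise ConfigurationError("phi must be positive")
    if n_boot < 100:
        raise ConfigurationError("n_boot must be >= 100")
    wo = _infer_weight_order(ratios)
    theta = _weighted_mode_point(ratios["theta"].to_numpy(),
                                 ratios["weight"].to_numpy(), phi)
    rng = np.random.default_rng(seed)
    bx, by = _bootstrap_draws(ratios, n_boot, rng, boot_center, theta)
    th_b = by / bx
    w_b = 1.0 / _ratio_sigma2(bx, ratios["se_x"].to_numpy(), by,
                              ratios["se_y"].to_numpy(), wo)
    ests = _weighted_mode_batch(th_b, w_b, phi)
    se = float(ests.std(ddof=1))
    return MREstimate("weighted_mode", theta, se, _normal_p(theta, se),
                      len(ratios), wo,
                      metadata={"n_boot": n_boot, "seed": seed, "phi": phi})


# ---------------------------------------------------------------------------
# serialization

ESTIMATE_COLUMNS = ["method", "theta", "se", "ci_low", "ci_high", "pval",
                    "n_instruments", "weight_order", "seed", "n_boot"]


def estimates_frame(estimates) -> pd.DataFrame:
    """Serialize MREstimates as one TSV-ready row each."""
    rows = []
    for est in estimates:
        rows.append({
            "method": est.method, "theta": est.theta, "se": est.se,
            "ci_low": est.ci_low, "ci_high": est.ci_high, "pval": est.pval,
            "n_instruments": est.n_instruments, "weight_order": est.weight_order,
            "seed": est.metadata.get("seed"), "n_boot": est.metadata.get("n_boot"),
        })
    return pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)
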