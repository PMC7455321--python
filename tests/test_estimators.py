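"""Estimator correctness against independent oracles and invariants."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from bpmr.estimators import (
    ivw_correlated, ivw_fixed, mr_egger, wald_estimate, wald_ratio, wald_ratios,
    weighted_median, weighted_mode,
)
from bpmr.exceptions import (
    ConfigurationError, DegenerateInstrumentError, InsufficientInstrumentsError,
)
from bpmr.instruments import LDMatrix
from conftest import ar1_ld, make_instruments, random_instruments


class TestWaldRatio:
    def test_exact_exposure_collapses_weight_orders(self):
        inst = dict(variant_id="rs1", beta_x=1.0, se_x=0.0, beta_y=0.5, se_y=0.1)
        for order in ("first", "second"):
            r = wald_ratio(inst, order)
            assert r["theta"] == pytest.approx(0.5)
            assert r["sigma2"] == pytest.approx(0.01)

    def test_second_order_variance_arithmetic(self):
        inst = dict(variant_id="rs1", beta_x=0.5, se_x=0.05, beta_y=0.2, se_y=0.1)
        r = wald_ratio(inst, "second")
        assert r["sigma2"] == pytest.approx(0.01 / 0.25 + 0.04 * 0.0025 / 0.0625)
        assert r["sigma2"] == pytest.approx(0.0416)

    def test_second_order_variance_matches_monte_carlo(self, rng):
        """Delta-method variance vs the empirical variance of simulated ratios."""
        bx, sx, by, sy = 0.5, 0.05, 0.2, 0.1
        draws_x = rng.normal(bx, sx, 1_000_000)
        draws_y = rng.normal(by, sy, 1_000_000)
        mc_var = np.var(draws_y / draws_x)
        r = wald_ratio(dict(variant_id="rs1", beta_x=bx, se_x=sx,
                            beta_y=by, se_y=sy), "second")
        # second-order delta truncates the expansion: a few % at these SEs
        assert r["sigma2"] == pytest.approx(mc_var, rel=0.05)

    def test_sign_symmetry(self):
        a = wald_ratio(dict(variant_id="r", beta_x=0.5, se_x=0.05,
                            beta_y=0.2, se_y=0.1))
        b = wald_ratio(dict(variant_id="r", beta_x=-0.5, se_x=0.05,
                            beta_y=0.2, se_y=0.1))
        assert b["theta"] == pytest.approx(-a["theta"])
        assert b["sigma2"] == pytest.approx(a["sigma2"])

    def test_zero_exposure_effect_is_degenerate(self):
        with pytest.raises(DegenerateInstrumentError, match="rs1"):
            wald_ratio(dict(variant_id="rs1", beta_x=0.0, se_x=0.1,
                            beta_y=0.2, se_y=0.1))

    def test_wald_estimate_ci_convention(self):
        est = wald_estimate(dict(variant_id="rs1", beta_x=1.0, se_x=0.0,
                                 beta_y=0.5, se_y=0.1))
        assert est.ci_low == pytest.approx(0.5 - 1.96 * 0.1)
        assert est.ci_high == pytest.approx(0.5 + 1.96 * 0.1)
        assert est.n_instruments == 1


class TestIVWFixed:
    def test_two_identical_ratios(self):
        insts = make_instruments([1.0, 1.0], [0.0, 0.0], [0.3, 0.3], [0.1, 0.1])
        est = ivw_fixed(wald_ratios(insts))
        assert est.theta == pytest.approx(0.3)
        assert est.se == pytest.approx(np.sqrt(1 / 200))

    def test_equal_weights_give_arithmetic_mean(self):
        insts = make_instruments([1, 1, 1], [0, 0, 0], [0.1, 0.2, 0.6], [0.1] * 3)
        est = ivw_fixed(wald_ratios(insts))
        assert est.theta == pytest.approx(0.3)

    def test_matches_weighted_least_squares_oracle(self, rng):
        """IVW equals WLS of beta_y on beta_x through the origin with weights
        1/(sigma2_j * beta_x^2), fit independently by statsmodels."""
        insts = random_instruments(rng)
        ratios = wald_ratios(insts, "second")
        est = ivw_fixed(ratios)
        w = 1.0 / (ratios["sigma2"] * ratios["beta_x"] ** 2)
        fit = sm.WLS(ratios["beta_y"], ratios["beta_x"], weights=w).fit()
        assert est.theta == pytest.approx(float(fit.params.iloc[0]), rel=1e-10)

    def test_insufficient_instruments(self):
        insts = make_instruments([1.0], [0.1], [0.3], [0.1])
        with pytest.raises(InsufficientInstrumentsError):
            ivw_fixed(wald_ratios(insts))

    def test_random_effects_inflation_never_shrinks_se(self, rng):
        ratios = wald_ratios(random_instruments(rng))
        fe = ivw_fixed(ratios)
        re = ivw_fixed(ratios, random_effects=True)
        assert re.se >= fe.se
        assert re.theta == pytest.approx(fe.theta)


def gls_oracle(bx, by, omega):
    """Independent GLS through the origin by explicit matrix inversion."""
    oi = np.linalg.inv(omega)
    denom = bx @ oi @ bx
    return (bx @ oi @ by) / denom, np.sqrt(1.0 / denom)


class TestIVWCorrelated:
    def test_identity_ld_equals_first_order_ivw(self, rng):
        insts = random_instruments(rng, j=30)
        ld = LDMatrix(list(insts["variant_id"]), np.eye(30))
        gls = ivw_correlated(insts, ld)
        ivw = ivw_fixed(wald_ratios(insts, "first"))
        assert gls.theta == pytest.approx(ivw.theta, rel=1e-10)
        assert gls.se == pytest.approx(ivw.se, rel=1e-10)

    def test_correlation_inflates_se(self):
        insts = make_instruments([0.5, 0.5], [0.02, 0.02], [0.1, 0.1], [0.05, 0.05])
        ids = list(insts["variant_id"])
        se_indep = ivw_correlated(insts, LDMatrix(ids, np.eye(2))).se
        se_corr = ivw_correlated(
            insts, LDMatrix(ids, [[1.0, 0.9], [0.9, 1.0]])).se
        assert se_corr > se_indep

    def test_matches_explicit_gls_oracle(self, rng):
        insts = random_instruments(rng, j=30)
        ld = ar1_ld(list(insts["variant_id"]), 0.6)
        est = ivw_correlated(insts, ld)
        sy = insts["se_y"].to_numpy()
        theta, se = gls_oracle(insts["beta_x"].to_numpy(),
                               insts["beta_y"].to_numpy(),
                               np.outer(sy, sy) * ld.rho)
        assert est.theta == pytest.approx(theta, rel=1e-10)
        assert est.se == pytest.approx(se, rel=1e-10)

    def test_near_singular_ld_triggers_ridge_warning(self, rng, caplog):
        insts = random_instruments(rng, j=3)
        ids = list(insts["variant_id"])
        rho = np.full((3, 3), 1.0 - 1e-12)
        np.fill_diagonal(rho, 1.0)
        est = ivw_correlated(insts, LDMatrix(ids, rho), cond_bound=1e6)
        assert np.isfinite(est.theta) and est.se > 0
        assert any("ridge" in r.message for r in caplog.records)


class TestMREgger:
    def test_noise_free_line_recovered_exactly(self):
        bx = np.array([0.2, 0.4, 0.6, 0.9])
        by = 0.1 + 0.3 * bx
        insts = make_instruments(bx, [0.02] * 4, by, [0.05] * 4)
        res = mr_egger(insts)
        assert res.intercept.value == pytest.approx(0.1, abs=1e-12)
        assert res.slope.theta == pytest.approx(0.3, abs=1e-12)

    def test_orientation_invariance(self, rng):
        insts = random_instruments(rng, j=20)
        res = mr_egger(insts)
        flipped = insts.copy()
        flip = rng.choice([1.0, -1.0], size=20)
        flipped["beta_x"] *= flip
        flipped["beta_y"] *= flip
        res_f = mr_egger(flipped)
        assert res_f.slope.theta == pytest.approx(res.slope.theta, rel=1e-10)
        assert res_f.intercept.value == pytest.approx(res.intercept.value, rel=1e-10)

    def test_minimum_three_instruments(self):
        insts = make_instruments([0.2, 0.4], [0.02] * 2, [0.1, 0.2], [0.05] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(insts)


class TestWeightedMedian:
    def test_identical_ratios_return_common_value(self):
        insts = make_instruments([1, 1, 1], [0.01] * 3, [0.2, 0.2, 0.2], [0.1] * 3)
        est = weighted_median(wald_ratios(insts), n_boot=100, seed=1)
        assert est.theta == pytest.approx(0.2)

    def test_robust_to_single_outlier(self):
        insts = make_instruments([1, 1, 1], [0.0] * 3, [1.0, 2.0, 100.0], [1.0] * 3)
        est = weighted_median(wald_ratios(insts), n_boot=100, seed=1)
        assert est.theta == pytest.approx(2.0)

    def test_seeded_bootstrap_is_deterministic(self, rng):
        ratios = wald_ratios(random_instruments(rng))
        a = weighted_median(ratios, n_boot=200, seed=7)
        b = weighted_median(ratios, n_boot=200, seed=7)
        assert a.se == b.se and a.theta == b.theta

    def test_small_bootstrap_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            weighted_median(wald_ratios(random_instruments(rng)), n_boot=10)


class TestWeightedMode:
    def test_degenerate_bandwidth_returns_common_value(self):
        insts = make_instruments([1, 1], [0.01] * 2, [0.4, 0.4], [0.1] * 2)
        est = weighted_mode(wald_ratios(insts), n_boot=100, seed=1)
        assert est.theta == pytest.approx(0.4)
        assert est.se > 0

    def test_plurality_cluster_wins(self, rng):
        # 6 precise ratios near 0.2 carry more weight than 3 diffuse near 0.8
        bx = np.ones(9)
        by = np.array([0.2, 0.21, 0.19, 0.2, 0.22, 0.18, 0.8, 0.82, 0.78])
        sy = np.array([0.02] * 6 + [0.2] * 3)
        insts = make_instruments(bx, np.zeros(9), by, sy)
        est = weighted_mode(wald_ratios(insts), n_boot=100, seed=1)
        assert abs(est.theta - 0.2) < 0.05

    def test_batch_bootstrap_matches_pointwise(self, rng):
        """The vectorized bootstrap path equals the scalar mode estimator."""
        from bpmr.estimators import (_weighted_mode_batch, _weighted_mode_point)
        th = rng.normal(0.3, 0.1, size=(5, 40))
        w = rng.uniform(0.5, 2.0, size=(5, 40))
        batch = _weighted_mode_batch(th, w, 1.0)
        for i in range(5):
            assert batch[i] == pytest.approx(_weighted_mode_point(th[i], w[i], 1.0))

    def test_invalid_phi(self, rng):
        with pytest.raises(ConfigurationError):
            weighted_mode(wald_ratios(random_instruments(rng)), phi=0.0)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(scale=st.floats(0.1, 10.0), seed=st.integers(0, 10_000))
def test_estimators_equivariant_under_exposure_rescaling(scale, seed):
    """Multiplying beta_x, se_x by c divides theta and se by c (all estimators)."""
    rng = np.random.default_rng(seed)
    insts = random_instruments(rng, j=12)
    scaled = insts.copy()
    scaled["beta_x"] *= scale
    scaled["se_x"] *= scale
    ld = ar1_ld(list(insts["variant_id"]), 0.3)

    for est_fn in (
        lambda d: ivw_fixed(wald_ratios(d)),
        lambda d: ivw_correlated(d, ld),
        lambda d: mr_egger(d).slope,
        lambda d: weighted_median(wald_ratios(d), n_boot=100, seed=3),
        lambda d: weighted_mode(wald_ratios(d), n_boot=100, seed=3),
    ):
        base, resc = est_fn(insts), est_fn(scaled)
        assert resc.theta * scale == pytest.approx(base.theta, rel=1e-6, abs=1e-9)
        assert resc.se * scale == pytest.approx(base.se, rel=1e-5, abs=1e-9)
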