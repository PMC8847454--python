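"""MR estimators: exact reductions, independent oracles, invariances."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st
from sklearn.base import clone

from tsmr.estimators import (
    EggerEstimator,
    IVWEstimator,
    InvalidInstrumentError,
    MREstimate,
    SimpleMedianEstimator,
    WeightedMedianEstimator,
    egger_regression,
    estimate_all,
    ivw_fixed,
    ratio_table,
    simple_median,
    to_odds_scale,
    wald_ratio,
    weighted_median,
)
from conftest import make_instruments


def _inst(ratios, sy=None, gamma=None):
    """Instrument table with prescribed Wald ratios."""
    ratios = np.asarray(ratios, dtype=float)
    gamma = np.ones_like(ratios) if gamma is None else np.asarray(gamma, float)
    sy = np.ones_like(ratios) if sy is None else np.asarray(sy, float)
    return pd.DataFrame(
        {
            "snp": [f"rs{i}" for i in range(ratios.size)],
            "gamma_hat": gamma,
            "sigma_x": 1e-6,
            "Gamma_hat": ratios * gamma,
            "sigma_y": sy,
        }
    )


class TestWaldRatio:
    def test_exact_division(self):
        r = wald_ratio({"snp": "rs1", "gamma_hat": 0.1, "Gamma_hat": 0.2, "sigma_y": 0.05})
        assert r.beta_ratio == pytest.approx(2.0)
        assert r.se_ratio == pytest.approx(0.5)
        assert r.weight == pytest.approx(4.0)

    def test_zero_numerator(self):
        r = wald_ratio({"snp": "rs1", "gamma_hat": 0.5, "Gamma_hat": 0.0, "sigma_y": 0.1})
        assert r.beta_ratio == 0.0 and r.se_ratio == pytest.approx(0.2)

    def test_zero_gamma_signalled_distinctly(self):
        with pytest.raises(InvalidInstrumentError):
            wald_ratio({"snp": "rs1", "gamma_hat": 0.0, "Gamma_hat": 0.1, "sigma_y": 0.1})

    def test_ratio_table_or_scale(self, instruments):
        tab = ratio_table(instruments)
        assert len(tab) == len(instruments)
        np.testing.assert_allclose(tab["or"], np.exp(tab["beta_ratio"]))
        assert (tab["or_ci_low"] < tab["or"]).all()
        assert (tab["or"] < tab["or_ci_high"]).all()


class TestIVW:
    def test_single_instrument_reduces_to_wald(self):
        inst = _inst([2.0], sy=[0.5], gamma=[0.4])
        est = ivw_fixed(inst)
        r = wald_ratio(inst.iloc[0])
        assert est.beta == pytest.approx(r.beta_ratio)
        assert est.se == pytest.approx(r.se_ratio)

    def test_equal_weight_mean(self):
        assert ivw_fixed(_inst([1.0, 3.0])).beta == pytest.approx(2.0)

    def test_matches_wls_through_origin(self, rng):
        """IVW equals weighted least squares of Gamma on gamma through the
        origin with weights sigma_y^-2 (statsmodels oracle)."""
        for _ in range(10):
            t = make_instruments(rng, j=10)
            fit = sm.WLS(
                t["Gamma_hat"], t["gamma_hat"], weights=1.0 / t["sigma_y"] ** 2
            ).fit()
            est = ivw_fixed(t)
            assert est.beta == pytest.approx(fit.params.iloc[0], abs=1e-10)

    def test_random_effects_never_shrinks_se(self, instruments):
        fe = ivw_fixed(instruments)
        re = ivw_fixed(instruments, random_effects=True)
        assert re.beta == fe.beta and re.se >= fe.se

    def test_empty_set_errors(self):
        with pytest.raises(Exception):
            ivw_fixed(_inst([]))


class TestMedians:
    def test_odd_count_median(self):
        est = simple_median(_inst([-1.0, 0.0, 5.0]), n_boot=10, seed=0)
        assert est.beta == 0.0

    def test_even_count_midpoint(self):
        est = simple_median(_inst([1.0, 3.0, 0.0, 2.0]), n_boot=10, seed=0)
        assert est.beta == pytest.approx(1.5)

    def test_fewer_than_three_instruments_error(self):
        with pytest.raises(InvalidInstrumentError, match="3 instruments"):
            simple_median(_inst([1.0, 3.0]), n_boot=10, seed=0)

    def test_equal_weights_weighted_equals_simple(self):
        inst = _inst([0.3, -1.2, 2.0, 0.7, 0.1])
        wm = weighted_median(inst, n_boot=10, seed=0)
        sm_ = simple_median(inst, n_boot=10, seed=0)
        assert wm.beta == pytest.approx(sm_.beta)

    def test_weighted_median_exact_midpoint_hit(self):
        # weights 0.25 / 0.5 / 0.25 -> cumulative midpoints 0.125, 0.5, 0.875
        inst = _inst([1.0, 2.0, 10.0], sy=[2.0, np.sqrt(2.0), 2.0])
        assert weighted_median(inst, n_boot=10, seed=0).beta == pytest.approx(2.0)

    def test_weighted_median_grid_oracle(self, rng):
        """Interpolated weighted median agrees with a brute-force scan for
        the weighted 50th percentile over a fine candidate grid."""
        for _ in range(10):
            t = make_instruments(rng, j=15)
            ratios = (t["Gamma_hat"] / t["gamma_hat"]).to_numpy()
            w = (t["gamma_hat"] / t["sigma_y"]).to_numpy() ** 2
            w = w / w.sum()
            grid = np.linspace(ratios.min(), ratios.max(), 300_001)
            below = (ratios[None, :] <= grid[:, None]) @ w
            candidate = grid[np.searchsorted(below, 0.5)]
            est = weighted_median(t, n_boot=10, seed=0)
            # the step-function scan brackets the interpolated estimator
            # within one gap between adjacent order statistics
            gap = np.max(np.diff(np.sort(ratios)))
            assert abs(est.beta - candidate) <= gap + 1e-12

    def test_bootstrap_se_reproducible_and_convergent(self, rng):
        t = make_instruments(rng, j=20)
        a = simple_median(t, n_boot=5000, seed=42)
        b = simple_median(t, n_boot=5000, seed=42)
        assert a.se == b.se  # deterministic given seed
        big = simple_median(t, n_boot=100_000, seed=7)
        assert a.se == pytest.approx(big.se, rel=0.05)

    def test_weighted_median_breakdown(self):
        """Corrupting one instrument carrying < 50% of the weight toward
        +/- infinity, away from the median, does not move the estimate."""
        inst = _inst([1.0, 2.0, 3.0, 4.0, 5.0])
        base = weighted_median(inst, n_boot=10, seed=0).beta
        hi = inst.copy()
        hi.loc[4, "Gamma_hat"] = 1e9  # ratio -> 1e9
        lo = inst.copy()
        lo.loc[0, "Gamma_hat"] = -1e9
        assert weighted_median(hi, n_boot=10, seed=0).beta == pytest.approx(base)
        assert weighted_median(lo, n_boot=10, seed=0).beta == pytest.approx(base)


class TestEgger:
    def test_exact_linear_data(self):
        g = np.array([0.02, 0.05, 0.08, 0.11])
        inst = _inst(np.full(4, 0.5), gamma=g, sy=np.full(4, 0.01))
        est = egger_regression(inst)
        assert est.slope.beta == pytest.approx(0.5, abs=1e-12)
        assert est.intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_lands_in_intercept(self):
        g = np.array([0.02, 0.05, 0.08, 0.11])
        inst = _inst(np.zeros(4), gamma=g)
        inst["Gamma_hat"] = 0.5 * g + 0.1
        est = egger_regression(inst)
        assert est.slope.beta == pytest.approx(0.5, abs=1e-12)
        assert est.intercept == pytest.approx(0.1, abs=1e-12)

    def test_matches_statsmodels_wls(self, rng):
        for _ in range(10):
            t = make_instruments(rng, j=12)
            X = sm.add_constant(t["gamma_hat"].to_numpy())
            fit = sm.WLS(t["Gamma_hat"], X, weights=1.0 / t["sigma_y"] ** 2).fit()
            est = egger_regression(t)
            params = np.asarray(fit.params)
            assert est.intercept == pytest.approx(params[0], abs=1e-10)
            assert est.slope.beta == pytest.approx(params[1], abs=1e-10)

    def test_zero_gamma_variance_unidentifiable(self):
        inst = _inst([1.0, 1.0, 1.0], gamma=[0.1, 0.1, 0.1])
        with pytest.raises(InvalidInstrumentError, match="unidentifiable"):
            egger_regression(inst)

    def test_i2_gx_precision_regimes(self, rng):
        t = make_instruments(rng, j=30)
        precise = t.copy()
        precise["sigma_x"] = 1e-6
        noisy = t.copy()
        noisy["sigma_x"] = t["gamma_hat"].std()  # SE on the scale of the spread
        assert egger_regression(precise).i2_gx > 0.999
        assert egger_regression(noisy).i2_gx < 0.9
        assert egger_regression(noisy).i2_gx <= 1.0

    def test_intercept_converges_to_mean_pleiotropy(self):
        """With exact exposure effects (sigma_x -> 0) and InSIDE holding,
        the Egger intercept estimates the mean direct effect."""
        rng = np.random.default_rng(4)
        g = rng.uniform(0.03, 0.15, size=2000)
        alpha = rng.normal(0.05, 0.01, size=2000)  # directional, indep of g
        sy = np.full(2000, 1e-4)
        inst = _inst(np.zeros(2000), gamma=g, sy=sy)
        inst["Gamma_hat"] = 0.3 * g + alpha + rng.normal(0, sy)
        est = egger_regression(inst)
        assert est.intercept == pytest.approx(0.05, abs=0.005)
        assert est.slope.beta == pytest.approx(0.3, abs=0.05)


class TestOddsScale:
    def test_null_maps_to_or_one(self):
        est = MREstimate("IVW", 0.0, 1.0, 5)
        assert to_odds_scale(est).odds_ratio == 1.0

    def test_hand_computed_interval(self):
        est = MREstimate("IVW", -0.0408, 0.020, 139)
        assert est.odds_ratio == pytest.approx(0.960, abs=5e-4)
        assert est.or_ci_low == pytest.approx(math.exp(-0.0408 - 1.96 * 0.02), rel=1e-12)
        assert est.or_ci_high == pytest.approx(math.exp(-0.0408 + 1.96 * 0.02), rel=1e-12)

    def test_log_round_trip(self):
        est = MREstimate("IVW", -0.3, 0.1, 3)
        assert math.log(est.odds_ratio) == pytest.approx(est.beta, rel=1e-15)


class TestSklearnSurface:
    def test_get_set_params_and_clone(self):
        est = WeightedMedianEstimator(n_boot=500, random_state=3)
        assert est.get_params() == {"n_boot": 500, "random_state": 3}
        twin = clone(est).set_params(n_boot=100)
        assert twin.n_boot == 100 and twin.random_state == 3

    def test_fit_predict_shapes(self, instruments):
        g = instruments["gamma_hat"].to_numpy().reshape(-1, 1)
        est = IVWEstimator().fit(
            g,
            instruments["Gamma_hat"],
            y_se=instruments["sigma_y"],
        )
        pred = est.predict(g)
        assert pred.shape == (len(instruments),)
        np.testing.assert_allclose(pred, est.effect_ * g[:, 0])
        assert est.ci_[0] < est.effect_ < est.ci_[1]

    def test_egger_predict_includes_intercept(self, instruments):
        est = EggerEstimator().fit(
            instruments["gamma_hat"],
            instruments["Gamma_hat"],
            x_se=instruments["sigma_x"],
            y_se=instruments["sigma_y"],
        )
        np.testing.assert_allclose(
            est.predict([0.0]), [est.intercept_], atol=1e-15
        )

    def test_missing_y_se_rejected(self, instruments):
        with pytest.raises(ValueError, match="y_se"):
            IVWEstimator().fit(instruments["gamma_hat"], instruments["Gamma_hat"])


class TestInvariances:
    @given(st.integers(min_value=0, max_value=10_000))
    def test_reordering_invariance(self, seed):
        rng = np.random.default_rng(seed)
        t = make_instruments(rng, j=8)
        perm = t.sample(frac=1.0, random_state=seed).reset_index(drop=True)
        assert ivw_fixed(perm).beta == pytest.approx(ivw_fixed(t).beta, rel=1e-12)
        assert egger_regression(perm).slope.beta == pytest.approx(
            egger_regression(t).slope.beta, rel=1e-12
        )
        assert weighted_median(perm, n_boot=10, seed=0).beta == pytest.approx(
            weighted_median(t, n_boot=10, seed=0).beta, rel=1e-12
        )

    def test_estimate_all_rows_complete(self, instruments):
        res = estimate_all(instruments, n_boot=50, seed=1)
        assert set(res["method"]) == {"ivw", "simple_median", "weighted_median", "egger"}
        egger_row = res.set_index("method").loc["egger"]
        assert np.isfinite(egger_row["egger_intercept"])
        assert np.isfinite(egger_row["i2_gx"])

    def test_estimate_all_records_failures_explicitly(self):
        res = estimate_all(_inst([1.0]), n_boot=10, seed=1)
        med = res.set_index("method").loc["simple_median"]
        assert isinstance(med["error"], str) and "3 instruments" in med["error"]
        assert np.isfinite(res.set_index("method").loc["ivw"]["beta"])
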