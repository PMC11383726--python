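"""Causal estimators against hand values and independent oracles."""

import numpy as np
import pytest
from scipy import stats

from mrlink.estimators import (
    _smoothed_mode,
    _weighted_quantile_half,
    egger,
    ivw,
    mode_estimate,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)
from mrlink.exceptions import InputError

from conftest import make_hset


def wls_oracle(bx, by, sy, intercept=False):
    """Independent weighted-least-squares fit via statsmodels."""
    import statsmodels.api as sm
    X = sm.add_constant(np.asarray(bx)) if intercept else np.asarray(bx)[:, None]
    fit = sm.WLS(np.asarray(by), X, weights=1.0 / np.asarray(sy) ** 2).fit()
    return fit.params


class TestWaldRatio:
    def test_null_outcome(self):
        assert wald_ratio(0.2, 0.01, 0.0, 0.02).beta == 0.0

    def test_hand_values(self):
        est = wald_ratio(0.2, 0.01, 0.1, 0.02)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_sign_symmetry(self):
        a = wald_ratio(0.2, 0.01, 0.1, 0.02)
        b = wald_ratio(-0.2, 0.01, -0.1, 0.02)
        assert a.beta == b.beta and a.se == b.se

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(InputError):
            wald_ratio(0.0, 0.01, 0.1, 0.02)


class TestIVW:
    def test_single_snp_reduces_to_wald(self):
        h = make_hset([0.2], [0.1], [0.02])
        est = ivw(h)
        wald = wald_ratio(0.2, 0.01, 0.1, 0.02)
        assert est.beta == pytest.approx(wald.beta)
        assert est.se == pytest.approx(wald.se)

    def test_two_snp_hand_value(self):
        h = make_hset([0.1, 0.2], [0.04, 0.12], [0.01, 0.01])
        assert ivw(h).beta == pytest.approx(0.56)

    def test_homogeneous_ratios_fixed_effects(self):
        h = make_hset([0.1, 0.2, 0.4], [0.05, 0.10, 0.20], [0.01, 0.02, 0.01])
        est = ivw(h, effects_model="auto")
        assert est.beta == pytest.approx(0.5)
        assert est.method == "ivw_fixed"

    def test_wls_oracle_random_instances(self, rng):
        for _ in range(100):
            k = int(rng.integers(3, 30))
            bx = rng.uniform(0.05, 0.5, k) * rng.choice([-1, 1], k)
            by = rng.normal(0.3 * bx, 0.05)
            sy = rng.uniform(0.01, 0.1, k)
            est = ivw(make_hset(bx, by, sy), effects_model="fixed")
            expected = wls_oracle(bx, by, sy)[0]
            assert est.beta == pytest.approx(expected, rel=1e-10)

    def test_random_effects_inflation_never_deflates(self, rng):
        bx = rng.uniform(0.1, 0.4, 10)
        by = rng.normal(0.5 * bx, 0.2)  # heterogeneous
        sy = np.full(10, 0.01)
        fixed = ivw(make_hset(bx, by, sy), effects_model="fixed")
        random_ = ivw(make_hset(bx, by, sy), effects_model="random")
        assert random_.se >= fixed.se
        assert random_.beta == pytest.approx(fixed.beta)

    def test_empty_rejected(self, rng):
        import pandas as pd
        from mrlink.gwas_io import HarmonizedInstrumentSet
        empty = HarmonizedInstrumentSet("x", "y", pd.DataFrame(
            columns=["snp", "beta_exp", "se_exp", "beta_out", "se_out", "eaf_exp"]))
        with pytest.raises(InputError):
            ivw(empty)


class TestEgger:
    def test_exact_linear_data(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.02 + 0.5 * bx
        fit = egger(make_hset(bx, by, np.full(4, 0.02)))
        assert fit.slope.beta == pytest.approx(0.5)
        assert fit.intercept == pytest.approx(0.02)

    def test_wls_oracle(self, rng):
        for _ in range(50):
            k = int(rng.integers(4, 25))
            bx = rng.uniform(0.05, 0.5, k)
            by = rng.normal(0.01 + 0.4 * bx, 0.05)
            sy = rng.uniform(0.02, 0.1, k)
            fit = egger(make_hset(bx, by, sy))
            expected = wls_oracle(bx, by, sy, intercept=True)
            assert fit.intercept == pytest.approx(expected[0], rel=1e-9, abs=1e-12)
            assert fit.slope.beta == pytest.approx(expected[1], rel=1e-9)

    def test_homogeneous_ratios_match_ivw(self):
        bx = np.array([0.1, 0.25, 0.4, 0.15])
        by = 0.5 * bx
        h = make_hset(bx, by, np.full(4, 0.02))
        fit = egger(h)
        assert fit.slope.beta == pytest.approx(ivw(h).beta, abs=1e-10)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_orients_negative_exposure_effects(self):
        bx = np.array([0.1, -0.2, 0.3, -0.4])
        by = 0.5 * bx + 0.01 * np.sign(bx)
        fit = egger(make_hset(bx, by, np.full(4, 0.02)))
        assert fit.slope.beta == pytest.approx(0.5)
        assert fit.intercept == pytest.approx(0.01)

    def test_intercept_null_calibration(self):
        """Balanced pleiotropy: intercept p approximately uniform."""
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(200):
            k = 20
            bx = rng.uniform(0.1, 0.6, k)
            sy = np.full(k, 0.05)
            by = rng.normal(0.3 * bx, sy)  # intercept truly zero
            pvals.append(egger(make_hset(bx, by, sy)).intercept_pval)
        d, p = stats.kstest(pvals, "uniform")
        assert p > 0.01

    def test_too_few_instruments(self):
        with pytest.raises(InputError):
            egger(make_hset([0.1, 0.2], [0.05, 0.1], [0.02, 0.02]))


def brute_force_weighted_quantile(ratios, weights):
    """Independent re-derivation of the interpolated weight-0.5 quantile."""
    order = np.argsort(ratios)
    r = np.asarray(ratios)[order]
    w = np.asarray(weights)[order]
    w = w / w.sum()
    s = np.cumsum(w) - 0.5 * w
    if 0.5 <= s[0]:
        return r[0]
    for j in range(1, len(r)):
        if s[j - 1] <= 0.5 <= s[j]:
            frac = (0.5 - s[j - 1]) / (s[j] - s[j - 1])
            return r[j - 1] + frac * (r[j] - r[j - 1])
    return r[-1]


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        h = make_hset([0.1, 0.1, 0.1], [0.04, 0.05, 0.06], [0.01, 0.01, 0.01])
        est = weighted_median(h, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.5)

    def test_brute_force_oracle(self, rng):
        for _ in range(100):
            k = int(rng.integers(3, 20))
            ratios = rng.normal(0.5, 0.3, k)
            weights = rng.uniform(0.1, 5.0, k)
            assert _weighted_quantile_half(ratios, weights / weights.sum()) == pytest.approx(
                brute_force_weighted_quantile(ratios, weights), rel=1e-10, abs=1e-12)

    def test_robust_to_one_outlier(self, rng):
        bx = np.full(10, 0.2)
        by = 0.5 * bx.copy()
        by[0] = 5.0 * bx[0]  # wild outlier ratio
        est = weighted_median(make_hset(bx, by, np.full(10, 0.02)), n_boot=50, seed=2)
        assert 0.4 <= est.beta <= 0.6

    def test_within_ratio_range(self, rng):
        for _ in range(20):
            k = int(rng.integers(3, 15))
            bx = rng.uniform(0.1, 0.5, k)
            by = rng.normal(0.2 * bx, 0.05)
            h = make_hset(bx, by, rng.uniform(0.01, 0.1, k))
            ratios = by / bx
            est = weighted_median(h, n_boot=10, seed=3)
            assert ratios.min() - 1e-12 <= est.beta <= ratios.max() + 1e-12

    def test_bootstrap_deterministic_under_seed(self):
        h = make_hset([0.1, 0.2, 0.3, 0.4], [0.06, 0.09, 0.16, 0.19],
                      [0.02, 0.02, 0.03, 0.02])
        a = weighted_median(h, n_boot=200, seed=42)
        b = weighted_median(h, n_boot=200, seed=42)
        assert a.se == b.se and a.beta == b.beta


class TestModeEstimators:
    def test_degenerate_identical_ratios(self):
        h = make_hset([0.1, 0.2, 0.4], [0.05, 0.10, 0.20], [0.02, 0.02, 0.02])
        est = mode_estimate(h, weighted=True, n_boot=10, seed=1)
        assert est.beta == pytest.approx(0.5)

    def test_bimodal_weighted_vs_simple(self):
        # cluster at 0.5 carries most inverse-variance weight (small se);
        # the cluster at 1.5 has more members but large se
        bx = np.array([0.30, 0.31, 0.32, 0.20, 0.21, 0.22, 0.23])
        ratios = np.array([0.498, 0.500, 0.502, 1.497, 1.499, 1.501, 1.503])
        by = ratios * bx
        sy = np.array([0.005, 0.005, 0.005, 0.2, 0.2, 0.2, 0.2])
        h = make_hset(bx, by, sy)
        w_mode = mode_estimate(h, weighted=True, n_boot=10, seed=1)
        s_mode = mode_estimate(h, weighted=False, n_boot=10, seed=1)
        assert w_mode.beta == pytest.approx(0.5, abs=0.1)
        assert s_mode.beta == pytest.approx(1.5, abs=0.2)

    def test_grid_oracle(self, rng):
        """Mode matches a dense independent grid search of the smoothed density."""
        for _ in range(20):
            k = int(rng.integers(5, 15))
            ratios = rng.normal(0.5, 0.2, k)
            weights = rng.uniform(0.5, 2.0, k)
            weights = weights / weights.sum()
            est = _smoothed_mode(ratios, weights, phi=1.0)
            spread = min(np.std(ratios, ddof=1), 1.4826 * np.median(np.abs(ratios - np.median(ratios))))
            h = 0.9 * spread / k ** 0.2
            grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 20001)
            dens = np.array([np.sum(weights * np.exp(-0.5 * ((g - ratios) / h) ** 2)) for g in grid])
            assert est == pytest.approx(grid[np.argmax(dens)], abs=(grid[1] - grid[0]) * 600)

    def test_oversmoothing_limit_is_weighted_mean(self, rng):
        # large (but numerically representable) bandwidth: density tends to
        # a quadratic peaked at the weighted mean
        ratios = rng.normal(0.5, 0.2, 12)
        weights = rng.uniform(0.5, 2.0, 12)
        weights = weights / weights.sum()
        est = _smoothed_mode(ratios, weights, phi=50.0)
        assert est == pytest.approx(float(np.sum(weights * ratios)), abs=0.05)

    def test_too_few_instruments(self):
        with pytest.raises(InputError):
            mode_estimate(make_hset([0.1, 0.2], [0.05, 0.1], [0.02, 0.02]),
                          n_boot=10, seed=1)


class TestSignFlipEquivariance:
    """All estimators are unchanged when (beta_X, beta_Y) flip sign jointly."""

    @pytest.mark.parametrize("method", ["ivw", "egger", "weighted_median", "weighted_mode"])
    def test_joint_flip(self, method, rng):
        k = 8
        bx = rng.uniform(0.1, 0.5, k)
        by = rng.normal(0.4 * bx, 0.05)
        sy = rng.uniform(0.02, 0.08, k)
        h = make_hset(bx, by, sy)
        h_flip = make_hset(-bx, -by, sy)
        if method == "ivw":
            a, b = ivw(h).beta, ivw(h_flip).beta
        elif method == "egger":
            a, b = egger(h).slope.beta, egger(h_flip).slope.beta
        elif method == "weighted_median":
            a = weighted_median(h, n_boot=10, seed=1).beta
            b = weighted_median(h_flip, n_boot=10, seed=1).beta
        else:
            a = mode_estimate(h, n_boot=10, seed=1).beta
            b = mode_estimate(h_flip, n_boot=10, seed=1).beta
        assert a == pytest.approx(b, rel=1e-9)


class TestOddsRatioTransform:
    @pytest.mark.parametrize("beta, se, or_expected, lo_expected, hi_expected", [
        (0.582, 0.208, 1.789, 1.190, 2.691),
        (0.739, 0.276, 2.093, 1.219, 3.594),
        (0.395, 0.200, 1.484, 1.002, 2.197),
        (-0.678, 0.315, 0.508, 0.274, 0.942),
    ])
    def test_published_fixtures(self, beta, se, or_expected, lo_expected, hi_expected):
        # tolerances reflect the 3-decimal rounding of the printed inputs
        or_, lo, hi = to_odds_ratio(beta, se)
        assert or_ == pytest.approx(or_expected, abs=1.5e-3)
        assert lo == pytest.approx(lo_expected, abs=4e-3)
        assert hi == pytest.approx(hi_expected, abs=4e-3)

    def test_null_effect_symmetric(self):
        or_, lo, hi = to_odds_ratio(0.0, 0.1)
        assert or_ == 1.0
        assert lo * hi == pytest.approx(1.0)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(InputError):
            to_odds_ratio(0.1, 0.0)
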