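import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mrforge.mr_core import (
    cochran_q,
    dispatch_mr,
    ivw,
    mr_egger,
    slope_hunter_adjust,
    steiger_filter,
    wald_ratio,
    weighted_median,
    weighted_mode,
    weighted_quantile,
    _mode_point,
)
from mrforge.synthetic_data import ColliderSpec, SimTruth, simulate_conditional

from conftest import make_harmonized, make_sumstats
from oracles import brute_weighted_quantile, wls_through_origin, wls_with_intercept


class TestWaldRatio:
    def test_direct_ratio(self):
        h = make_harmonized([0.5], [0.25], [0.1])
        res = wald_ratio(h)
        assert res.beta == pytest.approx(0.5)
        assert res.se == pytest.approx(0.2)
        assert res.method == "wald"

    def test_null_numerator_gives_p_one(self):
        res = wald_ratio(make_harmonized([0.5], [0.0], [0.1]))
        assert res.beta == 0.0
        assert res.pval == 1.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(make_harmonized([0.0], [0.1], [0.1]))

    def test_first_order_se_close_to_second_order_for_strong_instruments(self, rng):
        """The first-order delta SE agrees within 10% with the second-order
        delta SE (which includes se_exp) whenever |beta_exp|/se_exp > 10."""
        for _ in range(1000):
            bx = rng.uniform(0.1, 1) * rng.choice([-1, 1])
            sx = abs(bx) / rng.uniform(10.5, 100)
            sy = rng.uniform(0.01, 0.3)
            by = rng.uniform(-4, 4) * sy  # outcome z-scores in a realistic range
            first = abs(sy / bx)
            second = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
            res = wald_ratio(make_harmonized([bx], [by], [sy], se_exp=[sx]))
            assert res.se == pytest.approx(first, rel=1e-12)
            assert abs(first - second) / second < 0.10


class TestIvw:
    def test_homogeneous_ratios_fixed_equals_random(self):
        h = make_harmonized([0.2, 0.4], [0.1, 0.2], [0.05, 0.05])
        fixed = ivw(h, "fixed")
        mre = ivw(h, "multiplicative_random")
        assert fixed.beta == pytest.approx(0.5, abs=1e-12)
        assert fixed.Q == pytest.approx(0.0, abs=1e-20)
        assert mre.se == pytest.approx(fixed.se, rel=1e-12)

    def test_equal_weight_symmetry(self):
        h = make_harmonized([0.3, 0.3], [0.0, 0.3], [0.05, 0.05])
        assert ivw(h, "fixed").beta == pytest.approx(0.5, abs=1e-12)

    def test_requires_two_variants(self):
        with pytest.raises(ValueError, match="wald"):
            ivw(make_harmonized([0.2], [0.1], [0.05]))

    def test_matches_independent_wls_oracle(self, rng):
        """Point estimate and SE agree with a scaled-lstsq oracle to 1e-10
        on 500 random instrument sets (both effects models)."""
        for _ in range(500):
            L = int(rng.integers(2, 40))
            bx = rng.normal(0, 0.2, L)
            bx[np.abs(bx) < 0.01] = 0.05
            by = rng.normal(0, 0.1, L)
            sy = rng.uniform(0.01, 0.2, L)
            h = make_harmonized(bx, by, sy)
            theta, se_fixed, q = wls_through_origin(bx, by, sy)
            fixed = ivw(h, "fixed")
            mre = ivw(h, "multiplicative_random")
            assert fixed.beta == pytest.approx(theta, abs=1e-10)
            assert fixed.se == pytest.approx(se_fixed, abs=1e-10)
            assert fixed.Q == pytest.approx(q, rel=1e-9)
            assert mre.beta == pytest.approx(theta, abs=1e-10)
            assert mre.se == pytest.approx(
                se_fixed * max(1.0, np.sqrt(q / (L - 1))), abs=1e-10
            )

    def test_single_variant_consistency(self):
        """IVW on a duplicated variant equals the Wald ratio on that variant."""
        h2 = make_harmonized([0.3, 0.3], [0.12, 0.12], [0.04, 0.04])
        h1 = make_harmonized([0.3], [0.12], [0.04])
        assert ivw(h2, "fixed").beta == pytest.approx(wald_ratio(h1).beta, abs=1e-14)


class TestEgger:
    def test_exact_linear_data_recovers_slope_and_null_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_harmonized(bx, 0.5 * bx, [0.05] * 4)
        res = mr_egger(h)
        assert res.beta == pytest.approx(0.5, abs=1e-10)
        assert res.egger_intercept == pytest.approx(0.0, abs=1e-12)
        assert ivw(h).beta == pytest.approx(0.5, abs=1e-10)

    def test_translation_equivariance(self, rng):
        bx = rng.uniform(0.05, 0.4, 10)  # already positively oriented
        by = rng.normal(0, 0.1, 10)
        sy = rng.uniform(0.02, 0.1, 10)
        base = mr_egger(make_harmonized(bx, by, sy))
        shifted = mr_egger(make_harmonized(bx, by + 0.07, sy))
        assert shifted.egger_intercept - base.egger_intercept == pytest.approx(0.07, abs=1e-10)
        assert shifted.beta == pytest.approx(base.beta, abs=1e-10)

    def test_matches_independent_wls_oracle(self, rng):
        for _ in range(200):
            L = int(rng.integers(3, 40))
            bx = np.abs(rng.normal(0, 0.2, L)) + 0.01
            by = rng.normal(0, 0.1, L)
            sy = rng.uniform(0.01, 0.2, L)
            res = mr_egger(make_harmonized(bx, by, sy))
            coef, se, q = wls_with_intercept(bx, by, sy)
            phi = max(1.0, np.sqrt(q / (L - 2)))
            assert res.egger_intercept == pytest.approx(coef[0], abs=1e-10)
            assert res.beta == pytest.approx(coef[1], abs=1e-10)
            assert res.egger_intercept_se == pytest.approx(phi * se[0], rel=1e-9)
            assert res.se == pytest.approx(phi * se[1], rel=1e-9)

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        bx = np.abs(rng.normal(0, 0.2, 20)) + 0.01
        by = rng.normal(0.1, 0.1, 20)
        sy = rng.uniform(0.02, 0.1, 20)
        res = mr_egger(make_harmonized(bx, by, sy))
        fit = sm.WLS(by, sm.add_constant(bx), weights=1 / sy**2).fit()
        assert res.egger_intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert res.beta == pytest.approx(fit.params[1], abs=1e-10)

    def test_requires_three_variants(self):
        with pytest.raises(ValueError):
            mr_egger(make_harmonized([0.1, 0.2], [0.1, 0.1], [0.05, 0.05]))


class TestWeightedMedian:
    def test_middle_order_statistic(self):
        h = make_harmonized([1.0, 1.0, 1.0], [1.0, 2.0, 9.0], [1.0, 1.0, 1.0])
        res = weighted_median(h, reps=200, seed=1)
        assert res.beta == pytest.approx(2.0, abs=1e-12)

    def test_matches_brute_force_quantile_oracle(self, rng):
        for _ in range(500):
            L = int(rng.integers(3, 30))
            bx = np.abs(rng.normal(0.2, 0.1, L)) + 0.02
            by = rng.normal(0, 0.2, L)
            sy = rng.uniform(0.01, 0.2, L)
            ratios = by / bx
            weights = bx**2 / sy**2
            assert weighted_quantile(ratios, weights, 0.5) == pytest.approx(
                brute_weighted_quantile(ratios, weights, 0.5), abs=1e-12
            )

    def test_estimate_within_ratio_range(self, rng):
        for _ in range(50):
            L = int(rng.integers(3, 20))
            bx = np.abs(rng.normal(0.2, 0.1, L)) + 0.02
            by = rng.normal(0, 0.2, L)
            sy = rng.uniform(0.01, 0.2, L)
            res = weighted_median(make_harmonized(bx, by, sy), reps=100, seed=3)
            ratios = by / bx
            assert ratios.min() - 1e-12 <= res.beta <= ratios.max() + 1e-12

    def test_rep_validation(self):
        h = make_harmonized([1, 1, 1], [1, 2, 3], [1, 1, 1])
        with pytest.raises(ValueError):
            weighted_median(h, reps=1, seed=0)
        with pytest.warns(UserWarning):
            weighted_median(h, reps=50, seed=0)


class TestWeightedMode:
    def test_degenerate_identical_ratios(self):
        bx = np.array([0.1, 0.2, 0.4])
        h = make_harmonized(bx, 0.7 * bx, [0.05] * 3)
        for phi in (0.25, 1.0, 4.0):
            res = weighted_mode(h, phi=phi, reps=100, seed=0)
            assert res.beta == pytest.approx(0.7, abs=2e-2)

    def test_plurality_cluster_wins(self, rng):
        """60% of weight near ratio 0.2 and 40% near 1.0: the mode lands
        on the majority cluster."""
        L = 30
        bx = np.full(L, 0.3)
        truth = np.where(np.arange(L) < 18, 0.2, 1.0)
        by = truth * bx + rng.normal(0, 0.005, L)
        res = weighted_mode(make_harmonized(bx, by, [0.01] * L), reps=100, seed=4)
        assert abs(res.beta - 0.2) < 0.1

    def test_grid_argmax_matches_finer_grid(self, rng):
        for _ in range(200):
            L = int(rng.integers(3, 25))
            bx = np.abs(rng.normal(0.2, 0.1, L)) + 0.02
            by = rng.normal(0.1, 0.2, L)
            sy = rng.uniform(0.01, 0.2, L)
            ratios = by / bx
            weights = bx**2 / sy**2
            coarse, h = _mode_point(ratios, weights, 1.0, grid_size=512)
            fine, _ = _mode_point(ratios, weights, 1.0, grid_size=5120)
            step = (ratios.max() - ratios.min() + 6 * h) / 511
            assert abs(coarse - fine) <= step + 1e-12

    def test_phi_validation(self):
        h = make_harmonized([1, 1, 1], [1, 2, 3], [1, 1, 1])
        with pytest.raises(ValueError):
            weighted_mode(h, phi=0.0, reps=100, seed=0)


class TestDispatch:
    @pytest.mark.parametrize("L,method", [(1, "wald"), (2, "ivw_fixed"),
                                          (3, "ivw_fixed"), (4, "ivw_mre"), (10, "ivw_mre")])
    def test_variant_count_rule(self, L, method):
        bx = np.linspace(0.1, 0.4, L)
        h = make_harmonized(bx, 0.2 * bx, [0.05] * L)
        assert dispatch_mr(h).method == method


class TestCochranQ:
    def test_collinear_data_has_zero_q(self):
        bx = np.array([0.1, 0.2, 0.3])
        h = make_harmonized(bx, 0.4 * bx, [0.05] * 3)
        q, p = cochran_q(h, 0.4)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert p == pytest.approx(1.0)

    def test_outlier_dominates(self):
        bx = np.array([0.1, 0.2, 0.3])
        by = 0.4 * bx
        by[2] += 0.5
        h = make_harmonized(bx, by, [0.05] * 3)
        q, _ = cochran_q(h, 0.4)
        assert q == pytest.approx((0.5 / 0.05) ** 2, rel=1e-12)

    def test_homogeneous_simulation_moment(self, rng):
        """Under homogeneity Q/(L-1) averages about 1."""
        L, reps = 20, 1000
        vals = []
        for _ in range(reps):
            bx = rng.uniform(0.1, 0.3, L)
            by = 0.3 * bx + rng.normal(0, 0.05, L)
            h = make_harmonized(bx, by, [0.05] * L)
            theta = ivw(h, "fixed").beta
            q, _ = cochran_q(h, theta)
            vals.append(q / (L - 1))
        assert np.mean(vals) == pytest.approx(1.0, abs=0.05)


class TestSteiger:
    def _h(self, z_exp, z_out, n=50_000.0):
        se = 0.01
        return make_harmonized(
            [z * se for z in z_exp], [z * se for z in z_out],
            [se] * len(z_out), se_exp=[se] * len(z_exp), n_exp=n, n_out=n,
        )

    def test_exposure_dominant_kept_outcome_dominant_removed(self):
        h = self._h([10.0, 2.0], [2.0, 10.0])
        filtered, res = steiger_filter(h)
        assert list(res.table["keep"]) == [True, False]
        assert res.n_removed == 1
        assert list(filtered.df["variant_id"]) == ["v0"]

    def test_missing_n_raises(self):
        h = self._h([10.0], [2.0])
        h.df.loc[0, "n_exp"] = np.nan
        with pytest.raises(ValueError):
            steiger_filter(h)


class TestScaleEquivariance:
    def test_all_estimators_scale_inversely_with_exposure(self, rng):
        L = 12
        bx = np.abs(rng.normal(0.3, 0.1, L)) + 0.05
        by = 0.25 * bx + rng.normal(0, 0.02, L)
        sy = np.full(L, 0.03)
        c = 2.5
        h1 = make_harmonized(bx, by, sy)
        h2 = make_harmonized(c * bx, by, sy)
        assert ivw(h2).beta == pytest.approx(ivw(h1).beta / c, rel=1e-10)
        assert mr_egger(h2).beta == pytest.approx(mr_egger(h1).beta / c, rel=1e-10)
        m1 = weighted_median(h1, reps=100, seed=9)
        m2 = weighted_median(h2, reps=100, seed=9)
        assert m2.beta == pytest.approx(m1.beta / c, rel=1e-10)
        w1 = weighted_mode(h1, reps=100, seed=9)
        w2 = weighted_mode(h2, reps=100, seed=9)
        assert w2.beta == pytest.approx(w1.beta / c, rel=0.02, abs=1e-3)


class TestSlopeHunter:
    def _conditional(self, b, seed, **kw):
        truth = SimTruth(seed=seed, collider=ColliderSpec(b=b, **kw))
        return simulate_conditional(truth)

    def test_null_slope_leaves_effects_nearly_unchanged(self):
        sim = self._conditional(0.0, seed=5)
        fit, adjusted = slope_hunter_adjust(sim.incidence, sim.progression)
        assert abs(fit.b_hat) < 0.02
        delta = np.abs(adjusted["beta"] - sim.progression["beta"])
        assert np.max(delta) < 0.02 * np.max(np.abs(sim.progression["beta"])) + 1e-3

    def test_recovers_planted_slope(self):
        sim = self._conditional(-0.4, seed=6)
        fit, _ = slope_hunter_adjust(sim.incidence, sim.progression)
        assert fit.converged
        assert fit.b_hat == pytest.approx(-0.4, abs=0.05)

    def test_random_restarts_reach_same_fit(self):
        sim = self._conditional(-0.4, seed=7)
        ref, _ = slope_hunter_adjust(sim.incidence, sim.progression)
        for s in range(10):
            fit, _ = slope_hunter_adjust(sim.incidence, sim.progression, seed=s)
            assert fit.b_hat == pytest.approx(ref.b_hat, abs=1e-3)

    def test_adjusted_se_formula(self):
        sim = self._conditional(-0.4, seed=8)
        fit, adjusted = slope_hunter_adjust(sim.incidence, sim.progression)
        merged = sim.progression.merge(
            sim.incidence[["variant_id", "se"]], on="variant_id", suffixes=("", "_inc")
        )
        expect = np.sqrt(merged["se"] ** 2 + fit.b_hat**2 * merged["se_inc"] ** 2)
        np.testing.assert_allclose(adjusted["se"], expect, rtol=1e-10)
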