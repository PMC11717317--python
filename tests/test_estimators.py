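"""Causal-effect estimators against independent arithmetic oracles."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrkit import (
    ivw,
    mode_estimator,
    mr_egger,
    to_or_scale,
    wald_ratio,
    weighted_median,
)

from conftest import make_harmonized


def origin_wls_oracle(bx, by, sy):
    """Weighted least squares of by on bx through the origin, w = 1/sy^2."""
    w = 1.0 / np.asarray(sy) ** 2
    return float(np.sum(w * bx * by) / np.sum(w * bx * bx))


def egger_normal_equations_oracle(bx, by, sy):
    """Brute-force WLS with intercept via the normal equations, with the
    floored multiplicative overdispersion scale on the SEs."""
    bx, by, sy = map(np.asarray, (bx, by, sy))
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    W = np.diag(1.0 / sy**2)
    X = np.column_stack([np.ones_like(bx), bx])
    xtwx = X.T @ W @ X
    params = np.linalg.solve(xtwx, X.T @ W @ by)
    resid = by - X @ params
    rss_w = float(resid @ W @ resid)
    scale = max(1.0, rss_w / (len(bx) - 2))
    se = np.sqrt(np.diag(np.linalg.inv(xtwx)) * scale)
    return params, se  # (intercept, slope), (se_int, se_slope)


def weighted_median_oracle(theta, w):
    """Step-through of the cumulative-weight interpolation at 0.5."""
    order = np.argsort(theta)
    t, ww = np.asarray(theta)[order], np.asarray(w)[order]
    ww = ww / ww.sum()
    p = np.cumsum(ww) - ww / 2
    if 0.5 <= p[0]:
        return float(t[0])
    if 0.5 >= p[-1]:
        return float(t[-1])
    below = np.searchsorted(p, 0.5) - 1
    if p[below] == 0.5:
        return float(t[below])
    frac = (0.5 - p[below]) / (p[below + 1] - p[below])
    return float(t[below] + frac * (t[below + 1] - t[below]))


class TestWaldRatio:
    @pytest.mark.parametrize(
        "bx,by,sy,theta,se",
        [(0.1, 0.05, 0.01, 0.5, 0.1), (0.1, 0.0, 0.01, 0.0, 0.1), (-0.1, 0.05, 0.01, -0.5, 0.1)],
    )
    def test_ratio_and_delta_se(self, bx, by, sy, theta, se):
        hs = make_harmonized([bx], [by], [sy])
        est = wald_ratio(hs.records[0])
        assert est.theta == pytest.approx(theta)
        assert est.se == pytest.approx(se)

    def test_zero_exposure_beta_is_hard_error(self):
        hs = make_harmonized([0.0], [0.05], [0.01])
        with pytest.raises(ValueError):
            wald_ratio(hs.records[0])


class TestIVW:
    def test_two_snp_weighted_mean(self):
        # ratios 0.4 and 0.8 with ratio SEs 0.1 and 0.2 -> w = (100, 25)
        hs = make_harmonized([1.0, 1.0], [0.4, 0.8], [0.1, 0.2])
        est = ivw(hs, "fe")
        assert est.theta == pytest.approx(0.48)
        assert est.se == pytest.approx(0.089443, abs=1e-6)

    def test_point_estimate_identical_fe_mre_and_mre_never_smaller_se(self, rng):
        for _ in range(20):
            L = rng.integers(3, 12)
            hs = make_harmonized(
                rng.uniform(0.05, 0.2, L), rng.normal(0, 0.05, L), rng.uniform(0.01, 0.1, L)
            )
            fe, mre = ivw(hs, "fe"), ivw(hs, "mre")
            assert fe.theta == pytest.approx(mre.theta)
            assert mre.se >= fe.se

    def test_homogeneous_ratios_give_q_zero_so_mre_equals_fe(self):
        hs = make_harmonized([0.1, 0.2, 0.4], [0.05, 0.10, 0.20], [0.01, 0.02, 0.04])
        assert ivw(hs, "mre").se == pytest.approx(ivw(hs, "fe").se)

    def test_duplicated_pair_recovers_wald_ratio(self):
        hs = make_harmonized([0.1] * 5, [0.05] * 5, [0.01] * 5)
        single = make_harmonized([0.1], [0.05], [0.01])
        assert ivw(hs).theta == pytest.approx(wald_ratio(single.records[0]).theta)

    def test_fewer_than_two_records_is_hard_error(self):
        with pytest.raises(ValueError):
            ivw(make_harmonized([0.1], [0.05], [0.01]))

    def test_equals_origin_constrained_wls(self, rng):
        """IVW is WLS of beta_Y on beta_X through the origin with weights
        1/se_Y^2 — which is also the Egger fit with the intercept pinned
        at zero."""
        for _ in range(50):
            L = int(rng.integers(3, 15))
            bx = rng.uniform(0.03, 0.3, L) * rng.choice([-1, 1], L)
            by = rng.normal(0, 0.05, L)
            sy = rng.uniform(0.005, 0.08, L)
            est = ivw(make_harmonized(bx, by, sy))
            assert est.theta == pytest.approx(origin_wls_oracle(bx, by, sy), rel=1e-9)


class TestEgger:
    def test_exact_affine_data_recovered_with_zero_residuals(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        by = 0.01 + 0.5 * bx
        fit = mr_egger(make_harmonized(bx, by, [0.01] * 4))
        assert fit.slope.theta == pytest.approx(0.5, abs=1e-10)
        assert fit.intercept == pytest.approx(0.01, abs=1e-10)
        assert np.isfinite(fit.slope.se) and fit.slope.se > 0

    def test_no_pleiotropy_line_gives_zero_intercept(self):
        bx = np.array([0.05, 0.1, 0.2])
        fit = mr_egger(make_harmonized(bx, 0.5 * bx, [0.01] * 3))
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(50):
            L = int(rng.integers(4, 12))
            bx = rng.uniform(0.03, 0.3, L) * rng.choice([-1, 1], L)
            by = rng.normal(0.01, 0.05, L)
            sy = rng.uniform(0.005, 0.08, L)
            fit = mr_egger(make_harmonized(bx, by, sy))
            (b0, b1), (se0, se1) = egger_normal_equations_oracle(bx, by, sy)
            assert fit.intercept == pytest.approx(b0, rel=1e-8)
            assert fit.slope.theta == pytest.approx(b1, rel=1e-8)
            assert fit.intercept_se == pytest.approx(se0, rel=1e-8)
            assert fit.slope.se == pytest.approx(se1, rel=1e-8)

    def test_fewer_than_three_records_is_hard_error(self):
        with pytest.raises(ValueError):
            mr_egger(make_harmonized([0.1, 0.2], [0.05, 0.1], [0.01, 0.01]))

    def test_no_variation_in_exposure_beta_is_hard_error(self):
        with pytest.raises(ValueError):
            mr_egger(make_harmonized([0.1] * 4, [0.05, 0.1, 0.0, 0.2], [0.01] * 4))


class TestWeightedMedian:
    def test_equal_weights_middle_point(self):
        hs = make_harmonized([1, 1, 1], [0.2, 0.4, 0.6], [0.1, 0.1, 0.1])
        assert weighted_median(hs, n_boot=100, seed=0).theta == pytest.approx(0.4)

    def test_identical_ratios_degenerate_to_constant_with_tiny_se(self):
        hs = make_harmonized([1, 1, 1], [0.3, 0.3, 0.3], [1e-8] * 3)
        est = weighted_median(hs, n_boot=100, seed=0)
        assert est.theta == pytest.approx(0.3)
        assert est.se < 1e-6

    def test_matches_cumulative_weight_oracle(self, rng):
        for _ in range(50):
            L = int(rng.integers(3, 12))
            bx = rng.uniform(0.05, 0.3, L)
            by = rng.normal(0, 0.05, L)
            sy = rng.uniform(0.005, 0.08, L)
            est = weighted_median(make_harmonized(bx, by, sy), n_boot=100, seed=1)
            theta = by / bx
            w = (bx / sy) ** 2
            assert est.theta == pytest.approx(weighted_median_oracle(theta, w), rel=1e-9)

    def test_equal_weights_odd_l_equals_plain_median(self, rng):
        bx = np.ones(7)
        by = rng.normal(0, 0.1, 7)
        hs = make_harmonized(bx, by, np.full(7, 0.05))
        assert weighted_median(hs, n_boot=100, seed=0).theta == pytest.approx(np.median(by))

    def test_n_boot_floor(self):
        hs = make_harmonized([1, 1, 1], [0.2, 0.4, 0.6], [0.1, 0.1, 0.1])
        with pytest.raises(ValueError):
            weighted_median(hs, n_boot=10)


class TestModeEstimator:
    def test_point_mass(self):
        hs = make_harmonized([1, 1, 1], [0.3, 0.3, 0.3], [1e-6] * 3)
        assert mode_estimator(hs, n_boot=100, seed=0).theta == pytest.approx(0.3)

    def test_majority_cluster_wins_with_small_bandwidth(self):
        hs = make_harmonized([1, 1, 1, 1], [0.1, 0.1, 0.1, 0.9], [0.1] * 4)
        est = mode_estimator(hs, weighted=False, bandwidth_factor=0.3, n_boot=100, seed=0)
        assert est.theta == pytest.approx(0.1, abs=0.02)

    def test_heavy_weight_pulls_weighted_mode(self):
        # the 0.9 ratio gets 100x the weight via a 10x smaller outcome SE
        hs = make_harmonized([1, 1, 1, 1], [0.1, 0.1, 0.1, 0.9], [0.1, 0.1, 0.1, 0.01])
        est = mode_estimator(hs, weighted=True, bandwidth_factor=0.3, n_boot=100, seed=0)
        assert est.theta == pytest.approx(0.9, abs=0.02)

    def test_fewer_than_three_records_is_hard_error(self):
        with pytest.raises(ValueError):
            mode_estimator(make_harmonized([1, 1], [0.1, 0.2], [0.1, 0.1]))


class TestORScale:
    def test_null_effect(self):
        or_, lo, hi = to_or_scale(0.0, 0.01)
        assert or_ == pytest.approx(1.0)
        assert lo == pytest.approx(0.9806, abs=1e-4)
        assert hi == pytest.approx(1.0198, abs=1e-4)

    def test_direct_exponentiation(self):
        or_, lo, hi = to_or_scale(0.07, 0.026)
        assert (or_, lo, hi) == pytest.approx((1.0725, 1.0193, 1.1285), abs=1e-4)

    def test_sign_symmetry(self):
        p = to_or_scale(0.07, 0.026)
        n = to_or_scale(-0.07, 0.026)
        assert n[0] == pytest.approx(1 / p[0])
        assert n[1] == pytest.approx(1 / p[2])
        assert n[2] == pytest.approx(1 / p[1])


@settings(max_examples=40, derandomize=True, deadline=None)
@given(c=st.floats(0.2, 5.0), seed=st.integers(0, 10))
def test_scale_equivariance_of_all_estimators(c, seed):
    """Multiplying every exposure beta by c divides the slope by c."""
    rng = np.random.default_rng(seed)
    L = 6
    bx = rng.uniform(0.05, 0.3, L)
    by = rng.normal(0.02, 0.05, L)
    sy = rng.uniform(0.01, 0.05, L)
    base, scaled = make_harmonized(bx, by, sy), make_harmonized(c * bx, by, sy)
    assert ivw(scaled).theta == pytest.approx(ivw(base).theta / c, rel=1e-9)
    assert mr_egger(scaled).slope.theta == pytest.approx(mr_egger(base).slope.theta / c, rel=1e-6)
    wm_b = weighted_median(base, n_boot=100, seed=0).theta
    wm_s = weighted_median(scaled, n_boot=100, seed=0).theta
    assert wm_s == pytest.approx(wm_b / c, rel=1e-9)
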