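"""Wald ratios, IVW pooling, heterogeneity, leave-one-out, Egger, power."""

import numpy as np
import pytest
from scipy import stats

from mrlink.mr import (
    MREstimationError,
    WaldEstimate,
    cochran_q,
    egger,
    format_p,
    ivw_fixed,
    leave_one_out,
    mr_power,
    wald_ratio,
)
from mrlink.sumstats import HarmonizedPair


def est(theta, se, rsid=""):
    return WaldEstimate(rsid=rsid, theta=theta, se_theta=se)


def pair(rsid, bx, by, sx=0.02, sy=0.05):
    return HarmonizedPair(rsid=rsid, action="kept", beta_exp=bx, se_exp=sx,
                          beta_out=by, se_out=sy)


def ivw_oracle(thetas, ses):
    """Naive two-pass fixed-effect oracle."""
    w = 1.0 / np.asarray(ses) ** 2
    t = np.asarray(thetas)
    pooled = np.sum(w * t) / np.sum(w)
    q = float(np.sum(w * (t - pooled) ** 2))
    return pooled, np.sum(w) ** -0.5, q


class TestWaldRatio:
    def test_first_order(self):
        e = wald_ratio(0.2, 0.1, 0.1, 0.02, order="first")
        assert (e.theta, e.se_theta) == (2.0, pytest.approx(1.0))

    def test_zero_numerator(self):
        e = wald_ratio(0.0, 0.1, 0.5, 0.01, order="first")
        assert (e.theta, e.se_theta) == (0.0, pytest.approx(0.2))

    def test_second_order_delta_method(self):
        e = wald_ratio(0.2, 0.1, 0.1, 0.02, order="second")
        # plug-in oracle: sqrt(se_out^2/b^2 + b_out^2 se_exp^2 / b^4)
        assert e.se_theta == pytest.approx(np.sqrt(1.16), abs=1e-12)
        assert e.se_theta == pytest.approx(1.0770, abs=1e-4)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(MREstimationError):
            wald_ratio(0.1, 0.1, 0.0, 0.02)


class TestIVW:
    def test_single_estimate_identity(self):
        fit = ivw_fixed([est(0.7, 0.3)])
        assert fit.theta_hat == pytest.approx(0.7)
        assert fit.se == pytest.approx(0.3)
        assert fit.k == 1 and np.isnan(fit.p_het)

    def test_equal_weights(self):
        fit = ivw_fixed([est(1, 1), est(3, 1)])
        assert fit.theta_hat == pytest.approx(2.0)
        assert fit.se == pytest.approx(2**-0.5)
        assert fit.q == pytest.approx(2.0)
        assert fit.p_het == pytest.approx(stats.chi2.sf(2, 1), abs=1e-10)
        assert fit.p_het == pytest.approx(0.1573, abs=1e-4)

    def test_empty_rejected(self):
        with pytest.raises(MREstimationError):
            ivw_fixed([])

    def test_ci_brackets_or(self):
        fit = ivw_fixed([est(0.2, 0.1), est(0.1, 0.2)])
        lo, hi = fit.ci95
        assert lo < fit.or_ < hi

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(200):
            k = rng.integers(2, 30)
            t = rng.normal(0, 1, k)
            s = rng.uniform(0.05, 2.0, k)
            fit = ivw_fixed([est(a, b) for a, b in zip(t, s)])
            pooled, se, q = ivw_oracle(t, s)
            assert fit.theta_hat == pytest.approx(pooled, abs=1e-10)
            assert fit.se == pytest.approx(se, abs=1e-10)
            assert fit.q == pytest.approx(q, abs=1e-10)

    def test_se_decreases_with_added_instruments(self, rng):
        ests = [est(0.1, rng.uniform(0.1, 1)) for _ in range(10)]
        ses = [ivw_fixed(ests[: k + 1]).se for k in range(1, 10)]
        assert all(a > b for a, b in zip(ses, ses[1:]))


class TestCochranQ:
    def test_identical_estimates_degenerate(self):
        q, df, p = cochran_q([est(0.5, 0.2)] * 4, 0.5)
        assert (q, df, p) == (pytest.approx(0.0), 3, pytest.approx(1.0))

    def test_needs_two(self):
        with pytest.raises(MREstimationError):
            cochran_q([est(1, 1)], 1.0)

    def test_order_invariance(self, rng):
        ests = [est(t, s) for t, s in zip(rng.normal(size=8), rng.uniform(0.1, 1, 8))]
        pooled = ivw_fixed(ests).theta_hat
        q1, *_ = cochran_q(ests, pooled)
        q2, *_ = cochran_q(ests[::-1], pooled)
        assert q1 == pytest.approx(q2, abs=1e-12)


class TestLeaveOneOut:
    def test_planted_outlier_flagged(self):
        ests = [est(0.2, 0.05, f"v{i}") for i in range(20)]
        ests[7] = est(5.0, 0.05, "v7")
        res = leave_one_out(ests)
        assert res.dominant == "v7"
        assert res.outlier == "v7"
        assert res.fits["v7"].q < res.q_full

    def test_no_outlier_when_homogeneous(self):
        res = leave_one_out([est(0.3, 0.1, f"v{i}") for i in range(5)])
        # removal of any variant leaves p_het = 1; no single variant is
        # responsible for (non-existent) heterogeneity, but the rule still
        # reports no misleading Q reduction
        assert res.q_full == pytest.approx(0.0)

    def test_needs_three(self):
        with pytest.raises(MREstimationError):
            leave_one_out([est(1, 1), est(2, 1)])


class TestEgger:
    def test_exact_line_through_origin(self):
        pairs = [pair(f"v{i}", bx, 0.5 * bx) for i, bx in enumerate([0.05, 0.1, 0.2, 0.3])]
        fit = egger(pairs)
        assert fit.slope == pytest.approx(0.5, abs=1e-10)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)

    def test_exact_affine(self):
        pairs = [pair(f"v{i}", bx, 0.1 + 0.5 * bx) for i, bx in enumerate([0.05, 0.1, 0.2, 0.3])]
        fit = egger(pairs)
        assert fit.intercept == pytest.approx(0.1, abs=1e-10)
        assert fit.slope == pytest.approx(0.5, abs=1e-10)

    def test_orientation_invariance(self, rng):
        """Flipping the sign convention of any variant leaves the fit alone."""
        bx = rng.uniform(0.05, 0.3, 10)
        by = 0.3 * bx + rng.normal(0, 0.02, 10)
        pairs = [pair(f"v{i}", x, y) for i, (x, y) in enumerate(zip(bx, by))]
        flipped = [pair(p.rsid, -p.beta_exp, -p.beta_out) if i % 2 else p
                   for i, p in enumerate(pairs)]
        f1, f2 = egger(pairs), egger(flipped)
        assert f1.slope == pytest.approx(f2.slope, abs=1e-12)
        assert f1.intercept == pytest.approx(f2.intercept, abs=1e-12)

    def test_degenerate_design(self):
        with pytest.raises(MREstimationError):
            egger([pair(f"v{i}", 0.1, 0.05) for i in range(4)])

    def test_t_reference_distribution(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3, 0.15])
        by = 0.2 * bx + np.array([0.01, -0.02, 0.015, -0.01, 0.005])
        fit = egger([pair(f"v{i}", x, y) for i, (x, y) in enumerate(zip(bx, by))])
        expect = 2 * stats.t.sf(abs(fit.slope / fit.slope_se), fit.k - 2)
        assert fit.slope_p == pytest.approx(expect, rel=1e-6)


class TestPower:
    def test_null_or_gives_alpha(self):
        res = mr_power(52, 0.133, 17008, 37154, true_or=1.0, alpha=0.05)
        assert res.power == pytest.approx(0.05, abs=1e-9)

    def test_monotone_in_sample_size(self):
        p1 = mr_power(52, 0.133, 17008, 37154, 1.05).power
        p2 = mr_power(52, 0.133, 2 * 17008, 2 * 37154, 1.05).power
        assert p2 >= p1

    def test_closed_form_oracle(self):
        res = mr_power(52, 0.133, 17008, 37154, true_or=1.10, alpha=0.05)
        n = 17008 + 37154
        phi = 17008 / n
        b = abs(np.log(1.10)) * np.sqrt(n * 0.133 * phi * (1 - phi))
        expect = stats.norm.cdf(-1.959963984540054 + b) + stats.norm.cdf(-1.959963984540054 - b)
        assert res.power == pytest.approx(expect, abs=1e-12)
        # an analysis of this size is well powered for a ~10% effect
        assert res.power > 0.8

    def test_detectable_or_inverts_power(self):
        res = mr_power(52, 0.133, 17008, 37154, 1.10)
        back = mr_power(52, 0.133, 17008, 37154, res.detectable_or)
        assert back.power == pytest.approx(0.80, abs=1e-6)

    def test_validation(self):
        with pytest.raises(ValueError):
            mr_power(52, 1.5, 100, 100, 1.1)


def test_p_value_floor_formatting():
    assert format_p(1e-320) == "<2.2e-308"
    assert format_p(0.027) == "0.027"
    assert format_p(float("nan")) == "NA"
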