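"""Wald ratios, IVW-family pooling, penalty factors, robust fit, Cochran's Q.

Frozen expected values for the instrument fixture were derived by direct
arithmetic on the table rows (ratio = beta_out/beta_exp, weight =
beta_exp^2/se_out^2, chi-square(1) survival probabilities for the penalty
factors) independently of the implementation under test.
"""
import numpy as np
import pytest
from scipy import stats

from summarymr import (
    EstimationError,
    HarmonizedVariant,
    WaldEstimate,
    cochran_q,
    ivw,
    ivw_penalized,
    penalized_robust_ivw,
    penalty_factors,
    pool,
    robust_fit,
    wald_ratio,
    wald_ratios,
)


def _hv(vid, bx, sx, px, by, sy, py):
    return HarmonizedVariant(vid, bx, sx, px, by, sy, py, flipped=False)


def _west(vid, beta, se):
    return WaldEstimate(vid, beta, se)


class TestWaldRatio:
    def test_fixture_row_delta_method(self, t2dm_instruments):
        rs4537545 = next(v for v in t2dm_instruments if v.variant_id == "rs4537545")
        est = wald_ratio(rs4537545)
        assert est.beta_xy == pytest.approx(-0.01980 / -0.108, abs=1e-12)
        assert est.beta_xy == pytest.approx(0.183333, abs=1e-5)
        assert est.se_xy == pytest.approx(0.00991 / 0.108, abs=1e-12)
        assert est.se_xy == pytest.approx(0.091759, abs=1e-5)

    def test_sign_flip_across_zero_exposure_effect(self, t2dm_instruments):
        rs1183910 = next(v for v in t2dm_instruments if v.variant_id == "rs1183910")
        assert wald_ratio(rs1183910).beta_xy == pytest.approx(-0.217353, abs=1e-5)

    def test_zero_outcome_beta_gives_zero_ratio(self):
        assert wald_ratio(_hv("rs1", 0.1, 0.01, 1e-9, 0.0, 0.01, 1.0)).beta_xy == 0.0

    def test_zero_exposure_beta_errors_naming_variant(self):
        with pytest.raises(EstimationError, match="rs_bad"):
            wald_ratio(_hv("rs_bad", 0.0, 0.01, 1e-9, 0.01, 0.01, 0.5))

    def test_literal_se_rule_behind_flag(self):
        h = _hv("rs1", -0.147, 0.01429, 1e-9, -0.00995, 0.01493, 0.41)
        assert wald_ratio(h, se_method="literal").se_xy == pytest.approx(
            0.01493 / 0.01429, abs=1e-12)

    def test_weight_is_exact_inverse_variance(self):
        est = _west("rs1", 0.1, 0.3)
        assert est.weight == 0.3 ** -2


class TestIVW:
    def test_fixture_instruments_match_weighted_mean_oracle(self, t2dm_instruments):
        pooled = ivw(wald_ratios(t2dm_instruments))
        # independent oracle: direct weighted mean on the table rows
        bx = np.array([-0.147, -0.108, -0.207, -0.136])
        by = np.array([-0.00995, -0.01980, -0.01980, 0.02956])
        sy = np.array([0.01493, 0.00991, 0.01479, 0.00981])
        w = bx ** 2 / sy ** 2
        expected = np.sum(w * by / bx) / np.sum(w)
        assert pooled.beta == pytest.approx(expected, abs=1e-14)
        assert pooled.beta == pytest.approx(0.0087762, abs=1e-6)
        assert pooled.se == pytest.approx(np.sum(w) ** -0.5, abs=1e-14)
        assert np.all(pooled.penalty_factors == 1)
        assert np.all(pooled.robust_weights == 1)

    def test_single_estimate_is_identity(self):
        pooled = ivw([_west("rs1", 0.2, 0.05)])
        assert pooled.beta == pytest.approx(0.2) and pooled.se == pytest.approx(0.05)

    def test_two_identical_estimates_halve_variance(self):
        pooled = ivw([_west("rs1", 0.2, 0.05), _west("rs2", 0.2, 0.05)])
        assert pooled.beta == pytest.approx(0.2)
        assert pooled.se == pytest.approx(0.05 / np.sqrt(2))

    def test_ci_brackets_or(self, t2dm_instruments):
        pooled = ivw(wald_ratios(t2dm_instruments))
        assert pooled.ci_low < pooled.or_ < pooled.ci_high
        assert pooled.or_ == pytest.approx(np.exp(pooled.beta))
        assert pooled.ci_high == pytest.approx(np.exp(pooled.beta + 1.959964 * pooled.se))

    def test_empty_input_errors(self):
        with pytest.raises(EstimationError):
            ivw([])


class TestPenaltyFactors:
    def test_fixture_outlier_factor(self, t2dm_instruments):
        ests = wald_ratios(t2dm_instruments)
        ref = ivw(ests).beta
        f = penalty_factors(ests, ref)
        by_id = dict(zip([e.variant_id for e in ests], f))
        # oracle: Q = w (ratio - ref)^2 referred to chi2(1)
        rs = next(e for e in ests if e.variant_id == "rs1183910")
        q = rs.weight * (rs.beta_xy - ref) ** 2
        assert q == pytest.approx(9.8277, abs=2e-3)
        assert by_id["rs1183910"] == pytest.approx(20 * stats.chi2.sf(q, 1), abs=1e-12)
        assert by_id["rs1183910"] == pytest.approx(0.0344, abs=5e-4)
        for vid in ("rs6700896", "rs4537545", "rs7553007"):
            assert by_id[vid] == 1.0

    def test_zero_deviation_gives_unit_factor(self):
        f = penalty_factors([_west("rs1", 0.1, 0.05)], reference_beta=0.1)
        assert f[0] == 1.0

    def test_min_clamp(self):
        # p_j >= 1/penalty_mult -> factor exactly 1
        est = _west("rs1", 0.1, 0.05)
        q_for_p = stats.chi2.isf(0.06, 1)  # p = 0.06 > 1/20
        beta_ref = 0.1 - 0.05 * np.sqrt(q_for_p)
        f = penalty_factors([est], beta_ref, penalty_mult=20)
        assert f[0] == 1.0


class TestRobustFit:
    def test_exact_collinear_through_origin(self):
        x = np.array([1.0, 2.0, 3.0])
        fit = robust_fit(x, 0.7 * x, np.array([1.0, 2.0, 0.5]))
        assert fit.coefficients[0] == pytest.approx(0.7, abs=1e-12)
        assert np.all(fit.robust_weights == 1.0)
        assert fit.converged

    def test_gross_outlier_rejected(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0.5, 2.0, 20)
        y = 1.3 * x
        y[5] += 10.0
        w = np.ones(20)
        fit = robust_fit(x, y, w)
        assert fit.robust_weights[5] < 0.05
        clean = np.delete(np.arange(20), 5)
        slope_clean = np.sum(x[clean] * y[clean]) / np.sum(x[clean] ** 2)
        assert fit.coefficients[0] == pytest.approx(slope_clean, abs=1e-3)

    def test_symmetric_residuals_match_ordinary_fit(self):
        x = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        delta = 0.1
        y = 0.5 * x + np.array([delta, -delta] * 3)
        fit = robust_fit(x, y, np.ones(6))
        assert fit.coefficients[0] == pytest.approx(0.5, abs=1e-9)

    def test_matches_statsmodels_rlm(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 200)
        y = 2.0 * x + 0.5 + rng.normal(0, 0.3, 200)
        y[:5] += 8.0
        fit = robust_fit(x, y, np.ones(200), include_intercept=True)
        ref = sm.RLM(
            y, sm.add_constant(x), M=sm.robust.norms.TukeyBiweight(4.685)
        ).fit()
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-4)

    def test_weights_must_be_positive(self):
        with pytest.raises(EstimationError):
            robust_fit(np.ones(2), np.ones(2), np.array([1.0, 0.0]))


class TestPenalizedRobustIVW:
    def test_homogeneous_instruments_collapse_to_plain_ivw(self):
        ests = [_west(f"rs{i}", 0.12, 0.03 + 0.01 * i) for i in range(4)]
        pr = penalized_robust_ivw(ests)
        plain = ivw(ests)
        assert pr.beta == pytest.approx(plain.beta, abs=1e-10)
        assert np.all(pr.penalty_factors == 1.0)
        assert np.all(pr.robust_weights == 1.0)

    def test_fixture_downweights_discordant_instrument(self, t2dm_instruments):
        pr = penalized_robust_ivw(wald_ratios(t2dm_instruments))
        idx = pr.variant_ids.index("rs1183910")
        assert pr.penalty_factors[idx] < 0.05  # ~30-fold downweighting
        assert pr.or_ == pytest.approx(1.114, abs=2e-3)

    def test_dispatch_names(self, t2dm_instruments):
        w = wald_ratios(t2dm_instruments)
        assert pool(w, "ivw_penalized").beta == pytest.approx(
            ivw_penalized(w).beta, abs=1e-15)
        with pytest.raises(ValueError):
            pool(w, "median")

    def test_single_estimate_degenerate(self):
        pr = penalized_robust_ivw([_west("rs1", 0.2, 0.05)])
        assert pr.beta == pytest.approx(0.2) and pr.se == pytest.approx(0.05)


class TestCochranQ:
    def test_fixture_total_and_contributions(self, t2dm_instruments):
        res = cochran_q(wald_ratios(t2dm_instruments))
        assert res.q_total == pytest.approx(15.261, abs=2e-3)
        assert res.df == 3
        assert res.q_total == pytest.approx(np.sum(res.q_contributions), abs=1e-12)
        assert np.all(res.q_contributions >= 0)

    def test_identical_estimates_no_dispersion(self):
        res = cochran_q([_west("rs1", 0.1, 0.05), _west("rs2", 0.1, 0.07)])
        assert res.q_total == pytest.approx(0.0, abs=1e-20)
        assert res.pvalue == pytest.approx(1.0)

    def test_two_estimates_closed_form(self):
        b1, s1, b2, s2 = 0.1, 0.04, 0.25, 0.09
        res = cochran_q([_west("a", b1, s1), _west("b", b2, s2)])
        # closed form: squared standardized difference with harmonic weight
        expected = (b1 - b2) ** 2 / (s1 ** 2 + s2 ** 2)
        assert res.q_total == pytest.approx(expected, abs=1e-12)

    def test_requires_two(self):
        with pytest.raises(EstimationError):
            cochran_q([_west("rs1", 0.1, 0.05)])
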