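import warnings

import numpy as np
import pytest

from scoremr.associate import AssocEstimate
from scoremr.errors import ConfigurationError, UndefinedRatioError
from scoremr.mr import (
    ci_to_se,
    instrument_f,
    iv_power,
    iv_ratio,
    percent_change_per_10pct,
    summary_score,
)


def _est(beta, se, n=1000, **kw):
    return AssocEstimate(beta=beta, se=se, n=n, **kw)


class TestIVRatio:
    def test_bmi_direction_published_coefficients(self):
        """Score-outcome -0.06 (CI -0.10,-0.02) over score-exposure 0.14
        (CI 0.12,0.16): ratio ~ -0.43, CI ~ (-0.72, -0.14)."""
        num = _est(-0.06, ci_to_se(-0.10, -0.02))
        den = _est(0.14, ci_to_se(0.12, 0.16))
        iv = iv_ratio(num, den)
        assert iv.ratio == pytest.approx(-0.4286, abs=1e-3)
        assert iv.ci_low == pytest.approx(-0.721, abs=5e-3)
        assert iv.ci_high == pytest.approx(-0.136, abs=5e-3)
        assert iv.p < 0.01
        assert not iv.weak_denominator

    def test_metabolism_direction_published_coefficients(self):
        iv = iv_ratio(_est(0.17, 0.0944), _est(-5.38, 0.2321))
        assert iv.ratio == pytest.approx(-0.0316, abs=5e-4)
        assert round(iv.ratio, 2) == -0.03

    def test_zero_numerator_symmetric_ci(self):
        iv = iv_ratio(_est(0.0, 0.1), _est(2.0, 0.1))
        assert iv.ratio == 0.0
        assert iv.ci_low == pytest.approx(-iv.ci_high)
        assert iv.p == pytest.approx(1.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(UndefinedRatioError):
            iv_ratio(_est(1.0, 0.1), _est(0.0, 0.1))

    def test_weak_denominator_flagged(self):
        with pytest.warns(UserWarning, match="weak denominator"):
            iv = iv_ratio(_est(1.0, 0.1), _est(0.15, 0.1))
        assert iv.weak_denominator

    @pytest.mark.parametrize(
        "num,den", [(1.0, 2.0), (-1.0, 2.0), (1.0, -2.0), (-1.0, -2.0)]
    )
    def test_sign_consistency(self, num, den):
        iv = iv_ratio(_est(num, 0.01), _est(den, 0.01))
        assert np.sign(iv.ratio) == np.sign(num) * np.sign(den)

    def test_delta_method_matches_parametric_bootstrap(self):
        """With a strong denominator (z > 10) the Taylor se agrees with a
        10^6-draw simulation of the ratio distribution within 5%."""
        num, den = _est(-0.06, 0.0204), _est(0.14, 0.0102)
        assert den.beta / den.se > 10
        iv = iv_ratio(num, den)
        rng = np.random.default_rng(123)
        draws = rng.normal(num.beta, num.se, 1_000_000) / rng.normal(
            den.beta, den.se, 1_000_000
        )
        assert iv.se == pytest.approx(float(np.std(draws)), rel=0.05)


class TestInstrumentF:
    def test_zero_r2(self):
        assert instrument_f(0.0, 100) == 0.0

    @pytest.mark.parametrize(
        "r2,n,expected",
        [(0.0064, 35873, 231.06), (0.0126, 38191, 487.25),
         (0.0097, 32391, 317.25)],
    )
    def test_published_instrument_strengths(self, r2, n, expected):
        assert instrument_f(r2, n) == pytest.approx(expected, abs=0.5)
        assert instrument_f(r2, n) > 200

    def test_monotone_in_both_arguments(self):
        assert instrument_f(0.02, 1000) > instrument_f(0.01, 1000)
        assert instrument_f(0.01, 2000) > instrument_f(0.01, 1000)

    def test_domain_errors(self):
        with pytest.raises(ConfigurationError):
            instrument_f(1.0, 100)
        with pytest.raises(ConfigurationError):
            instrument_f(0.5, 2)


class TestSummaryScore:
    def test_single_snp_identity(self):
        est = _est(0.12, 0.03, n=500)
        out = summary_score([est], weights=[1.0])
        assert out.beta == est.beta and out.se == est.se

    def test_metabolism_score_from_consortium_rows(self):
        """The two published metabolism SNPs combine to 0.002 kg/m^2/allele."""
        rows = [
            _est(0.001, ci_to_se(-0.011, 0.010), n=123864),
            _est(0.003, ci_to_se(-0.008, 0.014), n=123864),
        ]
        out = summary_score(rows)
        assert round(out.beta, 3) == 0.002
        assert out.ci_low == pytest.approx(-0.006, abs=1.5e-3)
        assert out.ci_high == pytest.approx(0.009, abs=1.5e-3)

    def test_equal_se_unit_weights_is_plain_average(self):
        out = summary_score([_est(0.1, 0.05), _est(0.3, 0.05)])
        assert out.beta == pytest.approx(0.2)

    def test_weight_rescaling(self):
        """Halving a SNP's weight doubles its per-score-unit effect and se."""
        out = summary_score([_est(0.1, 0.05)], weights=[0.5])
        assert out.beta == pytest.approx(0.2)
        assert out.se == pytest.approx(0.1)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ConfigurationError):
            summary_score([_est(0.1, 0.05)], weights=[0.0])
        with pytest.raises(ConfigurationError):
            summary_score([], weights=[])


class TestScaleConversion:
    def test_published_per_10_percent_numbers(self):
        iv = iv_ratio(
            _est(-0.06, ci_to_se(-0.10, -0.02)),
            _est(0.14, ci_to_se(0.12, 0.16)),
        )
        scaled = percent_change_per_10pct(iv)
        assert scaled.ratio == pytest.approx(10 * iv.ratio)
        assert scaled.ratio == pytest.approx(-4.2, abs=0.15)
        assert scaled.ci_low == pytest.approx(-7.1, abs=0.15)
        assert scaled.ci_high == pytest.approx(-1.3, abs=0.15)
        assert scaled.p == iv.p

    def test_zero_maps_to_zero(self):
        iv = iv_ratio(_est(0.0, 0.1), _est(2.0, 0.1))
        assert percent_change_per_10pct(iv).ratio == 0.0


class TestIVPower:
    def test_size_equals_level_under_null(self):
        res = iv_power(0.0, 5000, 0.01, resid_sd=0.35, reps=500, seed=3)
        assert abs(res.power - res.alpha) < 3 * max(res.mc_se, 0.01)

    def test_power_increases_with_effect(self):
        strong = iv_power(0.02, 5000, 0.01, reps=500, seed=4)
        weak = iv_power(0.01, 5000, 0.01, reps=500, seed=4)
        assert strong.power > weak.power

    def test_power_increases_with_instrument_strength(self):
        strong = iv_power(0.02, 20000, 0.0126, reps=300, seed=5)
        weak = iv_power(0.02, 20000, 0.0064, reps=300, seed=5)
        assert strong.power > weak.power

    def test_mc_se_is_binomial(self):
        res = iv_power(0.02, 2000, 0.02, reps=200, seed=6)
        assert res.mc_se == pytest.approx(
            np.sqrt(res.power * (1 - res.power) / res.reps)
        )

    def test_preconditions(self):
        with pytest.raises(ConfigurationError):
            iv_power(0.02, 1000, 0.01, reps=50)
        with pytest.raises(ConfigurationError):
            iv_power(0.02, 1000, 1.5, reps=200)
        with pytest.raises(ConfigurationError):
            iv_power(0.02, 1000, 0.01, resid_sd=0.0, reps=200)
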