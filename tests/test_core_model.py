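"""Unit tests for the mathematical core: mean functions, scaling, error laws,
response densities, moments and quantiles."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from emem.core_model import (
    AllometryDataset,
    ErrorDistributionSpec,
    ErrorLaw,
    ErrorStructure,
    Family,
    ProtocolSpec,
    ScalingKind,
    SystematicSpec,
    VarianceScalingSpec,
    error_cdf,
    error_density,
    error_quantile,
    eval_scaling,
    eval_systematic,
    parse_label,
    response_density,
    response_mean_var,
    spec_from_config,
    spec_to_config,
)
from emem.likelihood_fit import KNOWN_LABELS

from conftest import TRUE

INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


class TestSystematic:
    def test_huxley_at_unit_covariate_returns_beta(self):
        spec = SystematicSpec(family=Family.HUXLEY, beta=TRUE["beta"], alpha=TRUE["alpha"])
        assert eval_systematic(spec, [1.0])[0] == pytest.approx(TRUE["beta"], rel=1e-15)

    def test_biphasic_continuous_at_breakpoint(self):
        spec = SystematicSpec(
            family=Family.BIPHASIC, beta=TRUE["beta"], alpha=TRUE["alpha"],
            lam=TRUE["lam"], xb=TRUE["xb"],
        )
        xb = TRUE["xb"]
        left = spec.beta * xb**spec.alpha
        right = spec.beta * xb ** (spec.alpha - spec.lam) * xb**spec.lam
        assert left == pytest.approx(right, rel=1e-12)
        delta = 1e-9 * xb
        w_lo, w_hi = eval_systematic(spec, [xb - delta, xb + delta])
        assert abs(w_lo - w_hi) / w_lo < 1e-6

    def test_biphasic_second_phase_matches_product_form(self):
        # oracle: the f,g product form beta * f(x)^alpha * g(x)^lam evaluated
        # directly must agree with the closed second-phase expression
        spec = SystematicSpec(
            family=Family.BIPHASIC, beta=TRUE["beta"], alpha=TRUE["alpha"],
            lam=TRUE["lam"], xb=TRUE["xb"],
        )
        x = 100.0
        f = min(x, spec.xb)
        g = max(x / spec.xb, 1.0)
        oracle = spec.beta * f**spec.alpha * g**spec.lam
        assert eval_systematic(spec, [x])[0] == pytest.approx(oracle, rel=1e-12)

    def test_through_origin(self):
        for family in (Family.HUXLEY, Family.BIPHASIC):
            spec = SystematicSpec(
                family=family, beta=TRUE["beta"], alpha=TRUE["alpha"],
                lam=TRUE["lam"] if family is Family.BIPHASIC else None,
                xb=TRUE["xb"] if family is Family.BIPHASIC else None,
            )
            assert eval_systematic(spec, [1e-12])[0] < 1e-8

    def test_offset_family(self):
        spec = SystematicSpec(family=Family.HUXLEY_OFFSET, beta=2.0, alpha=0.5, c0=0.25)
        assert eval_systematic(spec, [4.0])[0] == pytest.approx(2.0 * 2.0 + 0.25)

    def test_negative_covariate_rejected(self):
        spec = SystematicSpec(family=Family.HUXLEY, beta=1.0, alpha=1.0)
        with pytest.raises(ValueError):
            eval_systematic(spec, [-1.0])

    def test_biphasic_requires_positive_breakpoint(self):
        with pytest.raises(ValueError):
            SystematicSpec(family=Family.BIPHASIC, beta=1.0, alpha=1.0, lam=1.0, xb=-3.0)

    def test_beyond_xmax_warns_but_evaluates(self):
        spec = SystematicSpec(
            family=Family.BIPHASIC, beta=1.0, alpha=0.5, lam=1.0, xb=10.0, xmax=50.0
        )
        with pytest.warns(UserWarning):
            val = eval_systematic(spec, [80.0])
        assert np.isfinite(val).all()


class TestScaling:
    @pytest.mark.parametrize(
        "xb,c_exp,x,expected",
        [
            (TRUE["xb"], 0.5, 10.0, 1.0),   # below the breakpoint h = 1
            (TRUE["xb"], 2.3, TRUE["xb"], 1.0),  # continuity at xb
            (30.0, 1.0, 60.0, 0.5),         # (30/60)^1, hand evaluation
            (30.0, 2.0, 60.0, 0.25),
        ],
    )
    def test_piecewise_values(self, xb, c_exp, x, expected):
        spec = VarianceScalingSpec(kind=ScalingKind.PIECEWISE, c_exp=c_exp, xb=xb)
        assert eval_scaling(spec, [x])[0] == pytest.approx(expected, rel=1e-12)

    def test_constant_is_one(self):
        assert np.all(eval_scaling(VarianceScalingSpec(), [0.1, 5.0, 1e4]) == 1.0)

    def test_nonincreasing_beyond_breakpoint(self):
        spec = VarianceScalingSpec(kind=ScalingKind.PIECEWISE, c_exp=0.7, xb=30.0)
        x = np.linspace(30.0, 500.0, 100)
        h = eval_scaling(spec, x)
        assert np.all(np.diff(h) <= 0) and np.all(h <= 1.0)

    def test_nonpositive_covariate_rejected(self):
        with pytest.raises(ValueError):
            eval_scaling(VarianceScalingSpec(), [0.0])


class TestErrorLaw:
    def test_normal_mode(self):
        spec = ErrorDistributionSpec(law=ErrorLaw.NORMAL, sigma=1.0)
        assert error_density(spec, [0.0])[0] == pytest.approx(INV_SQRT2PI, rel=1e-12)

    def test_degenerate_mixture_collapses_to_normal(self):
        mix = ErrorDistributionSpec(
            law=ErrorLaw.NORMAL_MIXTURE, weights=(0.5, 0.5), sds=(1.0, 1.0)
        )
        single = ErrorDistributionSpec(law=ErrorLaw.NORMAL, sigma=1.0)
        e = np.linspace(-4, 4, 41)
        np.testing.assert_allclose(
            error_density(mix, e), error_density(single, e), rtol=0, atol=1e-12
        )

    def test_mixture_density_integrates_to_one(self, mixture_error):
        total, err = integrate.quad(
            lambda e: error_density(mixture_error, np.array(e)), -np.inf, np.inf
        )
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_mixture_overall_sd(self, mixture_error):
        expected = math.sqrt(0.3 * 0.25 + 0.7 * 4.0)
        assert mixture_error.overall_sd == pytest.approx(expected, rel=1e-12)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            ErrorDistributionSpec(
                law=ErrorLaw.NORMAL_MIXTURE, weights=(0.5, 0.4), sds=(1.0, 2.0)
            )

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            ErrorDistributionSpec(law=ErrorLaw.NORMAL, sigma=0.0)


class TestErrorQuantile:
    def test_normal_median_zero(self):
        spec = ErrorDistributionSpec(law=ErrorLaw.NORMAL, sigma=1.0)
        assert error_quantile(spec, [0.5])[0] == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_mixture_matches_standard_normal(self):
        mix = ErrorDistributionSpec(
            law=ErrorLaw.NORMAL_MIXTURE, weights=(0.5, 0.5), sds=(1.0, 1.0)
        )
        assert error_quantile(mix, [0.975])[0] == pytest.approx(1.959964, abs=1e-6)

    def test_quantile_cdf_roundtrip(self, mixture_error):
        q = np.linspace(0.01, 0.99, 99)
        e = error_quantile(mixture_error, q)
        assert np.all(np.diff(e) > 0)
        np.testing.assert_allclose(error_cdf(mixture_error, e), q, atol=1e-8)

    def test_mixture_quantile_against_bisection_oracle(self, mixture_error):
        # independent oracle: bisection on the quadrature CDF
        from scipy.optimize import bisect

        def cdf_quad(t):
            val, _ = integrate.quad(
                lambda e: error_density(mixture_error, np.array(e)), -30.0, t
            )
            return val

        target = 0.9
        oracle = bisect(lambda t: cdf_quad(t) - target, -10.0, 10.0, xtol=1e-10)
        assert error_quantile(mixture_error, [target])[0] == pytest.approx(
            oracle, abs=1e-7
        )

    def test_out_of_range_probability_rejected(self, mixture_error):
        with pytest.raises(ValueError):
            error_quantile(mixture_error, [0.0])


class TestResponseDensity:
    def test_reduces_to_standard_lognormal(self):
        proto = ProtocolSpec(
            error_structure=ErrorStructure.MULTIPLICATIVE,
            systematic=SystematicSpec(family=Family.HUXLEY, beta=1.0, alpha=1.0),
            error=ErrorDistributionSpec(law=ErrorLaw.NORMAL, sigma=1.0),
        )
        assert response_density(proto, 1.0, 1.0) == pytest.approx(INV_SQRT2PI, rel=1e-12)
        # cross-check against scipy's lognormal on a grid
        y = np.linspace(0.1, 5.0, 30)
        np.testing.assert_allclose(
            response_density(proto, np.ones_like(y), y),
            stats.lognorm.pdf(y, s=1.0),
            rtol=1e-12,
        )

    def test_additive_mode(self):
        proto = ProtocolSpec(
            error_structure=ErrorStructure.ADDITIVE,
            systematic=SystematicSpec(family=Family.HUXLEY, beta=2.0, alpha=0.0),
            error=ErrorDistributionSpec(law=ErrorLaw.NORMAL, sigma=1.0),
        )
        assert response_density(proto, 1.0, 2.0) == pytest.approx(INV_SQRT2PI, rel=1e-12)

    def test_nonpositive_response_has_zero_density(self, huxley_protocol):
        assert response_density(huxley_protocol, 10.0, -1.0) == 0.0
        assert response_density(huxley_protocol, 10.0, 0.0) == 0.0

    @pytest.mark.parametrize("label_protocol", ["mixture", "piecewise"])
    def test_density_integrates_to_one(self, label_protocol, hp_protocol, huxley_protocol):
        proto = hp_protocol if label_protocol == "piecewise" else ProtocolSpec(
            error_structure=ErrorStructure.MULTIPLICATIVE,
            systematic=huxley_protocol.systematic,
            error=ErrorDistributionSpec(
                law=ErrorLaw.NORMAL_MIXTURE, weights=(0.3, 0.7), sds=(0.05, 0.2)
            ),
        )
        x = 100.0
        mu, _ = response_mean_var(proto, np.array([x]))
        total, err = integrate.quad(
            lambda y: float(response_density(proto, x, y)),
            0.0,
            50.0 * mu[0],
            limit=500,
            points=[0.5 * mu[0], mu[0], 2.0 * mu[0]],
        )
        assert total == pytest.approx(1.0, abs=1e-8)


class TestResponseMoments:
    def test_lognormal_mean_identity(self, huxley_protocol):
        x = np.array([5.0, 50.0])
        mu, var = response_mean_var(huxley_protocol, x)
        w = eval_systematic(huxley_protocol.systematic, x)
        sigma = huxley_protocol.error.sigma
        np.testing.assert_allclose(mu, w * np.exp(sigma**2 / 2), rtol=1e-12)
        np.testing.assert_allclose(
            var, w**2 * (np.exp(2 * sigma**2) - np.exp(sigma**2)), rtol=1e-12
        )

    def test_degenerate_sigma_limit(self):
        proto = ProtocolSpec(
            error_structure=ErrorStructure.MULTIPLICATIVE,
            systematic=SystematicSpec(family=Family.HUXLEY, beta=2.0, alpha=0.5),
            error=ErrorDistributionSpec(law=ErrorLaw.NORMAL, sigma=1e-12),
        )
        mu, var = response_mean_var(proto, np.array([9.0]))
        assert mu[0] == pytest.approx(6.0, rel=1e-9)
        assert var[0] == pytest.approx(0.0, abs=1e-12)

    def test_mixture_moments_match_monte_carlo(self, mixture_error):
        # oracle: direct simulation of exp(eps); 1e6 draws, 3 MC standard errors
        proto = ProtocolSpec(
            error_structure=ErrorStructure.MULTIPLICATIVE,
            systematic=SystematicSpec(family=Family.HUXLEY, beta=1.0, alpha=0.0),
            error=mixture_error,
        )
        mu, var = response_mean_var(proto, np.array([1.0]))
        rng = np.random.default_rng(42)
        n = 10**6
        comp = rng.choice(2, size=n, p=mixture_error.component_weights)
        eps = rng.normal(0, 1, n) * mixture_error.component_sds[comp]
        draws = np.exp(eps)
        mc_se = draws.std() / math.sqrt(n)
        assert abs(mu[0] - draws.mean()) < 3 * mc_se

    def test_additive_bp_variance_grows_linearly(self):
        proto = ProtocolSpec(
            error_structure=ErrorStructure.ADDITIVE_BP,
            systematic=SystematicSpec(family=Family.HUXLEY, beta=1.0, alpha=1.0),
            error=ErrorDistributionSpec(law=ErrorLaw.NORMAL, sigma=0.5),
            bp_k=0.01,
        )
        _, var = response_mean_var(proto, np.array([0.0, 100.0]))
        assert var[0] == pytest.approx(0.25)
        assert var[1] == pytest.approx((0.5 * 2.0) ** 2)


class TestSpecPlumbing:
    @pytest.mark.parametrize("label", KNOWN_LABELS)
    def test_label_grammar_roundtrip(self, label):
        parsed = parse_label(label)
        if parsed["scaling"] is None:
            rebuilt = f"({parsed['error_structure'].value}, {parsed['family'].value}, {parsed['law'].value})"
        else:
            rebuilt = (
                f"(EMEM, {parsed['family'].value}, {parsed['scaling'].value}, "
                f"{parsed['law'].value})"
            )
        assert rebuilt == label

    def test_config_roundtrip(self, hp_protocol):
        cfg = spec_to_config(hp_protocol)
        back = spec_from_config(cfg)
        assert back.label == hp_protocol.label
        assert back.systematic == hp_protocol.systematic
        np.testing.assert_allclose(back.error.sds, hp_protocol.error.sds)

    def test_additive_requires_normal_law(self, mixture_error):
        with pytest.raises(ValueError):
            ProtocolSpec(
                error_structure=ErrorStructure.ADDITIVE,
                systematic=SystematicSpec(family=Family.HUXLEY, beta=1.0, alpha=1.0),
                error=mixture_error,
            )

    def test_dataset_length_mismatch(self):
        with pytest.raises(ValueError):
            AllometryDataset(x=np.array([1.0, 2.0]), y=np.array([1.0]))

    def test_dataset_positivity_guard(self):
        d = AllometryDataset(x=np.array([1.0, 2.0]), y=np.array([1.0, -1.0]))
        with pytest.raises(ValueError):
            d.require_positive()
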