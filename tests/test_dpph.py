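import numpy as np
import pytest

from antioxkit.dpph import (
    absorbance_to_dpph,
    dpph_to_absorbance,
    fit_kobs_excess_antioxidant,
    fit_kobs_excess_dpph,
    kobs_loglinear,
    second_order_constant,
)
from antioxkit.exceptions import DomainError, InsufficientDataError


class TestCalibration:
    def test_zero_absorbance_maps_to_printed_constant_ratio(self):
        assert absorbance_to_dpph(0.0) == pytest.approx(2.58e-3 / 12509)

    def test_direct_substitution(self):
        assert absorbance_to_dpph(1.25087) == pytest.approx(1.002e-4, rel=1e-3)

    @pytest.mark.parametrize("a", [0.1, 0.5, 1.0])
    def test_round_trip(self, a):
        assert dpph_to_absorbance(absorbance_to_dpph(a)) == pytest.approx(a, abs=1e-12)

    def test_strictly_increasing_and_affine(self):
        a = np.linspace(0, 2, 50)
        c = absorbance_to_dpph(a)
        assert np.all(np.diff(c) > 0)
        second_diff = np.diff(c, 2)
        assert np.allclose(second_diff, 0.0, atol=1e-18)

    def test_negative_absorbance_rejected(self):
        with pytest.raises(DomainError):
            absorbance_to_dpph(-0.01)


class TestKobsFits:
    def test_excess_dpph_noiseless_self_consistency(self):
        t = np.linspace(0, 3600, 40)
        kobs = 1e-3
        d = 70.0 - 1.0 * 15.0 * (1 - np.exp(-kobs * t))
        fit = fit_kobs_excess_dpph(t, d, dpph0=70.0, aox0=15.0)
        assert fit.kobs == pytest.approx(kobs, abs=1e-8)

    def test_flat_series_gives_zero_kobs(self):
        t = np.linspace(0, 3600, 10)
        fit = fit_kobs_excess_dpph(t, np.full_like(t, 70.0), dpph0=70.0, aox0=15.0)
        assert fit.kobs == pytest.approx(0.0, abs=1e-8)

    def test_excess_antioxidant_exact_exponential(self):
        t = np.linspace(0, 7200, 30)
        d = 70.0 * np.exp(-5e-4 * t)
        fit = fit_kobs_excess_antioxidant(t, d)
        assert fit.kobs == pytest.approx(5e-4, abs=1e-9)

    def test_constant_series_gives_zero_kobs(self):
        t = np.linspace(0, 3600, 10)
        fit = fit_kobs_excess_antioxidant(t, np.full_like(t, 55.0))
        assert fit.kobs == pytest.approx(0.0, abs=1e-9)

    def test_loglinear_and_nonlinear_agree_on_noiseless_data(self):
        t = np.linspace(0, 5000, 25)
        d = 60.0 * np.exp(-8e-4 * t)
        nls = fit_kobs_excess_antioxidant(t, d)
        lin = kobs_loglinear(t, d)
        assert nls.kobs == pytest.approx(lin.kobs, abs=1e-6)

    def test_regime_consistency_when_antioxidant_is_trace(self):
        """With [DPPH]0 >> [AH]0 both regime fits see the same rate constant."""
        t = np.linspace(0, 3600, 60)
        k2, dpph0, aox0 = 1e-5, 70.0, 0.5
        kobs_true = k2 * dpph0
        aox = aox0 * np.exp(-kobs_true * t)
        dpph = dpph0 - (aox0 - aox)
        bounded = fit_kobs_excess_dpph(t, dpph, dpph0=dpph0, aox0=aox0)
        exponential = fit_kobs_excess_antioxidant(t, aox)
        tol = max(bounded.se, exponential.se, 1e-9)
        assert abs(bounded.kobs - exponential.kobs) <= max(3 * tol, 1e-6 * kobs_true)

    def test_biphasic_decay_gives_larger_constant_on_short_window(self):
        """A fast initial phase plus a slow tail: the 60-minute window sees
        the fast phase, the 24-hour window mostly the slow one, so the
        short-window rate constant must come out larger."""
        t24 = np.linspace(0, 86400, 200)
        aox0, dpph0 = 15.0, 70.0
        consumed = aox0 * (0.6 * (1 - np.exp(-2e-3 * t24)) +
                           0.4 * (1 - np.exp(-2e-5 * t24)))
        d = dpph0 - consumed
        short = t24 <= 3600
        k60 = fit_kobs_excess_dpph(t24[short], d[short], dpph0, aox0).kobs
        k24 = fit_kobs_excess_dpph(t24, d, dpph0, aox0).kobs
        assert k60 > k24

    def test_preconditions(self):
        t = np.linspace(0, 100, 10)
        with pytest.raises(DomainError):
            fit_kobs_excess_dpph(t, np.ones(10), dpph0=5.0, aox0=10.0)
        with pytest.raises(InsufficientDataError):
            fit_kobs_excess_dpph(t[:3], np.ones(3), dpph0=70.0, aox0=10.0)
        with pytest.raises(DomainError):
            fit_kobs_excess_antioxidant(t, -np.ones(10))


class TestSecondOrderConstant:
    def test_exact_line_through_origin(self):
        fit = second_order_constant({10.0: 1e-4, 20.0: 2e-4, 30.0: 3e-4})
        assert fit.k2 == pytest.approx(1e-5, rel=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-18)

    def test_constant_kobs_gives_zero_slope(self):
        fit = second_order_constant({10.0: 2e-4, 20.0: 2e-4, 30.0: 2e-4})
        assert fit.k2 == pytest.approx(0.0, abs=1e-18)

    def test_slope_invariant_to_constant_offset(self, rng):
        conc = np.array([5.0, 10, 20, 40])
        kobs = 3e-6 * conc + rng.normal(0, 1e-7, 4)
        f1 = second_order_constant(conc, kobs)
        f2 = second_order_constant(conc, kobs + 7e-4)
        assert f1.k2 == pytest.approx(f2.k2, rel=1e-12)

    def test_needs_three_points(self):
        with pytest.raises(InsufficientDataError):
            second_order_constant({10.0: 1e-4, 20.0: 2e-4})
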