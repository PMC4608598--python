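import numpy as np
import pytest

from antioxkit.deoxyribose import (
    BlankSet,
    CompetitionModel,
    competition_analysis,
    correct_absorbance,
    dr2_blank_correct,
    dr2_ic50,
    dr2_inhibition_curve,
)
from antioxkit.exceptions import DomainError, InsufficientDataError, ProOxidantWarning
from antioxkit.simulate import dr2_spec, simulate_dr2

K_DR = 3.1e9  # test value for the probe + OH* rate constant, M^-1 s^-1


class TestBlankCorrection:
    def test_direct_substitution(self):
        assert correct_absorbance(BlankSet(1.0, 0.2, 0.3, 0.1)) == pytest.approx(0.8)

    def test_no_blank_identity(self):
        assert correct_absorbance(BlankSet(0.73, 0.2, 0.2, 0.0)) == pytest.approx(0.73)

    def test_full_self_degradation(self):
        got = correct_absorbance(BlankSet(0.5, 0.2, 0.3, 0.5))
        assert got == pytest.approx(0.0 - (0.3 - 0.2))

    def test_negative_result_warns_not_raises(self):
        with pytest.warns(ProOxidantWarning):
            value = correct_absorbance(BlankSet(0.1, 0.0, 0.3, 0.05))
        assert value < 0

    def test_negative_blank_rejected(self):
        with pytest.raises(DomainError):
            BlankSet(0.5, -0.1, 0.2, 0.0)

    def test_correction_is_linear_with_unit_coefficients(self, rng):
        """Finite differences recover coefficients (+1, +1, -1, -1)."""
        base = rng.uniform(0.1, 1.0, size=4)
        h = 1e-6
        coeffs = []
        for i in range(4):
            args_hi = base.copy(); args_hi[i] += h
            args_lo = base.copy(); args_lo[i] -= h
            d = (correct_absorbance(BlankSet(*args_hi))
                 - correct_absorbance(BlankSet(*args_lo))) / (2 * h)
            coeffs.append(round(d, 6))
        assert coeffs == [1.0, 1.0, -1.0, -1.0]


def _competition_points(k_s, a0=0.9, dr_conc=2.5e-3, conc_uM=(10, 25, 50, 100, 200)):
    conc = np.array(conc_uM, dtype=float)
    a = a0 / (1.0 + k_s * conc * 1e-6 / (K_DR * dr_conc))
    return conc, a


class TestCompetitionAnalysis:
    def test_exact_points_recover_k_s(self):
        k_s = 9.05e9
        conc, a = _competition_points(k_s)
        fit = competition_analysis((conc, a), a0=0.9, k_dr=K_DR, dr_conc=2.5e-3)
        assert fit.linearity == "linear"
        assert fit.k_s == pytest.approx(k_s, rel=1e-3)

    def test_constant_absorbance_gives_zero_k_s(self):
        conc = np.array([10.0, 25, 50, 100])
        fit = competition_analysis((conc, np.full(4, 0.8)), a0=0.8, k_dr=K_DR)
        assert fit.k_s == pytest.approx(0.0, abs=1e-3)  # numerically zero vs the 1e9-1e10 scale

    def test_quadratic_contamination_flagged_nonlinear(self):
        conc, a = _competition_points(9.05e9)
        x = 9.05e9 * conc * 1e-6 / (K_DR * 2.5e-3)
        a_bent = 0.9 / (1.0 + x + 3.0 * x**2)
        fit = competition_analysis((conc, a_bent), a0=0.9, k_dr=K_DR)
        assert fit.linearity == "nonlinear"
        assert fit.dual_mode
        assert np.isnan(fit.k_s)

    def test_k_s_scales_linearly_with_supplied_k_dr(self):
        conc, a = _competition_points(5e9)
        f1 = competition_analysis((conc, a), a0=0.9, k_dr=K_DR)
        f2 = competition_analysis((conc, a), a0=0.9, k_dr=2 * K_DR)
        assert f2.k_s == pytest.approx(2 * f1.k_s, rel=1e-12)

    def test_preconditions(self):
        conc = np.array([10.0, 25, 50])
        with pytest.raises(InsufficientDataError):
            CompetitionModel(conc, np.full(3, 0.5), 0.9, K_DR)
        with pytest.raises(DomainError):
            CompetitionModel(np.array([10.0, 25, 50, 100]), np.array([0.5, 0.4, -0.1, 0.2]), 0.9, K_DR)
        with pytest.raises(DomainError):
            CompetitionModel(np.array([10.0, 25, 50, 100]), np.full(4, 0.5), 0.9, k_dr=0.0)


class TestTableChain:
    def test_blank_correction_recovers_generating_curve(self):
        spec = dr2_spec(k_s=9.05e9, k_dr=K_DR, seed=5, noise_sd=0.0)
        table = simulate_dr2(spec)
        conc, corrected, a0 = dr2_blank_correct(table, "cmpd")
        assert a0 == pytest.approx(spec.true_params["a0"], abs=1e-12)
        fit = CompetitionModel(conc, corrected, a0, K_DR, 2.5e-3).fit()
        assert fit.k_s == pytest.approx(9.05e9, rel=1e-3)

    def test_ic50_chain_with_known_truth(self):
        ic50 = 45.0
        k_s = K_DR * 2.5e-3 / (ic50 * 1e-6)
        spec = dr2_spec(
            k_s=k_s, k_dr=K_DR, seed=6,
            concentrations_uM=(11.25, 22.5, 45.0, 90.0, 180.0),
        )
        curve = dr2_inhibition_curve(simulate_dr2(spec), "cmpd")
        fit = dr2_ic50(curve, n_boot=200, seed=7)
        assert fit.crossing_found
        assert fit.ci[0] <= ic50 <= fit.ci[1]

    def test_all_negative_inhibition_has_no_crossing(self):
        # a pro-oxidant raises probe degradation above the control at every dose
        spec = dr2_spec(k_s=-1e9, k_dr=K_DR, seed=8, noise_sd=0.0)
        curve = dr2_inhibition_curve(simulate_dr2(spec), "cmpd")
        assert np.all(curve.group_means()[1] < 0)
        fit = dr2_ic50(curve, n_boot=0)
        assert not fit.crossing_found
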