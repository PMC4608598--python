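import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from antioxkit.doseresponse import (
    FivePLModel,
    ResponseCurve,
    five_pl,
    fit_5pl,
    percent_aoa,
    percent_dpph_remaining,
    percent_inhibition,
    steady_state_signal,
)
from antioxkit.exceptions import DegenerateControlError, DomainError, ValidationError


class TestResponsePercentages:
    @pytest.mark.parametrize(
        "a0, af, expected",
        [(0.8, 0.4, 50.0), (0.7, 0.7, 100.0), (0.9, 0.0, 0.0)],
    )
    def test_percent_dpph_remaining(self, a0, af, expected):
        assert percent_dpph_remaining(a0, af) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "a0, a_s, expected",
        [(0.5, 0.25, 50.0), (0.5, 0.5, 0.0), (0.5, 0.6, -20.0)],
    )
    def test_percent_inhibition_sign_convention(self, a0, a_s, expected):
        assert percent_inhibition(a0, a_s) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "as0, as10, ac0, ac10, expected",
        [
            (0.6, 0.6, 0.6, 0.4, 100.0),   # no sample bleaching: full protection
            (0.6, 0.4, 0.6, 0.4, 0.0),     # sample drop equals control drop
            (0.6, 0.2, 0.6, 0.4, -100.0),  # double the control drop: pro-oxidant
        ],
    )
    def test_percent_aoa(self, as0, as10, ac0, ac10, expected):
        assert percent_aoa(as0, as10, ac0, ac10) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            percent_dpph_remaining(0.0, 0.5)
        with pytest.raises(DomainError):
            percent_inhibition(-0.1, 0.5)
        with pytest.raises(DegenerateControlError):
            percent_aoa(0.5, 0.4, 0.6, 0.6)

    @given(st.floats(0.01, 2.0), st.floats(0.0, 2.0))
    @settings(max_examples=50, deadline=None)
    def test_remaining_plus_scavenged_is_complete(self, a0, af):
        remaining = percent_dpph_remaining(a0, af)
        scavenged = (1 - af / a0) * 100.0
        assert remaining + scavenged == pytest.approx(100.0, abs=1e-9)


# ---------------------------------------------------------------------------
# independent 4PL oracle: profile the linear parameters on a (logC, B) grid,
# then polish with Nelder-Mead — shares no code with the 5PL fitter
# ---------------------------------------------------------------------------

def _fit_4pl_oracle(x, y):
    logx = np.log10(x)

    def profile_rss(v):
        logc, b = v
        w = 1.0 / (1.0 + 10.0 ** (b * (logc - logx)))  # weight toward asymptote A
        X = np.column_stack([1.0 - w, w])               # y = D*(1-w) + A*w
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r), beta

    best = None
    for logc in np.linspace(logx.min() - 1, logx.max() + 1, 40):
        for b in np.geomspace(0.1, 10, 25):
            rss, beta = profile_rss((logc, b))
            if best is None or rss < best[0]:
                best = (rss, (logc, b), beta)
    res = optimize.minimize(
        lambda v: profile_rss(v)[0], best[1], method="Nelder-Mead",
        options=dict(xatol=1e-12, fatol=1e-14, maxiter=20000, maxfev=20000),
    )
    rss, beta = profile_rss(res.x)
    d, a = beta
    return dict(D=d, A=a, logC=res.x[0], B=res.x[1], rss=rss)


class TestFivePL:
    def _curve(self, x, y, kind="percent_inhibition"):
        return ResponseCurve("t", x, y, kind)

    def test_noiseless_recovery_of_criterion_crossing(self):
        x = np.repeat([2.0, 5, 10, 15, 25, 40, 80, 150], 3)
        y = five_pl(x, 100.0, 0.0, np.log10(15.0), 1.2, 1.0)
        fit = fit_5pl(self._curve(x, y, "percent_dpph_remaining"), n_boot=0)
        assert fit.crossing_found
        assert fit.ec50 == pytest.approx(15.0, rel=1e-4)
        # fitted curve at the crossing equals the criterion
        assert fit.predict(fit.ec50) == pytest.approx(50.0, abs=1e-6)

    def test_agrees_with_independent_4pl_oracle(self):
        """With asymmetry frozen at 1, the fit must match a grid+refine 4PL."""
        rng = np.random.default_rng(7)
        x = np.array([1.0, 2, 4, 8, 15, 30, 60, 120, 250, 500])
        y = five_pl(x, 5.0, 95.0, np.log10(20.0), 1.1, 1.0) + rng.normal(0, 1.0, 10)
        fit = fit_5pl(self._curve(x, y), n_boot=0, fix_asymmetry=1.0)
        oracle = _fit_4pl_oracle(x, y)
        assert fit.params.D == pytest.approx(oracle["D"], abs=1e-6)
        assert fit.params.A == pytest.approx(oracle["A"], abs=1e-6)
        assert np.log10(fit.params.C) == pytest.approx(oracle["logC"], abs=1e-6)
        assert fit.params.B == pytest.approx(oracle["B"], abs=1e-6)

    def test_invariant_to_replicate_ordering(self):
        rng = np.random.default_rng(3)
        x = np.repeat([5.0, 10, 20, 40, 80], 3)
        y = five_pl(x, 0.0, 100.0, np.log10(18.0), 1.5, 1.3) + rng.normal(0, 1, x.size)
        perm = rng.permutation(x.size)
        f1 = fit_5pl(self._curve(x, y), n_boot=0)
        f2 = fit_5pl(self._curve(x[perm], y[perm]), n_boot=0)
        assert f1.ec50 == pytest.approx(f2.ec50, rel=1e-9)

    def test_concentration_rescaling_rescales_ec50(self):
        rng = np.random.default_rng(4)
        x = np.repeat([5.0, 10, 20, 40, 80], 3)
        y = five_pl(x, 0.0, 100.0, np.log10(18.0), 1.5, 1.3) + rng.normal(0, 1, x.size)
        f1 = fit_5pl(self._curve(x, y), n_boot=0)
        f2 = fit_5pl(self._curve(x * 10.0, y), n_boot=0)
        assert f2.ec50 == pytest.approx(10.0 * f1.ec50, rel=1e-6)

    def test_monotone_noiseless_crossing_is_bracketed_by_design(self):
        x = np.array([5.0, 10, 20, 40, 80])
        y = five_pl(x, 100.0, 0.0, np.log10(22.0), 1.4, 2.0)
        fit = fit_5pl(self._curve(x, y, "percent_dpph_remaining"), n_boot=0)
        below = x[y > 50].max()
        above = x[y < 50].min()
        assert below < fit.ec50 < above

    def test_criterion_outside_range_flags_no_crossing(self):
        x = np.repeat([5.0, 10, 20, 40], 3)
        y = np.full_like(x, 5.0)  # never approaches 50%
        fit = fit_5pl(ResponseCurve("flat", x, y), n_boot=0)
        assert not fit.crossing_found
        assert np.isnan(fit.ec50)

    def test_bootstrap_ci_brackets_estimate_and_is_seed_deterministic(self):
        rng = np.random.default_rng(5)
        x = np.repeat([5.0, 10, 20, 40], 3)
        y = five_pl(x, 0.0, 100.0, np.log10(18.0), 1.5, 1.0) + rng.normal(0, 2, x.size)
        c = self._curve(x, y)
        f1 = fit_5pl(c, n_boot=100, seed=11)
        f2 = fit_5pl(c, n_boot=100, seed=11)
        assert f1.ci == f2.ci
        assert f1.ci[0] <= f1.ec50 <= f1.ci[1]

    def test_requires_three_distinct_concentrations(self):
        with pytest.raises(ValidationError):
            ResponseCurve("t", [1.0, 1.0, 2.0], [10.0, 11.0, 50.0])


class TestSteadyState:
    def test_plateau_detected(self):
        t = np.linspace(0, 1000, 21)
        s = 0.5 + 0.3 * np.exp(-t / 50.0)  # flat well before the end
        value, steady = steady_state_signal(t, s, window_s=1000.0)
        assert steady
        assert value == pytest.approx(0.5, abs=1e-3)

    def test_still_drifting_flagged(self):
        t = np.linspace(0, 1000, 21)
        s = 0.8 - 1e-4 * t  # slope 1e-4 AU/s, above the 1e-5 tolerance
        _, steady = steady_state_signal(t, s, window_s=1000.0)
        assert not steady
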