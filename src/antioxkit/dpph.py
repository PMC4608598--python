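"""DPPH radical-scavenging kinetics.

The stable radical DPPH absorbs at 516 nm; its concentration follows from a
linear calibration, [DPPH] = (A + 2.58e-3) / 12509 mol/L.  Scavenging by an
antioxidant AH is second order overall; under pseudo-first-order conditions
a single-exponential observed rate constant kobs can be extracted in two
regimes:

* excess DPPH (the usual case):   [DPPH](t) = [DPPH]0 - s*[AH]0*(1 - e^(-kobs*t))
* excess antioxidant (slow compounds needing high doses):
                                  [DPPH](t) = [DPPH]0 * e^(-kobs*t)

``s`` is the stoichiometric factor (radicals consumed per antioxidant,
default 1).  The second-order constant k2 follows from how kobs varies with
the co-reactant concentration.  In the excess-antioxidant regime
kobs = k2*[AH]0, so k2 is the plain slope of kobs against [AH]0
(:func:`second_order_constant`).  In the excess-DPPH regime kobs tracks the
*DPPH* concentration, kobs ~ k2*[DPPH]_eff, so the pipeline regresses kobs
on [AH]0 and reads k2 off the intercept extrapolated to [AH]0 = 0, where
pseudo-first-order behaviour is exact and [DPPH]_eff = [DPPH]0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .doseresponse import ResponseCurve, percent_dpph_remaining, steady_state_signal
from .exceptions import DomainError, InsufficientDataError, KineticFitError
from .io import TimeCourseTable

__all__ = [
    "CAL_SLOPE_AU_PER_M",
    "CAL_SHIFT_AU",
    "absorbance_to_dpph",
    "dpph_to_absorbance",
    "KobsFit",
    "fit_kobs_excess_dpph",
    "fit_kobs_excess_antioxidant",
    "kobs_loglinear",
    "SecondOrderFit",
    "second_order_constant",
    "DPPHKineticsResults",
    "fit_dpph_second_order",
    "dpph_response_curve",
]

#: calibration line of the 516 nm absorbance against [DPPH] in mol/L
CAL_SLOPE_AU_PER_M = 12509.0
CAL_SHIFT_AU = 2.58e-3


def absorbance_to_dpph(a):
    """Convert 516 nm absorbance to [DPPH] in mol/L via the calibration line."""
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise DomainError("absorbance must be >= 0")
    out = (a + CAL_SHIFT_AU) / CAL_SLOPE_AU_PER_M
    return float(out) if out.ndim == 0 else out


def dpph_to_absorbance(conc_M):
    """Inverse calibration: [DPPH] in mol/L to 516 nm absorbance."""
    conc_M = np.asarray(conc_M, dtype=float)
    if np.any(conc_M < 0):
        raise DomainError("concentration must be >= 0")
    out = CAL_SLOPE_AU_PER_M * conc_M - CAL_SHIFT_AU
    return float(out) if out.ndim == 0 else out


@dataclass
class KobsFit:
    """A pseudo-first-order observed rate constant with its fit SE."""

    kobs: float                 # s^-1
    se: float                   # s^-1
    regime: str                 # 'excess_dpph' | 'excess_antioxidant'
    n_points: int

    def summary(self) -> str:
        return (
            f"kobs = {self.kobs:.4g} +/- {self.se:.2g} s^-1 "
            f"({self.regime}, n={self.n_points})"
        )


def _curve_fit_kobs(model, t, y, p0, bounds):
    try:
        popt, pcov = optimize.curve_fit(
            model, t, y, p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - divergence is data-driven
        raise KineticFitError(f"kinetic fit diverged: {exc}") from exc
    return popt, pcov


def fit_kobs_excess_dpph(time_s, dpph, dpph0, aox0, s: float = 1.0) -> KobsFit:
    """kobs under excess DPPH from the bounded-consumption exponential.

    Fits ``[DPPH](t) = dpph0 - s*aox0*(1 - exp(-kobs*t))`` with kobs the
    only free parameter; ``dpph0`` and ``aox0`` are the known initial
    concentrations (any consistent unit).
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(dpph, dtype=float)
    if not (dpph0 > aox0 > 0):
        raise DomainError("excess-DPPH regime requires dpph0 > aox0 > 0")
    if t.size < 5:
        raise InsufficientDataError("need at least 5 time points")

    def model(tt, k):
        return dpph0 - s * aox0 * (1.0 - np.exp(-k * tt))

    drop = dpph0 - y
    frac = np.clip(drop / (s * aox0), 1e-6, 1 - 1e-6)
    with np.errstate(divide="ignore"):
        k0_cands = -np.log(1 - frac[t > 0]) / t[t > 0]
    k0 = float(np.median(k0_cands)) if k0_cands.size else 1e-4
    k0 = min(max(k0, 1e-12), 10.0)
    popt, pcov = _curve_fit_kobs(model, t, y, [k0], ([0.0], [np.inf]))
    se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.nan
    return KobsFit(float(popt[0]), se, "excess_dpph", t.size)


def kobs_loglinear(time_s, dpph) -> KobsFit:
    """kobs from the linear regression of ln[DPPH] against time.

    The closed-form counterpart of :func:`fit_kobs_excess_antioxidant`; the
    two must agree on noiseless exponential data.
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(dpph, dtype=float)
    if np.any(y <= 0):
        raise DomainError("concentrations must be positive for a log fit")
    if t.size < 2:
        raise InsufficientDataError("need at least 2 time points")
    res = stats.linregress(t, np.log(y))
    return KobsFit(float(-res.slope), float(res.stderr), "excess_antioxidant", t.size)


def fit_kobs_excess_antioxidant(time_s, dpph) -> KobsFit:
    """kobs under excess antioxidant from ``[DPPH](t) = [DPPH]0*e^(-kobs*t)``."""
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(dpph, dtype=float)
    if np.any(y <= 0):
        raise DomainError("concentrations must be positive")
    if t.size < 5:
        raise InsufficientDataError("need at least 5 time points")
    start = kobs_loglinear(t, y)

    def model(tt, d0, k):
        return d0 * np.exp(-k * tt)

    p0 = [float(y[np.argmin(t)]), max(start.kobs, 0.0)]
    popt, pcov = _curve_fit_kobs(model, t, y, p0, ([0.0, 0.0], [np.inf, np.inf]))
    se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.nan
    return KobsFit(float(popt[1]), se, "excess_antioxidant", t.size)


@dataclass
class SecondOrderFit:
    """OLS line through (concentration, kobs) points."""

    k2: float            # slope, conc^-1 s^-1
    se: float
    intercept: float     # s^-1
    intercept_se: float
    r_squared: float
    n_points: int

    def summary(self) -> str:
        return (
            f"second-order constant k2 = {self.k2:.4g} +/- {self.se:.2g} "
            f"(intercept {self.intercept:.4g} +/- {self.intercept_se:.2g} s^-1, "
            f"R^2 = {self.r_squared:.4f}, n = {self.n_points})"
        )


def second_order_constant(conc, kobs=None) -> SecondOrderFit:
    """Second-order rate constant as the OLS slope of kobs vs concentration.

    The intercept is reported but not constrained to zero.  Accepts a
    mapping ``{conc: kobs}`` or two aligned arrays.
    """
    if isinstance(conc, dict):
        items = sorted(conc.items())
        conc = np.array([c for c, _ in items], dtype=float)
        kobs = np.array([k for _, k in items], dtype=float)
    else:
        conc = np.asarray(conc, dtype=float)
        kobs = np.asarray(kobs, dtype=float)
    if conc.size < 3:
        raise InsufficientDataError("need at least 3 concentrations")
    res = stats.linregress(conc, kobs)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
    return SecondOrderFit(
        k2=float(res.slope),
        se=float(res.stderr),
        intercept=float(res.intercept),
        intercept_se=float(res.intercept_stderr),
        r_squared=r2,
        n_points=int(conc.size),
    )


# ---------------------------------------------------------------------------
# pipeline over time-course tables
# ---------------------------------------------------------------------------

@dataclass
class DPPHKineticsResults:
    """Per-concentration kobs and the derived second-order constant."""

    compound_id: str
    regime: str
    window_s: float
    stoichiometry: float
    per_conc: pd.DataFrame          # columns conc_uM, kobs, se
    line: SecondOrderFit            # kobs regressed on [AH]0 in uM
    k2: float                       # uM^-1 s^-1
    k2_se: float

    def summary(self) -> str:
        head = (
            f"DPPH kinetics: {self.compound_id} ({self.regime}, "
            f"window {self.window_s:g} s, s = {self.stoichiometry:g})\n"
        )
        rows = "\n".join(
            f"  [AH]0 = {r.conc_uM:8.3g} uM   kobs = {r.kobs:.4g} +/- {r.se:.2g} s^-1"
            for r in self.per_conc.itertuples()
        )
        return (
            head + rows + "\n"
            f"  k2 = {self.k2:.4g} +/- {self.k2_se:.2g} uM^-1 s^-1"
        )


def fit_dpph_second_order(
    table: TimeCourseTable,
    compound_id: str,
    dpph0_uM: float = 70.0,
    window_s: float = 3600.0,
    stoichiometry: float = 1.0,
    regime: str = "excess_dpph",
) -> DPPHKineticsResults:
    """Full chain: absorbance traces -> per-concentration kobs -> k2.

    Readings up to ``window_s`` are used (the 60-minute and 24-hour
    constants of slow compounds come from the same data with different
    windows).  Replicate kobs values are averaged per concentration; the
    k2 estimator depends on the regime (see module docstring).
    """
    if regime not in ("excess_dpph", "excess_antioxidant"):
        raise DomainError(f"unknown regime {regime!r}")
    rows = []
    for (assay, cmpd, role, conc, rep), grp in table.series(
        assay_id="dpph", compound_id=compound_id, role="sample"
    ):
        sub = grp[grp["time_s"] <= window_s]
        if len(sub) < 5:
            continue
        t = sub["time_s"].to_numpy()
        a = np.clip(sub["signal"].to_numpy(), 0.0, None)
        d_uM = absorbance_to_dpph(a) * 1e6
        if regime == "excess_dpph":
            fit = fit_kobs_excess_dpph(t, d_uM, dpph0_uM, conc, stoichiometry)
        else:
            fit = fit_kobs_excess_antioxidant(t, d_uM)
        rows.append({"conc_uM": conc, "replicate": rep, "kobs": fit.kobs, "se": fit.se})
    if not rows:
        raise InsufficientDataError(
            f"no usable kinetic series for compound {compound_id!r}"
        )
    df = pd.DataFrame(rows)
    per_conc = (
        df.groupby("conc_uM", as_index=False)
        .agg(kobs=("kobs", "mean"), se=("kobs", lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan))
    )
    line = second_order_constant(per_conc["conc_uM"], per_conc["kobs"])
    if regime == "excess_dpph":
        k2 = line.intercept / dpph0_uM
        k2_se = line.intercept_se / dpph0_uM
    else:
        k2, k2_se = line.k2, line.se
    return DPPHKineticsResults(
        compound_id=compound_id,
        regime=regime,
        window_s=window_s,
        stoichiometry=stoichiometry,
        per_conc=per_conc,
        line=line,
        k2=float(k2),
        k2_se=float(k2_se),
    )


def dpph_response_curve(
    table: TimeCourseTable,
    compound_id: str,
    window_s: float = 86400.0,
    slope_tol: float = 1e-5,
) -> ResponseCurve:
    """%DPPH-remaining curve from steady-state endpoints of a plate table.

    ``A0`` is the initial radical absorbance — a property of the DPPH
    working solution, so it is pooled: the mean of the control-series
    readings when controls are present (the radical is stable without a
    scavenger), otherwise the mean of the t = 0 readings across the
    compound's series.  ``Af`` is the plateau mean of the incubation
    window, flagged if the trailing slope shows the reaction has not
    reached steady state.
    """
    ctrl = table.select(assay_id="dpph", compound_id=compound_id, role="control")
    if len(ctrl):
        a0 = float(ctrl["signal"].mean())
    else:
        t0 = table.select(assay_id="dpph", compound_id=compound_id, role="sample")
        t0 = t0[t0["time_s"] == 0.0]
        if t0.empty:
            raise InsufficientDataError(
                f"no control series and no t=0 readings for {compound_id!r}"
            )
        a0 = float(t0["signal"].mean())
    concs, resp = [], []
    for (assay, cmpd, role, conc, rep), grp in table.series(
        assay_id="dpph", compound_id=compound_id, role="sample"
    ):
        t = grp["time_s"].to_numpy()
        a = grp["signal"].to_numpy()
        af, steady = steady_state_signal(t, a, window_s, slope_tol=slope_tol)
        if not steady:
            import warnings

            warnings.warn(
                f"series {(compound_id, conc, rep)} not at steady state "
                f"within {window_s:g} s",
                stacklevel=2,
            )
        concs.append(conc)
        resp.append(percent_dpph_remaining(a0, af))
    return ResponseCurve(
        compound_id=compound_id,
        conc=np.array(concs),
        response=np.array(resp),
        response_kind="percent_dpph_remaining",
    )
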