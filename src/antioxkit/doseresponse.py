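"""Dose-response analysis: response percentages and asymmetric logistic fits.

Raw plate signals are first reduced to response percentages:

* ``%DPPH remaining = Af / A0 * 100`` — fraction of the radical left at the
  steady state of the scavenging reaction;
* ``%inhibition = (A0 - As) / A0 * 100`` — protection of the deoxyribose
  probe from hydroxyl-radical degradation (negative values mean the compound
  *promotes* degradation, i.e. is a pro-oxidant in that system);
* ``%AOA = [1 - (As0 - As10) / (Ac0 - Ac10)] * 100`` — protection of
  beta-carotene from peroxyl-radical bleaching relative to the control.

Half-maximal concentrations are then estimated with a five-parameter
asymmetric logistic (5PL) on log10 concentration,

    y(x) = D + (A - D) / (1 + 10^(B*(log10 C - log10 x)))^E

where D and A are the zero-dose and infinite-dose asymptotes, C the
inflection-region location, B > 0 the slope and E > 0 the asymmetry.  The
reported EC50/IC50 is the *absolute* criterion crossing — the concentration
at which the fitted curve equals 50% (or another criterion) — obtained by
inverting the fitted curve analytically, not the inflection parameter C.
Confidence intervals come from a case-resampling bootstrap over replicates,
stratified by concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import optimize, stats

from .exceptions import (
    DegenerateControlError,
    DomainError,
    FitError,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "percent_dpph_remaining",
    "percent_inhibition",
    "percent_aoa",
    "ResponseCurve",
    "PLParams",
    "DoseResponseFit",
    "FivePLModel",
    "fit_5pl",
    "five_pl",
    "steady_state_signal",
]


# ---------------------------------------------------------------------------
# response percentages
# ---------------------------------------------------------------------------

def percent_dpph_remaining(a0, af):
    """Percentage of DPPH remaining, ``af / a0 * 100``.

    ``a0`` is the initial radical absorbance, ``af`` the steady-state one.
    """
    a0 = np.asarray(a0, dtype=float)
    if np.any(a0 <= 0):
        raise DomainError("initial absorbance a0 must be > 0")
    out = np.asarray(af, dtype=float) / a0 * 100.0
    return float(out) if out.ndim == 0 else out


def percent_inhibition(a0, a_sample):
    """Percent inhibition of probe degradation, ``(a0 - As) / a0 * 100``.

    May be negative (pro-oxidant behaviour); negative values are propagated,
    never clipped.
    """
    a0 = np.asarray(a0, dtype=float)
    if np.any(a0 <= 0):
        raise DomainError("control absorbance a0 must be > 0")
    out = (a0 - np.asarray(a_sample, dtype=float)) / a0 * 100.0
    return float(out) if out.ndim == 0 else out


def percent_aoa(as0, as10, ac0, ac10):
    """Percent antioxidant activity in a bleaching assay.

    ``[1 - (as0 - as10)/(ac0 - ac10)] * 100`` with sample/control absorbance
    pairs at the start and end of the bleaching window.
    """
    denom = np.asarray(ac0, dtype=float) - np.asarray(ac10, dtype=float)
    if np.any(denom == 0):
        raise DegenerateControlError("control shows zero bleaching; %AOA undefined")
    out = (1.0 - (np.asarray(as0, float) - np.asarray(as10, float)) / denom) * 100.0
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# response curves
# ---------------------------------------------------------------------------

RESPONSE_KINDS = ("percent_dpph_remaining", "percent_inhibition", "percent_aoa")


@dataclass
class ResponseCurve:
    """Response percentages per (concentration, replicate) for one compound."""

    compound_id: str
    conc: np.ndarray
    response: np.ndarray
    response_kind: str = "percent_inhibition"

    def __post_init__(self):
        self.conc = np.asarray(self.conc, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.conc.shape != self.response.shape:
            raise ValidationError("conc and response must have the same length")
        if self.response_kind not in RESPONSE_KINDS:
            raise ValidationError(f"unknown response_kind {self.response_kind!r}")
        if np.unique(self.conc[self.conc > 0]).size < 3:
            raise ValidationError("need at least 3 distinct positive concentrations")
        if np.any(self.conc <= 0):
            raise ValidationError("concentrations must be positive for log-dose fitting")
        if not np.all(np.isfinite(self.response)):
            raise ValidationError("responses must be finite")

    def group_means(self) -> tuple[np.ndarray, np.ndarray]:
        levels = np.unique(self.conc)
        means = np.array([self.response[self.conc == c].mean() for c in levels])
        return levels, means


class PLParams(NamedTuple):
    """Parameters of the asymmetric logistic (log10-dose form)."""

    D: float       # zero-dose asymptote
    A: float       # infinite-dose asymptote
    C: float       # location (concentration units)
    B: float       # slope factor, > 0
    E: float       # asymmetry, > 0 (E = 1 recovers the 4PL)


def five_pl(x, D, A, logC, B, E):
    """Evaluate the 5PL at concentration ``x`` (same units as ``10**logC``)."""
    x = np.asarray(x, dtype=float)
    return D + (A - D) / (1.0 + 10.0 ** (B * (logC - np.log10(x)))) ** E


@dataclass
class DoseResponseFit:
    """Results of a 5PL dose-response fit."""

    params: PLParams
    ec50: float
    ci: tuple[float, float]
    converged: bool
    crossing_found: bool
    criterion: float
    response_kind: str
    compound_id: str
    n_boot: int
    residual_sd: float
    n_boot_failed: int = 0
    boot_ec50: np.ndarray | None = field(default=None, repr=False)

    def predict(self, x):
        D, A, C, B, E = self.params
        return five_pl(x, D, A, math.log10(C), B, E)

    def summary(self) -> str:
        p = self.params
        lines = [
            f"5PL dose-response fit: {self.compound_id} ({self.response_kind})",
            f"  D (zero-dose asymptote)    {p.D:12.4g}",
            f"  A (infinite-dose asymptote){p.A:12.4g}",
            f"  C (location, conc units)   {p.C:12.4g}",
            f"  B (slope)                  {p.B:12.4g}",
            f"  E (asymmetry)              {p.E:12.4g}",
            f"  residual sd                {self.residual_sd:12.4g}",
            f"  converged                  {self.converged}",
        ]
        if self.crossing_found:
            lines.append(
                f"  EC50 at {self.criterion:g}% criterion: {self.ec50:.4g} "
                f"[95% CI {self.ci[0]:.4g}, {self.ci[1]:.4g}] "
                f"({self.n_boot} bootstrap resamples)"
            )
        else:
            lines.append(
                f"  criterion {self.criterion:g}% not crossed by the fitted curve"
            )
        return "\n".join(lines)


def _invert_5pl(theta: np.ndarray, y: float) -> float | None:
    """Concentration at which the 5PL equals ``y``; None if no crossing."""
    D, A, logC, B, E = theta
    span = A - D
    if span == 0:
        return None
    f = (y - D) / span
    if not (0.0 < f < 1.0):
        return None
    u = f ** (-1.0 / E) - 1.0
    if u <= 0:
        return None
    return float(10.0 ** (logC - math.log10(u) / B))


class FivePLModel:
    """Five-parameter asymmetric logistic dose-response model.

    Parameters
    ----------
    curve : ResponseCurve
        Responses in percent per (concentration, replicate).
    criterion : float, default 50
        Absolute response criterion defining EC50/IC50: for DPPH the
        concentration leaving 50% of the radical, for inhibition/AOA the
        concentration giving 50% protection.

    ``fit()`` returns a :class:`DoseResponseFit`.  The asymmetry can be
    frozen (``fix_asymmetry=1`` gives the ordinary 4PL) for cross-checks.
    """

    #: bounds keeping the ill-conditioned 5PL away from degenerate corners
    _B_BOUNDS = (1e-3, 50.0)
    _E_BOUNDS = (1e-2, 20.0)

    def __init__(self, curve: ResponseCurve, criterion: float = 50.0):
        self.curve = curve
        self.criterion = float(criterion)
        order = np.argsort(curve.conc, kind="stable")
        self._x = curve.conc[order]
        self._y = curve.response[order]
        self._logx = np.log10(self._x)

    # -- internals -----------------------------------------------------------

    def _theta0(self, rng: np.random.Generator | None = None) -> np.ndarray:
        levels, means = self.curve.group_means()
        d0 = means[0]            # response at the lowest dose
        a0 = means[-1]           # response at the highest dose
        half = 0.5 * (means.min() + means.max())
        c0 = levels[np.argmin(np.abs(means - half))]
        theta = np.array([d0, a0, math.log10(c0), 1.0, 1.0])
        if rng is not None:
            theta = theta + rng.normal(0, [5.0, 5.0, 0.3, 0.2, 0.2])
        return theta

    def _bounds(self):
        lo_y, hi_y = self._y.min(), self._y.max()
        span = max(hi_y - lo_y, 1.0)
        ylo, yhi = lo_y - 2 * span, hi_y + 2 * span
        lx, hx = self._logx.min() - 2, self._logx.max() + 2
        lower = [ylo, ylo, lx, self._B_BOUNDS[0], self._E_BOUNDS[0]]
        upper = [yhi, yhi, hx, self._B_BOUNDS[1], self._E_BOUNDS[1]]
        return np.array(lower), np.array(upper)

    def _residuals(self, theta, x_log, y, fix_e):
        if fix_e is not None:
            D, A, logC, B = theta
            E = fix_e
        else:
            D, A, logC, B, E = theta
        pred = D + (A - D) / (1.0 + 10.0 ** (B * (logC - x_log))) ** E
        return pred - y

    @staticmethod
    def _jacobian(theta, x_log, y, fix_e):
        if fix_e is not None:
            D, A, logC, B = theta
            E = fix_e
        else:
            D, A, logC, B, E = theta
        u = 10.0 ** (B * (logC - x_log))
        g = (1.0 + u) ** (-E)          # d pred / d(A - D) factor
        span = A - D
        # d g / d u = -E (1+u)^(-E-1); d u / d logC = u ln10 B; d u / d B = u ln10 (logC - x)
        dg_du = -E * (1.0 + u) ** (-E - 1.0)
        ln10 = np.log(10.0)
        cols = [
            1.0 - g,                           # d/dD
            g,                                 # d/dA
            span * dg_du * u * ln10 * B,       # d/dlogC
            span * dg_du * u * ln10 * (logC - x_log),  # d/dB
        ]
        if fix_e is None:
            cols.append(span * g * (-np.log1p(u)))     # d/dE
        return np.column_stack(cols)

    def _solve(self, x_log, y, theta0, fix_e=None, fast=False):
        lower, upper = self._bounds()
        if fix_e is not None:
            lower, upper, theta0 = lower[:4], upper[:4], theta0[:4]
        theta0 = np.clip(theta0, lower, upper)
        tol = 1e-10 if fast else 1e-13
        res = optimize.least_squares(
            self._residuals,
            theta0,
            jac=self._jacobian,
            args=(x_log, y, fix_e),
            bounds=(lower, upper),
            xtol=tol,
            ftol=tol,
            gtol=tol,
            max_nfev=150 if fast else 3000,
        )
        # With replicated designs the 5PL is often rank-deficient (more
        # parameters than dose levels); the optimiser then stalls on flat
        # directions without formally meeting xtol.  A stall whose projected
        # gradient has collapsed by many orders relative to the starting
        # point is a converged fit for every identified quantity.
        if res.status == 0:
            r0 = self._residuals(theta0, x_log, y, fix_e)
            g0 = np.max(np.abs(self._jacobian(theta0, x_log, y, fix_e).T @ r0))
            if res.optimality <= 1e-4 * max(g0, 1.0):
                res.success = True
        theta = res.x
        if fix_e is not None:
            theta = np.append(theta, fix_e)
        return theta, res

    def _fit_point(self, x_log, y, seed_rng=None, fix_e=None):
        """Best of one plain start plus, on poor fits, 3 jittered restarts."""
        theta0 = self._theta0()
        best_theta, best = self._solve(x_log, y, theta0, fix_e)
        y_var = np.var(y)
        needs_restart = (not best.success) or (
            y_var > 0 and 2 * best.cost / len(y) > 0.25 * y_var
        )
        if needs_restart:
            rng = seed_rng if seed_rng is not None else np.random.default_rng(0)
            for _ in range(3):
                theta_j, res_j = self._solve(x_log, y, self._theta0(rng), fix_e)
                if res_j.cost < best.cost:
                    best, best_theta = res_j, theta_j
        return best_theta, best

    # -- public API ------------------------------------------------------------

    def fit(
        self,
        n_boot: int = 1000,
        seed: int | None = None,
        fix_asymmetry: float | None = None,
        boot_scheme: str = "residual",
    ) -> DoseResponseFit:
        """Least-squares 5PL fit with a bootstrap EC50 interval.

        Two resampling schemes are available:

        * ``'residual'`` (default): residuals around the fitted curve are
          pooled across doses, inflated by sqrt(N / dof) to undo the
          mean-centering bias, resampled onto the fitted values and the
          curve refit.  The interval is the bias-corrected symmetric
          t-interval, ``ec50 - bias_boot +/- t(dof, 0.975) * sd_boot``.
          With the handful of replicates per dose that plate assays
          provide, this pooled scheme is the only one whose variance
          estimate is stable enough for near-nominal coverage, and the
          symmetric form avoids the instability of extreme percentiles at
          moderate resample counts.
        * ``'case'``: classic case resampling of replicates within each
          dose with plain 2.5/97.5 percentiles; kept for reference, but
          with triplicate designs it covers well below its nominal level.
        """
        if boot_scheme not in ("residual", "case"):
            raise ValueError(f"unknown boot_scheme {boot_scheme!r}")
        rng = np.random.default_rng(seed)
        theta, res = self._fit_point(self._logx, self._y, rng, fix_asymmetry)
        if not res.success:
            raise FitError(
                "5PL fit did not converge",
                diagnostics={"status": res.status, "message": res.message,
                             "cost": float(res.cost)},
            )
        n_levels = np.unique(self._x).size
        n_par = len(res.x)
        # an over-parameterised fit interpolates the dose means, so the
        # residual dof is set by the dose levels, not the parameter count
        dof = max(len(self._y) - min(n_par, n_levels), 1)
        residual_sd = float(np.sqrt(2 * res.cost / dof))
        ec50 = _invert_5pl(theta, self.criterion)
        crossing = ec50 is not None

        ci = (math.nan, math.nan)
        boot_vals = None
        n_failed = 0
        if crossing and n_boot > 0:
            theta_used = theta[:4] if fix_asymmetry is not None else theta
            # _residuals returns pred - y
            fitted = self._y + self._residuals(
                theta_used, self._logx, self._y, fix_asymmetry
            )
            resid = self._y - fitted
            n = len(self._y)
            resid_pool = (resid - resid.mean()) * math.sqrt(n / dof)
            groups = [np.flatnonzero(self._x == c) for c in np.unique(self._x)]
            vals = []
            for _ in range(n_boot):
                if boot_scheme == "residual":
                    y_b = fitted + rng.choice(resid_pool, size=n, replace=True)
                    x_b = self._logx
                else:
                    idx = np.concatenate(
                        [rng.choice(g, size=g.size, replace=True) for g in groups]
                    )
                    x_b, y_b = self._logx[idx], self._y[idx]
                try:
                    theta_b, _ = self._solve(
                        x_b, y_b, theta.copy(), fix_asymmetry, fast=True
                    )
                except Exception:
                    n_failed += 1
                    continue
                v = _invert_5pl(theta_b, self.criterion)
                if v is None or not np.isfinite(v):
                    n_failed += 1
                    continue
                vals.append(v)
            if vals:
                boot_vals = np.asarray(vals)
                if boot_scheme == "residual":
                    # bias-corrected symmetric t-interval: stable at small
                    # replication where extreme percentiles are noisy
                    sd = float(np.std(boot_vals, ddof=1))
                    centre = ec50 - (float(np.mean(boot_vals)) - ec50)
                    half = stats.t.ppf(0.975, dof) * sd
                    ci = (centre - half, centre + half)
                else:
                    ci = tuple(np.percentile(boot_vals, [2.5, 97.5]))
                # clamp so the interval always brackets the point estimate
                ci = (min(ci[0], ec50), max(ci[1], ec50))

        return DoseResponseFit(
            params=PLParams(theta[0], theta[1], 10.0 ** theta[2], theta[3], theta[4]),
            ec50=ec50 if crossing else math.nan,
            ci=ci,
            converged=bool(res.success),
            crossing_found=crossing,
            criterion=self.criterion,
            response_kind=self.curve.response_kind,
            compound_id=self.curve.compound_id,
            n_boot=n_boot,
            residual_sd=residual_sd,
            n_boot_failed=n_failed,
            boot_ec50=boot_vals,
        )


def fit_5pl(
    curve: ResponseCurve,
    criterion: float = 50.0,
    n_boot: int = 1000,
    seed: int | None = None,
    fix_asymmetry: float | None = None,
) -> DoseResponseFit:
    """Functional wrapper: ``FivePLModel(curve, criterion).fit(...)``."""
    return FivePLModel(curve, criterion).fit(
        n_boot=n_boot, seed=seed, fix_asymmetry=fix_asymmetry
    )


# ---------------------------------------------------------------------------
# steady-state endpoint selection
# ---------------------------------------------------------------------------

def steady_state_signal(
    time_s: np.ndarray,
    signal: np.ndarray,
    window_s: float,
    tail_frac: float = 0.1,
    slope_tol: float = 1e-5,
) -> tuple[float, bool]:
    """Steady-state signal at an incubation window, with a plateau check.

    Returns ``(value, at_steady_state)``: ``value`` averages the readings in
    the trailing ``tail_frac`` of the window (they all sample the plateau,
    so their mean is the best endpoint estimate), and ``at_steady_state``
    reports whether the OLS slope over that tail stays below ``slope_tol``
    (absorbance units per second).  Scavenging reactions differ wildly in
    speed; slow compounds read before their plateau get flagged rather than
    silently producing an inflated endpoint.
    """
    time_s = np.asarray(time_s, dtype=float)
    signal = np.asarray(signal, dtype=float)
    inside = time_s <= window_s
    if not inside.any():
        raise InsufficientDataError("no readings inside the incubation window")
    t, s = time_s[inside], signal[inside]
    t_tail = window_s * (1.0 - tail_frac)
    tail = t >= t_tail
    if tail.sum() < 2:
        return float(s[np.argmax(t)]), False
    slope = stats.linregress(t[tail], s[tail]).slope
    return float(s[tail].mean()), bool(abs(slope) < slope_tol)
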