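"""2-deoxyribose assay: three-blank correction and competition kinetics.

Hydroxyl radicals generated in situ by Fenton chemistry degrade
2-deoxyribose (2-DR) to TBARS, read as absorbance at 532 nm.  The measured
signal also contains TBARS from heat-induced probe degradation and from
degradation of the tested compound itself, removed with a three-blank
correction::

    A_sample = A_measured - A_BL3 - (A_BL2 - A_BL1)

BL1 lacks the probe, the compound, Fe(III) and H2O2; BL2 lacks the
compound, Fe(III) and H2O2 (so BL2 - BL1 is the heat-induced probe
degradation); BL3 contains everything except the probe (TBARS from the
compound's own degradation).

Under pure competition for the radical between the probe and a scavenger S,
1/A is affine in the scavenger concentration and the scavenger's
second-order rate constant follows from

    k_S = slope * k_DR * [DR] * A0

where k_DR is the probe's own rate constant with the hydroxyl radical
(a user-supplied literature value; the package deliberately ships no
default) and A0 the corrected control absorbance.  Curvature of the
competition plot indicates a dual mode of action — direct scavenging of
hydrogen peroxide diminishes radical generation itself — and is detected
with a lack-of-fit F-test of the linear against the quadratic model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .doseresponse import DoseResponseFit, FivePLModel, ResponseCurve, percent_inhibition
from .exceptions import (
    DomainError,
    InsufficientDataError,
    ProOxidantWarning,
)
from .io import TimeCourseTable

__all__ = [
    "AESCULIN_K_OH",
    "BlankSet",
    "correct_absorbance",
    "CompetitionFit",
    "CompetitionModel",
    "competition_analysis",
    "dr2_ic50",
    "dr2_inhibition_curve",
    "dr2_blank_correct",
]

#: reference second-order constant of the assay's canonical slow standard
#: (aesculin) with the hydroxyl radical, (9.05 +/- 0.48)e9 M^-1 s^-1
AESCULIN_K_OH = 9.05e9
AESCULIN_K_OH_SE = 0.48e9


@dataclass
class BlankSet:
    """The four 532 nm absorbance roles of one sample."""

    a_measured: float
    a_bl1: float
    a_bl2: float
    a_bl3: float

    def __post_init__(self):
        for name in ("a_measured", "a_bl1", "a_bl2", "a_bl3"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")


def correct_absorbance(b: BlankSet) -> float:
    """Three-blank corrected absorbance.

    Negative results are returned as-is with a :class:`ProOxidantWarning`
    (pro-oxidant behaviour or over-correction), never clipped.
    """
    value = b.a_measured - b.a_bl3 - (b.a_bl2 - b.a_bl1)
    if value < 0:
        warnings.warn(
            f"corrected absorbance is negative ({value:.4g}): pro-oxidant "
            "behaviour or over-correction",
            ProOxidantWarning,
            stacklevel=2,
        )
    return float(value)


@dataclass
class CompetitionFit:
    """Competition-kinetics regression of 1/A on scavenger concentration."""

    slope: float               # AU^-1 M^-1
    slope_se: float
    intercept: float           # AU^-1
    a0: float                  # corrected control absorbance
    k_dr: float                # probe + OH* rate constant, M^-1 s^-1
    dr_conc: float             # probe concentration, M
    k_s: float                 # scavenger + OH* rate constant, M^-1 s^-1
    k_s_se: float
    linearity: str             # 'linear' | 'nonlinear'
    lack_of_fit_p: float
    n_points: int

    @property
    def dual_mode(self) -> bool:
        """True when curvature suggests direct H2O2 scavenging as well."""
        return self.linearity == "nonlinear"

    def summary(self) -> str:
        lines = [
            "Competition kinetics (1/A vs concentration):",
            f"  slope      {self.slope:.6g} AU^-1 M^-1 (+/- {self.slope_se:.2g})",
            f"  A0         {self.a0:.4g} AU",
            f"  lack-of-fit p = {self.lack_of_fit_p:.4g} -> {self.linearity}",
        ]
        if self.linearity == "linear":
            lines.append(
                f"  k_S = slope * k_DR * [DR] * A0 = {self.k_s:.4g} "
                f"+/- {self.k_s_se:.2g} M^-1 s^-1"
            )
        else:
            lines.append(
                "  nonlinear competition plot: dual antioxidant mode "
                "(direct H2O2 scavenging); k_S undefined"
            )
        return "\n".join(lines)


class CompetitionModel:
    """Competition-kinetics model for hydroxyl-radical scavenging.

    Parameters
    ----------
    conc_uM, absorbance : arrays
        Corrected 532 nm absorbances at each scavenger concentration
        (micromolar).  Replicates are averaged per concentration before the
        regression.
    a0 : float
        Corrected control (no scavenger) absorbance, > 0.
    k_dr : float
        Rate constant of 2-deoxyribose with the hydroxyl radical in
        M^-1 s^-1.  Required — the package ships no default because the
        published analyses never print the value they assumed.
    dr_conc : float
        2-deoxyribose concentration in mol/L (protocol value 2.5e-3).
    """

    def __init__(self, conc_uM, absorbance, a0: float, k_dr: float,
                 dr_conc: float = 2.5e-3):
        conc_uM = np.asarray(conc_uM, dtype=float)
        absorbance = np.asarray(absorbance, dtype=float)
        if np.any(absorbance <= 0):
            raise DomainError("corrected absorbances must be > 0 for 1/A")
        if a0 <= 0:
            raise DomainError("control absorbance a0 must be > 0")
        if k_dr <= 0:
            raise DomainError("k_dr must be > 0")
        if dr_conc <= 0:
            raise DomainError("dr_conc must be > 0")
        levels = np.unique(conc_uM)
        if levels.size < 4:
            raise InsufficientDataError(
                "competition analysis needs at least 4 concentrations"
            )
        self.conc_uM = conc_uM
        self.absorbance = absorbance
        self.a0 = float(a0)
        self.k_dr = float(k_dr)
        self.dr_conc = float(dr_conc)

    def fit(self, alpha: float = 0.05) -> CompetitionFit:
        """Regress 1/A on concentration (in M) and test linearity.

        The lack-of-fit statistic compares the linear model against the
        quadratic on replicate-averaged points: F = (RSS1 - RSS2) / (RSS2 /
        (n - 3)).  If p < ``alpha`` the plot is declared nonlinear and k_S
        left undefined (NaN).
        """
        levels = np.unique(self.conc_uM)
        y = np.array([
            (1.0 / self.absorbance[self.conc_uM == c]).mean() for c in levels
        ])
        x = levels * 1e-6  # uM -> M so the slope carries M^-1
        n = x.size
        X1 = np.column_stack([np.ones(n), x])
        X2 = np.column_stack([np.ones(n), x, x * x])
        beta1, rss1 = _ols(X1, y)
        beta2, rss2 = _ols(X2, y)
        if n > 3 and rss2 > 0:
            f_stat = (rss1 - rss2) / (rss2 / (n - 3))
            p = float(stats.f.sf(f_stat, 1, n - 3))
        else:
            p = 1.0 if rss1 <= max(rss2, 1e-300) else 0.0
        linear = p >= alpha
        dof = max(n - 2, 1)
        sigma2 = rss1 / dof
        sxx = np.sum((x - x.mean()) ** 2)
        slope_se = float(np.sqrt(sigma2 / sxx)) if sxx > 0 else np.nan
        slope = float(beta1[1])
        scale = self.k_dr * self.dr_conc * self.a0
        return CompetitionFit(
            slope=slope,
            slope_se=slope_se,
            intercept=float(beta1[0]),
            a0=self.a0,
            k_dr=self.k_dr,
            dr_conc=self.dr_conc,
            k_s=slope * scale if linear else float("nan"),
            k_s_se=slope_se * scale if linear else float("nan"),
            linearity="linear" if linear else "nonlinear",
            lack_of_fit_p=p,
            n_points=n,
        )


def _ols(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def competition_analysis(
    points, a0: float, k_dr: float, dr_conc: float = 2.5e-3,
    alpha: float = 0.05,
) -> CompetitionFit:
    """Functional wrapper around :class:`CompetitionModel`.

    ``points`` may be a mapping ``{conc_uM: corrected_absorbance}`` or a
    pair of aligned arrays.
    """
    if isinstance(points, dict):
        items = sorted(points.items())
        conc = [c for c, _ in items]
        absb = [a for _, a in items]
    else:
        conc, absb = points
    return CompetitionModel(conc, absb, a0, k_dr, dr_conc).fit(alpha=alpha)


# ---------------------------------------------------------------------------
# dose-response chain over time-course tables
# ---------------------------------------------------------------------------

def dr2_blank_correct(table: TimeCourseTable, compound_id: str):
    """Apply the three-blank correction to every sample row of one compound.

    Returns ``(conc_uM, corrected, a0)`` arrays/scalar: per-(conc, replicate)
    corrected sample absorbances and the corrected control absorbance.
    BL1/BL2 are plate-wide (stored at conc 0); BL3 is matched per
    concentration and replicate when available, else averaged.
    """
    df = table.select(assay_id="dr2", compound_id=compound_id)
    if df.empty:
        raise InsufficientDataError(f"no dr2 rows for compound {compound_id!r}")

    def _mean(role, conc=None, replicate=None):
        sub = df[df["role"] == role]
        if conc is not None:
            exact = sub[sub["conc_uM"] == conc]
            sub = exact if not exact.empty else sub
        if replicate is not None:
            exact = sub[sub["replicate"] == replicate]
            sub = exact if not exact.empty else sub
        return float(sub["signal"].mean()) if not sub.empty else 0.0

    bl1 = _mean("blank_bl1")
    bl2 = _mean("blank_bl2")
    samples = df[df["role"] == "sample"]
    concs, corrected = [], []
    for row in samples.itertuples():
        bl3 = _mean("blank_bl3", conc=row.conc_uM, replicate=row.replicate)
        b = BlankSet(row.signal, bl1, bl2, bl3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ProOxidantWarning)
            corrected.append(correct_absorbance(b))
        concs.append(row.conc_uM)
    ctrl = df[df["role"] == "control"]
    if ctrl.empty:
        raise InsufficientDataError("dr2 control series missing")
    a0 = float(ctrl["signal"].mean()) - (bl2 - bl1)
    return np.asarray(concs), np.asarray(corrected), a0


def dr2_inhibition_curve(table: TimeCourseTable, compound_id: str) -> ResponseCurve:
    """Percent-inhibition curve after the three-blank correction."""
    conc, corrected, a0 = dr2_blank_correct(table, compound_id)
    return ResponseCurve(
        compound_id=compound_id,
        conc=conc,
        response=percent_inhibition(a0, corrected),
        response_kind="percent_inhibition",
    )


def dr2_ic50(
    curve: ResponseCurve,
    n_boot: int = 1000,
    seed: int | None = None,
) -> DoseResponseFit:
    """IC50 of 2-DR protection via the shared 5PL machinery (criterion 50%)."""
    return FivePLModel(curve, criterion=50.0).fit(n_boot=n_boot, seed=seed)
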