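"""Synthetic assay-data generators with known ground truth.

No raw plate-reader data were ever deposited for the assays this package
analyses, so every analysis chain is exercised against simulated data whose
true parameters are known.  The generators emulate the published study
conditions: triplicates at four (2-DR: five) concentrations, a 70 uM
initial DPPH concentration (140 uM stock diluted 1:1 with the sample),
2.5 mM deoxyribose, a beta-carotene working solution at absorbance 0.68
monitored for 10 minutes, and additive Gaussian measurement noise
(default 0.002 AU on absorbance, 0.5% of the fluorescence plateau).

Every simulator is a deterministic function of its :class:`SimSpec` — the
seed is mandatory and the same spec always yields a byte-identical table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.integrate import solve_ivp

from .dpph import CAL_SHIFT_AU, CAL_SLOPE_AU_PER_M, dpph_to_absorbance
from .exceptions import DomainError, ValidationError
from .io import TimeCourseTable
from .screening import ScreenOutcome

__all__ = [
    "SimSpec",
    "simulate_dpph",
    "simulate_dr2",
    "simulate_bcb",
    "simulate_caa",
    "simulate_screen",
    "stoichiometry_for_ec50",
    "true_dpph_ec50",
    "true_bcb_k_prime",
    "protection_factor_for_caa",
    "dpph_kinetics_spec",
    "dpph_ec50_spec",
    "dr2_spec",
    "bcb_spec",
    "caa_spec",
]

#: study defaults: four concentrations, triplicates, 0.002 AU noise
DEFAULT_REPLICATES = 3
DEFAULT_NOISE_AU = 0.002
DPPH0_UM = 70.0
DR_CONC_M = 2.5e-3


@dataclass
class SimSpec:
    """Design and ground truth of one simulated assay dataset."""

    assay_id: str
    concentrations_uM: tuple[float, ...]
    time_s: tuple[float, ...]
    true_params: dict[str, Any]
    seed: int
    replicates: int = DEFAULT_REPLICATES
    noise_sd: float = DEFAULT_NOISE_AU
    compound_id: str = "cmpd"

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        self.concentrations_uM = tuple(float(c) for c in self.concentrations_uM)
        if len(set(self.concentrations_uM)) != len(self.concentrations_uM):
            raise ValidationError("concentrations must be distinct")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        self.time_s = tuple(float(t) for t in self.time_s)
        if any(np.diff(self.time_s) <= 0):
            raise ValidationError("time grid must be strictly increasing")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _rows(spec, role, conc, rep, t, signal):
    return pd.DataFrame(
        {
            "assay_id": spec.assay_id,
            "compound_id": spec.compound_id,
            "role": role,
            "conc_uM": conc,
            "replicate": rep,
            "time_s": t,
            "signal": signal,
        }
    )


# ---------------------------------------------------------------------------
# DPPH
# ---------------------------------------------------------------------------

def stoichiometry_for_ec50(ec50_uM: float, dpph0_uM: float = DPPH0_UM) -> float:
    """Stoichiometric factor giving a target steady-state EC50.

    At the steady state of an irreversible scavenging reaction with the
    antioxidant fully consumed, %DPPH remaining = 100*(1 - s*c/[DPPH]0),
    so the 50% crossing sits at [DPPH]0/(2 s).
    """
    if not (0 < ec50_uM):
        raise DomainError("ec50 must be > 0")
    return dpph0_uM / (2.0 * ec50_uM)


def true_dpph_ec50(spec: SimSpec, criterion: float = 50.0) -> float:
    """Exact criterion crossing of the *measured* %DPPH-remaining curve.

    The assay reads absorbance ratios, and the calibration line has a small
    additive offset, so the concentration at which the absorbance ratio
    reaches the criterion differs slightly from the purely stoichiometric
    [DPPH]0/(2 s): solving Af = f*A0 through the calibration gives

        c* = (1 - f) * ([DPPH]0 - offset) / s,   f = criterion / 100

    with ``offset`` the calibration shift expressed in uM.  This is the
    ground truth the analysis chain estimates.
    """
    p = spec.true_params
    dpph0 = p.get("dpph0_uM", DPPH0_UM)
    s = p.get("s", 1.0)
    f = criterion / 100.0
    offset_uM = CAL_SHIFT_AU / CAL_SLOPE_AU_PER_M * 1e6
    return (1.0 - f) * (dpph0 - offset_uM) / s


def _dpph_traces(spec: SimSpec) -> dict[float, np.ndarray]:
    """Noise-free [DPPH](t) in uM per concentration from the rate ODE."""
    p = spec.true_params
    k2 = p["k2"]                       # uM^-1 s^-1
    s = p.get("s", 1.0)
    dpph0 = p.get("dpph0_uM", DPPH0_UM)
    if k2 < 0 or s <= 0 or dpph0 <= 0:
        raise DomainError("non-physical kinetic parameters")
    t = np.asarray(spec.time_s)
    out = {}
    for c in spec.concentrations_uM:
        if k2 == 0 or c == 0:
            out[c] = np.full_like(t, dpph0, dtype=float)
            continue

        def rhs(_t, y):
            d, a = y
            r = k2 * max(d, 0.0) * max(a, 0.0)
            return [-r, -r / s]

        sol = solve_ivp(
            rhs,
            (0.0, t[-1]),
            [dpph0, c],
            t_eval=t,
            method="LSODA",
            rtol=1e-8,
            atol=1e-12,
        )
        if not sol.success:
            raise DomainError(f"kinetic integration failed: {sol.message}")
        out[c] = np.clip(sol.y[0], 0.0, None)
    return out


def simulate_dpph(spec: SimSpec) -> TimeCourseTable:
    """Simulate DPPH absorbance decays from second-order scavenging kinetics.

    ``true_params``: ``k2`` (uM^-1 s^-1), optional ``s`` (stoichiometry,
    default 1) and ``dpph0_uM`` (default 70).  The radical trace integrates
    d[DPPH]/dt = -k2*[DPPH]*[AH], d[AH]/dt = -(k2/s)*[DPPH]*[AH]; absorbance
    follows from the inverse calibration line, plus Gaussian noise.
    """
    rng = spec.rng()
    t = np.asarray(spec.time_s)
    traces = _dpph_traces(spec)
    dpph0 = spec.true_params.get("dpph0_uM", DPPH0_UM)
    frames = []
    a_ctrl = dpph_to_absorbance(dpph0 * 1e-6)
    for rep in range(1, spec.replicates + 1):
        noise = rng.normal(0.0, spec.noise_sd, t.size)
        frames.append(_rows(spec, "control", 0.0, rep, t, a_ctrl + noise))
    for c in spec.concentrations_uM:
        a_clean = dpph_to_absorbance(traces[c] * 1e-6)
        for rep in range(1, spec.replicates + 1):
            noise = rng.normal(0.0, spec.noise_sd, t.size)
            frames.append(_rows(spec, "sample", c, rep, t, a_clean + noise))
    return TimeCourseTable(pd.concat(frames, ignore_index=True))


def dpph_kinetics_spec(
    k2: float,
    seed: int,
    s: float = 1.0,
    concentrations_uM=(5.0, 10.0, 15.0, 20.0),
    time_s=tuple(np.arange(0.0, 3601.0, 60.0)),
    noise_sd: float = DEFAULT_NOISE_AU,
    replicates: int = DEFAULT_REPLICATES,
    compound_id: str = "cmpd",
) -> SimSpec:
    """Kinetic-plate design: excess DPPH over four antioxidant doses."""
    return SimSpec(
        assay_id="dpph",
        concentrations_uM=concentrations_uM,
        time_s=time_s,
        true_params={"k2": k2, "s": s, "dpph0_uM": DPPH0_UM},
        seed=seed,
        replicates=replicates,
        noise_sd=noise_sd,
        compound_id=compound_id,
    )


def dpph_ec50_spec(
    ec50_uM: float,
    seed: int,
    k2: float = 1e-4,
    concentrations_uM=(5.0, 10.0, 20.0, 35.0),
    noise_sd: float = DEFAULT_NOISE_AU,
    replicates: int = DEFAULT_REPLICATES,
    compound_id: str = "cmpd",
) -> SimSpec:
    """Steady-state plate design targeting a known EC50.

    The stoichiometry is set so the steady-state 50%-remaining crossing
    falls at ``ec50_uM``; the 24 h endpoint grid gives the plateau plus a
    trailing window for the steady-state check.
    """
    # coarse reads through the decay, then a denser sweep across the final
    # plateau so the steady-state endpoint averages several readings
    time_s = (0.0, 21600.0, 43200.0, 64800.0,
              79200.0, 81000.0, 82800.0, 84600.0, 86400.0)
    return SimSpec(
        assay_id="dpph",
        concentrations_uM=concentrations_uM,
        time_s=time_s,
        true_params={
            "k2": k2,
            "s": stoichiometry_for_ec50(ec50_uM),
            "dpph0_uM": DPPH0_UM,
        },
        seed=seed,
        replicates=replicates,
        noise_sd=noise_sd,
        compound_id=compound_id,
    )


# ---------------------------------------------------------------------------
# 2-deoxyribose
# ---------------------------------------------------------------------------

def dr2_spec(
    k_s: float,
    k_dr: float,
    seed: int,
    dr_conc: float = DR_CONC_M,
    a0: float = 0.9,
    concentrations_uM=(10.0, 25.0, 50.0, 100.0, 200.0),
    noise_sd: float = DEFAULT_NOISE_AU,
    replicates: int = DEFAULT_REPLICATES,
    dual_mode: bool = False,
    dual_mode_quad: float = 3.0,
    blanks=(0.05, 0.12, 0.02),
    bl3_slope: float = 0.0,
    compound_id: str = "cmpd",
) -> SimSpec:
    """Endpoint design for the Fenton/2-DR competition assay.

    ``k_s``/``k_dr`` in M^-1 s^-1, ``dr_conc`` in mol/L.  ``dual_mode``
    adds a quadratic term ``dual_mode_quad * (beta*c)^2`` to 1/A (relative
    curvature emulating direct H2O2 scavenging).  ``blanks`` are the BL1,
    BL2, BL3-at-zero absorbances; ``bl3_slope`` (AU/uM) lets the compound's
    own TBARS grow with its concentration.
    """
    return SimSpec(
        assay_id="dr2",
        concentrations_uM=concentrations_uM,
        time_s=(3600.0,),
        true_params={
            "k_s": k_s,
            "k_dr": k_dr,
            "dr_conc": dr_conc,
            "a0": a0,
            "dual_mode": dual_mode,
            "dual_mode_quad": dual_mode_quad,
            "blanks": tuple(blanks),
            "bl3_slope": bl3_slope,
        },
        seed=seed,
        replicates=replicates,
        noise_sd=noise_sd,
        compound_id=compound_id,
    )


def simulate_dr2(spec: SimSpec) -> TimeCourseTable:
    """Simulate three-blank 2-DR endpoint absorbances under competition.

    The corrected signal follows A(c) = a0 / (1 + k_s*c / (k_dr*[DR]))
    (concentrations in M); measured samples add the BL3 and the heat-induced
    (BL2 - BL1) components back so the analysis chain must undo them.
    """
    p = spec.true_params
    k_s, k_dr, dr_conc = p["k_s"], p["k_dr"], p["dr_conc"]
    a0 = p["a0"]
    # negative k_s is allowed: it emulates a pro-oxidant whose presence
    # *increases* probe degradation (corrected absorbance above the control)
    if min(k_dr, dr_conc, a0) <= 0:
        raise DomainError("non-physical competition parameters")
    bl1, bl2, bl3_0 = p.get("blanks", (0.05, 0.12, 0.02))
    bl3_slope = p.get("bl3_slope", 0.0)
    heat = bl2 - bl1
    rng = spec.rng()
    t = np.asarray(spec.time_s)
    frames = []

    def noisy(role, conc, rep, clean):
        noise = rng.normal(0.0, spec.noise_sd, t.size)
        return _rows(spec, role, conc, rep, t, clean + noise)

    for rep in range(1, spec.replicates + 1):
        frames.append(noisy("blank_bl1", 0.0, rep, bl1))
        frames.append(noisy("blank_bl2", 0.0, rep, bl2))
        frames.append(noisy("control", 0.0, rep, a0 + heat))
    beta = k_s / (k_dr * dr_conc)  # per M
    for c in spec.concentrations_uM:
        x = beta * c * 1e-6
        inv_a = (1.0 + x) / a0
        if p.get("dual_mode", False):
            inv_a = (1.0 + x + p.get("dual_mode_quad", 3.0) * x * x) / a0
        if inv_a <= 0:
            raise DomainError(
                f"competition curve crosses zero at {c:g} uM; reduce |k_s|"
            )
        clean = 1.0 / inv_a
        bl3 = bl3_0 + bl3_slope * c
        for rep in range(1, spec.replicates + 1):
            frames.append(noisy("sample", c, rep, clean + bl3 + heat))
            frames.append(noisy("blank_bl3", c, rep, bl3))
    return TimeCourseTable(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# beta-carotene bleaching
# ---------------------------------------------------------------------------

def bcb_spec(
    seed: int,
    k_prime_gen: float | None = None,
    ic50_uM: float | None = 36.0,
    a0: float = 0.68,
    delta_a0: float = 0.45,
    concentrations_uM=None,
    noise_sd: float = DEFAULT_NOISE_AU,
    replicates: int = DEFAULT_REPLICATES,
    compound_id: str = "cmpd",
) -> SimSpec:
    """10-minute bleaching design.

    The protection strength is set either through the generating k'
    (``k_prime_gen``, uM^-1) or through a target IC50 (``ic50_uM``); the two
    are linked by q = k'*dA0/a0 = 1/IC50 where q parameterises
    dA(c) = dA0/(1 + q*c).  When no concentrations are given the four doses
    are placed at (1/4, 1/2, 1, 2) x IC50 so the design tracks the
    compound's potency, as a bench protocol would.
    """
    if (k_prime_gen is None) == (ic50_uM is None):
        raise DomainError("give exactly one of k_prime_gen or ic50_uM")
    q = (1.0 / ic50_uM) if ic50_uM is not None else k_prime_gen * delta_a0 / a0
    if concentrations_uM is None:
        concentrations_uM = tuple(f / q for f in (0.25, 0.5, 1.0, 2.0))
    return SimSpec(
        assay_id="bcb",
        concentrations_uM=concentrations_uM,
        time_s=tuple(np.arange(0.0, 601.0, 60.0)),
        true_params={"a0": a0, "delta_a0": delta_a0, "q": q},
        seed=seed,
        replicates=replicates,
        noise_sd=noise_sd,
        compound_id=compound_id,
    )


def true_bcb_k_prime(spec: SimSpec) -> float:
    """Ground-truth k' implied by a bcb spec: slope(1/dA vs c) * a0."""
    p = spec.true_params
    return p["q"] * p["a0"] / p["delta_a0"]


def simulate_bcb(spec: SimSpec) -> TimeCourseTable:
    """Simulate beta-carotene bleaching traces.

    The control bleaches as a0*e^(-r*t) with the exponent chosen so its
    10-minute drop equals ``delta_a0``; a sample at concentration c bleaches
    along the same normalised trajectory scaled to the endpoint drop
    dA(c) = dA0/(1 + q*c), which makes 1/dA exactly affine in c — the model
    the k' analysis assumes — with true k' = q*a0/dA0.
    """
    p = spec.true_params
    a0, da0, q = p["a0"], p["delta_a0"], p["q"]
    if not (0 < da0 < a0) or q < 0:
        raise DomainError("need 0 < delta_a0 < a0 and q >= 0")
    t = np.asarray(spec.time_s)
    t_end = t[-1]
    r = -np.log(1.0 - da0 / a0) / t_end
    shape = (1.0 - np.exp(-r * t)) / (1.0 - np.exp(-r * t_end))  # 0 -> 1
    rng = spec.rng()
    frames = []
    for rep in range(1, spec.replicates + 1):
        clean = a0 - da0 * shape
        noise = rng.normal(0.0, spec.noise_sd, t.size)
        frames.append(_rows(spec, "control", 0.0, rep, t, clean + noise))
    for c in spec.concentrations_uM:
        da_c = da0 / (1.0 + q * c)
        clean = a0 - da_c * shape
        for rep in range(1, spec.replicates + 1):
            noise = rng.normal(0.0, spec.noise_sd, t.size)
            frames.append(_rows(spec, "sample", c, rep, t, clean + noise))
    return TimeCourseTable(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# cellular antioxidant activity
# ---------------------------------------------------------------------------

def _caa_area(rho: float, t_end: float) -> float:
    """Closed-form area under Fmax*(1 - e^(-rho*t)) on [0, t_end], Fmax = 1."""
    if rho == 0:
        return 0.0
    return t_end - (1.0 - np.exp(-rho * t_end)) / rho


def protection_factor_for_caa(
    target_caa: float, rho_control: float = 1.5e-4, t_end: float = 3600.0
) -> float:
    """Rate-scaling factor whose noiseless CAA score equals ``target_caa``.

    Factors below 1 slow DCF formation (antioxidant, CAA > 0); factors
    above 1 accelerate it (pro-oxidant, CAA < 0).
    """
    if target_caa >= 100.0:
        raise DomainError("CAA = 100 requires complete suppression (factor 0)")
    ca = _caa_area(rho_control, t_end)
    floor = 100.0 * (1.0 - t_end / ca)  # saturated-sample limit
    if target_caa <= floor:
        raise DomainError(
            f"target CAA {target_caa:g} is below the achievable floor "
            f"{floor:.1f} for rho_control = {rho_control:g}"
        )

    def f(g):
        return 100.0 * (1.0 - _caa_area(g * rho_control, t_end) / ca) - target_caa

    return float(optimize.brentq(f, 1e-12, 1e6, xtol=1e-12, rtol=1e-14))


def caa_spec(
    protection_factor: float,
    seed: int,
    rho_control: float = 1.5e-4,
    fmax: float = 1000.0,
    concentrations_uM=(31.25, 62.5),
    time_s=tuple(np.arange(0.0, 3601.0, 60.0)),
    noise_frac: float = 0.005,
    replicates: int = DEFAULT_REPLICATES,
    compound_id: str = "cmpd",
) -> SimSpec:
    """Two-concentration intracellular fluorescence design.

    ``protection_factor`` scales the control DCF formation rate for every
    sample concentration (a scalar, or a mapping conc -> factor); noise is
    ``noise_frac`` of the fluorescence plateau ``fmax``.
    """
    return SimSpec(
        assay_id="caa",
        concentrations_uM=concentrations_uM,
        time_s=time_s,
        true_params={
            "protection_factor": protection_factor,
            "rho_control": rho_control,
            "fmax": fmax,
        },
        seed=seed,
        replicates=replicates,
        noise_sd=noise_frac * fmax,
        compound_id=compound_id,
    )


def simulate_caa(spec: SimSpec) -> TimeCourseTable:
    """Simulate DCF fluorescence accumulation with and without protection."""
    p = spec.true_params
    rho = p["rho_control"]
    fmax = p["fmax"]
    factor = p["protection_factor"]
    if rho <= 0 or fmax <= 0:
        raise DomainError("rho_control and fmax must be > 0")
    t = np.asarray(spec.time_s)
    rng = spec.rng()
    frames = []
    for rep in range(1, spec.replicates + 1):
        clean = fmax * (1.0 - np.exp(-rho * t))
        noise = rng.normal(0.0, spec.noise_sd, t.size)
        frames.append(_rows(spec, "control", 0.0, rep, t, clean + noise))
    for c in spec.concentrations_uM:
        g = factor[c] if isinstance(factor, dict) else factor
        if g < 0:
            raise DomainError("protection factor must be >= 0")
        clean = fmax * (1.0 - np.exp(-g * rho * t))
        for rep in range(1, spec.replicates + 1):
            noise = rng.normal(0.0, spec.noise_sd, t.size)
            frames.append(_rows(spec, "sample", c, rep, t, clean + noise))
    return TimeCourseTable(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def simulate_screen(
    n_active: int,
    n_inactive: int,
    sens: float,
    spec_: float,
    seed: int,
) -> ScreenOutcome:
    """Binomial confusion matrix for a screen with given sensitivity/specificity."""
    if not (0 <= sens <= 1 and 0 <= spec_ <= 1):
        raise DomainError("sens and spec_ must be in [0, 1]")
    rng = np.random.default_rng(seed)
    tp = int(rng.binomial(n_active, sens))
    tn = int(rng.binomial(n_inactive, spec_))
    return ScreenOutcome(tp=tp, fp=n_inactive - tn, tn=tn, fn=n_active - tp)
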