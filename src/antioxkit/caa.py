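"""Cellular antioxidant activity (CAA) assay scoring.

Intracellular DCFH is oxidised to fluorescent DCF by reactive oxygen
species; an effective, cell-permeant antioxidant suppresses the
fluorescence rise.  The score for a compound at one concentration is

    CAA = 100 - (integral SA / integral CA) * 100

with integral SA/CA the areas under the sample and control fluorescence
curves over the shared acquisition window.  CAA is bounded above by 100
(complete protection); 0 means no effect and negative values mean
pro-oxidant behaviour (the compound *increases* intracellular oxidation).

Integration is a plain trapezoid on the acquired grid with no baseline
subtraction: the score is a ratio, so any common multiplicative gain
cancels, while additive baselines are the caller's responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import (
    DegenerateControlError,
    InsufficientDataError,
    ValidationError,
)
from .io import TimeCourseTable

__all__ = ["CAAResult", "integrate_fluorescence", "caa_value", "classify_caa",
           "caa_from_table"]

#: |CAA| below this is classified as inactive rather than a signed call
CAA_ZERO_TOL = 1e-9


def integrate_fluorescence(time_s, fluorescence) -> float:
    """Trapezoidal area under a fluorescence time series."""
    t = np.asarray(time_s, dtype=float)
    f = np.asarray(fluorescence, dtype=float)
    if t.size < 2:
        raise InsufficientDataError("need at least 2 time points to integrate")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("time points must be strictly increasing")
    return float(np.trapezoid(f, t))


def caa_value(area_sample: float, area_control: float) -> float:
    """CAA score, ``100 - (area_sample / area_control) * 100``."""
    if area_control <= 0:
        raise DegenerateControlError("control area must be > 0")
    return float(100.0 - (area_sample / area_control) * 100.0)


def classify_caa(value: float, tol: float = CAA_ZERO_TOL) -> str:
    if value > tol:
        return "antioxidant"
    if value < -tol:
        return "pro_oxidant"
    return "inactive"


@dataclass
class CAAResult:
    """Integrated areas and the CAA score for one (compound, concentration)."""

    compound_id: str
    conc_uM: float
    area_sample: float
    area_control: float
    caa: float
    classification: str

    def summary(self) -> str:
        return (
            f"CAA {self.compound_id} @ {self.conc_uM:g} uM: "
            f"SA = {self.area_sample:.4g}, CA = {self.area_control:.4g}, "
            f"CAA = {self.caa:.1f} ({self.classification})"
        )


def caa_from_table(table: TimeCourseTable, compound_id: str) -> list[CAAResult]:
    """CAA per concentration from a fluorescence time-course table.

    Sample and control areas are averaged over replicates before the ratio
    (the score is reported per concentration; no half-maximal concentration
    is attempted for two-point designs).
    """
    ctrl_areas = [
        integrate_fluorescence(grp["time_s"], grp["signal"])
        for _, grp in table.series(
            assay_id="caa", compound_id=compound_id, role="control"
        )
    ]
    if not ctrl_areas:
        raise DegenerateControlError(f"no caa control series for {compound_id!r}")
    area_control = float(np.mean(ctrl_areas))

    per_conc: dict[float, list[float]] = {}
    for (assay, cmpd, role, conc, rep), grp in table.series(
        assay_id="caa", compound_id=compound_id, role="sample"
    ):
        per_conc.setdefault(conc, []).append(
            integrate_fluorescence(grp["time_s"], grp["signal"])
        )
    if not per_conc:
        raise InsufficientDataError(f"no caa sample series for {compound_id!r}")

    out = []
    for conc in sorted(per_conc):
        area_sample = float(np.mean(per_conc[conc]))
        value = caa_value(area_sample, area_control)
        out.append(
            CAAResult(
                compound_id=compound_id,
                conc_uM=conc,
                area_sample=area_sample,
                area_control=area_control,
                caa=value,
                classification=classify_caa(value),
            )
        )
    return out
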