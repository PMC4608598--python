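"""End-to-end orchestration: time-course table -> results table -> report.

A :class:`RunConfig` fixes every analysis parameter (and the seed for every
stochastic step), so the same configuration over the same inputs always
produces an identical results file.  Per-compound failures do not abort the
run; the affected metric is written with qualifier ``not_tested`` and the
stage error is collected in the report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bcb import BCB_A0_DEFAULT, bcb_aoa_curve, bcb_delta_a, k_prime
from .caa import caa_from_table
from .deoxyribose import CompetitionModel, dr2_blank_correct, dr2_inhibition_curve
from .doseresponse import FivePLModel
from .dpph import dpph_response_curve, fit_dpph_second_order
from .exceptions import AntioxkitError, ValidationError
from .io import ResultsTable, TimeCourseTable, read_timecourses, write_results

logger = logging.getLogger("antioxkit")

_KNOWN_KEYS = {
    "input", "assays", "output_dir", "criterion", "n_boot", "seed", "k_dr",
    "dr_conc", "a0_default", "alpha", "window", "stoichiometry", "dpph0_uM",
    "regime",
}

_WINDOWS_S = {"60min": 3600.0, "6h": 21600.0, "24h": 86400.0}


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    input: str
    output_dir: str
    assays: tuple[str, ...] = ("dpph", "dr2", "bcb", "caa")
    criterion: float = 50.0
    n_boot: int = 1000
    seed: int | None = None
    k_dr: float | None = None          # required whenever dr2 is analysed
    dr_conc: float = 2.5e-3
    a0_default: float = BCB_A0_DEFAULT
    alpha: float = 0.05
    window: str = "24h"
    stoichiometry: float = 1.0
    dpph0_uM: float = 70.0
    regime: str = "excess_dpph"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.window not in _WINDOWS_S:
            raise ValidationError(f"window must be one of {sorted(_WINDOWS_S)}")
        if cfg.n_boot > 0 and cfg.seed is None:
            raise ValidationError("seed must be set whenever bootstrap is enabled")
        return cfg

    @property
    def window_s(self) -> float:
        return _WINDOWS_S[self.window]

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _fit_row(fit, compound, assay, metric, units="uM"):
    if fit.crossing_found:
        qualifier = "ok"
        return dict(
            compound_id=compound, assay_id=assay, metric=metric,
            estimate=fit.ec50, ci_low=fit.ci[0], ci_high=fit.ci[1],
            units=units, qualifier=qualifier,
        )
    qualifier = "no_effect"
    return dict(
        compound_id=compound, assay_id=assay, metric=metric,
        estimate=np.nan, ci_low=np.nan, ci_high=np.nan,
        units=units, qualifier=qualifier,
    )


def run_pipeline(config: RunConfig, table: TimeCourseTable | None = None):
    """Run every configured assay chain and write results + report.

    Returns ``(ResultsTable, report_text)``; also writes ``results.csv``
    and ``report.txt`` into ``config.output_dir``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if table is None:
        table = read_timecourses(config.input)
    logger.info(
        "antioxkit %s | config %s | seed %s", __version__, config.digest(), config.seed
    )
    rows: list[dict] = []
    errors: list[str] = []
    present = set(table.data["assay_id"].unique()) & set(config.assays)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if "dpph" in present:
            _run_dpph(config, table, rows, errors)
        if "dr2" in present:
            _run_dr2(config, table, rows, errors)
        if "bcb" in present:
            _run_bcb(config, table, rows, errors)
        if "caa" in present:
            _run_caa(config, table, rows, errors)

    results = ResultsTable(
        pd.DataFrame(
            rows,
            columns=[
                "compound_id", "assay_id", "metric", "estimate", "ci_low",
                "ci_high", "units", "qualifier", "conc_uM",
            ],
        )
        if rows
        else None
    ) if rows else ResultsTable()
    write_results(results, outdir / "results.csv")

    report = _report_text(config, table, results, errors)
    (outdir / "report.txt").write_text(report)
    return results, report


def _guard(errors, stage, compound):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is None:
                return False
            if isinstance(exc, AntioxkitError):
                errors.append(f"{stage} [{compound}]: {exc}")
                logger.warning("%s failed for %s: %s", stage, compound, exc)
                return True
            return False

    return _Ctx()


def _not_tested(rows, compound, assay, metric, units):
    rows.append(
        dict(compound_id=compound, assay_id=assay, metric=metric,
             estimate=np.nan, ci_low=np.nan, ci_high=np.nan,
             units=units, qualifier="not_tested", conc_uM=np.nan)
    )


def _run_dpph(cfg, table, rows, errors):
    for compound in table.compounds("dpph"):
        done = False
        with _guard(errors, "dpph ec50", compound):
            curve = dpph_response_curve(table, compound, window_s=cfg.window_s)
            fit = FivePLModel(curve, cfg.criterion).fit(n_boot=cfg.n_boot, seed=cfg.seed)
            row = _fit_row(fit, compound, "dpph", "ec50")
            row["conc_uM"] = np.nan
            rows.append(row)
            done = True
        if not done:
            _not_tested(rows, compound, "dpph", "ec50", "uM")
        metric = "k2_60min" if cfg.window == "60min" else "k2_24h"
        done = False
        with _guard(errors, "dpph kinetics", compound):
            kin = fit_dpph_second_order(
                table, compound, dpph0_uM=cfg.dpph0_uM,
                window_s=min(cfg.window_s, 86400.0),
                stoichiometry=cfg.stoichiometry, regime=cfg.regime,
            )
            if np.isfinite(kin.k2_se):
                rows.append(
                    dict(compound_id=compound, assay_id="dpph", metric=metric,
                         estimate=kin.k2, ci_low=kin.k2 - 1.96 * kin.k2_se,
                         ci_high=kin.k2 + 1.96 * kin.k2_se,
                         units="uM-1 s-1", qualifier="ok", conc_uM=np.nan)
                )
            else:
                # endpoint-style plate: no kinetic signal to fit
                _not_tested(rows, compound, "dpph", metric, "uM-1 s-1")
            done = True
        if not done:
            _not_tested(rows, compound, "dpph", metric, "uM-1 s-1")


def _run_dr2(cfg, table, rows, errors):
    for compound in table.compounds("dr2"):
        curve = None
        with _guard(errors, "dr2 ic50", compound):
            curve = dr2_inhibition_curve(table, compound)
            fit = FivePLModel(curve, cfg.criterion).fit(n_boot=cfg.n_boot, seed=cfg.seed)
            row = _fit_row(fit, compound, "dr2", "ic50")
            if not fit.crossing_found and np.all(curve.group_means()[1] < 0):
                row["qualifier"] = "pro_oxidant"
            row["conc_uM"] = np.nan
            rows.append(row)
        if curve is None:
            _not_tested(rows, compound, "dr2", "ic50", "uM")
        if cfg.k_dr is None:
            continue
        done = False
        with _guard(errors, "dr2 competition", compound):
            conc, corrected, a0 = dr2_blank_correct(table, compound)
            fit = CompetitionModel(
                conc, corrected, a0, cfg.k_dr, cfg.dr_conc
            ).fit(alpha=cfg.alpha)
            rows.append(
                dict(compound_id=compound, assay_id="dr2", metric="k_oh",
                     estimate=fit.k_s,
                     ci_low=fit.k_s - 1.96 * fit.k_s_se,
                     ci_high=fit.k_s + 1.96 * fit.k_s_se,
                     units="M-1 s-1",
                     qualifier="ok" if fit.linearity == "linear" else "not_tested",
                     conc_uM=np.nan)
            )
            done = True
        if not done:
            _not_tested(rows, compound, "dr2", "k_oh", "M-1 s-1")


def _run_bcb(cfg, table, rows, errors):
    for compound in table.compounds("bcb"):
        done = False
        with _guard(errors, "bcb ic50", compound):
            curve = bcb_aoa_curve(table, compound)
            fit = FivePLModel(curve, cfg.criterion).fit(n_boot=cfg.n_boot, seed=cfg.seed)
            row = _fit_row(fit, compound, "bcb", "ic50")
            row["conc_uM"] = np.nan
            rows.append(row)
            done = True
        if not done:
            _not_tested(rows, compound, "bcb", "ic50", "uM")
        done = False
        with _guard(errors, "bcb k_prime", compound):
            conc, da = bcb_delta_a(table, compound)
            fit = k_prime((conc, da), a0_control=cfg.a0_default)
            rows.append(
                dict(compound_id=compound, assay_id="bcb", metric="k_prime",
                     estimate=fit.k_prime,
                     ci_low=fit.k_prime - 1.96 * fit.k_prime_se,
                     ci_high=fit.k_prime + 1.96 * fit.k_prime_se,
                     units="uM-1", qualifier="ok", conc_uM=np.nan)
            )
            done = True
        if not done:
            _not_tested(rows, compound, "bcb", "k_prime", "uM-1")


def _run_caa(cfg, table, rows, errors):
    for compound in table.compounds("caa"):
        with _guard(errors, "caa", compound):
            for res in caa_from_table(table, compound):
                rows.append(
                    dict(compound_id=compound, assay_id="caa", metric="caa_value",
                         estimate=res.caa, ci_low=res.caa, ci_high=res.caa,
                         units="dimensionless", qualifier="ok",
                         conc_uM=res.conc_uM)
                )


def _report_text(cfg, table, results, errors) -> str:
    lines = [
        f"antioxkit {__version__} pipeline report",
        f"config digest: {cfg.digest()}   seed: {cfg.seed}",
        f"input rows: {len(table)}   results rows: {len(results)}",
        "",
    ]
    df = results.data
    for assay in sorted(df["assay_id"].unique()) if len(df) else []:
        lines.append(f"[{assay}]")
        for row in df[df["assay_id"] == assay].itertuples():
            if row.qualifier == "ok":
                lines.append(
                    f"  {row.compound_id:>12}  {row.metric:<9} "
                    f"{row.estimate:.4g} [{row.ci_low:.4g}, {row.ci_high:.4g}] {row.units}"
                )
            else:
                lines.append(
                    f"  {row.compound_id:>12}  {row.metric:<9} {row.qualifier}"
                )
        lines.append("")
    if errors:
        lines.append("stage errors:")
        lines.extend(f"  - {e}" for e in errors)
        lines.append("")
    return "\n".join(lines)
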