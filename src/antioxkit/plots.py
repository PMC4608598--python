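"""Plotting helpers for dose-response curves and kinetic traces.

All functions draw onto a provided matplotlib Axes (or create one) and
return it, following the usual convention of plotting layers over analysis
results.  The Agg backend is forced so reports render headlessly.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .doseresponse import DoseResponseFit, ResponseCurve
from .io import read_results, read_timecourses

__all__ = ["plot_dose_response", "plot_kinetics", "render_report"]


def plot_dose_response(curve: ResponseCurve, fit: DoseResponseFit | None = None,
                       ax=None):
    """Scatter the response curve and overlay the fitted 5PL."""
    if ax is None:
        _, ax = plt.subplots()
    ax.semilogx(curve.conc, curve.response, "o", alpha=0.6, label="data")
    if fit is not None:
        xg = np.geomspace(curve.conc.min() / 3, curve.conc.max() * 3, 200)
        ax.semilogx(xg, fit.predict(xg), "-", label="5PL fit")
        if fit.crossing_found:
            ax.axvline(fit.ec50, ls="--", lw=0.8, color="grey")
            ax.axhline(fit.criterion, ls="--", lw=0.8, color="grey")
            ax.annotate(f"EC50 = {fit.ec50:.3g} uM", (fit.ec50, fit.criterion),
                        textcoords="offset points", xytext=(5, 5), fontsize=8)
    ax.set_xlabel("concentration (uM)")
    ax.set_ylabel(curve.response_kind.replace("_", " "))
    ax.set_title(curve.compound_id)
    ax.legend(fontsize=8)
    return ax


def plot_kinetics(table, compound_id: str, assay_id: str = "dpph", ax=None):
    """Overlay signal traces of one compound, one line per (conc, replicate)."""
    if ax is None:
        _, ax = plt.subplots()
    for (assay, cmpd, role, conc, rep), grp in table.series(
        assay_id=assay_id, compound_id=compound_id, role="sample"
    ):
        ax.plot(grp["time_s"], grp["signal"], lw=0.8,
                label=f"{conc:g} uM" if rep == 1 else None)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("signal")
    ax.set_title(f"{compound_id} ({assay_id})")
    ax.legend(fontsize=7)
    return ax


def render_report(results_file, input_file, outdir) -> int:
    """Write summary figures for a results CSV (and optional raw table).

    Returns the number of figures written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results = read_results(results_file)
    n = 0

    df = results.data
    ok = df[(df["qualifier"] == "ok") & df["metric"].isin(["ec50", "ic50"])]
    if len(ok):
        fig, ax = plt.subplots(figsize=(6, 3 + 0.2 * len(ok)))
        labels = ok["compound_id"] + " (" + ok["assay_id"] + ")"
        y = np.arange(len(ok))
        ax.barh(y, ok["estimate"], xerr=[
            ok["estimate"] - ok["ci_low"], ok["ci_high"] - ok["estimate"]
        ], height=0.6)
        ax.set_yticks(y, labels, fontsize=7)
        ax.set_xlabel("EC50 / IC50 (uM)")
        fig.tight_layout()
        fig.savefig(outdir / "half_maximal_concentrations.png", dpi=120)
        plt.close(fig)
        n += 1

    if input_file is not None:
        table = read_timecourses(input_file)
        for assay in sorted(table.data["assay_id"].unique()):
            for compound in table.compounds(assay):
                fig, ax = plt.subplots()
                plot_kinetics(table, compound, assay, ax=ax)
                fig.tight_layout()
                fig.savefig(outdir / f"traces_{assay}_{compound}.png", dpi=120)
                plt.close(fig)
                n += 1
    return n
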