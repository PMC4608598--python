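"""Tabular I/O for plate-reader time courses and results tables.

The package works on a single canonical long ("tidy") layout: one row per
signal reading, keyed by assay, compound, well role, concentration,
replicate and time.  All unit conversions happen at ingestion; internally
concentrations are always micromolar and times are always seconds.

Reference values from the published activity tables of the source study
(EC50/IC50 intervals, rate constants, k' statistics, cellular antioxidant
activity scores) ship with the package and are exposed through
:func:`load_paper_fixtures`.  They are *fixtures*: the raw absorbance and
fluorescence data behind them were never deposited, so they support
ordering and magnitude checks, not recomputation.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError

ASSAYS = ("dpph", "dr2", "bcb", "caa")
ROLES = ("sample", "control", "blank_bl1", "blank_bl2", "blank_bl3")
BLANK_ROLES = ("blank_bl1", "blank_bl2", "blank_bl3")
METRICS = ("ec50", "ic50", "k2_60min", "k2_24h", "k_prime", "k_oh", "caa_value")
QUALIFIERS = ("ok", "no_effect", "pro_oxidant", "insoluble", "not_tested")

TIMECOURSE_COLUMNS = (
    "assay_id",
    "compound_id",
    "role",
    "conc_uM",
    "replicate",
    "time_s",
    "signal",
)

RESULTS_COLUMNS = (
    "compound_id",
    "assay_id",
    "metric",
    "estimate",
    "ci_low",
    "ci_high",
    "units",
    "qualifier",
)

# scale factors to the canonical units (uM, s)
_CONC_FACTORS = {"uM": 1.0, "µM": 1.0, "um": 1.0, "nM": 1e-3, "mM": 1e3, "M": 1e6}
_TIME_FACTORS = {"s": 1.0, "sec": 1.0, "min": 60.0, "h": 3600.0, "hr": 3600.0}

_SERIES_KEY = ["assay_id", "compound_id", "role", "conc_uM", "replicate"]


@dataclass
class TimeCourseTable:
    """Long-format signal measurements.

    One row per reading; a *series* is the set of rows sharing
    (assay_id, compound_id, role, conc_uM, replicate), ordered by time.
    """

    data: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self) -> "TimeCourseTable":
        df = self.data
        for col in TIMECOURSE_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing required column: {col!r}")
        bad_assay = set(df["assay_id"]) - set(ASSAYS)
        if bad_assay:
            raise ValidationError(f"unknown assay_id values: {sorted(bad_assay)}")
        bad_role = set(df["role"]) - set(ROLES)
        if bad_role:
            raise ValidationError(f"unknown role values: {sorted(bad_role)}")
        for col in ("conc_uM", "time_s", "signal"):
            if not np.issubdtype(df[col].dtype, np.number):
                raise ValidationError(f"column {col!r} must be numeric")
        if df[["conc_uM", "time_s", "signal"]].isna().any().any():
            raise ValidationError("missing values in conc_uM/time_s/signal are rejected")
        if (df["time_s"] < 0).any():
            raise ValidationError("time_s must be >= 0")
        if (df["conc_uM"] < 0).any():
            raise ValidationError("conc_uM must be >= 0")
        if (df["replicate"] < 1).any():
            raise ValidationError("replicate must be >= 1")
        ctrl = df[df["role"] == "control"]
        if (ctrl["conc_uM"] != 0).any():
            raise ValidationError("control rows must have conc_uM = 0")
        blanks = df[df["role"].isin(BLANK_ROLES)]
        if (blanks["assay_id"] != "dr2").any():
            raise ValidationError("blank roles are defined only for assay dr2")
        dup = df.duplicated(subset=_SERIES_KEY + ["time_s"])
        if dup.any():
            key = df.loc[dup.idxmax(), _SERIES_KEY + ["time_s"]].tolist()
            raise ValidationError(f"duplicated (series, time) key: {key}")
        for key, grp in df.groupby(_SERIES_KEY, sort=False):
            t = grp["time_s"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise ValidationError(
                    f"non-monotone time within series {tuple(key)}"
                )
        return self

    # -- convenience accessors -------------------------------------------------

    def select(self, **where) -> "pd.DataFrame":
        """Filter rows by column equality, e.g. ``select(assay_id='dpph')``."""
        df = self.data
        for col, val in where.items():
            df = df[df[col] == val]
        return df

    def series(self, **where):
        """Iterate ``(key_tuple, frame)`` over measurement series."""
        df = self.select(**where)
        yield from df.groupby(_SERIES_KEY, sort=True)

    def compounds(self, assay_id: str) -> list[str]:
        df = self.select(assay_id=assay_id, role="sample")
        return sorted(df["compound_id"].unique())

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.data)


def read_timecourses(path, dialect: str | None = None) -> TimeCourseTable:
    """Read a plate-reader time-course table from CSV or TSV.

    Parameters
    ----------
    path : str, Path or file-like
        The file to read.  Must contain the canonical columns
        ``assay_id, compound_id, role, conc_uM, replicate, time_s, signal``.
    dialect : {'csv', 'tsv'}, optional
        Field separator; inferred from the file extension when omitted.

    Optional columns ``units_conc`` and ``units_time`` trigger row-wise
    conversion of ``conc_uM`` and ``time_s`` to the canonical units
    (micromolar, seconds) and are then dropped.
    """
    if dialect is None:
        suffix = Path(path).suffix.lower() if not hasattr(path, "read") else ".csv"
        dialect = "tsv" if suffix in (".tsv", ".tab") else "csv"
    sep = "\t" if dialect == "tsv" else ","
    df = pd.read_csv(path, sep=sep)
    for col in TIMECOURSE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    if "units_conc" in df.columns:
        factors = df["units_conc"].map(_CONC_FACTORS)
        if factors.isna().any():
            bad = df.loc[factors.isna(), "units_conc"].unique()
            raise ValidationError(f"unknown concentration units: {list(bad)}")
        df["conc_uM"] = df["conc_uM"] * factors
        df = df.drop(columns=["units_conc"])
    if "units_time" in df.columns:
        factors = df["units_time"].map(_TIME_FACTORS)
        if factors.isna().any():
            bad = df.loc[factors.isna(), "units_time"].unique()
            raise ValidationError(f"unknown time units: {list(bad)}")
        df["time_s"] = df["time_s"] * factors
        df = df.drop(columns=["units_time"])
    df = df[list(TIMECOURSE_COLUMNS)].reset_index(drop=True)
    return TimeCourseTable(df)


@dataclass
class ResultsTable:
    """Per-(compound, assay, metric) estimates with 95% intervals.

    Mirrors the layout of the published activity tables.  ``qualifier``
    records why an estimate may be absent: ``no_effect`` (the response never
    reached the criterion), ``pro_oxidant`` (negative response),
    ``insoluble`` or ``not_tested``.  Optional columns ``conc_uM`` (for
    per-concentration metrics such as the cellular antioxidant activity
    score) and ``is_standard`` are preserved when present.
    """

    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=RESULTS_COLUMNS))

    def __post_init__(self):
        self.validate()

    def validate(self) -> "ResultsTable":
        df = self.data
        for col in RESULTS_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing required results column: {col!r}")
        if len(df) == 0:
            return self
        bad = set(df["metric"]) - set(METRICS)
        if bad:
            raise ValidationError(f"unknown metric values: {sorted(bad)}")
        bad = set(df["qualifier"]) - set(QUALIFIERS)
        if bad:
            raise ValidationError(f"unknown qualifier values: {sorted(bad)}")
        ok = df["qualifier"] == "ok"
        est, lo, hi = (df.loc[ok, c].astype(float) for c in ("estimate", "ci_low", "ci_high"))
        if ((lo > est) | (est > hi)).any():
            raise ValidationError("require ci_low <= estimate <= ci_high when qualifier is ok")
        units_per_metric = df.groupby("metric")["units"].nunique()
        if (units_per_metric > 1).any():
            mixed = units_per_metric[units_per_metric > 1].index.tolist()
            raise ValidationError(f"inconsistent units for metrics: {mixed}")
        return self

    def add_row(self, **row) -> None:
        new = pd.DataFrame([row])
        self.data = pd.concat([self.data, new], ignore_index=True) if len(self.data) else new
        self.validate()

    def __len__(self) -> int:
        return len(self.data)


def write_results(results: ResultsTable, path) -> None:
    """Write a results table to CSV.

    Numeric fields are written at full float precision so that a read-back
    reproduces the table exactly; a human-readable ``display`` column carries
    the rounded form.  Rows whose qualifier is not ``ok`` have their numeric
    fields serialised as empty.
    """
    df = results.data.copy()
    num_cols = ["estimate", "ci_low", "ci_high"]

    def _fmt(v):
        if pd.isna(v):
            return ""
        return format(float(v), ".17g")

    def _display(row):
        if row["qualifier"] != "ok":
            return row["qualifier"]
        est = float(row["estimate"])
        lo, hi = float(row["ci_low"]), float(row["ci_high"])
        return f"{est:.4g} ({lo:.4g}–{hi:.4g}) {row['units']}"

    out = df.copy()
    out["display"] = df.apply(_display, axis=1) if len(df) else ""
    not_ok = out["qualifier"] != "ok"
    for col in num_cols:
        out[col] = out[col].map(_fmt)
        out.loc[not_ok, col] = ""
    out.to_csv(path, index=False)


def read_results(path) -> ResultsTable:
    """Read back a CSV written by :func:`write_results`."""
    df = pd.read_csv(path, dtype={"compound_id": str})
    if "display" in df.columns:
        df = df.drop(columns=["display"])
    for col in ("estimate", "ci_low", "ci_high"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
    return ResultsTable(df)


def load_paper_fixtures() -> dict[str, ResultsTable]:
    """Load the packaged reference activity tables.

    Returns a mapping ``{"table1": ..., ..., "table6": ...}``:

    ========  =======================================================
    table1    DPPH assay EC50 95% intervals (10 novel + 8 standards)
    table2    DPPH second-order rate constants (60 min and 24 h)
    table3    2-deoxyribose assay IC50 95% intervals
    table4    beta-carotene bleaching assay IC50 95% intervals
    table5    beta-carotene bleaching k' statistics
    table6    cellular antioxidant activity scores per concentration
    ========  =======================================================

    Interval-only entries store the interval midpoint as the estimate;
    value +/- error entries store (value - err, value + err) as the bounds.
    """
    out = {}
    pkg = resources.files("antioxkit.data")
    for name in ("table1", "table2", "table3", "table4", "table5", "table6"):
        text = (pkg / f"{name}.csv").read_text(encoding="utf-8")
        df = pd.read_csv(_io.StringIO(text), dtype={"compound_id": str})
        for col in ("estimate", "ci_low", "ci_high"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        out[name] = ResultsTable(df)
    return out
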