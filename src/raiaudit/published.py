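"""Access to the published quarterly indicator tables.

The package ships the printed quarterly columns of the published
Ontario CCRS audit (1996-2011) as tidy fixture CSVs, one file per table:

==========  ==========================================================
table1      prevalence flags (admission share, CPS 3+, RUG-ADL 11+,
            ABS 5+, DRS 3+) by sector
table2      service use (therapy minutes, nursing rehabilitation,
            OT/PT receipt, rehabilitation intensity)
table4      convergent-validity statistics vs the CPS
table5      Cronbach's alpha for the ADL Long Form, DRS and ABS
table6      cross-sectional logical errors (mood, ADL, intake, ulcer)
table7      therapy logical errors and the any-problem rate
table8      height/weight/age range errors
table9      diagnosis reversals between consecutive assessments
table10     block carry-forward (autopopulation) indicators
table11     annual sign-off lag distribution
==========  ==========================================================

Quarterly rows are labelled ``YYYY_Q``; the published intercept/slope
summary rows are labelled ``intercept`` and ``slope``.  Values are in
the printed units (percent, minutes, correlations, alphas).
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .records import quarter_ordinal

_QUARTER_RE = r"^\d{4}_\d$"


def load_table(name: str) -> pd.DataFrame:
    """Full fixture table including the intercept/slope rows."""
    ref = resources.files("raiaudit").joinpath("data", "tables", f"{name}.csv")
    with ref.open() as fh:
        return pd.read_csv(fh, dtype={"quarter": str})


def published_series(table: str, column: str) -> pd.DataFrame:
    """Quarterly values of one printed column, shaped for fit_trend.

    Returns columns quarter / quarter_index / value / n; the index
    counts calendar quarters from the column's first non-missing
    quarter, so gap quarters keep their calendar spacing.
    """
    df = load_table(table)
    rows = df[df["quarter"].str.match(_QUARTER_RE)].dropna(subset=[column]).copy()
    ords = rows["quarter"].map(quarter_ordinal)
    rows["quarter_index"] = ords - ords.min()
    rows["value"] = pd.to_numeric(rows[column])
    ncol = "n_" + column.rsplit("_", 1)[-1]
    rows["n"] = pd.to_numeric(rows[ncol], errors="coerce") if ncol in df else pd.NA
    return rows[["quarter", "quarter_index", "value", "n"]].reset_index(drop=True)


def published_trend(table: str, column: str) -> tuple[float, float]:
    """The printed (intercept, slope) summary pair for one column."""
    df = load_table(table)
    intercept = float(df.loc[df["quarter"] == "intercept", column].iloc[0])
    slope = float(df.loc[df["quarter"] == "slope", column].iloc[0])
    return intercept, slope
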