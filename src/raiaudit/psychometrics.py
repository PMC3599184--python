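"""Quarterly aggregation, internal consistency, association statistics,
trend fits and cross-setting concordance.

Quarterly indicator series are summarized by unweighted ordinary least
squares on the quarter index; following the published convention the
first observed quarter of a sector sits at x = 1, so the intercept is
the fitted value one quarter-step before the first observation (numerically
close to the first observed value for a flat series).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import add_quarter_columns, quarter_ordinal


@dataclass
class QuarterlySeries:
    """Per-quarter values of one indicator in one sector."""

    sector: str
    indicator: str
    data: pd.DataFrame  # columns: quarter, quarter_index, value, n

    def __post_init__(self):
        d = self.data
        if len(d) and not d["quarter_index"].is_monotonic_increasing:
            raise ValueError("quarters must be strictly increasing")

    @property
    def values(self) -> np.ndarray:
        return self.data["value"].to_numpy(dtype=float)


@dataclass
class TrendFit:
    intercept: float
    slope: float
    n_quarters: int


def quarterly_rate(
    frame: pd.DataFrame,
    indicator,
    sector: str,
    name: str | None = None,
) -> QuarterlySeries:
    """Quarterly proportion (boolean indicator) or mean (numeric) for a sector.

    ``indicator`` is a column name or a callable mapping the frame to a
    Series; NaN entries drop out of that quarter's denominator, and
    quarters with an empty denominator are omitted.
    """
    sub = frame.loc[frame["sector"] == sector]
    if "quarter" not in sub.columns:
        sub = add_quarter_columns(sub)
    values = sub[indicator] if isinstance(indicator, str) else indicator(sub)
    values = pd.to_numeric(values, errors="coerce")
    grouped = values.groupby(sub["quarter"])
    table = pd.DataFrame({"value": grouped.mean(), "n": grouped.count()})
    table = table.loc[table["n"] >= 1].reset_index(names="quarter")
    ords = table["quarter"].map(quarter_ordinal)
    table["quarter_index"] = ords - ords.min()
    table = table.sort_values("quarter_index").reset_index(drop=True)
    table = table[["quarter", "quarter_index", "value", "n"]]
    return QuarterlySeries(sector=sector, indicator=name or str(indicator), data=table)


def fit_trend(series: QuarterlySeries | pd.DataFrame) -> TrendFit:
    """Unweighted OLS of the quarterly values on the quarter index.

    x = quarter_index + 1, so the sector's first observed quarter is at
    x = 1 (the published anchoring).  Requires at least two quarters.
    """
    data = series.data if isinstance(series, QuarterlySeries) else series
    data = data.dropna(subset=["value"])
    if len(data) < 2:
        raise ValueError("need at least two quarters to fit a trend")
    x = data["quarter_index"].to_numpy(dtype=float) + 1.0
    y = data["value"].to_numpy(dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    return TrendFit(intercept=float(intercept), slope=float(slope), n_quarters=len(data))


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha with listwise deletion of incomplete rows.

    alpha = k/(k-1) * (1 - sum of item variances / variance of the total),
    sample variances (denominator n-1).  Returns NaN when fewer than
    three complete rows remain or the total score has zero variance.
    """
    X = pd.DataFrame(item_matrix).apply(pd.to_numeric, errors="coerce")
    X = X.dropna(axis=0)
    k = X.shape[1]
    if k < 2 or len(X) < 3:
        return float("nan")
    arr = X.to_numpy(dtype=float)
    total_var = arr.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return float("nan")
    return float(k / (k - 1) * (1 - arr.var(axis=0, ddof=1).sum() / total_var))


def association(xs, ys, kind: str) -> float:
    """Pearson r, Spearman rho, or Cramér's V (no bias correction).

    Pairs with a missing member are dropped; degenerate (constant)
    input returns NaN.
    """
    x = pd.to_numeric(pd.Series(xs).reset_index(drop=True), errors="coerce")
    y = pd.to_numeric(pd.Series(ys).reset_index(drop=True), errors="coerce")
    keep = x.notna() & y.notna()
    x, y = x[keep].to_numpy(), y[keep].to_numpy()
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    if kind == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if kind == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    if kind == "cramers_v":
        table = pd.crosstab(x, y).to_numpy()
        chi2 = stats.chi2_contingency(table, correction=False).statistic
        n = table.sum()
        return float(np.sqrt(chi2 / (n * (min(table.shape) - 1))))
    raise ValueError(f"unknown association kind {kind!r}")


#: the four convergent-validity statistics tracked quarterly
CONVERGENT_PAIRS = (
    ("bowel_cps3_v", "bowel_continence", "cps_ge3", "cramers_v"),
    ("adl_cps_r", "adl_long_form", "cps", "pearson"),
    ("pain_cps_r", "pain", "cps", "pearson"),
    ("abs_cps_r", "abs", "cps", "pearson"),
)


def convergent_validity_series(
    scored: pd.DataFrame, sector: str
) -> dict[str, QuarterlySeries]:
    """Quarterly convergent-validity statistics for one sector.

    ``scored`` is a record frame with the scale columns appended
    (see :func:`raiaudit.scales.score_frame`).
    """
    sub = scored.loc[scored["sector"] == sector]
    if "quarter" not in sub.columns:
        sub = add_quarter_columns(sub)
    out = {}
    for name, xcol, ycol, kind in CONVERGENT_PAIRS:
        rows = []
        for quarter, g in sub.groupby("quarter"):
            v = association(g[xcol], g[ycol], kind)
            rows.append({"quarter": quarter, "value": v, "n": int(len(g))})
        table = pd.DataFrame(rows)
        ords = table["quarter"].map(quarter_ordinal)
        table["quarter_index"] = ords - ords.min()
        table = table.sort_values("quarter_index").reset_index(drop=True)
        out[name] = QuarterlySeries(sector, name, table[["quarter", "quarter_index", "value", "n"]])
    return out


def cross_setting_concordance(stats_a: Mapping[str, float], stats_b: Mapping[str, float]) -> float:
    """R² of the least-squares line through paired named statistics.

    The two mappings are matched on statistic name; at least three
    shared, non-missing statistics are required.
    """
    shared = [
        k
        for k in stats_a
        if k in stats_b
        and np.isfinite(stats_a[k])
        and np.isfinite(stats_b[k])
    ]
    if len(shared) < 3:
        raise ValueError("need at least three shared statistics")
    a = np.array([stats_a[k] for k in shared], dtype=float)
    b = np.array([stats_b[k] for k in shared], dtype=float)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0  # identical constant lists are perfectly concordant
    r = stats.pearsonr(a, b).statistic
    return float(r * r)
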