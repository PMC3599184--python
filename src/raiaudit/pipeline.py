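"""End-to-end orchestration: score, audit, aggregate, report.

The functions here glue the scoring, rule-engine and psychometric
modules into the table-shaped outputs the command line and the analysis
scripts emit: one tidy frame per published-table analogue, each with
columns sector / quarter / indicator / value / n and trend rows
appended (quarter = "intercept" / "slope").
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .dictionary import (
    ABS_ITEMS,
    ADL_LONG_FORM_NAMES,
    DIAGNOSIS_ITEMS,
    DRS_ITEMS,
    ItemDictionary,
    default_dictionary,
)
from .psychometrics import (
    QuarterlySeries,
    association,
    convergent_validity_series,
    cronbach_alpha,
    cross_setting_concordance,
    fit_trend,
    quarterly_rate,
)
from .records import add_quarter_columns, exclude_comatose, quarter_ordinal
from .rules import audit_frame, audit_pairs, service_frame
from .scales import SCALE_COLUMNS, score_frame

SCALE_ITEM_BLOCKS = {
    "adl": [f"adl_{n}_perf" for n in ADL_LONG_FORM_NAMES],
    "drs": list(DRS_ITEMS),
    "abs": list(ABS_ITEMS),
}


def scale_item_matrix(frame: pd.DataFrame, scale: str) -> pd.DataFrame:
    """Item columns entering a scale, on the scored metric.

    ADL items recode 8 ("did not occur") to 4, as the Long Form sums
    them; the mood and behaviour items enter as coded.
    """
    m = frame[SCALE_ITEM_BLOCKS[scale]]
    return m.replace(8, 4) if scale == "adl" else m

#: 19 items whose pairwise rank correlations enter the concordance list
CONCORDANCE_ITEMS = (
    list(DRS_ITEMS)
    + list(ABS_ITEMS)
    + ["short_term_memory", "decision_making", "making_self_understood",
       "pain_frequency", "pain_intensity", "bowel_continence",
       "adl_bed_mobility_perf", "adl_transfer_perf"]
)


def prepare(frame: pd.DataFrame, dictionary: ItemDictionary | None = None) -> pd.DataFrame:
    """Comatose exclusion, quarter assignment and scale scoring."""
    dictionary = dictionary or default_dictionary()
    frame = exclude_comatose(frame)
    frame = add_quarter_columns(frame)
    scores = score_frame(frame)
    return pd.concat([frame, scores], axis=1)


def _tidy(series_by_sector: dict[str, dict[str, "QuarterlySeries"]]) -> pd.DataFrame:
    rows = []
    for sector, series_map in series_by_sector.items():
        for indicator, qs in series_map.items():
            d = qs.data
            for _, r in d.iterrows():
                rows.append((sector, r["quarter"], indicator, r["value"], r["n"]))
            try:
                fit = fit_trend(qs)
                rows.append((sector, "intercept", indicator, fit.intercept, None))
                rows.append((sector, "slope", indicator, fit.slope, None))
            except ValueError:
                pass
    return pd.DataFrame(rows, columns=["sector", "quarter", "indicator", "value", "n"])


def _series_set(scored, sector, indicators, percent=False):
    out = {}
    for name, col in indicators.items():
        qs = quarterly_rate(scored, col, sector, name=name)
        if percent:
            qs.data["value"] *= 100.0
        out[name] = qs
    return out


def prevalence_table(scored: pd.DataFrame) -> pd.DataFrame:
    """Analogue of the published prevalence table (percent units)."""
    indicators = {
        "admission": lambda df: (df["assessment_type"] == "admission").astype(float),
        "cps3": "cps_ge3",
        "rugadl11": "rugadl_ge11",
        "abs5": "abs_ge5",
        "drs3": "drs_ge3",
    }
    return _tidy({
        s: _series_set(scored, s, indicators, percent=True)
        for s in sorted(scored["sector"].unique())
    })


def service_table(scored: pd.DataFrame, dictionary: ItemDictionary) -> pd.DataFrame:
    sv = service_frame(scored, dictionary)
    joined = pd.concat([scored, sv], axis=1)
    out = {}
    for s in sorted(scored["sector"].unique()):
        series = {"therapy_minutes": quarterly_rate(joined, "total_therapy_minutes", s,
                                                    name="therapy_minutes")}
        pct = _series_set(joined, s, {
            "nursing_rehab_2plus": "nursing_rehab_2plus",
            "any_ot": "any_ot",
            "any_pt": "any_pt",
            "rehab_3d45m": "rehab_3d45m",
            "rehab_5d150m": "rehab_5d150m",
        }, percent=True)
        series.update(pct)
        out[s] = series
    return _tidy(out)


def validity_table(scored: pd.DataFrame) -> pd.DataFrame:
    return _tidy({
        s: convergent_validity_series(scored, s)
        for s in sorted(scored["sector"].unique())
    })


def reliability_table(scored: pd.DataFrame) -> pd.DataFrame:
    """Quarterly Cronbach's alpha per scale block and sector."""
    out = {}
    for s in sorted(scored["sector"].unique()):
        sub = scored[scored["sector"] == s]
        series = {}
        for scale, items in SCALE_ITEM_BLOCKS.items():
            rows = []
            for quarter, g in sub.groupby("quarter"):
                rows.append({"quarter": quarter,
                             "value": cronbach_alpha(scale_item_matrix(g, scale)),
                             "n": len(g)})
            table = pd.DataFrame(rows).sort_values("quarter").reset_index(drop=True)
            ords = table["quarter"].map(quarter_ordinal)
            table["quarter_index"] = ords - ords.min()
            series[f"alpha_{scale}"] = QuarterlySeries(
                s, f"alpha_{scale}",
                table[["quarter", "quarter_index", "value", "n"]])
        out[s] = series
    return _tidy(out)


def error_tables(scored: pd.DataFrame, dictionary: ItemDictionary
                 ) -> dict[str, pd.DataFrame]:
    """Cross-sectional error-rate tables (percent) and the sign-off table."""
    flags = audit_frame(scored, dictionary)
    joined = pd.concat([scored, flags], axis=1)
    groups = {
        "clinical_errors": ["mood_persistence_err", "adl_dnoc_err",
                            "nutrition_err", "ulcer_err"],
        "therapy_errors": ["therapy_day15_err", "therapy_nodays_err",
                           "therapy_exceed_err", "any_therapy_err",
                           "any_logical_err"],
        "vitals_errors": ["height_err", "weight_err", "age_err"],
    }
    out = {}
    for name, cols in groups.items():
        out[name] = _tidy({
            s: _series_set(joined, s, {c: c for c in cols}, percent=True)
            for s in sorted(scored["sector"].unique())
        })

    # annual sign-off lag distribution
    rows = []
    joined["year"] = pd.to_datetime(joined["reference_date"]).dt.year
    for (s, year), g in joined.groupby(["sector", "year"]):
        n = g["signoff_category"].notna().sum()
        for cat in ("neg", "d0_6", "d7_30", "gt30"):
            share = (g["signoff_category"] == cat).sum() / n * 100 if n else np.nan
            rows.append((s, year, cat, share, n))
    out["signoff"] = pd.DataFrame(
        rows, columns=["sector", "year", "category", "percent", "n"])
    return out


def pair_tables(scored: pd.DataFrame, dictionary: ItemDictionary) -> pd.DataFrame:
    """Quarterly reversal and carry-forward rates (percent, by T2 quarter)."""
    pflags = audit_pairs(scored, dictionary)
    if pflags.empty:
        return pd.DataFrame(columns=["sector", "quarter", "indicator", "value", "n"])
    t2 = scored.loc[pflags["i2"]].reset_index(drop=True)
    joined = pd.concat([t2[["sector", "quarter"]],
                        pflags.reset_index(drop=True).drop(columns=["i1", "i2"])], axis=1)
    cols = [c for c in joined.columns if c.startswith(("reversal_", "auto_"))]
    return _tidy({
        s: _series_set(joined, s, {c: c for c in cols}, percent=True)
        for s in sorted(joined["sector"].unique())
    })


def sector_statistics(scored: pd.DataFrame, sector: str) -> dict[str, float]:
    """Named statistic list for cross-setting concordance.

    Three scale alphas, the 15 pairwise Pearson correlations among the
    six scale scores, and the pairwise Spearman rank correlations among
    19 individual items (171 pairs) — 189 statistics in total.
    """
    sub = scored[scored["sector"] == sector]
    stats: dict[str, float] = {}
    for scale in SCALE_ITEM_BLOCKS:
        stats[f"alpha_{scale}"] = cronbach_alpha(scale_item_matrix(sub, scale))
    for i, a in enumerate(SCALE_COLUMNS):
        for b in SCALE_COLUMNS[i + 1:]:
            stats[f"r_{a}_{b}"] = association(sub[a], sub[b], "pearson")
    for i, a in enumerate(CONCORDANCE_ITEMS):
        for b in CONCORDANCE_ITEMS[i + 1:]:
            stats[f"rho_{a}_{b}"] = association(sub[a], sub[b], "spearman")
    return stats


def concordance(scored: pd.DataFrame, sector_a: str = "CCC",
                sector_b: str = "LTC") -> float:
    return cross_setting_concordance(
        sector_statistics(scored, sector_a), sector_statistics(scored, sector_b)
    )


def recovery_report(frame: pd.DataFrame, truth: pd.DataFrame,
                    dictionary: ItemDictionary) -> pd.DataFrame:
    """Audited rate vs injected rate for every error type.

    Cross-sectional rules are deterministic, so on a cohort whose only
    triggering conditions are injected ones the audited and injected
    counts must agree exactly; the report makes that visible.
    """
    from .cohort import AUTOPOP_BLOCKS

    flags = audit_frame(frame, dictionary)
    pflags = audit_pairs(frame, dictionary)
    flag_of = {
        "mood": "mood_persistence_err", "adl_dnoc": "adl_dnoc_err",
        "nutrition": "nutrition_err", "ulcer": "ulcer_err",
        "therapy_day15": "therapy_day15_err", "therapy_nodays": "therapy_nodays_err",
        "therapy_exceed": "therapy_exceed_err", "height": "height_err",
        "weight": "weight_err", "age": "age_err",
    }
    rows = []
    for err, col in flag_of.items():
        detected = flags[col]
        rows.append({
            "error": err, "level": "record",
            "n": int(detected.notna().sum()),
            "detected": int((detected == 1).sum()),
            "injected": int(truth[f"injected_{err}"].sum()),
        })
    t2 = pflags["i2"].to_numpy() if len(pflags) else np.array([], dtype=int)
    for dx in DIAGNOSIS_ITEMS:
        col = pflags[f"reversal_{dx}"] if len(pflags) else pd.Series(dtype=float)
        rows.append({
            "error": f"reversal_{dx}", "level": "pair",
            "n": int(col.notna().sum()),
            "detected": int((col == 1).sum()),
            "injected": int(truth[f"injected_reversal_{dx}"].sum()),
        })
    for b in AUTOPOP_BLOCKS:
        name = {"clinical": "auto_all_clinical", "mood16": "auto_mood16",
                "adl20": "auto_adl20"}[b]
        col = pflags[name] if len(pflags) else pd.Series(dtype=float)
        injected = truth[f"injected_auto_{b}"]
        injected_in_pairs = int(injected.loc[t2].sum()) if len(t2) else 0
        rows.append({
            "error": name, "level": "pair",
            "n": int(col.notna().sum()),
            "detected": int((col == 1).sum()),
            "injected": injected_in_pairs,
        })
    report = pd.DataFrame(rows)
    report["detected_rate"] = report["detected"] / report["n"].where(report["n"] > 0)
    report["injected_rate"] = report["injected"] / report["n"].where(report["n"] > 0)
    return report
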