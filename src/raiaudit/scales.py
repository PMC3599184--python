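"""Embedded interRAI scale scoring.

Implements the scales used throughout the audit: the ADL Long Form
(0-28), Depression Rating Scale (0-14), Aggressive Behaviour Scale
(0-12), Cognitive Performance Scale (0-6, a decision tree), the RUG-III
embedded ADL index (4-18) and the Pain Scale (0-3), plus the
dichotomized prevalence flags (CPS 3+, RUG-ADL 11+, ABS 5+, DRS 3+).

Each scale has a scalar reference implementation operating on a single
record (mapping of item code to value, ``None`` for missing) and a
vectorized implementation in :func:`score_frame`; the two are held
equivalent by the test suite.  A missing required item makes the score
missing, and the flags missing with it.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .dictionary import ABS_ITEMS, ADL_LONG_FORM_NAMES, DRS_ITEMS

SCALE_COLUMNS = ("adl_long_form", "drs", "abs", "cps", "rug_adl", "pain")
FLAG_COLUMNS = ("cps_ge3", "rugadl_ge11", "abs_ge5", "drs_ge3")

#: dichotomy thresholds used by the prevalence flags
THRESHOLDS = {"cps": 3, "rug_adl": 11, "abs": 5, "drs": 3}


@dataclass(frozen=True)
class ScaleDefinition:
    """Declarative description of one scale.

    Sum scales are fully driven by their definition (items, recode map,
    range); the decision-tree scales (CPS, RUG-ADL, pain) list their
    inputs and range here for introspection while the branching lives in
    code.  The recode map covers the full value domain of each item.
    """

    name: str
    items: tuple[str, ...]
    aggregation: str  # "sum" or "decision_tree"
    recode: dict[int, int] | None = None  # raw value -> contribution
    range: tuple[int, int] = (0, 0)
    threshold: int | None = None  # dichotomy cut (score >= threshold)

    def contribution(self, value):
        if self.recode and value in self.recode:
            return self.recode[value]
        return value


SCALE_DEFINITIONS = {
    "adl_long_form": ScaleDefinition(
        "adl_long_form",
        tuple(f"adl_{n}_perf" for n in ADL_LONG_FORM_NAMES),
        "sum", recode={8: 4}, range=(0, 28),
    ),
    "drs": ScaleDefinition("drs", DRS_ITEMS, "sum", range=(0, 14), threshold=3),
    "abs": ScaleDefinition("abs", ABS_ITEMS, "sum", range=(0, 12), threshold=5),
    "cps": ScaleDefinition(
        "cps",
        ("comatose", "short_term_memory", "decision_making",
         "making_self_understood", "adl_eating_perf"),
        "decision_tree", range=(0, 6), threshold=3,
    ),
    "rug_adl": ScaleDefinition(
        "rug_adl",
        ("adl_bed_mobility_perf", "adl_bed_mobility_supp",
         "adl_transfer_perf", "adl_transfer_supp",
         "adl_toilet_use_perf", "adl_toilet_use_supp", "adl_eating_perf"),
        "decision_tree", range=(4, 18), threshold=11,
    ),
    "pain": ScaleDefinition(
        "pain", ("pain_frequency", "pain_intensity"),
        "decision_tree", range=(0, 3),
    ),
}


def _get(record: Mapping, code: str):
    v = record.get(code)
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return v


def _sum_items(record: Mapping, codes, recode=None):
    total = 0
    for c in codes:
        v = _get(record, c)
        if v is None:
            return None
        total += recode(v) if recode else v
    return total


# ---------------------------------------------------------------------------
# scalar reference implementations


def _score_sum(record: Mapping, definition: ScaleDefinition):
    return _sum_items(record, definition.items, recode=definition.contribution)


def score_adl_long_form(record: Mapping):
    """Sum of the 7 designated ADL self-performance items; 8 recodes to 4."""
    return _score_sum(record, SCALE_DEFINITIONS["adl_long_form"])


def score_drs(record: Mapping):
    """Depression Rating Scale: sum of 7 mood items coded 0/1/2."""
    return _score_sum(record, SCALE_DEFINITIONS["drs"])


def score_abs(record: Mapping):
    """Aggressive Behaviour Scale: sum of 4 behaviour items coded 0-3."""
    return _score_sum(record, SCALE_DEFINITIONS["abs"])


def score_cps(record: Mapping):
    """Cognitive Performance Scale decision tree.

    Comatose scores 6 outright.  Otherwise the tree counts impairments
    (memory problem, any decision-making impairment, any problem being
    understood) and severe impairments (decision-making or being
    understood at moderate/severe levels); severely impaired
    decision-making overrides to 5, or 6 with totally dependent eating.
    """
    comatose = _get(record, "comatose")
    if comatose == 1:
        return 6
    stm = _get(record, "short_term_memory")
    dm = _get(record, "decision_making")
    msu = _get(record, "making_self_understood")
    eat = _get(record, "adl_eating_perf")
    if None in (comatose, stm, dm, msu, eat):
        return None
    if dm == 3:
        return 6 if eat == 4 else 5
    count = int(stm == 1) + int(dm >= 1) + int(msu >= 1)
    if count == 0:
        return 0
    if count == 1:
        return 1
    severe = int(dm >= 2) + int(msu >= 2)
    return 2 + severe


def _rug_component(perf, supp):
    p = 4 if perf == 8 else perf
    if p <= 1:
        base = 1
    elif p == 2:
        base = 3
    else:
        base = 4
    if base == 4 and supp is not None and supp != 8 and supp >= 3:
        return 5  # extensive assistance from two or more persons
    return base


def score_rug_adl(record: Mapping):
    """RUG-III embedded ADL index over bed mobility, transfer, toilet use, eating."""
    total = 0
    for name in ("bed_mobility", "transfer", "toilet_use"):
        perf = _get(record, f"adl_{name}_perf")
        supp = _get(record, f"adl_{name}_supp")
        if perf is None or supp is None:
            return None
        total += _rug_component(perf, supp)
    eat = _get(record, "adl_eating_perf")
    if eat is None:
        return None
    e = 4 if eat == 8 else eat
    total += 1 if e <= 1 else (2 if e == 2 else 3)
    return total


def score_pain(record: Mapping):
    """Pain Scale: 0 no pain, 1 less than daily, 2 daily, 3 daily and severe."""
    freq = _get(record, "pain_frequency")
    if freq is None:
        return None
    if freq == 0:
        return 0
    if freq == 1:
        return 1
    intensity = _get(record, "pain_intensity")
    if intensity is None:
        return None
    return 3 if intensity == 3 else 2


def score_record(record: Mapping) -> dict:
    scores = {
        "adl_long_form": score_adl_long_form(record),
        "drs": score_drs(record),
        "abs": score_abs(record),
        "cps": score_cps(record),
        "rug_adl": score_rug_adl(record),
        "pain": score_pain(record),
    }
    for scale, thr in THRESHOLDS.items():
        flag = "rugadl_ge11" if scale == "rug_adl" else f"{scale}_ge{thr}"
        v = scores[scale]
        scores[flag] = None if v is None else v >= thr
    return scores


# ---------------------------------------------------------------------------
# vectorized implementation


def _col(frame: pd.DataFrame, code: str) -> np.ndarray:
    return pd.to_numeric(frame[code], errors="coerce").to_numpy(dtype=float)


def score_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Score every record of ``frame``; returns one column per scale/flag.

    NaN marks a missing score (some required item missing).
    """
    n = len(frame)
    out = pd.DataFrame(index=frame.index)

    # ADL Long Form
    perf = np.column_stack([_col(frame, f"adl_{nm}_perf") for nm in ADL_LONG_FORM_NAMES])
    out["adl_long_form"] = np.where(perf == 8, 4, perf).sum(axis=1)  # NaN propagates

    out["drs"] = np.column_stack([_col(frame, c) for c in DRS_ITEMS]).sum(axis=1)
    out["abs"] = np.column_stack([_col(frame, c) for c in ABS_ITEMS]).sum(axis=1)

    # CPS decision tree
    comatose = _col(frame, "comatose")
    stm = _col(frame, "short_term_memory")
    dm = _col(frame, "decision_making")
    msu = _col(frame, "making_self_understood")
    eat = _col(frame, "adl_eating_perf")
    count = (stm == 1).astype(float) + (dm >= 1) + (msu >= 1)
    severe = (dm >= 2).astype(float) + (msu >= 2)
    cps = np.where(count == 0, 0.0, np.where(count == 1, 1.0, 2.0 + severe))
    cps = np.where(dm == 3, np.where(eat == 4, 6.0, 5.0), cps)
    any_missing = np.isnan(comatose) | np.isnan(stm) | np.isnan(dm) | np.isnan(msu) | np.isnan(eat)
    cps = np.where(any_missing, np.nan, cps)
    cps = np.where(comatose == 1, 6.0, cps)  # comatose short-circuits missingness
    out["cps"] = cps

    # RUG-ADL
    total = np.zeros(n)
    missing = np.zeros(n, dtype=bool)
    for name in ("bed_mobility", "transfer", "toilet_use"):
        p = _col(frame, f"adl_{name}_perf")
        s = _col(frame, f"adl_{name}_supp")
        p4 = np.where(p == 8, 4, p)
        comp = np.where(p4 <= 1, 1.0, np.where(p4 == 2, 3.0, 4.0))
        comp = np.where((comp == 4) & (s >= 3) & (s != 8), 5.0, comp)
        missing |= np.isnan(p) | np.isnan(s)
        total = total + np.where(np.isnan(comp), 0, comp)
    e = np.where(eat == 8, 4, eat)
    total = total + np.where(e <= 1, 1.0, np.where(e == 2, 2.0, 3.0))
    missing |= np.isnan(eat)
    out["rug_adl"] = np.where(missing, np.nan, total)

    # Pain Scale
    freq = _col(frame, "pain_frequency")
    intensity = _col(frame, "pain_intensity")
    pain = np.where(freq == 0, 0.0, np.where(freq == 1, 1.0, np.where(intensity == 3, 3.0, 2.0)))
    pain = np.where(np.isnan(freq) | ((freq == 2) & np.isnan(intensity)), np.nan, pain)
    out["pain"] = pain

    for scale, thr in THRESHOLDS.items():
        flag = "rugadl_ge11" if scale == "rug_adl" else f"{scale}_ge{thr}"
        v = out[scale].to_numpy(dtype=float)
        out[flag] = np.where(np.isnan(v), np.nan, (v >= thr).astype(float))
    return out
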