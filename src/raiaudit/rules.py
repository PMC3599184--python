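"""The audit rule engine.

Cross-sectional logical-consistency checks (mood persistence without
mood items, one-sided ADL "did not occur" codes, parenteral/enteral
intake mismatches, ulcer staging without a count, three therapy-time
checks, and out-of-range height/weight/age), service-use indicators,
longitudinal diagnosis-reversal and block carry-forward (autopopulation)
indicators on consecutive assessment pairs, and sign-off lag
categorization.

Every rule has a scalar reference implementation on a single record
(mapping, ``None`` = missing) and a vectorized counterpart used by
:func:`audit_frame` / :func:`audit_pairs`; the suite holds them
equivalent.  A record whose rule inputs are missing is excluded from
that rule's denominator (the flag is missing, not False).
"""
from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .dictionary import DIAGNOSIS_ITEMS, ItemDictionary, MOOD_ITEMS, THERAPY_DISCIPLINES
from .records import pair_frame

RECORD_FLAGS = (
    "mood_persistence_err",
    "adl_dnoc_err",
    "nutrition_err",
    "ulcer_err",
    "therapy_day15_err",
    "therapy_nodays_err",
    "therapy_exceed_err",
    "any_therapy_err",
    "any_logical_err",
    "height_err",
    "weight_err",
    "age_err",
)

PAIR_FLAGS = (
    "reversal_multiple_sclerosis",
    "reversal_quadriplegia",
    "reversal_cerebral_palsy",
    "reversal_schizophrenia",
    "auto_all_clinical",
    "auto_mood16",
    "auto_adl20",
)

SIGNOFF_CATEGORIES = ("neg", "d0_6", "d7_30", "gt30")

MINUTES_PER_DAY = 1440


def _get(record: Mapping, code: str):
    v = record.get(code)
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return v


# ---------------------------------------------------------------------------
# cross-sectional rules (scalar reference)


def check_mood_persistence(record: Mapping, adl_pairs=None):
    """Mood persistence coded present while all 16 mood items are absent."""
    persistence = _get(record, "mood_persistence")
    if persistence is None:
        return None
    items = [_get(record, c) for c in MOOD_ITEMS]
    if any(v is None for v in items):
        return None
    return persistence >= 1 and all(v == 0 for v in items)


def check_adl_did_not_occur(record: Mapping, adl_pairs):
    """Exactly one of an ADL performance/support pair coded 8 (did not occur)."""
    flag = False
    for perf_code, supp_code in adl_pairs:
        p, s = _get(record, perf_code), _get(record, supp_code)
        if p is None or s is None:
            return None
        if (p == 8) != (s == 8):
            flag = True
    return flag


def check_nutrition(record: Mapping):
    """Parenteral/tube feeding route inconsistent with reported intake.

    Flagged in either direction: a route present with zero calorie and
    fluid intake codes, or intake coded with no route present.
    """
    iv = _get(record, "parenteral_iv")
    tube = _get(record, "feeding_tube")
    cal = _get(record, "calories_proportion_code")
    fluid = _get(record, "fluid_intake_code")
    if None in (iv, tube, cal, fluid):
        return None
    route = iv == 1 or tube == 1
    if route:
        return cal == 0 and fluid == 0
    return cal > 0 or fluid > 0


def check_ulcer(record: Mapping):
    """Ulcer highest stage assigned but the count at that stage missing or zero."""
    stage = _get(record, "ulcer_highest_stage")
    if stage is None:
        return None
    count = _get(record, "ulcer_count_at_stage")
    return stage >= 1 and (count is None or count == 0)


def check_therapy(record: Mapping):
    """Three therapy-time checks, each ORed over the disciplines.

    day15: therapy days counted without 15 minutes per counted day;
    nodays: zero days despite enough minutes for at least one day;
    exceed: weekly minutes above the minutes in the days reported
    (1440 per day, with one day assumed when days is zero).
    """
    day15 = nodays = exceed = False
    for disc in THERAPY_DISCIPLINES:
        days = _get(record, f"{disc}_days")
        minutes = _get(record, f"{disc}_minutes")
        if days is None or minutes is None:
            return None
        if days >= 1 and minutes < 15 * days:
            day15 = True
        if days == 0 and minutes >= 15:
            nodays = True
        if minutes > MINUTES_PER_DAY * max(days, 1):
            exceed = True
    return day15, nodays, exceed


def check_vitals(record: Mapping, reference_date):
    """Out-of-range height (<120 or >211 cm), weight (<20 or >200 kg) and
    age at assessment (<16 or >115 completed years).  Missing height or
    weight is not an error; missing birthdate makes the age flag missing.
    """
    h = _get(record, "height_cm")
    w = _get(record, "weight_kg")
    height_err = False if h is None else (h < 120 or h > 211)
    weight_err = False if w is None else (w < 20 or w > 200)
    birth = record.get("birthdate")
    if birth is None or (isinstance(birth, float) and math.isnan(birth)):
        age_err = None
    else:
        birth = pd.Timestamp(birth)
        ref = pd.Timestamp(reference_date)
        age = ref.year - birth.year - ((ref.month, ref.day) < (birth.month, birth.day))
        age_err = age < 16 or age > 115
    return height_err, weight_err, age_err


def any_logical_problem(flags: Mapping):
    """OR of the mood, ADL, nutrition, ulcer and therapy error flags."""
    parts = [
        flags.get("mood_persistence_err"),
        flags.get("adl_dnoc_err"),
        flags.get("nutrition_err"),
        flags.get("ulcer_err"),
        flags.get("any_therapy_err"),
    ]
    if any(p is None for p in parts):
        return None
    return any(parts)


def signoff_lag(record: Mapping):
    """(days, category) between reference date and sign-off; missing if either absent."""
    ref, signoff = record.get("reference_date"), record.get("signoff_date")
    if ref is None or signoff is None or pd.isna(ref) or pd.isna(signoff):
        return None, None
    days = (pd.Timestamp(signoff) - pd.Timestamp(ref)).days
    if days < 0:
        cat = "neg"
    elif days <= 6:
        cat = "d0_6"
    elif days <= 30:
        cat = "d7_30"
    else:
        cat = "gt30"
    return days, cat


def service_indicators(record: Mapping, nursing_rehab_items):
    """Therapy receipt and intensity indicators for one record."""
    minutes = {d: _get(record, f"{d}_minutes") for d in THERAPY_DISCIPLINES}
    days = {d: _get(record, f"{d}_days") for d in THERAPY_DISCIPLINES}
    if any(v is None for v in minutes.values()) or any(v is None for v in days.values()):
        return None
    total = sum(minutes.values())
    distinct = _get(record, "distinct_therapy_days")
    nrehab = [_get(record, c) for c in nursing_rehab_items]
    return {
        "total_therapy_minutes": total,
        "nursing_rehab_2plus": sum(1 for v in nrehab if v is not None and v >= 6) >= 2,
        "any_ot": minutes["ot"] > 0 or days["ot"] > 0,
        "any_pt": minutes["pt"] > 0 or days["pt"] > 0,
        "rehab_3d45m": distinct is not None and distinct >= 3 and total >= 45,
        "rehab_5d150m": distinct is not None and distinct >= 5 and total >= 150,
    }


# ---------------------------------------------------------------------------
# pair-level rules (scalar reference)


def diagnosis_reversal(pair, dx_code: str):
    """True if a chronic diagnosis present at T1 is coded absent at T2.

    Returns ``None`` (not in the denominator) when the diagnosis is not
    coded present at T1.
    """
    if dx_code not in DIAGNOSIS_ITEMS:
        raise ValueError(f"unknown diagnosis {dx_code!r}")
    at_t1 = pair.t1.get(dx_code)
    if at_t1 != 1:
        return None
    return pair.t2.get(dx_code) != 1


def autopopulation_flags(pair, dictionary: ItemDictionary):
    """Identical-block indicators for a consecutive pair.

    A block counts as carried forward when every item in it has the same
    value at T1 and T2 (missing matching missing counts as identical).
    """
    def identical(codes):
        for c in codes:
            a, b = pair.t1.get(c), pair.t2.get(c)
            if a is None and b is None:
                continue
            if a is None or b is None or a != b:
                return False
        return True

    adl20 = dictionary.block("ADL_PERF") + dictionary.block("ADL_SUPP")
    return (
        identical(dictionary.block("CLINICAL")),
        identical(dictionary.block("MOOD")),
        identical(adl20),
    )


# ---------------------------------------------------------------------------
# vectorized audit


def _col(frame, code):
    return pd.to_numeric(frame[code], errors="coerce").to_numpy(dtype=float)


def _mask_or(flag: np.ndarray, missing: np.ndarray) -> np.ndarray:
    return np.where(missing, np.nan, flag.astype(float))


def audit_frame(frame: pd.DataFrame, dictionary: ItemDictionary) -> pd.DataFrame:
    """All cross-sectional flags plus sign-off lag, one row per record.

    Flag columns are float-coded booleans with NaN for records excluded
    from that rule's denominator.
    """
    out = pd.DataFrame(index=frame.index)

    mood = np.column_stack([_col(frame, c) for c in MOOD_ITEMS])
    persistence = _col(frame, "mood_persistence")
    miss = np.isnan(persistence) | np.isnan(mood).any(axis=1)
    out["mood_persistence_err"] = _mask_or((persistence >= 1) & (mood == 0).all(axis=1), miss)

    dnoc = np.zeros(len(frame), dtype=bool)
    miss = np.zeros(len(frame), dtype=bool)
    for perf_code, supp_code in dictionary.adl_pairs():
        p, s = _col(frame, perf_code), _col(frame, supp_code)
        dnoc |= (p == 8) != (s == 8)
        miss |= np.isnan(p) | np.isnan(s)
    out["adl_dnoc_err"] = _mask_or(dnoc, miss)

    iv, tube = _col(frame, "parenteral_iv"), _col(frame, "feeding_tube")
    cal, fluid = _col(frame, "calories_proportion_code"), _col(frame, "fluid_intake_code")
    route = (iv == 1) | (tube == 1)
    nut = np.where(route, (cal == 0) & (fluid == 0), (cal > 0) | (fluid > 0))
    miss = np.isnan(iv) | np.isnan(tube) | np.isnan(cal) | np.isnan(fluid)
    out["nutrition_err"] = _mask_or(nut, miss)

    stage = _col(frame, "ulcer_highest_stage")
    count = _col(frame, "ulcer_count_at_stage")
    out["ulcer_err"] = _mask_or((stage >= 1) & (np.isnan(count) | (count == 0)),
                                np.isnan(stage))

    day15 = np.zeros(len(frame), dtype=bool)
    nodays = np.zeros(len(frame), dtype=bool)
    exceed = np.zeros(len(frame), dtype=bool)
    miss = np.zeros(len(frame), dtype=bool)
    for disc in THERAPY_DISCIPLINES:
        d, m = _col(frame, f"{disc}_days"), _col(frame, f"{disc}_minutes")
        day15 |= (d >= 1) & (m < 15 * d)
        nodays |= (d == 0) & (m >= 15)
        exceed |= m > MINUTES_PER_DAY * np.maximum(d, 1)
        miss |= np.isnan(d) | np.isnan(m)
    out["therapy_day15_err"] = _mask_or(day15, miss)
    out["therapy_nodays_err"] = _mask_or(nodays, miss)
    out["therapy_exceed_err"] = _mask_or(exceed, miss)
    out["any_therapy_err"] = _mask_or(day15 | nodays | exceed, miss)

    parts = out[["mood_persistence_err", "adl_dnoc_err", "nutrition_err",
                 "ulcer_err", "any_therapy_err"]].to_numpy(dtype=float)
    out["any_logical_err"] = _mask_or(np.nan_to_num(parts).any(axis=1),
                                      np.isnan(parts).any(axis=1))

    h, w = _col(frame, "height_cm"), _col(frame, "weight_kg")
    out["height_err"] = (~np.isnan(h) & ((h < 120) | (h > 211))).astype(float)
    out["weight_err"] = (~np.isnan(w) & ((w < 20) | (w > 200))).astype(float)

    ref = pd.to_datetime(frame["reference_date"])
    birth = pd.to_datetime(frame["birthdate"])
    age = ref.dt.year - birth.dt.year - (
        (ref.dt.month * 100 + ref.dt.day) < (birth.dt.month * 100 + birth.dt.day)
    ).astype(int)
    out["age_err"] = _mask_or(((age < 16) | (age > 115)).to_numpy(),
                              birth.isna().to_numpy())

    signoff = pd.to_datetime(frame["signoff_date"])
    lag = (signoff - ref).dt.days
    out["signoff_lag_days"] = lag
    out["signoff_category"] = pd.cut(
        lag, [-np.inf, -1, 6, 30, np.inf], labels=SIGNOFF_CATEGORIES
    ).astype(object).where(lag.notna(), None)
    return out


def service_frame(frame: pd.DataFrame, dictionary: ItemDictionary) -> pd.DataFrame:
    """Vectorized service-use indicators."""
    out = pd.DataFrame(index=frame.index)
    minutes = np.column_stack([_col(frame, f"{d}_minutes") for d in THERAPY_DISCIPLINES])
    days = np.column_stack([_col(frame, f"{d}_days") for d in THERAPY_DISCIPLINES])
    total = minutes.sum(axis=1)
    out["total_therapy_minutes"] = total
    nrehab = np.column_stack([_col(frame, c) for c in dictionary.block("NURSING_REHAB")])
    out["nursing_rehab_2plus"] = ((np.nan_to_num(nrehab) >= 6).sum(axis=1) >= 2).astype(float)
    out["any_ot"] = ((minutes[:, 1] > 0) | (days[:, 1] > 0)).astype(float)
    out["any_pt"] = ((minutes[:, 2] > 0) | (days[:, 2] > 0)).astype(float)
    distinct = _col(frame, "distinct_therapy_days")
    out["rehab_3d45m"] = ((distinct >= 3) & (total >= 45)).astype(float)
    out["rehab_5d150m"] = ((distinct >= 5) & (total >= 150)).astype(float)
    return out


def audit_pairs(frame: pd.DataFrame, dictionary: ItemDictionary,
                require_distinct_quarters: bool = True) -> pd.DataFrame:
    """Pair-level flags for every consecutive within-person pair.

    Returns one row per pair with the T2 row position (``i2``), the
    reversal flag per diagnosis (NaN when the diagnosis is absent at T1)
    and the three carry-forward indicators.  Pairs whose two reference
    dates fall in the same calendar quarter are dropped when
    ``require_distinct_quarters`` (reassessments in the audited data are
    compared against a previous quarter).
    """
    pairs = pair_frame(frame)
    if pairs.empty:
        return pd.DataFrame(columns=["i1", "i2", *PAIR_FLAGS])
    pos = frame.index.get_indexer
    i1 = pos(pairs["i1"])
    i2 = pos(pairs["i2"])
    if require_distinct_quarters:
        dates = pd.to_datetime(frame["reference_date"])
        q = (dates.dt.year * 4 + dates.dt.quarter).to_numpy()
        keep = q[i2] != q[i1]
        pairs, i1, i2 = pairs.loc[keep].reset_index(drop=True), i1[keep], i2[keep]

    out = pairs.copy()
    for dx in DIAGNOSIS_ITEMS:
        v = _col(frame, dx)
        flag = np.where(v[i1] == 1, (v[i2] != 1).astype(float), np.nan)
        out[f"reversal_{dx}"] = flag

    def identical(codes):
        same = np.ones(len(i1), dtype=bool)
        for c in codes:
            v = _col(frame, c)
            a, b = v[i1], v[i2]
            same &= (a == b) | (np.isnan(a) & np.isnan(b))
        return same

    out["auto_all_clinical"] = identical(dictionary.block("CLINICAL")).astype(float)
    out["auto_mood16"] = identical(dictionary.block("MOOD")).astype(float)
    out["auto_adl20"] = identical(
        dictionary.block("ADL_PERF") + dictionary.block("ADL_SUPP")
    ).astype(float)
    return out
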