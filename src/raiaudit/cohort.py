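"""Synthetic two-sector assessment cohort with labelled error injection.

The generator emulates the structure of a national continuing-care
repository extract: two sectors (CCC hospitals/units: short-stay,
post-acute, functionally impaired; LTC homes: long-stay, cognitively
impaired) observed quarterly, with admission/quarterly/annual assessment
types, person-level latent clinical traits drifting slowly over a stay,
and coded items produced by thresholding trait-plus-noise variables.

Item noise is calibrated at generation time: the within-block loading is
solved by bisection against the configured Cronbach's alpha target, so
the emitted cohort reproduces the target internal consistencies without
hand-tuned constants.  Error injection mutates clean records to create
exactly the triggering condition of each audit rule, recording every
mutation (and the original values) in a truth table that joins 1:1 to
the emitted records.

Clean generation is constraint-consistent by construction: with zero
injection the audit finds zero logical errors and zero diagnosis
reversals (block carry-forward indicators retain their natural
no-change baseline, which true clinical stability produces).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .dictionary import (
    ADL_NAMES,
    DIAGNOSIS_ITEMS,
    DRS_ITEMS,
    ItemDictionary,
    MOOD_ITEMS,
    NURSING_REHAB_ITEMS,
    THERAPY_DISCIPLINES,
    default_dictionary,
)
from .psychometrics import cronbach_alpha
from .records import IDENTITY_COLUMNS, pair_frame

TRAITS = ("cognition", "function", "mood", "aggression", "pain", "continence")

#: latent correlations among the clinical traits (positive = more impaired);
#: pain correlates negatively with cognitive impairment (under-detection in
#: impaired residents), everything else positively.
DEFAULT_LATENT_CORR = np.array(
    [
        # cog    fun    moo    agg    pai    con
        [1.00, 0.75, 0.20, 0.50, -0.30, 0.70],
        [0.75, 1.00, 0.20, 0.25, -0.10, 0.50],
        [0.20, 0.20, 1.00, 0.30, 0.15, 0.10],
        [0.50, 0.25, 0.30, 1.00, 0.00, 0.25],
        [-0.30, -0.10, 0.15, 0.00, 1.00, -0.10],
        [0.70, 0.50, 0.10, 0.25, -0.10, 1.00],
    ]
)

CROSS_SECTIONAL_ERRORS = (
    "mood",
    "adl_dnoc",
    "nutrition",
    "ulcer",
    "therapy_day15",
    "therapy_nodays",
    "therapy_exceed",
    "height",
    "weight",
    "age",
)
AUTOPOP_BLOCKS = ("clinical", "mood16", "adl20")

TRUTH_COLUMNS = (
    ["record_id", "person_id", "sector", "reference_date"]
    + [f"injected_{e}" for e in CROSS_SECTIONAL_ERRORS]
    + [f"injected_reversal_{dx}" for dx in DIAGNOSIS_ITEMS]
    + [f"injected_auto_{b}" for b in AUTOPOP_BLOCKS]
    + ["original_values"]
)


@dataclass
class SectorConfig:
    """One sector's volume, turnover and severity profile."""

    records_per_quarter: int
    admission_share: float  # per-quarter turnover; also the admission share
    n_facilities: int
    trait_offsets: dict[str, float]
    signoff_probs: tuple[float, float, float, float]  # neg, 0-6, 7-30, >30
    therapy_any_prob: dict[str, float] = field(default_factory=dict)
    nrehab_active_prob: float = 0.15


@dataclass
class ErrorRates:
    """Per-record (or per-eligible-pair) injection probabilities."""

    cross_sectional: dict[str, float] = field(default_factory=dict)
    reversal: dict[str, float] = field(default_factory=dict)
    autopopulation: dict[str, float] = field(default_factory=dict)

    @classmethod
    def uniform(cls, rate: float, reversal: float | None = None,
                autopopulation: float | None = None) -> "ErrorRates":
        return cls(
            cross_sectional={e: rate for e in CROSS_SECTIONAL_ERRORS},
            reversal={dx: (reversal if reversal is not None else rate)
                      for dx in DIAGNOSIS_ITEMS},
            autopopulation={b: (autopopulation if autopopulation is not None else rate)
                            for b in AUTOPOP_BLOCKS},
        )

    @classmethod
    def none(cls) -> "ErrorRates":
        return cls.uniform(0.0)


@dataclass
class CohortConfig:
    seed: int = 0
    n_quarters: int = 20
    start_quarter: str = "2006_1"
    latent_corr: np.ndarray = field(default_factory=lambda: DEFAULT_LATENT_CORR.copy())
    drift_sd: float = 0.10
    alpha_targets: dict[str, float] = field(
        default_factory=lambda: {"adl": 0.92, "drs": 0.74, "abs": 0.76}
    )
    diagnosis_prevalence: dict[str, float] = field(
        default_factory=lambda: {dx: 0.06 for dx in DIAGNOSIS_ITEMS}
    )
    sectors: dict[str, SectorConfig] = field(default_factory=dict)
    error_rates: ErrorRates = field(default_factory=ErrorRates.none)
    n_clinical: int = 231
    vital_missing_prob: float = 0.01
    adl_both8_prob: float = 0.004

    def validate(self) -> None:
        corr = np.asarray(self.latent_corr)
        if corr.shape != (len(TRAITS),) * 2 or not np.allclose(corr, corr.T):
            raise ValueError("latent correlation matrix must be symmetric 6x6")
        if np.linalg.eigvalsh(corr).min() < -1e-9:
            raise ValueError("latent correlation matrix is not positive semi-definite")
        for rates in (self.error_rates.cross_sectional,
                      self.error_rates.reversal,
                      self.error_rates.autopopulation):
            for k, v in rates.items():
                if not 0 <= v <= 1:
                    raise ValueError(f"error rate {k}={v} outside [0, 1]")
        for s in self.sectors.values():
            if not 0 < s.admission_share <= 1:
                raise ValueError("admission_share must be in (0, 1]")


def paper_shape_preset(seed: int = 0, records_per_quarter: int = 2000,
                       n_quarters: int = 20,
                       error_rates: ErrorRates | None = None) -> CohortConfig:
    """Config reproducing the qualitative two-sector contrast.

    CCC: high turnover (admission share near one half), heavier ADL
    impairment and pain, faster sign-off.  LTC: low turnover, more
    cognitive impairment, depression and behaviour disturbance, slower
    sign-off.  ``records_per_quarter`` is the total across sectors,
    split 40/60 between CCC and LTC.
    """
    n_ccc = int(round(records_per_quarter * 0.4))
    n_ltc = records_per_quarter - n_ccc
    sectors = {
        "CCC": SectorConfig(
            records_per_quarter=n_ccc,
            admission_share=0.45,
            n_facilities=8,
            trait_offsets={
                "cognition": 0.0,
                "function": 0.70,
                "mood": 0.0,
                "aggression": -0.20,
                "pain": 0.30,
                "continence": 0.20,
            },
            signoff_probs=(0.017, 0.671, 0.197, 0.115),
            therapy_any_prob={"speech": 0.10, "ot": 0.50, "pt": 0.65},
            nrehab_active_prob=0.30,
        ),
        "LTC": SectorConfig(
            records_per_quarter=n_ltc,
            admission_share=0.09,
            n_facilities=12,
            trait_offsets={
                "cognition": 0.25,
                "function": 0.25,
                "mood": 0.20,
                "aggression": 0.15,
                "pain": 0.0,
                "continence": 0.30,
            },
            signoff_probs=(0.0, 0.516, 0.440, 0.044),
            therapy_any_prob={"speech": 0.03, "ot": 0.04, "pt": 0.35},
            nrehab_active_prob=0.12,
        ),
    }
    return CohortConfig(seed=seed, n_quarters=n_quarters, sectors=sectors,
                        error_rates=error_rates or ErrorRates.none())


# ---------------------------------------------------------------------------
# item marginals (baseline cutpoints on the standard normal scale)


def _cuts(probs) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    return norm.ppf(np.cumsum(p[:-1]) / p.sum())


ADL_PERF_CUTS = _cuts([0.26, 0.14, 0.16, 0.20, 0.24])
ADL_EATING_CUTS = _cuts([0.45, 0.15, 0.15, 0.13, 0.12])
MOOD_CUTS = _cuts([0.80, 0.13, 0.07])
ABS_CUTS = _cuts([0.80, 0.10, 0.06, 0.04])
STM_CUTS = _cuts([0.45, 0.55])
DECISION_CUTS = _cuts([0.34, 0.22, 0.28, 0.16])
UNDERSTOOD_CUTS = _cuts([0.42, 0.22, 0.18, 0.11, 0.07])
PAIN_FREQ_CUTS = _cuts([0.55, 0.20, 0.25])
PAIN_INTENSITY_CUTS = _cuts([0.35, 0.40, 0.25])
BOWEL_CUTS = _cuts([0.45, 0.13, 0.12, 0.12, 0.18])
ULCER_STAGE_CUTS = _cuts([0.88, 0.05, 0.04, 0.02, 0.01])

#: loadings for item groups whose reliability is not alpha-calibrated
FIXED_LOADINGS = {
    "cognition": 0.78,
    "pain": 0.80,
    "continence": 0.80,
    "ulcer": 0.45,
}


def _ordinal(rng: np.random.Generator, z: np.ndarray, loading: float,
             cuts: np.ndarray, shift: float = 0.0) -> np.ndarray:
    """Threshold a loading-weighted trait plus fresh noise into ordinal codes."""
    y = loading * z + np.sqrt(1 - loading**2) * rng.standard_normal(len(z)) + shift
    return np.searchsorted(cuts, y).astype(float)


# ---------------------------------------------------------------------------
# reliability calibration


def calibrate_loading(rng: np.random.Generator, cuts: np.ndarray, k_items: int,
                      target_alpha: float, var_factor: float = 1.0,
                      mean_shift: float = 0.0,
                      n: int = 6000, tol: float = 0.003) -> float:
    """Bisection on the within-block loading to hit a Cronbach's alpha target.

    ``var_factor`` inflates the trait variance to match the drift-widened
    trait distribution of the emitted panel; ``mean_shift`` recentres it
    at the cohort's average severity offset (floor and ceiling categories
    attenuate the inter-item correlations, so both matter).
    """
    z = mean_shift + rng.standard_normal(n) * np.sqrt(var_factor)
    eps = rng.standard_normal((n, k_items))

    def alpha_at(lam: float) -> float:
        y = lam * z[:, None] + np.sqrt(1 - lam**2) * eps
        items = np.searchsorted(cuts, y)
        return cronbach_alpha(pd.DataFrame(items))

    lo, hi = 0.05, 0.995
    if alpha_at(hi) < target_alpha:
        return hi
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        a = alpha_at(mid)
        if abs(a - target_alpha) < tol:
            return mid
        if a < target_alpha:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# panel simulation


def _quarter_start(label: str) -> pd.Timestamp:
    year, q = label.split("_")
    return pd.Timestamp(int(year), 3 * (int(q) - 1) + 1, 1)


def _simulate_panel(rng: np.random.Generator, config: CohortConfig, sector: str):
    """Person-quarter panel for one sector.

    Returns dict of arrays: person ordinal, quarter index, within-person
    sequence number, latent trait matrix at assessment time, and the
    person-level attribute table.
    """
    sc = config.sectors[sector]
    n_q, n_per_q, d = config.n_quarters, sc.records_per_quarter, sc.admission_share
    chol = np.linalg.cholesky(config.latent_corr + 1e-12 * np.eye(len(TRAITS)))
    offsets = np.array([sc.trait_offsets.get(t, 0.0) for t in TRAITS])

    person_rows, quarter_rows, seq_rows, z_rows, admit_rows = [], [], [], [], []
    persons_z0, persons_admit_q = [], []

    def new_persons(count, quarter):
        start = len(persons_z0)
        z0 = (rng.standard_normal((count, len(TRAITS))) @ chol.T) + offsets
        persons_z0.extend(z0)
        persons_admit_q.extend([quarter] * count)
        return np.arange(start, start + count), z0.copy()

    n_admit0 = int(round(d * n_per_q))
    ids_new, z_new = new_persons(n_per_q, 0)
    active_ids = ids_new
    active_z = z_new
    active_seq = np.zeros(n_per_q, dtype=int)
    # persons beyond the admission share at the window start are mid-stay
    is_admission = np.zeros(n_per_q, dtype=bool)
    is_admission[:n_admit0] = True
    mid_stay = ~is_admission
    active_seq[mid_stay] = 1 + rng.integers(0, 8, mid_stay.sum())

    for q in range(n_q):
        person_rows.append(active_ids.copy())
        quarter_rows.append(np.full(len(active_ids), q))
        seq_rows.append(active_seq.copy())
        z_rows.append(active_z.copy())
        admit_rows.append(active_seq == 0 if q > 0 else is_admission.copy())
        if q == n_q - 1:
            break
        keep = rng.random(len(active_ids)) > d
        active_ids = active_ids[keep]
        active_z = active_z[keep] + config.drift_sd * rng.standard_normal(
            (keep.sum(), len(TRAITS))
        )
        active_seq = active_seq[keep] + 1
        n_new = n_per_q - len(active_ids)
        ids_new, z_new = new_persons(n_new, q + 1)
        active_ids = np.concatenate([active_ids, ids_new])
        active_z = np.vstack([active_z, z_new])
        active_seq = np.concatenate([active_seq, np.zeros(n_new, dtype=int)])

    panel = {
        "person": np.concatenate(person_rows),
        "quarter": np.concatenate(quarter_rows),
        "seq": np.concatenate(seq_rows),
        "z": np.vstack(z_rows),
        "is_admission": np.concatenate(admit_rows),
    }
    n_persons = len(persons_z0)
    persons = {
        "admit_q": np.array(persons_admit_q),
        "facility": rng.integers(0, sc.n_facilities, n_persons),
        "entry_age": rng.uniform(66, 100, n_persons),
        "height": np.clip(np.round(rng.normal(164, 10, n_persons)), 140, 205),
        "weight_base": np.clip(np.round(rng.normal(72, 14, n_persons)), 42, 150),
        "diagnoses": {
            dx: (rng.random(n_persons) < config.diagnosis_prevalence[dx]).astype(float)
            for dx in DIAGNOSIS_ITEMS
        },
    }
    return panel, persons


# ---------------------------------------------------------------------------
# item generation


def _generate_sector(rng: np.random.Generator, config: CohortConfig, sector: str,
                     loadings: Mapping[str, float],
                     dictionary: ItemDictionary) -> pd.DataFrame:
    sc = config.sectors[sector]
    panel, persons = _simulate_panel(rng, config, sector)
    n = len(panel["person"])
    z = {t: panel["z"][:, i] for i, t in enumerate(TRAITS)}
    cols: dict[str, np.ndarray] = {}

    # identity / dates ------------------------------------------------
    prefix = "C" if sector == "CCC" else "L"
    cols["person_id"] = np.array([f"{prefix}{p:06d}" for p in panel["person"]])
    cols["facility_id"] = np.array(
        [f"{prefix}F{persons['facility'][p]:02d}" for p in panel["person"]]
    )
    cols["sector"] = np.full(n, sector, dtype=object)
    a_type = np.where(panel["is_admission"], "admission",
                      np.where((panel["seq"] % 4 == 0) & (panel["seq"] > 0),
                               "annual", "quarterly"))
    cols["assessment_type"] = a_type

    start = _quarter_start(config.start_quarter)
    q_starts = pd.date_range(start, periods=config.n_quarters, freq="QS")
    ref = q_starts[panel["quarter"]] + pd.to_timedelta(rng.integers(0, 90, n), "D")
    cols["reference_date"] = ref

    cat = rng.choice(4, size=n, p=np.asarray(sc.signoff_probs) / sum(sc.signoff_probs))
    lag = np.select(
        [cat == 0, cat == 1, cat == 2, cat == 3],
        [-rng.integers(1, 6, n), rng.integers(0, 7, n),
         rng.integers(7, 31, n), rng.integers(31, 91, n)],
    )
    cols["signoff_date"] = ref + pd.to_timedelta(lag, "D")

    entry_age = persons["entry_age"][panel["person"]]
    admit_q = persons["admit_q"][panel["person"]]
    birth = (q_starts[np.clip(admit_q, 0, None)]
             - pd.to_timedelta((entry_age * 365.25).astype(int), "D"))
    cols["birthdate"] = birth

    cols["comatose"] = np.zeros(n)  # comatose persons are excluded upstream

    # mood block ------------------------------------------------------
    lam = loadings["drs"]
    mood = {c: _ordinal(rng, z["mood"], lam, MOOD_CUTS) for c in MOOD_ITEMS}
    cols.update(mood)
    any_mood = np.column_stack(list(mood.values())).sum(axis=1) > 0
    cols["mood_persistence"] = np.where(any_mood, rng.integers(1, 3, n).astype(float), 0.0)

    # ADL block -------------------------------------------------------
    lam = loadings["adl"]
    for name in ADL_NAMES:
        cuts = ADL_EATING_CUTS if name == "eating" else ADL_PERF_CUTS
        perf = _ordinal(rng, z["function"], lam, cuts)
        supp = np.clip(np.round(perf * 0.75 - 0.3
                                + 0.7 * rng.standard_normal(n)), 0, 3)
        both8 = rng.random(n) < config.adl_both8_prob
        perf = np.where(both8, 8.0, perf)
        supp = np.where(both8, 8.0, supp)
        cols[f"adl_{name}_perf"] = perf
        cols[f"adl_{name}_supp"] = supp

    # behaviour -------------------------------------------------------
    lam = loadings["abs"]
    for c in ("abs_verbal", "abs_physical", "abs_social", "abs_resists"):
        cols[c] = _ordinal(rng, z["aggression"], lam, ABS_CUTS)

    # cognition -------------------------------------------------------
    lam = FIXED_LOADINGS["cognition"]
    cols["short_term_memory"] = _ordinal(rng, z["cognition"], lam, STM_CUTS)
    cols["decision_making"] = _ordinal(rng, z["cognition"], lam, DECISION_CUTS)
    cols["making_self_understood"] = _ordinal(rng, z["cognition"], lam, UNDERSTOOD_CUTS)

    # pain ------------------------------------------------------------
    lam = FIXED_LOADINGS["pain"]
    freq = _ordinal(rng, z["pain"], lam, PAIN_FREQ_CUTS)
    intensity = 1 + _ordinal(rng, z["pain"], lam, PAIN_INTENSITY_CUTS)
    cols["pain_frequency"] = freq
    cols["pain_intensity"] = np.where(freq > 0, intensity, 0.0)

    cols["bowel_continence"] = _ordinal(
        rng, z["continence"], FIXED_LOADINGS["continence"], BOWEL_CUTS
    )

    # nutrition (internally consistent: intake codes iff a route) -----
    tube = (FIXED_LOADINGS["cognition"] * z["function"]
            + rng.standard_normal(n)) > 2.2
    iv = rng.random(n) < 0.015
    route = tube | iv
    cols["feeding_tube"] = tube.astype(float)
    cols["parenteral_iv"] = iv.astype(float)
    cols["calories_proportion_code"] = np.where(route, rng.integers(1, 5, n), 0.0)
    cols["fluid_intake_code"] = np.where(route, rng.integers(1, 6, n), 0.0)

    # ulcers (count present whenever a stage is assigned) -------------
    stage = _ordinal(rng, z["function"], FIXED_LOADINGS["ulcer"], ULCER_STAGE_CUTS)
    cols["ulcer_highest_stage"] = stage
    cols["ulcer_count_at_stage"] = np.where(stage > 0, 1 + rng.poisson(0.5, n), 0.0)

    # therapy (minutes consistent with days) --------------------------
    total_days = np.zeros(n)
    max_days = np.zeros(n)
    for disc in THERAPY_DISCIPLINES:
        active = rng.random(n) < sc.therapy_any_prob.get(disc, 0.2)
        days = np.where(active, rng.integers(1, 8, n), 0).astype(float)
        per_day = rng.integers(15, 61, n)
        cols[f"{disc}_days"] = days
        cols[f"{disc}_minutes"] = days * per_day
        total_days += days
        max_days = np.maximum(max_days, days)
    distinct = np.minimum(
        np.minimum(7, total_days),
        max_days + np.round(rng.random(n) * np.maximum(total_days - max_days, 0) * 0.5),
    )
    cols["distinct_therapy_days"] = np.maximum(distinct, max_days)

    # nursing rehabilitation ------------------------------------------
    for c in NURSING_REHAB_ITEMS:
        active = rng.random(n) < sc.nrehab_active_prob
        cols[c] = np.where(active, rng.integers(4, 8, n), 0).astype(float)

    # diagnoses (static within person) --------------------------------
    for dx in DIAGNOSIS_ITEMS:
        cols[dx] = persons["diagnoses"][dx][panel["person"]]

    # vitals ----------------------------------------------------------
    height = persons["height"][panel["person"]].astype(float)
    weight = np.round(persons["weight_base"][panel["person"]]
                      + rng.normal(0, 1.0, n))
    height[rng.random(n) < config.vital_missing_prob] = np.nan
    weight[rng.random(n) < config.vital_missing_prob] = np.nan
    cols["height_cm"] = height
    cols["weight_kg"] = np.clip(weight, 30, 250)

    # filler clinical items -------------------------------------------
    filler = [c for c in dictionary.block("CLINICAL") if c.startswith("clin_")]
    p_filler = np.linspace(0.05, 0.40, len(filler))
    u = rng.random((n, len(filler)))
    for j, c in enumerate(filler):
        cols[c] = (u[:, j] < p_filler[j]).astype(float)

    frame = pd.DataFrame(cols)
    frame["record_seq"] = panel["seq"]
    return frame


def generate_cohort(config: CohortConfig,
                    dictionary: ItemDictionary | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a clean cohort and its (all-false) truth table.

    Returns ``(frame, truth)``.  The frame is sorted by sector, person
    and reference date and carries a ``record_id`` column (also the
    truth-table join key).  Deterministic under ``config.seed``.
    """
    config.validate()
    dictionary = dictionary or default_dictionary(config.n_clinical)
    seed_cal, seed_gen, _ = np.random.SeedSequence(config.seed).spawn(3)
    rng_cal = np.random.default_rng(seed_cal)

    # average drift-inflated trait variance over the panel, for calibration
    shares = {s: c.records_per_quarter for s, c in config.sectors.items()}
    total = sum(shares.values())
    mean_seq = sum(
        shares[s] / total * (1 - c.admission_share) / max(c.admission_share, 1e-9) / 2
        for s, c in config.sectors.items()
    )
    var_factor = 1 + mean_seq * config.drift_sd**2

    def mean_offset(trait: str) -> float:
        return sum(
            shares[s] / total * c.trait_offsets.get(trait, 0.0)
            for s, c in config.sectors.items()
        )

    loadings = {
        "adl": calibrate_loading(rng_cal, ADL_PERF_CUTS, 7,
                                 config.alpha_targets["adl"], var_factor,
                                 mean_offset("function")),
        "drs": calibrate_loading(rng_cal, MOOD_CUTS, 7,
                                 config.alpha_targets["drs"], var_factor,
                                 mean_offset("mood")),
        "abs": calibrate_loading(rng_cal, ABS_CUTS, 4,
                                 config.alpha_targets["abs"], var_factor,
                                 mean_offset("aggression")),
    }

    frames = []
    for sector, seed in zip(sorted(config.sectors), seed_gen.spawn(len(config.sectors))):
        rng = np.random.default_rng(seed)
        frames.append(_generate_sector(rng, config, sector, loadings, dictionary))
    frame = pd.concat(frames, ignore_index=True)
    frame = frame.sort_values(["sector", "person_id", "reference_date"],
                              kind="mergesort").reset_index(drop=True)
    frame["record_id"] = frame["person_id"] + "_" + frame["record_seq"].astype(str)
    frame = frame.drop(columns=["record_seq"])
    order = ["record_id", *IDENTITY_COLUMNS, *dictionary.codes]
    frame = frame[order]

    truth = pd.DataFrame({c: False for c in TRUTH_COLUMNS if c.startswith("injected_")},
                         index=frame.index)
    truth.insert(0, "record_id", frame["record_id"])
    truth.insert(1, "person_id", frame["person_id"])
    truth.insert(2, "sector", frame["sector"])
    truth.insert(3, "reference_date", frame["reference_date"])
    truth["original_values"] = "{}"
    return frame, truth


# ---------------------------------------------------------------------------
# error injection


def _record_original(truth: pd.DataFrame, idx: int, frame: pd.DataFrame, codes) -> None:
    stored = json.loads(truth.at[idx, "original_values"])
    for c in codes:
        if c not in stored:
            v = frame.at[idx, c]
            stored[c] = None if pd.isna(v) else (str(v) if c == "birthdate" else float(v))
    truth.at[idx, "original_values"] = json.dumps(stored)


def inject_errors(frame: pd.DataFrame, config: CohortConfig,
                  truth: pd.DataFrame,
                  dictionary: ItemDictionary | None = None
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mutate clean records to create labelled rule-triggering conditions.

    Cross-sectional and carry-forward injections draw an exact count of
    targets (``round(rate * n)``) without replacement, so the injected
    rate is the configured rate up to rounding; reversals are sequential
    Bernoulli draws over eligible transitions (their denominator depends
    on the draw itself).  Order of operations: block carry-forward first
    (copying the previous record's current values, so the detector's
    identity condition holds exactly), then cross-sectional errors (at
    most one per record; records touched by a carry-forward copy are
    left alone so the two injections never mask each other), then
    diagnosis reversals (persistent: once cleared, the diagnosis stays
    absent for the rest of the stay).  Every mutation is recorded in the
    truth table together with the original values.
    """
    config.validate()
    dictionary = dictionary or default_dictionary(config.n_clinical)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    frame = frame.copy()
    truth = truth.copy()
    er = config.error_rates

    pairs = pair_frame(frame)
    prev_of = dict(zip(pairs["i2"], pairs["i1"]))  # row label -> previous row label

    # copied code sets: the mood section carries its persistence item along
    # (a copier reproduces the whole section; the identity check itself
    # stays on the 16 indicator items)
    blocks = {
        "clinical": list(dictionary.block("CLINICAL")),
        "mood16": list(dictionary.block("MOOD")) + ["mood_persistence"],
        "adl20": list(dictionary.block("ADL_PERF") + dictionary.block("ADL_SUPP")),
    }

    # --- autopopulation (exact-count sampling per block) -------------
    # The clinical block is copied first; the mood and ADL blocks are
    # subsets of it, so later block copies from the same source record
    # never break an earlier copy's identity condition.
    protected: set = set()
    eligible = pairs["i2"].to_numpy()
    for b in AUTOPOP_BLOCKS:
        rate = er.autopopulation.get(b, 0.0)
        if rate <= 0:
            continue
        k = int(round(rate * len(eligible)))
        allowed = np.array([p for p, i2 in enumerate(eligible)
                            if i2 not in protected and prev_of[i2] not in protected])
        if k > len(allowed):
            raise ValueError("autopopulation rates too high for the cohort size")
        hit = np.sort(allowed[rng.choice(len(allowed), size=k, replace=False)])
        codes = blocks[b]
        for i2 in eligible[hit]:  # chronological order within person
            i1 = prev_of[i2]
            _record_original(truth, i2, frame, codes)
            frame.loc[i2, codes] = frame.loc[i1, codes].to_numpy()
            truth.at[i2, f"injected_auto_{b}"] = True
            protected.update((i1, i2))

    # --- cross-sectional errors (exact-count; one type per record, ---
    # --- records touched by a block copy left alone) -----------------
    candidates = [i for i in frame.index if i not in protected]
    rng.shuffle(candidates)
    taken = 0
    for err in sorted(CROSS_SECTIONAL_ERRORS,
                      key=lambda e: -er.cross_sectional.get(e, 0.0)):
        rate = er.cross_sectional.get(err, 0.0)
        if rate <= 0:
            continue
        k = int(round(rate * len(frame)))
        if taken + k > len(candidates):
            raise ValueError("error rates too high for the cohort size")
        for idx in candidates[taken:taken + k]:
            _apply_cross_sectional(frame, truth, idx, err, rng)
        taken += k

    # --- diagnosis reversals (persistent clearing) -------------------
    person_rows: dict = {}
    for i2 in eligible:  # chronological within person
        person_rows.setdefault(frame.at[i2, "person_id"], [prev_of[i2]]).append(i2)
    for dx in DIAGNOSIS_ITEMS:
        rate = er.reversal.get(dx, 0.0)
        if rate <= 0:
            continue
        for rows in person_rows.values():
            if frame.at[rows[0], dx] != 1:
                continue
            for k, i2 in enumerate(rows[1:], start=1):
                if rng.random() < rate:
                    # clear here and at every later assessment of the stay
                    for later in rows[k:]:
                        _record_original(truth, later, frame, [dx])
                        frame.at[later, dx] = 0.0
                    truth.at[i2, f"injected_reversal_{dx}"] = True
                    break
    return frame, truth


def _apply_cross_sectional(frame: pd.DataFrame, truth: pd.DataFrame,
                           idx, error: str, rng: np.random.Generator) -> None:
    if error == "mood":
        codes = ["mood_persistence", *MOOD_ITEMS]
        _record_original(truth, idx, frame, codes)
        frame.at[idx, "mood_persistence"] = float(rng.integers(1, 3))
        frame.loc[idx, list(MOOD_ITEMS)] = 0.0
    elif error == "adl_dnoc":
        name = ADL_NAMES[rng.integers(0, len(ADL_NAMES))]
        codes = [f"adl_{name}_perf", f"adl_{name}_supp"]
        _record_original(truth, idx, frame, codes)
        frame.at[idx, codes[0]] = 8.0
        if frame.at[idx, codes[1]] == 8:
            frame.at[idx, codes[1]] = 2.0
    elif error == "nutrition":
        codes = ["parenteral_iv", "feeding_tube",
                 "calories_proportion_code", "fluid_intake_code"]
        _record_original(truth, idx, frame, codes)
        if frame.at[idx, "parenteral_iv"] == 1 or frame.at[idx, "feeding_tube"] == 1:
            frame.at[idx, "calories_proportion_code"] = 0.0
            frame.at[idx, "fluid_intake_code"] = 0.0
        else:
            frame.at[idx, "calories_proportion_code"] = float(rng.integers(1, 5))
    elif error == "ulcer":
        codes = ["ulcer_highest_stage", "ulcer_count_at_stage"]
        _record_original(truth, idx, frame, codes)
        if frame.at[idx, "ulcer_highest_stage"] == 0:
            frame.at[idx, "ulcer_highest_stage"] = float(rng.integers(1, 5))
        frame.at[idx, "ulcer_count_at_stage"] = 0.0
    elif error == "therapy_day15":
        codes = ["pt_days", "pt_minutes"]
        _record_original(truth, idx, frame, codes)
        days = float(rng.integers(1, 8))
        frame.at[idx, "pt_days"] = days
        frame.at[idx, "pt_minutes"] = max(0.0, 15 * days - float(rng.integers(1, 15)))
    elif error == "therapy_nodays":
        codes = ["ot_days", "ot_minutes"]
        _record_original(truth, idx, frame, codes)
        frame.at[idx, "ot_days"] = 0.0
        frame.at[idx, "ot_minutes"] = float(rng.integers(15, 200))
    elif error == "therapy_exceed":
        codes = ["speech_days", "speech_minutes"]
        _record_original(truth, idx, frame, codes)
        frame.at[idx, "speech_days"] = 1.0
        frame.at[idx, "speech_minutes"] = float(rng.integers(1441, 5000))
    elif error == "height":
        _record_original(truth, idx, frame, ["height_cm"])
        frame.at[idx, "height_cm"] = float(rng.choice([95, 110, 119, 212, 230, 250]))
    elif error == "weight":
        _record_original(truth, idx, frame, ["weight_kg"])
        frame.at[idx, "weight_kg"] = float(rng.choice([5, 12, 19, 201, 230, 320]))
    elif error == "age":
        _record_original(truth, idx, frame, ["birthdate"])
        ref = pd.Timestamp(frame.at[idx, "reference_date"])
        years = float(rng.choice([8, 12, 15, 117, 120]))
        frame.at[idx, "birthdate"] = ref - pd.to_timedelta(int(years * 365.25) + 30, "D")
    else:  # pragma: no cover
        raise ValueError(f"unknown error type {error!r}")
    truth.at[idx, f"injected_{error}"] = True
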