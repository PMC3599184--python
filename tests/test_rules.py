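"""Audit rules against independently written brute-force predicates."""
import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import base_record
from raiaudit.dictionary import ADL_NAMES, MOOD_ITEMS, default_dictionary
from raiaudit.records import frame_to_records, make_pairs
from raiaudit.rules import (
    audit_frame,
    audit_pairs,
    any_logical_problem,
    autopopulation_flags,
    check_adl_did_not_occur,
    check_mood_persistence,
    check_nutrition,
    check_therapy,
    check_ulcer,
    check_vitals,
    diagnosis_reversal,
    service_indicators,
    signoff_lag,
)

DICT = default_dictionary()
ADL_PAIRS = DICT.adl_pairs()


class TestMoodPersistence:
    def test_persistence_without_items_flags(self):
        rec = base_record(mood_persistence=2)
        assert check_mood_persistence(rec) is True

    def test_no_persistence_never_flags(self):
        rec = base_record(mood_persistence=0, mood_03=2)
        assert check_mood_persistence(rec) is False

    def test_brute_force_over_reduced_grid(self):
        """Persistence x binarized leading mood items, rest zero."""
        for persistence in (0, 1, 2):
            for bits in itertools.product([0, 1], repeat=8):
                rec = base_record(mood_persistence=persistence,
                                  **{MOOD_ITEMS[i]: b for i, b in enumerate(bits)})
                brute = persistence >= 1 and not any(bits)
                assert check_mood_persistence(rec) == brute


class TestAdlDidNotOccur:
    def test_one_sided_eight_flags(self):
        rec = base_record(adl_bathing_perf=8, adl_bathing_supp=2)
        assert check_adl_did_not_occur(rec, ADL_PAIRS) is True

    def test_both_eight_is_consistent(self):
        rec = base_record(adl_bathing_perf=8, adl_bathing_supp=8)
        assert check_adl_did_not_occur(rec, ADL_PAIRS) is False

    def test_exhaustive_pair_domain(self):
        for perf, supp in itertools.product([0, 1, 2, 3, 4, 8], [0, 1, 2, 3, 8]):
            rec = base_record(adl_dressing_perf=perf, adl_dressing_supp=supp)
            brute = (perf == 8) != (supp == 8)
            assert check_adl_did_not_occur(rec, ADL_PAIRS) == brute, (perf, supp)


class TestNutrition:
    def test_route_without_intake_flags(self):
        rec = base_record(feeding_tube=1)
        assert check_nutrition(rec) is True

    def test_route_with_intake_consistent(self):
        rec = base_record(feeding_tube=1, calories_proportion_code=3,
                          fluid_intake_code=1)
        assert check_nutrition(rec) is False

    def test_full_truth_table(self):
        for iv, tube, cal, fluid in itertools.product(
            [0, 1], [0, 1], range(5), range(6)
        ):
            rec = base_record(parenteral_iv=iv, feeding_tube=tube,
                              calories_proportion_code=cal, fluid_intake_code=fluid)
            route = iv or tube
            brute = (route and cal == 0 and fluid == 0) or (
                not route and (cal > 0 or fluid > 0)
            )
            assert check_nutrition(rec) == bool(brute), (iv, tube, cal, fluid)


class TestUlcer:
    def test_truth_table_with_missing_count(self):
        for stage in range(5):
            for count in (None, 0, 1, 3):
                rec = base_record(ulcer_highest_stage=stage,
                                  ulcer_count_at_stage=count)
                brute = stage >= 1 and (count is None or count == 0)
                assert check_ulcer(rec) == brute, (stage, count)


class TestTherapy:
    MINUTE_GRID = (0, 10, 15, 100, 1440, 1441, 2880, 10081)

    def test_spec_examples(self):
        assert check_therapy(base_record(pt_days=2, pt_minutes=20)) == (True, False, False)
        assert check_therapy(base_record()) == (False, False, False)
        assert check_therapy(base_record(speech_days=1, speech_minutes=1500)) == (
            False, False, True)

    def test_brute_force_grid_per_discipline(self):
        for disc in ("speech", "ot", "pt"):
            for days, minutes in itertools.product(range(8), self.MINUTE_GRID):
                rec = base_record(**{f"{disc}_days": days, f"{disc}_minutes": minutes})
                brute = (
                    days >= 1 and minutes < 15 * days,
                    days == 0 and minutes >= 15,
                    minutes > 1440 * max(days, 1),
                )
                assert check_therapy(rec) == brute, (disc, days, minutes)


class TestVitals:
    @pytest.mark.parametrize("height,expected", [(119, True), (120, False),
                                                 (211, False), (212, True),
                                                 (None, False)])
    def test_height_boundaries(self, height, expected):
        rec = base_record(height_cm=height)
        assert check_vitals(rec, rec["reference_date"])[0] == expected

    @pytest.mark.parametrize("weight,expected", [(19, True), (20, False),
                                                 (200, False), (201, True),
                                                 (None, False)])
    def test_weight_boundaries(self, weight, expected):
        rec = base_record(weight_kg=weight)
        assert check_vitals(rec, rec["reference_date"])[1] == expected

    def test_age_boundaries_completed_years(self):
        ref = pd.Timestamp("2008-03-10")
        for years, expected in ((15, True), (16, False), (115, False), (116, True)):
            rec = base_record(birthdate=ref - pd.DateOffset(years=years))
            assert check_vitals(rec, ref)[2] == expected, years
        # one day short of the 16th birthday is still age 15
        rec = base_record(birthdate=ref - pd.DateOffset(years=16) + pd.Timedelta("1D"))
        assert check_vitals(rec, ref)[2] is True


class TestAnyLogicalProblem:
    def test_or_identity_on_random_vectors(self):
        rng = np.random.default_rng(3)
        keys = ["mood_persistence_err", "adl_dnoc_err", "nutrition_err",
                "ulcer_err", "any_therapy_err"]
        for _ in range(1000):
            flags = {k: bool(rng.integers(0, 2)) for k in keys}
            assert any_logical_problem(flags) == any(flags.values())

    def test_missing_component_propagates(self):
        flags = {"mood_persistence_err": None, "adl_dnoc_err": False,
                 "nutrition_err": False, "ulcer_err": True, "any_therapy_err": False}
        assert any_logical_problem(flags) is None


class TestServiceIndicators:
    NREHAB = DICT.block("NURSING_REHAB")

    def test_no_therapy_all_false(self):
        out = service_indicators(base_record(), self.NREHAB)
        assert out["total_therapy_minutes"] == 0
        assert not any(out[k] for k in ("nursing_rehab_2plus", "any_ot", "any_pt",
                                        "rehab_3d45m", "rehab_5d150m"))

    def test_intense_pt_trips_thresholds(self):
        rec = base_record(pt_days=5, pt_minutes=200, distinct_therapy_days=5)
        out = service_indicators(rec, self.NREHAB)
        assert out["any_pt"] and out["rehab_3d45m"] and out["rehab_5d150m"]

    def test_two_nursing_rehab_items_at_six_days(self):
        rec = base_record(nrehab_rom_passive=6, nrehab_walking=7)
        assert service_indicators(rec, self.NREHAB)["nursing_rehab_2plus"]

    def test_nested_intensity_thresholds(self, small_cohort, dictionary):
        """5+days/150+min cannot hold without 3+days/45+min."""
        from raiaudit.rules import service_frame
        _, frame, _ = small_cohort
        sv = service_frame(frame, dictionary)
        assert not ((sv["rehab_5d150m"] == 1) & (sv["rehab_3d45m"] == 0)).any()


class TestSignoffLag:
    @pytest.mark.parametrize("days,category", [(-1, "neg"), (0, "d0_6"),
                                               (6, "d0_6"), (7, "d7_30"),
                                               (30, "d7_30"), (31, "gt30")])
    def test_boundaries(self, days, category):
        ref = pd.Timestamp("2008-03-10")
        rec = base_record(signoff_date=ref + pd.Timedelta(days=days))
        assert signoff_lag(rec) == (days, category)

    def test_missing_signoff(self):
        rec = base_record(signoff_date=None)
        assert signoff_lag(rec) == (None, None)

    def test_categories_partition(self, small_cohort, dictionary):
        _, frame, _ = small_cohort
        flags = audit_frame(frame, dictionary)
        present = flags["signoff_category"].notna()
        assert present.all()
        counts = flags.loc[present, "signoff_category"].value_counts()
        assert counts.sum() == len(frame)


class TestPairRules:
    def _pair(self, t1_items=None, t2_items=None):
        frame_rows = []
        for j, items in enumerate([t1_items or {}, t2_items or {}]):
            rec = base_record(**items)
            rec.update(person_id="p1", facility_id="f1", sector="CCC",
                       assessment_type="quarterly",
                       reference_date=pd.Timestamp("2008-01-10")
                       + pd.DateOffset(months=3 * j))
            frame_rows.append(rec)
        frame = pd.DataFrame(frame_rows)
        records = frame_to_records(frame, DICT)
        return make_pairs(records)[0]

    def test_reversal_requires_t1_presence(self):
        pair = self._pair({}, {})
        assert diagnosis_reversal(pair, "multiple_sclerosis") is None

    def test_reversal_stable_diagnosis_not_flagged(self):
        pair = self._pair({"quadriplegia": 1}, {"quadriplegia": 1})
        assert diagnosis_reversal(pair, "quadriplegia") is False

    def test_reversal_cleared_diagnosis_flagged(self):
        pair = self._pair({"schizophrenia": 1}, {"schizophrenia": 0})
        assert diagnosis_reversal(pair, "schizophrenia") is True

    def test_autopopulation_on_identical_records(self):
        pair = self._pair({"mood_02": 1, "clin_005": 1},
                          {"mood_02": 1, "clin_005": 1})
        assert autopopulation_flags(pair, DICT) == (True, True, True)

    def test_one_mood_item_breaks_mood_flag_only(self):
        pair = self._pair({}, {"mood_02": 1})
        clin, mood, adl = autopopulation_flags(pair, DICT)
        assert (clin, mood, adl) == (False, False, True)

    def test_missing_matches_missing(self):
        pair = self._pair({"height_cm": None}, {"height_cm": None})
        assert autopopulation_flags(pair, DICT)[0] is True


class TestVectorizedParity:
    def test_audit_frame_matches_scalar_rules(self, small_cohort, dictionary):
        _, frame, _ = small_cohort
        sub = frame.sample(150, random_state=1).reset_index(drop=True)
        flags = audit_frame(sub, dictionary)
        for i, row in enumerate(sub.to_dict("records")):
            checks = {
                "mood_persistence_err": check_mood_persistence(row),
                "adl_dnoc_err": check_adl_did_not_occur(row, dictionary.adl_pairs()),
                "nutrition_err": check_nutrition(row),
                "ulcer_err": check_ulcer(row),
            }
            day15, nodays, exceed = check_therapy(row)
            checks.update(therapy_day15_err=day15, therapy_nodays_err=nodays,
                          therapy_exceed_err=exceed)
            h, w, a = check_vitals(row, row["reference_date"])
            checks.update(height_err=h, weight_err=w, age_err=a)
            for col, want in checks.items():
                got = flags.at[i, col]
                if want is None:
                    assert pd.isna(got), (i, col)
                else:
                    assert got == float(want), (i, col)

    def test_pair_audit_same_quarter_pairs_dropped(self, dictionary):
        rows = []
        for j, day in enumerate(("2008-01-05", "2008-02-05", "2008-04-05")):
            rec = base_record()
            rec.update(person_id="p1", facility_id="f1", sector="CCC",
                       assessment_type="quarterly",
                       reference_date=pd.Timestamp(day))
            rows.append(rec)
        frame = pd.DataFrame(rows)
        out = audit_pairs(frame, dictionary)
        assert len(out) == 1  # Jan->Feb same quarter; Feb->Apr spans quarters
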