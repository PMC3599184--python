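"""Record schema, CSV round-trips, quarter assignment and pairing."""
import datetime as dt

import numpy as np
import pandas as pd
import pytest

from raiaudit.dictionary import default_dictionary
from raiaudit.records import (
    AssessmentRecord,
    SchemaError,
    assign_quarter,
    exclude_comatose,
    frame_to_records,
    make_pairs,
    pair_frame,
    quarter_label,
    read_assessments,
    read_frame,
    records_to_frame,
    write_assessments,
    write_frame,
)


def _record(person="p1", sector="CCC", date="2006-02-01", **items):
    base = {c: 0 for c in default_dictionary().codes}
    base.update(items)
    return AssessmentRecord(
        person_id=person,
        facility_id="f1",
        sector=sector,
        assessment_type="quarterly",
        reference_date=dt.date.fromisoformat(date),
        signoff_date=dt.date.fromisoformat(date),
        birthdate=dt.date(1930, 1, 1),
        items=base,
    )


class TestCsvRoundTrip:
    def test_three_row_file(self, tmp_path, dictionary, small_cohort):
        _, frame, _ = small_cohort
        path = tmp_path / "three.csv"
        write_frame(frame.head(3), path, dictionary)
        assert len(read_assessments(path, dictionary)) == 3

    def test_fifty_record_round_trip(self, tmp_path, dictionary, small_cohort):
        _, frame, _ = small_cohort
        subset = frame.head(50)
        path = tmp_path / "fifty.csv"
        write_frame(subset, path, dictionary)
        back = read_frame(path, dictionary)
        for code in dictionary.codes:
            np.testing.assert_allclose(
                back[code].to_numpy(dtype=float),
                subset[code].to_numpy(dtype=float),
                err_msg=code,
            )
        records = frame_to_records(subset, dictionary)
        path2 = tmp_path / "records.csv"
        write_assessments(records, path2, dictionary)
        assert read_assessments(path2, dictionary) == records

    def test_out_of_domain_value_names_cell(self, tmp_path, dictionary, small_cohort):
        _, frame, _ = small_cohort
        bad = frame.head(3).copy()
        bad.loc[bad.index[1], "adl_transfer_perf"] = 9  # outside {0..4, 8}
        path = tmp_path / "bad.csv"
        write_frame(bad, path, dictionary)
        with pytest.raises(SchemaError, match="adl_transfer_perf"):
            read_frame(path, dictionary)

    def test_header_mismatch_is_fatal(self, tmp_path, dictionary, small_cohort):
        _, frame, _ = small_cohort
        path = tmp_path / "short.csv"
        write_frame(frame.head(2), path, dictionary)
        text = path.read_text().splitlines()
        text[0] = text[0].replace("mood_01", "mood_XX")
        path.write_text("\n".join(text))
        with pytest.raises(SchemaError, match="header"):
            read_frame(path, dictionary)


class TestQuarterAssignment:
    @pytest.mark.parametrize(
        "date,sector,origin,label,index",
        [
            ("1996-08-15", "CCC", {"CCC": "1996_3"}, "1996_3", 0),
            ("2005-07-02", "LTC", {"LTC": "2005_3"}, "2005_3", 0),
            ("1997-01-01", "CCC", {"CCC": "1996_3"}, "1997_1", 2),
        ],
    )
    def test_label_and_sector_index(self, date, sector, origin, label, index):
        q = assign_quarter(_record(sector=sector, date=date), origin)
        assert (q.label, q.sector_index) == (label, index)

    def test_stable_under_reordering(self, small_cohort, dictionary):
        _, frame, _ = small_cohort
        records = frame_to_records(frame.head(40), dictionary)
        origin = {"CCC": "2006_1", "LTC": "2006_1"}
        expected = [assign_quarter(r, origin) for r in records]
        shuffled = list(records)
        np.random.default_rng(0).shuffle(shuffled)
        remapped = {id(r): assign_quarter(r, origin) for r in shuffled}
        assert [remapped[id(r)] for r in records] == expected


class TestPairs:
    def test_chain_of_three_gives_two_pairs(self):
        recs = [_record(date=d) for d in ("2006-01-05", "2006-04-05", "2006-07-05")]
        pairs = make_pairs(recs)
        assert [(p.t1.reference_date, p.t2.reference_date) for p in pairs] == [
            (dt.date(2006, 1, 5), dt.date(2006, 4, 5)),
            (dt.date(2006, 4, 5), dt.date(2006, 7, 5)),
        ]

    def test_singletons_give_no_pairs(self):
        recs = [_record(person="a"), _record(person="b", date="2006-05-01")]
        assert make_pairs(recs) == []

    def test_duplicate_dates_fatal(self):
        recs = [_record(), _record()]
        with pytest.raises(ValueError, match="duplicate"):
            make_pairs(recs)

    def test_closed_form_pair_count(self):
        """n persons with k assessments each yield n*(k-1) pairs."""
        rng = np.random.default_rng(5)
        recs = []
        total = 0
        for p in range(12):
            k = int(rng.integers(1, 6))
            total += max(0, k - 1)
            for j in range(k):
                recs.append(_record(person=f"p{p:02d}", date=str(dt.date(2006, 1, 1) + dt.timedelta(days=91 * j))))
        assert len(make_pairs(recs)) == total

    def test_pair_frame_matches_record_pairing(self, small_cohort, dictionary):
        _, frame, _ = small_cohort
        sub = frame.head(300)
        pf = pair_frame(sub)
        records = frame_to_records(
            sub.sort_values(["person_id", "sector", "reference_date"]), dictionary
        )
        assert len(pf) == len(make_pairs(records))


class TestComatoseExclusion:
    def test_counts_and_idempotence(self, small_cohort):
        _, frame, _ = small_cohort
        sub = frame.head(10).copy()
        sub.loc[sub.index[:2], "comatose"] = 1
        once = exclude_comatose(sub)
        assert len(once) == 8
        pd.testing.assert_frame_equal(exclude_comatose(once), once)

    def test_record_list_variant(self):
        recs = [_record(person=f"p{i}", comatose=int(i < 2)) for i in range(10)]
        kept = exclude_comatose(recs)
        assert len(kept) == 8 and all(r.get("comatose") == 0 for r in kept)


class TestDictionarySerialization:
    def test_yaml_round_trip(self, tmp_path, dictionary):
        path = tmp_path / "dictionary.yaml"
        dictionary.to_yaml(path)
        from raiaudit.dictionary import ItemDictionary
        back = ItemDictionary.from_yaml(path)
        assert back.codes == dictionary.codes
        assert back.blocks == dictionary.blocks
        assert back.items["adl_transfer_perf"].domain == frozenset({0, 1, 2, 3, 4, 8})

    def test_block_invariants_enforced(self, dictionary):
        from raiaudit.dictionary import ItemDictionary
        import pytest as _pytest
        bad_blocks = dict(dictionary.blocks)
        bad_blocks["MOOD"] = dictionary.blocks["MOOD"][:15]
        with _pytest.raises(ValueError, match="MOOD"):
            ItemDictionary(items=dictionary.items, blocks=bad_blocks)
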