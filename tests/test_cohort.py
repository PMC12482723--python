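"""Cohort construction: normalization, dedup, index correction, transactions."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comorbarm import cohort
from comorbarm.cohort import (
    CohortFunnel,
    PatientHistory,
    Transaction,
    TransactionDB,
    VisitRecord,
    aggregate_yearly,
    assign_timeframe,
    build_cohort,
    build_histories,
    build_transactions,
    chapter_in_scope,
    correct_index_year,
    extract_onset_year,
    first_occurrences,
    normalize_icd,
    truncated_share_pct,
)
from comorbarm.errors import ConsistencyError, FormatError, ValidationError


def _visit(pid, year, codes, sex="F", birth=1950, death=None, note=None):
    return VisitRecord(
        patient_id=pid,
        year=year,
        sex=sex,
        birth_year=birth,
        death_year=death,
        icd_codes=tuple(codes),
        note_text=note,
    )


class TestNormalizeIcd:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("E1120", "E11"),
            ("A00", "A00"),
            ("e11.2", "E11"),
            (" I10 ", "I10"),
            ("n18.4", "N18"),
        ],
    )
    def test_cleaning_steps(self, raw, expected):
        assert normalize_icd(raw) == expected

    @pytest.mark.parametrize("raw", ["", "A1", "E.", " .1 "])
    def test_too_short_raises(self, raw):
        with pytest.raises(FormatError):
            normalize_icd(raw)


class TestChapterScope:
    @pytest.mark.parametrize(
        "code,expected",
        [("A00", True), ("N18", True), ("O80", False), ("Z00", False), ("R51", False)],
    )
    def test_a_to_n_inclusive(self, code, expected):
        assert chapter_in_scope(code) is expected


class TestAggregateYearly:
    def test_same_year_visits_union(self):
        recs = [_visit("p1", 2010, ["I10"]), _visit("p1", 2010, ["I10", "E78"])]
        assert aggregate_yearly(recs)[("p1", 2010)] == {"I10", "E78"}

    def test_different_years_stay_separate(self):
        recs = [_visit("p1", 2010, ["I10"]), _visit("p1", 2011, ["E78"])]
        agg = aggregate_yearly(recs)
        assert agg[("p1", 2010)] == {"I10"} and agg[("p1", 2011)] == {"E78"}

    def test_out_of_scope_codes_dropped(self):
        agg = aggregate_yearly([_visit("p1", 2010, ["O800", "Z000", "I10"])])
        assert agg[("p1", 2010)] == {"I10"}

    def test_permutation_invariance(self):
        recs = [
            _visit(f"p{i % 7}", 2005 + (i % 9), [f"{c}{i % 30 + 10}"])
            for i, c in zip(range(60), "AIJKEMN" * 10)
        ]
        shuffled = recs[:]
        random.Random(3).shuffle(shuffled)
        assert aggregate_yearly(recs) == aggregate_yearly(shuffled)


class TestFirstOccurrences:
    def test_minimum_year_kept(self):
        agg = aggregate_yearly(
            [_visit("p1", 2011, ["I10"]), _visit("p1", 2008, ["I10"])]
        )
        firsts, _ = first_occurrences(agg)["p1"]
        assert firsts == {"I10": 2008}

    def test_no_e11_gives_no_index(self):
        agg = aggregate_yearly([_visit("p1", 2010, ["I10"])])
        assert first_occurrences(agg)["p1"][1] is None

    def test_matches_bruteforce_on_random_fixture(self):
        rng = random.Random(11)
        codes = ["I10", "E78", "E11", "N18", "J18", "M54"]
        recs = [
            _visit(
                f"p{rng.randrange(50)}",
                rng.randrange(2007, 2021),
                rng.sample(codes, rng.randrange(1, 4)),
            )
            for _ in range(400)
        ]
        result = first_occurrences(aggregate_yearly(recs))
        # brute force: scan every record per patient per code
        expected = {}
        for r in recs:
            for code in r.icd_codes:
                d = expected.setdefault(r.patient_id, {})
                d[code] = min(d.get(code, 9999), r.year)
        for pid, (firsts, index) in result.items():
            assert firsts == expected[pid]
            assert index == expected[pid].get("E11")


class TestOnsetExtraction:
    @pytest.mark.parametrize(
        "note,expected",
        [
            ("T2DM diagnosed in 2004, controlled", 2004),
            ("no chronic disease history", None),
            ("diabetes since 2003; hypertension since 1999", 2003),
            ("E11 first noted 2010; diabetes worse since 2012", 2010),
            ("seen in 2015 for diabetes since 2009", 2009),
            ("year 1850 diabetes", None),
        ],
    )
    def test_stem_scoped_years(self, note, expected):
        assert extract_onset_year(note) == expected


class TestCorrectIndexYear:
    def _hist(self, index):
        return PatientHistory(
            patient_id="p1",
            sex="F",
            birth_year=1950,
            death_year=None,
            first_occurrence={"E11": index},
            index_year=index,
            visit_years=frozenset([index]),
        )

    def test_earlier_note_updates(self):
        h = correct_index_year(self._hist(2009), 2004)
        assert h.index_year == 2004 and h.index_source == "note_corrected"

    def test_later_note_ignored(self):
        h = correct_index_year(self._hist(2009), 2012)
        assert h.index_year == 2009 and h.index_source == "recorded"

    def test_absent_note_unchanged(self):
        h = correct_index_year(self._hist(2009), None)
        assert h.index_year == 2009 and h.index_source == "recorded"


class TestBuildCohort:
    def test_age_filter_excludes_centenarian(self):
        recs = [
            _visit("p1", 2010, ["I10"], birth=1908),
            _visit("p1", 2012, ["E11"], birth=1908),
        ]
        kept, funnel = build_cohort(build_histories(recs))
        assert kept == []
        assert dict(funnel.steps)["age_at_index_le_100"] == 0

    def test_no_prior_visit_excluded(self):
        recs = [_visit("p1", 2012, ["E11", "I10"])]
        kept, funnel = build_cohort(build_histories(recs))
        assert kept == []
        assert dict(funnel.steps)["confirmed_e11_index"] == 1

    def test_prior_visit_retains(self):
        recs = [_visit("p1", 2010, ["I10"]), _visit("p1", 2012, ["E11"])]
        kept, _ = build_cohort(build_histories(recs))
        assert len(kept) == 1 and kept[0].index_year == 2012

    def test_planted_violation_counts_match_funnel(self, demo_records, demo_truth):
        _, funnel = build_cohort(build_histories(demo_records))
        steps = dict(funnel.steps)
        planted = demo_truth.planted_violations
        assert steps["input"] - steps["confirmed_e11_index"] == planted["no_e11"]
        assert (
            steps["confirmed_e11_index"] - steps["age_at_index_le_100"]
            == planted["over_age"]
        )
        assert (
            steps["age_at_index_le_100"] - steps["visit_within_5y_before_index"]
            == planted["no_prior_visit"]
        )
        assert steps["visit_within_5y_before_index"] == demo_truth.n_eligible

    def test_funnel_monotonic_and_rejects_increase(self):
        with pytest.raises(ValidationError):
            CohortFunnel([("a", 5), ("b", 7)])

    def test_share_report_truncates(self):
        assert truncated_share_pct(65467, 1028374) == 6.3


class TestAssignTimeframe:
    @pytest.mark.parametrize(
        "offset,label",
        [
            (-6, None),
            (-5, "n5-n1"),
            (-1, "n5-n1"),
            (0, "0-4"),
            (4, "0-4"),
            (5, "5-9"),
            (9, "5-9"),
            (10, "10-"),
            (37, "10-"),
        ],
    )
    def test_boundaries(self, offset, label):
        assert assign_timeframe(offset) == label


class TestBuildTransactions:
    def _hist(self, pid, firsts, index, visits, death=None, sex="F"):
        return PatientHistory(
            patient_id=pid,
            sex=sex,
            birth_year=1950,
            death_year=death,
            first_occurrence=firsts,
            index_year=index,
            visit_years=frozenset(visits),
        )

    def test_hand_computed_small_fixture(self):
        # p1: observed 2008-2020, index 2010, codes at offsets -2, 0, 6, 10
        h = self._hist(
            "p1",
            {"E11": 2010, "I10": 2008, "E78": 2010, "N18": 2016, "J18": 2020},
            2010,
            range(2008, 2021),
        )
        db = build_transactions([h])
        by_class = {t.timeframe: t.items for t in db.transactions}
        assert by_class == {
            "n5-n1": {"I10"},
            "0-4": {"E78"},
            "5-9": {"N18"},
            "10-": {"J18"},
        }

    def test_followup_truncates_observability(self):
        # observed only through index+3: contributes to n5-n1 and 0-4 only
        h = self._hist("p1", {"E11": 2010, "I10": 2009}, 2010, range(2009, 2014))
        db = build_transactions([h])
        assert sorted(t.timeframe for t in db.transactions) == ["0-4", "n5-n1"]

    def test_death_truncates_observability(self):
        h = self._hist(
            "p1", {"E11": 2010, "I10": 2009}, 2010, range(2009, 2021), death=2016
        )
        db = build_transactions([h])
        assert sorted(t.timeframe for t in db.transactions) == ["0-4", "5-9", "n5-n1"]

    def test_e11_never_an_item_and_pairs_unique(self, demo_db):
        seen = set()
        for t in demo_db.transactions:
            assert "E11" not in t.items
            for item in t.items:
                assert (t.patient_id, item) not in seen
                seen.add((t.patient_id, item))

    def test_empty_transactions_retained(self):
        h = self._hist("p1", {"E11": 2010}, 2010, range(2008, 2016))
        db = build_transactions([h])
        assert all(t.items == frozenset() for t in db.transactions)
        assert len(db.transactions) == 3  # n5-n1, 0-4, 5-9

    def test_pre_window_offsets_dropped(self):
        h = self._hist("p1", {"E11": 2016, "I10": 2008}, 2016, range(2008, 2021))
        db = build_transactions([h])
        for t in db.transactions:
            assert "I10" not in t.items  # offset -8 excluded entirely

    def test_index_outside_window_raises(self):
        h = self._hist("p1", {"E11": 2010, "I10": 2009}, 2010, range(2009, 2015))
        with pytest.raises(ConsistencyError):
            build_transactions([h], window=(2012, 2021))

    def test_class_sizes_non_increasing_with_attrition(self, demo_db):
        sizes = demo_db.class_sizes
        assert sizes["0-4"] >= sizes["5-9"] >= sizes["10-"]


class TestPipelineProperties:
    def test_record_order_invariance(self, demo_records):
        shuffled = list(demo_records)
        random.Random(5).shuffle(shuffled)
        a = build_histories(demo_records)
        b = build_histories(shuffled)
        assert a == b

    def test_transactions_roundtrip_jsonl(self, demo_db, tmp_path):
        path = tmp_path / "tx.jsonl"
        cohort.write_transactions_jsonl(demo_db, path)
        back = cohort.read_transactions_jsonl(path)
        assert back.transactions == demo_db.transactions
        assert back.class_sizes == demo_db.class_sizes


@settings(max_examples=200, deadline=None, derandomize=True)
@given(offset=st.integers(min_value=-50, max_value=80))
def test_timeframe_mapping_total_and_consistent(offset):
    """Every offset >= -5 maps to exactly one class whose bounds contain it."""
    label = assign_timeframe(offset)
    if offset < -5:
        assert label is None
    else:
        lo, hi = cohort.CLASS_BOUNDS[label]
        assert lo <= offset and (hi is None or offset <= hi)
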