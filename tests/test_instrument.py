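import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medlifenet.instrument import (
    CodingError,
    InstrumentDefinition,
    ItemDefinition,
    default_instrument,
    encode_cohort,
    encode_item,
    group_percentages,
    medlife_score,
    read_cohort_csv,
    score_matrix,
    stratify_quartiles,
    write_cohort_csv,
)

from conftest import adherent_answer, make_record, non_adherent_answer, random_record


class TestDefaultInstrument:
    def test_domain_partition(self, instrument):
        assert instrument.domain_sizes() == {
            "food_consumption": 15,
            "dietary_habits": 7,
            "lifestyle": 6,
        }
        assert len(instrument.items) == 28

    def test_indicator_expansion(self, instrument):
        # two tripartite items expand 28 items to 32 indicators
        assert len(instrument.score_indicators) == 28
        assert len(instrument.indicator_ids) == 32
        assert len(instrument.tripartite_items) == 2

    def test_duplicate_item_ids_rejected(self, instrument):
        with pytest.raises(ValueError, match="duplicate"):
            InstrumentDefinition(items=instrument.items + (instrument.items[0],))


class TestEncodeItem:
    def test_limit_item_scores_limitation(self, instrument):
        item = instrument.item("limit_sugar")
        assert encode_item(item, "limits") == (1,)
        assert encode_item(item, "unrestricted") == (0,)

    def test_moderate_item_excess_scores_zero(self, instrument):
        item = instrument.item("sweets")
        assert encode_item(item, "excess") == (0,)
        assert encode_item(item, "moderate") == (1,)

    @pytest.mark.parametrize(
        "answer,expected",
        [("low", (1, 0, 0)), ("moderate", (0, 1, 0)), ("high", (0, 0, 1))],
    )
    def test_tripartite_one_hot(self, instrument, answer, expected):
        assert encode_item(instrument.item("wine"), answer) == expected

    def test_unknown_answer_rejected_with_context(self, instrument):
        with pytest.raises(CodingError, match="wine.*'never'"):
            encode_item(instrument.item("wine"), "never")


class TestEncodeCohort:
    def test_default_instrument_yields_32_columns(self, instrument, fully_adherent_record):
        X = encode_cohort(instrument, [fully_adherent_record])
        assert X.values.shape == (1, 32)
        assert X.indicator_ids == instrument.indicator_ids

    def test_no_tripartite_gives_one_column_per_item(self):
        items = tuple(
            ItemDefinition(f"i{k}", "lifestyle", "simple", ("no", "yes"), ("yes",))
            for k in range(5)
        )
        inst = InstrumentDefinition(items=items)
        rec = make_record(inst, {f"i{k}": "yes" for k in range(5)})
        X = encode_cohort(inst, [rec])
        assert X.values.shape == (1, 5)

    def test_identical_records_identical_rows(self, instrument):
        rng = np.random.default_rng(0)
        base = random_record(instrument, rng)
        records = [
            make_record(instrument, dict(base.item_answers), rid=f"r{i}")
            for i in range(4)
        ]
        X = encode_cohort(instrument, records)
        assert (X.values == X.values[0]).all()

    def test_duplicate_respondent_rejected(self, instrument, fully_adherent_record):
        with pytest.raises(ValueError, match="duplicate respondent_id"):
            encode_cohort(instrument, [fully_adherent_record, fully_adherent_record])

    def test_tripartite_triples_one_hot_for_random_cohort(self, instrument):
        rng = np.random.default_rng(1)
        records = [random_record(instrument, rng, rid=f"r{i}") for i in range(50)]
        X = encode_cohort(instrument, records)
        for it in instrument.tripartite_items:
            cols = [X.indicator_ids.index(i) for i in it.indicator_ids]
            assert (X.values[:, cols].sum(axis=1) == 1).all()


class TestScore:
    def test_fully_adherent_scores_28(self, instrument, fully_adherent_record):
        assert medlife_score(instrument, fully_adherent_record) == 28

    def test_fully_nonadherent_scores_0(self, instrument, fully_nonadherent_record):
        assert medlife_score(instrument, fully_nonadherent_record) == 0

    def test_food_domain_only_scores_15(self, instrument):
        answers = {
            it.item_id: (
                adherent_answer(it)
                if it.domain == "food_consumption"
                else non_adherent_answer(it)
            )
            for it in instrument.items
        }
        assert medlife_score(instrument, make_record(instrument, answers)) == 15

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_score_additivity(self, seed):
        # score equals the sum of the 28 score-contributing indicator columns
        instrument = default_instrument()
        rng = np.random.default_rng(seed)
        rec = random_record(instrument, rng)
        X = encode_cohort(instrument, [rec])
        assert medlife_score(instrument, rec) == score_matrix(instrument, X)[0]

    def test_single_flip_never_decreases_score(self, instrument, fully_nonadherent_record):
        base = medlife_score(instrument, fully_nonadherent_record)
        for it in instrument.items:
            answers = dict(fully_nonadherent_record.item_answers)
            answers[it.item_id] = adherent_answer(it)
            rec = make_record(instrument, answers)
            assert medlife_score(instrument, rec) == base + 1

    def test_missing_answer_rejected(self, instrument, fully_adherent_record):
        answers = dict(fully_adherent_record.item_answers)
        del answers["water"]
        with pytest.raises(CodingError, match="water"):
            medlife_score(instrument, make_record(instrument, answers))


class TestStratification:
    def test_linear_interpolation_quartiles(self):
        # n=12, scores 0..11: Q1=2.75, Q3=8.25 under the p*(n-1) rank rule
        labels = stratify_quartiles(list(range(12)))
        assert [s for s, l in zip(range(12), labels) if l == "low"] == [0, 1, 2]
        assert [s for s, l in zip(range(12), labels) if l == "high"] == [9, 10, 11]
        assert labels.count("intermediate") == 6

    def test_all_equal_scores_all_intermediate(self):
        with pytest.warns(UserWarning, match="intermediate"):
            labels = stratify_quartiles([7] * 10)
        assert set(labels) == {"intermediate"}

    def test_single_outlier_is_only_high_member(self):
        labels = stratify_quartiles([1, 1, 1, 10])
        assert labels.count("high") == 1
        assert labels[3] == "high"

    def test_groups_partition_cohort(self):
        rng = np.random.default_rng(3)
        scores = rng.integers(0, 29, size=200)
        labels = stratify_quartiles(scores)
        assert len(labels) == 200
        assert set(labels) <= {"low", "intermediate", "high"}

    def test_too_few_respondents_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            stratify_quartiles([1, 2, 3])


def test_group_percentage_reporting():
    pct = group_percentages({"low": 84, "intermediate": 325, "high": 104})
    assert pct == {"low": 16.4, "intermediate": 63.3, "high": 20.3}


def test_cohort_csv_round_trip(tmp_path, instrument):
    rng = np.random.default_rng(5)
    records = [random_record(instrument, rng, rid=f"r{i}") for i in range(10)]
    path = tmp_path / "cohort.csv"
    write_cohort_csv(records, path)
    back = read_cohort_csv(path)
    assert [r.respondent_id for r in back] == [r.respondent_id for r in records]
    assert all(
        a.item_answers == b.item_answers and a.smoking == b.smoking
        for a, b in zip(records, back)
    )
    X1 = encode_cohort(instrument, records)
    X2 = encode_cohort(instrument, back)
    assert (X1.values == X2.values).all()
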