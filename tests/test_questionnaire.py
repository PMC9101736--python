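"""Scoring engine: section sums, composites, missingness and the
low-sex-drive rule."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from leamq import (
    SchemaError,
    ValidationError,
    categorize_low_sex_drive,
    compute_ehmc_score,
    compute_weight_flux,
    score_response,
    score_table,
)
from leamq.keys import SECTIONS

from conftest import baseline_answers


class TestSectionScoring:
    def test_all_adjusted_zero_scores_zero(self, key):
        res = score_response(baseline_answers(key), "v2", key)
        assert all(v == 0 for v in res.sections.values())
        assert res.total == 0
        assert res.ehmc_score == 0

    def test_single_step_increases_section_and_total_by_one(self, key):
        base = baseline_answers(key)
        ref = score_response(base, "v2", key)
        for item_id in ("1A", "4F", "5A1", "5B1", "6C"):
            it = key[item_id]
            bumped = dict(base)
            # one step up in *adjusted* space
            bumped[item_id] = it.max_code - 1 if it.reverse_coded else 1
            res = score_response(bumped, "v2", key)
            assert res.sections[it.section] == ref.sections[it.section] + 1
            assert res.total == ref.total + 1

    def test_two_section_hand_summation(self, key):
        # gastrointestinal {2,1,0} -> 3; injury/illness {3,1,1} -> 5
        answers = {"2A": 2, "2B": 1, "2C": 0, "4A": 3, "4B": 1, "4C": 1}
        res = score_response(answers, "v1", key)
        assert res.sections["gastrointestinal"] == 3
        assert res.sections["injury_illness"] == 5
        assert res.total == 8
        assert math.isnan(res.sections["wellbeing"])

    def test_all_items_of_section_missing_scores_missing(self, key):
        answers = baseline_answers(key)
        for it in key.items_for("v2", "dizziness"):
            del answers[it.item_id]
        res = score_response(answers, "v2", key)
        assert math.isnan(res.sections["dizziness"])
        full = score_response(baseline_answers(key), "v2", key)
        for s in SECTIONS:
            if s != "dizziness":
                assert res.sections[s] == full.sections[s]

    def test_unknown_item_raises_schema_error(self, key):
        with pytest.raises(SchemaError, match="99Z"):
            score_response({"99Z": 1}, "v2", key)

    def test_code_outside_allowed_raises_naming_item(self, key):
        with pytest.raises(ValidationError, match="2A"):
            score_response({"2A": 7}, "v2", key)

    def test_reverse_adjustment_is_an_involution(self, key):
        for it in key:
            for c in it.allowed_codes:
                assert it.adjust(it.adjust(c)) == c


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.data())
def test_total_equals_sum_of_sections_on_random_responses(data):
    from leamq import default_key

    key = default_key()
    version = data.draw(st.sampled_from(["v1", "v2"]))
    answers = {
        it.item_id: data.draw(st.sampled_from(list(it.allowed_codes)))
        for it in key.items_for(version)
    }
    res = score_response(answers, version, key)
    present = [v for v in res.sections.values() if not math.isnan(v)]
    assert res.total == sum(present)
    # monotone: all scores non-negative given non-negative codes
    assert all(v >= 0 for v in present)


class TestComposites:
    def test_weight_flux_arithmetic(self):
        assert compute_weight_flux(80, 80) == 0
        assert compute_weight_flux(85, 75) == 10
        assert math.isnan(compute_weight_flux(None, 75))
        with pytest.raises(ValidationError):
            compute_weight_flux(70, 75)

    @pytest.mark.parametrize(
        "a6,c6,d6,expected",
        [(2, 0, 0, True), (1, 2, 1, True), (1, 2, 0, False), (0, 0, 0, False)],
    )
    def test_low_sex_drive_rule_cases(self, a6, c6, d6, expected):
        assert categorize_low_sex_drive({"6A": a6, "6C": c6, "6D": d6}) is expected

    def test_low_sex_drive_rule_matches_bruteforce_cross_product(self, key):
        codes = key["6A"].allowed_codes
        for a6, c6, d6 in itertools.product(codes, codes, codes):
            expected = (a6 >= 2) or (c6 >= 2 and d6 >= 1)
            got = categorize_low_sex_drive({"6A": a6, "6C": c6, "6D": d6})
            assert got is expected, (a6, c6, d6)

    def test_low_sex_drive_missing_for_v1_with_warning(self):
        with pytest.warns(UserWarning):
            assert categorize_low_sex_drive({"6A": 2}, version="v1") is None

    def test_low_sex_drive_missing_when_constituent_missing(self):
        assert categorize_low_sex_drive({"6A": np.nan, "6C": 2, "6D": 1}) is None

    def test_ehmc_hand_summation_and_monotone_step(self, key):
        answers = baseline_answers(key)
        raised = dict(answers)
        raised["5A2"] = 2  # not reverse-coded: +2 adjusted
        assert compute_ehmc_score(raised, key) == compute_ehmc_score(answers, key) + 2
        # independent hand summation over the nine constituents
        rng = np.random.default_rng(7)
        vec = {i: int(rng.integers(0, 4)) for i in key.ehmc_items}
        answers.update(vec)
        expected = sum(
            (key[i].max_code - vec[i]) if key[i].reverse_coded else vec[i]
            for i in key.ehmc_items
        )
        assert compute_ehmc_score(answers, key) == expected

    def test_ehmc_missing_if_any_constituent_missing(self, key):
        answers = baseline_answers(key)
        del answers["6C"]
        assert math.isnan(compute_ehmc_score(answers, key))


class TestTableScoring:
    def test_table_agrees_with_per_response_scoring(self, key, cohort):
        responses, _ = cohort
        sample = responses.head(40)
        table = score_table(sample, key)
        for i, rec in sample.iterrows():
            answers = {
                it.item_id: rec[it.item_id]
                for it in key.items_for(rec["version"])
                if it.item_id in rec and not pd.isna(rec[it.item_id])
            }
            res = score_response(
                answers, rec["version"], key,
                highest_weight_kg=rec.get("highest_weight_kg"),
                lowest_weight_kg=rec.get("lowest_weight_kg"),
            )
            row = table.loc[i]
            for s in SECTIONS:
                a, b = row[f"{s}_score"], res.sections[s]
                assert (math.isnan(a) and math.isnan(b)) or a == b
            assert (math.isnan(row["total_score"]) and math.isnan(res.total)) or row["total_score"] == res.total

    def test_v1_rows_have_missing_sex_drive(self, cohort):
        responses, _ = cohort
        table = score_table(responses)
        v1 = table[table["version"] == "v1"]
        assert v1["low_sex_drive_score"].isna().all()
        assert v1["ehmc_score"].isna().all()

    def test_empty_table_scores_empty(self, key):
        out = score_table(pd.DataFrame({"athlete_id": [], "version": []}), key)
        assert len(out) == 0
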