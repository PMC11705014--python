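"""mHFII component scoring, totals and scoring-table validation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mhfii_foodsec.ffq import FFQRecord, WEEKLY_VALUES, weekly_frame
from mhfii_foodsec.mhfii import (
    ComponentRule,
    MHFIIScorer,
    ScoringError,
    ScoringTable,
    score_component,
    score_mhfii,
    validate_scoring_table,
)


def brute_score(freq: float, rule: ComponentRule) -> int:
    """Independent banding via bisection, for cross-checking."""
    ths = np.asarray(rule.thresholds)
    if rule.direction == "favourable":
        return int(np.searchsorted(ths, freq, side="right"))
    return int(rule.max_points - np.searchsorted(ths, freq, side="left"))


def optimal_record(table: ScoringTable) -> FFQRecord:
    """Top-band favourable intake, zero limiting intake."""
    responses = {}
    for rule in table.components:
        level = 6 if rule.direction == "favourable" else 0
        for item in rule.items:
            responses[item] = level
    return FFQRecord("optimal", responses)


def test_zero_intake_scores(scoring_table):
    for rule in scoring_table.components:
        expected = 0 if rule.direction == "favourable" else rule.max_points
        assert score_component(0.0, rule) == expected


def test_threshold_boundary_gives_higher_band(scoring_table):
    for rule in scoring_table.components:
        for k, t in enumerate(rule.thresholds):
            s = score_component(t, rule)
            if rule.direction == "favourable":
                assert s == k + 1
            else:
                assert s == rule.max_points - k


def test_negative_frequency_rejected(scoring_table):
    with pytest.raises(ScoringError):
        score_component(-0.1, scoring_table.components[0])


def test_score_component_matches_bisection_oracle(scoring_table):
    # every reachable frequency: all subset sums of the level values per
    # component, plus the thresholds themselves and near-boundary points
    for rule in scoring_table.components:
        sums = {0.0}
        for _ in rule.items:
            sums = {s + v for s in sums for v in WEEKLY_VALUES}
        probe = sums | set(rule.thresholds)
        probe |= {t + 1e-9 for t in rule.thresholds}
        probe |= {max(0.0, t - 1e-9) for t in rule.thresholds}
        for freq in probe:
            assert score_component(freq, rule) == brute_score(freq, rule), (
                rule.name,
                freq,
            )


def test_all_not_at_all_total(scoring_table):
    rec = FFQRecord(
        "none", {i: 0 for r in scoring_table.components for i in r.items}
    )
    result = score_mhfii(rec, scoring_table)
    limiting_max = sum(
        r.max_points
        for r in scoring_table.components
        if r.direction == "limiting"
    )
    assert result.total == limiting_max
    for rule in scoring_table.components:
        expected = 0 if rule.direction == "favourable" else rule.max_points
        assert result.component_scores[rule.name] == expected


def test_optimal_record_reaches_18(scoring_table):
    assert score_mhfii(optimal_record(scoring_table), scoring_table).total == 18


def test_hand_computed_fixture_total(scoring_table):
    """A fixed response vector scored by hand against the shipped table."""
    responses = {
        "fresh_vegetables": 4, "cooked_vegetables": 3,
        "vegetable_dishes": 2, "legumes": 1,            # 6.09 -> 2
        "fresh_fruits": 3, "berries": 2,
        "fruit_berry_dishes": 0,                        # 1.97 -> 0
        "rye_bread": 5, "wholegrain_bread": 3,
        "porridge": 0, "breakfast_cereals": 1,          # 7.62 -> 1
        "fish_dishes": 3, "fish_cold_cuts": 1,          # 1.62 -> 1
        "skimmed_milk": 4, "sour_milk": 0,              # 4.00 -> 1
        "red_meat_dishes": 3, "processed_meat_dishes": 2,
        "cold_cuts_sausage": 3,                         # 3.47 -> 1
        "sugary_soft_drinks": 2, "energy_drinks": 0,
        "sugary_juice_drinks": 0,                       # 0.47 -> 2
        "cooking_oil": 4, "oil_based_dressing": 0,      # 4.00 -> 1
        "nuts_unsalted": 2, "seeds": 0,                 # 0.47 -> 0
        "vegetable_fat_spread": 5,                      # 6.00 -> 1
        "sweets_chocolate": 3, "salty_snacks": 0,
        "sweet_pastry": 1, "ice_cream": 0,              # 1.62 -> 0
    }
    result = score_mhfii(FFQRecord("fix", responses), scoring_table)
    assert result.component_scores == {
        "vegetables": 2, "fruits_berries": 0, "fibre_rich_grains": 1,
        "fish": 1, "milk": 1, "red_processed_meat": 1,
        "sugar_sweetened_beverages": 2, "vegetable_oil": 1,
        "nuts_seeds": 0, "fat_spreads": 1, "snacks": 0,
    }
    assert result.total == 10


def test_totals_decompose_and_stay_in_bounds(scoring_table):
    rng = np.random.default_rng(1)
    items = [i for r in scoring_table.components for i in r.items]
    for _ in range(50):
        rec = FFQRecord(
            "r", {i: int(rng.integers(0, 7)) for i in items}
        )
        res = score_mhfii(rec, scoring_table)
        assert res.total == sum(res.component_scores.values())
        assert 0 <= res.total <= 18
        for rule in scoring_table.components:
            assert 0 <= res.component_scores[rule.name] <= rule.max_points


@given(data=st.data())
def test_monotonicity_in_single_items(data):
    from mhfii_foodsec.mhfii import load_default_scoring_table

    table = load_default_scoring_table()
    items = [i for r in table.components for i in r.items]
    levels = data.draw(
        st.lists(st.integers(0, 6), min_size=len(items), max_size=len(items))
    )
    idx = data.draw(st.integers(0, len(items) - 1))
    base = dict(zip(items, levels))
    if base[items[idx]] == 6:
        return
    bumped = dict(base)
    bumped[items[idx]] += 1
    t0 = score_mhfii(FFQRecord("a", base), table).total
    t1 = score_mhfii(FFQRecord("b", bumped), table).total
    direction = next(
        r.direction for r in table.components if items[idx] in r.items
    )
    if direction == "favourable":
        assert t1 >= t0
    else:
        assert t1 <= t0


def test_missing_component_flags_incomplete(scoring_table):
    items = [i for r in scoring_table.components for i in r.items]
    veg = scoring_table["vegetables"].items
    responses = {i: 3 for i in items if i not in veg}
    res = score_mhfii(FFQRecord("m", responses), scoring_table)
    assert res.n_missing_components == 1
    assert res.component_scores["vegetables"] is None
    assert res.total is None and not res.complete


def test_partially_missing_component_scored_on_observed(scoring_table):
    items = [i for r in scoring_table.components for i in r.items]
    responses = {i: 0 for i in items}
    responses.pop("fresh_vegetables")  # 3 of 4 vegetable items observed
    res = score_mhfii(FFQRecord("p", responses), scoring_table)
    assert res.component_scores["vegetables"] == 0
    assert res.complete


def test_validator_passes_shipped_table(scoring_table, schema):
    report = validate_scoring_table(scoring_table, schema.items)
    assert report.passed, report.messages


def test_validator_rejects_wrong_component_count(scoring_table):
    table = ScoringTable(components=scoring_table.components[:10])
    report = validate_scoring_table(table)
    assert not report.passed
    assert any("11" in m for m in report.messages)


def test_validator_rejects_wrong_point_budget(scoring_table):
    comps = list(scoring_table.components)
    veg = comps[0]
    comps[0] = dataclasses.replace(
        veg, max_points=1, thresholds=veg.thresholds[:1]
    )
    report = validate_scoring_table(ScoringTable(components=tuple(comps)))
    assert not report.passed
    assert any("18" in m for m in report.messages)


def test_scorer_transformer_matches_per_record_scoring(scoring_table):
    rng = np.random.default_rng(7)
    items = [i for r in scoring_table.components for i in r.items]
    codes = pd.DataFrame(
        rng.integers(0, 7, size=(40, len(items))), columns=items
    ).astype("Int64")
    codes.iloc[3, :4] = pd.NA  # knock out all vegetable items for one row
    scores = MHFIIScorer(scoring_table).fit(
        weekly_frame(codes)
    ).transform(weekly_frame(codes))
    for idx in range(len(codes)):
        responses = {
            item: int(codes.iloc[idx][item])
            for item in items
            if pd.notna(codes.iloc[idx][item])
        }
        expected = score_mhfii(FFQRecord(str(idx), responses), scoring_table)
        got_total = scores.iloc[idx]["mhfii_total"]
        if expected.total is None:
            assert pd.isna(got_total)
        else:
            assert got_total == expected.total


def test_yaml_round_trip(scoring_table, tmp_path):
    path = tmp_path / "table.yaml"
    scoring_table.to_yaml(path)
    assert ScoringTable.from_yaml(path) == scoring_table
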