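import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from diag360 import (
    AssessmentInput,
    ConfigError,
    DecisionRuleSpec,
    InputValidationError,
    TrafficStatus,
    build_profile,
    classify_blood_pressure,
    classify_element,
    classify_mental_health,
    combine_statuses,
)

G, O, R, GRAY = (
    TrafficStatus.GREEN,
    TrafficStatus.ORANGE,
    TrafficStatus.RED,
    TrafficStatus.GRAY,
)

from conftest import HEALTHY_CLINICAL, HEALTHY_ITEMS


class TestClassifyElement:
    @pytest.mark.parametrize(
        "value,expected",
        [(135, G), (150, O), (165, R), (140, O), (139.9, G), (160, R)],
    )
    def test_systolic_bands(self, config, value, expected):
        assert classify_element("systolic", value, config) is expected

    def test_left_closed_boundaries(self, config):
        # "140 to <160" style intervals include their lower edge
        assert classify_element("diastolic", 90, config) is O
        assert classify_element("diastolic", 100, config) is R

    def test_absent_value_is_gray(self, config):
        assert classify_element("systolic", None, config) is GRAY

    def test_out_of_range_value_rejected(self, config):
        with pytest.raises(InputValidationError, match="outside valid range"):
            classify_element("systolic", 500, config)

    def test_categorical_element(self, config):
        assert classify_element("albuminuria_stage", "A1", config) is G
        assert classify_element("albuminuria_stage", "A2", config) is O
        assert classify_element("albuminuria_stage", "A3", config) is R

    def test_unknown_category_rejected(self, config):
        with pytest.raises(InputValidationError):
            classify_element("albuminuria_stage", "A9", config)

    def test_reversed_bands_low_is_bad(self, config):
        assert classify_element("egfr", 20, config) is R
        assert classify_element("egfr", 45, config) is O
        assert classify_element("egfr", 90, config) is G

    def test_monotone_severity_along_each_numeric_element(self, config):
        """Increasing a value never skips against the band order direction."""
        for el in config.elements:
            if el.kind == "categorical":
                continue
            lo, hi = el.range
            grid = [lo + (hi - lo) * i / 200 for i in range(201)]
            seq = [classify_element(el, v, config).severity_rank for v in grid]
            diffs = {b - a for a, b in zip(seq, seq[1:]) if b != a}
            assert all(d > 0 for d in diffs) or all(d < 0 for d in diffs) or not diffs, el.id


class TestCombineStatuses:
    @pytest.mark.parametrize(
        "statuses,expected",
        [([G, G], G), ([O, R], R), ([G, O], O), ([GRAY, G], GRAY), ([R], R)],
    )
    def test_worst_of(self, statuses, expected):
        assert combine_statuses(statuses) is expected

    def test_empty_rejected(self):
        with pytest.raises(InputValidationError):
            combine_statuses([])

    def test_worst_of_equals_bruteforce_max_severity(self):
        for n in (1, 2, 3, 4):
            for combo in itertools.product((G, O, R), repeat=n):
                expected = max(combo, key=lambda s: s.severity_rank)
                assert combine_statuses(list(combo)) is expected

    def test_any_gray_forces_gray(self):
        for n in (1, 2, 3):
            for combo in itertools.product((G, O, R, GRAY), repeat=n):
                if GRAY in combo:
                    assert combine_statuses(list(combo)) is GRAY

    def test_explicit_table_lookup(self):
        table = {
            combo: max(combo, key=lambda s: s.severity_rank)
            for combo in itertools.product((G, O, R), repeat=2)
        }
        rule = DecisionRuleSpec(kind="explicit_table", table=table)
        assert combine_statuses([O, G], rule) is O

    def test_explicit_table_missing_combo_is_config_error(self):
        table = {
            combo: G for combo in itertools.product((G, O, R), repeat=2)
        }
        rule = DecisionRuleSpec(kind="explicit_table", table=table)
        with pytest.raises(ConfigError, match="missing combination"):
            combine_statuses([G, G, G], rule)


# the printed combined blood-pressure decision column, one representative
# (systolic, diastolic) pair per band combination
BP_TABLE = [
    (135, 85, G),
    (135, 95, O),
    (135, 105, R),
    (150, 85, O),
    (150, 95, O),
    (150, 105, R),
    (165, 85, R),
    (165, 95, R),
    (165, 105, R),
]


class TestBloodPressure:
    @pytest.mark.parametrize("sys_v,dia_v,expected", BP_TABLE)
    def test_all_nine_combinations(self, config, sys_v, dia_v, expected):
        assert classify_blood_pressure(sys_v, dia_v, config) is expected

    def test_published_spot_checks(self, config):
        assert classify_blood_pressure(150, 95, config) is O
        assert classify_blood_pressure(135, 102, config) is R
        assert classify_blood_pressure(162, 85, config) is R

    def test_one_absent_value_is_gray(self, config):
        assert classify_blood_pressure(None, 85, config) is GRAY
        assert classify_blood_pressure(150, None, config) is GRAY

    def test_worst_of_equals_explicit_table(self, config):
        """The printed combination rule is exactly max-severity."""
        # build the explicit table from the 9 printed rows
        status_of = {135: G, 150: O, 165: R, 85: G, 95: O, 105: R}
        table = {
            (status_of[s], status_of[d]): expected for s, d, expected in BP_TABLE
        }
        rule = DecisionRuleSpec(kind="explicit_table", table=table)
        for s, d, expected in BP_TABLE:
            statuses = [
                classify_element("systolic", s, config),
                classify_element("diastolic", d, config),
            ]
            assert combine_statuses(statuses, rule) is expected
            assert combine_statuses(statuses) is expected  # worst_of agrees


class TestMentalHealth:
    @pytest.mark.parametrize("score,expected", [(50, R), (51, G), (0, R), (100, G)])
    def test_cutoff(self, config, score, expected):
        assert classify_mental_health(score, config) is expected

    def test_never_orange_full_enumeration(self, config):
        statuses = {classify_mental_health(s, config) for s in range(101)}
        assert statuses == {R, G}

    def test_absent_is_gray(self, config):
        assert classify_mental_health(None, config) is GRAY

    def test_out_of_range_rejected(self, config):
        with pytest.raises(InputValidationError):
            classify_mental_health(101, config)


MIXED_CLINICAL = {
    "systolic": 150,
    "diastolic": 95,
    "hba1c": 70,
    "fasting_glucose": 6.0,
    "glucose_2h": 8.0,
    "hdl": 1.1,
    "ldl": 2.0,
    "total_cholesterol": 4.0,
    "cholesterol_ratio": 3.5,
    "triglycerides": 1.0,
    "bmi": 31,
    "waist_circumference": 95,
    "waist_hip_ratio": 0.85,
    "egfr": 55,
    "albuminuria_stage": "A1",
}

MIXED_ITEMS = {
    # who5 deliberately absent -> mental_health GRAY
    "perceived_health": (3,),
    "pain": (4,),
    "pss": (2,) * 10,  # 6 regular x2 + 4 reversed x(4-2) = 20 -> orange
    "paid5": (4, 4, 4, 1, 0),  # 13 -> red
    "alcohol": (1, 5, 3, 2, 4),  # 23/7 ~ 3.29 orange, no binge
    "smoking": (20, 5),  # red, orange
    "eating": (0, 2, 1, 1, 1),  # fruit red; rest green/orange
    "squash_activity": (2, 50),  # 100 min -> orange
    "sedentary": (12.0, 10.0),  # 80/7 ~ 11.4 -> red
    "dsmq": (1, 1, 1, 3, 3, 3),  # monitoring 3 red, adherence 9 green
    "env_items": (0, 0, 2, 3, 4, 0, 1),
}

# hand-applied band + worst-of oracle for the fixture above
MIXED_EXPECTED = {
    "glucose_metabolism": R,
    "blood_pressure": O,
    "cholesterol": O,
    "weight": R,
    "kidney_function": O,
    "perceived_health": O,
    "pain": R,
    "mental_health": GRAY,
    "perceived_stress": O,
    "problems_with_diabetes": R,
    "alcohol_consumption": O,
    "smoking": R,
    "eating_pattern": R,
    "physical_activity": O,
    "sedentary_behavior": R,
    "diabetes_management": R,
    "family": G,
    "loneliness": O,
    "work": R,
    "income": R,
    "housing": G,
}


class TestBuildProfile:
    def test_all_healthy_fixture_is_all_green(self, config, healthy_assessment):
        profile = build_profile(healthy_assessment, config)
        assert len(profile.parameter_status) == 21
        assert set(profile.parameter_status.values()) == {G}

    def test_missing_who5_turns_only_mental_health_gray(self, config, healthy_assessment):
        items = {k: v for k, v in healthy_assessment.item_responses.items() if k != "who5"}
        assessment = healthy_assessment.model_copy(update={"item_responses": items})
        profile = build_profile(assessment, config)
        assert profile.parameter_status["mental_health"] is GRAY
        others = {p: s for p, s in profile.parameter_status.items() if p != "mental_health"}
        assert set(others.values()) == {G}
        assert "who5_score" not in profile.element_status

    def test_mixed_fixture_matches_hand_oracle(self, config):
        assessment = AssessmentInput(
            patient_id="mixed-1",
            timepoint="2024-03-01",
            clinical_values=MIXED_CLINICAL,
            item_responses=MIXED_ITEMS,
        )
        profile = build_profile(assessment, config)
        assert profile.parameter_status == MIXED_EXPECTED

    def test_every_parameter_gets_a_status(self, config):
        empty = AssessmentInput(patient_id="empty", timepoint="2024-01-01")
        profile = build_profile(empty, config)
        assert set(profile.parameter_status) == set(config.parameter_ids)
        assert set(profile.parameter_status.values()) == {GRAY}
        assert profile.element_status == {}

    def test_unknown_elements_listed_in_error(self, config):
        assessment = AssessmentInput(
            patient_id="bad",
            timepoint="2024-01-01",
            clinical_values={"systolic": 120, "bogus_a": 1, "bogus_b": 2},
        )
        with pytest.raises(InputValidationError) as exc_info:
            build_profile(assessment, config)
        message = str(exc_info.value)
        assert "bogus_a" in message and "bogus_b" in message

    def test_deterministic(self, config, healthy_assessment):
        p1 = build_profile(healthy_assessment, config)
        p2 = build_profile(healthy_assessment, config)
        assert p1 == p2
        assert p1.to_dict() == p2.to_dict()

    def test_profile_records_config_provenance(self, config, healthy_assessment):
        profile = build_profile(healthy_assessment, config)
        assert profile.config_id == config.config_id
        assert profile.config_version == config.schema_version


@given(
    st.lists(st.sampled_from([G, O, R]), min_size=1, max_size=6),
)
def test_worst_of_property_matches_max_severity(statuses):
    assert combine_statuses(statuses) is max(statuses, key=lambda s: s.severity_rank)
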