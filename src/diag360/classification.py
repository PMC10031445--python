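"""Cutoff-band classification and decision-rule combination.

Pipeline: score questionnaires -> band each element value -> combine element
statuses per parameter -> :class:`~diag360.core_model.DiagnosisProfile`.

Missing-data rule: an absent element value is GRAY, and any GRAY among a
parameter's required elements makes the parameter GRAY (no partial credit).
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

from .core_model import (
    AssessmentInput,
    ConfigError,
    DecisionRuleSpec,
    DiagnosisProfile,
    ElementDef,
    ElementStatus,
    InputValidationError,
    RuleConfig,
    TrafficStatus,
    load_reference_config,
)
from .instrument_scoring import UNAVAILABLE, score_instrument

Number = Union[int, float]


def classify_element(
    element: Union[str, ElementDef],
    value: Optional[Union[Number, str]],
    config: Optional[RuleConfig] = None,
) -> TrafficStatus:
    """Status of the unique cutoff band containing ``value``; GRAY if absent.

    Numeric bands are half-open, left-closed ``[lo, max)``.  A value outside
    the declared valid range is an input error; a value inside the range but
    covered by no band is a configuration error, never GRAY.
    """
    if isinstance(element, str):
        if config is None:
            config = load_reference_config()
        el = config.element(element)
    else:
        el = element
    if value is None:
        return TrafficStatus.GRAY
    if el.kind == "categorical":
        if value not in (el.valid_values or ()):
            raise InputValidationError(
                [f"{el.id}: {value!r} not in categories {list(el.valid_values or ())}"]
            )
        for band in el.bands:
            if band.categories and value in band.categories:
                return band.status
        raise ConfigError(f"{el.id}: no band covers category {value!r}")
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise InputValidationError([f"{el.id}: expected a number, got {value!r}"])
    lo, hi = el.range  # type: ignore[misc]
    if not lo <= value <= hi:
        raise InputValidationError([f"{el.id}: value {value} outside valid range [{lo}, {hi}]"])
    for band in el.bands:
        if band.max is None or value < band.max:
            return band.status
    raise ConfigError(f"{el.id}: no band covers value {value} (configuration gap)")


def combine_statuses(
    statuses: Sequence[TrafficStatus], rule: Optional[DecisionRuleSpec] = None
) -> TrafficStatus:
    """Combine element statuses into one parameter status.

    ``worst_of`` (the default) returns the maximum severity; if any required
    status is GRAY the result is GRAY.  ``explicit_table`` rules look the
    ranked tuple up, GRAY short-circuiting first.
    """
    if not statuses:
        raise InputValidationError(["combine_statuses: empty status list"])
    statuses = [TrafficStatus(s) for s in statuses]
    if any(s is TrafficStatus.GRAY for s in statuses):
        return TrafficStatus.GRAY
    rule = rule or DecisionRuleSpec()
    if rule.kind == "worst_of":
        return max(statuses, key=lambda s: s.severity_rank)
    assert rule.table is not None
    key = tuple(statuses)
    try:
        return rule.table[key]
    except KeyError:
        raise ConfigError(
            f"explicit_table missing combination {tuple(s.value for s in key)}"
        ) from None


def classify_blood_pressure(
    systolic: Optional[Number],
    diastolic: Optional[Number],
    config: Optional[RuleConfig] = None,
) -> TrafficStatus:
    """Combined blood-pressure status from the two element statuses.

    Equivalent to classifying each element and applying the parameter's
    decision rule; one absent value makes the result GRAY.
    """
    if config is None:
        config = load_reference_config()
    par = config.parameter("blood_pressure")
    sys_el, dia_el = (config.element(eid) for eid in par.element_ids)
    return combine_statuses(
        [classify_element(sys_el, systolic), classify_element(dia_el, diastolic)],
        par.rule,
    )


def classify_mental_health(
    who5_score: Optional[Number], config: Optional[RuleConfig] = None
) -> TrafficStatus:
    """Well-being classification: <=50 RED, >50 GREEN, absent GRAY.

    There is deliberately no ORANGE anywhere on the 0..100 scale.
    """
    if config is None:
        config = load_reference_config()
    par = config.parameter("mental_health")
    return classify_element(config.element(par.element_ids[0]), who5_score)


def element_values(
    assessment: AssessmentInput, config: RuleConfig
) -> dict[str, Union[Number, str]]:
    """Resolve all present element values: clinical inputs plus scored items."""
    values: dict[str, Union[Number, str]] = {}
    for eid, value in assessment.clinical_values.items():
        if value is not None:
            values[eid] = value
    for inst in config.instruments:
        responses = assessment.item_responses.get(inst.id)
        if responses is None:
            continue
        for eid, score in score_instrument(inst, responses).items():
            if score is not UNAVAILABLE:
                values[eid] = score
    return values


def build_profile(assessment: AssessmentInput, config: Optional[RuleConfig] = None) -> DiagnosisProfile:
    """Run the full diagnosis: scoring, banding, and rule combination.

    Every parameter of the config receives a status (GRAY when undetermined);
    element statuses are recorded only for elements whose inputs were present.
    Pure: identical (assessment, config) always yield an identical profile.
    """
    if config is None:
        config = load_reference_config()
    errors = assessment.validation_errors(config)
    if errors:
        raise InputValidationError(errors)
    values = element_values(assessment, config)
    element_status = {
        eid: ElementStatus(value=value, status=classify_element(config.element(eid), value))
        for eid, value in values.items()
    }
    parameter_status: dict[str, TrafficStatus] = {}
    for par in config.parameters:
        statuses = [
            element_status[eid].status if eid in element_status else TrafficStatus.GRAY
            for eid in par.element_ids
        ]
        if not statuses:
            parameter_status[par.id] = TrafficStatus.GRAY
            continue
        parameter_status[par.id] = combine_statuses(statuses, par.rule)
    return DiagnosisProfile(
        patient_id=assessment.patient_id,
        timepoint=assessment.timepoint,
        config_id=config.config_id,
        config_version=config.schema_version,
        element_status=element_status,
        parameter_status=parameter_status,
    )
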