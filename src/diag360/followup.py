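"""Two-timepoint comparison of diagnosis profiles (baseline vs follow-up)."""

from __future__ import annotations

import enum
from typing import Any

from .core_model import DiagnosisProfile, InputValidationError, TrafficStatus, _Frozen


class Transition(str, enum.Enum):
    IMPROVED = "improved"
    WORSENED = "worsened"
    UNCHANGED = "unchanged"
    NEWLY_MEASURED = "newly_measured"
    NO_LONGER_MEASURED = "no_longer_measured"
    STILL_UNMEASURED = "still_unmeasured"


class TransitionReport(_Frozen):
    patient_id: str
    timepoint_baseline: str
    timepoint_followup: str
    config_id: str
    transitions: dict[str, Transition]

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema_id": "diag360.transitions",
            "schema_version": 1,
            "patient_id": self.patient_id,
            "timepoint_baseline": self.timepoint_baseline,
            "timepoint_followup": self.timepoint_followup,
            "config_id": self.config_id,
            "transitions": {k: v.value for k, v in self.transitions.items()},
        }


def _transition(s0: TrafficStatus, s1: TrafficStatus) -> Transition:
    if s0 is TrafficStatus.GRAY and s1 is TrafficStatus.GRAY:
        return Transition.STILL_UNMEASURED
    if s0 is TrafficStatus.GRAY:
        return Transition.NEWLY_MEASURED
    if s1 is TrafficStatus.GRAY:
        return Transition.NO_LONGER_MEASURED
    if s1.severity_rank < s0.severity_rank:
        return Transition.IMPROVED
    if s1.severity_rank > s0.severity_rank:
        return Transition.WORSENED
    return Transition.UNCHANGED


def compare_profiles(baseline: DiagnosisProfile, followup: DiagnosisProfile) -> TransitionReport:
    """Per-parameter status transitions between two profiles of one patient.

    Both profiles must come from the same patient and the same config version;
    otherwise statuses are not comparable and an error is raised.  Improvement
    means severity decreased; GRAY transitions are reported as newly / no
    longer / still unmeasured.  No minimum time interval is enforced.
    """
    errors = []
    if baseline.patient_id != followup.patient_id:
        errors.append(
            f"patient mismatch: '{baseline.patient_id}' vs '{followup.patient_id}'"
        )
    if (baseline.config_id, baseline.config_version) != (
        followup.config_id,
        followup.config_version,
    ):
        errors.append(
            "config mismatch: "
            f"'{baseline.config_id}' v{baseline.config_version} vs "
            f"'{followup.config_id}' v{followup.config_version} (statuses not comparable)"
        )
    if set(baseline.parameter_status) != set(followup.parameter_status):
        errors.append("profiles cover different parameter sets")
    if errors:
        raise InputValidationError(errors)
    transitions = {
        pid: _transition(baseline.parameter_status[pid], followup.parameter_status[pid])
        for pid in baseline.parameter_status
    }
    return TransitionReport(
        patient_id=baseline.patient_id,
        timepoint_baseline=baseline.timepoint,
        timepoint_followup=followup.timepoint,
        config_id=baseline.config_id,
        transitions=transitions,
    )
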