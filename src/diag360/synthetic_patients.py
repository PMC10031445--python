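"""Seeded synthetic patient generation with exact status control.

Patients are generated by *inverse sampling*: for every parameter a target
traffic-light status is drawn from a prevalence spec, then element values and
questionnaire item responses are sampled so that classification recovers the
drawn status exactly (with zero missingness).  This is a testing device, not
an epidemiological simulator: no realistic correlation structure is implied.

Reproducibility: each patient uses an independent seeded stream derived from
``(seed, patient_index)``, so changing ``n_patients`` never changes earlier
patients' records.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence, Union

import numpy as np
import yaml
from pydantic import Field, field_validator

from .classification import classify_element
from .core_model import (
    AssessmentInput,
    Diag360Error,
    ElementDef,
    InstrumentDef,
    RuleConfig,
    TrafficStatus,
    _Frozen,
)
from .instrument_scoring import score_alcohol

RANKED = (TrafficStatus.GREEN, TrafficStatus.ORANGE, TrafficStatus.RED)


class SimulationError(Diag360Error):
    """A simulation spec requests something the config's bands cannot produce."""


class Prevalence(_Frozen):
    green: float = Field(ge=0, le=1)
    orange: float = Field(ge=0, le=1)
    red: float = Field(ge=0, le=1)

    @field_validator("red")
    @classmethod
    def _sums_to_one(cls, v, info):
        total = v + info.data.get("green", 0) + info.data.get("orange", 0)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"prevalences must sum to 1 (got {total})")
        return v

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.green, self.orange, self.red)


class SimulationSpec(_Frozen):
    """Controls for :func:`generate_patients`.

    ``prevalence`` overrides the per-parameter status distribution; the
    default distribution is renormalized over the statuses a parameter can
    actually reach (e.g. a parameter with no orange band).  Explicit overrides
    putting positive mass on an unreachable status are an error.
    """

    n_patients: int = Field(gt=0)
    seed: int = 0
    timepoint: str = "2024-01-01"
    patient_prefix: str = "sim"
    default_prevalence: Prevalence = Prevalence(green=0.6, orange=0.25, red=0.15)
    prevalence: dict[str, Prevalence] = Field(default_factory=dict)
    default_missing_rate: float = Field(default=0.0, ge=0, le=1)
    missing_rate: dict[str, float] = Field(default_factory=dict)

    @field_validator("missing_rate")
    @classmethod
    def _rates_in_unit(cls, v):
        for key, rate in v.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"missing_rate.{key}: {rate} outside [0, 1]")
        return v

    def missing_for(self, key: str) -> float:
        return self.missing_rate.get(key, self.default_missing_rate)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationSpec":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)


def _reachable_statuses(elements: Sequence[ElementDef]) -> set[TrafficStatus]:
    """Parameter statuses producible by the all-take-target sampling scheme."""
    reachable = set()
    for status in RANKED:
        has_target = any(status in el.statuses_reachable() for el in elements)
        others_ok = all(
            status in el.statuses_reachable() or TrafficStatus.GREEN in el.statuses_reachable()
            for el in elements
        )
        if has_target and others_ok:
            reachable.add(status)
    return reachable


def validate_spec(spec: SimulationSpec, config: RuleConfig) -> None:
    """Raise :class:`SimulationError` if the spec asks for unreachable statuses."""
    errors = []
    for pid in spec.prevalence:
        if pid not in {p.id for p in config.parameters}:
            errors.append(f"prevalence.{pid}: unknown parameter")
    for key in spec.missing_rate:
        known = {i.id for i in config.instruments} | set(config.clinical_element_ids)
        if key not in known:
            errors.append(f"missing_rate.{key}: unknown instrument/element")
    for par in config.parameters:
        elements = [config.element(eid) for eid in par.element_ids]
        reachable = _reachable_statuses(elements)
        override = spec.prevalence.get(par.id)
        if override is not None:
            for status, p in zip(RANKED, override.as_tuple()):
                if p > 0 and status not in reachable:
                    errors.append(
                        f"prevalence.{par.id}: status '{status.value}' is unreachable "
                        f"under the config's cutoff bands"
                    )
        elif not reachable:
            errors.append(f"parameter '{par.id}': no status reachable (config defect)")
    if errors:
        raise SimulationError("; ".join(errors))


def _prevalence_for(spec: SimulationSpec, par_id: str, reachable: set[TrafficStatus]) -> np.ndarray:
    override = spec.prevalence.get(par_id)
    probs = np.array((override or spec.default_prevalence).as_tuple(), dtype=float)
    if override is None:
        # default distribution: drop unreachable statuses and renormalize
        mask = np.array([s in reachable for s in RANKED], dtype=float)
        probs = probs * mask
        probs = probs / probs.sum()
    return probs


def _target_interval(el: ElementDef, status: TrafficStatus) -> tuple[float, float]:
    """``[lo, hi)`` of the first band with ``status`` (hi capped at range top)."""
    for i, band in enumerate(el.bands):
        if band.status is status:
            lo, hi = el.band_interval(i)
            if hi is None:
                hi = el.range[1] + 1e-9  # type: ignore[index]
            else:
                hi = min(hi, el.range[1] + 1e-9)  # type: ignore[index]
            return lo, hi
    raise SimulationError(f"element '{el.id}' has no '{status.value}' band")


def _target_categories(el: ElementDef, status: TrafficStatus) -> tuple[str, ...]:
    for band in el.bands:
        if band.status is status and band.categories:
            return band.categories
    raise SimulationError(f"element '{el.id}' has no '{status.value}' band")


def _element_target(el: ElementDef, parameter_status: TrafficStatus) -> TrafficStatus:
    """Band status this element should land in for the parameter target.

    The element takes the target status when it has such a band, otherwise
    green; with the worst-of rule the parameter then scores exactly the target.
    """
    if parameter_status in el.statuses_reachable():
        return parameter_status
    if TrafficStatus.GREEN in el.statuses_reachable():
        return TrafficStatus.GREEN
    raise SimulationError(
        f"element '{el.id}' can reach neither '{parameter_status.value}' nor green"
    )


def _ints_in(lo: float, hi: float, scale_lo: float, scale_hi: float) -> list[int]:
    """Integers in ``[lo, hi) ∩ [scale_lo, scale_hi]``."""
    start = max(math.ceil(lo), math.ceil(scale_lo))
    stop = min(math.ceil(hi) - 1, math.floor(scale_hi))
    return list(range(start, stop + 1))


def _pick(rng: np.random.Generator, options: Sequence, what: str):
    if not options:
        raise SimulationError(f"no feasible responses for {what}")
    return options[int(rng.integers(len(options)))]


def _compose_sum(
    rng: np.random.Generator, total: int, n: int, item_max: int, item_min: int = 0
) -> list[int]:
    """Random composition of ``total`` into ``n`` parts each in [item_min, item_max]."""
    if not n * item_min <= total <= n * item_max:
        raise SimulationError(f"sum {total} not composable into {n} items")
    parts = []
    remaining = total
    for i in range(n):
        rest = n - i - 1
        lo = max(item_min, remaining - rest * item_max)
        hi = min(item_max, remaining - rest * item_min)
        part = int(rng.integers(lo, hi + 1))
        parts.append(part)
        remaining -= part
    return parts


def _sample_clinical(
    rng: np.random.Generator, el: ElementDef, status: TrafficStatus
) -> Union[float, str]:
    if el.kind == "categorical":
        return str(_pick(rng, _target_categories(el, status), el.id))
    lo, hi = _target_interval(el, status)
    hi = min(hi, el.range[1])  # type: ignore[index]
    value = float(rng.uniform(lo, hi)) if hi > lo else lo
    rounded = math.floor(value * 100) / 100.0
    # keep two decimals unless rounding would cross the band's lower edge
    return rounded if rounded >= lo else value


# ---------------------------------------------------------------------------
# per-scoring-procedure inverse samplers


def _inv_identity(rng, inst, targets, config):
    responses = []
    for i, eid in enumerate(inst.output_element_ids):
        el = config.element(eid)
        lo, hi = _target_interval(el, targets[eid])
        slo, shi = inst.item_scales[i]
        responses.append(_pick(rng, _ints_in(lo, hi, slo, shi), f"{inst.id}.{eid}"))
    return responses


def _inv_who5(rng, inst, targets, config):
    el = config.element(inst.output_element_ids[0])
    lo, hi = _target_interval(el, targets[el.id])
    item_hi = int(inst.item_scales[0][1])
    max_sum = inst.n_items * item_hi
    sums = [s for s in range(max_sum + 1) if lo <= 4 * s < hi]
    total = _pick(rng, sums, f"{inst.id} target sum")
    return _compose_sum(rng, total, inst.n_items, item_hi)


def _inv_plain_sum(rng, inst, targets, config):
    el = config.element(inst.output_element_ids[0])
    lo, hi = _target_interval(el, targets[el.id])
    item_hi = int(inst.item_scales[0][1])
    totals = _ints_in(lo, hi, 0, inst.n_items * item_hi)
    total = _pick(rng, totals, f"{inst.id} target sum")
    return _compose_sum(rng, total, inst.n_items, item_hi)


def _inv_reverse_sum(rng, inst, targets, config):
    scored = _inv_plain_sum(rng, inst, targets, config)
    reverse = set(inst.scoring_params.get("reverse_items", ()))
    raw = []
    for i, value in enumerate(scored):
        lo, hi = inst.item_scales[i]
        raw.append(int(hi + lo - value) if i in reverse else value)
    return raw


def _inv_smoking(rng, inst, targets, config):
    return _inv_identity(rng, inst, targets, config)


def _inv_dsmq(rng, inst, targets, config):
    half = inst.n_items // 2
    item_hi = int(inst.item_scales[0][1])
    responses = []
    for eid, n in zip(inst.output_element_ids, (half, inst.n_items - half)):
        el = config.element(eid)
        lo, hi = _target_interval(el, targets[eid])
        total = _pick(rng, _ints_in(lo, hi, 0, n * item_hi), f"{inst.id}.{eid}")
        responses.extend(_compose_sum(rng, total, n, item_hi))
    return responses


def _inv_sitting(rng, inst, targets, config):
    el = config.element(inst.output_element_ids[0])
    lo, hi = _target_interval(el, targets[el.id])
    slo, shi = inst.item_scales[0]
    hours = _pick(rng, _ints_in(lo, hi, slo, shi), f"{inst.id} hours")
    # same hours on weekdays and weekend days -> weekly average equals hours
    return [float(hours), float(hours)]


_ENUM_CACHE: dict = {}


def _alcohol_partition(inst: InstrumentDef, config: RuleConfig):
    """Enumerate the whole response space, bucketed by (avg, binge) statuses."""
    key = ("alcohol", config.config_id, inst.id)
    if key not in _ENUM_CACHE:
        avg_el = config.element(inst.output_element_ids[0])
        binge_el = config.element(inst.output_element_ids[1])
        threshold = inst.scoring_params.get("binge_threshold", 6)
        buckets: dict = {}
        candidates = [[0, 0, 0, 0, 0]]
        scales = [inst.item_scales[i] for i in range(1, 5)]
        for wd_d in range(int(scales[0][0]), int(scales[0][1]) + 1):
            for wd_g in range(int(scales[1][0]), int(scales[1][1]) + 1):
                for we_d in range(int(scales[2][0]), int(scales[2][1]) + 1):
                    for we_g in range(int(scales[3][0]), int(scales[3][1]) + 1):
                        candidates.append([1, wd_d, wd_g, we_d, we_g])
        for resp in candidates:
            avg, binge = score_alcohol(resp, binge_threshold=threshold)
            bucket_key = (
                classify_element(avg_el, avg),
                classify_element(binge_el, binge),
            )
            buckets.setdefault(bucket_key, []).append(resp)
        _ENUM_CACHE[key] = buckets
    return _ENUM_CACHE[key]


def _inv_alcohol(rng, inst, targets, config):
    buckets = _alcohol_partition(inst, config)
    key = (targets[inst.output_element_ids[0]], targets[inst.output_element_ids[1]])
    options = buckets.get(key, [])
    return list(_pick(rng, options, f"{inst.id} statuses {tuple(s.value for s in key)}"))


def _activity_partition(inst: InstrumentDef, config: RuleConfig):
    key = ("activity", config.config_id, inst.id)
    if key not in _ENUM_CACHE:
        el = config.element(inst.output_element_ids[0])
        buckets: dict = {}
        d_lo, d_hi = (int(x) for x in inst.item_scales[0])
        m_lo, m_hi = (int(x) for x in inst.item_scales[1])
        for days in range(d_lo, d_hi + 1):
            for minutes in range(m_lo, m_hi + 1, 5):
                status = classify_element(el, days * minutes)
                buckets.setdefault(status, []).append([days, minutes])
        _ENUM_CACHE[key] = buckets
    return _ENUM_CACHE[key]


def _inv_activity(rng, inst, targets, config):
    buckets = _activity_partition(inst, config)
    target = targets[inst.output_element_ids[0]]
    return list(_pick(rng, buckets.get(target, []), f"{inst.id} status {target.value}"))


_INVERSE_SAMPLERS = {
    "identity": _inv_identity,
    "who5": _inv_who5,
    "plain_sum": _inv_plain_sum,
    "reverse_sum": _inv_reverse_sum,
    "smoking": _inv_smoking,
    "dsmq_subscales": _inv_dsmq,
    "sitting_weekly": _inv_sitting,
    "alcohol_fq": _inv_alcohol,
    "activity_product": _inv_activity,
}


# ---------------------------------------------------------------------------


def generate_patients_with_targets(
    spec: SimulationSpec, config: Optional[RuleConfig] = None
) -> list[tuple[AssessmentInput, dict[str, TrafficStatus]]]:
    """Generate assessments together with each patient's drawn target statuses.

    With zero missingness, :func:`~diag360.classification.build_profile`
    recovers the targets exactly (the module's core correctness property).
    """
    if config is None:
        from .core_model import load_reference_config

        config = load_reference_config()
    validate_spec(spec, config)
    width = max(4, len(str(spec.n_patients)))
    out = []
    for index in range(spec.n_patients):
        rng = np.random.default_rng([spec.seed, index])
        targets: dict[str, TrafficStatus] = {}
        element_targets: dict[str, TrafficStatus] = {}
        for par in config.parameters:
            elements = [config.element(eid) for eid in par.element_ids]
            reachable = _reachable_statuses(elements)
            probs = _prevalence_for(spec, par.id, reachable)
            status = RANKED[int(rng.choice(3, p=probs))]
            targets[par.id] = status
            for el in elements:
                element_targets[el.id] = _element_target(el, status)
        clinical_values: dict[str, Union[float, str, None]] = {}
        for eid in config.clinical_element_ids:
            el = config.element(eid)
            clinical_values[eid] = _sample_clinical(rng, el, element_targets[eid])
        item_responses: dict[str, list] = {}
        for inst in config.instruments:
            sampler = _INVERSE_SAMPLERS[inst.scoring]
            inst_targets = {eid: element_targets[eid] for eid in inst.output_element_ids}
            item_responses[inst.id] = [
                float(x) if isinstance(x, float) else int(x)
                for x in sampler(rng, inst, inst_targets, config)
            ]
        # missingness: independent draws per clinical element, then per instrument
        for eid in config.clinical_element_ids:
            if rng.random() < spec.missing_for(eid):
                del clinical_values[eid]
        for inst in config.instruments:
            if rng.random() < spec.missing_for(inst.id):
                del item_responses[inst.id]
        assessment = AssessmentInput(
            patient_id=f"{spec.patient_prefix}-{index + 1:0{width}d}",
            timepoint=spec.timepoint,
            clinical_values=clinical_values,
            item_responses={k: tuple(v) for k, v in item_responses.items()},
        )
        out.append((assessment, targets))
    return out


def generate_patients(
    spec: SimulationSpec, config: Optional[RuleConfig] = None
) -> list[AssessmentInput]:
    """Seeded synthetic assessments (see :func:`generate_patients_with_targets`)."""
    return [assessment for assessment, _ in generate_patients_with_targets(spec, config)]
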