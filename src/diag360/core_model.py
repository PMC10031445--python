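"""Core data model: domains, parameters, elements, statuses, and records.

The engine is fully configuration-driven.  A :class:`RuleConfig` declares the
domain → parameter → element hierarchy together with cutoff bands, decision
rules, and questionnaire (instrument) definitions; every other module operates
on that declaration rather than on hard-coded clinical knowledge.
"""

from __future__ import annotations

import enum
from importlib import resources
from typing import Any, Literal, Optional, Sequence, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

SCHEMA_CONFIG = "diag360.rule_config"
SCHEMA_ASSESSMENT = "diag360.assessment"
SCHEMA_PROFILE = "diag360.profile"
SCHEMA_VERSION = 1

#: Hard ceiling on parameters per domain (visual comprehensibility constraint).
MAX_PARAMETERS_PER_DOMAIN = 6


class Diag360Error(Exception):
    """Base class for all package errors."""


class ConfigError(Diag360Error):
    """Raised when a rule configuration is structurally invalid."""


class InputValidationError(Diag360Error):
    """Raised when an input record violates its schema or the active config.

    Carries the complete list of violations, not just the first one.
    """

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class TrafficStatus(str, enum.Enum):
    """Traffic-light status of an element or parameter.

    GREEN/ORANGE/RED form a totally ordered severity scale; GRAY marks an
    undetermined score (unanswered questions / missing measurements) and never
    participates in severity comparison.
    """

    GREEN = "green"
    ORANGE = "orange"
    RED = "red"
    GRAY = "gray"

    @property
    def severity_rank(self) -> int:
        if self is TrafficStatus.GRAY:
            raise ValueError("GRAY has no severity rank")
        return _SEVERITY[self]

    @property
    def is_ranked(self) -> bool:
        return self is not TrafficStatus.GRAY

    @property
    def needs_improvement(self) -> bool:
        """Middle- and low-ranking scores identify areas of improvement."""
        return self in (TrafficStatus.ORANGE, TrafficStatus.RED)


_SEVERITY = {TrafficStatus.GREEN: 0, TrafficStatus.ORANGE: 1, TrafficStatus.RED: 2}

RANKED_STATUSES = (TrafficStatus.GREEN, TrafficStatus.ORANGE, TrafficStatus.RED)


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class CutoffBand(_Frozen):
    """One band of a cutoff set.

    Numeric bands are half-open, left-closed intervals ``[lo, max)`` where
    ``lo`` is the previous band's ``max`` (or the element's range minimum) and
    ``max: None`` means unbounded above.  Categorical bands list the category
    labels mapped to the status.
    """

    status: TrafficStatus
    max: Optional[float] = None
    categories: Optional[tuple[str, ...]] = None

    @field_validator("status")
    @classmethod
    def _ranked_only(cls, v: TrafficStatus) -> TrafficStatus:
        if not v.is_ranked:
            raise ValueError("cutoff bands carry ranked statuses only")
        return v


class ElementDef(_Frozen):
    """A measurable component of a parameter (e.g. systolic blood pressure)."""

    id: str
    parameter_id: str
    label: str
    lay_label: Optional[str] = None
    kind: Literal["numeric", "categorical", "derived-score"]
    units: Optional[str] = None
    range: Optional[tuple[float, float]] = None
    valid_values: Optional[tuple[str, ...]] = None
    bands: tuple[CutoffBand, ...]

    @model_validator(mode="after")
    def _check(self) -> "ElementDef":
        if self.kind == "categorical":
            if not self.valid_values:
                raise ValueError(f"element '{self.id}': categorical element needs valid_values")
            covered: list[str] = []
            for band in self.bands:
                if band.categories is None:
                    raise ValueError(f"element '{self.id}': categorical band without categories")
                covered.extend(band.categories)
            if sorted(covered) != sorted(self.valid_values) or len(covered) != len(set(covered)):
                raise ValueError(
                    f"element '{self.id}': bands must cover valid_values exactly once "
                    f"(bands cover {sorted(covered)}, declared {sorted(self.valid_values)})"
                )
        else:
            if self.range is None:
                raise ValueError(f"element '{self.id}': numeric element needs a range")
            lo, hi = self.range
            if not lo < hi:
                raise ValueError(f"element '{self.id}': range must satisfy lo < hi")
            prev = lo
            for i, band in enumerate(self.bands):
                if band.categories is not None:
                    raise ValueError(f"element '{self.id}': numeric band with categories")
                if band.max is None:
                    if i != len(self.bands) - 1:
                        raise ValueError(f"element '{self.id}': open band must be last")
                else:
                    if band.max <= prev:
                        raise ValueError(
                            f"element '{self.id}': band maxima must be strictly increasing"
                        )
                    prev = band.max
            last = self.bands[-1]
            if last.max is not None and last.max <= hi:
                raise ValueError(
                    f"element '{self.id}': bands do not cover the declared range "
                    f"(last band ends at {last.max}, range ends at {hi})"
                )
        if not self.bands:
            raise ValueError(f"element '{self.id}': at least one band required")
        return self

    @property
    def display_label(self) -> str:
        return self.lay_label or self.label

    def band_interval(self, index: int) -> tuple[float, Optional[float]]:
        """``[lo, hi)`` interval of the numeric band at ``index``."""
        assert self.range is not None
        lo = self.range[0] if index == 0 else self.bands[index - 1].max
        assert lo is not None
        return lo, self.bands[index].max

    def statuses_reachable(self) -> set[TrafficStatus]:
        return {band.status for band in self.bands}


class DecisionRuleSpec(_Frozen):
    """How a parameter combines its elements' statuses.

    ``worst_of`` takes the maximum severity; ``explicit_table`` looks the
    status tuple up in a table that must cover every ranked combination.
    """

    kind: Literal["worst_of", "explicit_table"] = "worst_of"
    table: Optional[dict[tuple[TrafficStatus, ...], TrafficStatus]] = None

    @model_validator(mode="after")
    def _check(self) -> "DecisionRuleSpec":
        if self.kind == "explicit_table" and not self.table:
            raise ValueError("explicit_table rule requires a table")
        if self.kind == "worst_of" and self.table is not None:
            raise ValueError("worst_of rule must not carry a table")
        return self


class ParameterDef(_Frozen):
    """A changeable diagnostic factor shown as one icon in the wheel."""

    id: str
    domain_id: str
    label: str
    lay_label: Optional[str] = None
    icon_id: str
    element_ids: tuple[str, ...]
    rule: DecisionRuleSpec = DecisionRuleSpec()

    @property
    def display_label(self) -> str:
        return self.lay_label or self.label


class DomainDef(_Frozen):
    id: str
    label: str
    lay_label: Optional[str] = None
    parameter_ids: tuple[str, ...]

    @property
    def display_label(self) -> str:
        return self.lay_label or self.label


class InstrumentDef(_Frozen):
    """A questionnaire (or question block) producing element-level scores."""

    id: str
    label: str
    n_items: int
    item_scales: tuple[tuple[float, float], ...]
    integer_items: bool = True
    scoring: str
    scoring_params: dict[str, Any] = Field(default_factory=dict)
    output_element_ids: tuple[str, ...]

    model_config = ConfigDict(frozen=False, extra="forbid")

    @model_validator(mode="after")
    def _check(self) -> "InstrumentDef":
        if len(self.item_scales) != self.n_items:
            raise ValueError(f"instrument '{self.id}': item_scales length != n_items")
        for lo, hi in self.item_scales:
            if not lo < hi:
                raise ValueError(f"instrument '{self.id}': bad item scale ({lo}, {hi})")
        return self


class RuleConfig(_Frozen):
    """Validated, immutable rule configuration driving the whole engine."""

    config_id: str
    schema_version: int = SCHEMA_VERSION
    domains: tuple[DomainDef, ...]
    parameters: tuple[ParameterDef, ...]
    elements: tuple[ElementDef, ...]
    instruments: tuple[InstrumentDef, ...]

    @model_validator(mode="after")
    def _check(self) -> "RuleConfig":
        dom_ids = [d.id for d in self.domains]
        par_ids = [p.id for p in self.parameters]
        el_ids = [e.id for e in self.elements]
        for name, ids in (("domain", dom_ids), ("parameter", par_ids), ("element", el_ids)):
            dupes = {i for i in ids if ids.count(i) > 1}
            if dupes:
                raise ValueError(f"duplicate {name} ids: {sorted(dupes)}")
        par_by_id = {p.id: p for p in self.parameters}
        el_by_id = {e.id: e for e in self.elements}
        for dom in self.domains:
            if not 1 <= len(dom.parameter_ids) <= MAX_PARAMETERS_PER_DOMAIN:
                raise ValueError(
                    f"domain '{dom.id}' has {len(dom.parameter_ids)} parameters; "
                    f"allowed 1..{MAX_PARAMETERS_PER_DOMAIN}"
                )
            for pid in dom.parameter_ids:
                if pid not in par_by_id:
                    raise ValueError(f"domain '{dom.id}' references unknown parameter '{pid}'")
                if par_by_id[pid].domain_id != dom.id:
                    raise ValueError(f"parameter '{pid}' domain mismatch with domain '{dom.id}'")
        claimed = [pid for d in self.domains for pid in d.parameter_ids]
        for pid in par_ids:
            if claimed.count(pid) != 1:
                raise ValueError(f"parameter '{pid}' must belong to exactly one domain")
        for par in self.parameters:
            for eid in par.element_ids:
                if eid not in el_by_id:
                    raise ValueError(f"parameter '{par.id}' references unknown element '{eid}'")
                if el_by_id[eid].parameter_id != par.id:
                    raise ValueError(f"element '{eid}' parameter mismatch with '{par.id}'")
            if par.rule.kind == "explicit_table":
                n = len(par.element_ids)
                expected = 3**n
                table = par.rule.table or {}
                if len(table) != expected or any(len(k) != n for k in table):
                    raise ValueError(
                        f"parameter '{par.id}': explicit_table must cover all {expected} "
                        f"ranked status combinations of its {n} elements"
                    )
        for el in self.elements:
            if el.parameter_id not in par_by_id:
                raise ValueError(f"element '{el.id}' references unknown parameter '{el.parameter_id}'")
            if el.id not in par_by_id[el.parameter_id].element_ids:
                raise ValueError(f"element '{el.id}' missing from its parameter's element list")
        scored: list[str] = []
        for inst in self.instruments:
            for eid in inst.output_element_ids:
                if eid not in el_by_id:
                    raise ValueError(f"instrument '{inst.id}' outputs unknown element '{eid}'")
                scored.append(eid)
        dupes = {e for e in scored if scored.count(e) > 1}
        if dupes:
            raise ValueError(f"elements scored by more than one instrument: {sorted(dupes)}")
        return self

    # -- lookups ---------------------------------------------------------

    def domain(self, domain_id: str) -> DomainDef:
        return self._index("domains")[domain_id]

    def parameter(self, parameter_id: str) -> ParameterDef:
        try:
            return self._index("parameters")[parameter_id]
        except KeyError:
            raise KeyError(f"unknown parameter '{parameter_id}'") from None

    def element(self, element_id: str) -> ElementDef:
        try:
            return self._index("elements")[element_id]
        except KeyError:
            raise KeyError(f"unknown element '{element_id}'") from None

    def instrument(self, instrument_id: str) -> InstrumentDef:
        try:
            return self._index("instruments")[instrument_id]
        except KeyError:
            raise KeyError(f"unknown instrument '{instrument_id}'") from None

    def _index(self, attr: str) -> dict[str, Any]:
        cache = object.__getattribute__(self, "__dict__").setdefault("_idx", {})
        if attr not in cache:
            cache[attr] = {item.id: item for item in getattr(self, attr)}
        return cache[attr]

    @property
    def parameter_ids(self) -> tuple[str, ...]:
        return tuple(p.id for p in self.parameters)

    def instrument_for_element(self, element_id: str) -> Optional[InstrumentDef]:
        for inst in self.instruments:
            if element_id in inst.output_element_ids:
                return inst
        return None

    @property
    def clinical_element_ids(self) -> tuple[str, ...]:
        """Elements entered directly as measurements (not scored from items)."""
        scored = {e for i in self.instruments for e in i.output_element_ids}
        return tuple(e.id for e in self.elements if e.id not in scored)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        """Nested, canonical plain-dict form (inverse of :func:`parse_config`)."""
        doc: dict[str, Any] = {
            "schema_id": SCHEMA_CONFIG,
            "schema_version": self.schema_version,
            "config_id": self.config_id,
            "domains": [],
            "instruments": [],
        }
        for dom in self.domains:
            dom_doc: dict[str, Any] = {"id": dom.id, "label": dom.label, "parameters": []}
            if dom.lay_label:
                dom_doc["lay_label"] = dom.lay_label
            for pid in dom.parameter_ids:
                par = self.parameter(pid)
                par_doc: dict[str, Any] = {
                    "id": par.id,
                    "label": par.label,
                    "icon": par.icon_id,
                    "elements": [],
                }
                if par.lay_label:
                    par_doc["lay_label"] = par.lay_label
                if par.rule.kind != "worst_of":
                    par_doc["rule"] = par.rule.kind
                    par_doc["table"] = {
                        ",".join(s.value for s in k): v.value
                        for k, v in (par.rule.table or {}).items()
                    }
                for eid in par.element_ids:
                    el = self.element(eid)
                    el_doc: dict[str, Any] = {"id": el.id, "label": el.label, "kind": el.kind}
                    if el.lay_label:
                        el_doc["lay_label"] = el.lay_label
                    if el.units:
                        el_doc["units"] = el.units
                    if el.range:
                        el_doc["range"] = list(el.range)
                    if el.valid_values:
                        el_doc["valid_values"] = list(el.valid_values)
                    el_doc["bands"] = []
                    for band in el.bands:
                        band_doc: dict[str, Any] = {"status": band.status.value}
                        if band.max is not None:
                            band_doc["max"] = band.max
                        if band.categories is not None:
                            band_doc["categories"] = list(band.categories)
                        el_doc["bands"].append(band_doc)
                    par_doc["elements"].append(el_doc)
                dom_doc["parameters"].append(par_doc)
            doc["domains"].append(dom_doc)
        for inst in self.instruments:
            inst_doc: dict[str, Any] = {
                "id": inst.id,
                "label": inst.label,
                "n_items": inst.n_items,
                "item_scales": [list(s) for s in inst.item_scales],
                "scoring": inst.scoring,
                "outputs": list(inst.output_element_ids),
            }
            if not inst.integer_items:
                inst_doc["integer_items"] = False
            if inst.scoring_params:
                inst_doc["scoring_params"] = inst.scoring_params
            doc["instruments"].append(inst_doc)
        return doc


def _parse_table(raw: dict[str, str], key: str) -> dict[tuple[TrafficStatus, ...], TrafficStatus]:
    table = {}
    for combo, out in raw.items():
        parts = tuple(TrafficStatus(s.strip()) for s in combo.split(","))
        table[parts] = TrafficStatus(out)
    return table


def parse_config(doc: dict[str, Any]) -> RuleConfig:
    """Parse the nested plain-dict form into a validated :class:`RuleConfig`.

    Raises :class:`ConfigError` naming the offending key on any violation.
    """
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")
    schema_id = doc.get("schema_id")
    if schema_id != SCHEMA_CONFIG:
        raise ConfigError(f"schema_id: expected '{SCHEMA_CONFIG}', got {schema_id!r}")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ConfigError(f"schema_version: unknown version {version!r}; documents are never coerced")
    try:
        domains, parameters, elements = [], [], []
        for dom_doc in doc.get("domains", []):
            pids = []
            for par_doc in dom_doc.get("parameters", []):
                eids = []
                for el_doc in par_doc.get("elements", []):
                    bands = tuple(
                        CutoffBand(
                            status=TrafficStatus(b["status"]),
                            max=b.get("max"),
                            categories=tuple(b["categories"]) if "categories" in b else None,
                        )
                        for b in el_doc.get("bands", [])
                    )
                    elements.append(
                        ElementDef(
                            id=el_doc["id"],
                            parameter_id=par_doc["id"],
                            label=el_doc["label"],
                            lay_label=el_doc.get("lay_label"),
                            kind=el_doc["kind"],
                            units=el_doc.get("units"),
                            range=tuple(el_doc["range"]) if "range" in el_doc else None,
                            valid_values=(
                                tuple(el_doc["valid_values"]) if "valid_values" in el_doc else None
                            ),
                            bands=bands,
                        )
                    )
                    eids.append(el_doc["id"])
                rule_kind = par_doc.get("rule", "worst_of")
                rule = DecisionRuleSpec(
                    kind=rule_kind,
                    table=_parse_table(par_doc["table"], par_doc["id"])
                    if rule_kind == "explicit_table"
                    else None,
                )
                parameters.append(
                    ParameterDef(
                        id=par_doc["id"],
                        domain_id=dom_doc["id"],
                        label=par_doc["label"],
                        lay_label=par_doc.get("lay_label"),
                        icon_id=par_doc.get("icon", par_doc["id"]),
                        element_ids=tuple(eids),
                        rule=rule,
                    )
                )
                pids.append(par_doc["id"])
            domains.append(
                DomainDef(
                    id=dom_doc["id"],
                    label=dom_doc["label"],
                    lay_label=dom_doc.get("lay_label"),
                    parameter_ids=tuple(pids),
                )
            )
        instruments = tuple(
            InstrumentDef(
                id=i_doc["id"],
                label=i_doc.get("label", i_doc["id"]),
                n_items=i_doc["n_items"],
                item_scales=tuple(tuple(s) for s in i_doc["item_scales"]),
                integer_items=i_doc.get("integer_items", True),
                scoring=i_doc["scoring"],
                scoring_params=i_doc.get("scoring_params", {}),
                output_element_ids=tuple(i_doc["outputs"]),
            )
            for i_doc in doc.get("instruments", [])
        )
        config = RuleConfig(
            config_id=doc["config_id"],
            schema_version=version,
            domains=tuple(domains),
            parameters=tuple(parameters),
            elements=tuple(elements),
            instruments=instruments,
        )
    except KeyError as exc:
        raise ConfigError(f"missing required config key: {exc.args[0]!r}") from exc
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc
    from . import instrument_scoring  # late import: scorer registry lives there

    for inst in config.instruments:
        if inst.scoring not in instrument_scoring.SCORING_PROCEDURES:
            raise ConfigError(f"instrument '{inst.id}': unknown scoring procedure '{inst.scoring}'")
        instrument_scoring.validate_instrument(inst)
    return config


def load_config(path: str) -> RuleConfig:
    """Load and validate a rule config from a YAML (or JSON) file."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return parse_config(doc)


def load_reference_config() -> RuleConfig:
    """Load the packaged reference configuration.

    The reference config declares the 4 domains (body; thinking and feeling;
    behavior; environment) and their 21 parameters with cutoff bands.  Cutoffs
    not fixed by the published decision rules are documented defaults in the
    YAML file and can be replaced without code changes.
    """
    text = resources.files("diag360.data").joinpath("reference_config.yaml").read_text("utf-8")
    return parse_config(yaml.safe_load(text))


def dump_config_yaml(config: RuleConfig) -> str:
    return yaml.safe_dump(config.to_dict(), sort_keys=False, allow_unicode=True)


Number = Union[int, float]


class AssessmentInput(_Frozen):
    """One patient's raw inputs at one timepoint.

    ``clinical_values`` maps element ids (professional-entered measurements)
    to numbers in the units declared by the config; ``item_responses`` maps
    instrument ids to ordered item-response lists in which ``None`` marks an
    unanswered item.  Absent keys mean the whole block was not collected.
    """

    patient_id: str
    timepoint: str
    clinical_values: dict[str, Optional[Union[Number, str]]] = Field(default_factory=dict)
    item_responses: dict[str, tuple[Optional[Number], ...]] = Field(default_factory=dict)

    @field_validator("timepoint")
    @classmethod
    def _iso_date(cls, v: str) -> str:
        import datetime

        datetime.date.fromisoformat(v[:10])
        return v

    def validation_errors(self, config: RuleConfig) -> list[str]:
        """All violations of this record against ``config`` (empty if valid)."""
        errors: list[str] = []
        clinical = set(config.clinical_element_ids)
        for eid, value in self.clinical_values.items():
            try:
                el = config.element(eid)
            except KeyError:
                errors.append(f"clinical_values.{eid}: unknown element")
                continue
            if eid not in clinical:
                errors.append(f"clinical_values.{eid}: element is questionnaire-scored, not clinical")
                continue
            if value is None:
                continue
            if el.kind == "categorical":
                if value not in (el.valid_values or ()):
                    errors.append(
                        f"clinical_values.{eid}: {value!r} not in categories {list(el.valid_values or ())}"
                    )
            else:
                if not isinstance(value, (int, float)) or isinstance(value, bool):
                    errors.append(f"clinical_values.{eid}: expected a number, got {value!r}")
                elif el.range and not (el.range[0] <= value <= el.range[1]):
                    errors.append(
                        f"clinical_values.{eid}: value {value} outside valid range {list(el.range)}"
                    )
        for iid, items in self.item_responses.items():
            try:
                inst = config.instrument(iid)
            except KeyError:
                errors.append(f"item_responses.{iid}: unknown instrument")
                continue
            if len(items) != inst.n_items:
                errors.append(
                    f"item_responses.{iid}: expected {inst.n_items} items, got {len(items)}"
                )
                continue
            for idx, (item, (lo, hi)) in enumerate(zip(items, inst.item_scales)):
                if item is None:
                    continue
                if not isinstance(item, (int, float)) or isinstance(item, bool):
                    errors.append(f"item_responses.{iid}[{idx}]: expected a number, got {item!r}")
                elif not lo <= item <= hi:
                    errors.append(f"item_responses.{iid}[{idx}]: {item} outside scale [{lo}, {hi}]")
                elif inst.integer_items and float(item) != int(item):
                    errors.append(f"item_responses.{iid}[{idx}]: expected an integer, got {item}")
        return errors

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema_id": SCHEMA_ASSESSMENT,
            "schema_version": SCHEMA_VERSION,
            "patient_id": self.patient_id,
            "timepoint": self.timepoint,
            "clinical_values": dict(self.clinical_values),
            "item_responses": {k: list(v) for k, v in self.item_responses.items()},
        }


class ElementStatus(_Frozen):
    value: Union[Number, str]
    status: TrafficStatus


class DiagnosisProfile(_Frozen):
    """Classified result of one assessment: the input to wheel, advice, follow-up.

    ``parameter_status`` covers every parameter of the config (GRAY when
    undetermined); ``element_status`` has entries only for elements whose
    inputs were present.
    """

    patient_id: str
    timepoint: str
    config_id: str
    config_version: int = SCHEMA_VERSION
    element_status: dict[str, ElementStatus] = Field(default_factory=dict)
    parameter_status: dict[str, TrafficStatus] = Field(default_factory=dict)

    def flagged_parameters(self) -> list[str]:
        """Parameter ids with middle- or low-ranking (orange/red) status."""
        return [p for p, s in self.parameter_status.items() if s.needs_improvement]

    def parameters_with_status(self, status: TrafficStatus) -> list[str]:
        return [p for p, s in self.parameter_status.items() if s is status]

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema_id": SCHEMA_PROFILE,
            "schema_version": SCHEMA_VERSION,
            "patient_id": self.patient_id,
            "timepoint": self.timepoint,
            "config_id": self.config_id,
            "config_version": self.config_version,
            "element_status": {
                k: {"value": v.value, "status": v.status.value}
                for k, v in self.element_status.items()
            },
            "parameter_status": {k: v.value for k, v in self.parameter_status.items()},
        }

    @classmethod
    def from_dict(cls, doc: dict[str, Any]) -> "DiagnosisProfile":
        if doc.get("schema_id") != SCHEMA_PROFILE:
            raise InputValidationError([f"schema_id: expected '{SCHEMA_PROFILE}'"])
        if doc.get("schema_version") != SCHEMA_VERSION:
            raise InputValidationError(
                [f"schema_version: unknown version {doc.get('schema_version')!r}"]
            )
        return cls(
            patient_id=doc["patient_id"],
            timepoint=doc["timepoint"],
            config_id=doc["config_id"],
            config_version=doc["config_version"],
            element_status={
                k: ElementStatus(value=v["value"], status=TrafficStatus(v["status"]))
                for k, v in doc["element_status"].items()
            },
            parameter_status={
                k: TrafficStatus(v) for k, v in doc["parameter_status"].items()
            },
        )
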