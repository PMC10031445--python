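"""Intervention catalog loading and matching against a diagnosis profile.

Middle- (orange) and low-ranking (red) parameters identify areas of
improvement; an intervention is offered when it targets at least one such
parameter and is available in the requested context.
"""

from __future__ import annotations

import csv
import io
import json
from importlib import resources
from typing import Iterable, Literal, Optional, Union

from pydantic import ValidationError

from .core_model import DiagnosisProfile, InputValidationError, TrafficStatus, _Frozen

#: The 7 intervention categories.
CATEGORIES = (
    "group_based",
    "events",
    "experts_knowledge_centers",
    "apps",
    "devices",
    "programs",
    "knowledge_platforms",
)

#: The 3 availability classes.
AVAILABILITY_CLASSES = (
    "proximity_to_practice",
    "within_municipality",
    "nationwide_web",
)

Category = Literal[
    "group_based",
    "events",
    "experts_knowledge_centers",
    "apps",
    "devices",
    "programs",
    "knowledge_platforms",
]
Availability = Literal["proximity_to_practice", "within_municipality", "nationwide_web"]


class InterventionEntry(_Frozen):
    id: str
    name: str
    category: Category
    availability: Availability
    target_parameter_ids: tuple[str, ...]
    description: str = ""


class InterventionCatalog(_Frozen):
    entries: tuple[InterventionEntry, ...]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def to_dict(self) -> dict:
        return {
            "schema_id": "diag360.catalog",
            "schema_version": 1,
            "interventions": [
                {
                    "id": e.id,
                    "name": e.name,
                    "category": e.category,
                    "availability": e.availability,
                    "targets": list(e.target_parameter_ids),
                    "description": e.description,
                }
                for e in self.entries
            ],
        }


def _entries_from_rows(rows: Iterable[dict]) -> InterventionCatalog:
    entries = []
    ids = set()
    for row in rows:
        entry_id = row.get("id", "<missing id>")
        try:
            entry = InterventionEntry(
                id=row["id"],
                name=row["name"],
                category=row["category"],
                availability=row["availability"],
                target_parameter_ids=tuple(row.get("targets", ())),
                description=row.get("description", ""),
            )
        except (ValidationError, KeyError) as exc:
            raise InputValidationError([f"catalog entry '{entry_id}': {exc}"]) from exc
        if entry.id in ids:
            raise InputValidationError([f"catalog entry '{entry.id}': duplicate id"])
        ids.add(entry.id)
        entries.append(entry)
    return InterventionCatalog(entries=tuple(entries))


def parse_catalog(doc: Union[dict, list]) -> InterventionCatalog:
    """Parse a catalog JSON document (either a list or ``{"interventions": []}``)."""
    rows = doc.get("interventions", []) if isinstance(doc, dict) else doc
    return _entries_from_rows(rows)


def load_catalog(path: str) -> InterventionCatalog:
    """Load a catalog from JSON or CSV (by extension); an empty file is valid.

    CSV columns: id, name, category, availability, targets (semicolon
    separated), description.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    if path.lower().endswith(".csv"):
        rows = []
        for row in csv.DictReader(io.StringIO(text)):
            row = dict(row)
            row["targets"] = [t for t in (row.get("targets") or "").split(";") if t]
            rows.append(row)
        return _entries_from_rows(rows)
    if not text.strip():
        return InterventionCatalog(entries=())
    return parse_catalog(json.loads(text))


def load_example_catalog() -> InterventionCatalog:
    """The packaged example catalog of 27 category-faithful synthetic entries."""
    text = resources.files("diag360.data").joinpath("interventions.json").read_text("utf-8")
    return parse_catalog(json.loads(text))


def match_interventions(
    profile: DiagnosisProfile,
    catalog: InterventionCatalog,
    context: Optional[Iterable[str]] = None,
) -> list[InterventionEntry]:
    """Interventions that could improve the profile's orange/red parameters.

    Returns catalog entries whose target parameters intersect the profile's
    ORANGE or RED parameters and whose availability class is in ``context``
    (all classes when omitted).  Entries targeting at least one RED parameter
    come first, then ORANGE-only matches; ties keep catalog order.  GREEN and
    GRAY parameters trigger nothing.
    """
    if context is None:
        allowed = set(AVAILABILITY_CLASSES)
    else:
        allowed = set(context)
        unknown = allowed - set(AVAILABILITY_CLASSES)
        if unknown:
            raise InputValidationError(
                [f"unknown availability class(es): {sorted(unknown)}"]
            )
    red = set(profile.parameters_with_status(TrafficStatus.RED))
    orange = set(profile.parameters_with_status(TrafficStatus.ORANGE))
    matched = []
    for index, entry in enumerate(catalog.entries):
        if entry.availability not in allowed:
            continue
        targets = set(entry.target_parameter_ids)
        if targets & red:
            matched.append((0, index, entry))
        elif targets & orange:
            matched.append((1, index, entry))
    matched.sort(key=lambda t: (t[0], t[1]))
    return [entry for _, _, entry in matched]
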