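"""The 15-card motivational-interviewing consultation deck.

The deck structure (titles, order, card kinds, and the step-5 summary fields)
is fixed packaged data; card body texts are placeholder prose keyed to the
titles and meant to be replaced by licensed card content.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from typing import Literal, Optional

from .core_model import ConfigError, DiagnosisProfile, RuleConfig, _Frozen

DECK_SIZE = 15

#: The printed card titles, in deck order.
CARD_TITLES = (
    "title page",
    "content",
    "MI basic attitude",
    "MI core skills 1",
    "MI core skills 2",
    "MI core skills 3",
    "diabetes coaching steps overview",
    "step 1 agenda",
    "step 2 current situation I",
    "step 2 current situation II",
    "step 3 motivation I",
    "step 3 motivation II",
    "step 4 planning I",
    "step 4 planning II",
    "step 5 rounding up",
)

#: Summary recorded on the final (rounding up) card.
STEP5_SUMMARY_FIELDS = (
    "current_situation",
    "goal_parameter",
    "chosen_intervention",
    "backup_plans",
    "resources",
)


class ProtocolCard(_Frozen):
    index: int
    title: str
    kind: Literal["front_matter", "mi_skill", "step"]
    goal: str = ""
    parts: tuple[str, ...] = ()
    examples: tuple[str, ...] = ()
    step_number: Optional[int] = None
    summary_fields: tuple[str, ...] = ()


def _validate_deck(cards: tuple[ProtocolCard, ...]) -> tuple[ProtocolCard, ...]:
    if len(cards) != DECK_SIZE:
        raise ConfigError(f"card deck must have {DECK_SIZE} cards, got {len(cards)}")
    for i, card in enumerate(cards, start=1):
        if card.index != i:
            raise ConfigError(f"card {i}: index {card.index} out of order")
        if card.title != CARD_TITLES[i - 1]:
            raise ConfigError(
                f"card {i}: title {card.title!r} does not match printed title {CARD_TITLES[i - 1]!r}"
            )
        if card.kind in ("mi_skill", "step"):
            if not (card.goal and card.parts and card.examples):
                raise ConfigError(
                    f"card {i} ({card.title!r}): skill/step cards need goal, parts, and examples"
                )
        if card.kind == "step" and not (card.step_number and 1 <= card.step_number <= 5):
            raise ConfigError(f"card {i}: step cards need step_number in 1..5")
    final = cards[-1]
    if tuple(final.summary_fields) != STEP5_SUMMARY_FIELDS:
        raise ConfigError("step 5 card must carry the five summary fields")
    return cards


@lru_cache(maxsize=1)
def get_card_deck() -> tuple[ProtocolCard, ...]:
    """The packaged deck, in printed order.  Idempotent and order-stable."""
    text = resources.files("diag360.data").joinpath("card_deck.json").read_text("utf-8")
    doc = json.loads(text)
    cards = tuple(ProtocolCard(**card) for card in doc["cards"])
    return _validate_deck(cards)


def render_protocol(
    deck: Optional[tuple[ProtocolCard, ...]] = None,
    profile: Optional[DiagnosisProfile] = None,
    config: Optional[RuleConfig] = None,
) -> str:
    """Render the deck as a printable markdown document, one section per card.

    With a ``profile``, the step-1 agenda section embeds the orange/red
    parameters to discuss (or an explicit note that none are flagged).
    """
    deck = deck if deck is not None else get_card_deck()
    _validate_deck(tuple(deck))
    lines = ["# 360-degree diagnosis consultation card deck", ""]
    for card in deck:
        lines.append(f"## Card {card.index}: {card.title}")
        lines.append("")
        if card.kind == "step":
            lines.append(f"*Step {card.step_number}*")
            lines.append("")
        if card.goal:
            lines.append(f"**Goal.** {card.goal}")
            lines.append("")
        if card.parts:
            lines.append("**Parts:**")
            lines.extend(f"- {part}" for part in card.parts)
            lines.append("")
        if card.examples:
            lines.append("**Examples:**")
            lines.extend(f"- {example}" for example in card.examples)
            lines.append("")
        if card.step_number == 1 and card.index == 8 and profile is not None:
            flagged = profile.flagged_parameters()
            lines.append("**Agenda from this profile:**")
            if not flagged:
                lines.append("- No orange or red parameters; all measured scores are green.")
            else:
                for pid in flagged:
                    status = profile.parameter_status[pid].value
                    label = pid
                    if config is not None:
                        try:
                            label = config.parameter(pid).display_label
                        except KeyError:
                            pass
                    lines.append(f"- {label} ({status})")
            lines.append("")
        if card.summary_fields:
            lines.append("**Summary to record:**")
            lines.extend(f"- {field.replace('_', ' ')}: ................" for field in card.summary_fields)
            lines.append("")
    return "\n".join(lines).rstrip() + "\n"
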