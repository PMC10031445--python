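"""Questionnaire scoring: raw item responses -> element-level scores.

Every scorer is a pure function.  A missing required item never yields a
silent number; it yields the explicit :data:`UNAVAILABLE` sentinel, which the
classification layer maps to GRAY.
"""

from __future__ import annotations

import enum
from fractions import Fraction
from typing import Optional, Sequence, Union

from .core_model import ConfigError, InputValidationError, InstrumentDef


class _UnavailableKind(enum.Enum):
    UNAVAILABLE = "unavailable"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "UNAVAILABLE"


#: Sentinel returned when required items are missing ("score unavailable").
UNAVAILABLE = _UnavailableKind.UNAVAILABLE

Number = Union[int, float]
Response = Optional[Number]
ScoreValue = Union[Number, str, _UnavailableKind]

#: Per-occasion glass count at or above which an episode counts as binge
#: drinking (common Dutch heavy-drinking definition; override per instrument
#: via ``scoring_params.binge_threshold``).
DEFAULT_BINGE_THRESHOLD = 6


def _check_items(
    items: Sequence[Response],
    scales: Sequence[tuple[float, float]],
    name: str,
    integer_items: bool = True,
) -> None:
    if len(items) != len(scales):
        raise InputValidationError(
            [f"{name}: expected {len(scales)} items, got {len(items)}"]
        )
    errors = []
    for i, (item, (lo, hi)) in enumerate(zip(items, scales)):
        if item is None:
            continue
        if not isinstance(item, (int, float)) or isinstance(item, bool):
            errors.append(f"{name}[{i}]: expected a number, got {item!r}")
        elif not lo <= item <= hi:
            errors.append(f"{name}[{i}]: {item} outside scale [{lo}, {hi}]")
        elif integer_items and float(item) != int(item):
            errors.append(f"{name}[{i}]: expected an integer, got {item}")
    if errors:
        raise InputValidationError(errors)


def score_who5(items: Sequence[Response]) -> ScoreValue:
    """Well-being index: 4 x (raw sum of the 5 items), yielding 0..100.

    0 means absence of well-being, 100 maximum well-being.  Any missing item
    makes the score unavailable.
    """
    _check_items(items, [(0, 5)] * 5, "who5")
    if any(item is None for item in items):
        return UNAVAILABLE
    return 4 * int(sum(items))  # type: ignore[arg-type]


def score_alcohol(
    responses: Sequence[Response], binge_threshold: int = DEFAULT_BINGE_THRESHOLD
) -> tuple[ScoreValue, ScoreValue]:
    """Frequency-quantity alcohol scoring.

    ``responses`` = [drinks alcohol (0/1), weekday drinking days (0-5),
    glasses per weekday drinking day, weekend drinking days (0-2), glasses per
    weekend day].  Returns ``(average glasses per day, binge flag)``.

    A "no" on the first question routes straight to ``(0, "none")`` without
    requiring the quantity answers.  Binge is flagged when any reported
    drinking occasion reaches ``binge_threshold`` glasses.
    """
    _check_items(responses, [(0, 1), (0, 5), (0, 20), (0, 2), (0, 20)], "alcohol")
    drinks = responses[0]
    if drinks is None:
        return UNAVAILABLE, UNAVAILABLE
    if drinks == 0:
        return 0.0, "none"
    if any(r is None for r in responses[1:]):
        return UNAVAILABLE, UNAVAILABLE
    wd_days, wd_glasses, we_days, we_glasses = responses[1:]
    avg = Fraction(int(wd_days * wd_glasses + we_days * we_glasses), 7)
    binge = (wd_days > 0 and wd_glasses >= binge_threshold) or (
        we_days > 0 and we_glasses >= binge_threshold
    )
    return float(avg), ("present" if binge else "none")


def _score_smoking(items: Sequence[Response], inst: InstrumentDef) -> list[ScoreValue]:
    cigarettes, craving = items
    if cigarettes is None:
        return [UNAVAILABLE, UNAVAILABLE]
    if craving is None:
        # non-smoker routing: no cigarettes means the craving question may be
        # skipped and counts as zero
        craving = 0 if cigarettes == 0 else UNAVAILABLE
    return [cigarettes, craving]


def _score_identity(items: Sequence[Response], inst: InstrumentDef) -> list[ScoreValue]:
    return [UNAVAILABLE if item is None else item for item in items]


def _score_plain_sum(items: Sequence[Response], inst: InstrumentDef) -> list[ScoreValue]:
    if any(item is None for item in items):
        return [UNAVAILABLE]
    return [int(sum(items))]  # type: ignore[arg-type]


def _score_reverse_sum(items: Sequence[Response], inst: InstrumentDef) -> list[ScoreValue]:
    """Sum with positively-worded items reverse-scored on their own scale."""
    if any(item is None for item in items):
        return [UNAVAILABLE]
    reverse = set(inst.scoring_params.get("reverse_items", ()))
    total = 0.0
    for i, item in enumerate(items):
        lo, hi = inst.item_scales[i]
        total += (hi + lo - item) if i in reverse else item  # type: ignore[operator]
    return [int(total) if float(total).is_integer() else total]


def _score_who5(items: Sequence[Response], inst: InstrumentDef) -> list[ScoreValue]:
    return [score_who5(items)]


def _score_alcohol(items: Sequence[Response], inst: InstrumentDef) -> list[ScoreValue]:
    threshold = inst.scoring_params.get("binge_threshold", DEFAULT_BINGE_THRESHOLD)
    return list(score_alcohol(items, binge_threshold=threshold))


def _score_activity_product(items: Sequence[Response], inst: InstrumentDef) -> list[ScoreValue]:
    # absent activity blocks count as 0 minutes
    days, minutes = (0 if item is None else item for item in items)
    return [days * minutes]


def _score_sitting_weekly(items: Sequence[Response], inst: InstrumentDef) -> list[ScoreValue]:
    if any(item is None for item in items):
        return [UNAVAILABLE]
    weekday, weekend = items
    return [(5 * weekday + 2 * weekend) / 7]  # type: ignore[operator]


def _score_dsmq(items: Sequence[Response], inst: InstrumentDef) -> list[ScoreValue]:
    half = len(items) // 2
    out: list[ScoreValue] = []
    for block in (items[:half], items[half:]):
        if any(item is None for item in block):
            out.append(UNAVAILABLE)
        else:
            out.append(int(sum(block)))  # type: ignore[arg-type]
    return out


_SCORERS = {
    "who5": _score_who5,
    "reverse_sum": _score_reverse_sum,
    "plain_sum": _score_plain_sum,
    "identity": _score_identity,
    "alcohol_fq": _score_alcohol,
    "smoking": _score_smoking,
    "activity_product": _score_activity_product,
    "sitting_weekly": _score_sitting_weekly,
    "dsmq_subscales": _score_dsmq,
}

SCORING_PROCEDURES = frozenset(_SCORERS)

# expected output arity per procedure; None = one output per item
_OUTPUT_ARITY = {
    "who5": 1,
    "reverse_sum": 1,
    "plain_sum": 1,
    "identity": None,
    "alcohol_fq": 2,
    "smoking": 2,
    "activity_product": 1,
    "sitting_weekly": 1,
    "dsmq_subscales": 2,
}

_REQUIRED_ITEMS = {"alcohol_fq": 5, "smoking": 2, "activity_product": 2, "sitting_weekly": 2}


def validate_instrument(inst: InstrumentDef) -> None:
    """Structural checks tying an instrument's scoring to its outputs."""
    if inst.scoring not in _SCORERS:
        raise ConfigError(f"instrument '{inst.id}': unknown scoring procedure '{inst.scoring}'")
    arity = _OUTPUT_ARITY[inst.scoring]
    expected = inst.n_items if arity is None else arity
    if len(inst.output_element_ids) != expected:
        raise ConfigError(
            f"instrument '{inst.id}': scoring '{inst.scoring}' produces {expected} "
            f"outputs but {len(inst.output_element_ids)} declared"
        )
    required = _REQUIRED_ITEMS.get(inst.scoring)
    if required is not None and inst.n_items != required:
        raise ConfigError(
            f"instrument '{inst.id}': scoring '{inst.scoring}' requires exactly "
            f"{required} items, got {inst.n_items}"
        )
    if inst.scoring == "dsmq_subscales" and inst.n_items % 2:
        raise ConfigError(f"instrument '{inst.id}': dsmq_subscales needs an even item count")


def score_instrument(
    instrument: Union[str, InstrumentDef],
    responses: Sequence[Response],
    config=None,
) -> dict[str, ScoreValue]:
    """Score one instrument's responses into ``{element_id: score}``.

    ``instrument`` may be an :class:`InstrumentDef` or an instrument id looked
    up in ``config`` (the packaged reference config when omitted).  Raises on
    unknown instruments and malformed responses; missing items map to
    :data:`UNAVAILABLE` per the instrument's own rule.
    """
    if isinstance(instrument, str):
        if config is None:
            from .core_model import load_reference_config

            config = load_reference_config()
        inst = config.instrument(instrument)
    else:
        inst = instrument
    validate_instrument(inst)
    _check_items(responses, inst.item_scales, inst.id, inst.integer_items)
    values = _SCORERS[inst.scoring](list(responses), inst)
    if len(values) != len(inst.output_element_ids):  # pragma: no cover - guarded by validate
        raise ConfigError(f"instrument '{inst.id}': scorer output arity mismatch")
    return dict(zip(inst.output_element_ids, values))
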