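"""Profile-wheel and detail-panel rendering as standalone SVG documents.

The wheel has 4 quadrants of equal size (one per domain) holding at most 6
parameter icons each, filled with the traffic-light color of the parameter's
status.  Each icon links to a per-parameter detail panel showing one colored
cutoff bar per element with the numeric score and a triangle position marker.

Output is deterministic: identical inputs produce byte-identical SVG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union
from xml.etree import ElementTree as ET

from .core_model import (
    DiagnosisProfile,
    ElementDef,
    InputValidationError,
    RuleConfig,
    TrafficStatus,
)

DEFAULT_COLORS = {
    TrafficStatus.GREEN: "#2e7d32",
    TrafficStatus.ORANGE: "#ef6c00",
    TrafficStatus.RED: "#c62828",
    TrafficStatus.GRAY: "#9e9e9e",
}

_QUADRANT_FILLS = ("#eef3f8", "#f3eef8", "#eef8f0", "#f8f3ee")


@dataclass(frozen=True)
class WheelLayout:
    """Geometry and styling of the profile wheel.

    Quadrant order and starting angle are free layout choices; defaults put
    the first domain top-left and proceed clockwise.
    """

    quadrant_order: tuple[str, ...]
    parameters_by_quadrant: dict[str, tuple[str, ...]]
    labels: dict[str, str]
    icons: dict[str, str] = field(default_factory=dict)
    colors: dict[TrafficStatus, str] = field(default_factory=lambda: dict(DEFAULT_COLORS))
    size: int = 640
    ring_radius: float = 200.0
    icon_radius: float = 27.0
    start_angle: float = -90.0
    decimal_separator: str = "."
    max_icons_per_quadrant: int = 6
    custom_symbols: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.quadrant_order) != 4:
            raise InputValidationError(
                [f"wheel layout needs exactly 4 quadrants, got {len(self.quadrant_order)}"]
            )
        for dom in self.quadrant_order:
            params = self.parameters_by_quadrant.get(dom, ())
            if len(params) > self.max_icons_per_quadrant:
                raise InputValidationError(
                    [
                        f"quadrant '{dom}' holds {len(params)} parameters; "
                        f"at most {self.max_icons_per_quadrant} icons fit"
                    ]
                )
            if not params:
                raise InputValidationError([f"quadrant '{dom}' has no parameters"])

    @classmethod
    def from_config(cls, config: RuleConfig, **overrides) -> "WheelLayout":
        labels = {d.id: d.display_label for d in config.domains}
        labels.update({p.id: p.display_label for p in config.parameters})
        return cls(
            quadrant_order=tuple(d.id for d in config.domains),
            parameters_by_quadrant={d.id: d.parameter_ids for d in config.domains},
            labels=labels,
            icons={p.id: p.icon_id for p in config.parameters},
            **overrides,
        )

    @property
    def parameter_ids(self) -> tuple[str, ...]:
        return tuple(p for d in self.quadrant_order for p in self.parameters_by_quadrant[d])


def _fmt(value: Union[int, float, str], separator: str = ".") -> str:
    """One decimal for continuous values, plain integers for counts."""
    if isinstance(value, str):
        return value
    if float(value).is_integer():
        return str(int(value))
    return f"{float(value):.1f}".replace(".", separator)


def _polar(cx: float, cy: float, radius: float, angle_deg: float) -> tuple[float, float]:
    # angle measured clockwise from 12 o'clock (SVG y grows downward)
    rad = math.radians(angle_deg)
    return cx + radius * math.sin(rad), cy - radius * math.cos(rad)


def _round(x: float) -> str:
    return f"{x:.2f}"


def _glyph(parent: ET.Element, icon_id: str, cx: float, cy: float, r: float) -> None:
    """Simple built-in glyph primitives keyed by icon id (white line work)."""
    s = {"fill": "none", "stroke": "#ffffff", "stroke-width": "2.5"}
    k = r * 0.45
    if icon_id == "bp_monitor":
        ET.SubElement(parent, "circle", {"cx": _round(cx), "cy": _round(cy), "r": _round(k), **s})
        ET.SubElement(
            parent,
            "path",
            {"d": f"M {_round(cx)} {_round(cy)} L {_round(cx + k * 0.7)} {_round(cy - k * 0.7)}", **s},
        )
    elif icon_id in ("head_bolts", "flash"):
        d = (
            f"M {_round(cx + k * 0.3)} {_round(cy - k)} L {_round(cx - k * 0.4)} {_round(cy + k * 0.2)} "
            f"L {_round(cx + k * 0.1)} {_round(cy + k * 0.2)} L {_round(cx - k * 0.3)} {_round(cy + k)}"
        )
        ET.SubElement(parent, "path", {"d": d, **s})
    elif icon_id == "glass":
        d = (
            f"M {_round(cx - k)} {_round(cy - k)} L {_round(cx + k)} {_round(cy - k)} "
            f"L {_round(cx)} {_round(cy + k * 0.2)} L {_round(cx)} {_round(cy + k)}"
        )
        ET.SubElement(parent, "path", {"d": d, **s})
    elif icon_id == "runner":
        ET.SubElement(
            parent, "circle", {"cx": _round(cx), "cy": _round(cy - k * 0.8), "r": _round(k * 0.4), **s}
        )
        d = (
            f"M {_round(cx - k)} {_round(cy + k)} L {_round(cx)} {_round(cy - k * 0.2)} "
            f"L {_round(cx + k)} {_round(cy + k * 0.6)}"
        )
        ET.SubElement(parent, "path", {"d": d, **s})
    elif icon_id == "house":
        d = (
            f"M {_round(cx - k)} {_round(cy)} L {_round(cx)} {_round(cy - k)} L {_round(cx + k)} {_round(cy)} "
            f"L {_round(cx + k)} {_round(cy + k)} L {_round(cx - k)} {_round(cy + k)} Z"
        )
        ET.SubElement(parent, "path", {"d": d, **s})
    elif icon_id == "droplet":
        d = (
            f"M {_round(cx)} {_round(cy - k)} C {_round(cx + k)} {_round(cy)} {_round(cx + k * 0.8)} "
            f"{_round(cy + k)} {_round(cx)} {_round(cy + k)} C {_round(cx - k * 0.8)} {_round(cy + k)} "
            f"{_round(cx - k)} {_round(cy)} {_round(cx)} {_round(cy - k)} Z"
        )
        ET.SubElement(parent, "path", {"d": d, **s})
    else:
        # default glyph: small dot
        ET.SubElement(
            parent,
            "circle",
            {"cx": _round(cx), "cy": _round(cy), "r": _round(k * 0.5), "fill": "#ffffff"},
        )


def _svg_root(width: int, height: int) -> ET.Element:
    return ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "xmlns:xlink": "http://www.w3.org/1999/xlink",
            "version": "1.1",
            "width": str(width),
            "height": str(height),
            "viewBox": f"0 0 {width} {height}",
        },
    )


def _serialize(root: ET.Element) -> str:
    return ET.tostring(root, encoding="unicode") + "\n"


def render_wheel(profile: DiagnosisProfile, layout: WheelLayout) -> str:
    """Render the 4-quadrant profile wheel for ``profile`` as an SVG document.

    One icon per parameter, filled with its status color (GRAY when
    undetermined).  Each icon carries stable ``id``/``data-*`` attributes that
    link it to its detail panel.
    """
    layout_params = set(layout.parameter_ids)
    profile_params = set(profile.parameter_status)
    if layout_params != profile_params:
        missing = sorted(layout_params ^ profile_params)
        raise InputValidationError(
            [f"profile and layout parameter sets differ (symmetric difference: {missing})"]
        )
    size = layout.size
    c = size / 2.0
    root = _svg_root(size, size)
    ET.SubElement(root, "title").text = "360-degree diagnosis profile wheel"
    outer = layout.ring_radius + layout.icon_radius + 18
    for qi, domain_id in enumerate(layout.quadrant_order):
        a0 = layout.start_angle + 90.0 * qi
        a1 = a0 + 90.0
        group = ET.SubElement(
            root,
            "g",
            {"class": "quadrant", "id": f"quadrant-{domain_id}", "data-domain": domain_id},
        )
        x0, y0 = _polar(c, c, outer, a0)
        x1, y1 = _polar(c, c, outer, a1)
        path = (
            f"M {_round(c)} {_round(c)} L {_round(x0)} {_round(y0)} "
            f"A {_round(outer)} {_round(outer)} 0 0 1 {_round(x1)} {_round(y1)} Z"
        )
        ET.SubElement(
            group,
            "path",
            {
                "d": path,
                "fill": _QUADRANT_FILLS[qi % 4],
                "stroke": "#ffffff",
                "stroke-width": "3",
            },
        )
        lx, ly = _polar(c, c, outer - 8, (a0 + a1) / 2.0)
        label = ET.SubElement(
            group,
            "text",
            {
                "x": _round(lx),
                "y": _round(ly),
                "text-anchor": "middle",
                "font-family": "sans-serif",
                "font-size": "15",
                "fill": "#444444",
                "class": "domain-label",
            },
        )
        label.text = layout.labels.get(domain_id, domain_id)
        params = layout.parameters_by_quadrant[domain_id]
        for pi, pid in enumerate(params):
            angle = a0 + (pi + 0.5) * 90.0 / len(params)
            px, py = _polar(c, c, layout.ring_radius, angle)
            status = profile.parameter_status[pid]
            icon = ET.SubElement(
                group,
                "g",
                {
                    "class": "param-icon",
                    "id": f"icon-{pid}",
                    "data-parameter": pid,
                    "data-status": status.value,
                    "data-detail": f"detail-{pid}.svg",
                },
            )
            link = ET.SubElement(icon, "a", {"href": f"detail-{pid}.svg"})
            ET.SubElement(
                link,
                "circle",
                {
                    "cx": _round(px),
                    "cy": _round(py),
                    "r": _round(layout.icon_radius),
                    "fill": layout.colors[status],
                    "stroke": "#ffffff",
                    "stroke-width": "2",
                },
            )
            icon_id = layout.icons.get(pid, pid)
            if icon_id in layout.custom_symbols:
                fragment = ET.fromstring(layout.custom_symbols[icon_id])
                fragment.set(
                    "transform",
                    f"translate({_round(px)},{_round(py)})",
                )
                link.append(fragment)
            else:
                _glyph(link, icon_id, px, py, layout.icon_radius)
            title = ET.SubElement(link, "title")
            title.text = layout.labels.get(pid, pid)
    return _serialize(root)


_BAR_X0, _BAR_X1 = 180, 600
_ROW_H = 64


def _element_segments(el: ElementDef) -> list[tuple[float, float, TrafficStatus, str]]:
    """(x0_frac, x1_frac, status, boundary-label) per band along the bar axis."""
    segments = []
    if el.kind == "categorical":
        cats = el.valid_values or ()
        n = len(cats)
        for i, cat in enumerate(cats):
            status = next(b.status for b in el.bands if b.categories and cat in b.categories)
            segments.append((i / n, (i + 1) / n, status, cat))
    else:
        lo, hi = el.range  # type: ignore[misc]
        span = hi - lo
        prev = lo
        for band in el.bands:
            upper = hi if band.max is None else min(band.max, hi)
            segments.append(((prev - lo) / span, (upper - lo) / span, band.status, _fmt(prev)))
            prev = upper
    return segments


def _value_fraction(el: ElementDef, value: Union[int, float, str]) -> float:
    if el.kind == "categorical":
        cats = list(el.valid_values or ())
        return (cats.index(str(value)) + 0.5) / len(cats)
    lo, hi = el.range  # type: ignore[misc]
    return min(1.0, max(0.0, (float(value) - lo) / (hi - lo)))


def render_detail(
    profile: DiagnosisProfile,
    parameter_id: str,
    config: RuleConfig,
    layout: Optional[WheelLayout] = None,
) -> str:
    """Render the click-through detail panel for one parameter.

    One horizontal cutoff bar per element with colored band segments; the
    patient's score appears as a black number and a small black triangle marks
    its position on the bar.  Absent values render the bar with an explicit
    "not answered" annotation and no marker.
    """
    par = config.parameter(parameter_id)  # KeyError on unknown parameter
    colors = (layout.colors if layout else DEFAULT_COLORS)
    separator = layout.decimal_separator if layout else "."
    n = len(par.element_ids)
    height = 70 + _ROW_H * max(n, 1)
    root = _svg_root(660, height)
    heading = ET.SubElement(
        root,
        "text",
        {
            "x": "24",
            "y": "36",
            "font-family": "sans-serif",
            "font-size": "20",
            "font-weight": "bold",
            "fill": "#222222",
            "class": "parameter-title",
        },
    )
    heading.text = par.display_label
    for i, eid in enumerate(par.element_ids):
        el = config.element(eid)
        y = 70 + i * _ROW_H
        row = ET.SubElement(
            root, "g", {"class": "element-row", "id": f"element-{eid}", "data-element": eid}
        )
        label = ET.SubElement(
            row,
            "text",
            {
                "x": "24",
                "y": _round(y + 26),
                "font-family": "sans-serif",
                "font-size": "13",
                "fill": "#333333",
                "class": "element-label",
            },
        )
        label.text = el.display_label + (f" ({el.units})" if el.units else "")
        bar_y = y + 14
        for x0f, x1f, status, boundary in _element_segments(el):
            x0 = _BAR_X0 + x0f * (_BAR_X1 - _BAR_X0)
            x1 = _BAR_X0 + x1f * (_BAR_X1 - _BAR_X0)
            ET.SubElement(
                row,
                "rect",
                {
                    "x": _round(x0),
                    "y": _round(bar_y),
                    "width": _round(x1 - x0),
                    "height": "18",
                    "fill": colors[status],
                    "class": "band-segment",
                    "data-status": status.value,
                },
            )
            tick = ET.SubElement(
                row,
                "text",
                {
                    "x": _round(x0 + (2 if el.kind != "categorical" else (x1 - x0) / 2)),
                    "y": _round(bar_y + 32),
                    "font-family": "sans-serif",
                    "font-size": "10",
                    "fill": "#666666",
                    "class": "band-boundary",
                },
            )
            tick.text = boundary
        entry = profile.element_status.get(eid)
        if entry is None:
            note = ET.SubElement(
                row,
                "text",
                {
                    "x": _round(_BAR_X1 + 8),
                    "y": _round(bar_y + 14),
                    "font-family": "sans-serif",
                    "font-size": "12",
                    "font-style": "italic",
                    "fill": "#777777",
                    "class": "not-answered",
                },
            )
            note.text = "not answered"
        else:
            vx = _BAR_X0 + _value_fraction(el, entry.value) * (_BAR_X1 - _BAR_X0)
            # small black triangle pointing down onto the bar
            tri = (
                f"M {_round(vx)} {_round(bar_y - 2)} L {_round(vx - 6)} {_round(bar_y - 12)} "
                f"L {_round(vx + 6)} {_round(bar_y - 12)} Z"
            )
            ET.SubElement(row, "path", {"d": tri, "fill": "#000000", "class": "value-marker"})
            score = ET.SubElement(
                row,
                "text",
                {
                    "x": _round(_BAR_X1 + 8),
                    "y": _round(bar_y + 14),
                    "font-family": "sans-serif",
                    "font-size": "14",
                    "font-weight": "bold",
                    "fill": "#000000",
                    "class": "value-label",
                },
            )
            score.text = _fmt(entry.value, separator)
    return _serialize(root)


def render_report(
    profile: DiagnosisProfile, config: RuleConfig, layout: Optional[WheelLayout] = None
) -> dict[str, str]:
    """Wheel + all detail panels + an HTML index page, as filename -> content."""
    layout = layout or WheelLayout.from_config(config)
    files = {"wheel.svg": render_wheel(profile, layout)}
    for pid in layout.parameter_ids:
        files[f"detail-{pid}.svg"] = render_detail(profile, pid, config, layout)
    rows = "\n".join(
        f'      <li><a href="detail-{pid}.svg">{layout.labels.get(pid, pid)}</a> '
        f'&mdash; {profile.parameter_status[pid].value}</li>'
        for pid in layout.parameter_ids
    )
    files["index.html"] = (
        "<!DOCTYPE html>\n"
        '<html lang="en">\n'
        "  <head>\n"
        '    <meta charset="utf-8"/>\n'
        f"    <title>360-degree diagnosis — {profile.patient_id} ({profile.timepoint})</title>\n"
        "  </head>\n"
        "  <body>\n"
        f"    <h1>Profile wheel — patient {profile.patient_id}, {profile.timepoint}</h1>\n"
        '    <object data="wheel.svg" type="image/svg+xml" width="640" height="640"></object>\n'
        "    <h2>Details per parameter</h2>\n"
        "    <ul>\n"
        f"{rows}\n"
        "    </ul>\n"
        "  </body>\n"
        "</html>\n"
    )
    return files
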