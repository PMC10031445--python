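from xml.etree import ElementTree as ET

import pytest

from diag360 import (
    AssessmentInput,
    InputValidationError,
    TrafficStatus,
    build_profile,
    parse_config,
    render_detail,
    render_report,
    render_wheel,
)
from diag360.wheel_render import DEFAULT_COLORS, WheelLayout, _fmt

from conftest import make_config_doc


def _icons(svg_text):
    root = ET.fromstring(svg_text)
    return root.findall(".//{http://www.w3.org/2000/svg}g[@class='param-icon']")


def _quadrants(svg_text):
    root = ET.fromstring(svg_text)
    return root.findall(".//{http://www.w3.org/2000/svg}g[@class='quadrant']")


@pytest.fixture()
def full_profile(config, healthy_assessment):
    return build_profile(healthy_assessment, config)


@pytest.fixture()
def gray_profile(config):
    empty = AssessmentInput(patient_id="ghost", timepoint="2024-01-01")
    return build_profile(empty, config)


class TestRenderWheel:
    def test_four_quadrant_groups(self, full_profile, layout):
        svg = render_wheel(full_profile, layout)
        assert len(_quadrants(svg)) == 4

    def test_one_icon_per_parameter(self, full_profile, layout, config):
        svg = render_wheel(full_profile, layout)
        icons = _icons(svg)
        assert len(icons) == 21
        assert {i.get("data-parameter") for i in icons} == set(config.parameter_ids)

    def test_all_gray_profile_renders_all_gray_icons(self, gray_profile, layout):
        svg = render_wheel(gray_profile, layout)
        for icon in _icons(svg):
            assert icon.get("data-status") == "gray"
            circle = icon.find(".//{http://www.w3.org/2000/svg}circle")
            assert circle.get("fill") == DEFAULT_COLORS[TrafficStatus.GRAY]

    def test_color_status_bijection(self, config, layout):
        """Every icon fill is one of the 4 configured colors matching its status."""
        mixed = {
            pid: (TrafficStatus.RED if i % 3 == 0 else TrafficStatus.ORANGE if i % 3 == 1 else TrafficStatus.GREEN)
            for i, pid in enumerate(config.parameter_ids)
        }
        from diag360 import DiagnosisProfile

        profile = DiagnosisProfile(
            patient_id="x",
            timepoint="2024-01-01",
            config_id=config.config_id,
            parameter_status=mixed,
        )
        svg = render_wheel(profile, layout)
        for icon in _icons(svg):
            status = TrafficStatus(icon.get("data-status"))
            assert status is mixed[icon.get("data-parameter")]
            circle = icon.find(".//{http://www.w3.org/2000/svg}circle")
            assert circle.get("fill") == layout.colors[status]

    def test_quadrant_spans_are_equal_90_degrees(self, full_profile, layout):
        import math

        svg = render_wheel(full_profile, layout)
        c = layout.size / 2.0
        spans = []
        for quadrant in _quadrants(svg):
            slice_path = quadrant.find(".//{http://www.w3.org/2000/svg}path")
            tokens = slice_path.get("d").split()
            x0, y0 = float(tokens[4]), float(tokens[5])
            x1, y1 = float(tokens[-3]), float(tokens[-2])
            a0 = math.atan2(y0 - c, x0 - c)
            a1 = math.atan2(y1 - c, x1 - c)
            spans.append(math.degrees((a1 - a0) % (2 * math.pi)))
        assert all(abs(span - 90.0) < 0.1 for span in spans)
        assert abs(sum(spans) - 360.0) < 0.1

    def test_byte_identical_across_runs(self, full_profile, layout):
        assert render_wheel(full_profile, layout) == render_wheel(full_profile, layout)

    def test_seven_parameters_in_a_quadrant_rejected(self, config):
        doc = make_config_doc(6)
        cfg = parse_config(doc)
        layout6 = WheelLayout.from_config(cfg)
        # force an oversized quadrant directly on the layout
        params = dict(layout6.parameters_by_quadrant)
        params["d1"] = params["d1"] + ("extra",)
        with pytest.raises(InputValidationError, match="at most 6"):
            WheelLayout(
                quadrant_order=layout6.quadrant_order,
                parameters_by_quadrant=params,
                labels=layout6.labels,
            )

    def test_profile_layout_mismatch_rejected(self, full_profile, config):
        cfg = parse_config(make_config_doc(2))
        other_layout = WheelLayout.from_config(cfg)
        with pytest.raises(InputValidationError, match="differ"):
            render_wheel(full_profile, other_layout)

    def test_lay_labels_used_in_svg_text(self, full_profile, layout, config):
        # plain-language labels: the tool says "blood sugar", not "glucose"
        assert config.parameter("glucose_metabolism").display_label == "blood sugar"
        svg = render_wheel(full_profile, layout)
        assert "blood sugar" in svg
        assert ">glucose<" not in svg

    def test_icons_carry_detail_linkage(self, full_profile, layout):
        svg = render_wheel(full_profile, layout)
        for icon in _icons(svg):
            pid = icon.get("data-parameter")
            assert icon.get("id") == f"icon-{pid}"
            assert icon.get("data-detail") == f"detail-{pid}.svg"

    def test_custom_symbol_injection(self, full_profile, config):
        layout = WheelLayout.from_config(
            config,
            custom_symbols={"bp_monitor": '<rect x="-5" y="-5" width="10" height="10" fill="#fff"/>'},
        )
        svg = render_wheel(full_profile, layout)
        root = ET.fromstring(svg)
        icon = root.find(".//{http://www.w3.org/2000/svg}g[@id='icon-blood_pressure']")
        assert icon.find(".//{http://www.w3.org/2000/svg}rect") is not None


class TestRenderDetail:
    def test_blood_pressure_two_bars_markers_in_orange(self, config, healthy_assessment):
        values = dict(healthy_assessment.clinical_values)
        values.update(systolic=150, diastolic=95)
        profile = build_profile(
            healthy_assessment.model_copy(update={"clinical_values": values}), config
        )
        svg = render_detail(profile, "blood_pressure", config)
        root = ET.fromstring(svg)
        rows = root.findall(".//{http://www.w3.org/2000/svg}g[@class='element-row']")
        assert len(rows) == 2
        for row in rows:
            marker = row.find(".//{http://www.w3.org/2000/svg}path[@class='value-marker']")
            assert marker is not None
            # marker x must fall inside the orange segment of that row's bar
            orange = [
                seg
                for seg in row.findall(".//{http://www.w3.org/2000/svg}rect")
                if seg.get("data-status") == "orange"
            ]
            assert len(orange) == 1
            x0 = float(orange[0].get("x"))
            x1 = x0 + float(orange[0].get("width"))
            marker_x = float(marker.get("d").split()[1])
            assert x0 <= marker_x <= x1

    def test_single_element_parameter_one_bar(self, config, healthy_assessment):
        profile = build_profile(healthy_assessment, config)
        svg = render_detail(profile, "perceived_stress", config)
        root = ET.fromstring(svg)
        rows = root.findall(".//{http://www.w3.org/2000/svg}g[@class='element-row']")
        assert len(rows) == 1

    def test_missing_element_annotated_without_marker(self, config, healthy_assessment):
        items = {k: v for k, v in healthy_assessment.item_responses.items() if k != "who5"}
        profile = build_profile(
            healthy_assessment.model_copy(update={"item_responses": items}), config
        )
        svg = render_detail(profile, "mental_health", config)
        root = ET.fromstring(svg)
        assert root.find(".//{http://www.w3.org/2000/svg}path[@class='value-marker']") is None
        note = root.find(".//{http://www.w3.org/2000/svg}text[@class='not-answered']")
        assert note is not None and note.text == "not answered"

    def test_value_label_matches_formatted_score(self, config, healthy_assessment):
        profile = build_profile(healthy_assessment, config)
        svg = render_detail(profile, "mental_health", config)
        root = ET.fromstring(svg)
        label = root.find(".//{http://www.w3.org/2000/svg}text[@class='value-label']")
        assert label.text == str(profile.element_status["who5_score"].value)

    def test_unknown_parameter_rejected(self, config, healthy_assessment):
        profile = build_profile(healthy_assessment, config)
        with pytest.raises(KeyError):
            render_detail(profile, "no_such_parameter", config)

    def test_every_parameter_has_a_detail_view(self, config, healthy_assessment):
        profile = build_profile(healthy_assessment, config)
        for pid in config.parameter_ids:
            svg = render_detail(profile, pid, config)
            assert svg.startswith("<svg")


class TestRenderReport:
    def test_report_bundles_wheel_details_index(self, config, healthy_assessment):
        profile = build_profile(healthy_assessment, config)
        files = render_report(profile, config)
        assert "wheel.svg" in files and "index.html" in files
        assert sum(1 for name in files if name.startswith("detail-")) == 21

    def test_report_deterministic(self, config, healthy_assessment):
        profile = build_profile(healthy_assessment, config)
        assert render_report(profile, config) == render_report(profile, config)


class TestNumberFormatting:
    @pytest.mark.parametrize(
        "value,expected",
        [(3, "3"), (3.0, "3"), (3.25, "3.2"), (11.428571, "11.4"), ("A2", "A2")],
    )
    def test_fmt(self, value, expected):
        assert _fmt(value) == expected

    def test_locale_separator(self):
        assert _fmt(3.25, separator=",") == "3,2"
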