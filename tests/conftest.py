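import pytest

from diag360 import AssessmentInput, load_reference_config
from diag360.wheel_render import WheelLayout


@pytest.fixture(scope="session")
def config():
    return load_reference_config()


@pytest.fixture(scope="session")
def layout(config):
    return WheelLayout.from_config(config)


HEALTHY_CLINICAL = {
    "hba1c": 48,
    "fasting_glucose": 6.0,
    "glucose_2h": 7.5,
    "systolic": 125,
    "diastolic": 80,
    "hdl": 1.5,
    "ldl": 2.0,
    "total_cholesterol": 4.5,
    "cholesterol_ratio": 3.0,
    "triglycerides": 1.2,
    "bmi": 23,
    "waist_circumference": 85,
    "waist_hip_ratio": 0.85,
    "egfr": 90,
    "albuminuria_stage": "A1",
}

HEALTHY_ITEMS = {
    "who5": [4, 4, 4, 4, 4],
    "pss": [0, 0, 0, 4, 4, 0, 4, 4, 0, 0],
    "paid5": [0, 1, 0, 1, 0],
    "perceived_health": [2],
    "pain": [1],
    "alcohol": [1, 2, 1, 1, 2],
    "smoking": [0, 0],
    "eating": [2, 3, 0, 0, 0],
    "squash_activity": [5, 60],
    "sedentary": [6.0, 7.0],
    "dsmq": [3, 3, 2, 3, 2, 3],
    "env_items": [0, 1, 0, 1, 0, 1, 0],
}


@pytest.fixture()
def healthy_assessment():
    """Fully answered record in which every value sits in a green band."""
    return AssessmentInput(
        patient_id="healthy-1",
        timepoint="2024-03-01",
        clinical_values=dict(HEALTHY_CLINICAL),
        item_responses={k: tuple(v) for k, v in HEALTHY_ITEMS.items()},
    )


def make_config_doc(largest_domain_size: int) -> dict:
    """Minimal 4-domain config document whose first domain has ``k`` parameters."""

    def param(domain, i):
        return {
            "id": f"{domain}_p{i}",
            "label": f"{domain} parameter {i}",
            "icon": "dot",
            "elements": [
                {
                    "id": f"{domain}_p{i}_e",
                    "label": f"{domain} element {i}",
                    "kind": "numeric",
                    "units": "u",
                    "range": [0, 100],
                    "bands": [
                        {"max": 40, "status": "green"},
                        {"max": 70, "status": "orange"},
                        {"status": "red"},
                    ],
                }
            ],
        }

    domains = [
        {
            "id": "d1",
            "label": "D1",
            "parameters": [param("d1", i) for i in range(largest_domain_size)],
        }
    ]
    for d in ("d2", "d3", "d4"):
        domains.append({"id": d, "label": d.upper(), "parameters": [param(d, 0)]})
    return {
        "schema_id": "diag360.rule_config",
        "schema_version": 1,
        "config_id": f"test-k{largest_domain_size}",
        "domains": domains,
        "instruments": [],
    }
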