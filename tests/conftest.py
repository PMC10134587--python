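import pytest
from hypothesis import settings

from kbcdss import SimulationConfig, generate_mock_kb
from kbcdss.kb import (
    AssessmentItem,
    Diagnosis,
    DiagnosisElement,
    DxType,
    ElementType,
    KnowledgeBase,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def mock_kb(config):
    return generate_mock_kb(config)


def make_tiny_kb(n_dx: int = 2, n_dc: int = 4, risk_last: bool = False) -> KnowledgeBase:
    """Hand-built minimal KB: n_dx diagnoses with n_dc evidence elements each,
    two assessment items."""
    items = [
        AssessmentItem(item_id="AI-001", aspect="physical", label="item one"),
        AssessmentItem(item_id="AI-002", aspect="psychological", label="item two"),
    ]
    diagnoses = []
    for i in range(n_dx):
        code = f"DX-{i + 1:03d}"
        is_risk = risk_last and i == n_dx - 1
        etype = ElementType.RISK_FACTOR if is_risk else ElementType.DEFINING_CHARACTERISTIC
        tag = "RF" if is_risk else "DC"
        elements = tuple(
            DiagnosisElement(element_id=f"{code}-{tag}-{j + 1:02d}", element_type=etype)
            for j in range(n_dc)
        )
        diagnoses.append(
            Diagnosis(
                dx_code=code,
                label=f"diagnosis {i + 1}",
                dx_type=DxType.RISK if is_risk else DxType.ACTUAL,
                elements=elements,
            )
        )
    return KnowledgeBase(diagnoses=diagnoses, assessment_items=items)


@pytest.fixture
def tiny_kb():
    return make_tiny_kb()
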