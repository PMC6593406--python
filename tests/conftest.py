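import pytest
from hypothesis import HealthCheck, settings

from abscreen.panels import PanelMember, PanelSet, ProteinPanel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def tiny_panel_set() -> PanelSet:
    """One target panel plus two single-member reference panels."""
    return PanelSet([
        ProteinPanel(
            "rbcL", "target", "CBB",
            [PanelMember("rbcL_1", "MKVADEWQRNSTLYHGFCIP" * 3, ("4.1.1.39",))],
        ),
        ProteinPanel(
            "refA", "reference", "TCA reference",
            [PanelMember("refA_1", "GHIKLMNPQRSTVWYACDEF" * 3)],
        ),
        ProteinPanel(
            "refB", "reference", "TCA reference",
            [PanelMember("refB_1", "PQRSTVWYACDEFGHIKLMN" * 3)],
        ),
    ])
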