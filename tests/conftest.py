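import numpy as np
import pytest

from soyco2 import FvCBParams, StudyConfig
from soyco2.simulate import generate_study


@pytest.fixture(scope="session")
def canonical_params() -> FvCBParams:
    """A representative C3 leaf at 25 °C."""
    return FvCBParams(vcmax=100.0, j=150.0, rd=1.5)


@pytest.fixture(scope="session")
def small_study():
    """A scaled-down synthetic study (3 treatments x 2 pots, 4 fields per
    surface) for fast structural tests."""
    cfg = StudyConfig(
        treatments=(400, 800, 1600),
        pots_per_treatment=2,
        fields_per_surface=4,
        seed=7,
    )
    return cfg, generate_study(cfg)


@pytest.fixture(scope="session")
def default_study():
    """The full-design study (7 treatments x 5 pots) at seed 1."""
    return generate_study(StudyConfig(seed=1))
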